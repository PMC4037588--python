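"""Peptide-to-protein rollup by robust linear regression.

A protein's peptides should share one labeled/unlabeled ratio, but single
peptides are routinely corrupted (co-eluting interference, weak signal).
Instead of iteratively discarding outliers, the rollup fits

    heavy_i = beta * light_i        (through the origin)

by iteratively reweighted least squares with the Huber psi function
(tuning constant 1.345, scale = median absolute residual rescaled by
1.4826), so outlier peptides are down-weighted but never removed.  The
slope beta is the protein ratio.  Proteins need at least two unique
peptides — distinct core sequences, ignoring 18O modification state and
charge — to be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Peptide
from .cluster import LabelState

__all__ = [
    "PeptideQuantRecord",
    "ProteinQuantResult",
    "count_unique_peptides",
    "fit_protein_ratio",
    "huber_slope",
    "exclude_records",
    "summarize_run",
    "HUBER_C",
    "MAD_SCALE",
]

HUBER_C = 1.345
MAD_SCALE = 1.4826
_MAX_ITER = 200
_REL_TOL = 1e-8


@dataclass
class PeptideQuantRecord:
    """One quantified peptide observation assigned to a protein group."""

    protein_acc: str
    peptide: Peptide
    charge: int
    label_state: LabelState
    light: float
    heavy: float
    ratio: float | None
    n_scans: int
    scan_range: tuple[int, int]
    flags: set[str] = field(default_factory=set)
    excluded: bool = False
    audit: str = ""
    observations: list = field(default_factory=list, repr=False)

    @property
    def log2_ratio(self) -> float | None:
        if self.ratio is None or self.ratio <= 0:
            return None
        return float(np.log2(self.ratio))


@dataclass
class ProteinQuantResult:
    """Robust-fit protein ratio with per-peptide weights and status."""

    protein_acc: str
    ratio: float | None
    log2_ratio: float | None
    robust_scale: float | None
    n_peptides_used: int
    n_unique_peptides: int
    peptide_weights: tuple[float, ...]
    status: str  # quantified | insufficient_peptides | fit_failed
    records: list[PeptideQuantRecord] = field(default_factory=list, repr=False)


def count_unique_peptides(records: list[PeptideQuantRecord]) -> int:
    """Distinct core sequences, ignoring modification state and charge."""
    return len({r.peptide.sequence for r in records})


def huber_slope(
    light: np.ndarray, heavy: np.ndarray
) -> tuple[float, np.ndarray, float, bool]:
    """IRLS Huber M-estimate of the through-origin slope heavy = beta*light.

    Returns (beta, final weights, final scale, converged).  Scale is the
    MAD of the residuals about zero rescaled by 1.4826; when the scale
    collapses (an exact fit for the majority of points) residual-free
    points keep weight one and all others drop to zero, which is the Huber
    weight limit as the scale tends to zero.
    """
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    denom = float(np.sum(light * light))
    if denom <= 0:
        raise ZeroDivisionError("all light abundances are zero")
    beta = float(np.sum(light * heavy)) / denom
    w = np.ones_like(light)
    scale = 0.0
    tiny = 1e-10 * max(float(np.max(np.abs(heavy), initial=0.0)), 1.0)
    for _ in range(_MAX_ITER):
        r = heavy - beta * light
        scale = MAD_SCALE * float(np.median(np.abs(r)))
        if scale < tiny:
            w = (np.abs(r) <= tiny).astype(float)
        else:
            with np.errstate(divide="ignore"):
                w = np.minimum(1.0, HUBER_C * scale / np.abs(r))
            w[r == 0] = 1.0
        wden = float(np.sum(w * light * light))
        if wden <= 0:
            return beta, w, scale, False
        beta_new = float(np.sum(w * light * heavy)) / wden
        if abs(beta_new - beta) <= _REL_TOL * max(abs(beta), 1e-300):
            return beta_new, w, scale, True
        beta = beta_new
    return beta, w, scale, False


def fit_protein_ratio(
    records: list[PeptideQuantRecord], min_unique_peptides: int = 2
) -> ProteinQuantResult:
    """Fit one protein's ratio from its non-excluded peptide records.

    Records with no light signal cannot anchor the regression and are left
    out of the fit; the unique-peptide filter is applied to the usable
    records.  Deterministic: no randomness anywhere in the fit.
    """
    acc = records[0].protein_acc if records else ""
    usable = [
        r for r in records if not r.excluded and r.light > 0 and r.heavy >= 0
    ]
    n_unique = count_unique_peptides(usable)
    if n_unique < min_unique_peptides:
        return ProteinQuantResult(
            protein_acc=acc,
            ratio=None,
            log2_ratio=None,
            robust_scale=None,
            n_peptides_used=0,
            n_unique_peptides=n_unique,
            peptide_weights=(),
            status="insufficient_peptides",
            records=records,
        )
    light = np.array([r.light for r in usable])
    heavy = np.array([r.heavy for r in usable])
    try:
        beta, w, scale, converged = huber_slope(light, heavy)
    except ZeroDivisionError:
        beta, w, scale, converged = float("nan"), np.zeros(len(usable)), 0.0, False
    if not converged or not np.isfinite(beta) or beta < 0:
        return ProteinQuantResult(
            protein_acc=acc,
            ratio=None,
            log2_ratio=None,
            robust_scale=float(scale),
            n_peptides_used=len(usable),
            n_unique_peptides=n_unique,
            peptide_weights=tuple(float(x) for x in w),
            status="fit_failed",
            records=records,
        )
    return ProteinQuantResult(
        protein_acc=acc,
        ratio=beta,
        log2_ratio=float(np.log2(beta)) if beta > 0 else None,
        robust_scale=float(scale),
        n_peptides_used=len(usable),
        n_unique_peptides=n_unique,
        peptide_weights=tuple(float(x) for x in w),
        status="quantified",
        records=records,
    )


def exclude_records(
    records: list[PeptideQuantRecord],
    sequence: str | None = None,
    charge: int | None = None,
    scan: int | None = None,
    reason: str = "manual exclusion",
) -> int:
    """Mark matching records excluded (with an audit note); returns count.

    Matching is by core sequence and optionally charge and/or the PSM scan
    falling inside the record's scan range.  A selector matching nothing is
    a warning condition for the caller, not an error.
    """
    n = 0
    for r in records:
        if sequence is not None and r.peptide.sequence != sequence:
            continue
        if charge is not None and r.charge != charge:
            continue
        if scan is not None and not (r.scan_range[0] <= scan <= r.scan_range[1]):
            continue
        if not r.excluded:
            r.excluded = True
            r.audit = reason
            n += 1
    return n


def summarize_run(
    proteins: list[ProteinQuantResult],
    peptide_records: list[PeptideQuantRecord] | None = None,
) -> dict:
    """Run-level summary: log2-ratio mean/SD over quantified proteins, counts."""
    quantified = [p for p in proteins if p.status == "quantified" and p.ratio]
    log2 = np.array([p.log2_ratio for p in quantified], dtype=float)
    summary = {
        "n_proteins": len(proteins),
        "n_proteins_quantified": len(quantified),
        "n_unique2_proteins": sum(1 for p in proteins if p.n_unique_peptides >= 2),
        "mean_log2_ratio": float(np.mean(log2)) if len(log2) else None,
        "sd_log2_ratio": float(np.std(log2, ddof=1)) if len(log2) > 1 else None,
        "mean_ratio": float(np.mean([p.ratio for p in quantified]))
        if quantified
        else None,
    }
    if peptide_records is not None:
        summary["n_peptide_records"] = len(peptide_records)
        summary["n_peptides_quantified"] = sum(
            1 for r in peptide_records if r.ratio is not None and not r.excluded
        )
    return summary
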