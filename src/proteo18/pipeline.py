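"""End-to-end quantification: PSMs + MS1 scans -> peptide and protein ratios.

This wires the modules together: predict the six-channel cluster for each
PSM, extract it across the elution profile, deconvolve into form abundances,
purity-correct into light/heavy, and roll peptides up to protein ratios.
Validation edits (per-peptide scan-range restrictions and exclusions) are
applied here so that re-quantification after manual review reuses exactly
the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import isotope_distribution, parse_peptide, peptide_composition
from .cluster import (
    Scan,
    collect_observations,
    predict_cluster,
    restrict_scan_range,
    sum_observed_vector,
)
from .io import Config, PsmRecord
from .protein import (
    PeptideQuantRecord,
    ProteinQuantResult,
    exclude_records,
    fit_protein_ratio,
    summarize_run,
)
from .quant import (
    TheoreticalVector,
    build_design_matrix,
    peptide_ratio,
    solve_abundances,
    split_light_heavy,
)

__all__ = ["ScanRestriction", "Exclusion", "Edits", "QuantifyResult", "quantify_run"]


@dataclass(frozen=True)
class ScanRestriction:
    """Recompute a peptide from a scan sub-window (manual validation)."""

    sequence: str
    first: int
    last: int
    charge: int | None = None


@dataclass(frozen=True)
class Exclusion:
    """Drop a peptide from protein fitting (manual validation)."""

    sequence: str
    charge: int | None = None
    reason: str = "manual exclusion"


@dataclass
class Edits:
    restrictions: list[ScanRestriction] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)

    def validate(self, known_sequences: set[str]) -> None:
        """Reject edits naming unknown peptides or conflicting duplicates."""
        seen: set[tuple[str, int | None]] = set()
        for i, r in enumerate(self.restrictions, start=1):
            if r.sequence not in known_sequences:
                raise ValueError(
                    f"restriction {i}: unknown peptide sequence {r.sequence!r}"
                )
            key = (r.sequence, r.charge)
            if key in seen:
                raise ValueError(
                    f"restriction {i}: duplicate edit for peptide {r.sequence!r}"
                )
            seen.add(key)
        for i, e in enumerate(self.exclusions, start=1):
            if e.sequence not in known_sequences:
                raise ValueError(
                    f"exclusion {i}: unknown peptide sequence {e.sequence!r}"
                )

    def restriction_for(self, sequence: str, charge: int) -> ScanRestriction | None:
        for r in self.restrictions:
            if r.sequence == sequence and r.charge in (None, charge):
                return r
        return None


@dataclass
class QuantifyResult:
    peptide_records: list[PeptideQuantRecord]
    proteins: list[ProteinQuantResult]
    summary: dict


def quantify_run(
    scans: list[Scan],
    psms: list[PsmRecord],
    config: Config,
    edits: Edits | None = None,
) -> QuantifyResult:
    """Quantify every PSM and roll up to protein ratios.

    PSMs listing several protein accessions contribute a record to every
    group, flagged ``shared``.  Per-peptide failure modes are encoded as
    flags (``weak_evidence``, ``no_light_signal``, ``zero_observed``,
    ``purity_overcorrection``), never as silent drops.
    """
    if not psms:
        raise ValueError("no PSMs")
    records: list[PeptideQuantRecord] = []
    if edits is not None:
        edits.validate({parse_peptide(p.sequence).sequence for p in psms})
    for psm in psms:
        peptide = parse_peptide(psm.sequence)
        comp = peptide_composition(peptide, fixed_mods=config.fixed_mods)
        v = isotope_distribution(comp, 6).abundances
        cluster = predict_cluster(psm.observed_mz, psm.charge, psm.label_state)
        obs = collect_observations(
            scans,
            psm.scan_number,
            cluster,
            tol_ppm=config.tol_ppm,
            min_fraction=config.charge_evidence_min_fraction,
            mode=config.match_mode,
            gap_tolerance=config.gap_tolerance,
        )
        flags: set[str] = set()
        if len(obs) == 1 and not (
            obs[0].charge_evidence_16O or obs[0].charge_evidence_18O2
        ):
            flags.add("weak_evidence")
        if edits is not None:
            r = edits.restriction_for(peptide.sequence, psm.charge)
            if r is not None:
                obs = restrict_scan_range(obs, r.first, r.last)
        y = sum_observed_vector(obs)
        x = build_design_matrix(TheoreticalVector(v=v))
        a = solve_abundances(x, y)
        ch = split_light_heavy(a, config.purity_p)
        flags |= set(ch.flags)
        ratio = peptide_ratio(ch)
        if ratio is None:
            flags.add("no_light_signal")
        elif config.ratio_orientation == "light_over_heavy" and ratio > 0:
            ratio = 1.0 / ratio
        if len(psm.protein_accs) > 1:
            flags.add("shared")
        for acc in psm.protein_accs:
            records.append(
                PeptideQuantRecord(
                    protein_acc=acc,
                    peptide=peptide,
                    charge=psm.charge,
                    label_state=psm.label_state,
                    light=ch.light,
                    heavy=ch.heavy,
                    ratio=ratio,
                    n_scans=y.n_scans,
                    scan_range=y.scan_range,
                    flags=set(flags),
                    observations=obs,
                )
            )
    if edits is not None:
        for e in edits.exclusions:
            exclude_records(records, sequence=e.sequence, charge=e.charge, reason=e.reason)
    groups: dict[str, list[PeptideQuantRecord]] = {}
    for r in records:
        groups.setdefault(r.protein_acc, []).append(r)
    proteins = [
        fit_protein_ratio(groups[acc], min_unique_peptides=config.min_unique_peptides)
        for acc in sorted(groups)
    ]
    return QuantifyResult(
        peptide_records=records,
        proteins=proteins,
        summary=summarize_run(proteins, records),
    )
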