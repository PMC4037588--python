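"""Synthetic 16O/18O-labeled LC-MS runs with known ground truth.

The forward model mirrors the quantification model's generative assumptions:
each peptide elutes as a Gaussian profile over MS1 scans; the light sample
lays down the natural isotope pattern at the 16O channel ladder; the heavy
sample (intensity ratio x light) distributes over 0/1/2 incorporated labels
by the binomial purity model, each copy of the natural pattern shifted by
0, d, or 2d; multiplicative log-normal noise perturbs every peak; optional
interference peaks emulate a co-eluting species landing inside a channel's
matching tolerance.  Contributions whose exact positions differ by less
than an Orbitrap-width (2x13C vs one 18O, 2.5 mDa) land on the same channel
ladder position, as they would merge into one centroid on the instrument.

Output is an mzML run, a PSM table, and a ground-truth CSV, byte-identical
for identical specs (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (
    C13_MASS_SHIFT,
    DEFAULT_FIXED_MODS,
    O18_MASS_SHIFT,
    isotope_distribution,
    monoisotopic_mz,
    parse_peptide,
    peptide_composition,
)
from .cluster import LabelState, Scan
from .io import PsmRecord, write_mzml, write_psm_table
from .quant import purity_fractions

__all__ = [
    "ProteinSpec",
    "Interference",
    "SimSpec",
    "SimulatedRun",
    "simulate_run",
    "make_acceptance_suite",
    "packaged_tryptic_peptides",
]

_N_LADDER = 8  # six cluster channels plus two natural-tail positions


@dataclass(frozen=True)
class ProteinSpec:
    accession: str
    true_ratio: float
    peptides: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        if not self.peptides:
            raise ValueError(f"protein {self.accession} has no peptides")


@dataclass(frozen=True)
class Interference:
    """A spurious peak present verbatim over a scan range."""

    mz: float
    intensity: float
    first_scan: int
    last_scan: int


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated run."""

    proteins: tuple[ProteinSpec, ...]
    purity_p: float = 0.95
    charges: dict[str, int] = field(default_factory=dict)
    apex_scan: int = 10
    width_scans: float = 2.0
    n_scans: int = 19
    base_intensity: float = 1e6
    noise_cv: float = 0.1
    min_peak_intensity: float = 50.0
    interference: tuple[Interference, ...] = ()
    label_states: dict[str, str] = field(default_factory=dict)
    fixed_mods: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIXED_MODS.items()}
    )
    default_charge: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 < self.purity_p <= 1.0:
            raise ValueError("purity_p must lie in (0, 1]")


@dataclass(frozen=True)
class SimulatedRun:
    mzml_path: Path
    psm_path: Path
    truth_path: Path
    truth: pd.DataFrame


def packaged_tryptic_peptides() -> list[str]:
    """The packaged pool of tryptic sequences (K/R C-termini)."""
    text = (resources.files("proteo18") / "data" / "tryptic_peptides.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _ladder(m16: float, z: int) -> np.ndarray:
    """Channel ladder: the six cluster channels then further +c/z steps."""
    d_z, c_z = O18_MASS_SHIFT / z, C13_MASS_SHIFT / z
    base = [m16, m16 + c_z, m16 + d_z, m16 + d_z + c_z, m16 + 2 * d_z, m16 + 2 * d_z + c_z]
    while len(base) < _N_LADDER:
        base.append(base[-1] + c_z)
    return np.asarray(base)


def _channel_intensities(
    v: np.ndarray, light: float, heavy: float, p: float
) -> np.ndarray:
    """Noise-free per-ladder-position intensity for one peptide.

    Light contributes its natural pattern at offset 0; the heavy sample's
    0/1/2-label fractions contribute the same pattern at offsets 0, +2, +4
    ladder positions (one 18O label spans two 13C spacings).
    """
    f0, f1, f2 = purity_fractions(p)
    out = np.zeros(_N_LADDER)
    n = min(len(v), _N_LADDER)
    out[:n] += (light + heavy * f0) * v[:n]
    out[2 : 2 + n][: _N_LADDER - 2] += heavy * f1 * v[: _N_LADDER - 2]
    out[4 : 4 + n][: _N_LADDER - 4] += heavy * f2 * v[: _N_LADDER - 4]
    return out


def simulate_run(
    spec: SimSpec, outdir: str | Path, run_id: str = "sim"
) -> SimulatedRun:
    """Write mzML + PSM table + ground-truth CSV for the given spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    sigma_ln = float(np.sqrt(np.log1p(spec.noise_cv**2)))

    peptide_rows = []
    for prot in spec.proteins:
        for seq in prot.peptides:
            pep = parse_peptide(seq)
            z = spec.charges.get(pep.sequence, spec.default_charge)
            comp = peptide_composition(pep, fixed_mods=spec.fixed_mods)
            v = np.asarray(isotope_distribution(comp, _N_LADDER).abundances)
            m16 = monoisotopic_mz(comp, z)
            state = LabelState(
                spec.label_states.get(
                    pep.sequence,
                    "modified" if (len(peptide_rows) % 2 == 0) else "unmodified",
                )
            )
            light = spec.base_intensity * rng.uniform(0.5, 2.0)
            heavy = prot.true_ratio * light
            peptide_rows.append(
                {
                    "accession": prot.accession,
                    "peptide": pep,
                    "charge": z,
                    "state": state,
                    "v": v,
                    "ladder": _ladder(m16, z),
                    "m16": m16,
                    "light": light,
                    "heavy": heavy,
                    "true_ratio": prot.true_ratio,
                }
            )

    scans: list[Scan] = []
    weights = np.exp(
        -((np.arange(1, spec.n_scans + 1) - spec.apex_scan) ** 2)
        / (2.0 * spec.width_scans**2)
    )
    for k in range(1, spec.n_scans + 1):
        w = weights[k - 1]
        mzs: list[float] = []
        intens: list[float] = []
        for row in peptide_rows:
            channels = _channel_intensities(
                row["v"], row["light"] * w, row["heavy"] * w, spec.purity_p
            )
            if spec.noise_cv > 0:
                noise = rng.lognormal(
                    mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=_N_LADDER
                )
                channels = channels * noise
            keep = channels >= spec.min_peak_intensity
            mzs.extend(row["ladder"][keep])
            intens.extend(channels[keep])
        for spike in spec.interference:
            if spike.first_scan <= k <= spike.last_scan:
                mzs.append(spike.mz)
                intens.append(spike.intensity)
        mz_arr = np.asarray(mzs)
        int_arr = np.asarray(intens)
        order = np.argsort(mz_arr, kind="stable")
        scans.append(
            Scan(
                scan_number=k,
                retention_time=float(k),
                mz=mz_arr[order],
                intensity=int_arr[order],
                ms_level=1,
            )
        )

    psms: list[PsmRecord] = []
    truth_rows = []
    for row in peptide_rows:
        z = row["charge"]
        observed = (
            row["m16"] + 2.0 * O18_MASS_SHIFT / z
            if row["state"] is LabelState.MODIFIED
            else row["m16"]
        )
        psms.append(
            PsmRecord(
                run_id=run_id,
                scan_number=spec.apex_scan,
                sequence=str(row["peptide"]),
                charge=z,
                observed_mz=observed,
                label_state=row["state"],
                protein_accs=(row["accession"],),
                score=100.0,
            )
        )
        truth_rows.append(
            {
                "accession": row["accession"],
                "sequence": row["peptide"].sequence,
                "charge": z,
                "label_state": row["state"].value,
                "true_ratio": row["true_ratio"],
                "light_intensity": row["light"],
                "heavy_intensity": row["heavy"],
            }
        )

    mzml_path = outdir / f"{run_id}.mzML"
    psm_path = outdir / f"{run_id}.psms.tsv"
    truth_path = outdir / f"{run_id}.truth.csv"
    write_mzml(mzml_path, scans, run_id=run_id)
    write_psm_table(psm_path, psms)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, index=False)
    return SimulatedRun(
        mzml_path=mzml_path, psm_path=psm_path, truth_path=truth_path, truth=truth
    )


def _collision_free_assignment(
    sequences: list[str],
    n_needed: int,
    charge_cycle: tuple[int, ...],
    fixed_mods: dict[str, dict[str, int]],
    min_separation_ppm: float = 30.0,
) -> list[tuple[str, int]]:
    """Pick sequences/charges whose channel ladders never collide in m/z.

    Two co-eluting peptides whose channels fall within the matching
    tolerance of each other would cross-contaminate extraction, which is an
    identification-level ambiguity, not a quantification property; the
    suite builder therefore keeps all ladder positions at least
    ``min_separation_ppm`` apart (3x the default matching tolerance).
    """
    accepted: list[tuple[str, int]] = []
    taken: set[str] = set()
    positions: list[float] = []
    ci = 0
    for seq in sequences:
        pep = parse_peptide(seq)
        if pep.sequence in taken:  # charges are keyed by core sequence
            continue
        z = charge_cycle[ci % len(charge_cycle)]
        comp = peptide_composition(pep, fixed_mods=fixed_mods)
        ladder = _ladder(monoisotopic_mz(comp, z), z)
        ok = all(
            abs(pos - q) / pos > min_separation_ppm * 1e-6
            for pos in ladder
            for q in positions
        )
        if ok:
            accepted.append((seq, z))
            taken.add(pep.sequence)
            positions.extend(ladder)
            ci += 1
            if len(accepted) == n_needed:
                return accepted
    raise ValueError(
        f"peptide pool exhausted: only {len(accepted)} of {n_needed} "
        "collision-free sequences available"
    )


def make_acceptance_suite(
    designed_ratios: list[float],
    n_proteins: int = 30,
    peptides_per_protein: int = 3,
    purity_p: float = 0.95,
    noise_cv: float = 0.1,
    base_seed: int = 101,
) -> list[SimSpec]:
    """One spec per designed labeled/unlabeled mixing ratio.

    Defaults are the designed-ratio recovery conditions: 30 proteins x 3
    peptides, purity 0.95, log-normal noise CV 0.1, fixed per-sample seeds
    derived from ``base_seed``.
    """
    if any(r <= 0 for r in designed_ratios):
        raise ValueError("designed ratios must be positive")
    specs: list[SimSpec] = []
    pool = packaged_tryptic_peptides()
    assignment = _collision_free_assignment(
        pool,
        n_proteins * peptides_per_protein,
        charge_cycle=(2, 3),
        fixed_mods={k: dict(v) for k, v in DEFAULT_FIXED_MODS.items()},
    )
    for i, ratio in enumerate(designed_ratios):
        proteins = []
        for j in range(n_proteins):
            chunk = assignment[
                j * peptides_per_protein : (j + 1) * peptides_per_protein
            ]
            proteins.append(
                ProteinSpec(
                    accession=f"SIMPROT{j + 1:03d}",
                    true_ratio=ratio,
                    peptides=tuple(seq for seq, _ in chunk),
                )
            )
        specs.append(
            SimSpec(
                proteins=tuple(proteins),
                purity_p=purity_p,
                charges={
                    parse_peptide(seq).sequence: z for seq, z in assignment
                },
                noise_cv=noise_cv,
                seed=base_seed + i,
            )
        )
    return specs
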