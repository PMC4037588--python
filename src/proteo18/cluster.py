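"""Isotope-cluster prediction and per-scan ion extraction.

For an identified peptide the six-channel cluster
``(16O, 16O+13C, 18O1, 18O1+13C, 18O2, 18O2+13C)`` is located from the
observed precursor m/z and the 18O modification state: the heavy forms sit
``d/z`` and ``2d/z`` above the natural form, where ``d`` is the 18O-16O
neutral mass difference, and each form has a ``+13C`` partner ``c/z`` higher.

Extraction walks outward from the identification scan across consecutive MS1
scans, keeping a scan while either the 16O or the 18O2 ion still shows charge
evidence (monoisotope plus 13C partner at the spacing expected for charge z),
and sums the per-scan channel intensities into the observed vector Y.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import C13_MASS_SHIFT, O18_MASS_SHIFT

__all__ = [
    "LabelState",
    "IsotopeCluster",
    "Scan",
    "ScanObservation",
    "ObservedVector",
    "predict_cluster",
    "match_channels",
    "detect_charge",
    "collect_observations",
    "sum_observed_vector",
    "restrict_scan_range",
]

N_CHANNELS = 6
CHANNEL_NAMES = ("16O", "16O_13C", "18O1", "18O1_13C", "18O2", "18O2_13C")


class LabelState(enum.Enum):
    """18O modification state of the identified peptide form."""

    MODIFIED = "modified"
    UNMODIFIED = "unmodified"


@dataclass(frozen=True)
class IsotopeCluster:
    """The six predicted m/z channels of one peptide ion."""

    mz_channels: tuple[float, ...]
    z: int
    d: float = O18_MASS_SHIFT
    c: float = C13_MASS_SHIFT

    def __post_init__(self) -> None:
        if len(self.mz_channels) != N_CHANNELS:
            raise ValueError("cluster must have exactly six channels")
        if any(b <= a for a, b in zip(self.mz_channels, self.mz_channels[1:])):
            raise ValueError("cluster channels must be strictly increasing")


@dataclass(frozen=True)
class Scan:
    """One centroided spectrum: (m/z, intensity) pairs sorted by m/z."""

    scan_number: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        if np.any(inten < 0):
            raise ValueError("negative intensity in scan")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass
class ScanObservation:
    """Measured channel intensities a_{k,i} for one scan."""

    scan_number: int
    retention_time: float
    a: np.ndarray  # six intensities, 0 when unmatched
    matched: np.ndarray  # six booleans
    charge_evidence_16O: bool
    charge_evidence_18O2: bool
    mz_observed: np.ndarray  # six observed centroid m/z, NaN when unmatched


@dataclass(frozen=True)
class ObservedVector:
    """Per-channel intensity sums y_i over the retained scans."""

    y: tuple[float, ...]
    n_scans: int
    scan_range: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.y) != N_CHANNELS:
            raise ValueError("observed vector must have six entries")


def predict_cluster(mz_obs: float, z: int, s: LabelState) -> IsotopeCluster:
    """Locate the six cluster channels from the observed precursor m/z.

    If the PSM was identified as the 18O-modified form, the precursor is the
    18O2 monoisotope and the natural form lies ``2 d / z`` below; if
    unmodified, the precursor *is* the natural monoisotope and the heavy
    forms lie above.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mz_obs <= 0:
        raise ValueError("observed m/z must be positive")
    d_z = O18_MASS_SHIFT / z
    c_z = C13_MASS_SHIFT / z
    if s is LabelState.MODIFIED:
        m16 = mz_obs - 2.0 * d_z
    else:
        m16 = mz_obs
    m18_1 = m16 + d_z
    m18_2 = m16 + 2.0 * d_z
    channels = (m16, m16 + c_z, m18_1, m18_1 + c_z, m18_2, m18_2 + c_z)
    return IsotopeCluster(mz_channels=channels, z=z)


def _best_peak(scan: Scan, mz: float, tol_ppm: float, mode: str = "intense") -> int:
    """Index of the matching centroid within +-tol_ppm, or -1."""
    tol = mz * tol_ppm * 1e-6
    lo = int(np.searchsorted(scan.mz, mz - tol, side="left"))
    hi = int(np.searchsorted(scan.mz, mz + tol, side="right"))
    if hi <= lo:
        return -1
    if mode == "intense":
        return lo + int(np.argmax(scan.intensity[lo:hi]))
    if mode == "nearest":
        return lo + int(np.argmin(np.abs(scan.mz[lo:hi] - mz)))
    raise ValueError(f"unknown peak-match mode {mode!r}")


def detect_charge(
    scan: Scan,
    mz: float,
    z: int,
    tol_ppm: float,
    min_fraction: float = 0.01,
    mode: str = "intense",
) -> bool:
    """Charge evidence: monoisotope plus 13C partner at spacing c/z.

    True iff a centroid sits within tolerance of ``mz`` and another within
    tolerance of ``mz + c/z`` with intensity at least ``min_fraction`` of
    the monoisotopic peak — the isotope spacing expected for charge ``z``.
    """
    i0 = _best_peak(scan, mz, tol_ppm, mode)
    if i0 < 0 or scan.intensity[i0] <= 0:
        return False
    i1 = _best_peak(scan, mz + C13_MASS_SHIFT / z, tol_ppm, mode)
    if i1 < 0:
        return False
    return scan.intensity[i1] >= min_fraction * scan.intensity[i0]


def match_channels(
    scan: Scan,
    cluster: IsotopeCluster,
    tol_ppm: float,
    min_fraction: float = 0.01,
    mode: str = "intense",
) -> ScanObservation:
    """Extract the six channel intensities from one MS1 scan.

    For each channel the most intense centroid within +-tol_ppm is taken
    (configurable to nearest); absent channels are encoded as zero, never
    raised.
    """
    a = np.zeros(N_CHANNELS)
    matched = np.zeros(N_CHANNELS, dtype=bool)
    mz_obs = np.full(N_CHANNELS, np.nan)
    for i, mz in enumerate(cluster.mz_channels):
        idx = _best_peak(scan, mz, tol_ppm, mode)
        if idx >= 0:
            a[i] = scan.intensity[idx]
            matched[i] = a[i] > 0
            mz_obs[i] = scan.mz[idx]
    return ScanObservation(
        scan_number=scan.scan_number,
        retention_time=scan.retention_time,
        a=a,
        matched=matched,
        charge_evidence_16O=detect_charge(
            scan, cluster.mz_channels[0], cluster.z, tol_ppm, min_fraction, mode
        ),
        charge_evidence_18O2=detect_charge(
            scan, cluster.mz_channels[4], cluster.z, tol_ppm, min_fraction, mode
        ),
        mz_observed=mz_obs,
    )


def collect_observations(
    run: list[Scan],
    id_scan: int,
    cluster: IsotopeCluster,
    tol_ppm: float,
    min_fraction: float = 0.01,
    mode: str = "intense",
    gap_tolerance: int = 0,
) -> list[ScanObservation]:
    """Extend the cluster across the elution profile around the PSM scan.

    Starting from the MS1 scan at (or nearest before) ``id_scan``, walks
    backward and forward over consecutive MS1 scans, stopping in each
    direction at the first scan lacking charge evidence on *both* the 16O
    and 18O2 channels (that scan excluded); ``gap_tolerance`` failing scans
    may be bridged when a later scan recovers evidence.  The starting scan
    is always retained, so every PSM yields at least one observation.
    """
    numbers = [s.scan_number for s in run]
    if id_scan not in numbers:
        raise KeyError(f"scan {id_scan} not found in run")
    ms1 = [s for s in run if s.ms_level == 1]
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    before = [i for i, s in enumerate(ms1) if s.scan_number <= id_scan]
    start = before[-1] if before else 0

    def has_evidence(scan: Scan) -> bool:
        return detect_charge(
            scan, cluster.mz_channels[0], cluster.z, tol_ppm, min_fraction, mode
        ) or detect_charge(
            scan, cluster.mz_channels[4], cluster.z, tol_ppm, min_fraction, mode
        )

    retained = [start]
    for step in (-1, 1):
        i = start + step
        gap = 0
        pending: list[int] = []
        while 0 <= i < len(ms1):
            if has_evidence(ms1[i]):
                retained.extend(pending)
                pending = []
                retained.append(i)
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
                pending.append(i)
            i += step
    retained.sort()
    return [
        match_channels(ms1[i], cluster, tol_ppm, min_fraction, mode) for i in retained
    ]


def sum_observed_vector(obs: list[ScanObservation]) -> ObservedVector:
    """Sum per-scan channel intensities into Y.

    Uses exact (fsum) per-channel summation so the result is independent of
    scan order and exactly additive under concatenation.
    """
    if not obs:
        raise ValueError("cannot sum an empty observation list")
    y = np.array(
        [math.fsum(float(o.a[i]) for o in obs) for i in range(N_CHANNELS)]
    )
    numbers = [o.scan_number for o in obs]
    return ObservedVector(
        y=tuple(y), n_scans=len(obs), scan_range=(min(numbers), max(numbers))
    )


def restrict_scan_range(
    obs: list[ScanObservation], first: int, last: int
) -> list[ScanObservation]:
    """Keep observations with ``first <= scan_number <= last`` (closed range).

    Used for manual validation: recompute a peptide from a clean sub-window
    of its elution profile (e.g. only the last few scans when early scans
    carry interference from a co-eluting species).
    """
    if first > last:
        raise ValueError(f"invalid scan range [{first}, {last}]")
    kept = [o for o in obs if first <= o.scan_number <= last]
    if not kept:
        raise ValueError(f"scan range [{first}, {last}] selects no observations")
    return kept
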