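"""Peptide elemental compositions and theoretical isotopic distributions.

The quantification model needs, for every identified peptide, the natural
isotopic abundance pattern of the unlabeled molecule.  This module provides

* a tiny peptide model (core sequence plus flanking residues, as written by
  search engines: ``R.YSYLKPR.A``),
* elemental composition arithmetic over C/H/N/O/S (user-extendable via the
  packaged constants tables),
* an isotope-pattern engine in the style of emass: per-element isotope
  vectors are combined by repeated discrete convolution (power-by-squaring
  per element), with fine isotopologues aggregated per nominal isotopomer
  (abundance-weighted mean mass) and terms below a pruning threshold dropped.

Abundances are reported as fractions of the *total* distribution (they sum to
1 over all isotopologues, so a truncated head sums to less than 1).  This
keeps the downstream least-squares deconvolution scale-consistent and makes
conservation checks exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Peptide",
    "ElementalComposition",
    "IsotopeDistribution",
    "PeptideParseError",
    "parse_peptide",
    "peptide_composition",
    "isotope_distribution",
    "monoisotopic_mz",
    "PROTON_MASS",
    "O18_MASS_SHIFT",
    "C13_MASS_SHIFT",
    "RESIDUE_COMPOSITIONS",
    "ISOTOPES",
    "WATER",
    "DEFAULT_FIXED_MODS",
]

_PRUNE_THRESHOLD = 1e-12
_MAX_PEAKS = 12  # only six cluster channels are ever consumed downstream


def _data_text(name: str) -> str:
    return (resources.files("proteo18") / "data" / name).read_text()


def _load_isotopes() -> dict[str, list[tuple[float, float]]]:
    table: dict[str, list[tuple[float, float]]] = {}
    for line in _data_text("isotopes.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, mass, ab = line.split("\t")
        table.setdefault(el, []).append((float(mass), float(ab)))
    for el in table:
        table[el].sort()
    return table


ISOTOPES: dict[str, list[tuple[float, float]]] = _load_isotopes()
"""Per-element stable isotope (mass, natural abundance) pairs, mass-sorted."""

PROTON_MASS: float = ISOTOPES.pop("proton")[0][0]

#: Neutral mass difference 18O - 16O, the per-label shift of the heavy forms.
O18_MASS_SHIFT: float = ISOTOPES["O"][2][0] - ISOTOPES["O"][0][0]

#: Neutral mass difference 13C - 12C, the spacing of natural isotope partners.
C13_MASS_SHIFT: float = ISOTOPES["C"][1][0] - ISOTOPES["C"][0][0]


class PeptideParseError(ValueError):
    """Raised when a flanked peptide string cannot be interpreted."""


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per element symbol.

    Addition is element-wise; unknown elements (not present in the isotope
    table) and negative counts are rejected.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise ValueError(f"element {el!r} not in isotope table")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def monoisotopic_mass(self) -> float:
        """Neutral mass of the all-lightest-isotope species, in Da."""
        return sum(n * ISOTOPES[el][0][0] for el, n in self.counts.items())


WATER = ElementalComposition({"H": 2, "O": 1})

#: Fixed modifications of the performic-acid workflow: cysteine oxidized to
#: cysteic acid (+3 O) and methionine to methionine sulfone (+2 O).
DEFAULT_FIXED_MODS: dict[str, dict[str, int]] = {"C": {"O": 3}, "M": {"O": 2}}


def _load_residues() -> dict[str, ElementalComposition]:
    table: dict[str, ElementalComposition] = {}
    for line in _data_text("residues.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, c, h, n, o, s = line.split("\t")
        table[aa] = ElementalComposition(
            {"C": int(c), "H": int(h), "N": int(n), "O": int(o), "S": int(s)}
        )
    return table


RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = _load_residues()


@dataclass(frozen=True)
class Peptide:
    """A peptide core sequence with single-letter flanking residues.

    ``fixed_mods`` carries per-residue composition deltas (e.g. cysteic acid
    ``("C", {"O": 3})``); the 18O label is *not* a modification here — it is
    handled structurally by the cluster geometry.
    """

    prev_aa: str = "-"
    sequence: str = ""
    next_aa: str = "-"
    fixed_mods: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, ch in enumerate(self.sequence):
            if ch not in RESIDUE_COMPOSITIONS:
                raise PeptideParseError(
                    f"unknown residue {ch!r} at position {i + 1} in {self.sequence!r}"
                )

    def __str__(self) -> str:
        if self.prev_aa == "-" and self.next_aa == "-":
            return self.sequence
        return f"{self.prev_aa}.{self.sequence}.{self.next_aa}"


_FLANKED = re.compile(r"^(?P<prev>[A-Za-z-])\.(?P<core>.+)\.(?P<next>[A-Za-z-])$")


def parse_peptide(text: str) -> Peptide:
    """Parse ``"SEQ"`` or ``"X.SEQ.Y"`` into a :class:`Peptide`.

    Flanks default to ``'-'`` when absent; the core is uppercased.  An
    unknown residue raises :class:`PeptideParseError` naming the character
    and its 1-based position.
    """
    text = text.strip()
    m = _FLANKED.match(text)
    if m:
        prev, core, nxt = m.group("prev"), m.group("core"), m.group("next")
    elif "." in text:
        raise PeptideParseError(f"malformed flanked peptide string {text!r}")
    else:
        prev, core, nxt = "-", text, "-"
    core = core.upper()
    for i, ch in enumerate(core):
        if ch not in RESIDUE_COMPOSITIONS:
            raise PeptideParseError(
                f"unknown residue {ch!r} at position {i + 1} in {core!r}"
            )
    return Peptide(prev_aa=prev.upper(), sequence=core, next_aa=nxt.upper())


def peptide_composition(
    p: Peptide, fixed_mods: dict[str, dict[str, int]] | None = None
) -> ElementalComposition:
    """Elemental composition of the (neutral, unlabeled) peptide.

    Sum of residue compositions plus one water, with fixed-modification
    composition deltas applied once per matching residue.  When
    ``fixed_mods`` is None the deltas attached to the peptide itself apply.
    """
    comp = WATER
    for aa in p.sequence:
        comp = comp + RESIDUE_COMPOSITIONS[aa]
    if fixed_mods is None:
        fixed_mods = {aa: dict(delta) for aa, delta in p.fixed_mods}
    for aa, delta in fixed_mods.items():
        n_sites = p.sequence.count(aa)
        if n_sites:
            comp = comp + ElementalComposition(
                {el: n * n_sites for el, n in delta.items()}
            )
    return comp


@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated isotopomer masses (Da) and relative abundances.

    Masses are abundance-weighted means within each nominal isotopomer;
    abundances are fractions of the full (untruncated) distribution.
    """

    masses: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.masses) != len(self.abundances):
            raise ValueError("masses and abundances must have equal length")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")
        if sum(self.abundances) > 1.0 + 1e-9:
            raise ValueError("abundances must sum to at most 1")


def _atom_distribution(el: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom (mass, abundance) arrays indexed by nominal mass shift."""
    iso = ISOTOPES[el]
    m0 = iso[0][0]
    shifts = [round(m - m0) for m, _ in iso]
    size = max(shifts) + 1
    ab = np.zeros(size)
    mw = np.zeros(size)
    for (m, a), s in zip(iso, shifts):
        ab[s] += a
        mw[s] += a * m
    mass = np.divide(mw, ab, out=np.zeros(size), where=ab > 0)
    return mass, ab


def _convolve(
    d1: tuple[np.ndarray, np.ndarray], d2: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    m1, a1 = d1
    m2, a2 = d2
    size = len(a1) + len(a2) - 1
    ab = np.zeros(size)
    mw = np.zeros(size)
    for i in range(len(a1)):
        if a1[i] <= 0:
            continue
        contrib = a1[i] * a2
        ab[i : i + len(a2)] += contrib
        mw[i : i + len(a2)] += contrib * (m1[i] + m2)
    mass = np.divide(mw, ab, out=np.zeros(size), where=ab > 0)
    return mass, ab


def _prune(
    d: tuple[np.ndarray, np.ndarray], max_len: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    mass, ab = d
    ab = ab.copy()
    ab[ab < _PRUNE_THRESHOLD] = 0.0
    nz = np.nonzero(ab)[0]
    end = min(nz[-1] + 1 if len(nz) else 1, max_len)
    return mass[:end], ab[:end]


def _power(d: tuple[np.ndarray, np.ndarray], n: int) -> tuple[np.ndarray, np.ndarray]:
    """n-fold self-convolution by binary exponentiation."""
    result: tuple[np.ndarray, np.ndarray] | None = None
    base = d
    while n:
        if n & 1:
            result = base if result is None else _prune(_convolve(result, base))
        n >>= 1
        if n:
            base = _prune(_convolve(base, base))
    assert result is not None
    return result


def isotope_distribution(
    c: ElementalComposition, n_peaks: int = 6
) -> IsotopeDistribution:
    """First ``n_peaks`` aggregated isotopomers of the molecule.

    Computed by iterated convolution of per-element isotope vectors with
    pruning of terms below 1e-12 relative abundance; ``n_peaks`` is capped
    at 12 since only six channels are ever consumed downstream.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if c.total_atoms == 0:
        raise ValueError("empty elemental composition")
    n_peaks = min(n_peaks, _MAX_PEAKS)
    dist: tuple[np.ndarray, np.ndarray] | None = None
    for el in sorted(c.counts):
        part = _power(_atom_distribution(el), c.counts[el])
        dist = part if dist is None else _prune(_convolve(dist, part))
    assert dist is not None
    mass, ab = dist
    if len(ab) < n_peaks:
        mass = np.pad(mass, (0, n_peaks - len(mass)))
        ab = np.pad(ab, (0, n_peaks - len(ab)))
    mass = mass[:n_peaks].copy()
    ab = ab[:n_peaks].copy()
    # Fill mass placeholders for zero-abundance isotopomers (possible for
    # sulfur-dominated species where the +3 isotopomer is missing).
    for i in range(1, len(mass)):
        if ab[i] == 0 and mass[i] == 0:
            mass[i] = mass[i - 1] + C13_MASS_SHIFT
    return IsotopeDistribution(masses=tuple(mass), abundances=tuple(ab))


def monoisotopic_mz(c: ElementalComposition, z: int) -> float:
    """m/z (Th) of the all-light isotopologue at charge ``z`` (protonation)."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (c.monoisotopic_mass() + z * PROTON_MASS) / z
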