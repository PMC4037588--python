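"""Deconvolution of the observed six-channel vector into form abundances.

The six observed channels mix three overlapping copies of the peptide's
natural isotope pattern V: the natural form at offset 0, the one-label heavy
form shifted two channels up, and the two-label form shifted four channels
up.  The design matrix

    X = [v1  0  0
         v2  0  0
         v3 v1  0
         v4 v2  0
         v5 v3 v1
         v6 v4 v2]

maps form abundances A = (A(16O), A(18O1), A(18O2)) onto expected channel
intensities; A is recovered by non-negative least squares.  The heavy-water
purity p then splits A into light/heavy sample abundances: with per-site
incorporation probability p the heavy sample distributes over 0/1/2 labels
as (f0, f1, f2) = ((1-p)^2, 2p(1-p), p^2), so A(heavy) is the least-squares
projection onto the two heavy-only forms and A(light) is the purity-corrected
remainder of the natural form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .cluster import N_CHANNELS, ObservedVector

__all__ = [
    "TheoreticalVector",
    "DesignMatrix",
    "FormAbundances",
    "ChannelAbundances",
    "build_design_matrix",
    "solve_abundances",
    "split_light_heavy",
    "purity_fractions",
    "peptide_ratio",
]


@dataclass(frozen=True)
class TheoreticalVector:
    """First six natural isotopomer abundances (v1..v6) of the peptide."""

    v: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.v) != N_CHANNELS:
            raise ValueError("theoretical vector must have six entries")
        if self.v[0] <= 0:
            raise ValueError("monoisotopic abundance v1 must be positive")
        if any(x < 0 for x in self.v):
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class DesignMatrix:
    """6x3 matrix of per-form theoretical channel contributions."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (N_CHANNELS, 3):
            raise ValueError("design matrix must be 6x3")
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class FormAbundances:
    """Deconvolved abundances of the 16O / 18O1 / 18O2 forms."""

    a16: float
    a18_1: float
    a18_2: float
    residual_norm: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.a16, self.a18_1, self.a18_2) < 0:
            raise ValueError("form abundances must be non-negative")


@dataclass(frozen=True)
class ChannelAbundances:
    """Purity-corrected per-sample abundances."""

    light: float
    heavy: float
    purity: float
    flags: frozenset[str] = frozenset()


def build_design_matrix(V: TheoreticalVector) -> DesignMatrix:
    """Stack the natural pattern at form offsets 0, +2, +4 channels."""
    v = V.v
    x = np.array(
        [
            [v[0], 0.0, 0.0],
            [v[1], 0.0, 0.0],
            [v[2], v[0], 0.0],
            [v[3], v[1], 0.0],
            [v[4], v[2], v[0]],
            [v[5], v[3], v[1]],
        ]
    )
    return DesignMatrix(x=x)


def solve_abundances(X: DesignMatrix, Y: ObservedVector) -> FormAbundances:
    """Solve Y = X A for A >= 0 by non-negative least squares.

    An all-zero Y yields A = 0 with a ``zero_observed`` flag rather than an
    error.
    """
    y = np.asarray(Y.y, dtype=float)
    if not np.any(y):
        return FormAbundances(0.0, 0.0, 0.0, 0.0, frozenset({"zero_observed"}))
    a, rnorm = scipy.optimize.nnls(X.x, y)
    return FormAbundances(float(a[0]), float(a[1]), float(a[2]), float(rnorm))


def purity_fractions(p: float) -> tuple[float, float, float]:
    """Binomial split of the heavy sample over 0/1/2 incorporated labels."""
    if not 0.0 < p <= 1.0:
        raise ValueError("purity p must lie in (0, 1]")
    return (1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p


def split_light_heavy(A: FormAbundances, p: float) -> ChannelAbundances:
    """Split form abundances into light/heavy sample abundances.

    The 18O1 and 18O2 forms can only come from the heavy sample, so
    A(heavy) is the least-squares projection of (a18_1, a18_2) onto
    (f1, f2); the heavy sample's unlabeled fraction f0 is then subtracted
    from the natural form to leave A(light), clipped at zero (negative
    remainders are flagged ``purity_overcorrection``).  Exact for complete
    two-site exchange; reduces to light = a16, heavy = a18_2 at p = 1.
    """
    f0, f1, f2 = purity_fractions(p)
    heavy = (f1 * A.a18_1 + f2 * A.a18_2) / (f1 * f1 + f2 * f2)
    raw_light = A.a16 - heavy * f0
    flags = set(A.flags)
    if raw_light < 0:
        flags.add("purity_overcorrection")
    return ChannelAbundances(
        light=max(0.0, raw_light), heavy=heavy, purity=p, flags=frozenset(flags)
    )


def peptide_ratio(ch: ChannelAbundances) -> float | None:
    """Labeled/unlabeled ratio heavy/light; None when no light signal.

    A zero light abundance is reported as missing (flagged upstream as
    ``no_light_signal``), never as infinity.
    """
    if ch.light <= 0:
        return None
    return ch.heavy / ch.light
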