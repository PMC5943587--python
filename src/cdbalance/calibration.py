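"""The CD chiral-balance signal model and the calibration solvers that invert it.

A chiral analyte and its enantiomer give equal and opposite CD signals, so a
mixture behaves like a two-pan balance: the detector reads

    I = K * (c_L - c_D) + b

and reads zero for a racemate on a zeroed instrument (b = 0). Three ways of
inverting this relation are provided:

* direct titration — spike the sample with increasing known amounts of the
  D-enantiomer and locate the null point of the fitted line;
* single-point calibration — ratio the sample signal against one standard
  mixture of known composition (assumes b = 0);
* bracket calibration — interpolate between a lower and a higher standard,
  which cancels any constant offset b exactly.

All functions are deterministic; measurement noise lives in
:mod:`cdbalance.simulate`.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .types import BracketStandards, CDMeasurement, DetectorModel, EnantiomerMix

__all__ = [
    "cd_signal",
    "solve_single_point",
    "solve_bracket",
    "bracket_detector",
    "solve_direct_titration",
    "TitrationFit",
]


def _intensity(x: CDMeasurement | float) -> float:
    value = x.intensity if isinstance(x, CDMeasurement) else float(x)
    if not math.isfinite(value):
        raise ValueError(f"intensity must be finite, got {value!r}")
    return value


def cd_signal(mix: EnantiomerMix, det: DetectorModel) -> float:
    """Noise-free CD signal of an enantiomer mixture: K*(c_L - c_D) + b."""
    return det.k * mix.delta + det.b


def solve_single_point(
    sample_i: CDMeasurement | float,
    std_i: CDMeasurement | float,
    std_mix: EnantiomerMix,
    sample_c_d: float,
) -> float:
    """Estimate the sample's c_L from one standard mixture.

    Inverts the signal ratio I / I_STD against a standard of known
    composition (c_LSTD, c_D1):

        c_L = (I / I_STD) * (c_LSTD - c_D1) + c_D2

    where c_D2 (``sample_c_d``) is the known internal-standard amount in the
    sample. Exact inverse of :func:`cd_signal` when the detector offset b is
    zero; with a nonzero offset prefer :func:`solve_bracket`.

    Raises
    ------
    ValueError
        If the standard intensity is zero or the standard is racemic
        (c_LSTD = c_D1), either of which makes the ratio degenerate.
    """
    i = _intensity(sample_i)
    i_std = _intensity(std_i)
    if i_std == 0:
        raise ValueError("degenerate standard: zero standard intensity")
    if std_mix.delta == 0:
        raise ValueError("degenerate standard: racemic standard (c_LSTD == c_D1)")
    return (i / i_std) * std_mix.delta + float(sample_c_d)


def bracket_detector(brackets: BracketStandards) -> DetectorModel:
    """Detector (K, b) solved from the two bracket standards.

    The two linear equations I_1 = K*d_1 + b and I_2 = K*d_2 + b (with
    d = c_L - c_D) determine K and b exactly.
    """
    (low_mix, low_i), (high_mix, high_i) = brackets.low, brackets.high
    i1, i2 = _intensity(low_i), _intensity(high_i)
    d1, d2 = low_mix.delta, high_mix.delta
    k = (i2 - i1) / (d2 - d1)
    if k == 0:
        raise ValueError("bracket standards give zero sensitivity")
    b = i1 - k * d1
    return DetectorModel(k=k, b=b)


def solve_bracket(
    sample_i: CDMeasurement | float,
    brackets: BracketStandards,
    sample_c_d: float,
) -> float:
    """Estimate the sample's c_L by bracket calibration.

    Linear interpolation of the sample intensity I between the lower
    standard (c_L1, c_D1, I_1) and the higher standard (c_L2, c_D2, I_2):

        c_L = [(I_2 - I)(c_L1 - c_D1) + (I - I_1)(c_L2 - c_D2)] / (I_2 - I_1)
              + c_D

    Because both standards carry the same constant offset b, the offset
    cancels: the bracket is an exact inverse of the signal model for any b.
    Use :func:`bracket_detector` for the implied (K, b).

    Raises
    ------
    ValueError
        If the two standards' intensities coincide (unresolvable bracket).
    """
    (low_mix, low_i), (high_mix, high_i) = brackets.low, brackets.high
    i = _intensity(sample_i)
    i1, i2 = _intensity(low_i), _intensity(high_i)
    if i2 == i1:
        raise ValueError("unresolvable bracket: identical standard intensities")
    num = (i2 - i) * low_mix.delta + (i - i1) * high_mix.delta
    return num / (i2 - i1) + float(sample_c_d)


class TitrationFit(NamedTuple):
    """Result of a direct-titration fit of I against the added c_D."""

    c_l: float
    slope: float  # equals -K for an ideal detector
    intercept: float


def solve_direct_titration(
    series: Iterable[tuple[float, CDMeasurement | float]] | Sequence,
) -> TitrationFit:
    """Estimate c_L from a titration of the sample with its enantiomer.

    A series of known D-enantiomer amounts is added to aliquots of the
    sample and the CD signal recorded for each. Under the balance model the
    signal falls linearly, I = -K*c_D + (K*c_L + b), and crosses zero where
    the pans balance, c_D = c_L (plus b/K if the instrument has an offset).
    An ordinary least-squares line over all points is fitted and its root
    returned as the c_L estimate.

    Raises
    ------
    ValueError
        If fewer than two distinct c_D values are given, or the fitted
        slope is zero (no crossing).
    """
    pts = [(float(c_d), _intensity(i)) for c_d, i in series]
    if len(pts) < 2:
        raise ValueError("need at least 2 titration points")
    c_d = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    if np.unique(c_d).size < 2:
        raise ValueError("degenerate titration: all points at the same c_D")
    if np.ptp(i) == 0:
        raise ValueError("zero titration slope: fitted line never crosses zero")
    slope, intercept = np.polyfit(c_d, i, 1)
    if slope == 0:
        raise ValueError("zero titration slope: fitted line never crosses zero")
    return TitrationFit(c_l=-intercept / slope, slope=float(slope), intercept=float(intercept))
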