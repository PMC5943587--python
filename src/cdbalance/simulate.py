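"""Synthetic-data generation for the chiral-balance pipeline.

Everything the quantitation pipeline consumes can be generated here with
the statistical structure the method's validation experiments assume:

* gravimetric dilution series of the L-enantiomer (0.005-1.2 mg/g) with a
  weighing-error model, mixed with a fixed or a matched ("variable")
  internal-standard amount of the D-enantiomer;
* CD intensity replicates I = K(c_L - c_D) + b + noise, where the noise SD
  scales as 1/sqrt(DIT) with the detector's digital integration time;
* full two-channel chromatograms (achiral DAD + CD) built from Gaussian
  peaks, with the CD peak of each analyte signed by its net chirality
  (L positive, D negative by default) and its area proportional to
  K*(c_L - c_D).

All randomness flows from a single ``numpy`` generator/seed: identical
seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .calibration import cd_signal
from .types import CDMeasurement, Chromatogram, DetectorModel, EnantiomerMix

__all__ = [
    "DEFAULT_DETECTOR",
    "SimDesign",
    "PeakSpec",
    "simulate_dilution_series",
    "simulate_cd_intensity",
    "simulate_chromatogram",
    "bracket_mixes",
    "make_table_fixtures",
]

#: Default detector: 200 signal units per mg/g, zeroed, 0.3 units of noise
#: at a 1-s digital integration time. At the default DIT of 32 s this puts
#: the limit of detection in the low microgram-per-gram range.
DEFAULT_DETECTOR = DetectorModel(k=200.0, b=0.0, sigma=0.3)

#: Standard uncertainty of one weighing: 0.01 mg balance readability treated
#: as a rectangular distribution (÷ sqrt(3)), on a ~200 mg aliquot.
DEFAULT_WEIGHING_REL_SD = 0.01 / math.sqrt(3.0) / 200.0


@dataclass(frozen=True)
class SimDesign:
    """One simulated validation experiment.

    ``levels`` are the nominal L-enantiomer mass fractions (mg/g);
    ``is_mode`` selects a fixed internal-standard amount (``c_d`` for every
    level) or a variable one matched to each level within
    ``matching_rel_tol``; ``relative_noise``, when set, makes each CD
    reading's noise SD that fraction of the true signal instead of the
    detector's absolute ``sigma/sqrt(DIT)``.
    """

    levels: tuple[float, ...] = (0.1, 0.3, 0.5, 0.8, 1.0, 1.2)
    is_mode: str = "fixed"
    c_d: float = 0.05
    matching_rel_tol: float = 0.02
    detector: DetectorModel = DEFAULT_DETECTOR
    dit: float = 32.0
    n_replicates: int = 6
    relative_noise: float | None = 0.005
    weighing_rel_sd: float = DEFAULT_WEIGHING_REL_SD
    bracket_span: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.levels):
            raise ValueError("all concentration levels must be positive")
        if self.is_mode not in ("fixed", "variable"):
            raise ValueError("is_mode must be 'fixed' or 'variable'")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.dit <= 0:
            raise ValueError("DIT must be positive")


def simulate_dilution_series(
    design: SimDesign, rng: np.random.Generator | None = None
) -> list[tuple[float, EnantiomerMix]]:
    """Gravimetric truth for each nominal level of the design.

    Each prepared mass fraction is the nominal value perturbed by the
    weighing-error model (independent normal, relative SD
    ``weighing_rel_sd``); the perturbed value is the *gravimetric truth* the
    analyst knows from the balance readings. In fixed mode every mix gets
    ``c_d`` of the D-form; in variable mode c_D is matched to c_L within
    the matching tolerance.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    out = []
    for nominal in design.levels:
        c_l = nominal * (1.0 + design.weighing_rel_sd * rng.standard_normal())
        if design.is_mode == "fixed":
            c_d = design.c_d * (1.0 + design.weighing_rel_sd * rng.standard_normal())
        else:
            c_d = c_l * (1.0 + design.matching_rel_tol * rng.uniform(-1.0, 1.0))
        out.append((nominal, EnantiomerMix(c_l=c_l, c_d=c_d)))
    return out


def _noise_sd(
    mix: EnantiomerMix,
    det: DetectorModel,
    dit: float,
    relative_noise: float | None,
) -> float:
    if relative_noise is not None:
        return relative_noise * abs(det.k * mix.delta)
    return det.sigma / math.sqrt(dit / 1.0)


def simulate_cd_intensity(
    mix: EnantiomerMix,
    det: DetectorModel,
    dit: float = 32.0,
    n: int = 1,
    rng: np.random.Generator | int | None = None,
    relative_noise: float | None = None,
) -> list[CDMeasurement]:
    """Noisy replicate CD readings of one mixture.

    The noise is additive Gaussian with SD ``sigma / sqrt(DIT / 1 s)`` —
    longer digital integration averages the detector noise down as
    1/sqrt(DIT) — or ``relative_noise`` times the true signal when that
    mode is selected.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    true = cd_signal(mix, det)
    sd = _noise_sd(mix, det, dit, relative_noise)
    return [
        CDMeasurement(intensity=true + sd * rng.standard_normal(), replicate_id=i)
        for i in range(n)
    ]


@dataclass(frozen=True)
class PeakSpec:
    """One analyte's peak in a simulated separation.

    ``c_l``/``c_d`` are the enantiomer mass fractions of the analyte in the
    injected solution; the CD peak area is K*(c_l - c_d) (signed), the DAD
    peak area ``dad_response``*(c_l + c_d) (achiral).
    """

    name: str
    apex_time: float
    sigma_t: float = 0.05
    c_l: float = 0.0
    c_d: float = 0.0
    dad_response: float = 500.0

    def __post_init__(self) -> None:
        if self.sigma_t <= 0:
            raise ValueError("peak width sigma_t must be positive")


def simulate_chromatogram(
    layout: Sequence[PeakSpec],
    det: DetectorModel = DEFAULT_DETECTOR,
    rng: np.random.Generator | int | None = None,
    run_time: float = 10.0,
    dt: float = 0.005,
    dit: float = 32.0,
    baseline_drift: tuple[float, float] = (0.0, 0.0),
    dad_noise_sd: float = 0.05,
    l_positive: bool = True,
) -> Chromatogram:
    """Two-channel chromatogram from a peak layout.

    Peaks are Gaussian in time; overlapping apexes simply sum (a merged
    peak). ``baseline_drift`` is the (intercept, slope per minute) of a
    linear CD baseline; CD point noise is ``det.sigma/sqrt(DIT)``. The sign
    convention ``l_positive`` puts the L-enantiomer's CD peak positive.
    """
    from .chromatography import gaussian_peak

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    times = np.arange(0.0, run_time + dt / 2, dt)
    dad = np.zeros_like(times)
    cd = np.zeros_like(times)
    sign = 1.0 if l_positive else -1.0
    gauss_norm = math.sqrt(2.0 * math.pi)
    for pk in layout:
        if pk.apex_time < 0 or pk.apex_time > run_time:
            raise ValueError(f"peak {pk.name!r} apex outside the run time")
        cd_area = sign * det.k * (pk.c_l - pk.c_d)
        dad_area = pk.dad_response * (pk.c_l + pk.c_d)
        cd += gaussian_peak(pk.apex_time, cd_area / (pk.sigma_t * gauss_norm), pk.sigma_t, times)
        dad += gaussian_peak(pk.apex_time, dad_area / (pk.sigma_t * gauss_norm), pk.sigma_t, times)
    cd += baseline_drift[0] + baseline_drift[1] * times
    cd_sd = det.sigma / math.sqrt(dit / 1.0)
    if cd_sd > 0:
        cd += cd_sd * rng.standard_normal(times.shape)
    if dad_noise_sd > 0:
        dad += dad_noise_sd * rng.standard_normal(times.shape)
    return Chromatogram(time=times, dad=dad, cd=cd)


def bracket_mixes(
    expected_delta: float, c_d: float, span: float = 0.10
) -> tuple[EnantiomerMix, EnantiomerMix]:
    """Symmetric bracket standards around an expected sample imbalance.

    The lower/higher standards are prepared at (1 -/+ ``span``) times the
    expected c_L - c_D of the sample, sharing the sample's internal-standard
    amount ``c_d``.
    """
    if expected_delta == 0:
        raise ValueError("cannot bracket a racemic (zero-imbalance) sample")
    low = EnantiomerMix(c_l=c_d + (1.0 - span) * expected_delta, c_d=c_d)
    high = EnantiomerMix(c_l=c_d + (1.0 + span) * expected_delta, c_d=c_d)
    return low, high


def make_table_fixtures(out_dir) -> dict:
    """Write the transcribed reference-table fixtures as CSV files."""
    from .reference_data import write_table_fixtures

    return write_table_fixtures(out_dir)
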