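"""Chromatogram peak shapes, baseline-corrected integration, resolution and
enantiopurity from peak areas."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import Chromatogram, Peak

__all__ = [
    "gaussian_peak",
    "gaussian_area",
    "integrate_peak",
    "resolution",
    "enantiopurity_from_areas",
    "batch_enantiopurity",
    "PurityReport",
    "find_peaks_naive",
]

# full width at half maximum of a Gaussian = 2*sqrt(2*ln2) * sigma
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def gaussian_peak(
    apex_time: float, height: float, sigma_t: float, times: np.ndarray
) -> np.ndarray:
    """Gaussian peak profile height*exp(-(t-apex)^2 / (2 sigma^2)).

    The closed-form area is ``height * sigma_t * sqrt(2*pi)``
    (:func:`gaussian_area`); traces are additive, so chromatograms are built
    by summing calls.
    """
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    t = np.asarray(times, dtype=float)
    return height * np.exp(-0.5 * ((t - apex_time) / sigma_t) ** 2)


def gaussian_area(height: float, sigma_t: float) -> float:
    """Closed-form area of a Gaussian peak (signal·min)."""
    return height * sigma_t * math.sqrt(2.0 * math.pi)


def _half_height_width(t: np.ndarray, y: np.ndarray, apex_idx: int) -> float:
    """Full width of y at half the apex value, by linear interpolation.

    Works on the baseline-corrected, sign-normalised (positive-apex) trace.
    Falls back to the Gaussian FWHM implied by the second-moment width when
    a half-height crossing is not bracketed inside the window.
    """
    half = y[apex_idx] / 2.0
    left = right = None
    for j in range(apex_idx, 0, -1):
        if y[j - 1] <= half <= y[j] and y[j] > y[j - 1]:
            f = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = t[j - 1] + f * (t[j] - t[j - 1])
            break
    for j in range(apex_idx, len(y) - 1):
        if y[j + 1] <= half <= y[j] and y[j] > y[j + 1]:
            f = (y[j] - half) / (y[j] - y[j + 1])
            right = t[j] + f * (t[j + 1] - t[j])
            break
    if left is not None and right is not None and right > left:
        return right - left
    # moment-based fallback: sigma^2 from the area-normalised second moment
    w = np.clip(y, 0, None)
    total = np.trapezoid(w, t)
    if total <= 0:
        # degenerate (flat / drift-only) window: report the window span so
        # the Peak invariants hold for a zero-area result
        return float(t[-1] - t[0])
    mu = np.trapezoid(w * t, t) / total
    var = np.trapezoid(w * (t - mu) ** 2, t) / total
    if var <= 0:
        return float(t[-1] - t[0])
    return _FWHM_FACTOR * math.sqrt(var)


def integrate_peak(
    chrom: Chromatogram, channel: str, window: tuple[float, float]
) -> Peak:
    """Integrate one peak between ``window`` bounds with a linear baseline.

    A straight baseline is drawn between the trace values at the window
    endpoints and subtracted; the residual is integrated by the trapezoidal
    rule. The apex is the largest |residual| sample, so negative (D-form CD)
    peaks integrate to signed negative areas. The reported half-height width
    refers to the baseline-corrected peak.

    Raises
    ------
    ValueError
        If the window lies outside the time range or spans fewer than
        3 samples.
    """
    t0, t1 = float(window[0]), float(window[1])
    t = chrom.time
    if t0 < t[0] or t1 > t[-1] or t0 >= t1:
        raise ValueError(f"window ({t0}, {t1}) outside time range ({t[0]}, {t[-1]})")
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 3:
        raise ValueError("integration window spans fewer than 3 samples")
    tw = t[mask]
    yw = chrom.channel(channel)[mask]
    baseline = yw[0] + (yw[-1] - yw[0]) * (tw - tw[0]) / (tw[-1] - tw[0])
    resid = yw - baseline
    area = float(np.trapezoid(resid, tw))
    apex_idx = int(np.argmax(np.abs(resid)))
    height = float(resid[apex_idx])
    sign = 1.0 if height >= 0 else -1.0
    width = _half_height_width(tw, sign * resid, apex_idx)
    apex_time = float(tw[apex_idx])
    if not (tw[0] < apex_time < tw[-1]):
        # apex pinned at a window edge (flat or drift-only trace): nudge it
        # inside so the Peak invariants hold for the degenerate case
        apex_time = 0.5 * (tw[0] + tw[-1])
    return Peak(
        apex_time=apex_time,
        area=area,
        height=height,
        half_height_width=width,
        start=float(tw[0]),
        end=float(tw[-1]),
    )


def resolution(p1: Peak, p2: Peak) -> float:
    """Chromatographic resolution from half-height widths.

    Rs = 1.18 * |t2 - t1| / (w_h1 + w_h2), the pharmacopoeial half-height
    convention. Two co-eluting peaks give Rs = 0; Rs >= 1.5 is the usual
    baseline-separation criterion.
    """
    wsum = p1.half_height_width + p2.half_height_width
    if wsum <= 0:
        raise ValueError("peak widths must be positive")
    return 1.18 * abs(p2.apex_time - p1.apex_time) / wsum


def enantiopurity_from_areas(area_major: float, area_minor: float) -> float:
    """Minor-enantiomer impurity in percent from the two peak areas.

    Returns 100 * area_minor / area_major, assuming equal detector response
    factors for the two enantiomers (they are chemically identical in an
    achiral detector).
    """
    if area_major <= 0:
        raise ValueError("major-enantiomer area must be positive")
    if area_minor < 0:
        raise ValueError("peak areas cannot be negative")
    return 100.0 * area_minor / area_major


@dataclass(frozen=True)
class PurityReport:
    """Per-sample impurity values (%) with their mean and RSD."""

    values: tuple[float, ...]
    mean: float
    rsd: float


def batch_enantiopurity(area_pairs) -> PurityReport:
    """Impurity for each (area_major, area_minor) pair, plus mean and RSD (%).

    RSD uses the n-1 sample standard deviation of the unrounded per-sample
    values.
    """
    values = [enantiopurity_from_areas(a, b) for a, b in area_pairs]
    arr = np.array(values)
    mean = float(arr.mean())
    rsd = float(100.0 * arr.std(ddof=1) / mean) if arr.size > 1 else 0.0
    return PurityReport(values=tuple(values), mean=mean, rsd=rsd)


def find_peaks_naive(
    chrom: Chromatogram,
    channel: str = "cd",
    noise_sd: float | None = None,
    min_snr: float = 5.0,
) -> list[float]:
    """Apex times of local extrema rising above ``min_snr`` times the noise.

    A deliberately simple detector for the simulator's known layouts; real
    analyses identify peaks by retention time and pass explicit windows to
    :func:`integrate_peak`.
    """
    from scipy.signal import find_peaks as _scipy_find_peaks

    y = chrom.channel(channel)
    if noise_sd is None:
        noise_sd = float(np.std(np.diff(y)) / math.sqrt(2.0)) or 1e-12
    height = min_snr * noise_sd
    apexes: list[float] = []
    for trace in (y, -y):  # CD peaks may point either way
        idx, _ = _scipy_find_peaks(trace, height=height)
        apexes.extend(chrom.time[idx].tolist())
    return sorted(apexes)
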