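"""Method-performance statistics: bias, RSD, LOD/LOQ, precision, GUM
uncertainty propagation, and normalized-error (En) method comparison.

Conventions fixed here and used everywhere in the package:

* RSD is the n-1 (sample) standard deviation divided by the mean, in %;
* bias is 100*(mean - truth)/truth, against the gravimetric truth;
* LOD and LOQ are the concentrations giving 3x and 10x the baseline noise;
* En compares two results through their expanded (k=2) uncertainties,
  |x_a - x_b| / sqrt(U_a^2 + U_b^2), with |En| < 1 meaning agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import Chromatogram

__all__ = [
    "PerformanceRow",
    "UncertainResult",
    "rsd",
    "bias_and_rsd",
    "lod_loq",
    "noise_sd_from_blank",
    "en_value",
    "en_consistent",
    "propagate_uncertainty",
    "precision_report",
    "PrecisionReport",
]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in %, with the n-1 denominator."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class PerformanceRow:
    """Replicate estimates at one gravimetric level with bias and RSD (%)."""

    truth: float
    estimates: tuple[float, ...]
    bias: float
    rsd: float


def bias_and_rsd(estimates: Sequence[float], gravimetric_truth: float) -> PerformanceRow:
    """Bias and RSD of replicate estimates against the gravimetric value."""
    if gravimetric_truth == 0:
        raise ValueError("gravimetric truth must be nonzero")
    arr = np.asarray(estimates, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicate estimates")
    bias = float(100.0 * (arr.mean() - gravimetric_truth) / gravimetric_truth)
    return PerformanceRow(
        truth=float(gravimetric_truth),
        estimates=tuple(arr.tolist()),
        bias=bias,
        rsd=rsd(arr),
    )


def lod_loq(noise_sd: float, sensitivity: float) -> tuple[float, float]:
    """Limits of detection and quantitation from baseline noise.

    LOD = 3*noise/K and LOQ = 10*noise/K in mass-fraction units, with K the
    detector sensitivity (signal per mg/g). The LOQ/LOD ratio is 10/3 by
    construction.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    if noise_sd < 0:
        raise ValueError("noise SD cannot be negative")
    return 3.0 * noise_sd / sensitivity, 10.0 * noise_sd / sensitivity


def noise_sd_from_blank(
    chrom: Chromatogram, channel: str = "cd", window: tuple[float, float] | None = None
) -> float:
    """Baseline noise: SD of a blank region of the trace.

    By default the first 1 minute of the run (or the whole trace if shorter)
    is taken as the blank region; a linear trend is removed first so slow
    baseline drift does not inflate the estimate.
    """
    t = chrom.time
    if window is None:
        window = (float(t[0]), float(min(t[0] + 1.0, t[-1])))
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError("blank window spans fewer than 3 samples")
    y = chrom.channel(channel)[mask]
    x = t[mask]
    slope, intercept = np.polyfit(x, y, 1)
    return float(np.std(y - (slope * x + intercept), ddof=1))


def en_value(x_a: float, u_a: float, x_b: float, u_b: float) -> float:
    """Normalized error between two results with expanded uncertainties.

    En = |x_a - x_b| / sqrt(U_a^2 + U_b^2); symmetric in its arguments.
    """
    denom = math.hypot(u_a, u_b)
    if denom == 0:
        raise ValueError("both uncertainties are zero; En undefined")
    return abs(x_a - x_b) / denom


def en_consistent(x_a: float, u_a: float, x_b: float, u_b: float) -> bool:
    """True when the two results agree within expanded uncertainties (En < 1)."""
    return en_value(x_a, u_a, x_b, u_b) < 1.0


@dataclass(frozen=True)
class UncertainResult:
    """A value with its combined and expanded standard uncertainty."""

    value: float
    combined: float
    k: float
    budget: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("coverage factor k must be positive")

    @property
    def expanded(self) -> float:
        return self.k * self.combined


def propagate_uncertainty(
    func: Callable[..., float],
    values: Mapping[str, float],
    uncertainties: Mapping[str, float],
    k: float = 2.0,
    method: str = "taylor",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> UncertainResult:
    """Combine input standard uncertainties through a measurement function.

    ``func`` is called with the inputs as keyword arguments. Inputs are
    treated as uncorrelated.

    method="taylor"
        First-order GUM propagation: sensitivities by central differences
        with a relative step of 1e-6 (absolute 1e-6 for zero-valued
        inputs); combined uncertainty is the quadrature sum of
        |dy/dx_i| * u_i. The returned budget lists each input's value,
        standard uncertainty, sensitivity and contribution.
    method="mc"
        Monte-Carlo propagation: inputs drawn independently from
        Normal(value, u); the combined uncertainty is the SD of the
        propagated outputs and the reported value stays the deterministic
        func(values) (the MC mean is in the budget).
    """
    bad = [n for n, u in uncertainties.items() if u < 0]
    if bad:
        raise ValueError(f"negative uncertainty for input(s) {bad}")
    unknown = set(uncertainties) - set(values)
    if unknown:
        raise ValueError(f"uncertainties given for unknown inputs {sorted(unknown)}")
    central = float(func(**values))
    if method == "taylor":
        rows = []
        total_var = 0.0
        for name, x in values.items():
            u = float(uncertainties.get(name, 0.0))
            if u == 0.0:
                rows.append((name, x, 0.0, 0.0, 0.0))
                continue
            h = abs(x) * 1e-6 if x != 0 else 1e-6
            hi = dict(values, **{name: x + h})
            lo = dict(values, **{name: x - h})
            sens = (float(func(**hi)) - float(func(**lo))) / (2.0 * h)
            if not math.isfinite(sens):
                raise ValueError(f"non-finite sensitivity for input {name!r}")
            contrib = sens * u
            total_var += contrib * contrib
            rows.append((name, x, u, sens, abs(contrib)))
        budget = pd.DataFrame(
            rows, columns=["input", "value", "u", "sensitivity", "contribution"]
        )
        return UncertainResult(value=central, combined=math.sqrt(total_var), k=k, budget=budget)
    if method == "mc":
        rng = np.random.default_rng(seed)
        draws = {
            name: rng.normal(x, uncertainties.get(name, 0.0), size=n_draws)
            for name, x in values.items()
        }
        out = np.empty(n_draws)
        vec = np.vectorize(lambda *args: func(**dict(zip(values.keys(), args))))
        out = vec(*draws.values())
        budget = pd.DataFrame(
            {"input": ["mc_mean", "mc_draws"], "value": [float(np.mean(out)), n_draws],
             "u": [np.nan, np.nan], "sensitivity": [np.nan, np.nan],
             "contribution": [np.nan, np.nan]}
        )
        return UncertainResult(
            value=central, combined=float(np.std(out, ddof=1)), k=k, budget=budget
        )
    raise ValueError(f"unknown method {method!r}; expected 'taylor' or 'mc'")


@dataclass(frozen=True)
class PrecisionReport:
    """Intra-group (per-day) RSDs plus the overall across-all RSD, in %."""

    per_group: dict[str, float]
    overall: float
    between_group: float


def precision_report(groups: Mapping[str, Sequence[float]]) -> PrecisionReport:
    """Intra-day and inter-day precision from day-grouped estimates.

    ``per_group`` holds each day's own RSD (intra-day precision);
    ``overall`` is the RSD of all values pooled together (the inter-day
    figure as usually reported for a replicated-days design); and
    ``between_group`` is the RSD of the group means.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {}
    all_values: list[float] = []
    means: list[float] = []
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        per_group[str(name)] = rsd(arr)
        all_values.extend(arr.tolist())
        means.append(float(arr.mean()))
    return PrecisionReport(
        per_group=per_group,
        overall=rsd(all_values),
        between_group=rsd(means) if len(means) > 1 else 0.0,
    )
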