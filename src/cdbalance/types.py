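"""Domain types for the CD chiral-balance quantitation pipeline.

Concentrations are carried as mass fractions in mg/g throughout: enantiomers
share a molar mass, so the detector sensitivity ``K`` absorbs the conversion
from molar concentration and every solver works directly on mass fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnantiomerMix",
    "DetectorModel",
    "CDMeasurement",
    "BracketStandards",
    "Chromatogram",
    "Peak",
    "ProteinSpec",
    "GravimetricPrep",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class EnantiomerMix:
    """Concentrations of the two enantiomers in one solution.

    Parameters
    ----------
    c_l, c_d
        Mass fractions (mg/g) of the L- and D-form. Both must be
        non-negative and finite.
    """

    c_l: float
    c_d: float

    def __post_init__(self) -> None:
        for name in ("c_l", "c_d"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def delta(self) -> float:
        """Chiral imbalance c_L - c_D (mg/g), the quantity the detector sees."""
        return self.c_l - self.c_d


@dataclass(frozen=True)
class DetectorModel:
    """Linear CD detector response I = K * (c_L - c_D) + b.

    Parameters
    ----------
    k
        Sensitivity in signal units per mg/g; must be nonzero. Physically
        this is the anisotropy (eps_L - eps_D) times the path length, with
        the molar-to-mass conversion absorbed.
    b
        Signal offset (signal units); zero for a perfectly zeroed instrument.
    sigma
        Additive noise standard deviation (signal units) at a digital
        integration time of 1 s; >= 0. Used only by the simulator.
    """

    k: float
    b: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k", "b", "sigma"):
            _require_finite(name, getattr(self, name))
        if self.k == 0:
            raise ValueError("detector sensitivity k must be nonzero")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class CDMeasurement:
    """One CD signal reading (or integrated peak area) with a replicate label."""

    intensity: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        _require_finite("intensity", self.intensity)


@dataclass(frozen=True)
class BracketStandards:
    """A lower and a higher standard straddling the sample signal.

    Each standard is an ``(EnantiomerMix, CDMeasurement)`` pair. The two
    standards must differ both in chiral imbalance (c_L - c_D) and in
    measured intensity, otherwise the bracket cannot be inverted.
    """

    low: tuple[EnantiomerMix, CDMeasurement]
    high: tuple[EnantiomerMix, CDMeasurement]

    def __post_init__(self) -> None:
        if self.low[0].delta == self.high[0].delta:
            raise ValueError(
                "bracket standards have identical chiral imbalance c_L - c_D"
            )
        if self.low[1].intensity == self.high[1].intensity:
            raise ValueError("bracket standards have identical measured intensity")


@dataclass
class Chromatogram:
    """Sampled chromatogram with a DAD absorbance and a CD channel.

    ``time`` is in minutes and must be strictly increasing with at least
    10 samples; the two channels must match its length. DAD is in mAU,
    the CD channel in detector signal units.
    """

    time: np.ndarray
    dad: np.ndarray
    cd: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dad = np.asarray(self.dad, dtype=float)
        self.cd = np.asarray(self.cd, dtype=float)
        if self.time.ndim != 1 or self.time.size < 10:
            raise ValueError("chromatogram needs a 1-D time axis with >= 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.dad.shape != self.time.shape or self.cd.shape != self.time.shape:
            raise ValueError("channel lengths must match the time axis")

    def channel(self, name: str) -> np.ndarray:
        if name not in ("dad", "cd"):
            raise ValueError(f"unknown channel {name!r}; expected 'dad' or 'cd'")
        return getattr(self, name)


@dataclass(frozen=True)
class Peak:
    """An integrated chromatographic peak.

    ``area`` is baseline-corrected and signed (signal·min): L-enantiomer CD
    peaks are positive, D-enantiomer peaks negative under the default sign
    convention. ``half_height_width`` is the full width at half of the apex
    height, in minutes.
    """

    apex_time: float
    area: float
    height: float
    half_height_width: float
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.apex_time < self.end):
            raise ValueError("peak apex must lie inside its integration bounds")
        _require_finite("area", self.area)
        if self.half_height_width <= 0:
            raise ValueError("half-height width must be positive")


@dataclass(frozen=True)
class ProteinSpec:
    """Sequence-derived constants needed to convert hydrolysate Phe to protein.

    ``m_protein`` and ``m_phe`` are average molar masses (g/mol); ``n_phe``
    is the number of phenylalanine residues across all chains.
    """

    name: str
    sequences: tuple[str, ...]
    n_phe: int
    m_protein: float
    m_phe: float

    def __post_init__(self) -> None:
        joined = "".join(self.sequences)
        if self.n_phe != joined.count("F"):
            raise ValueError(
                f"n_phe={self.n_phe} does not match sequence Phe count "
                f"{joined.count('F')}"
            )
        if self.m_protein <= 0 or self.m_phe <= 0:
            raise ValueError("molar masses must be positive")


@dataclass(frozen=True)
class GravimetricPrep:
    """The weighing chain for one hydrolysate ampoule.

    Parameters
    ----------
    m_total
        Total mass of the hydrolysate mixture in the ampoule (sample
        solution + internal standard + acid), mg.
    m_sample
        Mass of the sample solution aliquot added to the ampoule, mg.
    m_diluted
        Total mass of solid protein plus diluent after dilution, mg.
    m_solid
        Mass of solid protein weighed into the dilution, mg.
    """

    m_total: float
    m_sample: float
    m_diluted: float
    m_solid: float

    def __post_init__(self) -> None:
        for name in ("m_total", "m_sample", "m_diluted", "m_solid"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.m_sample > self.m_total:
            raise ValueError("sample aliquot cannot exceed the total hydrolysate mass")
        if self.m_solid > self.m_diluted:
            raise ValueError("solid mass cannot exceed the diluted total mass")
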