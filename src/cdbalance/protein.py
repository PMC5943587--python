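"""Protein mass fraction from hydrolysate phenylalanine.

Natural proteins contain only L-amino acids, so after complete acid
hydrolysis the L-Phe content of the hydrolysate carries the protein amount.
With the L-Phe mass fraction ``c_L`` measured against a D-Phe internal
standard, the mass fraction of protein in the weighed solid is

    c_protein = c_L * M_protein * M * m / (m_sample * n * M_phe * m_solid)

where n is the number of Phe residues per molecule, M_protein and M_phe are
average molar masses, M is the total hydrolysate mass in the ampoule,
m_sample the sample-solution aliquot weighed into it, and m / m_solid the
gravimetric dilution of the weighed solid protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

from .calibration import solve_bracket
from .chromatography import integrate_peak
from .types import (
    BracketStandards,
    Chromatogram,
    EnantiomerMix,
    GravimetricPrep,
    ProteinSpec,
)

__all__ = [
    "HYDROGEN_MASS",
    "protein_constants_from_sequences",
    "protein_constants_from_fasta",
    "protein_mass_fraction",
    "pins_pipeline",
    "summarize_mass_fraction_grid",
    "PinsResult",
]

HYDROGEN_MASS = 1.00794  # average, g/mol; two lost per disulfide bond

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Average molar mass of free phenylalanine (g/mol), residue + one water.
M_PHE = float(molecular_weight("F", seq_type="protein"))


def protein_constants_from_sequences(
    sequences: Sequence[str], name: str = "protein", n_disulfides: int = 0
) -> ProteinSpec:
    """Build a :class:`ProteinSpec` from one-letter chains.

    The average molar mass is the sum of residue masses plus one water per
    chain, minus two hydrogens per disulfide bond when a bond count is
    supplied.
    """
    seqs = tuple(s.strip().upper() for s in sequences)
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("empty protein sequence")
    for s in seqs:
        bad = set(s) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"unknown residue code(s) {sorted(bad)} in sequence")
    mass = sum(molecular_weight(s, seq_type="protein") for s in seqs)
    mass -= 2.0 * HYDROGEN_MASS * n_disulfides
    return ProteinSpec(
        name=name,
        sequences=seqs,
        n_phe="".join(seqs).count("F"),
        m_protein=float(mass),
        m_phe=M_PHE,
    )


def protein_constants_from_fasta(
    fasta: str | Path | IO[str], name: str | None = None, n_disulfides: int = 0
) -> ProteinSpec:
    """Read all records of a FASTA file as the chains of one protein."""
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise ValueError("no sequences found in FASTA input")
    return protein_constants_from_sequences(
        [str(r.seq) for r in records],
        name=name or records[0].id,
        n_disulfides=n_disulfides,
    )


def protein_mass_fraction(
    c_l: float,
    spec: ProteinSpec,
    prep: GravimetricPrep,
    recovery: float = 1.0,
    racemization: float = 0.0,
) -> float:
    """Protein-in-solid mass fraction (g/g) from the hydrolysate c_L (mg/g).

    ``recovery`` is an optional hydrolysis recovery factor for Phe (fraction
    of the residue surviving hydrolysis intact, default 1.0), and
    ``racemization`` the fraction of liberated L-Phe converted to D-Phe
    during hydrolysis (default 0.0). Both default to the ideal values; acid
    hydrolysis must be characterised before trusting non-defaults.
    """
    if c_l < 0:
        raise ValueError("c_l must be >= 0")
    if not 0 < recovery <= 1:
        raise ValueError("recovery must be in (0, 1]")
    if not 0 <= racemization < 1:
        raise ValueError("racemization fraction must be in [0, 1)")
    effective = recovery * (1.0 - racemization)
    c_l_gg = c_l / 1000.0  # mg/g -> g/g so the result is in g/g
    return (
        c_l_gg
        * spec.m_protein
        * prep.m_total
        * prep.m_diluted
        / (prep.m_sample * spec.n_phe * spec.m_phe * prep.m_solid)
        / effective
    )


@dataclass(frozen=True)
class PinsResult:
    """Per-vial/sample protein mass fractions with their summary."""

    table: pd.DataFrame  # index: vial, columns: sample labels, values g/g
    c_l_table: pd.DataFrame  # the hydrolysate c_L (mg/g) behind each cell
    mean: float
    rsd: float


def summarize_mass_fraction_grid(table: pd.DataFrame) -> tuple[float, float]:
    """Mean (g/g) and RSD (%) of all entries of a vial-by-sample grid."""
    values = table.to_numpy(dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 mass-fraction values to summarize")
    mean = float(values.mean())
    rsd = float(100.0 * values.std(ddof=1) / mean)
    return mean, rsd


def pins_pipeline(
    sample_chromatograms: Mapping[str, Mapping[str, Chromatogram]],
    bracket_low: tuple[EnantiomerMix, Chromatogram],
    bracket_high: tuple[EnantiomerMix, Chromatogram],
    window: tuple[float, float],
    spec: ProteinSpec,
    preps: Mapping[str, GravimetricPrep],
    sample_c_d: float,
    channel: str = "cd",
) -> PinsResult:
    """End-to-end hydrolysate quantitation: integrate, bracket, convert.

    For each vial (outer key) and injection (inner key) the CD peak in
    ``window`` is integrated; the areas of the two bracket standards anchor
    a bracket calibration that converts each sample area to a hydrolysate
    L-Phe mass fraction; the gravimetric chain of the vial then converts
    that to a protein-in-solid mass fraction. Peak areas replace raw
    intensities throughout — the calibration algebra is identical because
    area is proportional to the injected chiral imbalance.
    """
    low_mix, low_chrom = bracket_low
    high_mix, high_chrom = bracket_high
    a_low = integrate_peak(low_chrom, channel, window).area
    a_high = integrate_peak(high_chrom, channel, window).area
    brackets = BracketStandards(low=(low_mix, _cd(a_low)), high=(high_mix, _cd(a_high)))

    rows: dict[str, dict[str, float]] = {}
    c_l_rows: dict[str, dict[str, float]] = {}
    for vial, injections in sample_chromatograms.items():
        if vial not in preps:
            raise KeyError(f"no gravimetric prep for vial {vial!r}")
        rows[vial] = {}
        c_l_rows[vial] = {}
        for label, chrom in injections.items():
            area = integrate_peak(chrom, channel, window).area
            c_l = solve_bracket(area, brackets, sample_c_d)
            # noise can push an estimate below zero; a concentration cannot be
            c_l = max(c_l, 0.0)
            rows[vial][label] = protein_mass_fraction(c_l, spec, preps[vial])
            c_l_rows[vial][label] = c_l
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    c_l_table = pd.DataFrame.from_dict(c_l_rows, orient="index").sort_index()
    mean, rsd = summarize_mass_fraction_grid(table)
    return PinsResult(table=table, c_l_table=c_l_table, mean=mean, rsd=rsd)


def _cd(intensity: float):
    from .types import CDMeasurement

    return CDMeasurement(intensity=intensity)
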