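"""CSV and FASTA I/O with schema validation.

All tabular I/O is CSV with a single header line and period decimal
separator. Readers validate the column set and every value, and report
errors with the 1-based file line number (header = line 1) so malformed
inputs fail loudly and precisely.

Schemas
-------
standards:    role (low_std|high_std|sample), c_L, c_D, intensity
chromatogram: time_min, dad_mau, cd_signal
prep:         vial, M_mg, m_sample_mg, m_mg, m_ins_mg
purity areas: sample, area_d, area_l
mass-fraction grid: vial, then one column per sample
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BracketStandards,
    CDMeasurement,
    Chromatogram,
    EnantiomerMix,
    GravimetricPrep,
)

__all__ = [
    "SchemaError",
    "read_standards_csv",
    "standards_to_brackets",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_prep_csv",
    "read_purity_areas_csv",
    "read_mass_fraction_grid",
]

STANDARD_ROLES = ("low_std", "high_std", "sample")


class SchemaError(ValueError):
    """A CSV file does not match its documented schema."""


def _read_csv(path, expected: set[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty {name} file") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from None
    got = set(df.columns)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            f"{path}, line 1: {name} columns must be {sorted(expected)}; "
            f"missing {missing}, unexpected {extra}"
        )
    return df


def _numeric(df: pd.DataFrame, cols, path, allow_negative=()) -> pd.DataFrame:
    for col in cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[~np.isfinite(values)]
        if len(bad):
            line = int(bad[0]) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}, line {line}: non-numeric value {df[col].iloc[bad[0]]!r} "
                f"in column {col!r}"
            )
        if col not in allow_negative and (values < 0).any():
            line = int(values.index[values < 0][0]) + 2
            raise SchemaError(f"{path}, line {line}: negative value in column {col!r}")
        df[col] = values
    return df


def read_standards_csv(path) -> pd.DataFrame:
    """Read a standards/samples intensity table.

    Columns: role (one of low_std, high_std, sample), c_L, c_D (mg/g) and
    intensity (signal units; may be negative for D-rich mixtures).
    """
    df = _read_csv(path, {"role", "c_L", "c_D", "intensity"}, "standards")
    for idx, role in df["role"].items():
        if role not in STANDARD_ROLES:
            raise SchemaError(
                f"{path}, line {idx + 2}: role {role!r} not one of {STANDARD_ROLES}"
            )
    return _numeric(df, ["c_L", "c_D", "intensity"], path, allow_negative=("intensity",))


def standards_to_brackets(df: pd.DataFrame) -> tuple[BracketStandards, pd.DataFrame]:
    """Split a standards table into bracket standards and the sample rows.

    Replicate standard rows of the same role are averaged (mean intensity,
    mean composition) before building the bracket.
    """

    def _mean_standard(role: str):
        rows = df[df["role"] == role]
        if rows.empty:
            raise SchemaError(f"missing required {role!r} row(s) in standards table")
        mix = EnantiomerMix(c_l=float(rows["c_L"].mean()), c_d=float(rows["c_D"].mean()))
        return mix, CDMeasurement(float(rows["intensity"].mean()))

    brackets = BracketStandards(
        low=_mean_standard("low_std"), high=_mean_standard("high_std")
    )
    samples = df[df["role"] == "sample"].reset_index(drop=True)
    if samples.empty:
        raise SchemaError("no sample rows in standards table")
    return brackets, samples


def read_chromatogram_csv(path) -> Chromatogram:
    """Read a chromatogram (time_min, dad_mau, cd_signal)."""
    df = _read_csv(path, {"time_min", "dad_mau", "cd_signal"}, "chromatogram")
    df = _numeric(
        df, ["time_min", "dad_mau", "cd_signal"], path,
        allow_negative=("dad_mau", "cd_signal"),
    )
    return Chromatogram(
        time=df["time_min"].to_numpy(),
        dad=df["dad_mau"].to_numpy(),
        cd=df["cd_signal"].to_numpy(),
    )


def write_chromatogram_csv(chrom: Chromatogram, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_min": chrom.time, "dad_mau": chrom.dad, "cd_signal": chrom.cd}
    ).to_csv(path, index=False)
    return path


def read_prep_csv(path) -> dict[str, GravimetricPrep]:
    """Read gravimetric prep chains keyed by vial label."""
    df = _read_csv(
        path, {"vial", "M_mg", "m_sample_mg", "m_mg", "m_ins_mg"}, "prep"
    )
    df = _numeric(df, ["M_mg", "m_sample_mg", "m_mg", "m_ins_mg"], path)
    preps = {}
    for idx, row in df.iterrows():
        try:
            preps[str(row["vial"])] = GravimetricPrep(
                m_total=row["M_mg"],
                m_sample=row["m_sample_mg"],
                m_diluted=row["m_mg"],
                m_solid=row["m_ins_mg"],
            )
        except ValueError as exc:
            raise SchemaError(f"{path}, line {idx + 2}: {exc}") from None
    return preps


def read_purity_areas_csv(path) -> pd.DataFrame:
    """Read an enantiopurity area table (sample, area_d, area_l)."""
    df = _read_csv(path, {"sample", "area_d", "area_l"}, "purity areas")
    return _numeric(df, ["area_d", "area_l"], path)


def read_mass_fraction_grid(path) -> pd.DataFrame:
    """Read a vial-by-sample mass-fraction grid (first column: vial)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty mass-fraction file") from None
    if df.columns[0] != "vial":
        raise SchemaError(f"{path}, line 1: first column must be 'vial'")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}, line 1: no sample columns")
    df = df.set_index("vial")
    df = _numeric(df.reset_index(drop=True), list(df.columns), path).set_axis(
        df.index
    )
    return df
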