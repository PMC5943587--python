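"""Transcribed reference measurements used as validation fixtures.

Two small published validation datasets for the HPLC-CD chiral-balance
method are transcribed here verbatim so the reporting paths can be checked
against known summaries:

* a D-phenylalanine optical-purity check — six replicate chiral-column
  injections, each giving a D-Phe (major) and L-Phe (minor) peak area,
  with a reported per-sample L-Phe content of 0.070-0.071 %, mean 0.071 %;
* a porcine-insulin solid mass-fraction determination — three hydrolysate
  vials analysed six times each (18 values, g/g), with a reported mean of
  0.922 g/g and RSD of 1.5 %.

``write_table_fixtures`` serialises both to CSV for use as file-based
fixtures and round-trip tests.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "DPHE_PURITY_AREAS",
    "PINS_MASS_FRACTIONS",
    "dphe_purity_frame",
    "pins_mass_fraction_frame",
    "write_table_fixtures",
]

#: (D-Phe area, L-Phe area) per replicate injection of the D-Phe material.
DPHE_PURITY_AREAS: tuple[tuple[float, float], ...] = (
    (22466.9, 15.7),
    (22416.4, 15.8),
    (22421.9, 16.0),
    (22420.7, 16.0),
    (22475.8, 15.8),
    (22711.7, 16.1),
)

#: Porcine-insulin mass fractions (g/g): rows = vials 1-3, cols = samples 1-6.
PINS_MASS_FRACTIONS: tuple[tuple[float, ...], ...] = (
    (0.9024, 0.9226, 0.9335, 0.9051, 0.9391, 0.9029),
    (0.9159, 0.9208, 0.9269, 0.9281, 0.9096, 0.9312),
    (0.9139, 0.9397, 0.9482, 0.9032, 0.9304, 0.9267),
)


def dphe_purity_frame() -> pd.DataFrame:
    """The purity areas as a DataFrame with columns sample, area_d, area_l."""
    return pd.DataFrame(
        [
            {"sample": i + 1, "area_d": d, "area_l": l}
            for i, (d, l) in enumerate(DPHE_PURITY_AREAS)
        ]
    )


def pins_mass_fraction_frame() -> pd.DataFrame:
    """The insulin grid as a DataFrame: index vial_1..3, columns sample_1..6."""
    df = pd.DataFrame(
        list(PINS_MASS_FRACTIONS),
        index=[f"vial_{i + 1}" for i in range(len(PINS_MASS_FRACTIONS))],
        columns=[f"sample_{j + 1}" for j in range(len(PINS_MASS_FRACTIONS[0]))],
    )
    df.index.name = "vial"
    return df


def write_table_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write both reference tables as CSV fixture files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    purity_path = out / "dphe_purity_areas.csv"
    pins_path = out / "pins_mass_fractions.csv"
    dphe_purity_frame().to_csv(purity_path, index=False)
    pins_mass_fraction_frame().to_csv(pins_path, index=True, index_label="vial")
    return {"dphe_purity": purity_path, "pins_mass_fractions": pins_path}
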