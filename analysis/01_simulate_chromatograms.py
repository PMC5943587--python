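#!/usr/bin/env python
"""Simulate the two separations the quantitation workflow relies on:
a chiral separation of the phenylalanine enantiomers (for the optical-purity
check) and an achiral separation of a hydrolysate-like mixture in which L-
and D-Phe co-elute as one CD peak. Writes the chromatogram CSVs plus the
chiral-pair resolution to results/chromatograms/."""

from pathlib import Path

import pandas as pd

from cdbalance import (
    DetectorModel,
    PeakSpec,
    integrate_peak,
    resolution,
    simulate_chromatogram,
)
from cdbalance.io import write_chromatogram_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "chromatograms"
OUT.mkdir(parents=True, exist_ok=True)

det = DetectorModel(k=200.0, b=0.0, sigma=0.3)

# chiral column: D-Phe elutes before L-Phe, fully resolved
chiral = simulate_chromatogram(
    [
        PeakSpec(name="D-Phe", apex_time=4.2, sigma_t=0.06, c_d=0.05),
        PeakSpec(name="L-Phe", apex_time=6.8, sigma_t=0.08, c_l=0.05),
    ],
    det, rng=0, dt=0.02,
)
write_chromatogram_csv(chiral, OUT / "chiral_dl_phe.csv")
d_pk = integrate_peak(chiral, "cd", (3.6, 4.8))
l_pk = integrate_peak(chiral, "cd", (6.0, 7.6))
rs = resolution(d_pk, l_pk)

# achiral column: Phe enantiomers co-elute; neighbours elute nearby
hydrolysate = simulate_chromatogram(
    [
        PeakSpec(name="early", apex_time=2.1, sigma_t=0.07, c_l=0.30),
        PeakSpec(name="neighbour", apex_time=5.0, sigma_t=0.08, c_l=0.20),
        PeakSpec(name="Phe", apex_time=6.0, sigma_t=0.08, c_l=0.172, c_d=0.009),
    ],
    det, rng=1, dt=0.02,
)
write_chromatogram_csv(hydrolysate, OUT / "achiral_hydrolysate.csv")
phe_pk = integrate_peak(hydrolysate, "cd", (5.5, 6.5))

pd.DataFrame(
    [
        {"quantity": "chiral_resolution_Rs", "value": round(rs, 2)},
        {"quantity": "d_phe_area", "value": round(d_pk.area, 3)},
        {"quantity": "l_phe_area", "value": round(l_pk.area, 3)},
        {"quantity": "hydrolysate_phe_cd_area", "value": round(phe_pk.area, 3)},
    ]
).to_csv(OUT / "peak_summary.csv", index=False)

print(f"chiral D/L-Phe resolution Rs = {rs:.2f} (baseline separation needs >= 1.5)")
print(f"hydrolysate Phe CD area = {phe_pk.area:.3f} signal*min "
      f"(signed by the net L excess)")
print(f"wrote chromatograms and peak_summary.csv to {OUT}")
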