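#!/usr/bin/env python
"""Simulated method-performance study: bias and RSD of bracket-calibrated
L-Phe quantitation across the working range, for both internal-standard
designs (fixed amount vs matched "variable" amount), plus the LOD/LOQ
implied by the detector noise. Writes results/method_performance.csv."""

from pathlib import Path

import pandas as pd

from cdbalance import SimDesign, run_method_validation

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

frames = []
for mode in ("fixed", "variable"):
    design = SimDesign(
        levels=(0.1, 0.3, 0.5, 0.8, 1.0, 1.2),
        is_mode=mode,
        relative_noise=0.005,
        n_replicates=6,
        seed=0,
    )
    table = run_method_validation(design)
    table.insert(0, "is_mode", mode)
    frames.append(table)
    print(f"\n{mode} internal standard:")
    print(table[["nominal_mg_g", "bias_pct", "rsd_pct"]]
          .round(3).to_string(index=False))

result = pd.concat(frames, ignore_index=True)
result.to_csv(OUT / "method_performance.csv", index=False)

lod, loq = frames[0].attrs["lod_mg_g"], frames[0].attrs["loq_mg_g"]
pd.DataFrame(
    {"statistic": ["lod_mg_g", "loq_mg_g"], "value": [lod, loq]}
).to_csv(OUT / "lod_loq.csv", index=False)

worst_bias = result["bias_pct"].abs().max()
worst_rsd = result["rsd_pct"].max()
print(f"\nworst |bias| = {worst_bias:.3f} %, worst RSD = {worst_rsd:.3f} % "
      f"over 0.1-1.2 mg/g (both designs)")
print(f"LOD = {lod * 1000:.2f} ug/g, LOQ = {loq * 1000:.2f} ug/g "
      f"(3x and 10x the baseline noise at DIT 32 s)")
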