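"""Hippocampal detection under a simultaneous cortical activation.

Adds a 3 cm^2 visual-cortex patch whose Gaussian envelope peaks D_t ms
before the hippocampal one; sweeping D_t sets the cortical/subcortical
amplitude ratio R_c at the evaluation instant.  Reports, per operator, the
detection rate (a distinct local maximum within 4 cm of the truth at half
the map maximum), the thalamic ghost-source rate, and the relative shares
of estimated activation in hippocampus/amygdala/thalamus — and how those
shares vary when the cortical folding pattern (anatomy seed) changes.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from dba.anatomy import build_anatomy, build_sensors
from dba.forward import compute_gain
from dba.montecarlo import ExperimentGrid, run_grid
from dba.simulate import d_t_for_rc

OUT = Path(__file__).resolve().parent.parent / "results" / "two_source"
OUT.mkdir(parents=True, exist_ok=True)

sensors = build_sensors()
dts = (60.0,) + tuple(d_t_for_rc(rc) for rc in (0.25, 0.5, 0.75, 1.0))

def run_for(anatomy_seed):
    space = build_anatomy(seed=anatomy_seed, mesh_resolution="small")
    gain = compute_gain(space, sensors)
    grid = ExperimentGrid(structures=("hippocampus",), patch_sizes=(3.0,),
                          noise_seeds=(0, 1, 2), seed_stride=4,
                          with_cortical=True, d_t_values_ms=dts,
                          sloreta_unweighted=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_grid(grid, space, gain)

result = run_for(0)
result.results.to_csv(OUT / "cells_anatomy0.tsv", sep="\t", index=False)

print("reference model (anatomy seed 0):")
curves = []
for m in ("wmne", "dspm", "sloreta"):
    det = result.detection_curve(m).assign(method=m)
    ghost = result.ghost_rate(m)
    det = det.merge(ghost, on="r_c")
    curves.append(det)
    print(f"  {m:8s} R_c:", [f"{r:.2f}" for r in det.r_c],
          "detect:", [f"{d:.2f}" for d in det.detection_rate],
          "ghost:", [f"{g:.2f}" for g in det.ghost_rate])
pd.concat(curves).to_csv(OUT / "detection_curves.tsv", sep="\t", index=False)

shares25 = (result.results[np.isclose(result.results.r_c, 0.25)]
            .groupby("method")[["prop_hippocampus", "prop_amygdala",
                                "prop_thalamus"]].mean().round(1))
print("\nstructure shares at R_c = 25% (reference model):")
print(shares25)

# sensitivity of the shares to the folding realization
rows = []
for aseed in (0, 17, 42, 63):
    r = result if aseed == 0 else run_for(aseed)
    s = (r.results[np.isclose(r.results.r_c, 0.25)]
         .groupby("method")["prop_hippocampus"].mean())
    for m, v in s.items():
        rows.append({"anatomy_seed": aseed, "method": m,
                     "hippocampal_share_rc25_pct": round(float(v), 1)})
var_df = pd.DataFrame(rows)
var_df.to_csv(OUT / "share_vs_anatomy_seed.tsv", sep="\t", index=False)
print("\nhippocampal share at R_c=25% across folding seeds "
      "(leakage geometry of the cortical patch matters):")
print(var_df.pivot(index="anatomy_seed", columns="method",
                   values="hippocampal_share_rc25_pct"))

(OUT / "summary.json").write_text(json.dumps({
    "d_t_values_ms": list(dts),
    "note": "detection references the global map maximum; shares are "
            "relative within the three subcortical structures"}, indent=2))
print(f"outputs -> {OUT}")
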