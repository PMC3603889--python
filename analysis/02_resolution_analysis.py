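"""Point-spread and cross-talk structure of the three inverse operators.

Builds wMNE (w=0.6), dSPM and sLORETA kernels on the reference model with a
resting-noise covariance, forms the resolution matrix R = K G, and averages
normalized PSF and CTF maps over the hippocampus.  Confirms numerically
that noise normalization rescales but never reshapes the cross-talk
functions, and that classical sLORETA pins every noiseless point source.
Writes per-source average maps under results/resolution/.
"""

import json
from pathlib import Path

import numpy as np

from dba.anatomy import build_anatomy, build_sensors
from dba.forward import compute_gain
from dba.inverse import (NoiseCovariance, estimate_noise_cov, kernel_family,
                         resolution_matrix, sloreta_kernel, wmne_kernel)
from dba.noise import NoiseModel, generate_noise
from dba.resolution import average_structure_map
from dba import io

OUT = Path(__file__).resolve().parent.parent / "results" / "resolution"
OUT.mkdir(parents=True, exist_ok=True)

space = build_anatomy(seed=0, mesh_resolution="small")
sensors = build_sensors()
gain = compute_gain(space, sensors)
noise = generate_noise(NoiseModel(seed=0), gain.n_sensors, 0.4)
cov = estimate_noise_cov(noise[:, :250])

# one shared depth-weighted kernel, three row-normalizations
fam = kernel_family(gain, cov, sloreta_unweighted=False)
res = {m: resolution_matrix(k, gain) for m, k in fam.items()}

summary = {}
for m in fam:
    for kind in ("psf", "ctf"):
        avg = average_structure_map(res[m], space, "hippocampus", kind=kind)
        io.save_map_tsv(OUT / f"hippocampus_avg_{kind}_{m}.tsv", space,
                        avg.values, value_name=kind)

rows = {m: np.abs(r.matrix) / np.abs(r.matrix).max(axis=1, keepdims=True)
        for m, r in res.items()}
ctf_diff = max(float(np.abs(rows["wmne"] - rows["dspm"]).max()),
               float(np.abs(rows["wmne"] - rows["sloreta"]).max()))
summary["ctf_shape_max_abs_diff"] = ctf_diff
print(f"CTF shape identity across operators: max |diff| = {ctf_diff:.2e} "
      "(rows of R are only rescaled by the normalizations)")

# where does hippocampal point spread land?
avg_psf = average_structure_map(res["wmne"], space, "hippocampus", kind="psf")
hip = space.indices("hippocampus")
outside = np.setdiff1d(np.arange(space.n_sources), hip)
by_struct = {n: float(avg_psf.values[space.structure_slices[n]].sum())
             for n in space.structure_slices}
total = sum(by_struct.values())
summary["wmne_avg_psf_share_pct"] = {n: 100 * v / total for n, v in by_struct.items()}
print("wMNE average hippocampal PSF mass by structure (%):",
      {n: round(100 * v / total, 1) for n, v in by_struct.items()})

# classical sLORETA: exact noiseless point localization
eye_cov = NoiseCovariance(np.eye(gain.n_sensors) * 1e-26, 100, 0.0)
ks = sloreta_kernel(wmne_kernel(gain, eye_cov, w=0.0), gain)
am = np.abs(ks.matrix @ gain.values).argmax(axis=0)
frac = float((am == np.arange(space.n_sources)).mean())
summary["sloreta_noiseless_exact_fraction"] = frac
print(f"classical sLORETA noiseless point-source exact localization: {frac:.3f}")

(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
print(f"outputs -> {OUT}")
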