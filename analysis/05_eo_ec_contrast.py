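"""Thalamo-cortical alpha modulation: eyes-open vs eyes-closed contrast.

Synthesizes block-designed resting recordings in which thalamic and
occipital sources carry a shared 10 Hz rhythm, three times stronger with
eyes closed, projects the band-passed blocks through the wMNE kernel, and
t-tests per-source alpha power across blocks with BH-FDR control.  Repeats
over seven seeds (emulating seven recording sessions) plus a null
calibration at modulation ratio 1.
"""

import json
from pathlib import Path

import numpy as np

from dba.anatomy import build_anatomy, build_sensors
from dba.eoec import alpha_contrast, synthesize_eo_ec
from dba.forward import compute_gain
from dba.inverse import estimate_noise_cov, kernel_family
from dba.noise import NoiseModel, generate_noise
from dba import io

OUT = Path(__file__).resolve().parent.parent / "results" / "eo_ec"
OUT.mkdir(parents=True, exist_ok=True)

space = build_anatomy(seed=0, mesh_resolution="small")
sensors = build_sensors()
gain = compute_gain(space, sensors)
nm = NoiseModel(sampling_rate_hz=250.0, alpha_peak_gain=0.0,
                sensor_white_sd=2e-13, seed=99)
cov = estimate_noise_cov(generate_noise(nm, gain.n_sensors, 1.0))
kernel = kernel_family(gain, cov)["wmne"]
thal = space.indices("thalamus")

summary = {"per_seed": []}
hits = 0
for seed in range(7):
    eo, ec = synthesize_eo_ec(space, gain, modulation_ratio=3.0, seed=seed)
    c = alpha_contrast(eo, ec, kernel)
    sig_thal = int(c.significant[thal].sum())
    hits += sig_thal > 0
    summary["per_seed"].append({"seed": seed,
                                "n_significant": int(c.significant.sum()),
                                "n_significant_thalamus": sig_thal})
    if seed == 0:
        io.save_map_tsv(OUT / "contrast_t_seed0.tsv", space, c.t, value_name="t")
        io.save_map_tsv(OUT / "contrast_q_seed0.tsv", space, c.q, value_name="q")
summary["thalamic_recovery_rate"] = hits / 7

null_fracs = []
for seed in range(7):
    eo, ec = synthesize_eo_ec(space, gain, modulation_ratio=1.0, seed=100 + seed)
    c = alpha_contrast(eo, ec, kernel)
    null_fracs.append(float(c.significant.mean()))
summary["null_mean_significant_fraction"] = float(np.mean(null_fracs))

print("EO/EC contrast, modulation ratio 3, seven seeds:")
for row in summary["per_seed"]:
    print(f"  seed {row['seed']}: {row['n_significant']} significant sources, "
          f"{row['n_significant_thalamus']} thalamic")
print(f"thalamic recovery rate: {summary['thalamic_recovery_rate']:.2f}")
print(f"null calibration (ratio 1): mean significant fraction "
      f"{summary['null_mean_significant_fraction']:.4f}")
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
print(f"outputs -> {OUT}")
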