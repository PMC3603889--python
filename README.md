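# dba — deep brain activity imaging with MEG minimum-norm operators

Can magnetoencephalography see the hippocampus, the amygdala, the thalamus?
Subcortical structures are far from the sensors and their cyto-architecture
partially cancels its own fields, so the common assumption is that MEG is
blind to them. This package implements a simulation framework to test that
assumption quantitatively: a structure-specific dipole model of deep brain
activity (DBA), a spherical-conductor MEG forward model, the three standard
minimum-norm inverse operators, resolution (point-spread / cross-talk)
analysis, and Monte Carlo estimation of dipole localization errors — all on
synthetic anatomy, so no subject data are required.

It is aimed at MEG/EEG methods researchers who want a self-contained,
fully seeded sandbox in which operator-level claims about deep sources can
be verified or falsified.

## The model in brief

Each structure is tiled with current dipoles. Surface structures (neocortex
analog, hippocampal envelope) orient dipoles along the local surface
normal; closed-field nuclei (thalamus, putamen) and the amygdala use random
orientations. A dipole moment density (DMD) sets per-dipole currents
`q_i = DMD · A_i` so that a patch of `a` cm² (or cm³) carries
`DMD · a · 100` nAm — e.g. a 1 cm² hippocampal patch (DMD 0.4) totals
40 nAm, a 1 cm³ thalamic patch (DMD 0.025) 2.5 nAm.

Sensor data follow `M = G q(t) + noise`, with `G` the Sarvas spherical-
conductor lead field for 151 radial magnetometers. Estimates come from
three linear kernels built on `K = S Gᵗ (G S Gᵗ + λ²C)⁻¹`:

* **wMNE** — depth weighting `S_ii = ‖G3_i‖_F^{−2w}`, `w = 0.6`,
  `λ² = tr(GSGᵗ)/(tr(C)·snr²)`, `snr = 3`;
* **dSPM** — wMNE rows normalized by their noise sensitivity
  `sqrt((KCKᵗ)_ii)`;
* **sLORETA** — rows standardized by `sqrt(R_ii)`, `R = K G` the resolution
  matrix (classical, unweighted base kernel: noiseless point sources are
  then localized exactly).

Localization quality is summarized by `DLE_g` (distance from the
50%-thresholded map's gravity centre to the truth) and `DLE_m` (distance
from the map maximum to the truth), both in cm.

## Worked example

```python
import numpy as np
from dba import (build_anatomy, build_sensors, compute_gain, generate_noise,
                 NoiseModel, SimulationConfig, estimate_noise_cov,
                 kernel_family, grow_patch, simulate_recording, dle_g, dle_m)

space = build_anatomy(seed=0, mesh_resolution="small")   # ~1000 dipoles
sensors = build_sensors()                                # 151-channel helmet
gain = compute_gain(space, sensors)

patch = grow_patch(space, int(space.indices("hippocampus")[5]), 3.0)
print(f"patch: {len(patch.member_indices)} dipoles, "
      f"{patch.total_extent:.2f} cm^2, {patch.total_current:.1f} nAm")

noise = generate_noise(NoiseModel(seed=0), sensors.n_sensors, 0.4)
rec = simulate_recording(gain, [patch], SimulationConfig(snr_energy=20.0),
                         noise=noise)
cov = estimate_noise_cov(noise[:, :rec.baseline_samples])
kernels = kernel_family(gain, cov)

truth = space.positions[patch.seed_index]
snap = rec.data[:, rec.subcortical_peak_sample]
for name, k in kernels.items():
    est = k.apply(snap)
    print(f"{name:8s} DLE_g = {dle_g(est, space.positions, truth):.2f} cm, "
          f"DLE_m = {dle_m(est, space.positions, truth):.2f} cm")
```

Output:

```
patch: 42 dipoles, 3.07 cm^2, 122.9 nAm
wmne     DLE_g = 0.72 cm, DLE_m = 3.02 cm
dspm     DLE_g = 2.05 cm, DLE_m = 0.96 cm
sloreta  DLE_g = 1.29 cm, DLE_m = 1.54 cm
```

A 3 cm² hippocampal patch carrying ~123 nAm at energy SNR 20 is localized
to within a centimetre or two: deep sources are weak, not invisible. The
pattern is characteristic — wMNE has the best gravity-centre error but
misplaces its *maximum* superficially (3 cm), while the noise-normalized
operators keep the maximum closer at the cost of a broader map; medians
over all hippocampal seeds (see `analysis/03`) are 0.4–0.5 cm for DLE_g.

## Analysis pipeline

The study itself is organized as numbered drivers over the library, each
writing tables under `results/`:

| script | question it answers |
|--------|---------------------|
| `analysis/01_build_model.py` | how visible is each structure? (sensitivity medians; cortex ≈ 13x thalamus) |
| `analysis/02_resolution_analysis.py` | where do PSF/CTF maps leak? (CTF shape identical across operators) |
| `analysis/03_single_source_mc.py` | localization errors per structure, size, operator (hippocampal median DLE_g ≈ 0.4–0.5 cm) |
| `analysis/04_two_source_detection.py` | detection under a cortical co-activation vs the amplitude ratio R_c; sLORETA's thalamic ghost sources |
| `analysis/05_eo_ec_contrast.py` | can a 3x thalamic alpha modulation be recovered with FDR-controlled t-tests? (yes, 7/7 seeds) |

A thin CLI mirrors the library for shell use: `dba make-anatomy`,
`dba forward`, `dba simulate`, `dba invert`, `dba resolution`, `dba mc`,
`dba eoec`, `dba dle` (see `dba --help`).

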