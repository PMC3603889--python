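# Methods

This note documents the models and numerical choices behind `dba`, a
simulation framework for asking how well MEG minimum-norm source imaging can
localize deep brain activity — hippocampus, amygdala and central grey
nuclei — when those structures are modelled with realistic geometry, dipole
orientations and current densities.

## The deep-brain-activity source model

Neural currents are represented by current dipoles (CDs) tiling each
structure. Each structure carries four properties:

| structure   | geometry          | extent    | cell type | orientation rule | DMD   |
|-------------|-------------------|-----------|-----------|------------------|-------|
| cortex      | folded sheet      | 750 cm^2  | open      | surface normal   | 0.25  |
| hippocampus | curved tube sheet | 15 cm^2   | open      | surface normal   | 0.4   |
| amygdala    | ellipsoid grid    | 1 cm^3    | open      | random           | 1     |
| thalamus    | ellipsoid grid    | 8 cm^3    | closed    | random           | 0.025 |
| putamen     | ellipsoid grid    | 9 cm^3    | closed    | random           | 0.25  |
| LGN*        | ellipsoid grid    | 0.2 cm^3  | open      | principal axis   | 0.25  |
| EGP*        | ellipsoid grid    | 1.5 cm^3  | open      | principal axis   | 0.0025|
| RPN*        | ellipsoid grid    | 2 cm^3    | open      | principal axis   | 0.0025|

(*optional in the default model; built when `include_oriented_nuclei=True`.)

DMD is the dipole moment density: nAm per mm^2 for sheets and nAm per
10 mm^3 for volume grids. Under this convention every structure obeys the
same budget — a patch of a cm^2 (or cm^3) carries `DMD x a x 100` nAm of
total current — which is the scale at which open-field populations
(palisades of pyramidal cells) and closed-field populations (stellate
cells, whose fields largely self-cancel, hence the 10x-lower thalamic DMD)
are usually quoted. The amygdala is treated as a volume with randomly
oriented dipoles: its basolateral portion is pyramidal-cell rich but has no
preferred orientation.

Per-dipole currents are `q_i = DMD x A_i` (sheets, `A_i` the barycentric
vertex area in mm^2) or `q_i = DMD x V_i / 10` (grids, `V_i` the voxel
volume in mm^3).

### Synthetic anatomy

No subject data enter the pipeline; the anatomy is generated:

* **Cortex** — a spherical cap at base radius 77.5 mm, radially displaced
  by a sum of two seeded plane-wave harmonics, normalized to bump height
  11.5 mm and wavelength ~1.5–2 cm: sulcus-scale folding. The cap's polar
  angle is solved by bisection so the mesh area meets the 750 cm^2 target
  (realized within 5%, usually ≪1%). The folding matters physically:
  surface normals on a smooth cap are nearly radial, and radial dipoles in
  a spherical conductor are magnetically silent, so an unfolded "cortex"
  would be almost invisible to MEG. With folding, the median angle between
  the normal and the radial direction is ~55 degrees, which is what gives
  cortex its order-of-magnitude visibility advantage over the thalamus.
  The default mesh is an icosphere at subdivision 5 (~2.9 mm edges) so the
  folds are resolved; the `small` preset (subdivision 3, 4 mm grids,
  ~1000 dipoles total) is used for fast tests and Monte Carlo sweeps.
* **Hippocampus** — an open tube around a circular arc (radius 26 mm,
  140 degree span) whose plane is orthogonal to its radial offset, placing
  the whole tube on a shell at ~60% of the conductor radius; the tube
  radius is solved by bisection for the 15 cm^2 target. Dipoles point along
  the outward surface normal, mimicking the archeo-cortical palisade on the
  structure's envelope.
* **Nuclei** — regular 2 mm grids (6-connectivity) filling ellipsoids near
  the centre; the semi-axes are scaled by bisection until the voxel count
  matches the target volume. A deterministic sub-voxel grid offset breaks
  the ellipsoid/grid symmetry so counts grow in steps of ~1 voxel, which is
  what makes the small nuclei (0.2–2 cm^3) reachable within the 5%
  tolerance. Principal-axis orientations use the dominant eigenvector of
  the grid-point covariance.

The build seed controls the folding harmonics (directions, frequencies,
phases), all random orientations, and a ±0.5 mm jitter of nucleus centres —
a stand-in for inter-individual variability. Identical seeds give
bit-identical models. Structures are checked for mutual clearance (≥1 mm)
and strict containment in the conductor.

### Sensors and conductor

A single homogeneous sphere (radius 90 mm, centred at the origin) is the
volume conductor. 151 radial point magnetometers sit on a concentric sphere
of radius 104 mm, Fibonacci-spiralled over the upper 62% of the sphere — a
whole-head helmet ~1.4 cm above the scalp sphere.

## Forward model

The magnetic field of a dipole in a conducting sphere is evaluated with the
closed-form Sarvas expression and projected on each sensor's orientation.
Two exact consequences are used as oracles throughout the tests: radial
dipoles and dipoles at the centre are silent (`q x r0 = 0`), and for radial
sensors the field reduces to the primary term
`B·r̂ = (μ0/4π) [q x (r−r0)]·r̂ / |r−r0|^3` because volume currents
contribute no radial component. The implementation (full Sarvas) agrees
with this independent formula to ~1e-15 relative.

`compute_gain` stores both the fixed-orientation gain (sensors x sources,
T per A·m) and the free-orientation blocks (unit moments along x, y, z)
needed for depth weighting. Sensitivity maps are the RMS over sensors of
each gain column.

## Inverse operators

All estimates are linear: `ĵ = K m`. With gain `G`, noise covariance `C`
and diagonal source covariance `S`:

* **wMNE** — `K = S Gᵗ (G S Gᵗ + λ² C)⁻¹`, with
  `λ² = tr(G S Gᵗ) / (tr(C) · snr²)` and `snr = 3` by default. Depth
  weights `S_ii = ‖G3_i‖_F^(−2w)` are computed from the free-orientation
  gain (position-dependent only), `w = 0.6` by default. The weight dynamic
  range is capped so that no source is boosted more than 10x in amplitude
  relative to the strongest source, as standard inverse software does:
  without the cap the weights of near-centre dipoles — whose gain vanishes
  linearly with eccentricity — diverge and the operator is owned by the
  deepest handful of sources.
* **dSPM** — each wMNE row divided by its noise sensitivity
  `sqrt((K C Kᵗ)_ii)`; pure noise then projects to unit variance per source
  by construction.
* **sLORETA** — each row divided by `sqrt(R_ii)` where `R = K G`. By
  default the standardization is applied to the *unweighted* (`w = 0`)
  kernel: for that classical construction a Cauchy–Schwarz argument in the
  metric of `(G Gᵗ + λ² C)⁻¹` shows the score of the true source bounds
  every other score, so noiseless point sources are localized exactly —
  verified for all ~8100 sources of the default model. Standardizing a
  depth-weighted kernel loses this exactness (the position-dependent `S`
  no longer cancels; empirically ~85% of sources then mislocalize by one
  or more neighbours), which is why depth weighting is redundant-to-harmful
  under sLORETA. `kernel_family(..., sloreta_unweighted=False)` still
  builds the shared-base variant; the two-source experiments use it
  because its deep-variance inflation is what produces spurious thalamic
  maxima, the ghost-source phenomenon of interest.

The noise covariance is the sample covariance of a 200 ms baseline with 5%
diagonal loading (250 samples against 151 sensors is ill-conditioned),
raised to 10% for very short baselines.

**Resolution analysis.** `R = K G`; columns are point-spread functions
(where a point source's estimate lands), rows are cross-talk functions
(what leaks into a source's estimate). Row normalizations (dSPM, sLORETA)
rescale rows without reshaping them, so normalized CTFs are identical
across the three operators (max abs difference ~1e-15 numerically);
PSFs differ. Structure-average maps normalize each per-source map to unit
maximum before averaging, then renormalize.

## Simulations

Activation patches grow from a seed dipole by distance-ordered accretion
over the adjacency graph (ties broken by index) until the accumulated
element size reaches the target (1–5 cm^2/cm^3; clamped to the whole
structure with a warning if the structure is smaller). Gaussian envelopes
(FWHM 30 ms) modulate each patch after a 200 ms baseline; a cortical
co-activation (3 cm^2, visual-cortex analog on the posterior cap) peaks
`D_t` ms before the subcortical one, so the cortical amplitude at the
subcortical peak is `R_c = exp(−4 ln2 (D_t/FWHM)²)` — 100% at `D_t = 0`,
~0 at 60 ms. The summed clean signal is scaled once so that its total
energy is `snr_energy = 20` times the noise energy (noise-free runs are
left unscaled); the scale, envelopes and per-dipole currents are stored so
the truth reconstructs the data exactly.

Sensor noise emulates resting MEG: independent 1/f-coloured floors per
channel (per-sample SD 100 fT), plus one shared narrow-band 10 Hz source
mixed with random channel weights, giving the weak inter-channel
correlation and the alpha-peaked spectrum of real background activity.
Spectra are synthesized in the frequency domain, so the realized PSD
matches the configured shape exactly in expectation.

## Localization metrics and detection

All metrics are computed on the magnitude of the estimate at the
subcortical peak sample, in cm:

* `DLE_g` — distance from the amplitude-weighted gravity centre of the
  thresholded map (entries ≥50% of the maximum; whole-map scope) to the
  truth.
* `DLE_m` — distance from the estimate's maximum (ties to the lowest
  index) to the truth.
* Truth is the patch *seed* position by default (`truth="centroid"`
  switches to the current-weighted patch centroid).
* **Detection** — a graph-local maximum (value ≥ all adjacency neighbours)
  within 4 cm of the truth, with amplitude ≥50% of the global map maximum:
  the "local maximum dot" must be a distinct peak, not a leakage slope.
* **Thalamic ghost** — a graph-local maximum inside the thalamus at ≥50%
  of the global maximum when the true source is elsewhere.
* **Structure shares** — relative percentages of thresholded magnitude
  among hippocampus/amygdala/thalamus only (thresholded at 50% of the
  maximum over those structures), mirroring per-structure activation
  histograms.

The detection/ghost/share rules are this package's own formalization of
criteria that are usually applied visually to estimate maps.

## Monte Carlo driver

`run_grid` sweeps structures x seed sources (optionally strided) x patch
sizes x `D_t` values x noise seeds, rebuilding the noise covariance and the
kernel family per noise seed, and records one row per (cell, method) with
errors, detection and shares. Cells that fail are recorded with their error
message, never dropped. Runs are deterministic given the grid and noise
model; an optional TSV checkpoint allows resuming with identical results.
Seven noise seeds emulate the repeated-subjects averaging of a group study.

## EO/EC alpha contrast

The generator drives a shared unit-variance narrow-band 10 Hz series in
the thalamus and an occipital cortex disc (3 nAm per source with eyes open,
x3 with eyes closed) over condition-independent background noise, in 10
blocks of 8 s per condition at 250 Hz — a scaled-down version of a 30 s
block design. The contrast band-passes each block (4th-order Butterworth
8–12 Hz, forward–backward so zero-phase; band centre flat within 1 dB,
edges at −6 dB as a squared-magnitude response must be), projects through a
kernel, takes per-block per-source mean square as band power, and runs
two-sample t-tests across blocks with Benjamini–Hochberg FDR at 0.05 (own
implementation; agrees exactly with the statsmodels reference).

## What the synthetic data do and do not show

The generator reproduces the *physics* that makes deep MEG source imaging
hard — eccentricity-dependent silence, depth-dependent sensitivity,
orientation cancellation in closed-field nuclei, realistic current budgets,
1/f + alpha background — so operator-level properties (CTF invariance,
sLORETA exactness, depth-bias correction, ghost formation, SNR bookkeeping)
transfer to real data. It does not reproduce individual anatomy: there is
one synthetic "subject" per build seed, folding is a two-harmonic
caricature of sulci, the hippocampal tube has no subfields, and skull/brain
conductivity structure is absent (single sphere). Quantities that depend on
the precise leakage geometry — e.g. the structure shares under a strong
cortical co-activation — vary visibly with the folding seed (see
`analysis/04`), so their specific values characterize this model, not
brains in general; the orderings between operators are the robust findings.

## Numerical choices

* Bisections (cap angle, tube radius, ellipsoid scale) run 50–60 halvings;
  extent tolerance 5%, typically met to ≪1%.
* `λ²` follows the trace rule above, making kernels invariant to a global
  rescaling of `C`.
* Regularized systems are solved by Cholesky factorization.
* Degenerate inputs raise typed errors: sources on/outside the sphere,
  all-zero estimates, silent patches under an SNR target, unreachable
  extents, overlapping structures.
* Argmax ties everywhere resolve to the lowest index (numpy convention),
  making every metric deterministic.
* Experiment scale defaults (small preset, seed strides, 3–7 noise seeds,
  8 s blocks) are desk-scale choices; full-density runs just widen the grid.

## Known limitations

* The cortical co-activation experiments use one fixed visual-patch
  location; sweeping over many cortical sites is out of scope.
* The amygdala analog has only ~15 dipoles in the small preset, so its
  error statistics are coarse.
* No EEG, no gradiometers, no realistic (BEM/FEM) conductor, no
  beamformers or L1 estimators — the study design compares the three L2
  operators under MEG only.
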