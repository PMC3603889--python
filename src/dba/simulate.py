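"""Patch activation and sensor-level simulation.

Activation patches grow over the source-space adjacency from a seed dipole
until they reach a target extent; each member dipole carries a current equal
to its moment density times its area/volume element.  Gaussian envelopes
(FWHM 30 ms by default) modulate cortical and subcortical patches, offset by
a configurable delay D_t, and the summed field is mixed with resting-state
noise at a controlled energy signal-to-noise ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SourceSpace
from .forward import GainMatrix

NAM = 1e-9  # nAm -> A.m


class SilentPatchError(ValueError):
    """Patch produces no measurable field; the SNR target cannot be met."""


@dataclass
class Patch:
    """Connected set of co-activated dipoles within one structure.

    ``currents`` are per-dipole moments q_i in nAm (DMD x element size under
    the convention that a 1 cm^2 / 1 cm^3 patch totals DMD x 100 nAm).
    """

    seed_index: int
    member_indices: np.ndarray
    currents: np.ndarray
    structure: str
    total_extent: float  # cm^2 or cm^3

    @property
    def total_current(self) -> float:
        return float(self.currents.sum())


def grow_patch(space: SourceSpace, seed_index: int, target_extent: float) -> Patch:
    """Grow a patch from ``seed_index`` to ``target_extent`` (cm^2 or cm^3).

    Accretes neighbours over the adjacency graph, always taking the frontier
    candidate closest (Euclidean) to the seed, until the accumulated element
    size reaches the target.  The patch never leaves the seed's structure; if
    the whole structure is smaller than the target the patch is clamped to
    the full structure with a warning.
    """
    structure = space.structure_of(seed_index)
    spec = space.specs[structure]
    per_unit = 100.0 if spec.geometry_kind == "surface" else 1000.0
    target = target_extent * per_unit  # mm^2 or mm^3

    struct_extent = space.extent(structure) * per_unit
    if target > struct_extent:
        warnings.warn(f"{structure}: target {target_extent} exceeds structure "
                      f"extent {struct_extent / per_unit:.2f}; clamping to whole structure")
        members = space.indices(structure)
        order = np.argsort(np.linalg.norm(space.positions[members]
                                          - space.positions[seed_index], axis=1))
        members = members[order]
    else:
        in_struct = space.structure_labels == structure
        members_list = [seed_index]
        member_set = {seed_index}
        total = float(space.element_sizes[seed_index])
        pos_seed = space.positions[seed_index]
        frontier: dict[int, float] = {}

        def push(idx):
            for nb in space.adjacency[idx]:
                nb = int(nb)
                if nb not in member_set and in_struct[nb] and nb not in frontier:
                    frontier[nb] = float(np.linalg.norm(space.positions[nb] - pos_seed))

        push(seed_index)
        while total < target and frontier:
            # nearest candidate; ties broken by lowest index
            nxt = min(frontier, key=lambda k: (frontier[k], k))
            frontier.pop(nxt)
            members_list.append(nxt)
            member_set.add(nxt)
            total += float(space.element_sizes[nxt])
            push(nxt)
        members = np.array(members_list, dtype=np.intp)

    currents = patch_currents(members, space, spec.dmd)
    sizes = space.element_sizes[members]
    return Patch(seed_index=seed_index, member_indices=members, currents=currents,
                 structure=structure, total_extent=float(sizes.sum()) / per_unit)


def patch_currents(member_indices: np.ndarray, space: SourceSpace, dmd: float) -> np.ndarray:
    """Per-dipole currents in nAm: q_i = DMD x A_i (mm^2) for surface dipoles
    and q_i = DMD x V_i (mm^3) / 10 for volume dipoles, so any 1 cm^2 or
    1 cm^3 of tissue carries DMD x 100 nAm in total."""
    if dmd <= 0:
        raise ValueError("dmd must be positive")
    member_indices = np.asarray(member_indices, dtype=np.intp)
    if member_indices.size == 0:
        return np.zeros(0)
    sizes = space.element_sizes[member_indices]
    if np.any(sizes <= 0):
        raise ValueError("degenerate mesh: zero element sizes in patch")
    labels = space.structure_labels[member_indices]
    kinds = np.array([space.specs[str(l)].geometry_kind == "surface" for l in labels])
    return np.where(kinds, dmd * sizes, dmd * sizes / 10.0)


def gaussian_timecourse(fwhm_ms: float, peak_sample: int, n_samples: int,
                        rate_hz: float) -> np.ndarray:
    """Unit-peak Gaussian envelope; value 0.5 at peak +/- FWHM/2."""
    if fwhm_ms <= 0:
        raise ValueError("fwhm must be positive")
    if not 0 <= peak_sample < n_samples:
        raise ValueError("peak outside the record")
    t_ms = (np.arange(n_samples) - peak_sample) / rate_hz * 1000.0
    return np.exp(-4.0 * np.log(2.0) * (t_ms / fwhm_ms) ** 2)


def envelope_ratio(d_t_ms: float, fwhm_ms: float = 30.0) -> float:
    """Cortical envelope amplitude at the subcortical peak, relative to its
    own peak: R_c = exp(-4 ln2 (D_t / FWHM)^2).  1 at D_t=0, ~0 at 60 ms."""
    return float(np.exp(-4.0 * np.log(2.0) * (d_t_ms / fwhm_ms) ** 2))


def d_t_for_rc(r_c: float, fwhm_ms: float = 30.0) -> float:
    """Invert ``envelope_ratio``: the delay D_t (ms) giving ratio ``r_c``."""
    if not 0 < r_c <= 1:
        raise ValueError("r_c must be in (0, 1]")
    return float(fwhm_ms * np.sqrt(np.log(1.0 / r_c) / (4.0 * np.log(2.0))))


@dataclass
class SimulationConfig:
    """Timing and scaling of a simulated evoked recording."""

    fwhm_ms: float = 30.0
    baseline_ms: float = 200.0
    record_ms: float = 400.0
    subcortical_peak_ms: float = 320.0
    d_t_ms: float = 60.0
    snr_energy: float = 20.0
    sampling_rate_hz: float = 1250.0

    def __post_init__(self):
        if self.d_t_ms < 0:
            raise ValueError("d_t must be >= 0")
        if self.snr_energy <= 0:
            raise ValueError("snr_energy must be positive")
        if self.fwhm_ms <= 0:
            raise ValueError("fwhm must be positive")


@dataclass
class SimulatedRecording:
    """Sensor data plus exact ground truth.

    ``data`` is sensors x samples (Tesla), equal to ``scale x G q(t) + noise``
    where ``q(t)`` is reconstructed from ``patches``/``envelopes``/``scale``.
    ``r_c`` is the realized cortical/subcortical envelope amplitude ratio at
    the subcortical peak (None for single-patch simulations).
    """

    data: np.ndarray
    sampling_rate_hz: float
    baseline_samples: int
    subcortical_peak_sample: int
    cortical_peak_sample: int | None
    patches: list
    envelopes: list
    scale: float
    noise: np.ndarray
    r_c: float | None = None

    def clean_signal(self, gain: GainMatrix) -> np.ndarray:
        """Recompute scale x G q(t) from the stored truth."""
        sig = np.zeros_like(self.data)
        for patch, env in zip(self.patches, self.envelopes):
            topo = gain.values[:, patch.member_indices] @ (patch.currents * NAM)
            sig += topo[:, None] * env[None, :]
        return self.scale * sig


def simulate_recording(gain: GainMatrix, patches: list, config: SimulationConfig,
                       noise: np.ndarray | None = None) -> SimulatedRecording:
    """Mix patch activations with noise at the configured energy SNR.

    ``patches`` is a list of (patch, role) pairs where role is 'subcortical'
    or 'cortical', or bare Patch objects (treated as subcortical).  The
    cortical envelope peaks ``d_t_ms`` before the subcortical one.  The whole
    clean signal is scaled by one factor so that its total energy is
    ``snr_energy`` times the noise energy; with no noise the scale is 1.
    """
    fs = config.sampling_rate_hz
    n = int(round(config.record_ms / 1000.0 * fs))
    baseline_n = int(round(config.baseline_ms / 1000.0 * fs))
    sub_peak = int(round(config.subcortical_peak_ms / 1000.0 * fs))
    cort_peak = sub_peak - int(round(config.d_t_ms / 1000.0 * fs))
    if sub_peak >= n:
        raise ValueError("subcortical peak outside the record")
    if cort_peak <= baseline_n:
        raise ValueError("cortical activation would overlap the baseline")

    norm_patches, envelopes = [], []
    has_cortical = False
    for item in patches:
        patch, role = item if isinstance(item, tuple) else (item, "subcortical")
        peak = sub_peak if role == "subcortical" else cort_peak
        if role == "cortical":
            has_cortical = True
        norm_patches.append(patch)
        envelopes.append(gaussian_timecourse(config.fwhm_ms, peak, n, fs))

    sig = np.zeros((gain.n_sensors, n))
    for patch, env in zip(norm_patches, envelopes):
        topo = gain.values[:, patch.member_indices] @ (patch.currents * NAM)
        sig += topo[:, None] * env[None, :]

    if noise is None:
        noise = np.zeros_like(sig)
    if noise.shape != sig.shape:
        raise ValueError(f"noise shape {noise.shape} != {sig.shape}")
    e_noise = float((noise ** 2).sum())
    e_sig = float((sig ** 2).sum())
    if e_noise > 0:
        if e_sig <= 0:
            raise SilentPatchError("all-silent patch: cannot reach the SNR target")
        scale = float(np.sqrt(config.snr_energy * e_noise / e_sig))
    else:
        scale = 1.0

    data = scale * sig + noise
    r_c = envelope_ratio(config.d_t_ms, config.fwhm_ms) if has_cortical else None
    return SimulatedRecording(data=data, sampling_rate_hz=fs,
                              baseline_samples=baseline_n,
                              subcortical_peak_sample=sub_peak,
                              cortical_peak_sample=cort_peak if has_cortical else None,
                              patches=norm_patches, envelopes=envelopes,
                              scale=scale, noise=noise, r_c=r_c)
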