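"""Eyes-open / eyes-closed alpha-power contrast at the source level.

The synthetic generator drives a shared ~10 Hz rhythm in thalamic and
occipital-cortex sources, stronger (by ``modulation_ratio``) with eyes
closed, on top of condition-independent background noise.  The contrast
band-passes each block, projects it through an inverse kernel, computes
per-block per-source band power, and runs two-sample t-tests across blocks
with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .anatomy import SourceSpace
from .forward import GainMatrix
from .inverse import InverseKernel
from .montecarlo import VISUAL_DIRECTION
from .noise import NoiseModel, generate_noise
from .simulate import NAM


@dataclass
class ConditionRecording:
    """Block-designed sensor recordings of one resting-state condition."""

    condition: str  # 'eyes_open' | 'eyes_closed'
    blocks: list
    sampling_rate_hz: float


@dataclass
class ContrastMap:
    """Per-source t statistics, BH q-values and the significance mask."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    band_hz: tuple


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def default_alpha_sources(space: SourceSpace, occipital_angle_deg: float = 25.0) -> np.ndarray:
    """Thalamus plus occipital-cortex source indices (the thalamo-cortical
    alpha generators of the synthetic model)."""
    thal = space.indices("thalamus") if "thalamus" in space.structure_slices \
        else np.array([], np.intp)
    cortex = space.indices("cortex")
    unit = VISUAL_DIRECTION / np.linalg.norm(VISUAL_DIRECTION)
    pos = space.positions[cortex]
    cosang = (pos @ unit) / np.linalg.norm(pos, axis=1)
    occ = cortex[cosang >= np.cos(np.deg2rad(occipital_angle_deg))]
    return np.concatenate([thal, occ])


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                f0: float = 10.0, width: float = 1.0) -> np.ndarray:
    """Unit-variance narrow-band Gaussian signal centred at ``f0`` Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.exp(-((freqs - f0) ** 2) / (2.0 * width ** 2))
    zeta = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2)
    x = np.fft.irfft(shape * zeta, n=n)
    return x / x.std()


def synthesize_eo_ec(space: SourceSpace, gain: GainMatrix,
                     alpha_sources: np.ndarray | None = None,
                     modulation_ratio: float = 3.0, seed: int = 0,
                     n_blocks: int = 10, block_s: float = 8.0,
                     noise_model: NoiseModel | None = None,
                     alpha_amp_nam: float = 3.0,
                     ) -> tuple[ConditionRecording, ConditionRecording]:
    """Simulate block-designed EO/EC sensor recordings.

    Each block carries a shared narrow-band 10 Hz source time series in the
    alpha sources (amplitude ``alpha_amp_nam`` nAm per source with eyes
    open, times ``modulation_ratio`` with eyes closed) plus independent
    background noise in both conditions.  Reproducible for a fixed seed.
    """
    if modulation_ratio < 1:
        raise ValueError("modulation_ratio must be >= 1")
    if alpha_sources is None:
        alpha_sources = default_alpha_sources(space)
    alpha_sources = np.asarray(alpha_sources, dtype=np.intp)
    if noise_model is None:
        noise_model = NoiseModel(spectrum=1.0, alpha_peak_gain=0.0,
                                 sensor_white_sd=2e-13, sampling_rate_hz=250.0)
    fs = noise_model.sampling_rate_hz
    n = int(round(block_s * fs))
    topo = gain.values[:, alpha_sources] @ np.full(alpha_sources.size,
                                                   alpha_amp_nam * NAM)
    if float(np.abs(topo).max()) == 0.0:
        raise ValueError("silent alpha sources: nothing to modulate")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    recs = {}
    for cond, amp_scale in (("eyes_open", 1.0), ("eyes_closed", modulation_ratio)):
        blocks = []
        for b in range(n_blocks):
            s_t = _narrowband(rng, n, fs)
            noise_seed = int(rng.integers(2 ** 31))
            nm = NoiseModel(spectrum=noise_model.spectrum, alpha_peak_gain=0.0,
                            sensor_white_sd=noise_model.sensor_white_sd,
                            sampling_rate_hz=fs, seed=noise_seed)
            blk = amp_scale * topo[:, None] * s_t[None, :] \
                + generate_noise(nm, gain.n_sensors, block_s)
            blocks.append(blk)
        recs[cond] = ConditionRecording(cond, blocks, fs)
    return recs["eyes_open"], recs["eyes_closed"]


def alpha_contrast(rec_eo: ConditionRecording, rec_ec: ConditionRecording,
                   kernel: InverseKernel, band_hz: tuple = (8.0, 12.0),
                   alpha: float = 0.05) -> ContrastMap:
    """Source-level EC-vs-EO alpha-band power contrast.

    Zero-phase 4th-order Butterworth band-pass per block, projection through
    the kernel, per-block per-source mean square as the power statistic, and
    a two-sample t-test across blocks per source, BH-FDR thresholded at
    ``alpha``.  Positive t means stronger power with eyes closed.
    """
    if len(rec_eo.blocks) < 2 or len(rec_ec.blocks) < 2:
        raise ValueError("need at least two blocks per condition")
    fs = rec_eo.sampling_rate_hz
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")

    def block_powers(rec):
        out = []
        for blk in rec.blocks:
            filt = signal.sosfiltfilt(sos, blk, axis=1)
            src = kernel.apply(filt)
            out.append((src ** 2).mean(axis=1))
        return np.asarray(out)  # blocks x sources

    p_eo = block_powers(rec_eo)
    p_ec = block_powers(rec_ec)
    t, p = stats.ttest_ind(p_ec, p_eo, axis=0)
    q = bh_fdr(p)
    return ContrastMap(t=t, p=p, q=q, significant=q < alpha, band_hz=tuple(band_hz))
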