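"""Synthetic resting-state sensor noise.

Emulates ongoing MEG background activity: per-channel 1/f^beta coloured noise
plus a white sensor-noise floor, and a shared narrow-band alpha (~10 Hz)
source projected with random per-channel weights so that channels are weakly
correlated the way a common thalamo-cortical rhythm makes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of the synthetic resting-state background.

    ``spectrum`` is the 1/f exponent beta of the coloured floor (0 = white),
    ``alpha_peak_gain`` the power of the shared alpha component at its peak
    frequency relative to the floor's PSD there (0 disables it), and
    ``sensor_white_sd`` the per-sample standard deviation of the floor in
    Tesla.
    """

    spectrum: float = 1.0
    alpha_peak_hz: float = 10.0
    alpha_peak_gain: float = 30.0
    alpha_width_hz: float = 1.0
    sensor_white_sd: float = 1e-13
    sampling_rate_hz: float = 1250.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate_hz <= 2 * self.alpha_peak_hz:
            raise ValueError("sampling_rate must exceed twice the alpha peak")


def _colored_spectrum_amplitudes(freqs: np.ndarray, beta: float) -> np.ndarray:
    """Relative amplitude shaping ~ f^(-beta/2), flat below 1 Hz, zero at DC."""
    amp = np.ones_like(freqs)
    band = freqs >= 1.0
    amp[band] = freqs[band] ** (-beta / 2.0)
    amp[freqs == 0] = 0.0
    return amp


def generate_noise(model: NoiseModel, n_channels: int, duration_s: float) -> np.ndarray:
    """Generate a (channels x samples) resting-state noise segment in Tesla.

    The floor of each channel is independent coloured noise with per-sample
    standard deviation ``sensor_white_sd``; on top, a single shared alpha
    source with one-sided PSD ``alpha_peak_gain x floor_psd(alpha_peak_hz)``
    at its peak (Gaussian profile of width ``alpha_width_hz``) is mixed in
    with seeded random channel weights of unit mean square.

    Deterministic for a fixed ``model.seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if duration_s < 0.2:
        raise ValueError("duration must cover at least 0.2 s")
    fs = model.sampling_rate_hz
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(model.seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = model.sensor_white_sd

    amp = _colored_spectrum_amplitudes(freqs, model.spectrum)
    # rFFT synthesis: x = irfft(c * A_k * zeta_k) has per-sample variance
    # (2 c^2 / n^2) sum A^2; choose c for variance sigma^2.
    c = sigma * n / np.sqrt(2.0 * (amp ** 2).sum())
    zeta = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) / np.sqrt(2)
    data = np.fft.irfft(c * amp[None, :] * zeta, n=n, axis=1)

    if model.alpha_peak_gain > 0:
        # one-sided floor PSD at f: S(f) = 2 c^2 A(f)^2 / (n fs)
        k0 = int(np.argmin(np.abs(freqs - model.alpha_peak_hz)))
        floor_psd_f0 = 2.0 * c ** 2 * amp[k0] ** 2 / (n * fs)
        s_alpha = (model.alpha_peak_gain * floor_psd_f0
                   * np.exp(-((freqs - model.alpha_peak_hz) ** 2)
                            / (2.0 * model.alpha_width_hz ** 2)))
        zeta_a = (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2)
        # |X_k|^2 target: S_a(f) n fs / 2  ->  X_k = sqrt(S_a fs n / 2) zeta
        alpha = np.fft.irfft(np.sqrt(s_alpha * fs * n / 2.0) * zeta_a, n=n)
        w = rng.standard_normal(n_channels)
        w /= np.sqrt((w ** 2).mean())
        data = data + w[:, None] * alpha[None, :]
    return data
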