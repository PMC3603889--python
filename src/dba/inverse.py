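"""Minimum-norm inverse operators and the resolution matrix.

Three linear kernels over a fixed-orientation gain matrix G:

* depth-weighted MNE (wMNE): ``K = S Gt (G S Gt + lambda^2 C)^-1`` with
  diagonal source covariance ``S_ii = ||G3_i||_F^(-2w)`` computed from the
  free-orientation gain, and ``lambda^2 = tr(G S Gt) / (tr(C) snr^2)``;
* dSPM: wMNE rows normalized by each source's noise sensitivity
  ``sqrt((K C Kt)_ii)``;
* sLORETA: wMNE rows standardized by ``sqrt(R_ii)`` with ``R = K G``.

Rows of R (cross-talk functions) are only rescaled by these per-source
normalizations, so their shape is identical across the three methods, while
columns (point-spread functions) differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward import GainMatrix


@dataclass
class NoiseCovariance:
    """Sensor noise covariance with diagonal loading."""

    matrix: np.ndarray
    n_samples_used: int
    regularization_applied: float


def estimate_noise_cov(baseline: np.ndarray, loading_fraction: float = 0.05) -> NoiseCovariance:
    """Sample covariance of a (sensors x samples) baseline segment, with
    ``loading_fraction x mean(diag)`` added to the diagonal.

    A short baseline (fewer than sensors/4 samples) triggers heavier loading
    to keep the matrix well conditioned.
    """
    baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
    n_sens, n_samp = baseline.shape
    if n_samp < 2:
        raise ValueError("need at least two baseline samples")
    if n_samp < n_sens / 4:
        loading_fraction = max(loading_fraction, 0.1)
    centered = baseline - baseline.mean(axis=1, keepdims=True)
    var = centered.var(axis=1)
    if np.any(var == 0):
        warnings.warn("constant channels in baseline; covariance is rank deficient")
    cov = centered @ centered.T / (n_samp - 1)
    mean_diag = float(np.trace(cov)) / n_sens
    if mean_diag == 0:
        mean_diag = np.finfo(float).eps
    cov = cov + loading_fraction * mean_diag * np.eye(n_sens)
    return NoiseCovariance(matrix=cov, n_samples_used=n_samp,
                           regularization_applied=loading_fraction)


def depth_weights(gain: GainMatrix, w: float, limit: float = 10.0,
                  ceiling: float = 1e12) -> np.ndarray:
    """Diagonal of the source covariance: ``S_ii = ||G3_i||_F^(-2w)``.

    The norms come from the free-orientation (3-component) gain, i.e. before
    orientations are fixed, so the weights depend on position only.  ``w=0``
    gives plain MNE.

    ``limit`` caps the dynamic range of the weights the way standard inverse
    software does: no source is boosted by more than ``limit`` in amplitude
    (``limit**2`` in power) relative to the strongest source.  Without the
    cap the weights of near-centre dipoles, whose free-orientation gain
    vanishes linearly with eccentricity, diverge and the weighted operator
    is dominated by the deepest few sources.  Silent sources get the cap
    (or ``ceiling`` when ``limit`` is None), with a warning.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must be in [0, 1]")
    norms = gain.free_norms()
    weights = np.empty_like(norms)
    silent = norms == 0
    if silent.any():
        warnings.warn(f"{int(silent.sum())} silent sources; weight capped")
    weights[~silent] = norms[~silent] ** (-2.0 * w)
    if limit is not None and (~silent).any():
        cap = norms[~silent].max() ** (-2.0 * w) * limit ** 2
    else:
        cap = ceiling
    cap = min(cap, ceiling)
    weights[silent] = cap
    return np.minimum(weights, cap)


@dataclass
class InverseKernel:
    """Linear inverse operator (sources x sensors)."""

    matrix: np.ndarray
    method: str
    lambda2: float
    source_covariance_diag: np.ndarray
    weighting_exponent: float
    snr_reg: float

    def apply(self, data: np.ndarray) -> np.ndarray:
        return self.matrix @ data


@dataclass
class ResolutionMatrix:
    """R = K G: columns are point-spread, rows are cross-talk functions."""

    matrix: np.ndarray
    kernel_method: str


def wmne_kernel(gain: GainMatrix, cov: NoiseCovariance,
                source_cov_diag: np.ndarray | None = None,
                snr_reg: float = 3.0, w: float = 0.6) -> InverseKernel:
    """Depth-weighted minimum-norm kernel.

    ``source_cov_diag`` overrides the depth weights (pass ones for plain
    MNE); otherwise they are computed from the free-orientation gain with
    exponent ``w``.  Regularization: ``lambda^2 = tr(G S Gt)/(tr(C) snr^2)``.
    """
    g = gain.values
    s = depth_weights(gain, w) if source_cov_diag is None else np.asarray(source_cov_diag, float)
    c = cov.matrix
    gsg = (g * s[None, :]) @ g.T
    lambda2 = float(np.trace(gsg) / (np.trace(c) * snr_reg ** 2))
    a = gsg + lambda2 * c
    try:
        factor = cho_factor(a)
        inv_applied = cho_solve(factor, np.eye(a.shape[0]))
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular regularized system: {err}")
    k = (s[:, None] * g.T) @ inv_applied
    return InverseKernel(matrix=k, method="wmne", lambda2=lambda2,
                         source_covariance_diag=s, weighting_exponent=w,
                         snr_reg=snr_reg)


def dspm_kernel(kernel: InverseKernel, cov: NoiseCovariance) -> InverseKernel:
    """Noise-normalize each row by its noise sensitivity sqrt((K C Kt)_ii),
    giving unit variance under pure noise by construction."""
    k = kernel.matrix
    noise_var = np.einsum("is,st,it->i", k, cov.matrix, k)
    bad = noise_var <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} rows with zero noise sensitivity; capped")
        noise_var[bad] = noise_var[~bad].min() if (~bad).any() else 1.0
    k_d = k / np.sqrt(noise_var)[:, None]
    return InverseKernel(matrix=k_d, method="dspm", lambda2=kernel.lambda2,
                         source_covariance_diag=kernel.source_covariance_diag,
                         weighting_exponent=kernel.weighting_exponent,
                         snr_reg=kernel.snr_reg)


def sloreta_kernel(kernel: InverseKernel, gain: GainMatrix) -> InverseKernel:
    """Standardize each row by sqrt(R_ii) with R = K G (resolution matrix)."""
    k = kernel.matrix
    r_diag = np.einsum("is,si->i", k, gain.values)
    if np.any(r_diag <= 0):
        bad = np.nonzero(r_diag <= 0)[0]
        raise np.linalg.LinAlgError(
            f"non-positive resolution diagonal at sources {bad.tolist()[:10]}")
    k_s = k / np.sqrt(r_diag)[:, None]
    return InverseKernel(matrix=k_s, method="sloreta", lambda2=kernel.lambda2,
                         source_covariance_diag=kernel.source_covariance_diag,
                         weighting_exponent=kernel.weighting_exponent,
                         snr_reg=kernel.snr_reg)


def resolution_matrix(kernel: InverseKernel, gain: GainMatrix) -> ResolutionMatrix:
    """Exact product R = K G."""
    return ResolutionMatrix(matrix=kernel.matrix @ gain.values,
                            kernel_method=kernel.method)


def kernel_family(gain: GainMatrix, cov: NoiseCovariance, w: float = 0.6,
                  snr_reg: float = 3.0, sloreta_unweighted: bool = True) -> dict:
    """The three operators as used throughout the experiments.

    wMNE and dSPM share the depth-weighted base kernel.  sLORETA is by
    default standardized from the unweighted (w=0) minimum-norm kernel — the
    classical construction, for which standardization exactly cancels the
    depth bias and noiseless point sources are localized without error;
    pre-applying depth weights would break that exactness because the
    standardization no longer cancels a position-dependent source
    covariance.  Set ``sloreta_unweighted=False`` to standardize the shared
    depth-weighted kernel instead (then all three operators are row
    rescalings of one kernel and share cross-talk function shapes exactly).
    """
    base = wmne_kernel(gain, cov, snr_reg=snr_reg, w=w)
    if sloreta_unweighted and w != 0:
        slo_base = wmne_kernel(gain, cov, snr_reg=snr_reg, w=0.0)
    else:
        slo_base = base
    return {"wmne": base,
            "dspm": dspm_kernel(base, cov),
            "sloreta": sloreta_kernel(slo_base, gain)}
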