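"""Point-spread and cross-talk maps from the resolution matrix.

PSF (columns of R) shows where a point source's estimate is smeared to;
CTF (rows of R) shows which other sources leak into a given source's
estimate.  Maps are unsigned magnitudes, optionally max-normalized and
thresholded at a fraction of their maximum.  Structure-average maps
normalize each per-source map before averaging, then renormalize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import SourceSpace
from .inverse import ResolutionMatrix


@dataclass
class ResolutionMap:
    """Per-source magnitude map of one PSF, CTF, or a structure average."""

    kind: str  # 'psf' | 'ctf'
    source_scope: object  # source index or structure label
    values: np.ndarray
    normalized: bool
    threshold_fraction: float = 0.5

    def normalize(self) -> "ResolutionMap":
        m = self.values.max()
        vals = self.values / m if m > 0 else self.values.copy()
        return ResolutionMap(self.kind, self.source_scope, vals, True,
                             self.threshold_fraction)

    def thresholded(self) -> np.ndarray:
        """Values with entries below threshold_fraction x max zeroed."""
        cut = self.threshold_fraction * self.values.max()
        out = self.values.copy()
        out[out < cut] = 0.0
        return out


def psf_map(res: ResolutionMatrix, source_index: int,
            normalize: bool = False) -> ResolutionMap:
    """Point-spread function: |column| of R at ``source_index``."""
    vals = np.abs(res.matrix[:, source_index])
    m = ResolutionMap("psf", source_index, vals, False)
    return m.normalize() if normalize else m


def ctf_map(res: ResolutionMatrix, source_index: int,
            normalize: bool = False) -> ResolutionMap:
    """Cross-talk function: |row| of R at ``source_index``."""
    vals = np.abs(res.matrix[source_index, :])
    m = ResolutionMap("ctf", source_index, vals, False)
    return m.normalize() if normalize else m


def average_structure_map(res: ResolutionMatrix, space: SourceSpace,
                          structure: str, kind: str = "psf") -> ResolutionMap:
    """Average the normalized per-source maps of a structure, renormalized.

    Each source's map is max-normalized before averaging so that deep,
    weakly-estimated sources contribute on equal footing, as in per-map
    normalized displays.
    """
    idx = space.indices(structure)
    if idx.size == 0:
        raise ValueError(f"empty structure {structure!r}")
    fn = psf_map if kind == "psf" else ctf_map
    acc = np.zeros(res.matrix.shape[0])
    for i in idx:
        acc += fn(res, int(i), normalize=True).values
    acc /= idx.size
    return ResolutionMap(kind, structure, acc, False).normalize()
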