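"""Spherical-conductor MEG forward model.

The magnetic field of a current dipole inside a homogeneous conducting sphere
is given in closed form by the Sarvas expression; volume currents contribute
nothing to the field's radial component, and exactly radial dipoles (and
dipoles at the sphere centre) are magnetically silent.  The gain matrix maps
unit dipole moments (A.m) to sensor readings (Tesla) along each sensor's
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import Conductor, SensorArray, SourceSpace

MU0_OVER_4PI = 1e-7  # T.m/A


class ForwardDomainError(ValueError):
    """Source outside the conductor, or sensors inside it."""


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Full Sarvas magnetic field of dipole ``q`` (A.m) at ``r0`` for sensor
    positions ``r`` (all relative to the sphere centre); returns (n, 3) Tesla.

    Valid for any sensor orientation; exactly zero when ``q`` is parallel to
    ``r0`` or the dipole sits at the centre (``q x r0 = 0``).
    """
    a_vec = r - r0[None, :]
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn ** 2 - r @ r0)
    grad_f = ((a ** 2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r
              - (a + 2 * rn + ar / a)[:, None] * r0[None, :])
    qxr0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (f[:, None] * qxr0[None, :]
                                          - (r @ qxr0)[:, None] * grad_f)
    return b


def dipole_field(source_pos, moment, sensors: SensorArray,
                 conductor: Conductor | None = None) -> np.ndarray:
    """Field of one dipole projected on each sensor's orientation (Tesla).

    Parameters
    ----------
    source_pos : (3,) array
        Dipole position, metres, strictly inside the conductor.
    moment : (3,) array
        Dipole moment, A.m.
    sensors : SensorArray
        Sensor positions/orientations; all positions must lie outside the
        conductor.
    """
    if conductor is None:
        conductor = Conductor()
    c = conductor.center_arr
    r0 = np.asarray(source_pos, dtype=float) - c
    if np.linalg.norm(r0) >= conductor.radius:
        raise ForwardDomainError("source on or outside the conductor sphere")
    r = sensors.positions - c
    if np.any(np.linalg.norm(r, axis=1) <= conductor.radius):
        raise ForwardDomainError("sensors must be outside the conductor sphere")
    b = _sarvas_field(r0, np.asarray(moment, dtype=float), r)
    return np.einsum("ij,ij->i", b, sensors.orientations)


@dataclass
class GainMatrix:
    """Lead field: ``values`` is sensors x sources, Tesla per A.m, for the
    fixed per-dipole orientations; ``free`` is the unconstrained
    (sensors x sources x 3) gain used for depth weighting."""

    values: np.ndarray
    free: np.ndarray
    source_space: SourceSpace
    sensors: SensorArray

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]

    def free_norms(self) -> np.ndarray:
        """Frobenius norm of each source's 3-component gain block."""
        return np.sqrt((self.free ** 2).sum(axis=(0, 2)))


def compute_gain(space: SourceSpace, sensors: SensorArray) -> GainMatrix:
    """Gain matrix for every dipole of ``space`` at unit moment (1 A.m).

    Column ``i`` equals ``dipole_field`` at position ``i`` with a unit moment
    along the stored orientation; the free-orientation blocks (unit moments
    along x, y, z) are retained for depth weighting.
    """
    conductor = space.conductor
    c = conductor.center_arr
    r = sensors.positions - c
    if np.any(np.linalg.norm(r, axis=1) <= conductor.radius):
        raise ForwardDomainError("sensors must be outside the conductor sphere")
    r0_all = space.positions - c
    rad = np.linalg.norm(r0_all, axis=1)
    bad = np.nonzero(rad >= conductor.radius)[0]
    if bad.size:
        raise ForwardDomainError(f"dipoles outside conductor: {bad.tolist()[:10]}")

    n_sens, n_src = sensors.n_sensors, space.n_sources
    free = np.empty((n_sens, n_src, 3))
    eye = np.eye(3)
    for i in range(n_src):
        for comp in range(3):
            b = _sarvas_field(r0_all[i], eye[comp], r)
            free[:, i, comp] = np.einsum("ij,ij->i", b, sensors.orientations)
    values = np.einsum("sic,ic->si", free, space.orientations)
    return GainMatrix(values=values, free=free, source_space=space, sensors=sensors)


@dataclass
class SensitivityMap:
    """Per-source RMS contribution to the sensors, optionally max-normalized."""

    values: np.ndarray
    normalized: bool


def sensitivity_map(gain: GainMatrix, normalize: bool = False) -> SensitivityMap:
    """RMS over sensors of each gain column (how visible each source is)."""
    if gain.values.size == 0:
        raise ValueError("empty gain matrix")
    vals = np.sqrt((gain.values ** 2).mean(axis=0))
    if normalize and vals.max() > 0:
        vals = vals / vals.max()
    return SensitivityMap(values=vals, normalized=normalize)
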