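"""Shared fixtures: session-scoped anatomies, gains and noise covariances."""

import numpy as np
import pytest
from hypothesis import settings

from dba.anatomy import SourceSpace, StructureSpec, Conductor, build_anatomy, build_sensors
from dba.forward import compute_gain
from dba.inverse import estimate_noise_cov
from dba.noise import NoiseModel, generate_noise

settings.register_profile("package", deadline=None, derandomize=True)
settings.load_profile("package")


@pytest.fixture(scope="session")
def sensors():
    return build_sensors()


@pytest.fixture(scope="session")
def small_space():
    """Fast test-scale anatomy (~1000 sources)."""
    return build_anatomy(seed=0, mesh_resolution="small")


@pytest.fixture(scope="session")
def small_gain(small_space, sensors):
    return compute_gain(small_space, sensors)


@pytest.fixture(scope="session")
def default_space():
    """Full default anatomy (~8000 sources; folded cortex resolved)."""
    return build_anatomy(seed=0, mesh_resolution="default")


@pytest.fixture(scope="session")
def default_gain(default_space, sensors):
    return compute_gain(default_space, sensors)


@pytest.fixture(scope="session")
def noise_cov(small_gain):
    nm = NoiseModel(seed=0)
    baseline = generate_noise(nm, small_gain.n_sensors, 0.4)[:, :250]
    return estimate_noise_cov(baseline)


@pytest.fixture(scope="session")
def uniform_surface_space():
    """Synthetic flat 30 x 30 grid of 1 mm^2 surface elements (one structure),
    4-connected, used as an exactly countable patch-growing substrate."""
    n = 30
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    positions = np.zeros((n * n, 3))
    positions[:, 0] = xs.ravel() * 1e-3
    positions[:, 1] = ys.ravel() * 1e-3
    positions[:, 2] = 0.02  # inside the conductor
    orientations = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    sizes = np.ones(n * n)  # mm^2
    adjacency = []
    for i in range(n):
        for j in range(n):
            nbrs = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if 0 <= i + di < n and 0 <= j + dj < n:
                    nbrs.append((i + di) * n + (j + dj))
            adjacency.append(np.array(sorted(nbrs), dtype=np.intp))
    spec = StructureSpec("sheet", "surface", "open", "surface_normal",
                         dmd=0.4, target_extent=9.0, shape="cap")
    return SourceSpace(positions=positions, orientations=orientations,
                       element_sizes=sizes,
                       structure_labels=np.full(n * n, "sheet", dtype="U32"),
                       adjacency=adjacency, triangles={},
                       specs={"sheet": spec}, conductor=Conductor(),
                       structure_slices={"sheet": slice(0, n * n)})
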