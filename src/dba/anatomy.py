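"""Synthetic source anatomy and sensor layout.

This module builds the structure-specific dipole source model used throughout
the package: a convoluted cortex-like sheet just under the surface of a
spherical conductor, a curved hippocampus-like tube surface at mid depth, and
ellipsoidal volume grids standing in for the deep grey nuclei (thalamus,
putamen, amygdala and, optionally, LGN / external pallidum / reticular
perithalamic nucleus analogs).  Every structure carries the electrophysiology
that drives the simulations: a dipole moment density (DMD), a cell-type flag
(open / closed field populations) and an orientation rule.

Units
-----
Positions and conductor geometry are metres (head frame, conductor centred at
the origin).  Per-dipole element sizes are mm^2 for surfaces and mm^3 for
volume grids; structure extents are quoted in cm^2 / cm^3 as is conventional.
DMDs are nAm per mm^2 for surfaces and nAm per 10 mm^3 for volumes (the
convention under which a 1 cm^2 / 1 cm^3 patch carries DMD x 100 nAm of total
current, for every structure alike).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh


class GeometryError(ValueError):
    """Structures overlap, or a dipole falls outside the conductor."""


class SizingError(ValueError):
    """A target extent cannot be reached at the requested resolution."""


@dataclass(frozen=True)
class Conductor:
    """Single-sphere volume conductor."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.09  # m

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class StructureSpec:
    """Anatomical + electrophysiological description of one structure.

    Parameters
    ----------
    name : str
        Structure label.
    geometry_kind : {'surface', 'volume'}
        Whether dipoles tile a 2-D sheet or fill a 3-D grid.
    cell_type : {'open', 'closed'}
        Dominant neural population: open-field cells produce a net external
        field, closed-field cells largely self-cancel.
    orientation_rule : {'surface_normal', 'random', 'principal_axis'}
        How dipole orientations are assigned.
    dmd : float
        Dipole moment density, nAm/mm^2 (surface) or nAm per 10 mm^3 (volume).
    target_extent : float
        Total area (cm^2) or volume (cm^3) the discretized structure must
        reach within 5 %.
    shape : {'cap', 'tube', 'ellipsoid'}
        Geometric primitive used to realize the structure.
    shape_params : dict
        Primitive-specific geometry (centres, radii, semi-axes; metres).
    """

    name: str
    geometry_kind: str
    cell_type: str
    orientation_rule: str
    dmd: float
    target_extent: float
    shape: str = "ellipsoid"
    shape_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dmd <= 0:
            raise ValueError(f"{self.name}: dmd must be positive")
        if self.target_extent <= 0:
            raise ValueError(f"{self.name}: target_extent must be positive")
        if self.geometry_kind not in ("surface", "volume"):
            raise ValueError(f"{self.name}: bad geometry_kind")
        if self.cell_type not in ("open", "closed"):
            raise ValueError(f"{self.name}: bad cell_type")
        if self.orientation_rule not in ("surface_normal", "random", "principal_axis"):
            raise ValueError(f"{self.name}: bad orientation_rule")
        if self.geometry_kind == "surface" and self.orientation_rule != "surface_normal":
            raise ValueError(f"{self.name}: surface structures use surface_normal")
        if self.cell_type == "closed" and self.orientation_rule != "random":
            raise ValueError(f"{self.name}: closed-field structures use random orientation")


@dataclass
class SourceSpace:
    """Contiguous multi-structure dipole source space.

    ``positions`` are metres in the head frame, ``orientations`` unit vectors,
    ``element_sizes`` mm^2 (surface dipoles) or mm^3 (volume dipoles).
    ``adjacency`` holds one neighbour index array per dipole (mesh edges for
    surfaces, 6-connectivity for grids); ``triangles`` maps each surface
    structure to its (m, 3) face array in global dipole indices.
    """

    positions: np.ndarray
    orientations: np.ndarray
    element_sizes: np.ndarray
    structure_labels: np.ndarray
    adjacency: list
    triangles: dict
    specs: dict
    conductor: Conductor
    structure_slices: dict

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def indices(self, name: str) -> np.ndarray:
        sl = self.structure_slices[name]
        return np.arange(sl.start, sl.stop)

    def extent(self, name: str) -> float:
        """Realized extent in cm^2 (surface) or cm^3 (volume)."""
        sl = self.structure_slices[name]
        total = float(self.element_sizes[sl].sum())
        return total / 100.0 if self.specs[name].geometry_kind == "surface" else total / 1000.0

    def depths(self) -> np.ndarray:
        """Distance of every dipole from the conductor surface (m)."""
        r = np.linalg.norm(self.positions - self.conductor.center_arr, axis=1)
        return self.conductor.radius - r

    def structure_of(self, index: int) -> str:
        return str(self.structure_labels[index])


@dataclass
class SensorArray:
    """Radial point magnetometers on a spherical helmet."""

    positions: np.ndarray
    orientations: np.ndarray
    sphere_center: np.ndarray
    sphere_radius: float
    names: list = field(default_factory=list)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


# --------------------------------------------------------------------------
# default model: Table-style structure parameters
# --------------------------------------------------------------------------

def default_specs(include_oriented_nuclei: bool = False) -> list[StructureSpec]:
    """Structure set of the deep-brain-activity model (left-hemisphere scale).

    Cortex 750 cm^2 / DMD 0.25, hippocampus 15 cm^2 / 0.4, amygdala 1 cm^3 / 1,
    thalamus 8 cm^3 / 0.025, putamen 9 cm^3 / 0.25; with
    ``include_oriented_nuclei`` also LGN 0.2 cm^3, EGP 1.5 cm^3 and RPN 2 cm^3
    whose dipoles follow the principal axis of their envelope.
    """
    specs = [
        StructureSpec(
            "cortex", "surface", "open", "surface_normal", 0.25, 750.0,
            shape="cap",
            shape_params={"base_radius": 0.0775, "amp": 0.0115, "n_harmonics": 2,
                          "omega": (26.0, 36.0)},
        ),
        StructureSpec(
            "hippocampus", "surface", "open", "surface_normal", 0.4, 15.0,
            shape="tube",
            shape_params={"center": (0.008, 0.048, 0.008), "arc_radius": 0.026,
                          "arc_span_deg": 140.0, "tube_radius0": 0.0038},
        ),
        StructureSpec(
            "amygdala", "volume", "open", "random", 1.0, 1.0,
            shape="ellipsoid",
            shape_params={"center": (0.022, 0.016, -0.014),
                          "semi_axes": (0.0065, 0.0060, 0.0062)},
        ),
        StructureSpec(
            "thalamus", "volume", "closed", "random", 0.025, 8.0,
            shape="ellipsoid",
            shape_params={"center": (0.010, -0.007, 0.005),
                          "semi_axes": (0.0155, 0.0115, 0.0100)},
        ),
        StructureSpec(
            "putamen", "volume", "closed", "random", 0.25, 9.0,
            shape="ellipsoid",
            shape_params={"center": (-0.020, -0.007, 0.002),
                          "semi_axes": (0.0105, 0.0125, 0.0164)},
        ),
    ]
    if include_oriented_nuclei:
        specs += [
            StructureSpec(
                "lgn", "volume", "open", "principal_axis", 0.25, 0.2,
                shape="ellipsoid",
                shape_params={"center": (0.006, -0.024, -0.002),
                              "semi_axes": (0.0040, 0.0035, 0.0036)},
            ),
            StructureSpec(
                "egp", "volume", "open", "principal_axis", 0.0025, 1.5,
                shape="ellipsoid",
                shape_params={"center": (-0.016, 0.012, -0.010),
                              "semi_axes": (0.0083, 0.0060, 0.0072)},
            ),
            StructureSpec(
                "rpn", "volume", "open", "principal_axis", 0.0025, 2.0,
                shape="ellipsoid",
                shape_params={"center": (-0.004, 0.010, 0.022),
                              "semi_axes": (0.0097, 0.0062, 0.0082)},
            ),
        ]
    return specs


# Table-style electrophysiology for all eight structures, used by the current
# worked examples (name -> (kind, dmd, extent)).
STRUCTURE_TABLE = {
    "cortex": ("surface", 0.25, 750.0),
    "hippocampus": ("surface", 0.4, 15.0),
    "amygdala": ("volume", 1.0, 1.0),
    "thalamus": ("volume", 0.025, 8.0),
    "lgn": ("volume", 0.25, 0.2),
    "egp": ("volume", 0.0025, 1.5),
    "putamen": ("volume", 0.25, 9.0),
    "rpn": ("volume", 0.0025, 2.0),
}


# --------------------------------------------------------------------------
# mesh helpers
# --------------------------------------------------------------------------

def _face_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def vertex_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric vertex areas: one third of each adjacent face area."""
    fa = _face_areas(verts, faces)
    va = np.zeros(len(verts))
    for c in range(3):
        np.add.at(va, faces[:, c], fa / 3.0)
    return va


def vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Outward unit normals: area-weighted mean of adjacent face normals."""
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    fn = np.cross(a, b)  # face normal scaled by 2*area
    vn = np.zeros_like(verts)
    for c in range(3):
        np.add.at(vn, faces[:, c], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def mesh_adjacency(faces: np.ndarray, n_verts: int) -> list:
    nbrs = [set() for _ in range(n_verts)]
    for i, j, k in faces:
        nbrs[i].update((j, k))
        nbrs[j].update((i, k))
        nbrs[k].update((i, j))
    return [np.array(sorted(s), dtype=np.intp) for s in nbrs]


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# --------------------------------------------------------------------------
# structure builders
# --------------------------------------------------------------------------

def _wave_field(unit_pos: np.ndarray, amp: float, n_harmonics: int,
                omega: tuple, rng: np.random.Generator) -> np.ndarray:
    """Sulcus-like radial modulation in [-amp, amp] on the unit sphere.

    A sum of plane-wave harmonics with random directions and phases; the
    wavelength along the surface (~2*pi*R/omega, about 2 cm at default
    settings) and the bump amplitude (~3.5 mm) are chosen to mimic the
    dimensions of real sulci so that surface normals disperse away from the
    radial direction the way folded cortex does.
    """
    dirs = _random_unit_vectors(rng, n_harmonics)
    omegas = rng.uniform(omega[0], omega[1], n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    w = np.zeros(len(unit_pos))
    for d, o, p in zip(dirs, omegas, phases):
        w += np.cos(o * (unit_pos @ d) + p)
    w /= np.abs(w).max()  # unit peak -> amp is the bump height in metres
    return amp * w


def _build_cap(spec: StructureSpec, conductor: Conductor, subdivisions: int,
               rng: np.random.Generator):
    """Wavy spherical-cap cortex sheet; cap angle solved to hit target area."""
    p = spec.shape_params
    base_radius = p["base_radius"]
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(sphere.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    faces_all = np.asarray(sphere.faces, dtype=np.intp)
    wave = _wave_field(unit, p["amp"], p["n_harmonics"], p["omega"], rng)  # metres
    verts_full = unit * (base_radius + wave)[:, None]

    theta = np.arccos(np.clip(unit[:, 2], -1, 1))
    face_theta = theta[faces_all].mean(axis=1)
    target_mm2 = spec.target_extent * 100.0

    def cap_area(theta_max):
        keep = face_theta <= theta_max
        fa = _face_areas(verts_full, faces_all[keep])
        return fa.sum() * 1e6  # m^2 -> mm^2

    lo, hi = 0.2, np.pi
    if cap_area(hi) < target_mm2 * 0.95:
        raise SizingError(f"{spec.name}: target area unreachable (max "
                          f"{cap_area(hi) / 100:.1f} cm^2 < {spec.target_extent} cm^2)")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cap_area(mid) < target_mm2:
            lo = mid
        else:
            hi = mid
    theta_max = hi
    keep = face_theta <= theta_max
    faces = faces_all[keep]
    used = np.unique(faces)
    remap = -np.ones(len(verts_full), dtype=np.intp)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    verts = verts_full[used]

    areas = vertex_areas(verts, faces) * 1e6  # mm^2
    total = areas.sum()
    if abs(total - target_mm2) / target_mm2 > 0.05:
        raise SizingError(f"{spec.name}: realized area {total / 100:.1f} cm^2 "
                          f"misses target {spec.target_extent} cm^2 by >5%")
    normals = vertex_normals(verts, faces)
    return verts, normals, areas, faces


def _build_tube(spec: StructureSpec, conductor: Conductor, resolution: int,
                rng: np.random.Generator):
    """Curved open tube (hippocampus analog); tube radius solved for area."""
    p = spec.shape_params
    c = np.asarray(p["center"], dtype=float)
    c_hat = c / np.linalg.norm(c)
    # plane orthogonal to the radial direction -> all centreline points share
    # the same distance from the conductor centre (a shell at ~60% radius)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ref @ c_hat) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u1 = np.cross(c_hat, ref)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(c_hat, u1)

    n_u = 6 * resolution  # along the arc
    n_v = 2 * resolution  # around the tube
    span = np.deg2rad(p["arc_span_deg"])
    alphas = np.linspace(-span / 2, span / 2, n_u)
    target_mm2 = spec.target_extent * 100.0

    def build(rt):
        centreline = c + p["arc_radius"] * (np.cos(alphas)[:, None] * u1
                                            + np.sin(alphas)[:, None] * u2)
        tang = np.gradient(centreline, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        # frame: radial-ish normal and binormal per arc point
        n1 = np.cross(tang, c_hat)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(tang, n1)
        n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
        phis = np.arange(n_v) / n_v * 2 * np.pi
        verts = (centreline[:, None, :]
                 + rt * (np.cos(phis)[None, :, None] * n1[:, None, :]
                         + np.sin(phis)[None, :, None] * n2[:, None, :]))
        verts = verts.reshape(-1, 3)
        faces = []
        for i in range(n_u - 1):
            for j in range(n_v):
                a = i * n_v + j
                b = i * n_v + (j + 1) % n_v
                cc = (i + 1) * n_v + j
                d = (i + 1) * n_v + (j + 1) % n_v
                faces.append((a, b, d))
                faces.append((a, d, cc))
        faces = np.asarray(faces, dtype=np.intp)
        return verts, faces

    def area_of(rt):
        verts, faces = build(rt)
        return _face_areas(verts, faces).sum() * 1e6

    lo, hi = 0.2 * p["tube_radius0"], 4.0 * p["tube_radius0"]
    if not (area_of(lo) < target_mm2 < area_of(hi)):
        raise SizingError(f"{spec.name}: tube radius bracket misses target area")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if area_of(mid) < target_mm2:
            lo = mid
        else:
            hi = mid
    verts, faces = build(0.5 * (lo + hi))
    areas = vertex_areas(verts, faces) * 1e6
    normals = vertex_normals(verts, faces)
    # orient normals outward from the centreline (trimesh winding may flip)
    return verts, normals, areas, faces


def _build_ellipsoid(spec: StructureSpec, conductor: Conductor, spacing: float,
                     rng: np.random.Generator):
    """Regular grid filling an ellipsoid; semi-axes scaled to match volume."""
    p = spec.shape_params
    c = np.asarray(p["center"], dtype=float)
    semi = np.asarray(p["semi_axes"], dtype=float)
    target_mm3 = spec.target_extent * 1000.0
    voxel_mm3 = (spacing * 1000.0) ** 3

    # sub-voxel grid offset breaks the ellipsoid/grid symmetry so that the
    # voxel count grows in steps of ~1 as the envelope is scaled, letting the
    # bisection land within tolerance even for small nuclei
    grid_offset = spacing * np.array([0.23, 0.37, 0.41])

    def grid(scale):
        ax = semi * scale
        n = np.ceil(ax / spacing).astype(int) + 1
        ii = np.arange(-n[0], n[0] + 1)
        jj = np.arange(-n[1], n[1] + 1)
        kk = np.arange(-n[2], n[2] + 1)
        I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
        pts = np.stack([I, J, K], axis=-1).reshape(-1, 3) * spacing + grid_offset
        inside = ((pts / ax) ** 2).sum(axis=1) <= 1.0
        return pts[inside] + c, np.stack([I, J, K], axis=-1).reshape(-1, 3)[inside]

    def count(scale):
        return len(grid(scale)[0])

    n_target = target_mm3 / voxel_mm3
    lo, hi = 0.5, 2.0
    if not (count(lo) * voxel_mm3 < target_mm3 < count(hi) * voxel_mm3):
        raise SizingError(f"{spec.name}: volume bracket misses target")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if count(mid) < n_target:
            lo = mid
        else:
            hi = mid
    # pick whichever bracket end lands closer to the target volume
    best = min((lo, hi), key=lambda s: abs(count(s) * voxel_mm3 - target_mm3))
    pts, ijk = grid(best)
    total = len(pts) * voxel_mm3
    if abs(total - target_mm3) / target_mm3 > 0.05:
        raise SizingError(f"{spec.name}: realized volume {total / 1000:.2f} cm^3 "
                          f"misses target {spec.target_extent} cm^3 by >5%")
    sizes = np.full(len(pts), voxel_mm3)

    # 6-connectivity adjacency on the integer grid
    key = {tuple(v): i for i, v in enumerate(ijk)}
    adjacency = []
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for v in ijk:
        nb = [key[t] for o in offs if (t := (v[0] + o[0], v[1] + o[1], v[2] + o[2])) in key]
        adjacency.append(np.array(sorted(nb), dtype=np.intp))

    if spec.orientation_rule == "random":
        orients = _random_unit_vectors(rng, len(pts))
    else:  # principal_axis: dominant eigenvector of the envelope point cloud
        cov = np.cov((pts - c).T)
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, np.argmax(evals)]
        if axis[np.nonzero(axis)[0][0]] < 0:
            axis = -axis
        orients = np.tile(axis, (len(pts), 1))
    return pts, orients, sizes, adjacency


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def build_anatomy(specs: list[StructureSpec] | None = None,
                  conductor: Conductor | None = None,
                  mesh_resolution: str | dict = "default",
                  seed: int = 0) -> SourceSpace:
    """Build the full synthetic source space.

    Parameters
    ----------
    specs
        Structure definitions; ``default_specs()`` when omitted.
    conductor
        Spherical conductor (default radius 0.09 m at the origin).
    mesh_resolution
        ``'default'`` (icosphere subdivision 4, 2 mm grids), ``'small'``
        (subdivision 3, 4 mm grids — a fast test-scale model), or a dict with
        keys ``subdivisions``, ``grid_spacing``, ``tube_resolution``.
    seed
        Drives the cortical folding pattern, random dipole orientations and
        small nucleus-centre jitter, emulating inter-individual variability.

    Raises
    ------
    SizingError
        If a target extent cannot be met within 5 % at this resolution.
    GeometryError
        If structures overlap or any dipole leaves the conductor.
    """
    if specs is None:
        specs = default_specs()
    if not specs:
        raise ValueError("specs must be non-empty")
    if conductor is None:
        conductor = Conductor()
    if isinstance(mesh_resolution, str):
        res = {"default": {"subdivisions": 5, "grid_spacing": 0.002, "tube_resolution": 7},
               "small": {"subdivisions": 3, "grid_spacing": 0.004, "tube_resolution": 4},
               }[mesh_resolution]
    else:
        res = dict(mesh_resolution)

    ss = np.random.SeedSequence(seed)
    child_seeds = {s.name: np.random.default_rng(c)
                   for s, c in zip(specs, ss.spawn(len(specs)))}

    all_pos, all_ori, all_sizes, all_labels = [], [], [], []
    adjacency: list = []
    triangles: dict = {}
    slices: dict = {}
    offset = 0
    for spec in specs:
        rng = child_seeds[spec.name]
        if spec.shape == "cap":
            verts, orients, sizes, faces = _build_cap(spec, conductor,
                                                      res["subdivisions"], rng)
            adj = mesh_adjacency(faces, len(verts))
            triangles[spec.name] = faces + offset
        elif spec.shape == "tube":
            verts, orients, sizes, faces = _build_tube(spec, conductor,
                                                       res["tube_resolution"], rng)
            adj = mesh_adjacency(faces, len(verts))
            triangles[spec.name] = faces + offset
        elif spec.shape == "ellipsoid":
            # jitter nucleus centre by <=0.5 mm across seeds
            jitter = rng.uniform(-0.0005, 0.0005, 3)
            spec_j = replace(spec, shape_params={**spec.shape_params,
                                                 "center": tuple(np.asarray(spec.shape_params["center"]) + jitter)})
            verts, orients, sizes, adj = _build_ellipsoid(spec_j, conductor,
                                                          res["grid_spacing"], rng)
        else:
            raise ValueError(f"unknown shape {spec.shape!r}")

        all_pos.append(verts)
        all_ori.append(orients)
        all_sizes.append(sizes)
        all_labels.append(np.full(len(verts), spec.name, dtype="U32"))
        adjacency.extend([a + offset for a in adj])
        slices[spec.name] = slice(offset, offset + len(verts))
        offset += len(verts)

    positions = np.vstack(all_pos)
    orientations = np.vstack(all_ori)
    element_sizes = np.concatenate(all_sizes)
    labels = np.concatenate(all_labels)

    r = np.linalg.norm(positions - conductor.center_arr, axis=1)
    if np.any(r >= conductor.radius):
        bad = np.nonzero(r >= conductor.radius)[0]
        raise GeometryError(f"{len(bad)} dipoles on/outside the conductor "
                            f"(first: {bad[:5].tolist()})")

    _check_overlap(positions, labels, specs)

    return SourceSpace(positions=positions, orientations=orientations,
                       element_sizes=element_sizes, structure_labels=labels,
                       adjacency=adjacency, triangles=triangles,
                       specs={s.name: s for s in specs}, conductor=conductor,
                       structure_slices=slices)


def _check_overlap(positions: np.ndarray, labels: np.ndarray,
                   specs: list, margin: float = 0.001) -> None:
    """Raise if point clouds of distinct non-cortex structures come closer
    than ``margin`` metres (the cortex sheet sits on its own outer shell)."""
    names = [s.name for s in specs if s.name != "cortex"]
    clouds = {n: positions[labels == n] for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa, pb = clouds[a], clouds[b]
            d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
            if d2.min() < margin ** 2:
                raise GeometryError(f"structures {a!r} and {b!r} overlap "
                                    f"(min distance {np.sqrt(d2.min()) * 1000:.2f} mm)")


def build_sensors(n_sensors: int = 151, helmet_coverage: float = 0.62,
                  radius: float = 0.104,
                  conductor: Conductor | None = None) -> SensorArray:
    """Quasi-uniform radial magnetometer helmet on a concentric sphere.

    ``helmet_coverage`` is the covered fraction of the full sphere, spiralling
    down from the +z pole (0.5 = upper hemisphere).  Uses a Fibonacci spiral,
    so pairwise angular spacing is near-uniform.
    """
    if n_sensors < 64:
        raise ValueError("n_sensors must be >= 64")
    if not 0 < helmet_coverage <= 1:
        raise ValueError("helmet_coverage must be in (0, 1]")
    if conductor is None:
        conductor = Conductor()
    center = conductor.center_arr
    i = np.arange(n_sensors)
    z = 1.0 - 2.0 * helmet_coverage * (i + 0.5) / n_sensors
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1 - z ** 2, 0, None))
    unit = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    positions = center + radius * unit
    names = [f"MEG{k + 1:03d}" for k in range(n_sensors)]
    return SensorArray(positions=positions, orientations=unit,
                       sphere_center=center, sphere_radius=radius, names=names)

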