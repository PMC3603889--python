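"""File formats: HDF5 bundles, TSV tables, OBJ surface meshes."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .anatomy import Conductor, SensorArray, SourceSpace, StructureSpec
from .forward import GainMatrix
from .inverse import InverseKernel


def save_source_space(path, space: SourceSpace) -> None:
    """Write a source-space bundle (HDF5) plus a JSON sidecar of the
    structure specs and conductor."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=space.positions)
        f.create_dataset("orientations", data=space.orientations)
        f.create_dataset("element_sizes", data=space.element_sizes)
        f.create_dataset("labels", data=np.array(space.structure_labels, dtype="S32"))
        edges = np.array([(i, int(j)) for i, nbrs in enumerate(space.adjacency)
                          for j in nbrs if int(j) > i], dtype=np.int64)
        f.create_dataset("edges", data=edges)
        tri = f.create_group("triangles")
        for name, faces in space.triangles.items():
            tri.create_dataset(name, data=faces)
        sl = f.create_group("slices")
        for name, s in space.structure_slices.items():
            sl.create_dataset(name, data=np.array([s.start, s.stop]))
    sidecar = {"conductor": {"center": list(space.conductor.center),
                             "radius": space.conductor.radius},
               "specs": [{k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in spec.__dict__.items()}
                         for spec in space.specs.values()]}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_source_space(path) -> SourceSpace:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    conductor = Conductor(center=tuple(sidecar["conductor"]["center"]),
                          radius=sidecar["conductor"]["radius"])
    specs = {}
    for d in sidecar["specs"]:
        d = dict(d)
        d["shape_params"] = {k: (tuple(v) if isinstance(v, list) else v)
                             for k, v in d.get("shape_params", {}).items()}
        spec = StructureSpec(**d)
        specs[spec.name] = spec
    with h5py.File(path, "r") as f:
        positions = f["positions"][()]
        orientations = f["orientations"][()]
        element_sizes = f["element_sizes"][()]
        labels = f["labels"][()].astype("U32")
        edges = f["edges"][()]
        triangles = {k: f["triangles"][k][()] for k in f["triangles"]}
        slices = {k: slice(*f["slices"][k][()]) for k in f["slices"]}
    adjacency = [set() for _ in range(len(positions))]
    for i, j in edges:
        adjacency[i].add(int(j))
        adjacency[j].add(int(i))
    adjacency = [np.array(sorted(s), dtype=np.intp) for s in adjacency]
    return SourceSpace(positions=positions, orientations=orientations,
                       element_sizes=element_sizes, structure_labels=labels,
                       adjacency=adjacency, triangles=triangles, specs=specs,
                       conductor=conductor, structure_slices=slices)


def export_surfaces_obj(space: SourceSpace, directory) -> list:
    """One Wavefront OBJ per surface structure; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, faces in space.triangles.items():
        sl = space.structure_slices[name]
        mesh = trimesh.Trimesh(vertices=space.positions[sl],
                               faces=faces - sl.start, process=False)
        out = directory / f"{name}.obj"
        mesh.export(out)
        written.append(out)
    return written


def save_sensors_tsv(path, sensors: SensorArray) -> None:
    df = pd.DataFrame({"name": sensors.names,
                       "x": sensors.positions[:, 0], "y": sensors.positions[:, 1],
                       "z": sensors.positions[:, 2],
                       "ox": sensors.orientations[:, 0],
                       "oy": sensors.orientations[:, 1],
                       "oz": sensors.orientations[:, 2]})
    df.to_csv(path, sep="\t", index=False)


def load_sensors_tsv(path, sphere_center=(0.0, 0.0, 0.0),
                     sphere_radius: float = 0.11) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    return SensorArray(positions=df[["x", "y", "z"]].to_numpy(),
                       orientations=df[["ox", "oy", "oz"]].to_numpy(),
                       sphere_center=np.asarray(sphere_center, float),
                       sphere_radius=sphere_radius,
                       names=df["name"].tolist())


def save_gain(path, gain: GainMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=gain.values)
        f.create_dataset("gain_free", data=gain.free)
        f.create_dataset("row_sensors", data=np.array(gain.sensors.names, dtype="S16"))
        f.create_dataset("col_sources", data=np.arange(gain.n_sources))


def load_gain(path, space: SourceSpace, sensors: SensorArray) -> GainMatrix:
    with h5py.File(path, "r") as f:
        values = f["gain"][()]
        free = f["gain_free"][()]
    return GainMatrix(values=values, free=free, source_space=space, sensors=sensors)


def save_kernel(path, kernel: InverseKernel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kernel", data=kernel.matrix)
        f.create_dataset("weights", data=kernel.source_covariance_diag)
        f.attrs["method"] = kernel.method
        f.attrs["lambda2"] = kernel.lambda2
        f.attrs["w"] = kernel.weighting_exponent
        f.attrs["snr_reg"] = kernel.snr_reg


def load_kernel(path) -> InverseKernel:
    with h5py.File(path, "r") as f:
        return InverseKernel(matrix=f["kernel"][()], method=str(f.attrs["method"]),
                             lambda2=float(f.attrs["lambda2"]),
                             source_covariance_diag=f["weights"][()],
                             weighting_exponent=float(f.attrs["w"]),
                             snr_reg=float(f.attrs["snr_reg"]))


def save_map_tsv(path, space: SourceSpace, values: np.ndarray,
                 value_name: str = "value") -> None:
    """Per-source scalar map as TSV (source_id, structure, value)."""
    pd.DataFrame({"source_id": np.arange(space.n_sources),
                  "structure": space.structure_labels,
                  value_name: values}).to_csv(path, sep="\t", index=False)
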