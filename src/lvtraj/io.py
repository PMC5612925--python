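"""On-disk dataset formats.

A dataset directory holds:

``manifest.yaml``
    case list (id, group, raw frame count, raw ES phase), surfaces,
    landmark count and the ordered basal-rim landmark indices;
``<case_id>_<surface>.csv``
    tidy landmark table with columns ``frame, landmark, x, y, z``
    (1-based frame and landmark indices; coordinates in mm);
``mesh_<surface>.txt``
    triangle list, one ``3 i j k`` line per face (0-based vertex indices);
``clinical.csv`` (optional)
    per-case ground-truth or measured EDV/ESV/EF.

Plain-text round trips are exact: coordinates are written with ``repr``
shortest-float precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import RawMotionSequence, SURFACES
from .registration import LVMesh
from .simulate import SyntheticCase


@dataclass
class DatasetOnDisk:
    """A loaded dataset: per-surface raw sequences, mesh connectivity, clinical table."""

    sequences: dict              # surface -> list[RawMotionSequence], case-aligned
    meshes: dict                 # surface -> LVMesh
    clinical: pd.DataFrame | None
    manifest: dict

    def cases(self) -> list:
        return [c["case_id"] for c in self.manifest["cases"]]


def write_dataset(path, cases: list, clinical: pd.DataFrame | None = None) -> Path:
    """Write a simulated cohort (list of :class:`SyntheticCase`) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"surfaces": list(SURFACES),
                "n_landmarks": int(cases[0].endo.n_landmarks),
                "basal_ring": [int(i) for i in cases[0].mesh.basal_ring],
                "cases": []}
    for case in cases:
        manifest["cases"].append({"case_id": case.case_id, "group": case.group,
                                  "n_raw_frames": int(case.endo.n_frames),
                                  "es_phase_raw": float(case.endo.es_phase_raw)})
        for surf in SURFACES:
            seq = case.surface(surf)
            T, k, _ = seq.frames.shape
            table = pd.DataFrame({
                "frame": np.repeat(np.arange(1, T + 1), k),
                "landmark": np.tile(np.arange(1, k + 1), T),
                "x": seq.frames[:, :, 0].ravel(),
                "y": seq.frames[:, :, 1].ravel(),
                "z": seq.frames[:, :, 2].ravel(),
            })
            table.to_csv(path / f"{case.case_id}_{surf}.csv", index=False)
    for surf in SURFACES:
        faces = cases[0].mesh.faces
        with open(path / f"mesh_{surf}.txt", "w") as f:
            f.write("# triangle list, 0-based vertex indices\n")
            for tri in faces:
                f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    with open(path / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    if clinical is None:
        clinical = pd.DataFrame([{"case_id": c.case_id, "group": c.group,
                                  "edv": c.truth["edv_ml"], "esv": c.truth["esv_ml"],
                                  "ef": c.truth["ef"]} for c in cases])
    clinical.to_csv(path / "clinical.csv", index=False)
    return path


def read_mesh(path, basal_ring=None) -> LVMesh:
    faces = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] != "3" or len(parts) != 4:
                raise ValueError(f"{path}: bad triangle line {line!r}")
            faces.append([int(p) for p in parts[1:]])
    return LVMesh(faces=np.asarray(faces, dtype=int),
                  basal_ring=None if basal_ring is None else np.asarray(basal_ring, dtype=int))


def read_dataset(path) -> DatasetOnDisk:
    """Load a dataset directory, validating counts and coordinates case by case."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {path}")
    with open(manifest_path) as f:
        manifest = yaml.safe_load(f)
    k_expected = int(manifest["n_landmarks"])
    basal_ring = manifest.get("basal_ring")

    meshes = {}
    for surf in manifest["surfaces"]:
        meshes[surf] = read_mesh(path / f"mesh_{surf}.txt", basal_ring=basal_ring)

    sequences: dict = {surf: [] for surf in manifest["surfaces"]}
    for entry in manifest["cases"]:
        cid = entry["case_id"]
        for surf in manifest["surfaces"]:
            csv_path = path / f"{cid}_{surf}.csv"
            if not csv_path.exists():
                raise FileNotFoundError(f"missing landmark table for case {cid!r} "
                                        f"surface {surf!r}: {csv_path}")
            table = pd.read_csv(csv_path)
            bad = table[["x", "y", "z"]].isna().any(axis=1)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
                raise ValueError(f"case {cid!r} surface {surf!r}: NaN coordinate "
                                 f"at {csv_path.name} line {row}")
            T = int(entry["n_raw_frames"])
            k = table["landmark"].max()
            if k != k_expected or len(table) != T * k_expected:
                raise ValueError(f"case {cid!r} surface {surf!r}: inconsistent landmark "
                                 f"count (expected {T}x{k_expected}, got {len(table)} rows)")
            frames = np.empty((T, k_expected, 3))
            order = table.sort_values(["frame", "landmark"])
            frames[:, :, 0] = order["x"].to_numpy().reshape(T, k_expected)
            frames[:, :, 1] = order["y"].to_numpy().reshape(T, k_expected)
            frames[:, :, 2] = order["z"].to_numpy().reshape(T, k_expected)
            sequences[surf].append(RawMotionSequence(
                case_id=cid, group=entry["group"], surface=surf, frames=frames,
                es_phase_raw=float(entry["es_phase_raw"])))
    clinical = None
    if (path / "clinical.csv").exists():
        clinical = pd.read_csv(path / "clinical.csv")
    return DatasetOnDisk(sequences=sequences, meshes=meshes, clinical=clinical,
                         manifest=manifest)
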