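"""End-to-end orchestration: simulate/read -> register -> transport -> attributes
-> group tests -> classification, with provenance.

All randomness flows from one root seed: stage seeds are spawned from
``numpy.random.SeedSequence(root_seed)`` in a fixed order (simulation,
dispersion permutations, SVM splits), so a rerun with the same configuration
reproduces every output file byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import build_feature_sets, classification_table, \
    compute_traditional_indicators, run_repeated_svm
from .datatypes import SURFACES
from .io import DatasetOnDisk, read_dataset
from .registration import RegistrationSpec, register_sequence
from .simulate import SimulationSpec, generate_cohort, lv_mesh
from .trajectory import anova_adjusted, attribute_table, dispersion_test, per_time_tests, \
    trajectory_shape_analysis, trajectories
from .transport import run_ls_pca

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of a full analysis run."""

    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    registration: RegistrationSpec = field(default_factory=RegistrationSpec)
    dataset_path: str | None = None          # read instead of simulating if set
    spaces: tuple = ("sss", "ss")
    surfaces: tuple = SURFACES
    n_axes: int = 3
    n_shape_pcs: int = 15
    n_pc_all_times: int = 10
    n_runs: int = 1000
    n_train_per_class: int = 200
    n_test_per_class: int = 100
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for s in self.spaces:
            if s not in ("sss", "ss"):
                raise ValueError(f"unknown space label {s!r}")
        for s in self.surfaces:
            if s not in SURFACES:
                raise ValueError(f"unknown surface label {s!r}")
        if self.n_axes < 2:
            raise ValueError("n_axes must be >= 2 (plane angles need PC2/PC3)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "simulation" in raw:
            raw["simulation"] = SimulationSpec(**raw["simulation"])
        if "registration" in raw:
            raw["registration"] = RegistrationSpec(**raw["registration"])
        for key in ("spaces", "surfaces"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def _stage_seeds(root_seed: int) -> dict:
    children = np.random.SeedSequence(root_seed).spawn(3)
    return {name: int(c.generate_state(1)[0]) % (2 ** 31)
            for name, c in zip(("simulation", "dispersion", "svm"), children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write result tables under ``config.out_dir``.

    Returns a dict with the in-memory products (transported datasets,
    attribute tables, test tables, classification reports).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings = {}
    t0 = time.perf_counter()

    # --- data ---------------------------------------------------------
    if config.dataset_path is not None:
        disk: DatasetOnDisk = read_dataset(config.dataset_path)
        raw = disk.sequences
        mesh = disk.meshes["endo"]
        n_cases = len(disk.manifest["cases"])
    else:
        sim = dataclasses.replace(config.simulation, seed=seeds["simulation"])
        cases = generate_cohort(sim)
        raw = {surf: [c.surface(surf) for c in cases] for surf in config.surfaces}
        mesh = cases[0].mesh
        n_cases = len(cases)
    timings["data"] = time.perf_counter() - t0

    # --- temporal registration ----------------------------------------
    t0 = time.perf_counter()
    registered = {}
    for surf in config.surfaces:
        for s in raw[surf]:
            try:
                registered.setdefault(surf, []).append(
                    register_sequence(s, config.registration))
            except Exception as exc:
                raise RuntimeError(f"stage 'registration' failed for case "
                                   f"{s.case_id!r} surface {surf!r}") from exc
    timings["registration"] = time.perf_counter() - t0
    es_index = config.registration.nominal_es_frame

    # --- traditional indicators ---------------------------------------
    t0 = time.perf_counter()
    clinical = compute_traditional_indicators(registered["endo"], mesh) \
        if "endo" in config.surfaces else None
    if clinical is not None:
        clinical.to_csv(out / "clinical_measured.csv", index=False)
    timings["volumes"] = time.perf_counter() - t0

    # --- transport + attributes + tests -------------------------------
    t0 = time.perf_counter()
    transported = {}
    attributes = {}
    test_rows = []
    per_time = {}
    for space in config.spaces:
        for surf in config.surfaces:
            try:
                ds, attr, rows, pt = _analyze_space_surface(
                    config, registered[surf], space, surf, es_index, seeds, out)
            except Exception as exc:
                raise RuntimeError(f"stage 'transport/attributes' failed for space "
                                   f"{space!r} surface {surf!r}") from exc
            transported[(space, surf)] = ds
            attributes[(space, surf)] = attr
            test_rows.extend(rows)
            per_time[(space, surf)] = pt
    tests = pd.DataFrame(test_rows)
    tests.to_csv(out / "group_tests.csv", index=False)
    timings["transport_attributes"] = time.perf_counter() - t0

    # --- classification -------------------------------------------------
    t0 = time.perf_counter()
    table = None
    reports = []
    if config.n_runs > 0:
        feature_sets = build_feature_sets(transported, clinical=clinical,
                                          n_axes=config.n_axes,
                                          n_shape_pcs=config.n_shape_pcs,
                                          es_index=es_index,
                                          n_pc_all_times=config.n_pc_all_times)
        labels = next(iter(transported.values())).group_labels()
        reports = [run_repeated_svm(fs, labels, n_runs=config.n_runs,
                                    n_train_per_class=config.n_train_per_class,
                                    n_test_per_class=config.n_test_per_class,
                                    seed=seeds["svm"], kernel=config.svm_kernel,
                                    C=config.svm_c)
                   for fs in feature_sets]
        table = classification_table(reports)
        table.to_csv(out / "classification.csv", index=False)
        with open(out / "classification_summary.json", "w") as f:
            json.dump({f"{r.space}/{r.surface}/{r.feature_set}": r.means
                       for r in reports}, f, indent=2)
    timings["classification"] = time.perf_counter() - t0

    provenance = {"config": config.to_dict(), "config_hash": config.config_hash(),
                  "stage_seeds": seeds, "n_cases": n_cases,
                  "timings_s": {k: round(v, 3) for k, v in timings.items()},
                  "versions": _versions()}
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2, default=str)

    return {"transported": transported, "attributes": attributes, "tests": tests,
            "per_time": per_time, "classification": table, "reports": reports,
            "clinical": clinical, "provenance": provenance}


def _analyze_space_surface(config: PipelineConfig, sequences: list, space: str,
                           surf: str, es_index: int, seeds: dict, out: Path):
    """Transport + attributes + group tests for one (space, surface) combination."""
    ds = run_ls_pca(sequences, mode=space)
    attr = attribute_table(ds, n_axes=config.n_axes,
                           n_shape_pcs=config.n_shape_pcs, es_index=es_index)
    attr.to_csv(out / f"attributes_{space}_{surf}.csv", index=False)

    labels = ds.group_labels()
    rows = []
    res = anova_adjusted(attr["traj_size"], labels)
    rows.append({"attribute": "traj_size", "space": space, "surface": surf,
                 "statistic": res.statistic, "p_value": res.p_value,
                 "r_squared_adj": res.r_squared_adj, "test": res.test_kind})
    for plane in ("12", "13"):
        vals = attr[f"angle_{plane}"]
        ok = vals.notna()
        res = anova_adjusted(vals[ok], labels[ok.to_numpy()])
        rows.append({"attribute": f"angle_pc1_pc{plane[1]}", "space": space,
                     "surface": surf, "statistic": res.statistic,
                     "p_value": res.p_value,
                     "r_squared_adj": res.r_squared_adj, "test": res.test_kind})
    trajs = trajectories(ds, n_axes=config.n_axes)
    shape_scores, _, manova = trajectory_shape_analysis(
        trajs, labels, n_pcs=config.n_shape_pcs)
    rows.append({"attribute": "traj_shape", "space": space, "surface": surf,
                 "statistic": manova.statistic, "p_value": manova.p_value,
                 "r_squared_adj": None, "test": manova.test_kind})
    disp = dispersion_test(shape_scores, labels, n_perm=config.n_perm,
                           seed=seeds["dispersion"])
    rows.append({"attribute": "traj_shape_dispersion", "space": space,
                 "surface": surf, "statistic": disp.statistic,
                 "p_value": disp.p_value, "r_squared_adj": None,
                 "test": disp.test_kind})
    pt = per_time_tests(ds, axis=0)
    pt.to_csv(out / f"per_time_pc1_{space}_{surf}.csv")
    return ds, attr, rows, pt


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels
    from . import __version__
    return {"lvtraj": __version__, "numpy": np.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__, "statsmodels": statsmodels.__version__,
            "pandas": pd.__version__}
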