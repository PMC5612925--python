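"""Disease-status classification by repeated random-split SVM.

The evaluation protocol: the two classes are repeatedly (1,000 times by
default) split into stratified, disjoint train/test subsets (200 + 200
train, 100 + 100 test at full cohort size; two-thirds / one-third per class
when the cohort is smaller), a support vector machine is fitted on the
standardized training features, and accuracy, specificity, sensitivity and
ROC AUC are recorded on the held-out cases.  Mean metrics over all runs
summarize each feature set.  Controls are the negative class, MI the
positive class.  Traditional clinical indicators (EDV, ESV, EF from cavity
volume integration) run through the identical protocol for comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .registration import LVMesh, sequence_volumes
from .trajectory import trajectories, trajectory_angle, trajectory_shape_analysis, \
    trajectory_size
from .transport import TransportedDataset

logger = logging.getLogger(__name__)

NEGATIVE, POSITIVE = "Control", "MI"


@dataclass
class FeatureSet:
    """A named per-case feature matrix entering the classification protocol."""

    name: str
    matrix: np.ndarray           # (n_cases, d)
    space: str = "none"          # sss | ss | none
    surface: str = "none"        # endo | epi | none

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D (n_cases, d)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"feature set {self.name!r} contains missing values")


@dataclass
class ClassificationReport:
    """Mean and per-run classification metrics for one feature set."""

    feature_set: str
    n_runs: int
    seed: int
    accuracy: np.ndarray         # per-run
    specificity: np.ndarray
    sensitivity: np.ndarray
    auc: np.ndarray
    space: str = "none"
    surface: str = "none"

    @property
    def means(self) -> dict:
        return {"accuracy": float(self.accuracy.mean()),
                "specificity": float(self.specificity.mean()),
                "sensitivity": float(self.sensitivity.mean()),
                "auc": float(self.auc.mean())}

    def to_row(self) -> dict:
        row = {"feature_set": self.feature_set, "space": self.space,
               "surface": self.surface, "n_runs": self.n_runs, "seed": self.seed}
        row.update(self.means)
        return row


def _split_sizes(class_counts: dict, n_train: int, n_test: int) -> tuple[int, int]:
    """Scale the per-class split down (2/3 train, 1/3 test) for small cohorts."""
    smallest = min(class_counts.values())
    if smallest >= n_train + n_test:
        return n_train, n_test
    tr = max(2, int(np.floor(smallest * 2 / 3)))
    te = smallest - tr
    if te < 1:
        raise ValueError(f"class of size {smallest} too small to split")
    logger.warning("cohort smaller than %d+%d per class; scaled split to %d train / %d test",
                   n_train, n_test, tr, te)
    return tr, te


def run_repeated_svm(fs: FeatureSet, labels, n_runs: int = 1000,
                     n_train_per_class: int = 200, n_test_per_class: int = 100,
                     seed: int = 0, kernel: str = "linear", C: float = 1.0,
                     null_permutation: bool = False) -> ClassificationReport:
    """Repeated stratified random-split SVM evaluation of one feature set.

    Features are z-scored on the training portion of each split only; AUC
    uses continuous decision values.  ``null_permutation=True`` permutes the
    labels independently before every split — the exact permutation null of
    the whole protocol, used for calibration.
    """
    labels = np.asarray(labels)
    X = fs.matrix
    if len(labels) != len(X):
        raise ValueError("labels and feature rows are misaligned")
    classes = (NEGATIVE, POSITIVE)
    idx = {c: np.flatnonzero(labels == c) for c in classes}
    counts = {c: len(v) for c, v in idx.items()}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 cases; got {counts}")
    n_tr, n_te = _split_sizes(counts, n_train_per_class, n_test_per_class)

    rng = np.random.default_rng(seed)
    acc = np.empty(n_runs)
    spe = np.empty(n_runs)
    sen = np.empty(n_runs)
    auc = np.empty(n_runs)
    for r in range(n_runs):
        run_labels = rng.permutation(labels) if null_permutation else labels
        run_idx = {c: np.flatnonzero(run_labels == c) for c in classes}
        tr_rows, te_rows = [], []
        for c in classes:
            perm = rng.permutation(run_idx[c])
            tr_rows.append(perm[:n_tr])
            te_rows.append(perm[n_tr:n_tr + n_te])
        tr = np.concatenate(tr_rows)
        te = np.concatenate(te_rows)
        assert not np.intersect1d(tr, te).size, "train/test overlap"
        y_tr = (run_labels[tr] == POSITIVE).astype(int)
        y_te = (run_labels[te] == POSITIVE).astype(int)
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel=kernel, C=C)
        clf.fit(scaler.transform(X[tr]), y_tr)
        Xte = scaler.transform(X[te])
        pred = clf.predict(Xte)
        dec = clf.decision_function(Xte)
        tp = np.sum((pred == 1) & (y_te == 1))
        tn = np.sum((pred == 0) & (y_te == 0))
        acc[r] = (tp + tn) / len(y_te)
        sen[r] = tp / max(np.sum(y_te == 1), 1)
        spe[r] = tn / max(np.sum(y_te == 0), 1)
        if len(np.unique(y_te)) < 2:
            auc[r] = 0.5
        else:
            auc[r] = roc_auc_score(y_te, dec)
    return ClassificationReport(feature_set=fs.name, n_runs=n_runs, seed=seed,
                                accuracy=acc, specificity=spe, sensitivity=sen,
                                auc=auc, space=fs.space, surface=fs.surface)


# ---------------------------------------------------------------------------
# Feature-set menu
# ---------------------------------------------------------------------------

def build_feature_sets(transported: dict, clinical: pd.DataFrame | None = None,
                       n_axes: int = 3, n_shape_pcs: int = 15, es_index: int = 11,
                       n_pc_all_times: int = 10) -> list:
    """Emit the full menu of morphometric and traditional feature sets.

    ``transported`` maps ``(space, surface)`` (e.g. ``("sss", "endo")``) to a
    :class:`TransportedDataset`.  Per space and surface: the two plane
    angles, trajectory size, the leading trajectory-shape PCs, single-PC
    scores at all homologous times (PC1..PC3, d = n_frames each) and
    PC1-PC10 at all homologous times (d = 10 * n_frames).  ``clinical``
    (columns ``case_id``, ``ef``, ``edv``, ``esv``) contributes the
    traditional indicators.  All matrices are aligned on the case order of
    the first transported dataset.
    """
    out: list[FeatureSet] = []
    ref_ids = None
    for (space, surface), ds in transported.items():
        if ref_ids is None:
            ref_ids = list(ds.case_ids)
        elif list(ds.case_ids) != ref_ids:
            raise ValueError(f"case order of {(space, surface)} differs from the first dataset")
        trajs = trajectories(ds, n_axes=n_axes)
        labels = ds.group_labels()
        sizes = np.array([trajectory_size(t) for t in trajs])[:, None]
        out.append(FeatureSet("traj_size", sizes, space, surface))
        for plane in ("12", "13"):
            ang = np.array([trajectory_angle(t, plane, es_index=es_index) for t in trajs])
            out.append(FeatureSet(f"angle_pc1_pc{plane[1]}", ang[:, None], space, surface))
        shape_scores, _, _ = trajectory_shape_analysis(trajs, labels, n_pcs=n_shape_pcs)
        out.append(FeatureSet(f"traj_shape_{shape_scores.shape[1]}pc", shape_scores,
                              space, surface))
        per_frame = ds.case_scores()
        for axis in range(min(n_axes, per_frame.shape[2])):
            out.append(FeatureSet(f"pc{axis + 1}_all_times", per_frame[:, :, axis],
                                  space, surface))
        k = min(n_pc_all_times, per_frame.shape[2])
        out.append(FeatureSet(f"pc1_{k}_all_times",
                              per_frame[:, :, :k].reshape(len(trajs), -1), space, surface))
    if clinical is not None:
        cl = clinical.set_index("case_id")
        if ref_ids is not None:
            missing = [c for c in ref_ids if c not in cl.index]
            if missing:
                raise ValueError(f"clinical table missing cases {missing[:5]}")
            cl = cl.loc[ref_ids]
        for name in ("ef", "edv", "esv"):
            out.append(FeatureSet(name, cl[name].to_numpy()[:, None]))
    return out


def compute_traditional_indicators(endo_sequences: list, mesh: LVMesh) -> pd.DataFrame:
    """EDV, ESV (ml) and EF from registered endocardial sequences.

    EDV is the frame-1 volume, ESV the minimum frame volume,
    EF = (EDV - ESV) / EDV.  Coordinates are interpreted as mm.
    """
    rows = []
    for seq in endo_sequences:
        vols = sequence_volumes(seq, mesh) / 1000.0
        edv = float(vols[0])
        esv = float(vols.min())
        rows.append({"case_id": seq.case_id, "group": seq.group,
                     "edv": edv, "esv": esv, "ef": (edv - esv) / edv,
                     "es_frame": int(np.argmin(vols)) + 1})
    return pd.DataFrame(rows)


def classification_table(reports: list) -> pd.DataFrame:
    """Summary table of mean metrics, one row per feature set."""
    return pd.DataFrame([r.to_row() for r in reports])
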