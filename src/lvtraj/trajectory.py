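"""Attributes of cycle trajectories in PC space, and their group tests.

After Linear Shift + PCA each case traces an ordered path of ``n_frames``
points in PC-score space (the first three axes by default).  The path is
treated as a geometric object with three attributes:

size
    centroid size of the point set (tested by one-way ANOVA with
    adjusted R-squared as the effect size);
orientation
    the four-quadrant angle, in the PC1/PC2 and PC1/PC3 planes, of the
    vector from the ED score to the ES score, reported in [0, 360) degrees;
shape
    the Procrustes shape of the path: trajectories are superimposed as
    configurations of ``n_frames`` "landmarks" in m dimensions (with
    scaling — size is its own attribute), PCA'd, and the leading scores
    compared by MANOVA (Wilks' lambda with Rao's F approximation) plus a
    permutation test of multivariate dispersion.

Per-frame score differences are additionally tested with one ANOVA per
homologous time, flagged after Benjamini-Hochberg correction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import SS, centroid_size, fit_pca, gpa
from .transport import TransportedDataset

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    """Outcome of one group-difference test."""

    statistic: float
    p_value: float
    r_squared_adj: float | None
    test_kind: str                    # anova | manova_wilks | dispersion_perm
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-trajectory attributes
# ---------------------------------------------------------------------------

def trajectories(ds: TransportedDataset, n_axes: int = 3) -> np.ndarray:
    """Per-case paths of PC scores, ``(n_cases, n_frames, n_axes)``."""
    if n_axes > ds.scores.shape[1]:
        raise IndexError(f"requested {n_axes} axes; only {ds.scores.shape[1]} available")
    return ds.case_scores(n_axes)


def trajectory_size(points) -> float:
    """Centroid size of one trajectory's point set (translation-invariant)."""
    return centroid_size(points)


def trajectory_angle(points, plane: str = "12", es_index: int = 11) -> float:
    """Orientation of the ED -> ES vector in a 2-D PC plane, degrees in [0, 360).

    ``plane`` selects PC1/PC2 (``"12"``) or PC1/PC3 (``"13"``); ``es_index``
    is the 1-based nominal ES frame (11 under the default registration).
    """
    pts = np.asarray(points, dtype=float)
    axes = {"12": (0, 1), "13": (0, 2)}
    if plane not in axes:
        raise ValueError(f"plane must be '12' or '13'; got {plane!r}")
    i, j = axes[plane]
    if not 1 < es_index <= pts.shape[0]:
        raise ValueError(f"es_index {es_index} outside trajectory of {pts.shape[0]} frames")
    vec = pts[es_index - 1, [i, j]] - pts[0, [i, j]]
    if np.hypot(*vec) == 0.0:
        raise ValueError("undefined angle: ED and ES coincide in this plane")
    return float(np.degrees(np.arctan2(vec[1], vec[0])) % 360.0)


def circular_variance(angles_deg) -> float:
    """1 - mean resultant length; diagnostic for angle comparisons on the circle."""
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(1.0 - np.abs(np.mean(np.exp(1j * ang))))


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    return values, groups, labels


def anova_adjusted(values, groups) -> GroupTestResult:
    """One-way ANOVA with adjusted R-squared effect size.

    ``adj R^2 = 1 - (1 - R^2) (n - 1) / (n - g)``; degenerate inputs with
    zero within-group variance and equal means report F = 0, p = 1.
    """
    values, groups, labels = _group_arrays(values, groups)
    samples = [values[groups == lab] for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two cases")
    n, g = len(values), len(labels)
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    sst = ssb + ssw
    if sst == 0.0:
        return GroupTestResult(0.0, 1.0, 0.0, "anova")
    if ssw == 0.0:
        stat, p = (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    else:
        stat = (ssb / (g - 1)) / (ssw / (n - g))
        p = float(stats.f.sf(stat, g - 1, n - g))
    r2 = ssb / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - g)
    return GroupTestResult(float(stat), float(p), float(r2_adj), "anova",
                           extra={"r_squared": float(r2)})


def wilks_manova(X, groups) -> GroupTestResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    ``lambda = det(W) / det(W + B)`` for within/between SSCP matrices;
    columns with (near-)zero total variance are dropped first.  Degenerate
    inputs with no variation return lambda = 1, p = 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X, groups, labels = _group_arrays(X, groups)
    n, g = X.shape[0], len(labels)
    total_var = X.var(axis=0)
    keep = total_var > 1e-12 * max(total_var.max(initial=0.0), 1.0)
    X = X[:, keep]
    p = X.shape[1]
    if p == 0:
        return GroupTestResult(1.0, 1.0, None, "manova_wilks", extra={"wilks_lambda": 1.0})
    if n - g < p:
        raise ValueError(f"too few error df ({n - g}) for {p} variables")

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        sub = X[groups == lab]
        m = sub.mean(axis=0)
        d = sub - m
        W += d.T @ d
        B += np.outer(m - grand, m - grand) * len(sub)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular within-group SSCP; reduce the number of score columns")
    lam = float(np.exp(logdet_w - logdet_t))

    q = g - 1                                  # hypothesis df
    v = n - g                                  # error df
    t = np.sqrt((p ** 2 * q ** 2 - 4) / (p ** 2 + q ** 2 - 5)) if p ** 2 + q ** 2 - 5 > 0 else 1.0
    w = v + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q) / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    p_value = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return GroupTestResult(float(F), p_value, None, "manova_wilks",
                           extra={"wilks_lambda": lam, "df1": df1, "df2": float(df2)})


def trajectory_shape_analysis(trajs, groups, n_pcs: int = 15):
    """Procrustes shape analysis of trajectories plus a MANOVA on the scores.

    Trajectories (``(n, n_frames, m)``) are superimposed by GPA *with*
    scaling (shape-space GPA — trajectory size is analyzed separately),
    PCA'd, and the first ``n_pcs`` score columns tested for a group
    difference with Wilks' lambda.  Returns ``(shape_scores, PCModel,
    GroupTestResult)``.
    """
    trajs = np.asarray(trajs, dtype=float)
    if trajs.ndim != 3:
        raise ValueError("trajs must be (n_cases, n_frames, m)")
    aligned = gpa(trajs, mode=SS)
    model = fit_pca(aligned.aligned.reshape(len(trajs), -1))
    scores = model.transform(aligned.aligned.reshape(len(trajs), -1))
    available = int(np.sum(model.variances > 1e-12 * max(model.variances.max(initial=0.0), 1.0)))
    if n_pcs > available:
        logger.warning("requested %d trajectory-shape PCs but only %d informative; clipping",
                       n_pcs, available)
        n_pcs = available
    shape_scores = scores[:, :n_pcs]
    # keep error df ahead of dimensionality for the MANOVA
    n, g = len(trajs), len(pd.unique(np.asarray(groups)))
    max_p = max(1, n - g - 1)
    test = wilks_manova(shape_scores[:, :min(n_pcs, max_p)], groups) if n_pcs else \
        GroupTestResult(1.0, 1.0, None, "manova_wilks", extra={"wilks_lambda": 1.0})
    return shape_scores, model, test


def dispersion_test(shape_scores, groups, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Permutation test of multivariate dispersion differences between groups.

    Each case's Euclidean distance to its group centroid in score space is
    the dispersion measure; the observed one-way F statistic on those
    distances is compared with its distribution under ``n_perm`` random
    relabelings (p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, groups, labels = _group_arrays(np.atleast_2d(np.asarray(shape_scores, dtype=float)),
                                      groups)
    for lab in labels:
        if np.sum(groups == lab) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 cases")

    def f_stat(g_labels):
        dists = np.empty(len(X))
        for lab in labels:
            m = g_labels == lab
            cen = X[m].mean(axis=0)
            dists[m] = np.linalg.norm(X[m] - cen, axis=1)
        samples = [dists[g_labels == lab] for lab in labels]
        n, g = len(dists), len(labels)
        grand = dists.mean()
        ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        if ssw == 0.0:
            return 0.0 if ssb == 0.0 else np.inf
        return (ssb / (g - 1)) / (ssw / (n - g))

    obs = f_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(groups)) >= obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return GroupTestResult(float(obs), float(p), None, "dispersion_perm",
                           extra={"n_perm": n_perm})


def per_time_tests(ds: TransportedDataset, axis: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """One ANOVA of the chosen PC score per homologous frame.

    Returns a frame-indexed table with F, raw p, adjusted R-squared, and
    Benjamini-Hochberg significance flags at level ``alpha`` (raw p-values
    are reported alongside; the correction choice is a reporting decision).
    """
    if not 0 <= axis < ds.scores.shape[1]:
        raise IndexError(f"axis {axis} out of range")
    scores = ds.case_scores()[:, :, axis]          # (n_cases, n_frames)
    labels = ds.group_labels()
    rows = []
    for t in range(ds.n_frames):
        res = anova_adjusted(scores[:, t], labels)
        rows.append({"frame": t + 1, "F": res.statistic, "p": res.p_value,
                     "r_squared_adj": res.r_squared_adj})
    table = pd.DataFrame(rows).set_index("frame")
    rejected, p_adj, *_ = multipletests(table["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    table["p_bh"] = p_adj
    table["significant_bh"] = rejected
    return table


# ---------------------------------------------------------------------------
# Attribute table
# ---------------------------------------------------------------------------

def attribute_table(ds: TransportedDataset, n_axes: int = 3, n_shape_pcs: int = 15,
                    es_index: int = 11) -> pd.DataFrame:
    """Tidy per-case table of trajectory size, plane angles and shape scores.

    Cases whose ED -> ES vector is zero-length in a plane get NaN for that
    angle (excluded and logged rather than failing the whole table).
    """
    trajs = trajectories(ds, n_axes=n_axes)
    shape_scores, _, _ = trajectory_shape_analysis(trajs, ds.group_labels(),
                                                   n_pcs=n_shape_pcs)
    rows = []
    for i, cid in enumerate(ds.case_ids):
        row = {"case_id": cid, "group": ds.groups[i], "surface": ds.surface,
               "space": ds.mode, "traj_size": trajectory_size(trajs[i])}
        for plane in ("12", "13"):
            try:
                row[f"angle_{plane}"] = trajectory_angle(trajs[i], plane, es_index=es_index)
            except ValueError:
                logger.warning("case %s: undefined ED->ES angle in plane %s", cid, plane)
                row[f"angle_{plane}"] = np.nan
        for j in range(shape_scores.shape[1]):
            row[f"shape_pc{j + 1}"] = shape_scores[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
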