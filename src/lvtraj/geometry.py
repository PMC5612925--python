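"""Procrustes machinery for landmark configurations.

A *configuration* is a ``(k, d)`` float array of ``k`` homologous landmarks in
``d`` dimensions (``d = 3`` for cardiac surfaces; trajectory-shape analysis
reuses the same code with ``d = m`` principal-component axes).  Landmark order
is the homology and is never permuted.

Two quotient spaces are supported, selected by ``mode``:

``"sss"`` (size-and-shape space)
    translation and rotation are removed, size is retained;
``"ss"`` (shape space)
    translation, rotation and scale are removed — every aligned
    configuration has unit centroid size.

Rotations are restricted to proper rotations (determinant +1): anatomical
homology must not mirror.  Shape vectors are row-major landmark-by-(x,y,z)
flattenings throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SSS = "sss"
SS = "ss"
_MODES = (SSS, SS)


def _check_mode(mode: str) -> str:
    m = str(mode).lower()
    if m not in _MODES:
        raise ValueError(f"unknown space mode {mode!r}; expected one of {_MODES}")
    return m


def as_configuration(coords) -> np.ndarray:
    """Validate and return a configuration as a float64 ``(k, d)`` array."""
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"configuration must be 2-D (k, d); got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("configuration contains non-finite coordinates")
    return x


def centroid(coords) -> np.ndarray:
    return as_configuration(coords).mean(axis=0)


def center(coords) -> np.ndarray:
    """Translate a configuration so its centroid is at the origin."""
    x = as_configuration(coords)
    return x - x.mean(axis=0)


def centroid_size(coords) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    x = center(coords)
    return float(np.sqrt(np.sum(x * x)))


def displacement_magnitude(a, b) -> np.ndarray:
    """Per-landmark Euclidean distance ``||b_i - a_i||`` between two configurations."""
    a = as_configuration(a)
    b = as_configuration(b)
    if a.shape != b.shape:
        raise ValueError(f"configuration shapes differ: {a.shape} vs {b.shape}")
    return np.linalg.norm(b - a, axis=1)


# ---------------------------------------------------------------------------
# Ordinary Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class OPAResult:
    """Outcome of aligning a target configuration onto a source."""

    aligned: np.ndarray         # centered, scaled, rotated target
    rotation: np.ndarray        # (d, d), det +1
    scale: float                # scale applied to the target (1 in SSS)
    residual: float             # sum of squared landmark distances to the source


def _rotation_from_cross_covariance(M: np.ndarray, degenerate_tol: float = 1e-9):
    """Proper rotation R maximizing trace(R^T M), with a documented tie-break.

    When the optimum is ambiguous (rank-deficient M), the rotation closest to
    the identity in Frobenius norm among the optima is returned and a warning
    is logged.
    """
    d = M.shape[0]
    U, s, Vt = np.linalg.svd(M)
    scale_ref = s[0] if s[0] > 0 else 1.0
    if s[0] <= degenerate_tol * max(1.0, np.abs(M).max(initial=1.0)) or s[0] == 0.0:
        logger.warning("fully degenerate cross-covariance; rotation tie-broken to identity")
        return np.eye(d)
    if d == 3 and s[1] <= degenerate_tol * scale_ref:
        # rank-1 optimum: any proper rotation taking v1 to u1 is optimal;
        # the minimal-angle (geodesic) one is the closest to the identity.
        logger.warning("rank-deficient cross-covariance; minimal-angle rotation tie-break")
        v1, u1 = Vt[0], U[:, 0]
        return _minimal_rotation_between(v1, u1)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.ones(d)
    D[-1] = sign if sign != 0 else 1.0
    return (U * D) @ Vt


def _minimal_rotation_between(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Smallest 3-D rotation mapping unit vector v onto unit vector u."""
    c = float(np.dot(v, u))
    axis = np.cross(v, u)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate by pi about a deterministic perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(v))]
        axis = np.cross(v, perp)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * (K @ K)
    axis /= n
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    sin_t = n
    cos_t = c
    return np.eye(3) + sin_t * K + (1.0 - cos_t) * (K @ K)


def opa_align(target, source, mode: str = SSS) -> OPAResult:
    """Align ``target`` onto ``source`` by ordinary Procrustes analysis.

    Both configurations are centered; in shape space the target is scaled to
    the source's centroid size before the optimal proper rotation is applied.
    Returns the aligned target, rotation, scale and the minimized residual
    sum of squares.
    """
    mode = _check_mode(mode)
    X = center(target)
    Y = center(source)
    if X.shape != Y.shape:
        raise ValueError(f"configuration shapes differ: {X.shape} vs {Y.shape}")
    cs_y = np.sqrt(np.sum(Y * Y))
    if cs_y == 0.0:
        raise ValueError("source configuration is fully degenerate (zero centroid size)")
    scale = 1.0
    if mode == SS:
        cs_x = np.sqrt(np.sum(X * X))
        if cs_x == 0.0:
            raise ValueError("target configuration is fully degenerate (zero centroid size)")
        scale = float(cs_y / cs_x)
        X = X * scale
    R = _rotation_from_cross_covariance(X.T @ Y)
    aligned = X @ R
    residual = float(np.sum((aligned - Y) ** 2))
    return OPAResult(aligned=aligned, rotation=R, scale=scale, residual=residual)


def _batch_rotations(configs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotations aligning each centered config in (n,k,d) onto reference."""
    M = np.einsum("nki,kj->nij", configs, reference)
    U, s, Vt = np.linalg.svd(M)
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    D = np.ones((M.shape[0], M.shape[1]))
    D[:, -1] = np.sign(det)
    D[D == 0] = 1.0
    return np.einsum("nij,nj,njk->nik", U, D, Vt)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Superimposed sample from a generalized Procrustes analysis."""

    aligned: np.ndarray               # (n, k, d), centered (unit size in SS)
    consensus: np.ndarray             # (k, d), arithmetic mean of `aligned`
    rotations: np.ndarray             # (n, d, d) accumulated proper rotations
    scales: np.ndarray                # (n,) scale applied to each input (1 in SSS)
    objective_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else float("nan")


def gpa(configs, mode: str = SSS, tol: float = 1e-10, max_iter: int = 500) -> AlignmentResult:
    """Generalized Procrustes superimposition of a sample of configurations.

    Iterates rotation-to-consensus / consensus-update until the relative
    change in the objective (sum of squared residuals about the mean) falls
    below ``tol``.  The consensus used as rotation reference is re-normalized
    to unit centroid size each iteration in shape space; the returned
    consensus is the arithmetic mean of the aligned configurations.
    """
    mode = _check_mode(mode)
    X = np.asarray(configs, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("gpa requires a (n>=2, k, d) stack of configurations")
    if not np.all(np.isfinite(X)):
        raise ValueError("configurations contain non-finite coordinates")
    n, k, d = X.shape

    X = X - X.mean(axis=1, keepdims=True)
    scales = np.ones(n)
    if mode == SS:
        cs = np.sqrt(np.sum(X * X, axis=(1, 2)))
        if np.any(cs == 0):
            raise ValueError("degenerate configuration (zero centroid size) in SS mode")
        scales = 1.0 / cs
        X = X * scales[:, None, None]

    rotations = np.broadcast_to(np.eye(d), (n, d, d)).copy()
    reference = X.mean(axis=0)
    if mode == SS:
        reference = reference / np.sqrt(np.sum(reference * reference))

    trace: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        R = _batch_rotations(X, reference)
        X = np.einsum("nki,nij->nkj", X, R)
        rotations = np.einsum("nij,njk->nik", rotations, R)
        mean = X.mean(axis=0)
        obj = float(np.sum((X - mean) ** 2))
        trace.append(obj)
        if prev - obj <= tol * max(prev, 1e-30) and np.isfinite(prev):
            converged = True
            break
        prev = obj
        reference = mean
        if mode == SS:
            reference = reference / np.sqrt(np.sum(reference * reference))
    if not converged:
        last_change = trace[-2] - trace[-1] if len(trace) > 1 else float("inf")
        logger.warning("GPA did not converge in %d iterations (last change %.3e)",
                       max_iter, last_change)
    return AlignmentResult(aligned=X, consensus=X.mean(axis=0), rotations=rotations,
                           scales=scales, objective_trace=trace, converged=converged)


def tangent_project(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent plane at the consensus.

    Removes, from each shape vector, its component along the consensus
    direction in excess of the consensus itself — the standard geometric
    morphometrics linearization before multivariate statistics.
    """
    X = np.asarray(aligned, dtype=float).reshape(len(aligned), -1)
    c = np.asarray(consensus, dtype=float).ravel()
    c_unit = c / np.linalg.norm(c)
    coef = X @ c_unit
    proj = X - np.outer(coef - np.linalg.norm(c), c_unit)
    return proj.reshape(np.shape(aligned))


# ---------------------------------------------------------------------------
# Principal component analysis of vectorized configurations
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """PCA of mean-centered shape vectors.

    ``components`` rows are orthonormal; ``variances`` are the sample
    (ddof=1) variances of the corresponding score columns, sorted descending.
    The sign of each component is fixed so its largest-magnitude entry is
    positive, making score signs reproducible across platforms.
    """

    mean_vector: np.ndarray        # (p,)
    components: np.ndarray         # (r, p), row-orthonormal
    variances: np.ndarray          # (r,), non-increasing
    explained_fraction: np.ndarray  # (r,), sums to <= 1

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_vector) @ self.components.T

    def inverse_transform(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return self.mean_vector + scores @ self.components


def fit_pca(vectors) -> PCModel:
    """Fit a PCA to an ``(n, p)`` matrix of shape vectors (n >= 2)."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca requires an (n>=2, p) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s ** 2 / (n - 1)
    # sign convention: largest-|.| entry of each component positive
    idx = np.argmax(np.abs(Vt), axis=1)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), idx])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    total = variances.sum()
    frac = variances / total if total > 0 else np.zeros_like(variances)
    return PCModel(mean_vector=mean, components=Vt, variances=variances,
                   explained_fraction=frac)


def reconstruct_shape_at_score(model: PCModel, axis: int, score: float,
                               magnification: float = 1.0, n_dim: int = 3) -> np.ndarray:
    """Configuration predicted at a given score along one PC axis.

    Returns ``mean + magnification * score * component[axis]`` reshaped to
    ``(k, n_dim)``; magnification > 1 exaggerates the deformation for
    visualization of low-variance axes.
    """
    if not 0 <= axis < model.components.shape[0]:
        raise IndexError(f"axis {axis} out of range for {model.components.shape[0]} components")
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    vec = model.mean_vector + magnification * score * model.components[axis]
    return vec.reshape(-1, n_dim)
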