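"""Synthetic left-ventricular motion cohorts with known ground truth.

Each case is a pair of nested, open-based, prolate-spheroid-like surfaces
(endocardium inside epicardium) sampled on a rings-by-meridians landmark
grid plus an apex point.  A smooth cyclic contraction (ED -> ES -> ED, with
its peak at a case-specific raw ES phase) scales the radii and the long
axis; infarcted cases contract with lower amplitude and a different
shape-change coefficient.  Inter-individual baseline variation (size,
length, orientation, position), per-frame rigid jitter, variable raw frame
counts and i.i.d. landmark noise force every downstream stage to do real
work.  True EDV/ESV/EF are recorded per case by integrating the noise-free
ED and ES surfaces over the same mesh the pipeline uses.

The generator emulates the data structure of a feature-tracked cardiac MR
cohort.  It is not a biophysical myocardium model: wall thickness is
uniform, the base is fixed in its plane, and contraction is a smooth
separable field, so passing tests demonstrate the statistical machinery,
not fidelity to real myocardial mechanics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .datatypes import GROUPS, MotionSequence, RawMotionSequence
from .registration import LVMesh, cavity_volume, warp_phase


@dataclass(frozen=True)
class AkinesiaSpec:
    """Angular-sector damping of the contraction field (septal wall-motion defect)."""

    center_deg: float = 0.0
    width_deg: float = 90.0
    damping: float = 0.7          # 1 = no motion inside the sector

    def factor(self, theta: np.ndarray) -> np.ndarray:
        """Multiplicative contraction factor per meridian angle (radians)."""
        delta = np.angle(np.exp(1j * (theta - np.deg2rad(self.center_deg))))
        half = np.deg2rad(self.width_deg) / 2.0
        bump = np.where(np.abs(delta) < half,
                        0.5 * (1.0 + np.cos(np.pi * delta / half)), 0.0)
        return 1.0 - self.damping * bump


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort-level study conditions.

    Contraction ``amplitude`` is the fractional endocardial radial
    contraction at ES (Control 0.55 vs MI 0.30 by default).  Lengths are mm;
    angular spreads are degrees; all noise parameters are standard
    deviations.  The same seed always reproduces the identical cohort.
    """

    n_per_group: int = 30
    rings: int = 9
    meridians: int = 12
    n_raw_frames_range: tuple = (20, 35)
    es_phase_range: tuple = (0.4, 0.6)
    amplitude: dict = field(default_factory=lambda: {"Control": 0.55, "MI": 0.30})
    epi_amp_ratio: dict = field(default_factory=lambda: {"Control": 0.45, "MI": 0.55})
    sphericity_change: dict = field(default_factory=lambda: {"Control": 0.0, "MI": 0.3})
    sphericity_sd: float = 0.15         # per-case jitter of the shape-change coefficient
    long_amp_ratio: float = 0.15        # long-axis shortening per unit radial amplitude
    akinesia: AkinesiaSpec | None = None
    endo_radius: float = 28.0
    endo_length: float = 80.0
    wall_thickness: float = 10.0
    apex_thickness: float = 6.0
    radius_sd: float = 0.07             # fractional baseline size jitter
    length_sd: float = 0.06
    orientation_sd_deg: float = 5.0
    translation_sd: float = 5.0
    amp_sd: float = 0.05                # per-case amplitude jitter (absolute)
    frame_jitter_rot_deg: float = 0.5
    frame_jitter_trans: float = 0.5
    noise_sd: float = 0.5               # i.i.d. landmark noise, mm
    seed: int = 0

    def __post_init__(self):
        for g in GROUPS:
            if not 0.0 < self.amplitude[g] < 1.0:
                raise ValueError(f"amplitude[{g}] must lie in (0, 1)")
        for name in ("radius_sd", "length_sd", "orientation_sd_deg", "translation_sd",
                     "amp_sd", "frame_jitter_rot_deg", "frame_jitter_trans", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.endo_radius <= 0 or self.endo_length <= 0:
            raise ValueError("endocardial dimensions must be positive")
        if self.wall_thickness <= 0 or self.apex_thickness <= 0:
            raise ValueError("wall thickness must be positive (endo >= epi radius otherwise)")
        if self.rings < 3 or self.meridians < 4:
            raise ValueError("grid too coarse: need >= 3 rings and >= 4 meridians")

    @property
    def n_landmarks(self) -> int:
        return self.rings * self.meridians + 1

    def with_target_ef(self, ef_control: float = 0.60, ef_mi: float = 0.40) -> "SimulationSpec":
        """Variant whose groups have exact programmed ejection fractions.

        Shape-change modulation and akinesia are switched off so the
        ED -> ES deformation is an anisotropic affine scaling, making
        EF = 1 - (1-A)^2 (1-beta*A) exact for any closed mesh; the radial
        amplitude A is solved per group, and per-case amplitude jitter is
        removed so the programmed value is the per-case truth.
        """
        amps = {"Control": amplitude_for_ef(ef_control, self.long_amp_ratio),
                "MI": amplitude_for_ef(ef_mi, self.long_amp_ratio)}
        return replace(self, amplitude=amps, amp_sd=0.0, sphericity_sd=0.0,
                       sphericity_change={"Control": 0.0, "MI": 0.0}, akinesia=None)


def amplitude_for_ef(ef: float, long_amp_ratio: float) -> float:
    """Radial contraction amplitude giving ejection fraction ``ef``.

    Solves ``1 - (1 - A)^2 (1 - beta * A) = ef`` for A in (0, 1), the exact
    volume ratio of the generator's affine ED -> ES deformation.
    """
    if not 0.0 < ef < 1.0:
        raise ValueError("ef must lie in (0, 1)")
    beta = long_amp_ratio
    return float(brentq(lambda a: 1.0 - (1.0 - a) ** 2 * (1.0 - beta * a) - ef,
                        1e-9, 1.0 - 1e-9))


# ---------------------------------------------------------------------------
# Surface template and mesh
# ---------------------------------------------------------------------------

def lv_surface(radius: float, length: float, rings: int, meridians: int) -> np.ndarray:
    """Half-spheroid landmark grid: base ring in z = 0, apex at z = -length.

    Ring i (i = 0 .. rings-1) sits at polar angle ``alpha_i = i * (pi/2) /
    rings`` with the apex point appended last; landmark index is
    ``i * meridians + j`` for meridian j.
    """
    alphas = np.arange(rings) * (np.pi / 2) / rings
    thetas = np.arange(meridians) * 2 * np.pi / meridians
    r = radius * np.cos(alphas)[:, None]
    x = (r * np.cos(thetas)[None, :]).ravel()
    y = (r * np.sin(thetas)[None, :]).ravel()
    z = np.repeat(-length * np.sin(alphas), meridians)
    pts = np.column_stack([x, y, z])
    apex = np.array([[0.0, 0.0, -length]])
    return np.vstack([pts, apex])


def lv_mesh(rings: int, meridians: int) -> LVMesh:
    """Triangulation of the rings-by-meridians grid with apex fan and basal cap."""
    R, M = rings, meridians
    idx = lambda i, j: i * M + (j % M)
    faces = []
    for i in range(R - 1):
        for j in range(M):
            faces.append([idx(i, j), idx(i, j + 1), idx(i + 1, j)])
            faces.append([idx(i, j + 1), idx(i + 1, j + 1), idx(i + 1, j)])
    apex = R * M
    for j in range(M):
        faces.append([idx(R - 1, j), idx(R - 1, j + 1), apex])
    mesh = LVMesh(faces=np.asarray(faces, dtype=int), basal_ring=np.arange(M))
    # fix outward orientation once, on the template geometry
    template = lv_surface(1.0, 1.0, rings, meridians)
    if cavity_volume(template, mesh) < 0:
        mesh = LVMesh(faces=mesh.faces[:, ::-1].copy(), basal_ring=mesh.basal_ring[::-1].copy())
    return mesh


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCase:
    """One simulated case: raw sequences for both surfaces plus ground truth."""

    case_id: str
    group: str
    endo: RawMotionSequence
    epi: RawMotionSequence
    mesh: LVMesh
    truth: dict                  # edv_ml, esv_ml, ef, es_phase_raw, amplitudes, ...

    def surface(self, name: str) -> RawMotionSequence:
        if name == "endo":
            return self.endo
        if name == "epi":
            return self.epi
        raise KeyError(name)


def contraction_profile(phi, es_phase: float):
    """Smooth cyclic activation in [0, 1]: 0 at ED (phase 0), 1 at ``es_phase``.

    ``sin^2(pi * u)`` of the phase warped so the peak sits at the ES phase;
    continuous and 1-periodic, with a slope break at ES only.
    """
    return np.sin(np.pi * warp_phase(phi, es_phase, 0.5)) ** 2


def _deform(base: np.ndarray, alphas_per_lm: np.ndarray, thetas_per_lm: np.ndarray,
            g: float, amp: float, beta: float, sphericity: float,
            akinesia: AkinesiaSpec | None) -> np.ndarray:
    """Apply the contraction field at activation level ``g`` to a baseline surface."""
    mod = 1.0 + sphericity * (0.5 - np.sin(alphas_per_lm))
    wk = akinesia.factor(thetas_per_lm) if akinesia is not None else 1.0
    f_r = 1.0 - amp * g * mod * wk
    f_l = 1.0 - beta * amp * g
    out = base.copy()
    out[:, 0] *= f_r
    out[:, 1] *= f_r
    out[:, 2] *= f_l
    return out


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Rotation matrix with axis-angle drawn from an isotropic normal (SD in degrees)."""
    rotvec = rng.normal(0.0, np.deg2rad(sd_deg), size=3)
    angle = np.linalg.norm(rotvec)
    if angle < 1e-12:
        return np.eye(3)
    k = rotvec / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_case(spec: SimulationSpec, group: str, case_id: str,
                  rng: np.random.Generator) -> SyntheticCase:
    R, M = spec.rings, spec.meridians
    mesh = lv_mesh(R, M)
    alphas = np.arange(R) * (np.pi / 2) / R
    alphas_lm = np.append(np.repeat(alphas, M), np.pi / 2)
    thetas = np.arange(M) * 2 * np.pi / M
    thetas_lm = np.append(np.tile(thetas, R), 0.0)

    # baseline anatomy with inter-individual jitter
    s_rad = max(0.5, 1.0 + rng.normal(0.0, spec.radius_sd))
    s_len = max(0.5, 1.0 + rng.normal(0.0, spec.length_sd))
    a_endo = spec.endo_radius * s_rad
    c_endo = spec.endo_length * s_len
    a_epi = (spec.endo_radius + spec.wall_thickness) * s_rad
    c_epi = (spec.endo_length + spec.apex_thickness) * s_len
    base = {"endo": lv_surface(a_endo, c_endo, R, M),
            "epi": lv_surface(a_epi, c_epi, R, M)}

    amp_endo = float(np.clip(spec.amplitude[group] + rng.normal(0.0, spec.amp_sd), 0.02, 0.95))
    amp_epi = spec.epi_amp_ratio[group] * amp_endo
    sphericity = spec.sphericity_change[group] + rng.normal(0.0, spec.sphericity_sd)
    beta = spec.long_amp_ratio
    amps = {"endo": amp_endo, "epi": amp_epi}

    R_case = _small_rotation(rng, spec.orientation_sd_deg)
    t_case = rng.normal(0.0, spec.translation_sd, size=3)

    es_phase = float(rng.uniform(*spec.es_phase_range))
    lo, hi = spec.n_raw_frames_range
    T = int(rng.integers(lo, hi + 1))
    phases = np.arange(T) / T

    # ground truth from the noise-free ED and peak-contraction surfaces
    ed_truth = base["endo"]
    es_truth = _deform(base["endo"], alphas_lm, thetas_lm, 1.0, amp_endo, beta,
                       sphericity, spec.akinesia)
    edv = cavity_volume(ed_truth, mesh) / 1000.0
    esv = cavity_volume(es_truth, mesh) / 1000.0

    seqs = {}
    for surf in ("endo", "epi"):
        frames = np.empty((T, spec.n_landmarks, 3))
        for j, phi in enumerate(phases):
            g = float(contraction_profile(phi, es_phase))
            frames[j] = _deform(base[surf], alphas_lm, thetas_lm, g, amps[surf],
                                beta, sphericity, spec.akinesia)
        seqs[surf] = frames

    # rigid motion shared by the two surfaces (the whole heart moves together)
    for j in range(T):
        R_f = _small_rotation(rng, spec.frame_jitter_rot_deg) @ R_case
        t_f = t_case + rng.normal(0.0, spec.frame_jitter_trans, size=3)
        for surf in ("endo", "epi"):
            seqs[surf][j] = seqs[surf][j] @ R_f.T + t_f
    for surf in ("endo", "epi"):
        seqs[surf] += rng.normal(0.0, spec.noise_sd, size=seqs[surf].shape)

    truth = {"edv_ml": edv, "esv_ml": esv, "ef": 1.0 - esv / edv,
             "es_phase_raw": es_phase, "n_raw_frames": T,
             "amp_endo": amp_endo, "amp_epi": amp_epi}
    make = lambda surf: RawMotionSequence(case_id=case_id, group=group, surface=surf,
                                          frames=seqs[surf], es_phase_raw=es_phase)
    return SyntheticCase(case_id=case_id, group=group, endo=make("endo"),
                         epi=make("epi"), mesh=mesh, truth=truth)


def generate_cohort(spec: SimulationSpec) -> list:
    """Generate the full two-group cohort described by ``spec`` (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    cases = []
    for group in GROUPS:
        for i in range(spec.n_per_group):
            cid = f"{group.lower()}{i:03d}"
            cases.append(generate_case(spec, group, cid, rng))
    return cases


# ---------------------------------------------------------------------------
# Canonical fixture for the transport-nulling property
# ---------------------------------------------------------------------------

def generate_null_transport_pair(n_frames: int = 30, rings: int = 6, meridians: int = 10,
                                 seed: int | None = None) -> tuple:
    """Two cases with different baseline shapes but the identical deformation.

    Both cases live in a common orthonormal coordinate frame Q (the QR basis
    of a centered LV template); their templates are different diagonal axis
    scalings ``Q diag(a)`` / ``Q diag(b)`` and the shared within-cycle
    displacement field is ``Q diag(c_t)``.  Every cross-covariance the
    size-and-shape-space pipeline forms is then symmetric positive definite,
    so all Procrustes rotations are exactly the identity and the transported
    trajectories of the pair coincide to machine precision — while the raw
    trajectories differ, since the axis ratios differ.

    Returns two already-registered ``MotionSequence`` objects (the fixture
    exercises the transport stage; resampling would blur the guarantee).
    """
    template = lv_surface(30.0, 80.0, rings, meridians)
    P = template - template.mean(axis=0)
    Q, _ = np.linalg.qr(P)
    # fix basis signs for reproducibility
    signs = np.sign(Q[np.argmax(np.abs(Q), axis=0), np.arange(3)])
    Q = Q * signs

    a = np.array([45.0, 40.0, 75.0])
    b = np.array([38.0, 46.0, 70.0])
    d_amp = np.array([12.0, 9.0, 18.0])
    if seed is not None:
        rng = np.random.default_rng(seed)
        a = a * rng.uniform(0.85, 1.15, size=3)
        b = b * rng.uniform(0.85, 1.15, size=3)
        d_amp = d_amp * rng.uniform(0.7, 1.2, size=3)

    phases = np.arange(n_frames) / n_frames
    g = contraction_profile(phases, 0.35)
    frames_a = np.stack([Q * (a - gt * d_amp) for gt in g])
    frames_b = np.stack([Q * (b - gt * d_amp) for gt in g])
    seq_a = MotionSequence(case_id="nullA", group="Control", surface="endo", frames=frames_a)
    seq_b = MotionSequence(case_id="nullB", group="Control", surface="endo", frames=frames_b)
    return seq_a, seq_b
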