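"""Shared containers for time-resolved landmark data.

A cardiac cycle is a closed loop ED -> ES -> ED.  Raw sequences carry a
case-specific number of frames and an expert-marked end-systolic phase;
registered sequences carry exactly ``n_frames`` frames at uniform phases
``(t - 1) / n_frames`` with end-diastole at frame 1 (phase 0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GROUPS = ("Control", "MI")
SURFACES = ("endo", "epi")


def _check_frames(frames, min_frames: int) -> np.ndarray:
    f = np.asarray(frames, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError(f"frames must be a (T, k, 3) array; got shape {f.shape}")
    if f.shape[0] < min_frames:
        raise ValueError(f"sequence needs >= {min_frames} frames; got {f.shape[0]}")
    if f.shape[1] < 4:
        raise ValueError("configurations need at least 4 landmarks")
    if not np.all(np.isfinite(f)):
        raise ValueError("frames contain non-finite coordinates")
    return f


def _check_label(value: str, allowed: tuple, what: str) -> str:
    if value not in allowed:
        raise ValueError(f"{what} must be one of {allowed}; got {value!r}")
    return value


@dataclass
class RawMotionSequence:
    """One surface of one case as acquired: variable frame count, marked ES phase."""

    case_id: str
    group: str
    surface: str
    frames: np.ndarray          # (T_raw >= 8, k, 3); frame 1 is ED (phase 0)
    es_phase_raw: float         # fraction of the raw cycle at which ES occurs

    def __post_init__(self):
        self.frames = _check_frames(self.frames, min_frames=8)
        _check_label(self.group, GROUPS, "group")
        _check_label(self.surface, SURFACES, "surface")
        if not 0.0 < float(self.es_phase_raw) < 1.0:
            raise ValueError(f"es_phase_raw must lie strictly in (0, 1); "
                             f"got {self.es_phase_raw} for case {self.case_id}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.frames.shape[1]

    @property
    def phases(self) -> np.ndarray:
        """Raw frame phases j / T_raw, j = 0 .. T_raw - 1."""
        T = self.n_frames
        return np.arange(T) / T


@dataclass
class MotionSequence:
    """A temporally registered cycle: frame t at phase (t - 1) / n_frames, ED at t = 1."""

    case_id: str
    group: str
    surface: str
    frames: np.ndarray          # (n_frames, k, 3)

    def __post_init__(self):
        self.frames = _check_frames(self.frames, min_frames=3)
        _check_label(self.group, GROUPS, "group")
        _check_label(self.surface, SURFACES, "surface")

    ed_index: int = 1           # 1-based; phase 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.frames.shape[1]

    @property
    def phases(self) -> np.ndarray:
        n = self.n_frames
        return np.arange(n) / n
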