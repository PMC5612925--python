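"""Parallel transport of within-cycle deformations via Linear Shift.

Repeated deformation series (one cycle per individual) superimposed by a
plain GPA mix inter- and intra-individual shape variation.  Linear Shift is
the Euclidean parallel transport that removes the inter-individual part:
each individual's frames are expressed as deformations of its own cycle
mean (the local template, LT), and those deformation vectors are added to
the grand mean of the whole sample (the common template, CT).  The full
composition is

    GPA (whole sample, only to find CT)
    + per-individual GPAs (to find LTs)
    + OPA of each LT onto CT
    + OPA of each frame onto its CT-aligned LT, subtraction, addition to CT
    + common GPA of all transported shapes
    + PCA

after which nearby PC scores mean "same deformation", not "same shape".
Everything runs in either size-and-shape space (``"sss"``) or shape space
(``"ss"``); in SS every alignment scales to unit centroid size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .datatypes import MotionSequence
from . import geometry
from .geometry import SS, SSS, PCModel, fit_pca, gpa, opa_align

logger = logging.getLogger(__name__)


@dataclass
class LocalTemplate:
    """One individual's cycle-mean shape from its per-case GPA."""

    case_id: str
    surface: str
    shape: np.ndarray            # (k, 3), centered; unit centroid size in SS


@dataclass
class TransportedDataset:
    """Linear-Shift-transported, GPA-aligned deformations with their PC model."""

    mode: str
    surface: str
    ct: np.ndarray               # (k, 3) common template (grand mean)
    aligned: np.ndarray          # (n_cases * n_frames, k, 3) final GPA output
    pc_model: PCModel
    scores: np.ndarray           # (n_cases * n_frames, p)
    case_ids: list               # length n_cases
    groups: list                 # length n_cases
    n_frames: int

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def case_scores(self, n_axes: int | None = None) -> np.ndarray:
        """Scores reshaped to (n_cases, n_frames, p) [first ``n_axes`` axes]."""
        p = self.scores.shape[1]
        out = self.scores.reshape(self.n_cases, self.n_frames, p)
        return out if n_axes is None else out[:, :, :n_axes]

    def group_labels(self) -> np.ndarray:
        return np.asarray(self.groups)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["mode"] = self.mode
            f.attrs["surface"] = self.surface
            f.attrs["n_frames"] = self.n_frames
            f.create_dataset("ct", data=self.ct)
            f.create_dataset("aligned", data=self.aligned)
            f.create_dataset("scores", data=self.scores)
            f.create_dataset("case_index", data=np.array(self.case_ids, dtype="S"))
            f.create_dataset("group_index", data=np.array(self.groups, dtype="S"))
            f.create_dataset("mean", data=self.pc_model.mean_vector)
            f.create_dataset("components", data=self.pc_model.components)
            f.create_dataset("variances", data=self.pc_model.variances)

    @classmethod
    def load(cls, path) -> "TransportedDataset":
        with h5py.File(path, "r") as f:
            variances = f["variances"][:]
            total = variances.sum()
            model = PCModel(mean_vector=f["mean"][:], components=f["components"][:],
                            variances=variances,
                            explained_fraction=variances / total if total > 0 else variances)
            return cls(mode=f.attrs["mode"], surface=f.attrs["surface"],
                       ct=f["ct"][:], aligned=f["aligned"][:], pc_model=model,
                       scores=f["scores"][:],
                       case_ids=[s.decode() for s in f["case_index"][:]],
                       groups=[s.decode() for s in f["group_index"][:]],
                       n_frames=int(f.attrs["n_frames"]))


def _check_sequences(sequences: list) -> tuple[int, int]:
    if len(sequences) < 2:
        raise ValueError("need at least two cases")
    n_frames = sequences[0].n_frames
    k = sequences[0].n_landmarks
    surface = sequences[0].surface
    for s in sequences:
        if s.n_frames != n_frames:
            raise ValueError(f"case {s.case_id}: frame count {s.n_frames} != {n_frames}")
        if s.n_landmarks != k:
            raise ValueError(f"case {s.case_id}: landmark count {s.n_landmarks} != {k}")
        if s.surface != surface:
            raise ValueError(f"case {s.case_id}: surface {s.surface} != {surface}")
    return n_frames, k


def compute_local_templates(sequences: list, mode: str = SSS) -> list:
    """Per-case GPA over each individual's frames; the LT is the consensus."""
    out = []
    for seq in sequences:
        try:
            res = gpa(seq.frames, mode=mode)
        except Exception as exc:
            raise RuntimeError(f"per-case GPA failed for case {seq.case_id}") from exc
        lt = res.consensus
        if mode == SS:
            lt = lt / np.sqrt(np.sum(lt * lt))
        out.append(LocalTemplate(case_id=seq.case_id, surface=seq.surface, shape=lt))
    return out


def linear_shift_transport(sequences: list, lts: list, ct: np.ndarray,
                           mode: str = SSS) -> np.ndarray:
    """Transport every frame's deformation from its LT onto the CT.

    Per case: the LT is OPA-aligned onto the CT; each frame is OPA-aligned
    onto that CT-aligned LT; the deformation (frame - LT) is added to the
    CT.  Returns the transported shapes, ``(n_cases, n_frames, k, 3)``.
    Transporting the LT itself yields the CT exactly, and the deformation
    norm is preserved: ``||transported_t - CT|| = ||frame_t - LT||``.
    """
    if len(lts) != len(sequences):
        raise ValueError("one local template per sequence required")
    n_frames, k = _check_sequences(sequences)
    out = np.empty((len(sequences), n_frames, k, 3))
    for i, (seq, lt) in enumerate(zip(sequences, lts)):
        if lt.case_id != seq.case_id:
            raise ValueError(f"LT/sequence mismatch: {lt.case_id} vs {seq.case_id}")
        lt_aligned = opa_align(lt.shape, ct, mode=mode).aligned
        for t in range(n_frames):
            frame = opa_align(seq.frames[t], lt_aligned, mode=mode).aligned
            out[i, t] = ct + (frame - lt_aligned)
    return out


def run_ls_pca(sequences: list, mode: str = SSS) -> TransportedDataset:
    """Full Linear-Shift composition ending in a joint PCA over all case-frames.

    The PCA is fitted on every transported case-frame jointly (not
    per-frame) so per-frame scores share axes across the cycle.
    """
    mode = geometry._check_mode(mode)
    n_frames, k = _check_sequences(sequences)
    all_frames = np.concatenate([s.frames for s in sequences], axis=0)

    grand = gpa(all_frames, mode=mode)           # only to find the CT
    ct = grand.consensus

    lts = compute_local_templates(sequences, mode=mode)
    transported = linear_shift_transport(sequences, lts, ct, mode=mode)
    flat = transported.reshape(-1, k, 3)

    final = gpa(flat, mode=mode)
    angles = _rotation_angles(final.rotations)
    logger.info("final GPA after transport: max rotation angle %.2e rad, consensus drift %.3e",
                angles.max(initial=0.0),
                float(np.linalg.norm(final.consensus - (ct - ct.mean(0)))
                      / max(np.linalg.norm(ct), 1e-30)))

    model = fit_pca(final.aligned.reshape(len(flat), -1))
    scores = model.transform(final.aligned.reshape(len(flat), -1))
    return TransportedDataset(mode=mode, surface=sequences[0].surface, ct=ct,
                              aligned=final.aligned, pc_model=model, scores=scores,
                              case_ids=[s.case_id for s in sequences],
                              groups=[s.group for s in sequences],
                              n_frames=n_frames)


def _rotation_angles(rotations: np.ndarray) -> np.ndarray:
    tr = np.clip((np.trace(rotations, axis1=-2, axis2=-1) - 1.0) / 2.0, -1.0, 1.0)
    return np.arccos(tr)
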