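"""Per-residue fluctuation analysis of prediction ensembles.

A simulated-annealing trajectory carries, frame by frame, information about
which parts of a predicted fold are converged and which are still mobile.
The root-mean-square fluctuation (r.m.s.f.) of each residue's Cα about its
trajectory-mean position quantifies that mobility; it converts to an
isotropic temperature factor through

    B_k = (8 π² / 3) · r.m.s.f._k²

and residues fluctuating beyond a cutoff (1.5 Å by default) are removed from
the search model outright, since flexible coil regions tend to poison the
molecular-replacement likelihood search rather than merely dilute it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, PreconditionError
from .model_io import CoarseModel, Ensemble
from .similarity import kabsch_superpose

#: conversion constant between mean-square fluctuation and B factor, 8π²/3
B_FACTOR_CONSTANT = 8.0 * math.pi**2 / 3.0


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue r.m.s.f. (Å) and derived B factor (Å²) over a frame window."""

    residue_index: np.ndarray
    rmsf: np.ndarray
    b_factor: np.ndarray
    window: tuple

    def __post_init__(self):
        idx = np.asarray(self.residue_index, dtype=int)
        rmsf = np.asarray(self.rmsf, dtype=float)
        b = np.asarray(self.b_factor, dtype=float)
        if not (idx.shape == rmsf.shape == b.shape):
            raise ConsistencyError("profile arrays have inconsistent lengths")
        if not np.all(np.isfinite(rmsf)) or np.any(rmsf < 0):
            raise ConsistencyError("r.m.s.f. values must be finite and non-negative")
        if not np.allclose(b, B_FACTOR_CONSTANT * rmsf**2, rtol=1e-9, atol=1e-12):
            raise ConsistencyError("b_factor column violates B = (8π²/3)·rmsf²")
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "rmsf", rmsf)
        object.__setattr__(self, "b_factor", b)

    def __len__(self) -> int:
        return len(self.residue_index)


@dataclass(frozen=True)
class TrimReport:
    """Outcome of r.m.s.f.-based trimming: which residues were cut and kept."""

    cutoff: float
    removed_indices: np.ndarray
    kept_indices: np.ndarray
    fraction_removed: float

    def __post_init__(self):
        rem = np.sort(np.asarray(self.removed_indices, dtype=int))
        kept = np.sort(np.asarray(self.kept_indices, dtype=int))
        if np.intersect1d(rem, kept).size:
            raise ConsistencyError("removed and kept residue sets overlap")
        total = rem.size + kept.size
        frac = rem.size / total if total else 0.0
        if not math.isclose(frac, self.fraction_removed, abs_tol=1e-12):
            raise ConsistencyError("fraction_removed inconsistent with index sets")
        object.__setattr__(self, "removed_indices", rem)
        object.__setattr__(self, "kept_indices", kept)


def rmsf_to_bfactor(rmsf) -> float | np.ndarray:
    """Convert r.m.s.f. (Å) to an isotropic B factor (Å²), B = (8π²/3)·rmsf².

    Accepts scalars or arrays; strictly increasing in its argument.
    """
    arr = np.asarray(rmsf, dtype=float)
    if np.any(arr < 0):
        raise PreconditionError("r.m.s.f. must be non-negative")
    out = B_FACTOR_CONSTANT * arr**2
    return float(out) if np.isscalar(rmsf) or arr.ndim == 0 else out


def compute_rmsf(
    ensemble: Ensemble,
    window_fraction: float = 0.25,
    superpose: bool = True,
) -> FluctuationProfile:
    """Per-residue Cα r.m.s.f. over the trailing window of a trajectory.

    The window holds the last ``ceil(window_fraction · n_frames)`` frames —
    the equilibrated tail of an annealing run (the default quarter matches
    the convention of analysing the final million of four million steps).
    For each residue the r.m.s.f. is the root of the mean squared deviation
    of its Cα from that residue's mean position over the window frames.

    When ``superpose`` is set (default), each window frame is rigid-body
    superposed (Kabsch over all Cα) onto the window-mean structure first,
    and the mean/superposition cycle is iterated twice, so global drift and
    tumbling do not masquerade as internal flexibility.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise PreconditionError("window_fraction must be in (0, 1]")
    n = len(ensemble)
    n_window = math.ceil(window_fraction * n)
    first = n - n_window
    coords = ensemble.ca_trajectory()[first:]
    if coords.shape[0] < 2:
        raise PreconditionError(
            f"need at least 2 frames in the window, got {coords.shape[0]}"
        )

    if superpose:
        coords = coords.copy()
        for _ in range(2):  # two-pass: mean → fit → refreshed mean → fit
            mean = coords.mean(axis=0)
            for f in range(coords.shape[0]):
                rot, trans, _ = kabsch_superpose(coords[f], mean)
                coords[f] = coords[f] @ rot.T + trans

    mean = coords.mean(axis=0)
    sq_dev = np.sum((coords - mean) ** 2, axis=2)  # (frames, residues)
    rmsf = np.sqrt(sq_dev.mean(axis=0))
    model = ensemble.frames[0]
    return FluctuationProfile(
        residue_index=model.residue_index.copy(),
        rmsf=rmsf,
        b_factor=rmsf_to_bfactor(rmsf),
        window=(first, n - 1),
    )


def trim_by_rmsf(
    model: CoarseModel,
    profile: FluctuationProfile,
    cutoff: float = 1.5,
) -> tuple[CoarseModel, TrimReport]:
    """Remove residues whose r.m.s.f. strictly exceeds ``cutoff`` (Å).

    A residue sitting exactly at the cutoff is kept ("over" is read as a
    strict inequality).  All atoms of a trimmed residue are removed; kept
    residues retain their original numbering, so the output drops straight
    into a phasing pipeline without renumbering bookkeeping.
    """
    if len(profile) != len(model) or not np.array_equal(
        profile.residue_index, model.residue_index
    ):
        raise ConsistencyError("fluctuation profile does not cover the model roster")
    keep = profile.rmsf <= cutoff
    trimmed = model.subset(keep)
    report = TrimReport(
        cutoff=float(cutoff),
        removed_indices=model.residue_index[~keep],
        kept_indices=model.residue_index[keep],
        fraction_removed=float((~keep).sum() / len(model)) if len(model) else 0.0,
    )
    return trimmed, report


#: recognised secondary-structure classes: helix, strand, coil, unstructured
SS_CLASSES = ("H", "E", "C", "U")


def stratify_trimmed(report: TrimReport, ss_labels, residue_index=None) -> dict:
    """Fraction of trimmed residues falling in each secondary-structure class.

    ``ss_labels`` carries one label from {H, E, C, U} per roster residue
    (helix / strand / coil / unstructured, i.e. absent from the reference
    crystal structure).  ``residue_index`` gives the roster order the labels
    follow; by default the sorted union of kept and removed indices.
    Fractions sum to 1 whenever anything was removed, and are all zero
    otherwise.
    """
    labels = list(ss_labels)
    bad = sorted({lab for lab in labels if lab not in SS_CLASSES})
    if bad:
        raise PreconditionError(f"unknown secondary-structure labels: {bad}")
    if residue_index is None:
        residue_index = np.union1d(report.kept_indices, report.removed_indices)
    residue_index = np.asarray(residue_index, dtype=int)
    if len(labels) != residue_index.size:
        raise ConsistencyError("need exactly one label per roster residue")

    removed = set(report.removed_indices.tolist())
    counts = {cls: 0 for cls in SS_CLASSES}
    for idx, lab in zip(residue_index.tolist(), labels):
        if idx in removed:
            counts[lab] += 1
    total = sum(counts.values())
    if total == 0:
        return {cls: 0.0 for cls in SS_CLASSES}
    return {cls: counts[cls] / total for cls in SS_CLASSES}
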