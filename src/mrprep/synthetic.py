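"""Synthetic structures, ensembles and trial tables for testing the pipeline.

Everything the pipeline consumes can be generated here deterministically
from a seed: ideal secondary-structure geometries (α-helix, extended
strand), noisy prediction ensembles with a controlled per-residue
fluctuation profile, planted two-fold ensembles for clustering tests, and
molecular-replacement trial tables.

The noise model is deliberately simple: each residue receives an
independent isotropic Gaussian displacement per frame, so the expected
Cα r.m.s.f. is analytically √3·σ_k and parameter-recovery tests have an
exact target.  Real annealing trajectories are time-correlated and
anisotropic; nothing downstream depends on those features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConsistencyError, PreconditionError
from .model_io import CoarseModel, Ensemble
from .mr_triage import MRTrialRecord

logger = logging.getLogger(__name__)

#: canonical α-helix geometry for the Cα trace
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

#: extended-strand zigzag giving ~3.8 Å consecutive Cα spacing
STRAND_RISE = 3.3
STRAND_OFFSET = 0.95

#: residue names cycled through fixtures; includes glycine to exercise
#: the no-Cβ rule
_NAME_CYCLE = ("ALA", "GLY", "SER", "LEU", "GLU")

TOPOLOGIES = ("helix", "strand", "two_fold")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic ensemble; the seed fixes all randomness."""

    n_residues: int
    sigma_profile: np.ndarray
    n_frames: int
    seed: int
    topology: str = "helix"
    rigid_motions: bool = False

    def __post_init__(self):
        if self.n_residues < 4:
            raise PreconditionError("need at least 4 residues")
        sigma = np.asarray(self.sigma_profile, dtype=float).reshape(-1)
        if sigma.shape != (self.n_residues,):
            raise ConsistencyError("sigma_profile length must equal n_residues")
        if np.any(sigma < 0):
            raise PreconditionError("σ values must be non-negative")
        if self.topology not in TOPOLOGIES:
            raise PreconditionError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "sigma_profile", sigma)

    @classmethod
    def uniform(cls, n_residues, sigma, n_frames, seed, **kw) -> "FixtureSpec":
        return cls(
            n_residues=n_residues,
            sigma_profile=np.full(n_residues, float(sigma)),
            n_frames=n_frames,
            seed=seed,
            **kw,
        )


def _residue_names(n: int) -> tuple:
    return tuple(_NAME_CYCLE[i % len(_NAME_CYCLE)] for i in range(n))


def _assemble(ca, cb_dir, o_offset, names, label) -> CoarseModel:
    """Build a CoarseModel from a Cα trace plus Cβ directions and O offsets."""
    n = len(names)
    cb = np.full((n, 3), math.nan)
    for i, name in enumerate(names):
        if name != "GLY":
            cb[i] = ca[i] + 1.5 * cb_dir[i]
    o = ca + o_offset
    zeros = np.zeros(n)
    b_cb = np.where([nm != "GLY" for nm in names], 0.0, math.nan)
    return CoarseModel(
        residue_index=np.arange(1, n + 1),
        residue_name=names,
        ca=ca,
        cb=cb,
        o=o,
        b_ca=zeros,
        b_cb=b_cb,
        b_o=zeros,
        chain_id="A",
        label=label,
    )


def make_ideal_helix(n_residues: int) -> CoarseModel:
    """Ideal α-helix: 1.5 Å rise, 100° twist, 2.3 Å Cα radius.

    Cβ sits 1.5 Å radially outward from its Cα; the carbonyl O is placed
    along the local backbone direction.  Deterministic for a given length;
    consecutive Cα are ~3.8 Å apart and (i, i+4) pairs fall inside the
    9.5 Å contact cutoff, as in a real helix.
    """
    if n_residues < 4:
        raise PreconditionError("need at least 4 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    ca = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    cb_dir = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_residues)])
    # O along the chain direction: towards the next Cα (previous, for the end)
    nxt = np.vstack([ca[1:], ca[-1] + (ca[-1] - ca[-2])])
    step = nxt - ca
    step /= np.linalg.norm(step, axis=1, keepdims=True)
    o_offset = 1.2 * step
    return _assemble(ca, cb_dir, o_offset, _residue_names(n_residues), "ideal-helix")


def make_extended_strand(n_residues: int) -> CoarseModel:
    """Extended β-strand-like zigzag with ~3.8 Å consecutive Cα spacing."""
    if n_residues < 4:
        raise PreconditionError("need at least 4 residues")
    i = np.arange(n_residues)
    ca = np.column_stack(
        [STRAND_OFFSET * (-1.0) ** i, np.zeros(n_residues), STRAND_RISE * i]
    )
    cb_dir = np.column_stack(
        [np.zeros(n_residues), np.ones(n_residues), np.zeros(n_residues)]
    )
    nxt = np.vstack([ca[1:], ca[-1] + (ca[-1] - ca[-2])])
    step = nxt - ca
    step /= np.linalg.norm(step, axis=1, keepdims=True)
    return _assemble(
        ca, cb_dir, 1.2 * step, _residue_names(n_residues), "extended-strand"
    )


def random_rigid_motion(rng: np.random.Generator, translation_scale: float = 10.0):
    """Uniform random proper rotation and Gaussian translation."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(scale=translation_scale, size=3)
    return rot, trans


def apply_rigid_motion(model: CoarseModel, rotation, translation) -> CoarseModel:
    """Apply x → R·x + t to every atom of a model."""
    def move(xyz):
        out = xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out
    return model.with_coords(ca=move(model.ca), cb=move(model.cb), o=move(model.o))


def perturb_ensemble(model: CoarseModel, spec: FixtureSpec) -> Ensemble:
    """Noisy copies of ``model`` with per-residue Gaussian displacement.

    Frame f displaces residue k's atoms by one shared draw from
    N(0, σ_k² I₃), so Cβ and O ride along with their Cα.  With
    ``spec.rigid_motions`` each frame is additionally rotated and
    translated as a rigid body — useful for testing that superposition
    removes global motion.  Bit-reproducible from (model, spec).
    """
    if spec.n_residues != len(model):
        raise ConsistencyError("spec.n_residues does not match the model")
    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in range(spec.n_frames):
        disp = rng.normal(size=(len(model), 3)) * spec.sigma_profile[:, None]
        frame = model.with_coords(
            ca=model.ca + disp, cb=model.cb + disp, o=model.o + disp
        )
        if spec.rigid_motions:
            rot, trans = random_rigid_motion(rng)
            frame = apply_rigid_motion(frame, rot, trans)
        frames.append(frame)
    return Ensemble(frames, source=f"perturbed:{model.label}:seed={spec.seed}")


def make_two_fold_ensemble(spec: FixtureSpec) -> Ensemble:
    """Planted two-fold ensemble: half helix copies, half strand copies.

    Both folds share one residue roster, so within-fold Qw is high (set by
    σ) while between-fold Qw is low by construction — a ground-truth
    partition for clustering tests.  Odd frame counts are rounded down to
    an even split with a warning.
    """
    if spec.topology != "two_fold":
        raise PreconditionError("spec.topology must be 'two_fold'")
    per_fold = spec.n_frames // 2
    if spec.n_frames % 2:
        logger.warning(
            "odd n_frames=%d rounded down to %d per fold", spec.n_frames, per_fold
        )
    if per_fold < 1:
        raise PreconditionError("need at least 2 frames for two folds")
    fold_a = make_ideal_helix(spec.n_residues)
    fold_b = make_extended_strand(spec.n_residues)
    # same roster by construction (same length, same name cycle)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for base in (fold_a, fold_b):
        for _ in range(per_fold):
            disp = rng.normal(size=(len(base), 3)) * spec.sigma_profile[:, None]
            frames.append(
                base.with_coords(ca=base.ca + disp, cb=base.cb + disp, o=base.o + disp)
            )
    return Ensemble(frames, source=f"two-fold:seed={spec.seed}")


def make_trial_records(
    n_success: int,
    n_failure: int,
    seed: int,
    r_free_cutoff: float = 0.45,
) -> list:
    """Synthetic molecular-replacement trial table.

    Successful trials draw R_free uniformly from [0.22, cutoff − 0.01] (the
    range observed for confirmed rebuilds) with TFZ in [8, 25]; failures
    draw R_free from [cutoff + 0.01, 0.58] with TFZ in [4, 14], so some
    failures carry a confidently high TFZ — the false-positive regime the
    triage advisories exist for.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_success):
        records.append(
            MRTrialRecord(
                trial_id=f"trial_{k + 1:03d}",
                tfz=float(rng.uniform(8.0, 25.0)),
                llg=float(rng.uniform(60.0, 400.0)),
                r_free=float(rng.uniform(0.22, r_free_cutoff - 0.01)),
                map_cc=float(rng.uniform(0.25, 0.6)),
            )
        )
    for k in range(n_failure):
        records.append(
            MRTrialRecord(
                trial_id=f"trial_{n_success + k + 1:03d}",
                tfz=float(rng.uniform(4.0, 14.0)),
                llg=float(rng.uniform(20.0, 80.0)),
                r_free=float(rng.uniform(r_free_cutoff + 0.01, 0.58)),
                map_cc=float(rng.uniform(-0.05, 0.1)),
            )
        )
    return records
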