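"""Structure-comparison metrics for coarse-grained models.

All metrics operate on the Cα trace.  Two families are provided:

* superposition-based — optimal rigid-body r.m.s.d. (Kabsch) and GDT-TS,
  the mean over 1/2/4/8 Å thresholds of the fraction of Cα within
  threshold of the reference after superposition;
* distance-difference-based — Qw and its template-restricted variant
  Q_template, Gaussian-weighted agreement of internal pairwise distances,

      Q = (1/n_pairs) Σ_{|i-j| ≥ 3} exp( -(r_ij - r'_ij)² / (2 σ_ij²) ),
      σ_ij = (1 + |i-j|)^0.15 Å,

  which need no superposition and are invariant under rigid motion by
  construction.  Q_template additionally restricts the sum to residue pairs
  covered by a template alignment and drops pairs whose template distance is
  below 2 Å (a step-function exclusion of unphysical reference distances).

Cα–Cα contact maps (default 9.5 Å cutoff, sequence separation ≥ 3) and their
precision/recall/Jaccard overlap complete the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConsistencyError, PreconditionError
from .model_io import CoarseModel

#: exponent of the sequence-separation-dependent Gaussian width σ_ij
SIGMA_EXPONENT = 0.15

#: minimum template pair distance admitted into Q_template (Å)
TEMPLATE_MIN_DISTANCE = 2.0

#: GDT-TS distance thresholds (Å)
GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class AlignmentMap:
    """Injective residue-index correspondence model ↔ template (1-based)."""

    pairs: tuple

    def __post_init__(self):
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        left = [a for a, _ in pairs]
        right = [b for _, b in pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ConsistencyError("alignment must be injective on both sides")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, model: CoarseModel) -> "AlignmentMap":
        idx = model.residue_index.tolist()
        return cls(tuple(zip(idx, idx)))


@dataclass(frozen=True)
class ContactMap:
    """Set of Cα–Cα contacts below a distance cutoff at a minimum separation."""

    n_residues: int
    contacts: frozenset
    cutoff: float
    min_seq_sep: int

    def __post_init__(self):
        contacts = frozenset(
            (min(i, j), max(i, j)) for i, j in self.contacts
        )
        for i, j in contacts:
            if abs(i - j) < self.min_seq_sep:
                raise ConsistencyError(
                    f"contact ({i},{j}) violates min_seq_sep={self.min_seq_sep}"
                )
        object.__setattr__(self, "contacts", contacts)

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class SimilarityScores:
    """Bundle of the standard model-vs-reference metrics."""

    rmsd: float
    qw: float
    gdt_ts: float
    q_template: float | None = None


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(mobile, target):
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the r.m.s.d. to
    ``target`` over the given one-to-one correspondence.  The rotation is
    proper (determinant +1); reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ConsistencyError(
            f"coordinate lists differ in length: {mobile.shape[0]} vs {target.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise PreconditionError("superposition needs at least 3 points")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = tc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# Q metrics


def _aligned_arrays(model_a, model_b, alignment):
    """Cα coordinates and residue indices restricted to an alignment."""
    if alignment is None:
        if model_a.roster() != model_b.roster():
            raise ConsistencyError(
                "models have different rosters; supply an AlignmentMap"
            )
        return model_a.ca, model_b.ca, model_a.residue_index
    pos_a = {int(r): k for k, r in enumerate(model_a.residue_index)}
    pos_b = {int(r): k for k, r in enumerate(model_b.residue_index)}
    try:
        ia = [pos_a[a] for a, _ in alignment.pairs]
        ib = [pos_b[b] for _, b in alignment.pairs]
    except KeyError as exc:
        raise ConsistencyError(f"alignment references missing residue {exc}") from exc
    order = np.argsort([alignment.pairs[k][0] for k in range(len(alignment))])
    ia = np.asarray(ia)[order]
    ib = np.asarray(ib)[order]
    return model_a.ca[ia], model_b.ca[ib], model_a.residue_index[ia]


def _pair_sum(xyz_a, xyz_b, seq_index, min_seq_sep, reference_min=None):
    """Gaussian distance-difference sum over qualifying pairs.

    Returns (sum of terms, number of qualifying pairs).  ``reference_min``
    additionally excludes pairs whose distance in the *second* structure is
    below that value (the Θ filter of the template-restricted metric).
    """
    da = squareform(pdist(xyz_a))
    db = squareform(pdist(xyz_b))
    sep = np.abs(seq_index[:, None] - seq_index[None, :])
    iu = np.triu_indices(len(seq_index), k=1)
    mask = sep[iu] >= min_seq_sep
    if reference_min is not None:
        mask &= db[iu] >= reference_min
    if not mask.any():
        return 0.0, 0
    diff = da[iu][mask] - db[iu][mask]
    sigma = (1.0 + sep[iu][mask].astype(float)) ** SIGMA_EXPONENT
    terms = np.exp(-(diff**2) / (2.0 * sigma**2))
    return float(terms.sum()), int(mask.sum())


def qw(
    model_a: CoarseModel,
    model_b: CoarseModel,
    alignment: AlignmentMap | None = None,
    min_seq_sep: int = 3,
) -> float:
    """Qw similarity in (0, 1]: Gaussian-weighted pairwise-distance agreement.

    Symmetric in its arguments and free of any superposition step.  Pairs
    closer than ``min_seq_sep`` in sequence are excluded as trivially
    constrained; for a contiguous N-residue chain at the default separation
    the normalisation reduces to the textbook 2/((N−2)(N−3)) prefactor.
    """
    xyz_a, xyz_b, seq = _aligned_arrays(model_a, model_b, alignment)
    if len(seq) < 4:
        raise PreconditionError("Qw needs at least 4 residues")
    total, n_pairs = _pair_sum(xyz_a, xyz_b, seq, min_seq_sep)
    if n_pairs == 0:
        raise PreconditionError("no residue pairs satisfy the separation rule")
    return total / n_pairs


def q_template(
    model: CoarseModel,
    template: CoarseModel,
    alignment: AlignmentMap,
    min_seq_sep: int = 3,
) -> float:
    """Template-restricted Q in (0, 1].

    The pair sum runs only over residue pairs covered by ``alignment``
    (model index on the left, template index on the right), with sequence
    separation taken on the model side; template pairs closer than 2 Å are
    excluded from both the sum and the normalisation, so the score stays in
    (0, 1] regardless of template pathologies.
    """
    xyz_m, xyz_t, seq = _aligned_arrays(model, template, alignment)
    total, n_pairs = _pair_sum(
        xyz_m, xyz_t, seq, min_seq_sep, reference_min=TEMPLATE_MIN_DISTANCE
    )
    if n_pairs == 0:
        raise PreconditionError(
            "no aligned pairs survive the separation and 2 Å template filters"
        )
    return total / n_pairs


# ---------------------------------------------------------------------------
# GDT-TS


def gdt_ts(
    model: CoarseModel,
    reference: CoarseModel,
    presuperpose: bool = True,
    alignment: AlignmentMap | None = None,
) -> float:
    """Global Distance Test (total score) over thresholds 1, 2, 4 and 8 Å.

    The fraction of aligned Cα whose deviation from the reference is within
    each threshold, averaged over the four thresholds.  With ``presuperpose``
    (default) a single all-residue Kabsch superposition is applied first;
    without it the coordinates are compared as given, which is useful when a
    fixed frame is already shared.
    """
    xyz_m, xyz_r, _seq = _aligned_arrays(model, reference, alignment)
    if xyz_m.shape[0] == 0:
        raise PreconditionError("empty alignment")
    if presuperpose:
        rot, trans, _ = kabsch_superpose(xyz_m, xyz_r)
        xyz_m = xyz_m @ rot.T + trans
    dev = np.linalg.norm(xyz_m - xyz_r, axis=1)
    return float(np.mean([(dev <= t).mean() for t in GDT_THRESHOLDS]))


# ---------------------------------------------------------------------------
# Contact maps


def contact_map(
    model: CoarseModel, cutoff: float = 9.5, min_seq_sep: int = 3
) -> ContactMap:
    """All unordered residue pairs with Cα distance ≤ cutoff and |i−j| ≥ sep."""
    if len(model) < 2:
        raise PreconditionError("contact map needs at least 2 residues")
    idx = model.residue_index
    dmat = squareform(pdist(model.ca))
    sep = np.abs(idx[:, None] - idx[None, :])
    iu = np.triu_indices(len(model), k=1)
    hit = (dmat[iu] <= cutoff) & (sep[iu] >= min_seq_sep)
    contacts = frozenset(
        (int(idx[i]), int(idx[j]))
        for i, j, h in zip(iu[0], iu[1], hit)
        if h
    )
    return ContactMap(
        n_residues=len(model),
        contacts=contacts,
        cutoff=float(cutoff),
        min_seq_sep=int(min_seq_sep),
    )


def contact_overlap(predicted: ContactMap, reference: ContactMap):
    """Precision, recall and Jaccard overlap of two contact maps.

    Both maps must be built with the same residue count, cutoff and
    separation.  An empty predicted (or reference) set makes precision
    (recall) undefined, reported as NaN; the Jaccard index of two empty
    maps is likewise NaN.
    """
    for attr in ("n_residues", "cutoff", "min_seq_sep"):
        if getattr(predicted, attr) != getattr(reference, attr):
            raise ConsistencyError(
                f"contact maps differ in {attr}: "
                f"{getattr(predicted, attr)} vs {getattr(reference, attr)}"
            )
    p, r = predicted.contacts, reference.contacts
    inter = len(p & r)
    union = len(p | r)
    precision = inter / len(p) if p else float("nan")
    recall = inter / len(r) if r else float("nan")
    jaccard = inter / union if union else float("nan")
    return precision, recall, jaccard


# ---------------------------------------------------------------------------
# Convenience roll-up


def score_pair(
    model: CoarseModel,
    reference: CoarseModel,
    alignment: AlignmentMap | None = None,
    template: CoarseModel | None = None,
    template_alignment: AlignmentMap | None = None,
) -> SimilarityScores:
    """Compute the standard metric bundle for one model/reference pair."""
    xyz_m, xyz_r, _ = _aligned_arrays(model, reference, alignment)
    _, _, rmsd = kabsch_superpose(xyz_m, xyz_r)
    qt = None
    if template is not None:
        if template_alignment is None:
            raise PreconditionError("template scoring requires template_alignment")
        qt = q_template(model, template, template_alignment)
    return SimilarityScores(
        rmsd=rmsd,
        qw=qw(model, reference, alignment=alignment),
        gdt_ts=gdt_ts(model, reference, alignment=alignment),
        q_template=qt,
    )
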