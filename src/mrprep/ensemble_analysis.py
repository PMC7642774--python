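"""Mutual-Q clustering of prediction ensembles.

Independent structure-prediction runs for the same target either converge
on one basin or scatter across several folds.  Clustering the runs by their
pairwise Qw similarity makes that visible before any expensive phasing
trial: a single dominant cluster suggests a well-determined prediction
(run more molecular-replacement trials if the first failed); several
mutually similar clusters still merit more trials; a dispersed pattern —
many small, mutually dissimilar clusters — is the signature of a target
the protocol finds too hard.

Clustering is agglomerative with average linkage on the dissimilarity
d = 1 − Q, cut at a Q threshold (default 0.75, between the ~0.9 typical of
within-basin similarity and the ~0.5 observed between distinct folds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ConsistencyError, PreconditionError
from .similarity import qw

#: recognised clustergram patterns
PATTERNS = ("single_dominant", "multi_cluster", "dispersed")

ADVISORY = {
    "single_dominant": (
        "runs converge on one basin; if phasing failed, more trials of the "
        "same protocol are worthwhile"
    ),
    "multi_cluster": (
        "several coherent folds sampled; more trials are worthwhile and each "
        "cluster representative deserves a phasing attempt"
    ),
    "dispersed": (
        "runs do not cluster; the target itself may be too hard for the "
        "protocol — consider better templates or contacts before more trials"
    ),
}


@dataclass(frozen=True)
class ClusterResult:
    """Clustering of an ensemble by mutual Q."""

    q_matrix: np.ndarray
    labels: np.ndarray
    linkage_method: str
    threshold: float
    pattern: str
    linkage_matrix: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q_matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ConsistencyError("q_matrix must be square")
        if labels.shape != (q.shape[0],):
            raise ConsistencyError("labels must cover all frames")
        if self.pattern not in PATTERNS:
            raise ConsistencyError(f"unknown pattern {self.pattern!r}")
        object.__setattr__(self, "q_matrix", q)
        object.__setattr__(self, "labels", labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> np.ndarray:
        """Cluster sizes in decreasing order."""
        _, counts = np.unique(self.labels, return_counts=True)
        return np.sort(counts)[::-1]

    @property
    def advisory(self) -> str:
        return ADVISORY[self.pattern]


def mutual_q_matrix(models) -> np.ndarray:
    """Symmetric matrix of pairwise Qw values with a unit diagonal."""
    models = list(models)
    if len(models) < 2:
        raise PreconditionError("need at least 2 models")
    roster = models[0].roster()
    for k, m in enumerate(models[1:], start=2):
        if m.roster() != roster:
            raise ConsistencyError(f"model {k} roster differs from model 1")
    n = len(models)
    q = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            q[i, j] = q[j, i] = qw(models[i], models[j])
    return q


def cluster_models(
    q_matrix,
    linkage_method: str = "average",
    q_threshold: float = 0.75,
    dominant_fraction: float = 0.5,
    between_q_threshold: float = 0.5,
) -> ClusterResult:
    """Agglomerative clustering of a mutual-Q matrix.

    Works on the dissimilarity d = 1 − Q with the requested linkage
    (average by default) and cuts the dendrogram at d = 1 − ``q_threshold``.
    Deterministic for a fixed input matrix.
    """
    q = np.asarray(q_matrix, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ConsistencyError("q_matrix must be square")
    if not np.allclose(q, q.T, atol=1e-8):
        raise ConsistencyError("q_matrix is not symmetric")
    q = (q + q.T) / 2.0
    dist = 1.0 - q
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(z, t=1.0 - q_threshold, criterion="distance")
    pattern = _classify(labels, q, dominant_fraction, between_q_threshold)
    return ClusterResult(
        q_matrix=q,
        labels=labels,
        linkage_method=linkage_method,
        threshold=float(1.0 - q_threshold),
        pattern=pattern,
        linkage_matrix=z,
    )


def mean_between_cluster_q(q_matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean Q over all frame pairs belonging to different clusters.

    NaN when everything sits in one cluster.
    """
    labels = np.asarray(labels)
    diff = labels[:, None] != labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    mask = diff[iu]
    if not mask.any():
        return float("nan")
    return float(np.asarray(q_matrix)[iu][mask].mean())


def _classify(labels, q_matrix, dominant_fraction, between_q_threshold) -> str:
    _, counts = np.unique(labels, return_counts=True)
    n = labels.size
    if counts.max() >= dominant_fraction * n:
        return "single_dominant"
    if (counts >= 2).sum() >= 2:
        if mean_between_cluster_q(q_matrix, labels) > between_q_threshold:
            return "multi_cluster"
    return "dispersed"


def classify_pattern(
    result: ClusterResult,
    dominant_fraction: float = 0.5,
    between_q_threshold: float = 0.5,
) -> str:
    """Classify a clustering into single_dominant / multi_cluster / dispersed.

    ``single_dominant``: the largest cluster holds at least
    ``dominant_fraction`` of the frames (default half — the regime where a
    single basin dominates the runs and a failed phasing attempt warrants
    more trials).  ``multi_cluster``: no dominant cluster, but at least two
    clusters of size ≥ 2 that remain mutually similar (mean between-cluster
    Q above ``between_q_threshold``; distinct folds from converged runs).
    ``dispersed``: everything else — mostly singletons, or small clusters
    whose mutual Q has dropped to the ~0.5 level seen for targets the
    protocol cannot handle.
    """
    return _classify(
        result.labels, result.q_matrix, dominant_fraction, between_q_threshold
    )


def export_clustergram(result: ClusterResult, path, image_path=None) -> None:
    """Write the dendrogram-reordered Q matrix as TSV (and optionally a figure).

    Rows/columns follow the dendrogram leaf order, so coherent clusters show
    up as blocks along the diagonal.  The TSV is deterministic for a fixed
    input; ``image_path`` additionally renders a heatmap with the dendrogram.
    """
    order = leaves_list(result.linkage_matrix)
    reordered = result.q_matrix[np.ix_(order, order)]
    header = "\t".join(f"frame_{i + 1}" for i in order)
    lines = [header]
    for row in reordered:
        lines.append("\t".join(f"{v:.6f}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if image_path is not None:
        _render_clustergram(result, order, reordered, image_path)


def _render_clustergram(result, order, reordered, image_path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(6, 8), height_ratios=[1, 3], constrained_layout=True
    )
    dendrogram(
        result.linkage_matrix,
        ax=ax_d,
        color_threshold=result.threshold,
        no_labels=True,
    )
    ax_d.axhline(result.threshold, ls="--", lw=0.8, color="grey")
    ax_d.set_ylabel("1 − Q")
    im = ax_h.imshow(reordered, vmin=0, vmax=1, cmap="viridis")
    ax_h.set_xticks(range(len(order)))
    ax_h.set_yticks(range(len(order)))
    ax_h.set_xticklabels([str(i + 1) for i in order], fontsize=6, rotation=90)
    ax_h.set_yticklabels([str(i + 1) for i in order], fontsize=6)
    fig.colorbar(im, ax=ax_h, label="mutual Q")
    ax_h.set_title(f"pattern: {result.pattern}")
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
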