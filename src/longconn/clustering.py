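"""Multiview group-wise spectral clustering of connectivity views.

Every subject-session's FC matrix is one "view" of the same node set; the
goal is a single node partition into k clusters (default 8) such that
nodes within a cluster are more strongly connected to each other than to
nodes of other clusters, *consistently across individuals*.

The scheme is a co-training-style multiview spectral clustering:

1. per view, the affinity is the positive part of the FC matrix (or |r|
   by flag), diagonal zeroed, symmetrically degree-normalized;
2. each view's spectral embedding (top-k eigenvectors) is computed;
3. for a fixed number of rounds each view's normalized affinity is
   projected onto the average spectral subspace of the *other* views
   (symmetrized), and the embeddings are recomputed — this is the
   "projecting each view on the others" step that transfers cluster
   structure between individuals;
4. the consensus embedding is the column-wise concatenation of the
   row-normalized view embeddings, partitioned by seeded k-means
   (20 restarts, best inertia kept).

Iteration stops early when the consensus assignment stabilizes.  The
whole procedure is deterministic given the seed.  With all views
identical the projection is a fixed point and the result coincides with
ordinary spectral clustering of the single view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .connectome import FCMatrix

__all__ = [
    "ClusterAssignment",
    "ClusterPairSummary",
    "multiview_cluster",
    "spectral_cluster",
    "categorize_signatures_by_cluster",
]


@dataclass
class ClusterAssignment:
    """node_id -> cluster label in {1..k} plus per-view agreement scores.

    ``per_view_agreement`` is the adjusted Rand index between the
    consensus partition and the single-view spectral partition of each
    view, a diagnostic of how consistently the views carry the consensus
    structure.
    """

    labels: dict[str, int]
    k: int
    per_view_agreement: list[float] = field(default_factory=list)
    n_iterations: int = 0
    eigengap: float | None = None

    def __post_init__(self) -> None:
        used = sorted(set(self.labels.values()))
        if used != list(range(1, self.k + 1)):
            raise ValueError(
                f"labels must be contiguous 1..{self.k} with no empty cluster, got {used}"
            )

    def labels_array(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[n] for n in node_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": list(self.labels), "cluster": list(self.labels.values())}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "cluster": int})
        labels = dict(zip(df["node_id"], df["cluster"]))
        return cls(labels=labels, k=int(max(labels.values())))


def _affinity(fc: FCMatrix | np.ndarray, mode: str) -> np.ndarray:
    w = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    w = np.abs(w) if mode == "abs" else np.clip(w, 0.0, None)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def _check_connected(w: np.ndarray, view_index: int, k: int) -> None:
    """Reject affinities the spectral embedding cannot handle.

    Up to ``k`` connected components are fine (their indicators span the
    top eigenspace); more than ``k``, or an isolated zero-degree node,
    cannot be clustered into k groups meaningfully.
    """
    n = w.shape[0]
    if np.any(w.sum(axis=1) <= 0):
        raise ValueError(
            f"view {view_index} has isolated zero-degree nodes; consider "
            "adding a small affinity floor (e.g. w + eps) or the 'abs' affinity"
        )
    adj = w > 0
    seen = np.zeros(n, dtype=bool)
    n_comp = 0
    for start in range(n):
        if seen[start]:
            continue
        n_comp += 1
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            nxt = np.nonzero(adj[u] & ~seen)[0]
            seen[nxt] = True
            stack.extend(nxt.tolist())
    if n_comp > k:
        raise ValueError(
            f"affinity graph of view {view_index} splits into {n_comp} > k "
            "connected components; consider adding a small affinity floor "
            "(e.g. w + eps) or the 'abs' affinity"
        )


def _normalize(w: np.ndarray) -> np.ndarray:
    deg = w.sum(axis=1)
    inv = 1.0 / np.sqrt(deg)
    return w * inv[:, None] * inv[None, :]


def _embedding(m: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Top-k eigenvectors of a symmetric matrix (descending), sign-fixed.

    Also returns the eigengap |lambda_k - lambda_{k+1}| as a diagnostic.
    """
    n = m.shape[0]
    lo = max(n - k - 1, 0)
    vals, vecs = linalg.eigh(m, subset_by_index=[lo, n - 1])
    vals, vecs = vals[::-1], vecs[:, ::-1]
    u = vecs[:, :k].copy()
    gap = float(vals[k - 1] - vals[k]) if len(vals) > k else float("nan")
    for c in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, c])))
        if u[j, c] < 0:
            u[:, c] = -u[:, c]
    return u, gap


def _row_normalize(u: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = 1.0
    return u / norms[:, None]


def _kmeans_labels(x: np.ndarray, k: int, seed: int, restarts: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(x)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def spectral_cluster(
    fc: FCMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    affinity: str = "positive",
    kmeans_restarts: int = 20,
) -> np.ndarray:
    """Ordinary normalized spectral clustering of a single view (labels 1..k)."""
    w = _affinity(fc, affinity)
    _check_connected(w, 0, k)
    u, _ = _embedding(_normalize(w), k)
    raw = _kmeans_labels(_row_normalize(u), k, seed, kmeans_restarts)
    return _canonical_labels(raw)


def multiview_cluster(
    views: Sequence[FCMatrix | np.ndarray],
    k: int = 8,
    n_iter: int = 10,
    seed: int = 0,
    affinity: str = "positive",
    kmeans_restarts: int = 20,
    node_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Consensus node partition across all connectivity views.

    Raises on k < 2, k >= n_nodes, or a disconnected view affinity.
    Deterministic given ``seed``.
    """
    if len(views) < 1:
        raise ValueError("need at least one view")
    mats = [_affinity(v, affinity) for v in views]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all views must share the same node set")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the node count {n}")
    if node_ids is None:
        first = views[0]
        node_ids = (
            list(first.node_ids)
            if isinstance(first, FCMatrix)
            else [f"n{i:03d}" for i in range(n)]
        )
    for vi, m in enumerate(mats):
        _check_connected(m, vi, k)
    norms = [_normalize(m) for m in mats]
    embeds, gaps = zip(*(_embedding(m, k) for m in norms))
    embeds = list(embeds)

    prev_labels: np.ndarray | None = None
    n_done = 0
    for it in range(n_iter):
        projections = [u @ u.T for u in embeds]
        total = np.sum(projections, axis=0)
        new_norms = []
        for v in range(len(norms)):
            if len(norms) == 1:
                pbar = projections[0]
            else:
                pbar = (total - projections[v]) / (len(norms) - 1)
            pm = pbar @ norms[v]
            new_norms.append((pm + pm.T) / 2.0)
        norms = new_norms
        embeds = [_embedding(m, k)[0] for m in norms]
        n_done = it + 1
        concat = np.hstack([_row_normalize(u) for u in embeds])
        labels = _canonical_labels(_kmeans_labels(concat, k, seed, kmeans_restarts))
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels

    concat = np.hstack([_row_normalize(u) for u in embeds])
    labels = _canonical_labels(_kmeans_labels(concat, k, seed, kmeans_restarts))
    agreement = [
        float(
            adjusted_rand_score(
                labels,
                _canonical_labels(_kmeans_labels(_row_normalize(u), k, seed, kmeans_restarts)),
            )
        )
        for u in embeds
    ]
    return ClusterAssignment(
        labels=dict(zip(node_ids, labels.tolist())),
        k=int(labels.max()),
        per_view_agreement=agreement,
        n_iterations=n_done,
        eigengap=float(np.mean(gaps)),
    )


@dataclass
class ClusterPairSummary:
    """Signature counts per unordered cluster pair.

    ``counts`` holds each unordered pair once, in the cell whose row
    cluster number <= column cluster number; the diagonal is the
    within-cluster count.
    """

    counts: pd.DataFrame
    total: int

    @property
    def within_total(self) -> int:
        return int(np.diag(self.counts.to_numpy()).sum())

    @property
    def between_total(self) -> int:
        return self.total - self.within_total

    @property
    def percent_defined(self) -> bool:
        return self.total > 0

    @property
    def between_percent(self) -> float:
        return 100.0 * self.between_total / self.total if self.total else 0.0

    @property
    def within_percent(self) -> float:
        return 100.0 * self.within_total / self.total if self.total else 0.0

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def categorize_signatures_by_cluster(
    edges: Iterable[tuple[str, str]],
    assign: ClusterAssignment,
) -> ClusterPairSummary:
    """Count signatures per unordered cluster pair and the within/between split."""
    edges = list(edges)
    missing = sorted({str(n) for e in edges for n in e if n not in assign.labels})
    if missing:
        raise KeyError(f"nodes without a cluster label: {missing}")
    k = assign.k
    idx = list(range(1, k + 1))
    counts = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    for a, b in edges:
        ca, cb = assign.labels[a], assign.labels[b]
        if ca > cb:
            ca, cb = cb, ca
        counts.loc[ca, cb] += 1
    return ClusterPairSummary(counts=counts, total=len(edges))
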