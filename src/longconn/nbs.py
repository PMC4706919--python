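"""Network-based statistic (NBS) with permutation FWER control.

Edge statistics are thresholded (default 3.5 on the |t| scale, i.e.
sqrt(F) for the 1-df mixed-ANOVA effects), suprathreshold edges are
grouped into connected components (two edges connect iff they share a
node), and each observed component of extent K (edge count) receives a
family-wise-error-corrected p-value from the permutation null
distribution of the *maximal* component extent:

    fwer_p = (1 + #{permutation maxima >= K}) / (M + 1)

which can never be 0 and is exact under exchangeability.  Permutation
schemes respect the mixed design: for the group and interaction effects
subjects are the exchangeability blocks (group labels are permuted across
subjects, both sessions moving together); for the time effect session
labels are flipped independently within each subject (sign flips of the
within-subject differences).

Thresholding uses a strict inequality (ties at exactly the threshold are
excluded); degenerate zero-variance edges never enter components.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .connectome import FCStack, tri_indices
from .edge_stats import ANOVA_EFFECTS, EdgeStatMap, edgewise_stats, stack_edge_values

__all__ = [
    "NBSConfig",
    "ComponentResult",
    "NBSResult",
    "threshold_edges",
    "connected_components",
    "permutation_scheme",
    "nbs_test",
]


@dataclass
class NBSConfig:
    """NBS settings (defaults follow the emulated study's analysis)."""

    threshold: float = 3.5  # on the |t| scale for 1-df effects
    n_permutations: int = 5000
    component_measure: str = "extent"
    alpha: float = 0.05
    direction: str = "both"  # "both" | "positive" | "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.component_measure != "extent":
            raise ValueError("only the extent (edge count) component measure is supported")
        if self.direction not in ("both", "positive", "negative"):
            raise ValueError("direction must be both/positive/negative")


@dataclass
class ComponentResult:
    """One suprathreshold connected component and its corrected p-value."""

    edges: list[tuple[int, int]]  # node-index pairs
    edge_indices: np.ndarray  # positions in the canonical edge vector
    nodes: list[int]
    extent: int
    fwer_p: float
    direction: str  # "increase" | "decrease" | "mixed"
    significant: bool


@dataclass
class NBSResult:
    """Observed components, their p-values, and the permutation null."""

    components: list[ComponentResult]
    null_max_extent: np.ndarray
    stats: EdgeStatMap
    config: NBSConfig
    effect: str

    @property
    def significant_components(self) -> list[ComponentResult]:
        return [c for c in self.components if c.significant]

    def significant_edges(self) -> list[tuple[int, int]]:
        """Pooled node-index edge list over all significant components."""
        return [e for c in self.significant_components for e in c.edges]

    def significant_edge_ids(self) -> list[tuple[str, str]]:
        ids = self.stats.node_ids
        return [(ids[i], ids[j]) for i, j in self.significant_edges()]

    def write_components_tsv(self, path: str | Path) -> None:
        ids = self.stats.node_ids
        rows = []
        for ci, comp in enumerate(self.components):
            for (i, j), k in zip(comp.edges, comp.edge_indices):
                rows.append(
                    {
                        "component_id": ci,
                        "node_i": ids[i],
                        "node_j": ids[j],
                        "statistic": self.stats.stat[k],
                        "sign": self.stats.sign[k],
                        "extent": comp.extent,
                        "fwer_p": comp.fwer_p,
                        "significant": comp.significant,
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "component_id", "node_i", "node_j", "statistic",
                "sign", "extent", "fwer_p", "significant",
            ],
        ).to_csv(path, sep="\t", index=False)

    def write_null_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"max_extent": self.null_max_extent}).to_csv(
            path, sep="\t", index=False
        )

    def summary(self) -> dict:
        return {
            "effect": self.effect,
            "threshold": self.config.threshold,
            "n_permutations": self.config.n_permutations,
            "alpha": self.config.alpha,
            "direction": self.config.direction,
            "seed": self.config.seed,
            "n_components": len(self.components),
            "components": [
                {
                    "extent": c.extent,
                    "fwer_p": c.fwer_p,
                    "direction": c.direction,
                    "significant": c.significant,
                    "n_nodes": len(c.nodes),
                }
                for c in self.components
            ],
            "n_significant_components": len(self.significant_components),
            "n_significant_edges": len(self.significant_edges()),
        }


# ---------------------------------------------------------------------------
# thresholding and components
# ---------------------------------------------------------------------------

def threshold_edges(stats: EdgeStatMap, config: NBSConfig) -> np.ndarray:
    """Indices of edges whose statistic strictly exceeds the threshold.

    The comparison is on the signed t scale; ``direction="both"`` keeps
    |t| > threshold, one-sided modes keep only the matching sign.
    Degenerate edges are always excluded.
    """
    t = stats.t_equivalent()
    if config.direction == "both":
        keep = np.abs(t) > config.threshold
    elif config.direction == "positive":
        keep = t > config.threshold
    else:
        keep = -t > config.threshold
    keep &= ~stats.degenerate
    return np.nonzero(keep)[0]


class _UnionFind:
    """Array-backed union-find over integer node labels."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent
        root = p.setdefault(x, x)
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def connected_components(
    edges: Iterable[tuple[int, int]]
) -> list[tuple[list[tuple[int, int]], list[int], int]]:
    """Partition an edge set into connected components.

    Two edges belong to the same component iff they are linked through
    shared nodes (components of the suprathreshold graph; isolated nodes
    are ignored).  Returns ``(edges, nodes, extent)`` triples sorted by
    extent descending, ties by smallest member node.
    """
    edges = [(int(a), int(b)) for a, b in edges]
    uf = _UnionFind()
    for a, b in edges:
        uf.union(a, b)
    groups: dict[int, list[tuple[int, int]]] = {}
    for e in edges:
        groups.setdefault(uf.find(e[0]), []).append(e)
    comps = []
    for es in groups.values():
        nodes = sorted({n for e in es for n in e})
        comps.append((es, nodes, len(es)))
    comps.sort(key=lambda c: (-c[2], c[1][0]))
    return comps


def _max_extent(edges_a: np.ndarray, edges_b: np.ndarray) -> int:
    """Extent of the largest component over (i, j) index arrays; 0 if empty."""
    if len(edges_a) == 0:
        return 0
    uf = _UnionFind()
    for a, b in zip(edges_a.tolist(), edges_b.tolist()):
        uf.union(a, b)
    counts: dict[int, int] = {}
    for a in edges_a.tolist():
        r = uf.find(a)
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


# ---------------------------------------------------------------------------
# permutation schemes
# ---------------------------------------------------------------------------

def permutation_scheme(
    effect: str,
    patient: np.ndarray,
    n_permutations: int | None = None,
    seed: int = 0,
    exhaustive: bool = False,
) -> Iterator[np.ndarray]:
    """Stream of permuted designs respecting the effect's exchangeability.

    For ``group`` and ``interaction`` each draw is a permuted boolean
    patient indicator (subjects are exchangeability blocks: both sessions
    of a subject move together, group sizes preserved).  For ``time``
    each draw is a +/-1 session-flip vector per subject.  ``exhaustive``
    enumerates every distinct design exactly once (identity included).
    """
    patient = np.asarray(patient, dtype=bool)
    S = len(patient)
    if effect in ("group", "interaction"):
        if exhaustive:
            n1 = int(patient.sum())
            for pos in itertools.combinations(range(S), n1):
                out = np.zeros(S, dtype=bool)
                out[list(pos)] = True
                yield out
            return
        rng = np.random.default_rng(seed)
        for _ in range(int(n_permutations)):
            yield rng.permutation(patient)
    elif effect == "time":
        if exhaustive:
            for signs in itertools.product((1, -1), repeat=S):
                yield np.array(signs, dtype=int)
            return
        rng = np.random.default_rng(seed)
        for _ in range(int(n_permutations)):
            yield rng.integers(0, 2, S) * 2 - 1
    else:
        raise ValueError(f"unsupported effect {effect!r} for permutation")


# ---------------------------------------------------------------------------
# permutation statistics (vectorized across permutations x edges)
# ---------------------------------------------------------------------------

def _group_perm_t2(v: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Squared pooled two-sample t for many permuted group labelings.

    ``v`` is (subjects, edges); ``indicators`` is (n_perm, subjects) bool
    with fixed group sizes.  Returns (n_perm, edges); degenerate slots 0.
    """
    S, _ = v.shape
    n1 = int(indicators[0].sum())
    n0 = S - n1
    tot = v.sum(axis=0)
    tot2 = (v * v).sum(axis=0)
    B = indicators.astype(float)
    s1 = B @ v
    q1 = B @ (v * v)
    s0 = tot - s1
    ss1 = q1 - s1 * s1 / n1
    ss0 = (tot2 - q1) - s0 * s0 / n0
    sp2 = (ss0 + ss1) / (S - 2) * (1.0 / n0 + 1.0 / n1)
    diff = s1 / n1 - s0 / n0
    bad = sp2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(bad, 0.0, diff * diff / np.where(bad, 1.0, sp2))
    return t2, np.sign(diff)


def _time_perm_t2(d: np.ndarray, flips: np.ndarray, patient: np.ndarray) -> np.ndarray:
    """Squared time-effect t under session sign flips.

    ``d`` is (subjects, edges) within-subject differences; ``flips`` is
    (n_perm, subjects) of +/-1.
    """
    S = d.shape[0]
    ssq_by_group = [((d[~patient]) ** 2).sum(axis=0), ((d[patient]) ** 2).sum(axis=0)]
    n_by_group = [int((~patient).sum()), int(patient.sum())]
    F = flips.astype(float)
    total = F @ d
    ss = np.zeros_like(total)
    for gmask, ssq, ng in zip((~patient, patient), ssq_by_group, n_by_group):
        sum_g = (F * gmask) @ d
        ss = ss + (ssq - sum_g * sum_g / ng)
    mse = ss / (S - 2)
    mean = total / S
    bad = mse <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(bad, 0.0, mean * mean / np.where(bad, 1.0, mse / S))
    return t2, np.sign(mean)


# ---------------------------------------------------------------------------
# the NBS test
# ---------------------------------------------------------------------------

def nbs_test(
    stack: FCStack,
    effect: str,
    config: NBSConfig | None = None,
    scale: str = "z",
) -> NBSResult:
    """Full NBS inference for one effect of the mixed design.

    Observed components are computed once; each of M permutations permutes
    the design per the effect's exchangeability scheme, recomputes all
    edge statistics, and records the maximal suprathreshold component
    extent.  Deterministic given ``config.seed``.
    """
    config = config or NBSConfig()
    if effect not in ANOVA_EFFECTS:
        raise ValueError(
            f"nbs_test supports the mixed-ANOVA effects {ANOVA_EFFECTS}, got {effect!r}"
        )
    if 1.0 / (config.n_permutations + 1) > config.alpha:
        warnings.warn(
            f"{config.n_permutations} permutations cannot resolve "
            f"alpha = {config.alpha}: smallest attainable p is "
            f"{1.0 / (config.n_permutations + 1):.4g}",
            stacklevel=2,
        )

    stats = edgewise_stats(stack, effect, scale=scale)
    supra = threshold_edges(stats, config)
    ii, jj = stats.edge_index()
    # component edges oriented (small node, large node); tri order is i > j
    comps_raw = connected_components(zip(jj[supra], ii[supra]))
    pos = {(int(b), int(a)): int(k) for a, b, k in zip(ii[supra], jj[supra], supra)}

    y, _, patient = stack_edge_values(stack, scale)
    if min(int(patient.sum()), int((~patient).sum())) < 2:
        raise ValueError("degenerate permutation space: need >= 2 subjects per group")
    m = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]
    v = m if effect == "group" else d

    M = config.n_permutations
    E = v.shape[1]
    chunk = max(1, min(M, int(8_000_000 // max(E, 1)) or 1))
    rng = np.random.default_rng(config.seed)
    thr2 = config.threshold**2
    null_max = np.empty(M, dtype=int)
    done = 0
    while done < M:
        c = min(chunk, M - done)
        if effect == "time":
            flips = rng.integers(0, 2, (c, v.shape[0])) * 2 - 1
            t2, sgn = _time_perm_t2(d, flips, patient)
        else:
            idx = np.argsort(rng.random((c, v.shape[0])), axis=1)
            indicators = patient[idx]
            t2, sgn = _group_perm_t2(v, indicators)
        mask = t2 > thr2
        if config.direction == "positive":
            mask &= sgn > 0
        elif config.direction == "negative":
            mask &= sgn < 0
        rows, cols = np.nonzero(mask)
        if len(rows):
            bounds = np.searchsorted(rows, np.arange(c + 1))
            for p in range(c):
                sel = cols[bounds[p]:bounds[p + 1]]
                null_max[done + p] = _max_extent(ii[sel], jj[sel])
        else:
            null_max[done:done + c] = 0
        done += c

    components = []
    for es, nodes, extent in comps_raw:
        fwer_p = (1.0 + int((null_max >= extent).sum())) / (M + 1.0)
        signs = [stats.sign[pos[e]] for e in es]
        if all(s > 0 for s in signs):
            direction = "increase"
        elif all(s < 0 for s in signs):
            direction = "decrease"
        else:
            direction = "mixed"
        components.append(
            ComponentResult(
                edges=es,
                edge_indices=np.array([pos[e] for e in es], dtype=int),
                nodes=nodes,
                extent=extent,
                fwer_p=fwer_p,
                direction=direction,
                significant=fwer_p <= config.alpha,
            )
        )
    return NBSResult(
        components=components,
        null_max_extent=null_max,
        stats=stats,
        config=config,
        effect=effect,
    )
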