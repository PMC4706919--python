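"""Functional-domain annotation of connectomic signatures.

Each network node carries a major functional category — one of Action,
Perception, Cognition, Interoception, Emotion — and a finer subcategory
(53 in total, each nested under exactly one major category).  A significant
edge ("connectomic signature") between a node labelled, say, Cognition and
one labelled Emotion is interpreted as an alteration of the
Cognition–Emotion interaction; counting signatures per unordered category
pair summarises which functional domains an effect involves.

The node-to-category table is an *input* (real landmark labels come from
meta-analytic databases, outside this package's scope); a synthetic
taxonomy and label generator live in :mod:`longconn.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAJOR_CATEGORIES",
    "SUBCATEGORIES",
    "SUBCATEGORY_PARENT",
    "CategoryMap",
    "CategoryPairSummary",
    "categorize_edges",
    "aggregate_to_major",
    "top_pairs",
    "plot_pair_heatmap",
]

MAJOR_CATEGORIES: tuple[str, ...] = (
    "Action",
    "Perception",
    "Cognition",
    "Interoception",
    "Emotion",
)

# Synthetic 53-subcategory taxonomy patterned on the behavioural-domain
# hierarchies used by neuroimaging meta-analysis databases (8 + 12 + 14 +
# 9 + 10 = 53).  Real node labels can replace it via any TSV with the same
# nesting structure.
_TAXONOMY: dict[str, tuple[str, ...]] = {
    "Action": (
        "Execution",
        "Imagination",
        "Inhibition",
        "Motor Learning",
        "Observation",
        "Preparation",
        "Rest",
        "Sequencing",
    ),
    "Perception": (
        "Audition",
        "Gustation",
        "Olfaction",
        "Somesthesis Pain",
        "Somesthesis Proprioception",
        "Somesthesis Temperature",
        "Somesthesis Touch",
        "Vision Color",
        "Vision Motion",
        "Vision Shape",
        "Vision Other",
        "Somesthesis Other",
    ),
    "Cognition": (
        "Attention",
        "Working Memory",
        "Declarative Memory",
        "Explicit Memory",
        "Implicit Memory",
        "Language Orthography",
        "Language Phonology",
        "Language Semantics",
        "Language Speech",
        "Language Syntax",
        "Music",
        "Reasoning",
        "Social Cognition",
        "Spatial Cognition",
    ),
    "Interoception": (
        "Air Hunger",
        "Baroregulation",
        "Bladder",
        "Heartbeat",
        "Hunger",
        "Osmoregulation",
        "Sexuality",
        "Sleep",
        "Thirst",
    ),
    "Emotion": (
        "Anger",
        "Anxiety",
        "Disgust",
        "Empathy",
        "Fear",
        "Happiness",
        "Humor",
        "Sadness",
        "Valence Negative",
        "Valence Positive",
    ),
}

SUBCATEGORY_PARENT: dict[str, str] = {
    sub: major for major, subs in _TAXONOMY.items() for sub in subs
}
SUBCATEGORIES: tuple[str, ...] = tuple(SUBCATEGORY_PARENT)
assert len(SUBCATEGORIES) == 53


@dataclass
class CategoryMap:
    """node_id -> (major category, subcategory), subcategory nested under major."""

    major: dict[str, str]
    sub: dict[str, str]
    parent: dict[str, str] = field(default_factory=lambda: dict(SUBCATEGORY_PARENT))

    def __post_init__(self) -> None:
        if set(self.major) != set(self.sub):
            raise ValueError("major and sub maps must cover the same nodes")
        for nid, s in self.sub.items():
            if s not in self.parent:
                raise ValueError(f"unknown subcategory {s!r} for node {nid}")
            if self.parent[s] != self.major[nid]:
                raise ValueError(
                    f"node {nid}: subcategory {s!r} is nested under "
                    f"{self.parent[s]!r}, not {self.major[nid]!r}"
                )

    def labels(self, level: str) -> dict[str, str]:
        if level == "major":
            return self.major
        if level == "sub":
            return self.sub
        raise ValueError("level must be 'major' or 'sub'")

    def categories(self, level: str) -> tuple[str, ...]:
        if level == "major":
            return MAJOR_CATEGORIES
        return tuple(self.parent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.major),
                "major": list(self.major.values()),
                "sub": [self.sub[n] for n in self.major],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CategoryMap":
        return cls(
            major=dict(zip(df["node_id"], df["major"])),
            sub=dict(zip(df["node_id"], df["sub"])),
        )


@dataclass
class CategoryPairSummary:
    """Signature counts over unordered category pairs.

    ``counts`` is a square DataFrame over the category set of the chosen
    level in which each unordered pair is counted in exactly one cell —
    the one whose row category precedes the column category in the
    canonical category order (within-category edges sit on the diagonal).
    The grand total of ``counts`` therefore equals the number of input
    edges.  ``symmetric()`` mirrors the matrix for display.  ``percent``
    is 100 * count / total; with zero input edges percentages are
    undefined and reported as 0 with ``percent_defined = False``.
    """

    counts: pd.DataFrame
    total: int
    level: str

    @property
    def percent_defined(self) -> bool:
        return self.total > 0

    @property
    def percent(self) -> pd.DataFrame:
        if self.total == 0:
            return self.counts * 0.0
        return 100.0 * self.counts / self.total

    def symmetric(self) -> pd.DataFrame:
        m = self.counts.to_numpy()
        return pd.DataFrame(
            m + m.T - np.diag(np.diag(m)),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def pair_counts(self) -> pd.Series:
        """Nonzero unordered-pair counts keyed by canonical (cat_a, cat_b)."""
        cats = list(self.counts.index)
        out: dict[tuple[str, str], int] = {}
        for ia, a in enumerate(cats):
            for b in cats[ia:]:
                c = int(self.counts.loc[a, b])
                if c:
                    out[(a, b)] = c
        return pd.Series(out, dtype=int)


def categorize_edges(
    edges: Iterable[tuple[str, str]],
    cmap: CategoryMap,
    level: str = "major",
) -> CategoryPairSummary:
    """Count signatures per unordered functional-category pair.

    Each edge increments exactly one cell — the canonically ordered pair
    of its endpoints' labels — so counts over all cells conserve the edge
    total.  Raises ``KeyError`` listing all node IDs missing from the map.
    """
    labels = cmap.labels(level)
    cats = list(cmap.categories(level))
    order = {c: i for i, c in enumerate(cats)}
    edges = list(edges)
    missing = sorted(
        {str(n) for e in edges for n in e if n not in labels}
    )
    if missing:
        raise KeyError(f"nodes without a category label: {missing}")
    counts = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for a, b in edges:
        ca, cb = labels[a], labels[b]
        if order[ca] > order[cb]:
            ca, cb = cb, ca
        counts.loc[ca, cb] += 1
    return CategoryPairSummary(counts=counts, total=len(edges), level=level)


def aggregate_to_major(summary: CategoryPairSummary, cmap: CategoryMap) -> CategoryPairSummary:
    """Collapse a subcategory-level summary onto the 5 major categories.

    Exact: each subcategory-pair cell maps to the canonically ordered pair
    of the parents, so totals and cell counts are conserved.
    """
    if summary.level != "sub":
        raise ValueError("can only aggregate a subcategory-level summary")
    cats = list(MAJOR_CATEGORIES)
    order = {c: i for i, c in enumerate(cats)}
    agg = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    sub_cats = list(summary.counts.index)
    mat = summary.counts.to_numpy()
    for ia, a in enumerate(sub_cats):
        for ib, b in enumerate(sub_cats):
            c = int(mat[ia, ib])
            if not c:
                continue
            pa, pb = cmap.parent[a], cmap.parent[b]
            if order[pa] > order[pb]:
                pa, pb = pb, pa
            agg.loc[pa, pb] += c
    return CategoryPairSummary(counts=agg, total=summary.total, level="major")


def top_pairs(summary: CategoryPairSummary, k: int | None = None) -> pd.DataFrame:
    """Category pairs ranked by signature count, descending.

    Ties are broken lexicographically on the (sorted) pair labels so the
    ranking is deterministic.
    """
    if summary.total == 0:
        raise ValueError("cannot rank pairs of an empty summary")
    pairs = summary.pair_counts()
    rows = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    if k is not None:
        rows = rows[:k]
    return pd.DataFrame(
        {
            "category_a": [a for (a, _), _ in rows],
            "category_b": [b for (_, b), _ in rows],
            "count": [c for _, c in rows],
            "percent": [100.0 * c / summary.total for _, c in rows],
        }
    )


def plot_pair_heatmap(summary: CategoryPairSummary, path: str | Path) -> None:
    """Write the category-pair percentage matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if summary.total:
        mat = 100.0 * summary.symmetric() / summary.total
    else:
        mat = summary.counts * 0.0
    im = ax.imshow(mat.to_numpy(), cmap="viridis")
    small = len(mat) <= 12
    ax.set_xticks(range(len(mat)))
    ax.set_yticks(range(len(mat)))
    if small:
        ax.set_xticklabels(mat.columns, rotation=90, fontsize=7)
        ax.set_yticklabels(mat.index, fontsize=7)
    else:
        ax.set_xticklabels([])
        ax.set_yticklabels([])
    fig.colorbar(im, ax=ax, label="% of signatures")
    ax.set_title(f"signature share per {summary.level}-category pair")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
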