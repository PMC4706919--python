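"""Edge-wise statistics for the mixed 2x2 (group x time) design.

One between-subject factor (group: control vs patient) crosses one
within-subject factor (session: acute vs subacute).  For a two-level
within factor the classical mixed-model sums-of-squares decomposition
reduces exactly to three t statistics computed from per-subject session
*means* ``m`` and session *differences* ``d``:

* group main effect      — pooled unpaired t on ``m`` between groups,
  ``F_group = t^2`` on (1, N-2) df, tested against subjects-within-group;
* group x time interaction — pooled unpaired t on ``d`` between groups,
  ``F_interaction = t^2`` on (1, N-2) df;
* time main effect       — overall mean of ``d`` against the pooled
  within-group variance of ``d`` (the time-by-subjects-within-group
  error), ``F_time = t^2`` on (1, N-2) df.

These identities hold for unequal group sizes (24 vs 16 in the emulated
cohort) and are what the implementation computes, vectorized across all
``n(n-1)/2`` edges at once.  Edges with zero variance everywhere are
guarded: statistic 0 with a degenerate flag instead of NaN, and excluded
from downstream thresholding.

Values are analysed on the Fisher-z scale by default (``scale="r"`` for
raw correlations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import FCStack, devectorize_fc, tri_indices, vectorize_fc

__all__ = [
    "EdgeStatMap",
    "mixed_anova_2x2",
    "edgewise_stats",
    "simple_effect_tests",
    "stack_edge_values",
]

ANOVA_EFFECTS = ("interaction", "group", "time")
SIMPLE_EFFECTS = ("group_t_unpaired", "time_t_paired")

_KIND = {
    "interaction": "F_interaction",
    "group": "F_group",
    "time": "F_time",
    "group_t_unpaired": "t_unpaired",
    "time_t_paired": "t_paired",
}


@dataclass
class EdgeStatMap:
    """Per-edge statistic over the lower-triangle edge enumeration.

    ``stat`` is F (>= 0) for ANOVA effects or signed t for simple
    effects; ``sign`` records the effect direction on the analysis scale
    (patient minus control, or subacute minus acute).  ``degenerate``
    flags zero-variance edges whose statistic was guarded to 0.
    """

    stat: np.ndarray
    kind: str
    df1: int
    df2: int
    sign: np.ndarray
    degenerate: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if len(self.stat) != n * (n - 1) // 2:
            raise ValueError(
                f"expected {n * (n - 1) // 2} edge statistics for {n} nodes, "
                f"got {len(self.stat)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.stat)

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) node-index arrays, row-major over i > j."""
        return tri_indices(self.n_nodes, include_diagonal=False)

    def t_equivalent(self) -> np.ndarray:
        """Signed statistic on the t scale (sqrt(F) for 1-df F statistics)."""
        if self.kind.startswith("F"):
            return self.sign * np.sqrt(self.stat)
        return self.stat

    def to_frame(self) -> pd.DataFrame:
        i, j = self.edge_index()
        return pd.DataFrame(
            {
                "node_i": [self.node_ids[k] for k in i],
                "node_j": [self.node_ids[k] for k in j],
                "statistic": self.stat,
                "kind": self.kind,
                "df1": self.df1,
                "df2": self.df2,
                "sign": self.sign,
                "degenerate": self.degenerate,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_matrix(self) -> np.ndarray:
        """Square symmetric rendering of the statistic (diagonal 0)."""
        return devectorize_fc(self.stat, self.n_nodes, include_diagonal=False, diag_fill=0.0)


def _variance_floor(v: np.ndarray) -> np.ndarray:
    """Relative tolerance below which a variance term counts as zero.

    Guards against float residue when values are numerically identical
    (e.g. the mean of three equal numbers differing from them by 1 ulp).
    """
    scale = (v * v).mean(axis=0)
    return 1e-24 * (1.0 + scale)


def _pooled_unpaired_t(v: np.ndarray, g1: np.ndarray, welch: bool = False):
    """Vectorized two-sample t of group1 minus group0 over axis 0.

    Returns (t, denominator-degenerate mask, mean difference).
    ``v`` is (subjects, ...).
    """
    g0 = ~g1
    n0, n1 = int(g0.sum()), int(g1.sum())
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 subjects per group")
    mean0 = v[g0].mean(axis=0)
    mean1 = v[g1].mean(axis=0)
    ss0 = ((v[g0] - mean0) ** 2).sum(axis=0)
    ss1 = ((v[g1] - mean1) ** 2).sum(axis=0)
    if welch:
        se2 = ss0 / (n0 - 1) / n0 + ss1 / (n1 - 1) / n1
    else:
        se2 = (ss0 + ss1) / (n0 + n1 - 2) * (1.0 / n0 + 1.0 / n1)
    bad = se2 <= _variance_floor(v)
    diff = mean1 - mean0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bad, 0.0, diff / np.sqrt(np.where(bad, 1.0, se2)))
    return t, bad, diff


def mixed_anova_2x2(y: np.ndarray, patient: np.ndarray) -> dict[str, dict]:
    """Classical mixed 2x2 ANOVA for every trailing slot of ``y``.

    Parameters
    ----------
    y:
        Array of shape ``(n_subjects, 2, ...)`` — sessions ordered
        (acute, subacute); trailing axes are independent edges.
    patient:
        Boolean per-subject group indicator (True = patient).

    Returns
    -------
    dict keyed by effect (``group``, ``time``, ``interaction``) with
    fields ``F``, ``sign``, ``df`` and ``degenerate``.  Zero-variance
    slots yield F = 0 with the degenerate flag set.
    """
    y = np.asarray(y, dtype=float)
    patient = np.asarray(patient, dtype=bool)
    if y.ndim < 2 or y.shape[1] != 2:
        raise ValueError("y must have shape (n_subjects, 2, ...)")
    if y.shape[0] != len(patient):
        raise ValueError("group indicator length does not match subjects")
    N = y.shape[0]
    if min(int(patient.sum()), int((~patient).sum())) < 2:
        raise ValueError("each group needs at least 2 subjects")

    m = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]

    t_m, bad_m, diff_m = _pooled_unpaired_t(m, patient)
    t_d, bad_d, diff_d = _pooled_unpaired_t(d, patient)

    # time effect: overall mean difference vs pooled within-group variance of d
    g0, g1 = ~patient, patient
    ss0 = ((d[g0] - d[g0].mean(axis=0)) ** 2).sum(axis=0)
    ss1 = ((d[g1] - d[g1].mean(axis=0)) ** 2).sum(axis=0)
    mse = (ss0 + ss1) / (N - 2)
    bad_t = mse <= _variance_floor(d)
    dbar = d.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_time = np.where(bad_t, 0.0, dbar / np.sqrt(np.where(bad_t, 1.0, mse / N)))

    df = (1, N - 2)
    return {
        "group": {"F": t_m**2, "sign": np.sign(diff_m), "df": df, "degenerate": bad_m},
        "interaction": {"F": t_d**2, "sign": np.sign(diff_d), "df": df, "degenerate": bad_d},
        "time": {"F": t_time**2, "sign": np.sign(dbar), "df": df, "degenerate": bad_t},
    }


def stack_edge_values(stack: FCStack, scale: str = "z"):
    """Per-subject-session edge values of an FC stack.

    Returns ``(y, subjects, patient)`` where ``y`` has shape
    ``(n_subjects, 2, n_edges)`` with sessions ordered (acute, subacute)
    and edges in canonical lower-triangle order (diagonal excluded).
    """
    if scale not in ("z", "r"):
        raise ValueError("scale must be 'z' or 'r'")
    subjects = stack.subjects()
    groups = stack.groups()
    n = stack.n_nodes
    n_edges = n * (n - 1) // 2
    y = np.empty((len(subjects), 2, n_edges))
    for si, sid in enumerate(subjects):
        for ti, session in enumerate(("acute", "subacute")):
            vec = vectorize_fc(stack.get(sid, session), include_diagonal=False)
            if scale == "z":
                amax = np.abs(vec).max(initial=0.0)
                if amax >= 1.0:
                    k = int(np.argmax(np.abs(vec) >= 1.0))
                    i, j = tri_indices(n, include_diagonal=False)
                    raise ValueError(
                        f"|r| = 1 on edge ({stack.node_ids[i[k]]}, "
                        f"{stack.node_ids[j[k]]}) of {sid}/{session}; "
                        "cannot Fisher-z transform"
                    )
                vec = np.arctanh(vec)
            y[si, ti] = vec
    patient = np.array([groups[s] == "patient" for s in subjects])
    return y, subjects, patient


def edgewise_stats(
    stack: FCStack,
    effect: str,
    scale: str = "z",
    session: str = "acute",
    group: str = "patient",
    welch: bool = False,
) -> EdgeStatMap:
    """Apply the chosen statistic to every off-diagonal edge of the stack.

    ``effect`` is one of ``interaction | group | time`` (mixed-ANOVA F) or
    ``group_t_unpaired | time_t_paired`` (simple effects; ``session`` /
    ``group`` select the stratum).
    """
    if effect in ANOVA_EFFECTS:
        y, _, patient = stack_edge_values(stack, scale)
        res = mixed_anova_2x2(y, patient)[effect]
        return EdgeStatMap(
            stat=res["F"],
            kind=_KIND[effect],
            df1=res["df"][0],
            df2=res["df"][1],
            sign=res["sign"],
            degenerate=res["degenerate"],
            node_ids=list(stack.node_ids),
        )
    if effect in SIMPLE_EFFECTS:
        return simple_effect_tests(
            stack, effect, scale=scale, session=session, group=group, welch=welch
        )
    raise ValueError(f"unsupported effect {effect!r}")


def simple_effect_tests(
    stack: FCStack,
    which: str,
    scale: str = "z",
    session: str = "acute",
    group: str = "patient",
    welch: bool = False,
) -> EdgeStatMap:
    """Simple-effect t-tests at every edge.

    ``group_t_unpaired`` compares patients minus controls at a fixed
    ``session`` (pooled variance by default, Welch optional);
    ``time_t_paired`` is the paired t of subacute minus acute within one
    ``group``.  Degenerate zero-variance edges yield t = 0 with a flag.
    """
    y, subjects, patient = stack_edge_values(stack, scale)
    sess_idx = {"acute": 0, "subacute": 1}
    if which == "group_t_unpaired":
        v = y[:, sess_idx[session]]
        t, bad, _ = _pooled_unpaired_t(v, patient, welch=welch)
        n0, n1 = int((~patient).sum()), int(patient.sum())
        df2 = n0 + n1 - 2
        return EdgeStatMap(
            stat=t,
            kind=_KIND[which],
            df1=1,
            df2=df2,
            sign=np.sign(t),
            degenerate=bad,
            node_ids=list(stack.node_ids),
        )
    if which == "time_t_paired":
        sel = patient if group == "patient" else ~patient
        if int(sel.sum()) < 2:
            raise ValueError(f"group {group!r} needs at least 2 subjects")
        d = y[sel, 1] - y[sel, 0]
        nS = d.shape[0]
        sd = d.std(axis=0, ddof=1)
        bad = sd * sd <= _variance_floor(d)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(bad, 0.0, d.mean(axis=0) / np.where(bad, 1.0, sd / np.sqrt(nS)))
        return EdgeStatMap(
            stat=t,
            kind=_KIND[which],
            df1=1,
            df2=nS - 1,
            sign=np.sign(t),
            degenerate=bad,
            node_ids=list(stack.node_ids),
        )
    raise ValueError(f"unsupported simple effect {which!r}")
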