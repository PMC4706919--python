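"""Synthetic longitudinal rsfMRI cohorts with known ground truth.

Emulates the data structure of a two-group (24 controls, 16 patients),
two-session (acute / subacute) landmark-connectome study: 358 nodes with
240 time points at TR = 2 s per subject-session, block-community
correlation structure, and an optional *planted* hyperconnectivity effect
on a connected edge set.

Unaffected acquisitions follow a latent-factor model — fast, and
positive semidefinite by construction::

    x_i(t) = a * g(t) + b * f_{block(i)}(t) + c * e_i(t)

with a^2 = between-block correlation, a^2 + b^2 = within-block
correlation and a^2 + b^2 + c^2 = 1, giving closed-form population
correlations.

The planted effect lives in the idiosyncratic-residual space: for each
planted edge (i, j) the residuals e_i, e_j are given correlation
``rho = (tanh(atanh(r0) + effect_delta_z) - r0) / c^2``, so the
population correlation of the edge equals the base value raised by
exactly ``effect_delta_z`` on the Fisher-z scale.  The residual
correlation matrix over the effect-component nodes is completed to a
positive-semidefinite matrix with the prescribed edge entries held
exactly: zero fill-in when the prescribed pattern is already PSD (low
planted-edge degree, moderate rho), the Gaussian tree/Markov completion
(entry = product of rho along the tree path) when the planted set is a
tree, and Dykstra alternating projections otherwise.  Any fill-in leaks
correlation increments onto pairs *within* the effect component only —
never elsewhere in the network.  A required rho >= 1
(increment larger than the residual variance headroom ``c^2 = 1 -
within_block_corr`` allows) or a non-convergent completion raises a
configuration error naming the offending edge.  ``effect_delta_z`` must
be nonnegative, matching the hyperconnectivity direction the design
targets.

Temporal noise is white by default (emulating a prewhitened, fully
preprocessed series); an AR(1) option with unit marginal variance is
available.  All draws are deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .annotation import MAJOR_CATEGORIES, SUBCATEGORY_PARENT, CategoryMap
from .connectome import GROUPS, SESSIONS, NodeTimeSeriesSet

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "VolumeFixture",
    "generate_cohort",
    "generate_volume_fixture",
    "generate_category_map",
    "write_cohort",
]

EFFECT_TYPES = ("group", "time", "interaction", "none")


@dataclass
class SimulationConfig:
    """Cohort dimensions, correlation structure and planted effect.

    Defaults mirror the emulated study: 358 nodes, 240 volumes at
    TR = 2 s, 24 controls vs 16 patients, two sessions.  ``effect_edges``
    may be an explicit list of node-index pairs (must form one connected
    component) or an integer edge count for a randomly grown connected
    set; ``None`` with an active effect type defaults to 20 edges.
    """

    n_nodes: int = 358
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    n_controls: int = 24
    n_patients: int = 16
    n_sessions: int = 2
    n_blocks: int = 8
    within_block_corr: float = 0.6
    between_block_corr: float = 0.1
    noise_model: str = "white"  # "white" | "ar1"
    ar1_phi: float = 0.0
    effect_edges: int | Sequence[tuple[int, int]] | None = None
    effect_delta_z: float = 0.5
    effect_type: str = "group"  # "group" | "time" | "interaction" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"effect_type must be one of {EFFECT_TYPES}")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError("noise_model must be 'white' or 'ar1'")
        if not (0 <= self.ar1_phi < 1):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if not (0.0 <= self.between_block_corr <= self.within_block_corr <= 1.0):
            raise ValueError(
                "need 0 <= between_block_corr <= within_block_corr <= 1"
            )
        if self.n_sessions != 2:
            raise ValueError("the longitudinal design has exactly 2 sessions")
        if min(self.n_controls, self.n_patients) < 1:
            raise ValueError("each group needs at least one subject")
        if self.effect_type != "none" and self.effect_delta_z < 0:
            raise ValueError(
                "effect_delta_z must be nonnegative (planted effects are "
                "hyperconnectivity increments on the Fisher-z scale)"
            )
        if self.n_blocks < 1 or self.n_blocks > self.n_nodes:
            raise ValueError("n_blocks must lie in [1, n_nodes]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("effect_edges"), list):
            d["effect_edges"] = [tuple(e) for e in d["effect_edges"]]
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated time series plus the design table and the planted truth."""

    timeseries: list[NodeTimeSeriesSet]
    design: pd.DataFrame
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None

    def node_ids(self) -> list[str]:
        return self.timeseries[0].node_ids


@dataclass
class VolumeFixture:
    """4D BOLD volume + gray-matter mask + landmark table for one acquisition."""

    bold: nib.Nifti1Image
    gm_mask: nib.Nifti1Image
    landmarks: np.ndarray  # (n_nodes, 3) world mm, RAS
    node_ids: list[str]


def block_labels(n_nodes: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal block assignment of nodes (0-based labels)."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n_nodes, n_blocks + 1).astype(int)))


def _population_base_corr(labels: np.ndarray, within: float, between: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    r = np.where(same, within, between).astype(float)
    np.fill_diagonal(r, 1.0)
    return r


def _grow_connected_edges(n_nodes: int, n_edges: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random path of ``n_edges`` edges over ``n_edges + 1`` distinct nodes.

    A path keeps every planted-edge degree <= 2, which maximises the
    feasible planted increment for the residual-correlation construction.
    """
    if n_edges + 1 > n_nodes:
        raise ValueError(
            f"cannot place {n_edges} connected edges over {n_nodes} nodes"
        )
    nodes = rng.choice(n_nodes, size=n_edges + 1, replace=False)
    return [
        (int(min(a, b)), int(max(a, b))) for a, b in zip(nodes[:-1], nodes[1:])
    ]


def _is_connected(edges: Sequence[tuple[int, int]]) -> bool:
    if not edges:
        return True
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    roots = {find(x) for x in parent}
    return len(roots) == 1


def _required_residual_corr(
    r0: np.ndarray, edges: Sequence[tuple[int, int]], delta_z: float, c2: float
) -> np.ndarray:
    """Residual correlation each planted edge needs for an exact z increment."""
    rho = np.empty(len(edges))
    for k, (i, j) in enumerate(edges):
        base = r0[i, j]
        if np.abs(base) >= 1.0:
            raise ValueError(
                f"effect edge ({i}, {j}) has baseline |r| >= 1; cannot plant an increment"
            )
        target = np.tanh(np.arctanh(base) + delta_z)
        if np.abs(target) >= 1.0:
            raise ValueError(
                f"infeasible correlation target on effect edge ({i}, {j}): |r| >= 1"
            )
        need = target - base
        if need > 0 and c2 <= 0:
            raise ValueError(
                f"effect edge ({i}, {j}): no residual variance left "
                "(within_block_corr = 1) to carry the planted increment"
            )
        rho[k] = need / c2 if c2 > 0 else 0.0
        if rho[k] >= 1.0:
            raise ValueError(
                f"infeasible correlation target on effect edge ({i}, {j}): the "
                f"increment needs residual correlation {rho[k]:.3f} >= 1 "
                f"(headroom c^2 = {c2:.3f}); reduce effect_delta_z or "
                "within_block_corr"
            )
    return rho


def _is_tree(nodes: list[int], edges: Sequence[tuple[int, int]]) -> bool:
    return len(edges) == len(nodes) - 1  # connectivity is validated upstream


def _tree_completion(
    nodes: list[int], edges: Sequence[tuple[int, int]], rho: np.ndarray
) -> np.ndarray:
    """Gaussian-Markov completion over a tree: entry = path product of rho.

    Always a valid correlation matrix for |rho| < 1 (it is the
    correlation of a tree-structured Gauss-Markov field).
    """
    pos = {n: k for k, n in enumerate(nodes)}
    m = len(nodes)
    adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(m)}
    for (i, j), r in zip(edges, rho):
        adj[pos[i]].append((pos[j], float(r)))
        adj[pos[j]].append((pos[i], float(r)))
    E = np.eye(m)
    for src in range(m):
        stack = [(src, 1.0)]
        seen = {src}
        while stack:
            u, prod = stack.pop()
            for v, r in adj[u]:
                if v not in seen:
                    seen.add(v)
                    E[src, v] = prod * r
                    stack.append((v, prod * r))
    return E


def _complete_residual_corr(
    nodes: list[int],
    edges: Sequence[tuple[int, int]],
    rho: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-11,
) -> np.ndarray:
    """PSD completion of the effect-node residual correlation matrix.

    Prescribed: unit diagonal and ``rho`` on planted edges.  Zero
    fill-in is used when the prescribed pattern is already PSD; a tree
    edge set falls back to the exact Markov (path-product) completion;
    anything else runs Dykstra alternating projections (PSD cone vs.
    affine constraints) and raises if no completion is reached.
    """
    pos = {n: k for k, n in enumerate(nodes)}
    m = len(nodes)
    fixed = np.zeros((m, m), dtype=bool)
    np.fill_diagonal(fixed, True)
    vals = np.eye(m)
    for (i, j), r in zip(edges, rho):
        a, b = pos[i], pos[j]
        fixed[a, b] = fixed[b, a] = True
        vals[a, b] = vals[b, a] = r
    start = vals.copy()
    if np.linalg.eigvalsh(start).min() >= 0.0:
        return start  # the zero-fill-in completion is already valid
    if _is_tree(nodes, edges):
        return _tree_completion(nodes, edges, rho)
    E = start
    P = np.zeros_like(E)  # Dykstra correction for the PSD projection
    for _ in range(max_iter):
        Y = E + P
        w, V = np.linalg.eigh(Y)
        X = (V * np.clip(w, 0.0, None)) @ V.T
        P = Y - X
        E_new = X.copy()
        E_new[fixed] = vals[fixed]
        if np.max(np.abs(E_new - E)) < tol and w.min() > -1e-8:
            E = E_new
            break
        E = E_new
    w = np.linalg.eigvalsh(E)
    if w.min() < -1e-6:
        raise ValueError(
            "residual-correlation completion for the planted effect did not "
            "converge to a positive semidefinite matrix; reduce "
            "effect_delta_z or the planted-edge density"
        )
    return E


def _psd_factor(r: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = r for a (near-)PSD symmetric matrix."""
    vals, vecs = np.linalg.eigh(r)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _effect_overlay(config: "SimulationConfig"):
    """(nodes, residual-corr matrix, factor) for the planted effect, or None."""
    edges = resolve_effect_edges(config)
    if not edges:
        return None
    labels = block_labels(config.n_nodes, config.n_blocks)
    r0 = _population_base_corr(
        labels, config.within_block_corr, config.between_block_corr
    )
    c2 = 1.0 - config.within_block_corr
    rho = _required_residual_corr(r0, edges, config.effect_delta_z, c2)
    nodes = sorted({n for e in edges for n in e})
    E = _complete_residual_corr(nodes, edges, rho)
    return nodes, E, _psd_factor(E)


def population_fc(config: SimulationConfig, affected: bool) -> np.ndarray:
    """Population correlation matrix implied by the generator.

    ``affected=True`` gives the matrix of a subject-session carrying the
    planted effect: the exact z-increment on every planted edge; other
    entries equal the base matrix except for any PSD-completion fill-in
    among effect-component nodes.
    """
    labels = block_labels(config.n_nodes, config.n_blocks)
    r0 = _population_base_corr(labels, config.within_block_corr, config.between_block_corr)
    overlay = _effect_overlay(config) if affected and config.effect_type != "none" else None
    if overlay is None:
        return r0
    nodes, E, _ = overlay
    c2 = 1.0 - config.within_block_corr
    out = r0.copy()
    ix = np.ix_(nodes, nodes)
    out[ix] = out[ix] + c2 * (E - np.eye(len(nodes)))
    return out


def resolve_effect_edges(config: SimulationConfig) -> list[tuple[int, int]]:
    """Materialise the planted edge set from the config (deterministic)."""
    if config.effect_type == "none":
        return []
    spec = config.effect_edges
    if spec is None:
        spec = 20
    if isinstance(spec, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 911]).generate_state(1))
        return _grow_connected_edges(config.n_nodes, int(spec), rng)
    edges = [(int(min(a, b)), int(max(a, b))) for a, b in spec]
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate effect edges")
    for a, b in edges:
        if a == b or not (0 <= a < config.n_nodes and 0 <= b < config.n_nodes):
            raise ValueError(f"invalid effect edge ({a}, {b})")
    if not _is_connected(edges):
        raise ValueError("effect_edges must form a single connected component")
    return edges


def _ar1_filter(white: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) series with unit marginal variance from unit white noise rows."""
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[:, 0] = white[:, 0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, white.shape[1]):
        out[:, t] = phi * out[:, t - 1] + c * white[:, t]
    return out


def _affected(effect_type: str, group: str, session: str) -> bool:
    if effect_type == "none":
        return False
    if effect_type == "group":
        return group == "patient"
    if effect_type == "time":
        return session == "subacute"
    return group == "patient" and session == "subacute"  # interaction


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Sample a full synthetic cohort (deterministic given ``config.seed``)."""
    n, T = config.n_nodes, config.n_timepoints
    labels = block_labels(n, config.n_blocks)
    a = np.sqrt(config.between_block_corr)
    b = np.sqrt(config.within_block_corr - config.between_block_corr)
    c = np.sqrt(1.0 - config.within_block_corr)
    edges = resolve_effect_edges(config)
    overlay = _effect_overlay(config)

    node_ids = [f"n{i:03d}" for i in range(n)]
    subjects = [(f"ctrl{i+1:02d}", "control") for i in range(config.n_controls)] + [
        (f"pat{i+1:02d}", "patient") for i in range(config.n_patients)
    ]
    rows = []
    timeseries = []
    root = np.random.SeedSequence(int(config.seed))
    streams = root.spawn(len(subjects) * config.n_sessions)
    k = 0
    for sid, group in subjects:
        for session in SESSIONS[: config.n_sessions]:
            rng = np.random.default_rng(streams[k])
            k += 1
            g = _ar1_filter(rng.standard_normal((1, T)), config.ar1_phi, rng)
            f = _ar1_filter(rng.standard_normal((config.n_blocks, T)), config.ar1_phi, rng)
            eps = _ar1_filter(rng.standard_normal((n, T)), config.ar1_phi, rng)
            if overlay is not None and _affected(config.effect_type, group, session):
                enodes, _, L = overlay
                w = _ar1_filter(
                    rng.standard_normal((len(enodes), T)), config.ar1_phi, rng
                )
                eps[enodes, :] = L @ w
            x = a * g + b * f[labels] + c * eps
            timeseries.append(NodeTimeSeriesSet(x, node_ids, sid, session))
            rows.append({"subject_id": sid, "group": group, "session": session})
    design = pd.DataFrame(rows)
    truth = {
        "block_labels": labels.tolist(),
        "effect_type": config.effect_type,
        "effect_edges": [list(e) for e in edges],
        "effect_edge_ids": [[node_ids[i], node_ids[j]] for i, j in edges],
        "effect_delta_z": config.effect_delta_z if edges else 0.0,
    }
    return SyntheticCohort(timeseries, design, truth, config)


# ---------------------------------------------------------------------------
# volume fixture
# ---------------------------------------------------------------------------

_SPACING = np.array([3.125, 3.125, 3.5])  # mm; matches the emulated acquisition
_STEP = 4  # voxels between landmarks per axis -> >= 12.5 mm separation


def generate_volume_fixture(
    config: SimulationConfig,
    ts: NodeTimeSeriesSet,
    radius_mm: float = 5.0,
    grid_shape: tuple[int, int, int] | None = None,
) -> VolumeFixture:
    """Embed node time series into a synthetic 4D volume for round-trip tests.

    Landmarks are placed on a lattice with >= 12 mm separation so their
    ``radius_mm`` neighborhoods are disjoint; every gray-matter voxel of a
    node's neighborhood carries an identical copy of that node's series,
    all other voxels carry independent noise.  Extraction therefore
    returns the input series exactly (up to averaging identical copies).
    """
    n = ts.n_nodes
    if grid_shape is None:
        per_axis = int(np.ceil(n ** (1.0 / 3.0)))
        while per_axis**3 < n:
            per_axis += 1
        dim = _STEP * (per_axis - 1) + 5
        grid_shape = (dim, dim, dim)
    shape = tuple(int(d) for d in grid_shape)
    counts = [max((d - 5) // _STEP + 1, 0) for d in shape]
    if int(np.prod(counts)) < n:
        raise ValueError(
            f"grid {shape} too small to place {n} disjoint {radius_mm} mm "
            f"neighborhoods (capacity {int(np.prod(counts))})"
        )
    # voxel-index lattice positions, margin 2 voxels
    sites = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for kk in range(counts[2]):
                sites.append((2 + _STEP * i, 2 + _STEP * j, 2 + _STEP * kk))
                if len(sites) == n:
                    break
            if len(sites) == n:
                break
        if len(sites) == n:
            break
    sites = np.array(sites, dtype=float)

    affine = np.diag([*(_SPACING), 1.0])
    affine[:3, 3] = -_SPACING * np.array(shape) / 2.0  # roughly centered, RAS
    landmarks = sites @ affine[:3, :3].T + affine[:3, 3]

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4077]).generate_state(1))
    T = ts.n_timepoints
    bold = rng.standard_normal((*shape, T))
    mask = np.zeros(shape, dtype=np.uint8)

    # stamp each node's series into its neighborhood
    halfw = np.ceil(radius_mm / _SPACING).astype(int)
    for k in range(n):
        ctr = sites[k].astype(int)
        lo = np.maximum(ctr - halfw, 0)
        hi = np.minimum(ctr + halfw + 1, shape)
        gi, gj, gk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        idx = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
        centers = idx @ affine[:3, :3].T + affine[:3, 3]
        d2 = ((centers - landmarks[k]) ** 2).sum(axis=1)
        sel = idx[d2 <= radius_mm**2]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
        bold[sel[:, 0], sel[:, 1], sel[:, 2], :] = ts.data[k]

    bold_img = nib.Nifti1Image(bold, affine)
    mask_img = nib.Nifti1Image(mask, affine)
    return VolumeFixture(bold_img, mask_img, landmarks, list(ts.node_ids))


# ---------------------------------------------------------------------------
# category map generation
# ---------------------------------------------------------------------------

def generate_category_map(
    n_nodes: int,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
    major_weights: dict[str, float] | None = None,
) -> CategoryMap:
    """Random node labels: major category ~ uniform (or ``major_weights``),
    subcategory uniform within the drawn major category.  Deterministic
    given ``seed``."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]).generate_state(1))
    if major_weights:
        p = np.array([major_weights.get(m, 0.0) for m in MAJOR_CATEGORIES], dtype=float)
        p = p / p.sum()
    else:
        p = np.full(len(MAJOR_CATEGORIES), 1.0 / len(MAJOR_CATEGORIES))
    subs_by_major = {
        m: [s for s, pm in SUBCATEGORY_PARENT.items() if pm == m] for m in MAJOR_CATEGORIES
    }
    major, sub = {}, {}
    for nid in node_ids:
        m = MAJOR_CATEGORIES[rng.choice(len(MAJOR_CATEGORIES), p=p)]
        major[nid] = m
        sub[nid] = subs_by_major[m][rng.integers(len(subs_by_major[m]))]
    return CategoryMap(major=major, sub=sub)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Persist a cohort: per-subject-session TSV series, design TSV, truth JSON."""
    from .connectome import write_timeseries_tsv

    out = Path(outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries_tsv(ts, out / "timeseries" / f"{ts.subject_id}_{ts.session}.tsv")
    cohort.design.to_csv(out / "design.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    if cohort.config is not None:
        cfg = asdict(cohort.config)
        if isinstance(cfg.get("effect_edges"), list):
            cfg["effect_edges"] = [list(e) for e in cfg["effect_edges"]]
        with open(out / "sim_config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
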