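"""Functional-connectivity construction from landmark node time series.

The connectome is represented by one symmetric Pearson-correlation matrix
per subject per scanning session, computed between the BOLD time series
assigned to each cortical landmark node.  Node series can either be
supplied directly (rows = nodes, columns = time points) or extracted from
a 4D volume as the mean over gray-matter voxels within a fixed-radius
spherical neighborhood of each landmark (world-mm geometry, so anisotropic
voxels are handled correctly).

Conventions
-----------
* Landmark coordinates are world mm, RAS orientation; voxel indices are
  0-based.  Neighborhood membership is decided by the Euclidean distance
  of the *voxel center* from the landmark in world mm.
* Vectorized feature order is the lower triangle in row-major order over
  ``i >= j`` (row index >= column index).  For ``n`` nodes that gives
  ``n(n+1)/2`` features with the diagonal and ``n(n-1)/2`` without.
  Statistical testing always excludes the diagonal (self-correlation is
  the constant 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "NodeTimeSeriesSet",
    "FCMatrix",
    "FCStack",
    "extract_node_timeseries",
    "compute_fc",
    "vectorize_fc",
    "devectorize_fc",
    "tri_indices",
    "fisher_z",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_fc_tsv",
    "write_fc_tsv",
]

GROUPS = ("control", "patient")
SESSIONS = ("acute", "subacute")


@dataclass
class NodeTimeSeriesSet:
    """Node-by-time matrix of mean BOLD signals for one subject-session.

    Parameters
    ----------
    data:
        Array of shape ``(n_nodes, n_timepoints)``.
    node_ids:
        Ordered node identifiers; the order must be identical across all
        subject-sessions entering one analysis.
    subject_id, session:
        Design labels for this acquisition.
    """

    data: np.ndarray
    node_ids: list[str]
    subject_id: str
    session: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2D (nodes x time)")
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids but {self.data.shape[0]} series"
            )

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def constant_nodes(self) -> list[str]:
        """IDs of nodes whose series has zero variance."""
        sd = self.data.std(axis=1)
        return [nid for nid, s in zip(self.node_ids, sd) if s == 0.0]


@dataclass
class FCMatrix:
    """Symmetric node-by-node Pearson correlation matrix."""

    values: np.ndarray
    node_ids: list[str]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if len(self.node_ids) != n:
            raise ValueError("node_ids length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("FC matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("FC diagonal must be 1")
        if np.any(np.abs(v) > 1 + atol):
            raise ValueError("FC entries must lie in [-1, 1]")


@dataclass
class FCStack:
    """All subject-session FC matrices of a cohort plus the design table.

    ``design`` has one row per subject-session with columns
    ``subject_id, group, session``; every subject must appear exactly once
    per session and belong to exactly one group.
    """

    matrices: list[FCMatrix]
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_design(self.design)
        keyed = {(m.subject_id, m.session) for m in self.matrices}
        wanted = {
            (r.subject_id, r.session) for r in self.design.itertuples(index=False)
        }
        if keyed != wanted:
            missing = sorted(wanted - keyed)
            extra = sorted(keyed - wanted)
            raise ValueError(
                f"FC stack does not match design (missing {missing}, extra {extra})"
            )
        orders = {tuple(m.node_ids) for m in self.matrices}
        if len(orders) > 1:
            raise ValueError("inconsistent node ordering across FC matrices")

    @property
    def node_ids(self) -> list[str]:
        return self.matrices[0].node_ids

    @property
    def n_nodes(self) -> int:
        return self.matrices[0].n_nodes

    def get(self, subject_id: str, session: str) -> FCMatrix:
        for m in self.matrices:
            if m.subject_id == subject_id and m.session == session:
                return m
        raise KeyError((subject_id, session))

    def subjects(self) -> list[str]:
        """Subject IDs in design order (controls first if so listed)."""
        seen: list[str] = []
        for sid in self.design["subject_id"]:
            if sid not in seen:
                seen.append(sid)
        return seen

    def groups(self) -> pd.Series:
        """subject_id -> group mapping."""
        return self.design.drop_duplicates("subject_id").set_index("subject_id")[
            "group"
        ]


def validate_design(design: pd.DataFrame) -> None:
    required = {"subject_id", "group", "session"}
    if not required.issubset(design.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    bad_group = set(design["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}")
    bad_sess = set(design["session"]) - set(SESSIONS)
    if bad_sess:
        raise ValueError(f"unknown session labels {sorted(bad_sess)}")
    per = design.groupby("subject_id")["session"].apply(list)
    for sid, sessions in per.items():
        if sorted(sessions) != sorted(SESSIONS):
            raise ValueError(
                f"subject {sid} must have exactly one row per session, got {sessions}"
            )
    ngroups = design.groupby("subject_id")["group"].nunique()
    multi = ngroups[ngroups > 1]
    if len(multi):
        raise ValueError(f"subjects in multiple groups: {list(multi.index)}")


# ---------------------------------------------------------------------------
# time-series extraction from volumes
# ---------------------------------------------------------------------------

def extract_node_timeseries(
    volume: nib.spatialimages.SpatialImage | tuple[np.ndarray, np.ndarray],
    landmarks: np.ndarray,
    gm_mask: nib.spatialimages.SpatialImage | np.ndarray,
    radius_mm: float = 5.0,
    node_ids: Sequence[str] | None = None,
    subject_id: str = "",
    session: str = "",
) -> NodeTimeSeriesSet:
    """Mean gray-matter BOLD series in the ``radius_mm`` neighborhood of each landmark.

    Parameters
    ----------
    volume:
        4D NIfTI image (or an ``(array, affine)`` pair); the affine maps
        0-based voxel indices to world mm (RAS).
    landmarks:
        ``(n_nodes, 3)`` world-mm coordinates.
    gm_mask:
        3D binary gray-matter mask on the same grid as ``volume``.
    radius_mm:
        Neighborhood radius; a voxel belongs to a node's neighborhood when
        its center lies within ``radius_mm`` (Euclidean, world mm) of the
        landmark *and* inside the mask.

    Raises
    ------
    ValueError
        If the mask grid is misaligned with the volume, or any node has an
        empty neighborhood (all offending node IDs are listed).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if isinstance(volume, tuple):
        data, affine = volume
        data = np.asarray(data, dtype=float)
    else:
        data = np.asarray(volume.get_fdata(), dtype=float)
        affine = volume.affine
    if data.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, time)")
    if isinstance(gm_mask, nib.spatialimages.SpatialImage):
        if not np.allclose(gm_mask.affine, affine, atol=1e-6):
            raise ValueError("gray-matter mask affine differs from volume affine")
        mask = np.asarray(gm_mask.get_fdata()) > 0
    else:
        mask = np.asarray(gm_mask) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} misaligned with volume grid {data.shape[:3]}"
        )

    landmarks = np.atleast_2d(np.asarray(landmarks, dtype=float))
    n_nodes = landmarks.shape[0]
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    inv = np.linalg.inv(affine)
    # conservative per-axis half-width of the search box, in voxels
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    halfw = np.ceil(radius_mm / spacing).astype(int) + 1

    series = np.empty((n_nodes, data.shape[3]))
    empty: list[str] = []
    for k, lm in enumerate(landmarks):
        ijk = (inv @ np.append(lm, 1.0))[:3]
        lo = np.maximum(np.round(ijk).astype(int) - halfw, 0)
        hi = np.minimum(np.round(ijk).astype(int) + halfw + 1, mask.shape)
        if np.any(lo >= hi):
            empty.append(node_ids[k])
            continue
        gi, gj, gk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        idx = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
        centers = idx @ affine[:3, :3].T + affine[:3, 3]
        within = np.einsum("ij,ij->i", centers - lm, centers - lm) <= radius_mm**2
        idx = idx[within]
        sel = idx[mask[idx[:, 0], idx[:, 1], idx[:, 2]]]
        if len(sel) == 0:
            empty.append(node_ids[k])
            continue
        series[k] = data[sel[:, 0], sel[:, 1], sel[:, 2], :].mean(axis=0)
    if empty:
        raise ValueError(
            f"empty gray-matter neighborhood (radius {radius_mm} mm) for nodes: {empty}"
        )
    return NodeTimeSeriesSet(series, list(node_ids), subject_id, session)


# ---------------------------------------------------------------------------
# FC computation and vectorization
# ---------------------------------------------------------------------------

def compute_fc(ts: NodeTimeSeriesSet) -> FCMatrix:
    """Pearson correlation between every pair of node time series.

    The result is symmetric with unit diagonal; values are clipped to
    [-1, 1] to absorb floating-point overshoot.
    """
    if ts.n_timepoints < 3:
        raise ValueError(
            f"need at least 3 time points for a correlation, got {ts.n_timepoints}"
        )
    const = ts.constant_nodes()
    if const:
        raise ValueError(f"constant (zero-variance) node series: {const}")
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, list(ts.node_ids), ts.subject_id, ts.session)


def tri_indices(n: int, include_diagonal: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Canonical lower-triangle index pair arrays, row-major over ``i >= j``."""
    k = 0 if include_diagonal else -1
    return np.tril_indices(n, k=k)


def vectorize_fc(fc: FCMatrix | np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Lower-triangle feature vector of a symmetric matrix.

    Length is ``n(n+1)/2`` with the diagonal (the "unique features" count;
    64261 for 358 nodes) and ``n(n-1)/2`` without.  ``devectorize_fc``
    inverts the mapping.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    i, j = tri_indices(values.shape[0], include_diagonal)
    return values[i, j]


def devectorize_fc(
    vec: np.ndarray, n: int, include_diagonal: bool = True, diag_fill: float = 1.0
) -> np.ndarray:
    """Rebuild the full symmetric matrix from its lower-triangle vector."""
    vec = np.asarray(vec)
    i, j = tri_indices(n, include_diagonal)
    if vec.shape[-1] != len(i):
        raise ValueError(f"expected {len(i)} entries for n={n}, got {vec.shape[-1]}")
    out = np.zeros(vec.shape[:-1] + (n, n), dtype=vec.dtype)
    out[..., i, j] = vec
    out[..., j, i] = vec
    if not include_diagonal:
        ii = np.arange(n)
        out[..., ii, ii] = diag_fill
    return out


def fisher_z(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Fisher variance-stabilizing transform ``z = atanh(r)``.

    Off-diagonal entries with ``|r| = 1`` are degenerate (infinite z) and
    raise; the diagonal is mapped to 0 and never enters statistics.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    off = ~np.eye(values.shape[0], dtype=bool)
    bad = off & (np.abs(values) >= 1.0)
    if np.any(bad):
        i, j = np.nonzero(bad)
        raise ValueError(
            f"degenerate edge(s) with |r| = 1 cannot be z-transformed: "
            f"{list(zip(i[:5].tolist(), j[:5].tolist()))}"
        )
    z = np.zeros_like(values)
    z[off] = np.arctanh(values[off])
    return z


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: NodeTimeSeriesSet, path: str | Path) -> None:
    """Rows = time points, columns = node IDs."""
    pd.DataFrame(ts.data.T, columns=ts.node_ids).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(
    path: str | Path, subject_id: str = "", session: str = ""
) -> NodeTimeSeriesSet:
    df = pd.read_csv(path, sep="\t")
    return NodeTimeSeriesSet(df.to_numpy().T, list(df.columns), subject_id, session)


def write_fc_tsv(fc: FCMatrix, path: str | Path) -> None:
    """Full symmetric matrix with node IDs as header and index."""
    pd.DataFrame(fc.values, index=fc.node_ids, columns=fc.node_ids).to_csv(
        path, sep="\t"
    )


def read_fc_tsv(path: str | Path, subject_id: str = "", session: str = "") -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(df.to_numpy(), [str(c) for c in df.columns], subject_id, session)


def save_fc_stack(stack: FCStack, outdir: str | Path) -> None:
    """Persist a stack as one array file plus a JSON manifest and design TSV."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.stack([m.values for m in stack.matrices])
    np.savez_compressed(out / "fc_stack.npz", matrices=arr)
    manifest = {
        "node_ids": stack.node_ids,
        "entries": [
            {"subject_id": m.subject_id, "session": m.session}
            for m in stack.matrices
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    stack.design.to_csv(out / "design.tsv", sep="\t", index=False)


def load_fc_stack(indir: str | Path) -> FCStack:
    import json

    ind = Path(indir)
    arr = np.load(ind / "fc_stack.npz")["matrices"]
    with open(ind / "manifest.json") as fh:
        manifest = json.load(fh)
    design = pd.read_csv(ind / "design.tsv", sep="\t")
    mats = [
        FCMatrix(arr[k], list(manifest["node_ids"]), e["subject_id"], e["session"])
        for k, e in enumerate(manifest["entries"])
    ]
    return FCStack(mats, design)


def build_fc_stack(
    timeseries: Sequence[NodeTimeSeriesSet], design: pd.DataFrame
) -> FCStack:
    """Compute FC for every subject-session and assemble the cohort stack."""
    return FCStack([compute_fc(ts) for ts in timeseries], design.copy())
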