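"""Functional connectome construction: Pearson correlation matrices and
sparsity-thresholded binary networks.

A subject's connectome is the matrix of Pearson correlations between every
pair of regional time series. Binary undirected networks are derived from
it by *sparsity* (density) thresholding: at sparsity S, the
K = round(S * N(N-1)/2) strongest positive correlations become edges, so
every subject's network has exactly the same number of edges and group
differences cannot be driven by overall correlation level. A family of
networks over a sparsity grid (default 0.05-0.40 in steps of 0.01, 36
values) is nested: the edge set at a lower sparsity is a subset of the
edge set at any higher one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import TimeSeriesMatrix

__all__ = [
    "ConnectivityMatrix",
    "SparsityGrid",
    "BinaryNetwork",
    "correlation_matrix",
    "threshold_by_sparsity",
    "build_network_family",
    "edge_count",
]


class ConnectomeError(ValueError):
    """Raised for degenerate signals or infeasible thresholds."""


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson-r matrix; diagonal stored as 0 and never an edge."""

    subject_id: str
    r: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape[1] != n:
            raise ConnectomeError("correlation matrix must be square")
        if not np.all(np.isfinite(self.r)):
            raise ConnectomeError("correlation matrix contains non-finite values")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ConnectomeError("correlation matrix must be symmetric")
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-12:
            raise ConnectomeError("|r| must be <= 1")
        if not self.region_ids:
            self.region_ids = [str(i + 1) for i in range(n)]
        if len(self.region_ids) != n:
            raise ConnectomeError("region_ids length mismatch")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class SparsityGrid:
    """Inclusive sparsity grid s_min, s_min+step, ..., s_max (36 values at defaults)."""

    s_min: float = 0.05
    s_max: float = 0.40
    step: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.s_min <= self.s_max < 1.0):
            raise ConnectomeError("need 0 < s_min <= s_max < 1")
        if self.s_max > self.s_min and self.step <= 0:
            raise ConnectomeError("step must be positive")
        if self.s_max > self.s_min:
            k = (self.s_max - self.s_min) / self.step
            if abs(k - round(k)) > 1e-8:
                raise ConnectomeError("s_max must lie on the grid s_min + k*step")

    @property
    def values(self) -> np.ndarray:
        if self.s_max == self.s_min:
            return np.array([self.s_min])
        n = int(round((self.s_max - self.s_min) / self.step))
        return np.round(self.s_min + self.step * np.arange(n + 1), 10)

    def __len__(self) -> int:
        return len(self.values)

    def subrange(self, lo: float, hi: float) -> np.ndarray:
        vals = self.values
        mask = (vals >= lo - 1e-9) & (vals <= hi + 1e-9)
        sub = vals[mask]
        if len(sub) == 0 or abs(sub[0] - lo) > 1e-9 or abs(sub[-1] - hi) > 1e-9:
            raise ConnectomeError(f"range [{lo}, {hi}] endpoints not on the grid")
        return sub


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at one sparsity; node set fixed to the region list."""

    subject_id: str
    sparsity: float
    adjacency: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        n = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape[1] != n:
            raise ConnectomeError("adjacency must be square")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ConnectomeError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ConnectomeError("self-loops are not allowed")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ConnectomeError("adjacency must be 0/1")
        if not self.region_ids:
            self.region_ids = [str(i + 1) for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_set(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


def edge_count(sparsity: float, n_nodes: int) -> int:
    """K = round(S * N(N-1)/2), rounding half away from zero."""
    x = sparsity * n_nodes * (n_nodes - 1) / 2.0
    return int(math.floor(x + 0.5))


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional series; diagonal set to 0."""
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if len(dead):
        raise ConnectomeError(
            f"zero-variance signal in region {ts.region_ids[dead[0]]!r} "
            f"of subject {ts.subject_id!r}"
        )
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, r=r, region_ids=list(ts.region_ids))


def _ranked_pairs(cm: ConnectivityMatrix, edge_sign: str):
    """Candidate node pairs sorted by descending strength, ties by ascending (i, j)."""
    if edge_sign not in ("positive", "absolute"):
        raise ConnectomeError(f"edge_sign must be 'positive' or 'absolute', got {edge_sign!r}")
    n = cm.n_regions
    iu, ju = np.triu_indices(n, 1)
    w = cm.r[iu, ju]
    if edge_sign == "absolute":
        w = np.abs(w)
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_by_sparsity(
    cm: ConnectivityMatrix, sparsity: float, edge_sign: str = "positive"
) -> BinaryNetwork:
    """Binarize at one sparsity: the K strongest candidate correlations become edges.

    Candidates are positive correlations by default (``edge_sign='absolute'``
    ranks by magnitude instead). Ties at the K-th value are broken by
    ascending lexicographic (i, j) order, so edge sets are reproducible
    bit-for-bit.
    """
    if not (0.0 < sparsity < 1.0):
        raise ConnectomeError(f"sparsity must be in (0, 1), got {sparsity}")
    n = cm.n_regions
    k = edge_count(sparsity, n)
    iu, ju = _ranked_pairs(cm, edge_sign)
    if k > len(iu):
        s_max = len(iu) / (n * (n - 1) / 2.0)
        raise ConnectomeError(
            f"only {len(iu)} candidate edges available for K={k}; "
            f"maximum achievable sparsity is {s_max:.4f}"
        )
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryNetwork(
        subject_id=cm.subject_id,
        sparsity=float(sparsity),
        adjacency=adj,
        region_ids=list(cm.region_ids),
    )


def build_network_family(
    cm: ConnectivityMatrix, grid: SparsityGrid = SparsityGrid(), edge_sign: str = "positive"
) -> list:
    """One BinaryNetwork per grid value; nested in S by construction (prefix of one ranking)."""
    n = cm.n_regions
    iu, ju = _ranked_pairs(cm, edge_sign)
    family = []
    for s in grid.values:
        k = edge_count(float(s), n)
        if k > len(iu):
            s_max = len(iu) / (n * (n - 1) / 2.0)
            raise ConnectomeError(
                f"only {len(iu)} candidate edges available for K={k} at S={s}; "
                f"maximum achievable sparsity is {s_max:.4f}"
            )
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu[:k], ju[:k]] = 1
        adj |= adj.T
        family.append(
            BinaryNetwork(
                subject_id=cm.subject_id,
                sparsity=float(s),
                adjacency=adj,
                region_ids=list(cm.region_ids),
            )
        )
    return family
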