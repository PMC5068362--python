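"""Moran's eigenvector map (MEM) spatial predictors and Moran's I tests.

Site coordinates are turned into a connectivity graph by linking every pair
closer than the longest edge of the Euclidean minimum spanning tree (which
guarantees a connected graph).  Eigenvectors of the doubly centred
connectivity matrix form an orthogonal basis of spatial patterns ordered by
their Moran's I; the eigenvector of the largest positive eigenvalue is the
default spatial predictor, representing a landscape-wide trend of positive
autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """Symmetric binary (or distance-decay weighted) site adjacency."""

    ids: list[str]
    W: np.ndarray
    threshold: float
    mst_edges: list[tuple[int, int]]
    style: str = "binary"  # "binary" | "decay"

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class MEMBasis:
    """Eigenvectors/eigenvalues of the centred connectivity matrix."""

    ids: list[str]
    eigenvectors: np.ndarray  # sites x k, descending eigenvalue order
    eigenvalues: np.ndarray
    selected: int = 0

    def predictor(self, k: int | None = None) -> pd.Series:
        k = self.selected if k is None else k
        return pd.Series(self.eigenvectors[:, k], index=self.ids, name=f"MEM{k + 1}")

    def predictors(self, k: int) -> pd.DataFrame:
        """The first k eigenvectors as columns MEM1..MEMk."""
        return pd.DataFrame(
            self.eigenvectors[:, :k], index=self.ids,
            columns=[f"MEM{i + 1}" for i in range(k)],
        )

    def to_csv(self, path) -> None:
        df = self.predictors(self.eigenvectors.shape[1])
        df.index.name = "site_id"
        df.to_csv(path)


def build_connectivity(
    coords: pd.DataFrame, style: str = "binary"
) -> ConnectivityMatrix:
    """Threshold/MST connectivity from site coordinates (columns x, y).

    The threshold is the longest edge of the minimum spanning tree, so every
    MST edge is linked and the graph is connected by construction.  With
    ``style="decay"`` linked pairs get weight 1 - (d/threshold)^2 instead
    of 1.  Projected planar coordinates are assumed; columns named
    lon/lat are accepted but treated as planar, with a logged warning.
    """
    cols = {c.lower(): c for c in coords.columns}
    for lon, lat in (("lon", "lat"), ("longitude", "latitude")):
        if lon in cols and lat in cols:
            logger.warning(
                "coordinates look geographic (%s/%s); distances are computed "
                "on a flat plane in degree units", cols[lon], cols[lat])
            coords = coords.rename(columns={cols[lon]: "x", cols[lat]: "y"})
            break
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = xy.shape[0]
    if n < 3:
        raise InputError("need at least 3 sites to build spatial predictors")
    d = squareform(pdist(xy))
    off = d[~np.eye(n, dtype=bool)]
    if np.any(off == 0):
        raise InputError("duplicate site coordinates")

    mst = minimum_spanning_tree(d).toarray()
    edges = [(i, j) for i, j in zip(*np.nonzero(mst))]
    threshold = float(mst.max())
    linked = (d > 0) & (d <= threshold)
    if style == "binary":
        W = linked.astype(float)
    elif style == "decay":
        W = np.where(linked, 1.0 - (d / threshold) ** 2, 0.0)
        # decay weight vanishes exactly at the threshold; keep MST edges linked
        W[W == 0] = 0.0
        for i, j in edges:
            W[i, j] = W[j, i] = max(W[i, j], 1e-8)
    else:
        raise InputError(f"unknown connectivity style {style!r}")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(ids=list(coords.index), W=W, threshold=threshold,
                              mst_edges=edges, style=style)


def mem_basis(conn: ConnectivityMatrix) -> MEMBasis:
    """Eigen-decomposition of (I - 11'/n) W (I - 11'/n).

    Eigenvectors are sorted by descending eigenvalue; each sums to zero
    (centring identity) and they are mutually orthogonal.  Sign convention:
    largest-magnitude entry positive.  The selected predictor is the
    eigenvector of the largest positive eigenvalue.
    """
    n = conn.n
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    C = H @ conn.W @ H
    C = (C + C.T) / 2.0
    # the constant vector is a trivial eigenvector (C @ 1 = 0); restrict the
    # decomposition to its orthogonal complement so every returned
    # eigenvector sums to zero exactly
    Q = np.linalg.qr(H[:, : n - 1])[0]
    eigvals, eigvecs = np.linalg.eigh(Q.T @ C @ Q)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = Q @ eigvecs[:, order]
    if eigvals[0] <= 1e-10:
        raise InputError("no positive eigenvalue: no positive spatial structure")
    for k in range(n - 1):
        v = eigvecs[:, k]
        i = int(np.argmax(np.round(np.abs(v), 12)))
        if v[i] < 0:
            eigvecs[:, k] = -v
    return MEMBasis(ids=list(conn.ids), eigenvectors=eigvecs,
                    eigenvalues=eigvals, selected=0)


def moran_i(
    values: "pd.Series | np.ndarray",
    conn: ConnectivityMatrix,
    nperm: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Moran's I with a permutation test (two-sided by default).

    I = (n / S0) * z'Wz / z'z with z the centred values and S0 the sum of
    all weights.  The p-value is (#{permuted |I| >= observed |I|} + 1) /
    (nperm + 1) with values permuted across sites; with
    ``alternative="greater"`` the comparison is one-sided on I itself
    (positive autocorrelation).
    """
    if alternative not in ("two-sided", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    z = np.asarray(values, dtype=float)
    if z.shape[0] != conn.n:
        raise InputError("value vector length does not match number of sites")
    if nperm < 99:
        raise InputError("nperm must be at least 99")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise UndefinedStatisticError("Moran's I undefined for zero-variance values")
    W = conn.W
    s0 = W.sum()
    scale = conn.n / s0

    def stat(v: np.ndarray) -> float:
        return scale * float(v @ W @ v) / float(v @ v)

    obs = stat(z)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = stat(rng.permutation(z))
        if alternative == "greater":
            hits += perm >= obs
        else:
            hits += abs(perm) >= abs(obs)
    p = (hits + 1) / (nperm + 1)
    return obs, float(p)
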