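"""Signed co-expression network inference: mutual information + CLR.

Pairwise mutual information is estimated from a joint histogram under
equal-frequency (quantile) marginal binning, then background-corrected with
the context likelihood of relatedness (CLR) transform: each MI value is
z-scored against the MI distributions of both genes and the two (clipped)
z-scores combined as ``sqrt(z_i^2 + z_j^2)``.  Edges are the pairs whose
CLR score reaches the network threshold (five by default); each edge is
signed by the Pearson correlation of the two profiles, distinguishing
co-induced from anticorrelated gene pairs.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .containers import SectionSeries


def default_bins(n: int) -> int:
    """Default bin count: min(10, floor(sqrt(n)))."""
    return min(10, int(np.floor(np.sqrt(n))))


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` near-equal-count bins.

    Ties at bin boundaries are broken by stable rank order of the values.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    out = np.empty(n, dtype=np.intp)
    out[order] = (np.arange(n) * bins) // n
    return out


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) of two profiles.

    Marginals are binned by equal-frequency binning with ``bins`` bins
    (default ``min(10, floor(sqrt(n)))``).  Zero-variance input returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if bins is None:
        bins = default_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    terms = p[nz] * np.log(p[nz] / outer[nz])
    # summing in sorted order makes MI(x, y) == MI(y, x) bit-exact
    return float(np.sort(terms).sum())


def mi_matrix(series: SectionSeries, bins: int | None = None) -> pd.DataFrame:
    """All-pairs MI matrix (nats) over the genes of a section series.

    Symmetric and nonnegative with zero diagonal by convention.
    Zero-variance genes have MI 0 to everything.
    """
    X = series.values.to_numpy(dtype=float)
    genes = series.genes
    g, n = X.shape
    if n < 4:
        raise ValueError("need at least 4 sections")
    if bins is None:
        bins = default_bins(n)
    if bins < 2:
        raise ValueError("bins must be >= 2")

    variable = np.ptp(X, axis=1) > 0
    binned = np.zeros((g, n), dtype=np.intp)
    for i in range(g):
        if variable[i]:
            binned[i] = _equal_frequency_bins(X[i], bins)
    onehot = np.zeros((g, n, bins))
    rows = np.repeat(np.arange(g), n)
    cols = np.tile(np.arange(n), g)
    onehot[rows, cols, binned.ravel()] = 1.0

    M = np.zeros((g, g))
    for i in range(g - 1):
        if not variable[i]:
            continue
        rest = onehot[i + 1 :]
        joint = np.einsum("na,mnb->mab", onehot[i], rest) / n
        pa = joint.sum(axis=2)  # marginal of gene i per pair
        pb = joint.sum(axis=1)
        outer = pa[:, :, None] * pb[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(joint > 0, joint * np.log(joint / outer), 0.0)
        mi = term.sum(axis=(1, 2))
        mi[~variable[i + 1 :]] = 0.0
        M[i, i + 1 :] = mi
        M[i + 1 :, i] = mi
    np.fill_diagonal(M, 0.0)
    M[M < 0] = 0.0  # guard tiny negative rounding
    return pd.DataFrame(M, index=pd.Index(genes, name="gene"), columns=genes)


def clr_transform(mi: pd.DataFrame) -> pd.DataFrame:
    """Context-likelihood-of-relatedness z-composite of an MI matrix.

    For gene i, ``z_i(j) = max(0, (MI_ij - mean_i) / sd_i)`` using the mean
    and sd of row i excluding the diagonal (rows with sd 0 contribute 0);
    the symmetric score is ``Z_ij = sqrt(z_i(j)^2 + z_j(i)^2)``.
    """
    M = mi.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError("MI matrix must be symmetric")
    g = M.shape[0]
    if g < 2:
        raise ValueError("need at least 2 genes")
    off = ~np.eye(g, dtype=bool)
    mean = np.array([M[i, off[i]].mean() for i in range(g)])
    sd = np.array([M[i, off[i]].std() for i in range(g)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - mean[:, None]) / sd[:, None]
    z[sd == 0] = 0.0
    z = np.clip(z, 0.0, None)
    Z = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(Z, 0.0)
    return pd.DataFrame(Z, index=mi.index, columns=mi.columns)


def edge_sign(series: SectionSeries, i: str, j: str) -> str:
    """Sign ('+' or '-') of the Pearson correlation of two gene profiles.

    A correlation of exactly 0 resolves to '+'.
    """
    x = series.values.loc[i].to_numpy(dtype=float)
    y = series.values.loc[j].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance profile has no defined sign")
    r = np.corrcoef(x, y)[0, 1]
    return "-" if r < 0 else "+"


def build_network(
    clr: pd.DataFrame, series: SectionSeries, threshold: float = 5.0
) -> nx.Graph:
    """Threshold the CLR matrix into a signed undirected network.

    Every gene of the series is a node (isolated nodes kept); an edge
    (i, j) exists iff ``Z_ij >= threshold`` with attributes ``clr`` (the
    score) and ``sign`` ('+'/'-' from the Pearson correlation).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if list(clr.index) != list(series.genes):
        raise ValueError("clr and series must share gene ids")
    genes = list(clr.index)
    Z = clr.to_numpy(dtype=float)
    X = series.values.to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))

    net = nx.Graph()
    net.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(Z >= threshold, k=1))
    for a, b in zip(ii, jj):
        if norms[a] == 0 or norms[b] == 0:
            raise ValueError("zero-variance profile has no defined sign")
        r = centered[a] @ centered[b] / (norms[a] * norms[b])
        net.add_edge(genes[a], genes[b], clr=float(Z[a, b]), sign="-" if r < 0 else "+")
    return net
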