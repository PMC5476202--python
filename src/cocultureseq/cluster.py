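"""Gene selection, uncentered-correlation complete-linkage clustering and
hypergeometric term enrichment.

The distance is 1 - r_u with the uncentered correlation
r_u(x, y) = sum(x*y) / sqrt(sum(x^2) * sum(y^2)) — a cosine-style similarity
that, unlike Pearson, does not subtract means and so keeps the magnitude of
expression in play. Negative correlations give distances above 1 (range
[0, 2]). FPKM matrices are log2(x + 1)-transformed before clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.base import BaseEstimator

from .diffexpr import bh_adjust


def select_cluster_genes(
    fpkm: pd.DataFrame,
    de_vs_glucose: dict[str, pd.DataFrame],
    straw_samples: dict[str, list[str]],
    annotation_filter=None,
    alpha: float = 0.05,
    min_fpkm: float = 1.0,
    display_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Genes for the clustering heatmap.

    Retains genes that (a) change significantly versus the respective
    glucose control in at least one straw condition (BH-adjusted p < 0.05),
    (b) reach FPKM >= 1 in at least one straw condition, and (c) pass the
    annotation filter (e.g. CAZy membership). Columns are the straw
    conditions' replicate means, with any ``display_columns`` (typically the
    glucose control) retained in front.
    """
    sig = pd.Series(False, index=fpkm.index)
    for cond, tbl in de_vs_glucose.items():
        padj = tbl["p_adj"] if "p_adj" in tbl else pd.Series(bh_adjust(tbl["p"].to_numpy()), index=tbl.index)
        sig |= padj.reindex(fpkm.index).fillna(1.0) < alpha
    expressed = pd.Series(False, index=fpkm.index)
    cond_means = {}
    for cond, cols in straw_samples.items():
        mean = fpkm[cols].mean(axis=1)
        cond_means[cond] = mean
        expressed |= mean >= min_fpkm
    keep = sig & expressed
    if annotation_filter is not None:
        keep &= fpkm.index.map(annotation_filter).astype(bool)
    mat = pd.DataFrame(cond_means).loc[keep]
    if display_columns:
        front = pd.DataFrame({c: fpkm.loc[keep, c] for c in display_columns})
        mat = pd.concat([front, mat], axis=1)
    if mat.empty:
        warnings.warn("gene selection produced an empty matrix")
    return mat


def log_transform(matrix: pd.DataFrame | np.ndarray, offset: float = 1.0):
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("log transform requires non-negative values")
    out = np.log2(x + offset)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def uncentered_correlation_distance(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - sum(x*y)/sqrt(sum(x^2)sum(y^2)) between rows."""
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    norms = np.sqrt((x**2).sum(axis=1))
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        name = matrix.index[zero[0]] if isinstance(matrix, pd.DataFrame) else zero[0]
        raise ValueError(f"all-zero row (gene {name!r}) has no defined uncentered correlation")
    r = (x @ x.T) / np.outer(norms, norms)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.maximum((d + d.T) / 2.0, 0.0)  # symmetrise away float noise


class Dendrogram:
    """Complete-linkage merge tree with non-decreasing heights."""

    def __init__(self, linkage_matrix: np.ndarray, labels: list):
        self.linkage = linkage_matrix
        self.labels = list(labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in leaves_list(self.linkage)]

    def cut(self, n_clusters: int | None = None, height: float | None = None) -> pd.Series:
        if (n_clusters is None) == (height is None):
            raise ValueError("specify exactly one of n_clusters or height")
        if n_clusters is not None:
            flat = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        else:
            flat = fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, id_list=self.labels)
        return str(tree).strip()


def complete_linkage(dist: np.ndarray, labels: list | None = None) -> Dendrogram:
    """Agglomerative clustering with max inter-cluster distance."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations to cluster")
    z = linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(z, labels if labels is not None else list(range(n)))


class UncenteredCorrelationLinkage(BaseEstimator):
    """Estimator facade: log-transform, uncentered-correlation distance,
    complete linkage, optional flat cut.

    Attributes after ``fit``: ``distance_`` (square matrix), ``dendrogram_``,
    ``linkage_`` and, when ``n_clusters``/``height`` is set, ``labels_``.
    """

    def __init__(self, n_clusters: int | None = None, height: float | None = None,
                 log_offset: float | None = 1.0):
        self.n_clusters = n_clusters
        self.height = height
        self.log_offset = log_offset

    def fit(self, X, y=None):
        mat = X if self.log_offset is None else log_transform(X, self.log_offset)
        self.distance_ = uncentered_correlation_distance(mat)
        idx = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(self.distance_)))
        self.dendrogram_ = complete_linkage(self.distance_, labels=idx)
        self.linkage_ = self.dendrogram_.linkage
        if self.n_clusters is not None or self.height is not None:
            self.labels_ = self.dendrogram_.cut(self.n_clusters, self.height).to_numpy()
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        if not hasattr(self, "labels_"):
            raise ValueError("set n_clusters or height to obtain flat cluster labels")
        return self.labels_


def hypergeom_enrich(
    gene_list,
    background,
    term_map: dict[str, set | list],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of terms in a gene list.

    For a background of N genes of which K carry a term, and a list of n
    genes of which k carry it, p = P[X >= k] under the hypergeometric draw.
    BH adjustment across terms. Terms with no background gene are skipped
    with a warning.
    """
    bg = set(background)
    lst = set(gene_list)
    if not lst <= bg:
        raise ValueError("gene list must be a subset of the background")
    N, n = len(bg), len(lst)
    rows = []
    for term, members in sorted(term_map.items()):
        members = set(members) & bg
        if not set(term_map[term]):
            warnings.warn(f"term {term!r} has no genes; skipped")
            continue
        K = len(members)
        k = len(members & lst)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, N, K, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"]).set_index("term")
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = []
    return out
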