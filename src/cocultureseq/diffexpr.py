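"""Two-group count-based differential expression with the study's DE filters.

The test is a negative-binomial Wald test on median-of-ratios-normalised
counts. Per-gene dispersion is estimated by the method of moments and then
floored at a binned-median trend across genes (a max rule): with three
replicates per group the raw moment estimate is noisy enough to make a
plain Wald test anticonservative, and flooring at the trend restores
near-nominal type-I error while keeping power for large planted effects.

A gene is called differentially expressed only when all three filters hold:
fold change >= 2 on normalised counts, Benjamini-Hochberg adjusted p < 0.05,
and mean FPKM >= 1 in the test condition (up-calls) or control condition
(down-calls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

DEFAULT_FOLD = 2.0
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FPKM = 1.0
PSEUDO_MEAN = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    s_j = median over genes (nonzero in every sample) of C_gj divided by the
    gene's geometric mean across samples.
    """
    c = counts.to_numpy(dtype=float)
    ok = (c > 0).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a pseudo-reference "
            "(e.g. add a pseudocount) before computing size factors"
        )
    logc = np.log(c[ok])
    geo = np.exp(logc.mean(axis=1))
    s = np.median(c[ok] / geo[:, None], axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def _trend_dispersion(mu: np.ndarray, alpha_g: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Median gene-wise dispersion in log-mean bins, piecewise constant."""
    out = np.full(mu.shape, np.nan)
    ok = mu > 0
    if ok.sum() < 3:
        return np.full(mu.shape, DISPERSION_FLOOR)
    lm = np.log(mu[ok])
    n_bins = max(1, min(n_bins, ok.sum() // 10 or 1))
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
    med = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = idx == i
        if sel.sum() >= 3:
            med[i] = np.median(alpha_g[ok][sel])
    fallback = np.nanmedian(med) if np.isfinite(med).any() else float(np.median(alpha_g[ok]))
    med = np.where(np.isfinite(med), med, fallback)
    vals = np.full(mu.shape, fallback)
    vals[ok] = med[idx]
    return np.maximum(vals, DISPERSION_FLOOR)


def nb_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict | list,
    s: pd.Series | None = None,
    pseudo_mean: float = PSEUDO_MEAN,
    moderate_dispersion: bool = True,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A.

    ``groups`` labels each sample column with one of exactly two labels;
    the log2 fold change is log2((mean_B + eps) / (mean_A + eps)) with the
    groups taken in sorted label order.
    """
    if isinstance(groups, (dict,)):
        groups = pd.Series(groups)
    groups = pd.Series(list(groups), index=counts.columns) if not isinstance(groups, pd.Series) else groups
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga = groups.index[groups == labels[0]]
    gb = groups.index[groups == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 samples per group")
    if s is None:
        s = size_factors(counts)
    q = counts.div(s, axis=1).to_numpy(dtype=float)
    a = q[:, [counts.columns.get_loc(c) for c in ga]]
    b = q[:, [counts.columns.get_loc(c) for c in gb]]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)

    ss = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    var_pooled = ss / (n1 + n2 - 2)
    mu = (m1 * n1 + m2 * n2) / (n1 + n2)
    alpha_g = np.maximum((var_pooled - mu) / np.maximum(mu, 1e-12) ** 2, DISPERSION_FLOOR)
    if moderate_dispersion:
        alpha = np.maximum(alpha_g, _trend_dispersion(mu, alpha_g))
    else:
        alpha = alpha_g

    eps = pseudo_mean
    log2fc = np.log2((m2 + eps) / (m1 + eps))
    ln2 = np.log(2.0)
    var_l = ((m1 + alpha * m1**2) / n1 / (m1 + eps) ** 2
             + (m2 + alpha * m2**2) / n2 / (m2 + eps) ** 2) / ln2**2
    se = np.sqrt(var_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    # degenerate genes: zero variance in both groups and equal means
    degenerate = (se == 0) & (log2fc == 0)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "base_mean_a": m1,
            "base_mean_b": m2,
            "log2fc": log2fc,
            "dispersion": alpha,
            "stat": z,
            "p": p,
        },
        index=counts.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    stats_table: pd.DataFrame,
    fpkm: pd.DataFrame,
    test_samples: list[str],
    control_samples: list[str],
    fold: float = DEFAULT_FOLD,
    alpha: float = DEFAULT_ALPHA,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> pd.DataFrame:
    """Apply the three DE filters and call genes up/down (test vs control).

    ``stats_table`` must contain log2fc (test over control) and p; p_adj is
    (re)computed here with Benjamini-Hochberg.
    """
    out = stats_table.copy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    lfc = out["log2fc"].to_numpy()
    thresh = np.log2(fold)
    fpkm_test = fpkm[test_samples].mean(axis=1).reindex(out.index).to_numpy()
    fpkm_control = fpkm[control_samples].mean(axis=1).reindex(out.index).to_numpy()

    p_pass = out["p_adj"].to_numpy() < alpha
    up_fold = lfc >= thresh
    down_fold = lfc <= -thresh
    up = up_fold & p_pass & (fpkm_test >= min_fpkm)
    down = down_fold & p_pass & (fpkm_control >= min_fpkm)
    out["fold_pass"] = up_fold | down_fold
    out["p_pass"] = p_pass
    out["fpkm_pass"] = np.where(up_fold, fpkm_test >= min_fpkm,
                                np.where(down_fold, fpkm_control >= min_fpkm, False))
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


@dataclass
class DEResult:
    table: pd.DataFrame
    size_factors: pd.Series
    test_samples: list[str]
    control_samples: list[str]

    @property
    def up_genes(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "down"])


class NegativeBinomialWaldDE(BaseEstimator):
    """Two-group NB Wald differential expression with the study's call rule.

    Parameters follow the DE definition: ``fold`` and ``alpha`` thresholds
    on normalised counts and BH-adjusted p, ``min_fpkm`` on the relevant
    condition. ``fit`` expects a gene x sample count matrix plus group
    labels; FPKM (for the >=1 filter) is supplied to :meth:`call`.
    """

    def __init__(self, fold: float = DEFAULT_FOLD, alpha: float = DEFAULT_ALPHA,
                 min_fpkm: float = DEFAULT_MIN_FPKM, moderate_dispersion: bool = True):
        self.fold = fold
        self.alpha = alpha
        self.min_fpkm = min_fpkm
        self.moderate_dispersion = moderate_dispersion

    def fit(self, counts: pd.DataFrame, groups):
        groups = pd.Series(list(groups), index=counts.columns) if not isinstance(groups, pd.Series) else groups
        self.size_factors_ = size_factors(counts)
        self.results_ = nb_test(counts, groups, s=self.size_factors_,
                                moderate_dispersion=self.moderate_dispersion)
        self.results_["p_adj"] = bh_adjust(self.results_["p"].to_numpy())
        self.dispersions_ = self.results_["dispersion"]
        labels = sorted(groups.unique())
        self.group_labels_ = labels
        self.group_samples_ = {lab: list(groups.index[groups == lab]) for lab in labels}
        return self

    def call(self, fpkm: pd.DataFrame, test_label: str | None = None) -> DEResult:
        """Call DE genes; ``test_label`` names the test group (default: group B)."""
        test = test_label or self.group_labels_[1]
        control = [lab for lab in self.group_labels_ if lab != test][0]
        tbl = self.results_.copy()
        if test == self.group_labels_[0]:  # flip sign so log2fc is test-over-control
            tbl["log2fc"] = -tbl["log2fc"]
        tbl = call_de(
            tbl, fpkm,
            test_samples=self.group_samples_[test],
            control_samples=self.group_samples_[control],
            fold=self.fold, alpha=self.alpha, min_fpkm=self.min_fpkm,
        )
        return DEResult(tbl, self.size_factors_, self.group_samples_[test], self.group_samples_[control])
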