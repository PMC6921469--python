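"""Multi-group differential analysis of site intensities and expression.

Samples from several cell types are compared jointly: intensities are
quantile-normalized across samples (assuming most sites behave alike, so
signal-to-noise differences between samples are technical), log2
transformed, and tested row by row with a one-way fixed-effects ANOVA
across cell-type groups.  P-values are adjusted by Benjamini-Hochberg;
rows passing a stringent FDR cut are summarized per cell type as row
Z-scores of group representatives and partitioned by k-means (k = 6 by
default) to expose the major cross-type patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 1e-5
DEFAULT_K = 6
DEFAULT_PSEUDOCOUNT = 1.0


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization.

    Each column's values are replaced by the across-column mean of the
    sorted values at their rank; tied values receive the mean of the
    targets spanned by their rank range.  Afterwards every column has the
    same sorted value vector (exactly so in the absence of ties).
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    vals = m.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensities are not allowed")
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        order = np.argsort(vals[:, j], kind="stable")
        col = np.empty(vals.shape[0])
        col[order] = mean_sorted
        # ties: average the targets over each tied block
        v = vals[:, j]
        uniq, inv = np.unique(v, return_inverse=True)
        sums = np.bincount(inv, weights=col)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


@dataclass
class DifferentialResult:
    """Row-wise test results plus optional cluster labels."""

    table: pd.DataFrame           # F, p, fdr, significant per row
    groups: pd.Series             # column -> group label
    fdr_threshold: float
    z_by_group: Optional[pd.DataFrame] = None
    clusters: Optional[pd.Series] = None

    @property
    def significant_ids(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _group_indices(columns, groups: Mapping[str, str]) -> Tuple[list, np.ndarray]:
    labels = [groups[c] for c in columns]
    uniq = sorted(set(labels))
    idx = np.array([uniq.index(l) for l in labels])
    return uniq, idx


def anova_like_test(
    m: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_transform: bool = True,
) -> DifferentialResult:
    """One-way ANOVA per row across cell-type groups with BH-FDR.

    Values are log2(x + pseudocount) transformed unless ``log_transform``
    is off.  F = [SS_between/(g-1)] / [SS_within/(n-g)] against the
    F(g-1, n-g) reference distribution.  Rows with zero variance overall
    get p = 1; rows with between- but no within-group variance get p = 0.
    """
    uniq, gidx = _group_indices(m.columns, groups)
    g, n = len(uniq), m.shape[1]
    if g < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(gidx, minlength=g)
    if (counts == 0).any():
        raise ValueError("every group needs at least one column")
    if n - g < 1:
        raise ValueError("need at least one group with >= 2 columns")
    x = m.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + pseudocount)
    grand = x.mean(axis=1, keepdims=True)
    gsum = np.zeros((x.shape[0], g))
    for j in range(g):
        gsum[:, j] = x[:, gidx == j].sum(axis=1)
    gmean = gsum / counts
    ss_between = (counts * (gmean - grand) ** 2).sum(axis=1)
    ss_total = ((x - grand) ** 2).sum(axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / (g - 1)) / (ss_within / (n - g))
    p = stats.f.sf(F, g - 1, n - g)
    flat = ss_total <= 1e-12 * np.maximum(np.abs(grand[:, 0]), 1.0) ** 2
    F = np.where(flat, 0.0, F)
    p = np.where(flat, 1.0, p)
    sep = (~flat) & (ss_within <= 1e-12 * ss_between)
    p = np.where(sep, 0.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"F": F, "p": p, "fdr": fdr, "significant": fdr < fdr_threshold},
        index=m.index,
    )
    return DifferentialResult(table=table, groups=pd.Series(dict(groups)),
                              fdr_threshold=fdr_threshold)


def group_representatives(
    m: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_transform: bool = True,
) -> pd.DataFrame:
    """One representative column per group: the within-group mean of
    logged values."""
    x = m.astype(float)
    if log_transform:
        x = np.log2(x + pseudocount)
    uniq = sorted(set(groups[c] for c in m.columns))
    return pd.DataFrame(
        {u: x[[c for c in m.columns if groups[c] == u]].mean(axis=1) for u in uniq}
    )


def zscore_rows(m: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Row Z-scores with sample (ddof=1) standard deviation.

    Constant rows become all-zero and are flagged in the returned mask.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 columns")
    x = m.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z[constant] = 0.0
    return (pd.DataFrame(z, index=m.index, columns=m.columns),
            pd.Series(constant, index=m.index, name="constant"))


def kmeans_cluster(
    z: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
) -> Tuple[pd.Series, float]:
    """k-means (Lloyd, k-means++ seeding, best of ``n_restarts``) on row
    Z-score profiles.

    Labels are 1..k, renumbered by descending cluster size so output is
    stable across runs with the same seed.  Returns (labels, objective).
    """
    if len(z) < k:
        raise ValueError(f"need >= {k} rows for k = {k}, got {len(z)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(z.to_numpy(dtype=float))
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return (pd.Series(relabel[raw], index=z.index, name="cluster"),
            float(km.inertia_))


def differential_pipeline(
    m: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    k: int = DEFAULT_K,
    seed: int = 0,
    quantile: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DifferentialResult:
    """Quantile-normalize, test, z-score group representatives of the
    significant rows and cluster them (when there are at least k)."""
    mn = quantile_normalize(m) if quantile else m
    res = anova_like_test(mn, groups, fdr_threshold, pseudocount)
    sig = res.significant_ids
    if len(sig):
        reps = group_representatives(mn.loc[sig], groups, pseudocount)
        z, _ = zscore_rows(reps)
        res.z_by_group = z
        if len(sig) >= k:
            res.clusters, _ = kmeans_cluster(z, k=k, seed=seed)
        else:
            logger.info("only %d significant rows (< k = %d): clustering skipped",
                        len(sig), k)
    return res
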