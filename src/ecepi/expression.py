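"""Two-variable regression linking promoter histone marks to expression.

The model predicts log expression of a gene from the log-scale base-pair
coverage of H3K4me3 (x1) and H3K27ac (x2) in the 4-kb window around its
TSS, restricted to bases inside called peaks:

    f(x1, x2) = a + b1*x1 + b2*x2

fitted by ordinary least squares over protein-coding autosomal genes,
pooling all samples.  Model quality is read off the Pearson correlation
between predicted and observed expression: predictions from a sample's
ChIP data should correlate highly with matched RNA samples and poorly
with unrelated cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .intervals import IntervalSet, normalize

logger = logging.getLogger(__name__)

DEFAULT_TSS_WINDOW = 4000
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class RegressionModel:
    """Fitted coefficients of the two-mark expression model."""

    a: float    # intercept
    b1: float   # H3K4me3 coefficient
    b2: float   # H3K27ac coefficient

    def predict(self, features: pd.DataFrame) -> pd.Series:
        return self.a + self.b1 * features["x1"] + self.b2 * features["x2"]


def tss_features(
    k4_peaks: IntervalSet,
    k27_peaks: IntervalSet,
    tss: pd.DataFrame,
    window: int = DEFAULT_TSS_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    coverage: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None,
) -> pd.DataFrame:
    """Per-gene log peak coverage of both marks around the TSS.

    The window is symmetric, [pos - window/2, pos + window/2), regardless
    of strand.  In the default peak-base-count mode the signal is the
    number of window bases lying inside a called peak; when ``coverage``
    supplies per-base depth arrays (mark -> chrom -> array) the depth is
    summed over those bases instead.  Returns a frame indexed by gene_id
    with columns x1 (H3K4me3) and x2 (H3K27ac).
    """
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2
    out = pd.DataFrame(index=pd.Index(tss["gene_id"], name="gene_id"),
                       columns=["x1", "x2"], dtype=float)
    for xcol, mark, peaks in (("x1", "H3K4me3", k4_peaks), ("x2", "H3K27ac", k27_peaks)):
        norm = normalize(peaks)
        for chrom, grp in tss.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy(dtype=np.int64)
            lo = np.maximum(pos - half, 0)
            hi = pos + half
            arr = norm.arrays(str(chrom))
            if arr.size == 0:
                vals = np.zeros(len(grp))
            elif coverage is not None:
                depth = coverage.get(mark, {}).get(str(chrom))
                if depth is None:
                    vals = np.zeros(len(grp))
                else:
                    mask = np.zeros(depth.size, dtype=bool)
                    for s, e in arr:
                        mask[s:e] = True
                    masked = np.where(mask, depth, 0.0)
                    cumd = np.concatenate(([0.0], np.cumsum(masked)))
                    vals = cumd[np.minimum(hi, depth.size)] - cumd[np.minimum(lo, depth.size)]
            else:
                starts, ends = arr[:, 0], arr[:, 1]
                widths = ends - starts
                cum = np.concatenate(([0], np.cumsum(widths)))

                def F(x):
                    k = np.searchsorted(starts, x, side="right") - 1
                    kk = np.maximum(k, 0)
                    full = cum[kk]
                    part = np.clip(x - starts[kk], 0, widths[kk])
                    return np.where(k >= 0, full + part, 0)

                vals = F(hi) - F(lo)
            out.loc[grp["gene_id"].to_numpy(), xcol] = np.log(pseudocount + vals)
    return out


def fit_model(features: pd.DataFrame, y: pd.Series) -> RegressionModel:
    """OLS fit of log expression on the two mark features.

    ``features`` and ``y`` are aligned on their gene index; the caller is
    expected to have restricted genes to the protein-coding autosomal set
    and to pass ``y = log(TPM + pseudocount)``.  Samples are pooled by
    concatenating their (features, y) pairs before calling.
    """
    common = features.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with features and expression")
    X = np.column_stack([
        np.ones(len(common)),
        features.loc[common, "x1"].to_numpy(dtype=float),
        features.loc[common, "x2"].to_numpy(dtype=float),
    ])
    yy = y.loc[common].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    if rank < 3:
        raise ValueError(
            "rank-deficient design: mark features are collinear or constant "
            "(check the pseudocount and that both marks have peaks)"
        )
    return RegressionModel(a=float(coef[0]), b1=float(coef[1]), b2=float(coef[2]))


def pooled_fit(
    features_by_sample: Mapping[str, pd.DataFrame],
    log_expr_by_sample: Mapping[str, pd.Series],
) -> RegressionModel:
    """Fit one model on the concatenation of all matched sample pairs."""
    feats, ys = [], []
    for sample, f in features_by_sample.items():
        if sample not in log_expr_by_sample:
            continue
        y = log_expr_by_sample[sample]
        common = f.index.intersection(y.index)
        g = f.loc[common].copy()
        g.index = [f"{sample}:{i}" for i in common]
        feats.append(g)
        yy = y.loc[common].copy()
        yy.index = g.index
        ys.append(yy)
    if not feats:
        raise ValueError("no sample is present in both feature and expression maps")
    return fit_model(pd.concat(feats), pd.concat(ys))


def predict_correlate(
    model: RegressionModel,
    features_by_chip: Mapping[str, pd.DataFrame],
    log_expr: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of predicted vs observed expression.

    Rows are ChIP samples (predictions from their mark features), columns
    are RNA samples (observed log expression).  Correlations are over the
    shared gene universe; a constant observed or predicted vector yields a
    missing entry.
    """
    out = pd.DataFrame(index=list(features_by_chip), columns=log_expr.columns,
                       dtype=float)
    for chip, f in features_by_chip.items():
        common = f.index.intersection(log_expr.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 shared genes for ChIP sample {chip!r}")
        pred = model.predict(f.loc[common]).to_numpy(dtype=float)
        for rna in log_expr.columns:
            obs = log_expr.loc[common, rna].to_numpy(dtype=float)
            if np.std(pred) == 0 or np.std(obs) == 0:
                out.loc[chip, rna] = np.nan
                logger.info("degenerate correlation for %s vs %s", chip, rna)
            else:
                out.loc[chip, rna] = float(np.corrcoef(pred, obs)[0, 1])
    return out


def log_tpm(expr: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Natural-log TPM with a pseudocount (the model's response scale)."""
    if (expr < 0).any().any():
        raise ValueError("TPM values must be non-negative")
    return np.log(expr + pseudocount)
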