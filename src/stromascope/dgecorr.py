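"""Differential expression and stromal-score correlation screens.

The differential screen contrasts one molecular subgroup against the
pooled amalgamation of the remaining subgroups with Welch's two-sample
t-test on log2 expression (log2 fold-change = difference of group means).
The correlation screen computes, per gene, the Pearson correlation with a
per-sample stromal score and its two-sided t-distribution p-value.
Both are estimator-shaped; ``screen`` combines them into the per-gene
result table the associate classifier consumes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix
from .scoring import _frame_samples_by_genes


def welch_t(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t-test between matched columns of a and b.

    ``a``, ``b``: observations x genes arrays. Returns (t, df, p); genes
    with zero variance in both groups get t = 0, p = 1 (no evidence under
    a degenerate variance estimate), per the screen's stated convention.
    """
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    se2_safe = np.where(degenerate, 1.0, se2)
    t = (m1 - m2) / np.sqrt(se2_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = se2_safe ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                              + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    df = np.where(degenerate, n1 + n2 - 2.0, df)
    return t, df, p


def pearson_with_p(values: np.ndarray, y: np.ndarray):
    """Pearson r of each row of ``values`` (genes x samples) with ``y``,
    plus two-sided t-distribution p-values. Constant rows give r = NaN."""
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    xc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("score vector is constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.where(sx == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = np.where(np.isnan(r), np.nan,
                 np.where(np.abs(r) >= 1.0, 0.0,
                          2.0 * stats.t.sf(np.abs(t), n - 2)))
    return r, p


class DifferentialExpressionScreen(BaseEstimator):
    """One-vs-pooled-rest differential expression per gene.

    ``fit(X, y)`` takes samples x genes expression and per-sample subgroup
    labels; ``results_`` holds ``log2fc`` (target mean minus pooled-rest
    mean), ``p_dge`` (Welch, two-sided, unadjusted by default) and
    ``direction``. Benjamini-Hochberg adjustment is available via
    ``adjust=True`` and adds a ``p_dge_adj`` column.
    """

    def __init__(self, target: str, adjust: bool = False):
        self.target = target
        self.adjust = adjust

    def fit(self, X, y):
        X = _frame_samples_by_genes(X)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != X.shape[0]:
            raise ValueError("labels and samples are misaligned")
        mask = y == self.target
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(
                f"need >=2 samples in target {self.target!r} and in the "
                f"pooled rest (got {int(mask.sum())} vs {int((~mask).sum())})")
        a = X.to_numpy(dtype=float)[mask]
        b = X.to_numpy(dtype=float)[~mask]
        t, df, p = welch_t(a, b)
        log2fc = a.mean(axis=0) - b.mean(axis=0)
        res = pd.DataFrame({
            "log2fc": log2fc,
            "t": t,
            "p_dge": p,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }, index=pd.Index(X.columns, name="gene"))
        if self.adjust:
            res["p_dge_adj"] = multipletests(res["p_dge"], method="fdr_bh")[1]
        self.results_ = res
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self


class StromaCorrelation(BaseEstimator):
    """Per-gene Pearson correlation with a per-sample stromal score.

    ``fit(X, y)``: samples x genes expression and an aligned score vector.
    ``results_`` holds ``r_stroma``, ``p_corr`` and ``defined`` (False for
    constant genes, whose correlation is undefined and which are never
    classified downstream).
    """

    def fit(self, X, y):
        X = _frame_samples_by_genes(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("scores and samples are misaligned")
        r, p = pearson_with_p(X.to_numpy(dtype=float).T, y)
        self.results_ = pd.DataFrame({
            "r_stroma": r,
            "p_corr": p,
            "defined": ~np.isnan(r),
        }, index=pd.Index(X.columns, name="gene"))
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self


# ---------------------------------------------------------------------------
# functional wrappers (genes x samples orientation, label alignment)


def _check_alignment(mat_samples, other, what: str):
    missing = [s for s in mat_samples if s not in set(other)]
    extra = [s for s in other if s not in set(mat_samples)]
    if missing or extra:
        raise ValueError(
            f"{what} do not match matrix samples "
            f"(missing: {missing[:5]}, unmatched: {extra[:5]})")


def dge(mat: ExpressionMatrix, ann: pd.DataFrame,
        target_subgroup: str, adjust: bool = False) -> pd.DataFrame:
    """Welch DGE of ``target_subgroup`` vs the pooled remaining subgroups."""
    if "subgroup" not in ann.columns:
        raise ValueError("annotation lacks a 'subgroup' column")
    _check_alignment(mat.samples, ann.index, "annotated samples")
    labels = ann.loc[mat.samples, "subgroup"].to_numpy(dtype=object)
    est = DifferentialExpressionScreen(target_subgroup, adjust=adjust)
    est.fit(mat.values.T, labels)
    return est.results_


def stroma_correlation(mat: ExpressionMatrix,
                       scores: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation with the stromal score, label-aligned."""
    _check_alignment(mat.samples, scores.index, "score samples")
    y = scores.loc[mat.samples].to_numpy(dtype=float)
    est = StromaCorrelation()
    est.fit(mat.values.T, y)
    return est.results_


def screen(mat: ExpressionMatrix, ann: pd.DataFrame, scores: pd.Series,
           target_subgroup: str, subgroup_filter: Sequence[str] | None = None,
           adjust: bool = False) -> pd.DataFrame:
    """Combined per-gene screen: DGE vs pooled rest + stromal correlation.

    ``subgroup_filter`` restricts the correlation (not the DGE contrast) to
    the named subgroups, for subgroup-specific correlation profiles; by
    default the correlation uses the full cohort.
    """
    d = dge(mat, ann, target_subgroup, adjust=adjust)
    if subgroup_filter is not None:
        keep = ann.loc[mat.samples, "subgroup"].isin(subgroup_filter)
        sub = ExpressionMatrix(mat.values.loc[:, keep.to_numpy()],
                               mat.scale_tag)
        c = stroma_correlation(sub, scores.loc[sub.samples])
    else:
        c = stroma_correlation(mat, scores)
    return d.join(c)
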