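"""Per-cell stroma activity and developmental potential.

Cells are profiled by the number of stroma-associate ligands and receptors
they detectably express ("expressed" = normalised expression > 0), classed
as stroma-active (count > active_min), stroma-inactive (count <
inactive_max) or intermediate — both inequalities strict, so with the
default cutoffs 5 and 2 the counts 2..5 are intermediate. Markers of
active vs inactive cells come from a two-sided Wilcoxon rank-sum test with
Benjamini-Hochberg adjustment. Developmental potential is a simplified
gene-counts score: genes most correlated with the per-cell detected-gene
count form a signature whose mean expression is rank-rescaled to [0, 1]
(1 = least differentiated). The expression-similarity smoothing of the
full published potential estimator is deliberately omitted; the score is
validated against synthetic activity gradients only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix
from .scoring import _frame_samples_by_genes

ACTIVE, INACTIVE, INTERMEDIATE = "active", "inactive", "intermediate"


class CellActivityProfiler(BaseEstimator, TransformerMixin):
    """Count expressed stroma-associates per cell and classify the state.

    Parameters
    ----------
    associates
        Associate table (index = gene, with a ``role`` column) or a plain
        gene list (then every gene counts toward ``n_total`` only).
    active_min, inactive_max
        Strict count cutoffs: n > active_min -> active, n < inactive_max ->
        inactive, otherwise intermediate.
    count_on
        Which count drives the state: ``"total"`` (default), ``"ligand"``
        or ``"receptor"``.
    """

    def __init__(self, associates, active_min: int = 5, inactive_max: int = 2,
                 count_on: str = "total"):
        self.associates = associates
        self.active_min = active_min
        self.inactive_max = inactive_max
        self.count_on = count_on

    def fit(self, X, y=None):
        X = _frame_samples_by_genes(X)  # cells x genes
        if self.inactive_max > self.active_min:
            raise ValueError("inactive_max must not exceed active_min")
        if self.count_on not in ("total", "ligand", "receptor"):
            raise ValueError(f"unknown count_on {self.count_on!r}")
        if isinstance(self.associates, pd.DataFrame):
            genes = list(self.associates.index)
            roles = (self.associates["role"].to_dict()
                     if "role" in self.associates.columns else {})
        else:
            genes = list(self.associates)
            roles = {}
        present = [g for g in genes if g in X.columns]
        if not present:
            raise ValueError("no associate gene present in the matrix")
        detected = X[present].to_numpy(dtype=float) > 0
        role = np.asarray([roles.get(g, "unknown") for g in present])
        lig = np.isin(role, ("ligand", "both"))
        rec = np.isin(role, ("receptor", "both"))
        counts = pd.DataFrame({
            "n_ligands": detected[:, lig].sum(axis=1),
            "n_receptors": detected[:, rec].sum(axis=1),
            "n_total": detected.sum(axis=1),
        }, index=X.index)
        key = {"total": "n_total", "ligand": "n_ligands",
               "receptor": "n_receptors"}[self.count_on]
        counts["state"] = classify_state(counts[key], self.active_min,
                                         self.inactive_max)
        self.counts_ = counts
        self.genes_used_ = present
        return self

    def transform(self, X):
        check_is_fitted(self)
        return self.counts_


def count_associates(sc_mat: ExpressionMatrix, associates) -> pd.DataFrame:
    """Per-cell expressed-associate counts (ligand, receptor, total)."""
    prof = CellActivityProfiler(associates)
    prof.fit(sc_mat.values.T)
    return prof.counts_


def classify_state(counts: pd.Series, active_min: int = 5,
                   inactive_max: int = 2) -> pd.Series:
    """Strict-inequality state call per cell from an associate count."""
    if inactive_max > active_min:
        raise ValueError("inactive_max must not exceed active_min")
    c = counts.to_numpy()
    state = np.where(c > active_min, ACTIVE,
                     np.where(c < inactive_max, INACTIVE, INTERMEDIATE))
    return pd.Series(state, index=counts.index, name="state")


def find_markers(sc_mat: ExpressionMatrix, states: pd.Series,
                 alpha: float = 0.05, min_frac: float = 0.01) -> pd.DataFrame:
    """Active-vs-inactive marker screen (Wilcoxon rank-sum, BH-adjusted).

    Genes detected in fewer than ``min_frac`` of cells in both states are
    not tested. ``log2fc`` is the difference of state means on the
    log-normalised scale converted to log2 units; markers are upregulated
    genes with adjusted p < alpha.
    """
    states = states.loc[sc_mat.samples]
    act = states == ACTIVE
    inact = states == INACTIVE
    if act.sum() < 3 or inact.sum() < 3:
        raise ValueError("need at least 3 cells in each of the active and "
                         "inactive states")
    vals = sc_mat.values.to_numpy(dtype=float)
    a = vals[:, act.to_numpy()]
    b = vals[:, inact.to_numpy()]
    frac_a = (a > 0).mean(axis=1)
    frac_b = (b > 0).mean(axis=1)
    testable = (frac_a >= min_frac) | (frac_b >= min_frac)
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        return pd.DataFrame(columns=["log2fc", "p", "p_adj", "marker"])
    with np.errstate(invalid="ignore"):
        stat, p = stats.mannwhitneyu(a[idx], b[idx], axis=1,
                                     alternative="two-sided")
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    log2fc = (a[idx].mean(axis=1) - b[idx].mean(axis=1)) / np.log(2)
    res = pd.DataFrame({
        "log2fc": log2fc,
        "p": p,
        "p_adj": p_adj,
        "frac_active": frac_a[idx],
        "frac_inactive": frac_b[idx],
    }, index=pd.Index(np.asarray(sc_mat.genes)[idx], name="gene"))
    res["marker"] = (res["log2fc"] > 0) & (res["p_adj"] < alpha)
    return res


def metastasis_contrast(counts: pd.DataFrame, ann: pd.DataFrame,
                        count_col: str = "n_total") -> dict:
    """Contrast per-cell associate counts by tumour metastasis status.

    Wilcoxon rank-sum over cells grouped by the metastasis flag of their
    tumour, plus per-tumour mean counts (the unit on which an inference
    robust to pseudoreplication would be made).
    """
    need = {"tumour_id", "metastasis"}
    if not need <= set(ann.columns):
        raise ValueError("annotation needs 'tumour_id' and 'metastasis'")
    ann = ann.loc[counts.index]
    met = ann["metastasis"].astype(bool).to_numpy()
    if met.all() or not met.any():
        raise ValueError("both metastatic and non-metastatic tumours required")
    c = counts[count_col].to_numpy(dtype=float)
    a, b = c[met], c[~met]
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    per_tumour = (pd.DataFrame({count_col: c,
                                "tumour_id": ann["tumour_id"].to_numpy(),
                                "metastasis": met})
                  .groupby(["tumour_id", "metastasis"], observed=True)[count_col]
                  .mean().reset_index())
    return {
        "mean_metastatic": float(a.mean()),
        "mean_nonmetastatic": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "per_tumour_means": per_tumour,
    }


class DevelopmentalPotential(BaseEstimator, TransformerMixin):
    """Simplified gene-counts developmental-potential score.

    ``fit_transform(X)`` (cells x genes) computes per-cell detected-gene
    counts, correlates every gene with that count, averages the ``top_k``
    most count-correlated genes into a signature, and returns the per-cell
    rank of that signature rescaled to [0, 1] (ties share the average
    rank; 1 = least differentiated).
    """

    def __init__(self, top_k: int = 200):
        self.top_k = top_k

    def fit(self, X, y=None):
        X = _frame_samples_by_genes(X)  # cells x genes
        if X.shape[0] < 10:
            raise ValueError("need at least 10 cells")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")
        vals = X.to_numpy(dtype=float)
        gene_counts = (vals > 0).sum(axis=1).astype(float)
        if gene_counts.std() == 0:
            raise ValueError("detected-gene count is constant across cells; "
                             "potential undefined")
        gc_c = gene_counts - gene_counts.mean()
        xc = vals - vals.mean(axis=0, keepdims=True)
        sx = np.sqrt((xc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (xc.T @ gc_c) / (sx * np.sqrt((gc_c ** 2).sum()))
        corr = np.where(sx == 0, -np.inf, corr)  # constant genes never chosen
        k = min(self.top_k, int(np.isfinite(corr).sum()))
        top = np.argsort(-corr, kind="stable")[:k]
        self.gene_counts_ = pd.Series(gene_counts, index=X.index,
                                      name="gene_counts")
        self.signature_genes_ = list(np.asarray(X.columns)[top])
        self.correlations_ = pd.Series(corr, index=X.columns,
                                       name="count_correlation")
        sig = vals[:, top].mean(axis=1)
        ranks = stats.rankdata(sig)
        self.potential_ = pd.Series((ranks - 1) / (len(ranks) - 1),
                                    index=X.index, name="potential")
        return self

    def transform(self, X):
        check_is_fitted(self)
        return self.potential_


def dev_potential(sc_mat: ExpressionMatrix, top_k: int = 200) -> pd.Series:
    """Per-cell developmental potential in [0, 1] (1 = least differentiated)."""
    est = DevelopmentalPotential(top_k=top_k)
    est.fit(sc_mat.values.T)
    return est.potential_


def potential_vs_activity(potential: pd.Series,
                          counts: pd.DataFrame,
                          count_col: str = "n_total") -> dict:
    """Pearson correlation of potential with the associate count, plus a
    binned summary for count classes <2, 2-5 and >5."""
    common = potential.index.intersection(counts.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned cells")
    x = counts.loc[common, count_col].to_numpy(dtype=float)
    y = potential.loc[common].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant potential or counts; correlation undefined")
    r, p = stats.pearsonr(x, y)
    bins = pd.cut(x, bins=[-np.inf, 1.5, 5.5, np.inf],
                  labels=["<2", "2-5", ">5"])
    summary = (pd.DataFrame({"bin": bins, "potential": y})
               .groupby("bin", observed=False)["potential"]
               .agg(["count", "mean", "median"]))
    return {"r": float(r), "p_value": float(p), "by_count_bin": summary}
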