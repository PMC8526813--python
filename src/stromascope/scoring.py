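"""Signature-based sample and cell scoring.

Three scorers are provided, all estimator-shaped (fit/transform, sklearn
conventions) with thin functional wrappers that accept the package's
genes x samples :class:`~stromascope.formats.ExpressionMatrix`:

* ssGSEA-style single-sample enrichment: a rank-based running-sum statistic
  computed independently per sample, the scoring core used to derive
  stromal and immune microenvironment scores from bulk expression.
* scaled-average signature score: mean z-scored expression of the signature
  genes minus the mean z-scored expression of all remaining genes.
* module meta-gene: the first principal component of a gene module's
  expression across samples, sign-oriented to the mean module expression.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .formats import ExpressionMatrix, GeneSignature


def _frame_samples_by_genes(X) -> pd.DataFrame:
    """Validate a samples x genes input with gene names as columns."""
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with gene identifiers as "
                        "columns (samples as rows)")
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("X contains non-finite values")
    return X


def _ssgsea_sample(x: np.ndarray, in_set: np.ndarray, alpha: float,
                   names: np.ndarray) -> float:
    """Running-sum enrichment for one sample.

    Genes are walked in descending expression order; expression ties are
    broken by gene label, so the score never depends on the storage order
    of the input (the rank *weights* additionally use average ranks, so
    tied genes carry identical weight). At each position the statistic
    accumulates the weighted in-set CDF minus the unweighted out-of-set
    CDF; the enrichment score is the sum over all positions.
    """
    n = x.size
    order = np.lexsort((names, -x))
    weight = rankdata(x) ** alpha  # average ranks 1..n, higher expr = higher
    in_ord = in_set[order]
    w_ord = weight[order]
    w_in = np.where(in_ord, w_ord, 0.0).cumsum()
    p_in = w_in / w_in[-1]
    p_out = np.cumsum(~in_ord) / (n - int(in_set.sum()))
    return float(np.sum(p_in - p_out))


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Per-sample signature scores, one output column per signature.

    Parameters
    ----------
    signatures
        Sequence of :class:`GeneSignature`.
    method
        ``"ssgsea"`` (rank-based running sum, default) or
        ``"scaled_average"`` (difference of mean z-scores).
    alpha
        Rank-weight exponent for ssGSEA; 0.25 is the convention of the
        purity-scoring tools this reimplements.

    Attributes
    ----------
    feature_names_in_ : ndarray of gene identifiers seen in ``fit``.
    signature_names_ : list of output column names.
    """

    def __init__(self, signatures: Sequence[GeneSignature],
                 method: str = "ssgsea", alpha: float = 0.25):
        self.signatures = signatures
        self.method = method
        self.alpha = alpha

    def fit(self, X, y=None):
        X = _frame_samples_by_genes(X)
        if self.method not in ("ssgsea", "scaled_average"):
            raise ValueError(f"unknown method {self.method!r}")
        genes = set(map(str, X.columns))
        for sig in self.signatures:
            overlap = genes & set(sig.genes)
            if not overlap:
                raise ValueError(f"signature {sig.name!r} shares no genes "
                                 "with the matrix")
            if self.method == "ssgsea" and overlap >= genes:
                raise ValueError(f"signature {sig.name!r} covers every gene; "
                                 "out-of-set walk undefined")
            if self.method == "scaled_average" and overlap >= genes:
                raise ValueError(f"signature {sig.name!r} leaves no "
                                 "non-signature genes")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.signature_names_ = [s.name for s in self.signatures]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _frame_samples_by_genes(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("gene columns differ from those seen in fit")
        vals = X.to_numpy(dtype=float)
        names = np.asarray(X.columns, dtype=str)
        out = {}
        for sig in self.signatures:
            in_set = np.asarray([g in set(sig.genes) for g in X.columns])
            if self.method == "ssgsea":
                out[sig.name] = np.array(
                    [_ssgsea_sample(row, in_set, self.alpha, names)
                     for row in vals])
            else:
                out[sig.name] = _scaled_average(vals.T, in_set)
        return pd.DataFrame(out, index=X.index)


def _scaled_average(values: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """values: genes x samples; z-score each gene across samples (population
    SD; zero-variance genes contribute z = 0), then mean(in) - mean(out)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.zeros_like(values)
    nz = sd[:, 0] > 0
    z[nz] = (values[nz] - mu[nz]) / sd[nz]
    return z[in_set].mean(axis=0) - z[~in_set].mean(axis=0)


class ModuleMetagene(TransformerMixin, BaseEstimator):
    """First-principal-component meta-gene of a gene module.

    ``fit`` learns the PC1 loading over the module genes (genes centred
    across the fitting samples); ``transform`` projects samples onto it.
    The sign is oriented so the meta-gene correlates non-negatively with
    the mean module expression on the fitting data.
    """

    def __init__(self, module_genes: Sequence[str]):
        self.module_genes = module_genes

    def fit(self, X, y=None):
        X = _frame_samples_by_genes(X)
        present = [g for g in self.module_genes if g in X.columns]
        if not present:
            raise ValueError("no module gene present in the matrix")
        sub = X[present].to_numpy(dtype=float)  # samples x module genes
        self.mean_ = sub.mean(axis=0)
        centred = sub - self.mean_
        if not np.any(centred.std(axis=0) > 0):
            raise ValueError("all module genes are constant")
        # PC1 over samples; SVD of the centred samples x genes block
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        loading = vt[0]
        scores = centred @ loading
        mean_expr = sub.mean(axis=1)
        c = np.corrcoef(scores, mean_expr)[0, 1] if scores.std() > 0 else 0.0
        if c < 0:
            loading = -loading
        self.components_ = loading
        self.genes_used_ = list(present)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = _frame_samples_by_genes(X)
        sub = X[self.genes_used_].to_numpy(dtype=float)
        return (sub - self.mean_) @ self.components_


# ---------------------------------------------------------------------------
# functional wrappers over the estimators (genes x samples orientation)


def ssgsea_score(mat: ExpressionMatrix, sig: GeneSignature,
                 alpha: float = 0.25) -> pd.Series:
    """Per-sample ssGSEA enrichment of ``sig`` in ``mat`` (genes x samples)."""
    scorer = SignatureScorer([sig], method="ssgsea", alpha=alpha)
    df = scorer.fit_transform(mat.values.T)
    return df[sig.name].rename(sig.name)


def scaled_average_score(mat: ExpressionMatrix,
                         sig: GeneSignature) -> pd.Series:
    """Mean z-scored signature expression minus mean z-scored rest."""
    scorer = SignatureScorer([sig], method="scaled_average")
    df = scorer.fit_transform(mat.values.T)
    return df[sig.name].rename(sig.name)


def metagene(mat: ExpressionMatrix, module_genes: Sequence[str]) -> pd.Series:
    """PC1 meta-gene value per sample for a gene module."""
    est = ModuleMetagene(module_genes)
    vals = est.fit_transform(mat.values.T)
    return pd.Series(vals, index=mat.samples, name="metagene")


def score_table(mat: ExpressionMatrix, signatures: Sequence[GeneSignature],
                method: str = "ssgsea", alpha: float = 0.25) -> pd.DataFrame:
    """ScoreTable: one row per sample, one column per signature."""
    scorer = SignatureScorer(signatures, method=method, alpha=alpha)
    df = scorer.fit_transform(mat.values.T)
    df.index.name = "sample_id"
    return df
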