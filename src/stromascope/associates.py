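"""Stroma-associate classification.

A *stroma driver* is a receptor/ligand gene positively correlated with the
stromal score (r > r_min, p < alpha) that is either upregulated in the
stroma-enriched subgroup or downregulated in the stroma-suppressed one
(|log2FC| > log2(fc_min), p < alpha, vs the pooled rest). A *stroma
suppressor* is the mirror image (negative correlation; up in the
suppressed subgroup or down in the enriched one). Genes belonging to any
exclusion signature (e.g. the stromal signature panel itself) are removed,
as are genes whose correlation is undefined; a gene qualifying for both
classes is dropped with a warning. All threshold comparisons are strict.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .formats import ExpressionMatrix, GeneSignature, ReceptorLigandTable


class AssociateClassifier(BaseEstimator):
    """Rule-based driver/suppressor classifier over two pooled-rest screens.

    Parameters
    ----------
    rl_table
        Receptor-ligand table; only its genes are classifiable.
    exclude
        Signatures whose genes are removed before classification.
    fc_min
        Linear fold-change cutoff (strict); applied as |log2FC| > log2(fc_min).
    r_min
        Stromal-correlation magnitude cutoff (strict).
    alpha
        Significance level for both the DGE and correlation p-values.

    ``fit(enriched, suppressed)`` takes the two screen tables (per-gene
    ``log2fc``, ``p_dge``, ``r_stroma``, ``p_corr``); ``associates_`` holds
    the classified genes with their evidence and provenance flags.
    """

    def __init__(self, rl_table: ReceptorLigandTable,
                 exclude: Sequence[GeneSignature] = (),
                 fc_min: float = 2.0, r_min: float = 0.2,
                 alpha: float = 0.05):
        self.rl_table = rl_table
        self.exclude = exclude
        self.fc_min = fc_min
        self.r_min = r_min
        self.alpha = alpha

    def fit(self, enriched: pd.DataFrame, suppressed: pd.DataFrame):
        if len(self.rl_table) == 0:
            raise ValueError("receptor-ligand table is empty")
        for thr in (self.fc_min, self.r_min, self.alpha):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        lfc_min = float(np.log2(self.fc_min))
        excluded = set()
        for sig in self.exclude:
            excluded |= set(sig.genes)

        rows = []
        candidates = (self.rl_table.genes & set(enriched.index)
                      & set(suppressed.index)) - excluded
        for gene in sorted(candidates):
            e = enriched.loc[gene]
            s = suppressed.loc[gene]
            r, p_corr = e["r_stroma"], e["p_corr"]
            if not np.isfinite(r):
                continue  # constant gene: correlation undefined
            up_enr = e["log2fc"] > lfc_min and e["p_dge"] < self.alpha
            dn_enr = e["log2fc"] < -lfc_min and e["p_dge"] < self.alpha
            up_sup = s["log2fc"] > lfc_min and s["p_dge"] < self.alpha
            dn_sup = s["log2fc"] < -lfc_min and s["p_dge"] < self.alpha
            corr_pos = r > self.r_min and p_corr < self.alpha
            corr_neg = r < -self.r_min and p_corr < self.alpha
            is_driver = corr_pos and (up_enr or dn_sup)
            is_suppr = corr_neg and (up_sup or dn_enr)
            if is_driver and is_suppr:  # impossible given sign rules, kept
                warnings.warn(f"{gene} qualifies as both driver and "
                              "suppressor; dropped", stacklevel=2)
                continue
            if not (is_driver or is_suppr):
                continue
            rows.append({
                "gene": gene,
                "class": "driver" if is_driver else "suppressor",
                "role": self.rl_table.roles[gene],
                "r_stroma": float(r),
                "p_corr": float(p_corr),
                "log2fc_enriched": float(e["log2fc"]),
                "p_enriched": float(e["p_dge"]),
                "log2fc_suppressed": float(s["log2fc"]),
                "p_suppressed": float(s["p_dge"]),
                "provenance": ("up-in-enriched" if (is_driver and up_enr) else
                               "down-in-suppressed" if is_driver else
                               "up-in-suppressed" if up_sup else
                               "down-in-enriched"),
            })
        cols = ["gene", "class", "role", "r_stroma", "p_corr",
                "log2fc_enriched", "p_enriched", "log2fc_suppressed",
                "p_suppressed", "provenance"]
        self.associates_ = (pd.DataFrame(rows, columns=cols)
                            .set_index("gene"))
        return self


def classify_associates(dge_enriched: pd.DataFrame,
                        dge_suppressed: pd.DataFrame,
                        rl: ReceptorLigandTable,
                        exclude: Sequence[GeneSignature] = (),
                        fc_min: float = 2.0, r_min: float = 0.2,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Classify receptor/ligand genes into stroma drivers and suppressors."""
    clf = AssociateClassifier(rl, exclude=exclude, fc_min=fc_min,
                              r_min=r_min, alpha=alpha)
    clf.fit(dge_enriched, dge_suppressed)
    return clf.associates_


def filter_sc_expressed(genes: Sequence[str], sc_mat: ExpressionMatrix,
                        min_frac: float = 0.01) -> list[str]:
    """Keep genes with nonzero expression in >= min_frac of cells.

    Genes absent from the matrix are dropped. The boundary is inclusive:
    a gene detected in exactly min_frac of cells is kept.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must lie in [0, 1]")
    n_cells = sc_mat.shape[1]
    kept = []
    for g in genes:
        if g not in sc_mat.genes:
            continue
        frac = float((sc_mat.values.loc[g] > 0).sum()) / n_cells
        if frac >= min_frac:
            kept.append(g)
    return kept
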