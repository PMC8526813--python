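"""Readers, writers and containers for the pipeline's external artifacts.

Everything on disk is plain text: tab-delimited matrices and annotation
tables, MatrixMarket triples with ``features.tsv``/``barcodes.tsv``
sidecars, GMT gene-set files, and two-column receptor-ligand pair tables.
Genes are always rows in every on-disk matrix dialect, and gene identifiers
are opaque strings (no alias resolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse as _sparse

BULK_LOG2 = "bulk-log2"
SC_LOGNORM = "sc-lognorm"

SUBGROUPS = ("WNT", "SHH", "Group3", "Group4")


def _duplicates(labels: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen and lab not in dups:
            dups.append(lab)
        seen.add(lab)
    return dups


class ExpressionMatrix:
    """A labelled genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample (or cell)
        identifiers as columns. Bulk values are log2 intensities;
        single-cell values are log-normalised counts. The convention is
        recorded in ``scale_tag`` and never inferred from the numbers.
    scale_tag
        One of ``"bulk-log2"`` or ``"sc-lognorm"``.
    allow_nan
        Permit NaN entries (explicitly flagged missing values). Infinite
        values are never accepted.
    """

    def __init__(self, values: pd.DataFrame, scale_tag: str = BULK_LOG2,
                 allow_nan: bool = False):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        dup_g = _duplicates(values.index)
        if dup_g:
            raise ValueError(f"duplicate gene identifiers: {dup_g}")
        dup_s = _duplicates(values.columns)
        if dup_s:
            raise ValueError(f"duplicate sample identifiers: {dup_s}")
        arr = values.to_numpy(dtype=float)
        if allow_nan:
            if np.isinf(arr).any():
                raise ValueError("matrix contains infinite values")
        elif not np.isfinite(arr).all():
            raise ValueError("matrix contains non-finite values")
        if scale_tag not in (BULK_LOG2, SC_LOGNORM):
            raise ValueError(f"unknown scale_tag {scale_tag!r}")
        self.values = values.astype(float)
        self.scale_tag = scale_tag

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale_tag)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, {self.scale_tag})"


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set (e.g. a stromal or immune signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReceptorLigandTable:
    """Ligand-receptor pair list with a per-gene role index.

    A gene appearing in both columns of the pair table gets role
    ``"both"``. Self-pairs are rejected at construction with a warning.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ReceptorLigandTable":
        kept: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for lig, rec in pairs:
            if lig == rec:
                warnings.warn(f"self-pair {lig!r} ignored", stacklevel=2)
                continue
            if (lig, rec) in seen:
                continue
            seen.add((lig, rec))
            kept.append((lig, rec))
        ligands = {l for l, _ in kept}
        receptors = {r for _, r in kept}
        roles = {}
        for g in ligands | receptors:
            if g in ligands and g in receptors:
                roles[g] = "both"
            elif g in ligands:
                roles[g] = "ligand"
            else:
                roles[g] = "receptor"
        return cls(pairs=kept, roles=roles)

    @property
    def genes(self) -> set[str]:
        return set(self.roles)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path: str | Path, format: str = "tsv",
                scale_tag: str = BULK_LOG2,
                features: str | Path | None = None,
                barcodes: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression matrix (genes as rows).

    ``format="tsv"``: tab-delimited with a header row of sample ids and the
    gene id in the first column. ``format="mtx"``: MatrixMarket coordinate
    file with ``features.tsv`` (gene ids) and ``barcodes.tsv`` (cell ids)
    sidecars, by default looked up next to the ``.mtx`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str).rename(None)
        return ExpressionMatrix(df, scale_tag)
    if format == "mtx":
        feat = Path(features) if features else path.parent / "features.tsv"
        bars = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        for side in (feat, bars):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar file {side}")
        genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(bars, sep="\t", header=None)[0].astype(str).tolist()
        m = _spio.mmread(path)
        m = _sparse.coo_matrix(m).toarray()
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {m.shape} does not match {len(genes)} features "
                f"x {len(cells)} barcodes")
        df = pd.DataFrame(m, index=genes, columns=cells)
        return ExpressionMatrix(df, scale_tag)
    raise ValueError(f"unknown matrix format {format!r}")


def write_matrix(mat: ExpressionMatrix, path: str | Path, format: str = "tsv",
                 float_format: str = "%.10g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        mat.values.to_csv(path, sep="\t", float_format=float_format,
                          index_label="gene")
        return
    if format == "mtx":
        _spio.mmwrite(str(path), _sparse.coo_matrix(mat.values.to_numpy()))
        pd.Series(mat.genes).to_csv(path.parent / "features.tsv", sep="\t",
                                    header=False, index=False)
        pd.Series(mat.samples).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
        return
    raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read a GMT file (name TAB description TAB gene ...), one set per line.

    Duplicate genes within a line are collapsed with a warning; a line with
    fewer than three fields is an error naming the line number.
    """
    path = Path(path)
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)")
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            dup = False
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup = True
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                warnings.warn(f"{path}:{lineno}: duplicate genes in set "
                              f"{name!r} collapsed", stacklevel=2)
            sigs.append(GeneSignature(name, tuple(genes)))
    return sigs


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path,
              description: str = "na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# receptor-ligand pairs


def read_rl_pairs(path: str | Path) -> ReceptorLigandTable:
    """Read a two-column (ligand, receptor) TSV; a header row is detected by
    the literal column names 'ligand'/'receptor' (case-insensitive)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    if first[0] in ("ligand", "ligand_gene") or first[1] in ("receptor", "receptor_gene"):
        df = df.iloc[1:]
    pairs = [(str(l), str(r)) for l, r in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return ReceptorLigandTable.from_pairs(pairs)


def write_rl_pairs(table: ReceptorLigandTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\n")
        for lig, rec in table.pairs:
            fh.write(f"{lig}\t{rec}\n")


# ---------------------------------------------------------------------------
# annotations and cohort summaries


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample/cell annotation TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    dup = _duplicates(df.index)
    if dup:
        raise ValueError(f"duplicate sample identifiers in annotation: {dup}")
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path, sep="\t", index_label="sample_id")


def round_pct(numer: int, denom: int) -> float:
    """Percentage 100*numer/denom rounded half-up to one decimal."""
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(100 * numer) / Decimal(denom)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(ann: pd.DataFrame) -> dict:
    """Summarise a cohort annotation table.

    Returns a dict with:

    ``n_samples``
        total row count.
    ``subgroups``
        DataFrame (count, percent) per subgroup, percent of all samples,
        half-up to one decimal.
    ``metastasis``
        DataFrame (n_annotated, n_metastatic, percent) with an ``overall``
        row and one row per subgroup; denominators exclude samples with a
        missing metastasis flag. Absent when nothing is annotated.
    ``cells_per_tumour``
        dict (n_tumours, mean, min, max) when a ``tumour_id`` column is
        present.
    """
    if "subgroup" not in ann.columns:
        raise ValueError("annotation table lacks a 'subgroup' column")
    n = len(ann)
    counts = ann["subgroup"].value_counts()
    sub = pd.DataFrame({
        "count": counts,
        "percent": [round_pct(int(c), n) for c in counts],
    })
    sub.index.name = "subgroup"
    out: dict = {"n_samples": n, "subgroups": sub}

    if "metastasis" in ann.columns:
        met = ann["metastasis"]
        annotated = met.notna()
        if annotated.any():
            flags = met[annotated].astype(bool)
            rows = {"overall": (int(annotated.sum()), int(flags.sum()))}
            for sg, grp in ann[annotated].groupby("subgroup", observed=True):
                g = grp["metastasis"].astype(bool)
                rows[str(sg)] = (len(g), int(g.sum()))
            tab = pd.DataFrame(
                {"n_annotated": {k: v[0] for k, v in rows.items()},
                 "n_metastatic": {k: v[1] for k, v in rows.items()}})
            tab["percent"] = [round_pct(int(m), int(a)) if a else float("nan")
                              for a, m in zip(tab["n_annotated"],
                                              tab["n_metastatic"])]
            out["metastasis"] = tab

    if "tumour_id" in ann.columns:
        per = ann.groupby("tumour_id", observed=True).size()
        if len(per):
            out["cells_per_tumour"] = {
                "n_tumours": int(len(per)),
                "mean": float(per.mean()),
                "min": int(per.min()),
                "max": int(per.max()),
            }
    return out
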