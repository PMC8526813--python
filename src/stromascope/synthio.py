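"""Synthetic paired bulk and single-cell cohorts with planted structure.

The bulk generator emulates a subgroup-labelled microarray cohort on the
log2 scale: each sample carries a latent stromal fraction drawn from a
subgroup-specific Beta distribution (the "SHH"-like subgroup stroma-rich,
the "Group3"-like subgroup stroma-poor), stromal/immune signature genes
track their latent fractions, and a set of planted receptor/ligand driver
genes is both shifted in the stroma-rich subgroup and linearly coupled to
the latent stromal fraction. Decoy receptor/ligand genes with no planted
signal are included so that false discoveries are measurable downstream.

The single-cell generator emulates per-tumour cell populations carrying a
latent stroma-activity gradient in [0, 1]: associate-gene detection follows
a logistic function of activity, the total detected-gene count rises with
activity, and counts are negative-binomial then log-normalised the way
droplet pipelines normalise (counts / cell total * 1e4, natural log1p).

All randomness flows from a single ``numpy.random.default_rng(seed)``; the
seed is a required config field, so identical configs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (BULK_LOG2, SC_LOGNORM, ExpressionMatrix, GeneSignature,
                      ReceptorLigandTable, write_annotation, write_gmt,
                      write_matrix, write_rl_pairs)

_DEFAULT_PROPS = {"SHH": 0.29, "Group3": 0.19, "Group4": 0.43, "WNT": 0.09}
_DEFAULT_BETA = {"SHH": (5.0, 2.0), "Group3": (2.0, 5.0),
                 "Group4": (3.0, 3.0), "WNT": (3.0, 3.0)}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class BulkSimConfig:
    """Configuration for the bulk cohort generator.

    Defaults reproduce the study conditions exercised by the test suite:
    200 samples x 2000 genes, 30 planted drivers at log2 fold-change 1.5
    with a stroma coupling of 1.2 log2 units per unit stromal fraction,
    giving a population gene-score correlation near 0.5 at noise_sd 0.5.
    """

    seed: int
    n_genes: int = 2000
    n_samples: int = 200
    subgroup_props: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPS))
    stroma_beta_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BETA))
    n_signature_genes: int = 50
    n_driver_genes: int = 30
    n_rl_decoys: int = 150
    driver_log2fc: float = 1.5
    driver_stroma_coupling: float = 1.2
    signature_coupling: float = 2.0
    noise_sd: float = 0.5
    driver_subgroup: str = "SHH"

    def __post_init__(self):
        tot = float(sum(self.subgroup_props.values()))
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"subgroup proportions sum to {tot}, not 1")
        for name, p in self.subgroup_props.items():
            if p < 0:
                raise ConfigError(f"negative proportion for {name}")
            if name not in self.stroma_beta_params:
                raise ConfigError(f"no stroma Beta parameters for {name}")
        for n in (self.n_genes, self.n_samples, self.n_signature_genes,
                  self.n_driver_genes):
            if n <= 0:
                raise ConfigError("all counts must be positive")
        if self.n_rl_decoys < 0:
            raise ConfigError("n_rl_decoys must be non-negative")
        reserved = 2 * self.n_signature_genes + self.n_driver_genes + self.n_rl_decoys
        if reserved >= self.n_genes:
            raise ConfigError(
                f"signature + driver + decoy genes ({reserved}) must be fewer "
                f"than n_genes ({self.n_genes})")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.driver_subgroup not in self.subgroup_props:
            raise ConfigError(f"driver subgroup {self.driver_subgroup!r} not "
                              "among subgroups")


@dataclass
class ScSimConfig:
    """Configuration for the single-cell generator.

    ``activity_dist`` maps metastasis status to the (a, b) Beta parameters
    of the per-cell latent activity within a tumour; metastatic tumours
    default to a higher activity mean, planting the direction that the
    metastasis contrast is meant to detect.
    """

    seed: int
    n_genes: int = 1500
    n_tumours: int = 10
    cells_per_tumour: tuple[int, int] = (300, 300)
    activity_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"nonmetastatic": (2.0, 4.0),
                                 "metastatic": (4.0, 2.0)})
    detection_coupling: float = 6.0
    potential_coupling: float = 1.5
    nb_dispersion: float = 2.0
    metastatic_tumours: tuple[int, ...] = (0, 1, 2, 3, 4)
    subgroup: str = "SHH"

    def __post_init__(self):
        lo, hi = self.cells_per_tumour
        if lo <= 0 or hi < lo:
            raise ConfigError("cells_per_tumour range must be positive and "
                              "ordered (lo, hi)")
        if self.n_genes <= 0 or self.n_tumours <= 0:
            raise ConfigError("counts must be positive")
        for key in ("metastatic", "nonmetastatic"):
            if key not in self.activity_dist:
                raise ConfigError(f"activity_dist missing {key!r}")
            a, b = self.activity_dist[key]
            if a <= 0 or b <= 0:
                raise ConfigError("Beta parameters must be positive")
        if any(t < 0 or t >= self.n_tumours for t in self.metastatic_tumours):
            raise ConfigError("metastatic tumour index out of range")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")


def gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


@dataclass
class BulkSimResult:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    stromal_signature: GeneSignature
    immune_signature: GeneSignature
    rl_table: ReceptorLigandTable
    truth: dict


@dataclass
class ScSimResult:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    truth: dict


def _pair_up(genes: Sequence[str]) -> list[tuple[str, str]]:
    """Pair consecutive genes as (ligand, receptor); an odd leftover gene
    becomes a ligand of the previous receptor."""
    pairs = []
    for i in range(0, len(genes) - 1, 2):
        pairs.append((genes[i], genes[i + 1]))
    if len(genes) % 2 == 1 and len(genes) >= 3:
        pairs.append((genes[-1], genes[-2]))
    return pairs


def generate_bulk(config: BulkSimConfig) -> BulkSimResult:
    """Generate a subgroup-labelled bulk cohort with planted stroma structure.

    Returns the log2 expression matrix, the sample annotation, the planted
    stromal and immune truth signatures, a receptor-ligand table covering
    planted drivers and signal-free decoys, and a truth record holding the
    latent stromal fraction per sample and the planted driver list.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)
    nsig = config.n_signature_genes
    stromal = genes[:nsig]
    immune = genes[nsig:2 * nsig]
    drivers = genes[2 * nsig:2 * nsig + config.n_driver_genes]
    decoys = genes[2 * nsig + config.n_driver_genes:
                   2 * nsig + config.n_driver_genes + config.n_rl_decoys]

    names = sorted(config.subgroup_props)
    props = np.array([config.subgroup_props[k] for k in names], dtype=float)
    subgroup = rng.choice(names, size=config.n_samples, p=props / props.sum())

    # latent fractions
    s = np.empty(config.n_samples)
    for k in names:
        mask = subgroup == k
        a, b = config.stroma_beta_params[k]
        s[mask] = rng.beta(a, b, size=int(mask.sum()))
    immune_latent = rng.beta(2.0, 5.0, size=config.n_samples)

    baseline = rng.normal(7.0, 1.0, size=config.n_genes)
    expr = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples))

    gidx = {g: i for i, g in enumerate(genes)}
    st_rows = [gidx[g] for g in stromal]
    im_rows = [gidx[g] for g in immune]
    dr_rows = [gidx[g] for g in drivers]
    expr[st_rows, :] += config.signature_coupling * s[None, :]
    expr[im_rows, :] += config.signature_coupling * immune_latent[None, :]
    in_target = (subgroup == config.driver_subgroup).astype(float)
    expr[dr_rows, :] += (config.driver_log2fc * in_target[None, :]
                         + config.driver_stroma_coupling * s[None, :])

    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    mat = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples),
                           BULK_LOG2)
    ann = pd.DataFrame({"subgroup": subgroup}, index=pd.Index(samples,
                                                              name="sample_id"))

    rl_genes = list(drivers) + list(decoys)
    rl = ReceptorLigandTable.from_pairs(_pair_up(rl_genes))
    truth = {
        "stromal_fraction": pd.Series(s, index=samples, name="stromal_fraction"),
        "immune_fraction": pd.Series(immune_latent, index=samples,
                                     name="immune_fraction"),
        "drivers": list(drivers),
        "rl_decoys": list(decoys),
        "driver_subgroup": config.driver_subgroup,
        "stromal_signature": list(stromal),
        "immune_signature": list(immune),
    }
    return BulkSimResult(
        matrix=mat, annotation=ann,
        stromal_signature=GeneSignature("stromal", tuple(stromal)),
        immune_signature=GeneSignature("immune", tuple(immune)),
        rl_table=rl, truth=truth)


def generate_sc(config: ScSimConfig,
                associate_genes: Sequence[str]) -> ScSimResult:
    """Generate per-tumour single cells along a latent stroma-activity axis.

    Each cell's activity ``a`` is Beta-distributed with tumour-level
    parameters chosen by metastasis status. Associate genes are detected
    with probability ``logistic(detection_coupling * (a - 0.5))`` and, when
    detected, carry at least one count. Every other gene's negative-binomial
    mean is scaled by ``exp(potential_coupling * (a - 0.5))`` so the
    detected-gene count rises with activity. Counts are normalised per cell
    to 1e4 total and natural-log1p transformed.
    """
    genes = gene_names(config.n_genes)
    gset = set(genes)
    missing = [g for g in associate_genes if g not in gset]
    if missing:
        raise ValueError(f"associate genes not in gene universe: {missing[:5]}")
    rng = np.random.default_rng(config.seed)

    lo, hi = config.cells_per_tumour
    n_cells_per = rng.integers(lo, hi + 1, size=config.n_tumours)
    tumour_ids, met_flags, activity = [], [], []
    for t in range(config.n_tumours):
        met = t in config.metastatic_tumours
        a, b = config.activity_dist["metastatic" if met else "nonmetastatic"]
        acts = rng.beta(a, b, size=int(n_cells_per[t]))
        activity.append(acts)
        tumour_ids += [f"T{t + 1:02d}"] * int(n_cells_per[t])
        met_flags += [met] * int(n_cells_per[t])
    a_c = np.concatenate(activity)
    n_cells = a_c.size
    cells = [f"C{i + 1:05d}" for i in range(n_cells)]

    assoc_idx = np.array([genes.index(g) for g in associate_genes], dtype=int)
    is_assoc = np.zeros(config.n_genes, dtype=bool)
    is_assoc[assoc_idx] = True

    mu = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    cell_factor = np.exp(config.potential_coupling * (a_c - 0.5))
    mean = mu[:, None] * cell_factor[None, :]
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean),
                                   size=mean.shape).astype(float)

    if assoc_idx.size:
        p_detect = 1.0 / (1.0 + np.exp(-config.detection_coupling * (a_c - 0.5)))
        detected = rng.random((assoc_idx.size, n_cells)) < p_detect[None, :]
        base = rng.negative_binomial(
            theta, theta / (theta + mu[assoc_idx][:, None] * np.ones((1, n_cells))),
            size=(assoc_idx.size, n_cells)).astype(float)
        counts[assoc_idx, :] = np.where(detected, 1.0 + base, 0.0)

    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    lognorm = np.log1p(1e4 * counts / totals[None, :])

    mat = ExpressionMatrix(pd.DataFrame(lognorm, index=genes, columns=cells),
                           SC_LOGNORM)
    ann = pd.DataFrame({
        "subgroup": config.subgroup,
        "tumour_id": tumour_ids,
        "metastasis": met_flags,
    }, index=pd.Index(cells, name="cell_id"))
    truth = {"activity": pd.Series(a_c, index=cells, name="activity"),
             "associate_genes": list(associate_genes)}
    return ScSimResult(matrix=mat, annotation=ann, truth=truth)


# ---------------------------------------------------------------------------
# on-disk emission (formats the formats module reads back)


def write_bulk(result: BulkSimResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "bulk_matrix.tsv",
        "annotation": outdir / "bulk_annotation.tsv",
        "signatures": outdir / "signatures.gmt",
        "rl_pairs": outdir / "rl_pairs.tsv",
        "truth": outdir / "bulk_truth.tsv",
    }
    write_matrix(result.matrix, paths["matrix"])
    write_annotation(result.annotation, paths["annotation"])
    write_gmt([result.stromal_signature, result.immune_signature],
              paths["signatures"])
    write_rl_pairs(result.rl_table, paths["rl_pairs"])
    truth = pd.DataFrame({
        "stromal_fraction": result.truth["stromal_fraction"],
        "immune_fraction": result.truth["immune_fraction"],
    })
    truth.to_csv(paths["truth"], sep="\t", index_label="sample_id")
    with open(outdir / "bulk_truth_drivers.tsv", "w") as fh:
        fh.write("gene\trole\n")
        for g in result.truth["drivers"]:
            fh.write(f"{g}\t{result.rl_table.roles.get(g, 'unknown')}\n")
    paths["truth_drivers"] = outdir / "bulk_truth_drivers.tsv"
    return paths


def write_sc(result: ScSimResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "sc_matrix.mtx",
        "annotation": outdir / "sc_annotation.tsv",
        "truth": outdir / "sc_truth.tsv",
    }
    write_matrix(result.matrix, paths["matrix"], format="mtx")
    write_annotation(result.annotation, paths["annotation"])
    result.truth["activity"].to_frame().to_csv(paths["truth"], sep="\t",
                                               index_label="cell_id")
    return paths
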