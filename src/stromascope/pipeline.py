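"""End-to-end orchestration: score -> screen -> associates -> network ->
cell states, from a single YAML config, with a reproducibility manifest.

Stages are plain compositions of the public module functions — the
pipeline adds no hidden logic. Every output file is listed in
``manifest.json`` with its SHA-256 hash, alongside the seed, the software
version and every threshold actually applied, so identical config + seed
reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associates import classify_associates, filter_sc_expressed
from .cellstate import (count_associates, dev_potential, find_markers,
                        metastasis_contrast, potential_vs_activity)
from .dgecorr import screen
from .formats import (ExpressionMatrix, read_annotation, read_gmt,
                      read_matrix, read_rl_pairs, summarize_cohort,
                      SC_LOGNORM)
from .netcent import build_network, closeness, export_edgelist, export_graphml
from .scoring import score_table
from .synthio import (BulkSimConfig, ScSimConfig, generate_bulk, generate_sc,
                      write_bulk, write_sc)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_THRESHOLDS = {
    "fc_min": 2.0,           # linear fold-change cutoff for the DGE screen
    "r_assoc": 0.2,          # |Pearson r| with stromal score for associates
    "alpha": 0.05,           # significance level throughout
    "r_min_bulk": 0.6,       # bulk network edge threshold
    "r_min_sc": 0.2,         # single-cell network edge threshold
    "active_min": 5,         # state: active iff count > active_min
    "inactive_max": 2,       # state: inactive iff count < inactive_max
    "sc_expressed_frac": 0.01,  # detection fraction floor in single cells
    "ssgsea_alpha": 0.25,    # ssGSEA rank-weight exponent
    "top_k": 200,            # genes in the potential signature
}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    simulate: dict | None = None      # {"bulk": {...}, "sc": {...}} overrides
    inputs: dict | None = None        # explicit input paths
    thresholds: dict = field(default_factory=dict)
    enriched_subgroup: str = "SHH"
    suppressed_subgroup: str = "Group3"
    stromal_signature: str = "stromal"
    immune_signature: str = "immune"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def resolved_thresholds(self) -> dict:
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds or {})
        return thr


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_inputs(inputs: dict) -> None:
    for key, p in inputs.items():
        if p and not Path(p).exists():
            raise PipelineError("inputs", f"missing input path for "
                                f"{key!r}: {p}")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.resolved_thresholds()
    outputs: dict[str, str] = {}
    notes: list[str] = []

    # ---- inputs --------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate or {}
        bulk_kw = dict(sim.get("bulk") or {})
        bulk_kw.setdefault("seed", config.seed)
        bulk = generate_bulk(BulkSimConfig(**bulk_kw))
        sc_kw = dict(sim.get("sc") or {})
        sc_kw.setdefault("seed", config.seed + 1)
        sc = generate_sc(ScSimConfig(**sc_kw), bulk.truth["drivers"])
        indir = outdir / "inputs"
        in_paths = {**write_bulk(bulk, indir), **write_sc(sc, indir)}
        bulk_mat, bulk_ann = bulk.matrix, bulk.annotation
        signatures = [bulk.stromal_signature, bulk.immune_signature]
        rl = bulk.rl_table
        sc_mat, sc_ann = sc.matrix, sc.annotation
        inputs_rec = {k: str(v) for k, v in in_paths.items()}
    elif config.inputs is not None:
        _check_inputs(config.inputs)
        inp = config.inputs
        bulk_mat = read_matrix(inp["bulk_matrix"])
        bulk_ann = read_annotation(inp["bulk_annotation"])
        signatures = read_gmt(inp["signatures"])
        rl = read_rl_pairs(inp["rl_pairs"])
        sc_fmt = "mtx" if str(inp["sc_matrix"]).endswith(".mtx") else "tsv"
        sc_mat = read_matrix(inp["sc_matrix"], format=sc_fmt,
                             scale_tag=SC_LOGNORM)
        sc_ann = read_annotation(inp["sc_annotation"])
        inputs_rec = {k: str(v) for k, v in inp.items()}
    else:
        raise PipelineError("inputs", "config needs a 'simulate' block or "
                            "an 'inputs' block")

    sig_by_name = {s.name: s for s in signatures}
    for need in (config.stromal_signature,):
        if need not in sig_by_name:
            raise PipelineError("inputs", f"signature {need!r} not found")

    def emit(name: str, df: pd.DataFrame, **kw):
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        outputs[name] = str(path)
        return path

    # ---- stage: cohort summary ----------------------------------------
    try:
        summary = summarize_cohort(bulk_ann)
        emit("cohort_subgroups.tsv", summary["subgroups"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("summarize", str(e)) from e

    # ---- stage: score --------------------------------------------------
    try:
        scores = score_table(bulk_mat, list(sig_by_name.values()),
                             method="ssgsea", alpha=thr["ssgsea_alpha"])
        emit("scores.tsv", scores)
        stromal_scores = scores[config.stromal_signature]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("score", str(e)) from e

    # ---- stage: screen -------------------------------------------------
    try:
        scr_enr = screen(bulk_mat, bulk_ann, stromal_scores,
                         config.enriched_subgroup)
        scr_sup = screen(bulk_mat, bulk_ann, stromal_scores,
                         config.suppressed_subgroup)
        emit("screen_enriched.tsv", scr_enr)
        emit("screen_suppressed.tsv", scr_sup)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("screen", str(e)) from e

    # ---- stage: associates --------------------------------------------
    try:
        assoc = classify_associates(
            scr_enr, scr_sup, rl, exclude=list(sig_by_name.values()),
            fc_min=thr["fc_min"], r_min=thr["r_assoc"], alpha=thr["alpha"])
        expressed = filter_sc_expressed(list(assoc.index), sc_mat,
                                        min_frac=thr["sc_expressed_frac"])
        assoc = assoc.loc[[g for g in assoc.index if g in set(expressed)]]
        emit("associates.tsv", assoc)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("associates", str(e)) from e

    # ---- stage: network ------------------------------------------------
    try:
        for label, mat, r_min in (("bulk", bulk_mat, thr["r_min_bulk"]),
                                  ("sc", sc_mat, thr["r_min_sc"])):
            present = [g for g in assoc.index if g in set(mat.genes)]
            if len(present) < 2:
                notes.append(f"{label} network skipped: <2 associates in "
                             "matrix")
                continue
            G = build_network(mat, assoc.loc[present], r_min=r_min,
                              alpha=thr["alpha"])
            export_edgelist(G, outdir / f"network_{label}_edges.tsv")
            export_graphml(G, outdir / f"network_{label}.graphml")
            outputs[f"network_{label}_edges.tsv"] = str(
                outdir / f"network_{label}_edges.tsv")
            outputs[f"network_{label}.graphml"] = str(
                outdir / f"network_{label}.graphml")
            emit(f"closeness_{label}.tsv",
                 closeness(G).rename_axis("gene").to_frame())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", str(e)) from e

    # ---- stage: cellstate ----------------------------------------------
    try:
        from .cellstate import classify_state  # local alias for clarity
        counts = count_associates(sc_mat, assoc)
        counts["state"] = classify_state(counts["n_total"],
                                         thr["active_min"],
                                         thr["inactive_max"])
        potential = dev_potential(sc_mat, top_k=thr["top_k"])
        cell_table = counts.join(potential)
        emit("cell_activity.tsv", cell_table, index_label="cell_id")

        st = counts["state"]
        if (st == "active").sum() >= 3 and (st == "inactive").sum() >= 3:
            markers = find_markers(sc_mat, st, alpha=thr["alpha"],
                                   min_frac=thr["sc_expressed_frac"])
            emit("markers.tsv", markers)
        else:
            notes.append("marker screen skipped: <3 cells in a state")

        stats_block: dict = {}
        if "metastasis" in sc_ann.columns and sc_ann["metastasis"].nunique() == 2:
            mc = metastasis_contrast(counts, sc_ann)
            stats_block["metastasis_contrast"] = {
                k: v for k, v in mc.items() if k != "per_tumour_means"}
            emit("metastasis_per_tumour.tsv", mc["per_tumour_means"],
                 index=False)
        pva = potential_vs_activity(potential, counts)
        stats_block["potential_vs_activity"] = {
            "r": pva["r"], "p_value": pva["p_value"]}
        with open(outdir / "cellstate_stats.json", "w") as fh:
            json.dump(stats_block, fh, indent=2)
        outputs["cellstate_stats.json"] = str(outdir / "cellstate_stats.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cellstate", str(e)) from e

    # ---- manifest ------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": thr,
        "enriched_subgroup": config.enriched_subgroup,
        "suppressed_subgroup": config.suppressed_subgroup,
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                   for k, v in inputs_rec.items() if Path(v).exists()},
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                    for k, v in outputs.items()},
        "notes": notes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %d outputs under %s", len(outputs), outdir)
    return manifest
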