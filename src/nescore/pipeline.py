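"""End-to-end workflow: simulate/load -> derive -> score -> evaluate.

Every run writes a resolved-config copy and a manifest (file checksums,
package version, config hash, seed) next to its outputs, so any artifact is
re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, fields
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import evaluate, io, markers, scoring, simulate
from .containers import Annotation, ExpressionMatrix, GeneSignature, ValidationError

logger = logging.getLogger(__name__)

DERIVE_DEFAULTS = {
    "lfc_threshold": 0.5,
    "p_adj_threshold": 0.01,
    "min_pct": 0.20,
    "support_min": 1,
    "min_cells_fraction": 0.001,
}
SCORE_DEFAULTS = {
    "method": "ssgsea",
    "alpha": scoring.DEFAULT_ALPHA,
    "max_rank_fraction": scoring.DEFAULT_MAX_RANK_FRACTION,
}


def version_info(config: dict | None = None, seed: int | None = None) -> dict:
    """Provenance record: package version, config hash, seed."""
    try:
        ver = pkg_version("nescore")
    except PackageNotFoundError:  # running from a source tree
        ver = "0.0.0+src"
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "package": "nescore",
        "version": ver,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_signature(
    counts: ExpressionMatrix,
    cell_ann: Annotation,
    meta_markers: set[str],
    module_genes: set[str],
    ne_cell_type: str = "NE",
    ne_group: str = "NEPC",
    lfc_threshold: float = 0.5,
    p_adj_threshold: float = 0.01,
    min_pct: float = 0.20,
    support_min: int = 1,
    min_cells_fraction: float = 0.001,
) -> dict[str, Any]:
    """Full signature derivation from a single-cell atlas.

    QC-filters cells, drops mitochondrial and high-dropout genes, runs the
    pseudobulk NE-rich-vs-adeno contrast, intersects with the evidence
    streams into the feature-gene set, then thins against cell-level
    NE-vs-rest markers. Returns every intermediate of interest.
    """
    cell_ann.check_covers(counts)
    filtered, qc_report = markers.qc_filter_cells(counts)
    mito = [g for g in filtered.genes if g.startswith(("MT-", "mt-"))]
    filtered = markers.filter_genes(
        filtered, exclude_lists=[mito], min_cells_fraction=min_cells_fraction
    )

    pb = markers.pseudobulk_aggregate(filtered, cell_ann, group_by="sample_id")
    pb_cpm = io.tpm_from_counts(pb, {g: 1.0 for g in pb.genes})  # unit lengths = CPM
    sample_groups = (
        cell_ann.table.loc[filtered.columns, ["sample_id", "sample_group"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    pb_ann = Annotation(sample_groups)
    pb_markers = markers.wilcoxon_de(
        pb_cpm, pb_ann, "sample_group", ne_group, correction="bonferroni"
    )

    evidence = markers.EvidenceSet(
        pseudobulk_degs=pb_markers, meta_markers=meta_markers, module_genes=module_genes
    )
    ne_fg = markers.derive_ne_fg(
        evidence,
        lfc_threshold=lfc_threshold,
        p_adj_threshold=p_adj_threshold,
        support_min=support_min,
    )

    cell_markers = markers.wilcoxon_de(
        filtered, cell_ann, "cell_type", ne_cell_type, correction="bonferroni"
    )
    ne_up_dn = markers.thin_signature(
        ne_fg,
        cell_markers,
        lfc_threshold=lfc_threshold,
        p_adj_threshold=p_adj_threshold,
        min_pct=min_pct,
    )
    return {
        "qc_report": qc_report,
        "pseudobulk_markers": pb_markers,
        "cell_markers": cell_markers,
        "ne_fg": ne_fg,
        "signature": ne_up_dn,
    }


def _resolve_config(config: dict) -> dict:
    cfg = {"seed": 0, "sim": {}, "derive": {}, "score": {}, "inputs": {}}
    cfg.update(config or {})
    cfg["derive"] = {**DERIVE_DEFAULTS, **cfg.get("derive", {})}
    cfg["score"] = {**SCORE_DEFAULTS, **cfg.get("score", {})}
    return cfg


def _sim_config(cfg: dict, **overrides) -> simulate.SimConfig:
    allowed = {f.name for f in fields(simulate.SimConfig)}
    params = {k: v for k, v in cfg.get("sim", {}).items() if k in allowed}
    params.setdefault("seed", cfg["seed"])
    params.update(overrides)
    if "ne_fraction_range" in params:
        params["ne_fraction_range"] = tuple(params["ne_fraction_range"])
    return simulate.SimConfig(**params)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute derive -> score -> evaluate and write a checksummed manifest.

    Without an ``inputs`` section the study data are simulated from the
    ``sim`` section (a single-cell atlas for derivation plus an independent
    bulk cohort for scoring); with one, the named files are loaded instead.
    On a stage failure the partial outputs are renamed with a ``.partial``
    suffix and the error is re-raised naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = _resolve_config(config)
    seed = int(cfg["seed"])
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        emit("resolved_config.yaml",
             lambda p: p.write_text(yaml.safe_dump(cfg, sort_keys=True)))

        stage = "inputs"
        if cfg["inputs"]:
            inp = cfg["inputs"]
            counts = io.read_expression(inp["counts_dir"], format="mtx_dir", kind="counts")
            cell_ann = io.read_annotation(inp["cell_ann"])
            meta_sets, _ = io.read_gmt(inp["meta_markers"])
            module_sets, _ = io.read_gmt(inp["module_genes"])
            meta = set().union(*(s.up for s in meta_sets))
            modules = set().union(*(s.up for s in module_sets))
            bulk = io.read_expression(inp["expr"], format="tsv", kind=inp.get("expr_kind", "tpm"))
            bulk_ann = io.read_annotation(inp["labels"])
            truth = None
        else:
            atlas_cfg = _sim_config(cfg, n_qc_violators=cfg.get("sim", {}).get("n_qc_violators", 12))
            counts, cell_ann, truth = simulate.simulate_sc_atlas(atlas_cfg)
            bulk_cfg = _sim_config(cfg, seed=seed + 10_000)
            bulk, bulk_ann, _ = simulate.simulate_bulk_cohort(bulk_cfg)
            # evidence streams: planted truth diluted with background decoys,
            # emulating a published marker union and co-expression modules
            rng = atlas_cfg.rng()
            bg = [g for g in counts.genes
                  if g not in set(truth.up) | set(truth.down) and not g.startswith("MT-")]
            meta = set(truth.up) | set(truth.down) | set(rng.choice(bg, 200, replace=False))
            modules = set(truth.up) | set(rng.choice(bg, 100, replace=False))
            emit("truth_up.txt", lambda p: p.write_text("".join(f"{g}\n" for g in truth.up)))
            emit("truth_dn.txt", lambda p: p.write_text("".join(f"{g}\n" for g in truth.down)))
            emit("cells.tsv", lambda p: io.write_annotation(cell_ann, p))
            emit("bulk_annotation.tsv", lambda p: io.write_annotation(bulk_ann, p))

        stage = "derive"
        derived = derive_signature(
            counts, cell_ann, meta, modules, **cfg["derive"]
        )
        sig: GeneSignature = derived["signature"]
        emit("ne_fg.gmt", lambda p: io.write_gmt([derived["ne_fg"]], p))
        emit("ne_up.txt", lambda p: p.write_text("".join(f"{g}\n" for g in sig.up)))
        emit("ne_dn.txt", lambda p: p.write_text("".join(f"{g}\n" for g in sig.down)))
        emit("markers.tsv",
             lambda p: derived["cell_markers"].to_csv(p, sep="\t", index_label="gene"))
        emit("pseudobulk_markers.tsv",
             lambda p: derived["pseudobulk_markers"].to_csv(p, sep="\t", index_label="gene"))

        stage = "score"
        table = scoring.risk_score(
            bulk, sig,
            method=cfg["score"]["method"],
            alpha=cfg["score"]["alpha"],
            max_rank_fraction=cfg["score"]["max_rank_fraction"],
        )
        emit("scores.tsv", lambda p: scoring.write_scores(table, p))

        stage = "evaluate"
        report = evaluate.EvalReport(name=sig.name)
        labels = bulk_ann.column("ne_status", table.scores.index)
        report.auc = evaluate.roc_auc(table.risk.to_numpy(), labels.to_numpy())
        if "ne_fraction" in bulk_ann.table.columns:
            frac = bulk_ann.column("ne_fraction", table.scores.index)
            report.pearson_r, report.pearson_p = evaluate.correlate(
                table.risk.to_numpy(), frac.to_numpy(), "pearson"
            )
        if {"time", "event"} <= set(bulk_ann.table.columns):
            surv = bulk_ann
        elif truth is not None:
            surv = simulate.simulate_survival(table.risk, _sim_config(cfg, seed=seed + 20_000))
            emit("survival.tsv", lambda p: io.write_annotation(surv, p))
        else:
            surv = None
        if surv is not None:
            t = surv.column("time", table.scores.index).to_numpy()
            e = surv.column("event", table.scores.index).to_numpy()
            report.c_index = evaluate.concordance_index(table.risk.to_numpy(), t, e)
            km = evaluate.km_logrank(table.risk.to_numpy(), t, e)
            report.logrank_chi2, report.logrank_p = km.logrank_chi2, km.logrank_p
            report.group_sizes = km.group_sizes
        rep = {k: v for k, v in asdict(report).items() if k != "extras" and v is not None}
        emit("report.tsv",
             lambda p: pd.Series(rep).to_csv(p, sep="\t", header=False))
    except Exception as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "provenance": version_info(cfg, seed),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
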