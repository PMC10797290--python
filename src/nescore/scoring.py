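"""Single-sample gene-set enrichment engines and the up-minus-down risk score.

Two rank-based engines are provided:

* ``ssgsea`` — the single-sample GSEA statistic: genes are ranked within
  each sample, in-set genes contribute weight ``rank**alpha`` (normalized to
  the in-set total) and out-of-set genes contribute ``1/(N - |S|)``; the
  enrichment score is the *integrated* running sum (summed over every rank
  position), not the max-deviation statistic of classic GSEA.
* ``aucell`` — per-cell gene-set activity as the area under the in-set gene
  recovery curve within the top-ranked fraction of genes, normalized so that
  a cell whose in-set genes occupy the top ranks scores exactly 1.

The combined risk score of a signature with up and down lists is

    risk = NES_UP - NES_DN

where for ssgsea the raw up and down scores of a cohort are jointly
normalized by their overall max - min range, and for aucell the scores are
already on the [0, 1] scale. Both engines depend on expression only through
within-column ranks, so any strictly increasing per-column transform of the
data leaves every score unchanged.

Tie handling is deterministic: tied expression values share their average
rank for the ssgsea weights, while positions along the ranked list follow
stable input (gene) order for both engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GeneSignature, ValidationError

DEFAULT_ALPHA = 0.25  # ssGSEA weight exponent, GSVA's ssgsea default
DEFAULT_MAX_RANK_FRACTION = 0.05  # AUCell's aucMaxRank default (top 5% of genes)
MIN_OVERLAP_WARN = 0.30  # warn when < 30% of a gene list is present

Method = Literal["ssgsea", "aucell"]


@dataclass
class ScoreTable:
    """Per-column enrichment and risk scores for one signature."""

    scores: pd.DataFrame  # columns: ES_up, ES_dn, NES_UP, NES_DN, risk
    method: Method
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores[["NES_UP", "NES_DN", "risk"]].to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite score produced")

    @property
    def risk(self) -> pd.Series:
        return self.scores["risk"]


def _descending_order(x: np.ndarray) -> np.ndarray:
    """Stable descending order of a (genes x columns) array, per column."""
    return np.argsort(-x, axis=0, kind="stable")


def _check_set(genes: Sequence[str], gene_set: Sequence[str]) -> np.ndarray:
    present = set(genes) & set(gene_set)
    if not present:
        raise ValidationError("gene set shares no genes with the matrix")
    if len(present) == len(genes):
        raise ValidationError(
            "gene set covers every matrix gene — no out-of-set genes to "
            "contrast against; use a smaller set"
        )
    return np.fromiter((g in present for g in genes), bool, count=len(genes))


def ssgsea_es(
    values: np.ndarray | Sequence[float],
    genes: Sequence[str],
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """ssGSEA enrichment score of one expression column.

    Ranks ascend from the least expressed gene (rank 1) to the most
    expressed (rank N), with average ranks at ties; the running sum walks
    the genes from the most to the least expressed.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    x = np.asarray(values, dtype=float)
    return float(_ssgsea_es_matrix(x[:, None], list(genes), gene_set, alpha)[0])


def _ssgsea_es_matrix(
    x: np.ndarray, genes: list[str], gene_set: Sequence[str], alpha: float
) -> np.ndarray:
    """Vectorized ssGSEA ES for every column of a (genes x columns) array."""
    in_set = _check_set(genes, gene_set)
    n_genes, _ = x.shape
    n_miss = n_genes - int(in_set.sum())

    ranks = rankdata(x, axis=0)  # ascending, average ties
    weights = np.where(in_set[:, None], ranks**alpha, 0.0)
    order = _descending_order(x)

    w_ord = np.take_along_axis(weights, order, axis=0)
    hit_ord = np.take_along_axis(np.broadcast_to(in_set[:, None], x.shape), order, axis=0)
    p_hit = np.cumsum(w_ord, axis=0) / w_ord.sum(axis=0, keepdims=True)
    p_miss = np.cumsum(~hit_ord, axis=0) / n_miss
    return (p_hit - p_miss).sum(axis=0)


def aucell_score(
    values: np.ndarray | Sequence[float],
    genes: Sequence[str],
    gene_set: Sequence[str],
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
) -> float:
    """AUCell activity of one cell: normalized area under the recovery curve."""
    x = np.asarray(values, dtype=float)
    return float(_aucell_matrix(x[:, None], list(genes), gene_set, max_rank_fraction)[0])


def _aucell_matrix(
    x: np.ndarray, genes: list[str], gene_set: Sequence[str], max_rank_fraction: float
) -> np.ndarray:
    if not 0 < max_rank_fraction <= 1:
        raise ValidationError("max_rank_fraction must be in (0, 1]")
    in_set = _check_set(genes, gene_set)
    n_genes, _ = x.shape
    k = int(np.ceil(max_rank_fraction * n_genes))
    m = int(in_set.sum())

    order = _descending_order(x)
    hit_ord = np.take_along_axis(np.broadcast_to(in_set[:, None], x.shape), order, axis=0)
    recovery = np.cumsum(hit_ord[:k], axis=0)  # in-set genes found at ranks 1..k
    area = recovery.sum(axis=0)
    max_area = np.minimum(np.arange(1, k + 1), m).sum()  # all in-set genes on top
    return area / max_area


def _engine_scores(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    method: Method,
    alpha: float,
    max_rank_fraction: float,
) -> np.ndarray:
    x = expr.values.to_numpy(dtype=float)
    if method == "ssgsea":
        return _ssgsea_es_matrix(x, expr.genes, gene_set, alpha)
    if method == "aucell":
        return _aucell_matrix(x, expr.genes, gene_set, max_rank_fraction)
    raise ValidationError(f"unknown scoring method {method!r}")


def ssgsea_normalize(raw: np.ndarray) -> np.ndarray:
    """Normalize a collection of raw ES by its max - min range (0 if flat)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("no scores to normalize")
    rng = raw.max() - raw.min()
    if rng == 0:
        return np.zeros_like(raw)
    return raw / rng


def risk_score(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    method: Method = "ssgsea",
    alpha: float = DEFAULT_ALPHA,
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
) -> ScoreTable:
    """Score every column of ``expr`` with the up-minus-down risk model.

    ssgsea requires a tpm or log matrix; aucell accepts any kind (it only
    uses ranks). Signature genes absent from the matrix are dropped with the
    retained fraction recorded in ``params``; below 30% coverage of the up
    list a warning is recorded, at 0% scoring fails.
    """
    if method == "ssgsea" and expr.kind not in ("tpm", "log"):
        raise ValidationError(
            f"ssgsea expects kind in (tpm, log), got {expr.kind}; convert counts first"
        )
    genes = set(expr.genes)
    up = [g for g in sig.up if g in genes]
    down = [g for g in sig.down if g in genes]
    if not up:
        raise ValidationError(f"signature {sig.name!r}: no up gene present in the matrix")

    params: dict = {
        "alpha": alpha,
        "max_rank_fraction": max_rank_fraction,
        "up_present": len(up),
        "up_total": len(sig.up),
        "dn_present": len(down),
        "dn_total": len(sig.down),
        "warnings": [],
    }
    up_frac = len(up) / len(sig.up)
    if up_frac < MIN_OVERLAP_WARN:
        params["warnings"].append(
            f"only {up_frac:.0%} of up genes present in the matrix"
        )
    if sig.down and not down:
        params["warnings"].append("no down gene present; risk reduces to NES_UP")

    es_up = _engine_scores(expr, up, method, alpha, max_rank_fraction)
    es_dn = (
        _engine_scores(expr, down, method, alpha, max_rank_fraction)
        if down
        else np.zeros(expr.shape[1])
    )

    if method == "ssgsea":
        pooled = np.concatenate([es_up, es_dn]) if down else es_up
        normed = ssgsea_normalize(pooled)
        nes_up = normed[: len(es_up)]
        nes_dn = normed[len(es_up):] if down else np.zeros_like(es_up)
    else:
        nes_up, nes_dn = es_up, es_dn

    table = pd.DataFrame(
        {
            "ES_up": es_up,
            "ES_dn": es_dn,
            "NES_UP": nes_up,
            "NES_DN": nes_dn,
            "risk": nes_up - nes_dn,
        },
        index=pd.Index(expr.columns, name="id"),
    )
    return ScoreTable(table, method, params)


def score_many(
    expr: ExpressionMatrix,
    signatures: Sequence[GeneSignature],
    method: Method = "ssgsea",
    alpha: float = DEFAULT_ALPHA,
    max_rank_fraction: float = DEFAULT_MAX_RANK_FRACTION,
) -> tuple[dict[str, ScoreTable], dict[str, str]]:
    """Score several signatures independently (normalization never pools
    across signatures). Per-signature failures are collected, not raised."""
    if not signatures:
        raise ValidationError("no signatures given")
    results: dict[str, ScoreTable] = {}
    failures: dict[str, str] = {}
    for sig in signatures:
        try:
            results[sig.name] = risk_score(
                expr, sig, method=method, alpha=alpha, max_rank_fraction=max_rank_fraction
            )
        except ValidationError as exc:
            failures[sig.name] = str(exc)
    return results, failures


def write_scores(table: ScoreTable, path, id_label: str = "id") -> None:
    table.scores.to_csv(path, sep="\t", index_label=id_label)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
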