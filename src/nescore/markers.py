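"""Derivation of neuroendocrine signature genes from single-cell evidence.

The derivation pipeline mirrors the signature-construction workflow for
neuroendocrine prostate cancer (NEPC):

1. QC-filter cells (<250 detected genes, <500 transcripts, or >20%
   mitochondrial content are removed) and drop excluded / high-dropout genes.
2. Aggregate cells to per-sample pseudobulk and test NEPC samples against
   the rest with a Wilcoxon rank-sum test (Bonferroni-corrected).
3. Intersect the passing differentially expressed genes with independent
   evidence streams (published marker meta-sets, co-expression module gene
   lists) to obtain the NE feature genes (NE_FG role).
4. Thin NE_FG against cell-level NE-vs-rest markers, keeping up genes
   detected in more than 20% of NE cells, yielding the final up/down
   signature (NE_UP / NE_DN role).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .containers import Annotation, ExpressionMatrix, GeneSignature, ValidationError

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["avg_log2FC", "p_val", "p_val_adj", "pct_in", "pct_out", "direction"]

# full enumeration of group assignments is tie-safe but factorial; beyond
# this per-group size the tie-corrected normal approximation takes over
EXACT_MAX_GROUP = 8


# ---------------------------------------------------------------------------
# QC and gene filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_removed: int
    removed_low_genes: int
    removed_low_counts: int
    removed_high_mito: int
    removed_ids: list[str] = field(default_factory=list)


def qc_filter_cells(
    counts: ExpressionMatrix,
    mito_prefix: str | Sequence[str] = ("MT-", "mt-"),
    min_genes: int = 250,
    min_counts: int = 500,
    max_mito: float = 0.20,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells.

    A cell is removed when it has fewer than ``min_genes`` detected genes,
    fewer than ``min_counts`` transcripts, or more than ``max_mito``
    mitochondrial content. Thresholds are strict on the removal side: a
    cell at exactly 250 genes, 500 counts and 20.0% mito is retained.
    Mitochondrial genes are recognized by symbol prefix, which keeps the
    rule species-portable (MT- for human, mt- for mouse).
    """
    if counts.kind != "counts":
        raise ValidationError(f"qc_filter_cells needs kind=counts, got {counts.kind}")
    prefixes = (mito_prefix,) if isinstance(mito_prefix, str) else tuple(mito_prefix)
    x = counts.values.to_numpy()
    n_detected = (x > 0).sum(axis=0)
    n_transcripts = x.sum(axis=0)
    is_mito = np.array([g.startswith(prefixes) for g in counts.genes])
    mito_counts = x[is_mito].sum(axis=0) if is_mito.any() else np.zeros(x.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_transcripts > 0, mito_counts / n_transcripts, 0.0)

    low_genes = n_detected < min_genes
    low_counts = n_transcripts < min_counts
    high_mito = mito_frac > max_mito
    fail = low_genes | low_counts | high_mito
    keep = [c for c, f in zip(counts.columns, fail) if not f]
    if not keep:
        raise ValidationError("no cell survives QC")
    report = QCReport(
        n_input=len(counts.columns),
        n_removed=int(fail.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_low_counts=int(low_counts.sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_ids=[c for c, f in zip(counts.columns, fail) if f],
    )
    return counts.subset_columns(keep), report


def filter_genes(
    expr: ExpressionMatrix,
    exclude_lists: Sequence[Sequence[str]] = (),
    min_cells_fraction: float = 0.001,
) -> ExpressionMatrix:
    """Drop excluded genes (e.g. mitochondrial / ribosomal lists) and genes
    detected in fewer than ``min_cells_fraction`` of columns (high-dropout)."""
    excluded: set[str] = set()
    for lst in exclude_lists:
        excluded |= set(lst)
    detect_frac = (expr.values.to_numpy() > 0).mean(axis=1)
    keep = [
        g
        for g, f in zip(expr.genes, detect_frac)
        if g not in excluded and not f < min_cells_fraction
    ]
    return ExpressionMatrix(expr.values.loc[keep].copy(), expr.kind)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk_aggregate(
    counts: ExpressionMatrix, annotation: Annotation, group_by: str = "sample_id"
) -> ExpressionMatrix:
    """Sum cell counts per group; column order follows first appearance."""
    ann = annotation.table
    missing = [c for c in counts.columns if c not in ann.index or pd.isna(ann.loc[c, group_by])]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells without a {group_by!r} annotation, e.g. {missing[:5]}"
        )
    groups = ann.loc[counts.columns, group_by].astype(str)
    order = list(dict.fromkeys(groups))
    agg = counts.values.T.groupby(groups.values, sort=False).sum().T
    agg = agg.loc[:, order]
    return ExpressionMatrix(agg, counts.kind)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

def _adjust_p(p: np.ndarray, method: Literal["bonferroni", "bh"]) -> np.ndarray:
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        return np.minimum(adj, 1.0)
    raise ValidationError(f"unknown correction {method!r}")


def _exact_rank_sum_p(xa: np.ndarray, xb: np.ndarray, combos: np.ndarray) -> float:
    """Two-sided p by full enumeration of group assignments (tie-safe)."""
    ranks = rankdata(np.concatenate([xa, xb]))
    w_obs = ranks[: len(xa)].sum()
    w_null = ranks[combos].sum(axis=1)
    eps = 1e-9
    p_lo = np.mean(w_null <= w_obs + eps)
    p_hi = np.mean(w_null >= w_obs - eps)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def _normal_rank_sum_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Two-sided p, normal approximation with tie and continuity correction."""
    na, nb = len(xa), len(xb)
    n = na + nb
    combined = np.concatenate([xa, xb])
    ranks = rankdata(combined)
    w = ranks[:na].sum()
    mean_w = na * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    d = w - mean_w
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var_w) if d != 0 else 0.0
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_de(
    expr: ExpressionMatrix,
    annotation: Annotation,
    group_col: str,
    group_a: str,
    group_b: str | None = None,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test of group A vs group B.

    ``group_b=None`` contrasts A against all other annotated columns.
    Fold changes follow the single-cell marker-testing convention:
    ``avg_log2FC = log2(mean(2^x - 1 over A) + 1) - log2(mean over B ...)``
    computed on log2(x+1)-scale data (counts/TPM inputs are transformed
    first). ``pct_in`` / ``pct_out`` are the nonzero detection fractions.
    Exact enumeration of the rank-sum null is used when both groups have
    <= 8 members; larger groups use the tie- and continuity-corrected
    normal approximation.
    """
    if expr.kind != "log":
        logger.info("wilcoxon_de: applying log2(x+1) to kind=%s input", expr.kind)
        expr = expr.to_log()
    groups = annotation.column(group_col, expr.columns).astype(str)
    a_cols = [c for c, g in groups.items() if g == str(group_a)]
    if group_b is None:
        b_cols = [c for c, g in groups.items() if g != str(group_a)]
    else:
        b_cols = [c for c, g in groups.items() if g == str(group_b)]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValidationError(
            f"need >=2 columns per group, got {len(a_cols)} vs {len(b_cols)}"
        )

    xa = expr.values[a_cols].to_numpy()
    xb = expr.values[b_cols].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]

    mean_a = np.expm1(xa * np.log(2)).mean(axis=1)  # de-logged group means
    mean_b = np.expm1(xb * np.log(2)).mean(axis=1)
    lfc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    pct_in = (xa > 0).mean(axis=1)
    pct_out = (xb > 0).mean(axis=1)

    exact = na <= EXACT_MAX_GROUP and nb <= EXACT_MAX_GROUP
    combos = (
        np.array(list(itertools.combinations(range(na + nb), na))) if exact else None
    )
    p = np.array(
        [
            _exact_rank_sum_p(xa[i], xb[i], combos)
            if exact
            else _normal_rank_sum_p(xa[i], xb[i])
            for i in range(xa.shape[0])
        ]
    )
    table = pd.DataFrame(
        {
            "avg_log2FC": lfc,
            "p_val": p,
            "p_val_adj": _adjust_p(p, correction),
            "pct_in": pct_in,
            "pct_out": pct_out,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=pd.Index(expr.genes, name="gene"),
    )
    return table


# ---------------------------------------------------------------------------
# evidence intersection
# ---------------------------------------------------------------------------

@dataclass
class EvidenceSet:
    """The three evidence streams feeding the feature-gene intersection."""

    pseudobulk_degs: pd.DataFrame  # MarkerTable from pseudobulk DE
    meta_markers: set[str] = field(default_factory=set)  # published marker union
    module_genes: set[str] = field(default_factory=set)  # co-expression modules


def derive_ne_fg(
    evidence: EvidenceSet,
    lfc_threshold: float = 0.5,
    p_adj_threshold: float = 0.01,
    support_min: int = 1,
) -> GeneSignature:
    """Feature genes: passing pseudobulk DEGs supported by other evidence.

    A gene enters the up (down) list when its pseudobulk |avg_log2FC| >=
    ``lfc_threshold`` with adjusted p < ``p_adj_threshold`` and at least
    ``support_min`` of the other streams (marker meta-set, module genes)
    also contain it. Per-gene provenance is kept in the signature metadata.
    """
    degs = evidence.pseudobulk_degs
    passing = degs[
        (degs["avg_log2FC"].abs() >= lfc_threshold)
        & (degs["p_val_adj"] < p_adj_threshold)
    ]
    provenance: dict[str, list[str]] = {}
    up, down = [], []
    for gene, row in passing.iterrows():
        streams = ["pseudobulk"]
        if gene in evidence.meta_markers:
            streams.append("meta_markers")
        if gene in evidence.module_genes:
            streams.append("module_genes")
        if len(streams) - 1 < support_min:
            continue
        provenance[gene] = streams
        (up if row["avg_log2FC"] > 0 else down).append(gene)
    if not up:
        raise ValidationError(
            "no up-regulated feature gene survives the intersection; "
            "consider relaxing lfc/p_adj thresholds or support_min"
        )
    sig = GeneSignature(name="NE_FG", up=up, down=down)
    sig.metadata["provenance"] = provenance
    return sig


def thin_signature(
    ne_fg: GeneSignature,
    celltype_markers: pd.DataFrame,
    lfc_threshold: float = 0.5,
    p_adj_threshold: float = 0.01,
    min_pct: float = 0.20,
) -> GeneSignature:
    """Thin feature genes to cell-intrinsic markers.

    Up genes must be cell-level up markers of the NE population detected in
    more than ``min_pct`` of NE cells (intrinsic detectability); down genes
    must be cell-level down markers — no detection floor, since genes lost
    in NE cells are lowly detected there by construction.
    """
    cm = celltype_markers
    sig_ok = cm["p_val_adj"] < p_adj_threshold
    up_ok = cm.index[sig_ok & (cm["avg_log2FC"] >= lfc_threshold) & (cm["pct_in"] > min_pct)]
    dn_ok = cm.index[sig_ok & (cm["avg_log2FC"] <= -lfc_threshold)]
    up = [g for g in ne_fg.up if g in set(up_ok)]
    down = [g for g in ne_fg.down if g in set(dn_ok)]
    if not up:
        raise ValidationError("thinned up signature is empty")
    return GeneSignature(name="NE_UP_DN", up=up, down=down, species=ne_fg.species)
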