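"""Readers and writers for GMT gene sets, expression matrices and annotations.

Formats supported at the boundary:

* GMT — tab-separated, one gene set per line: name, description, genes...
* dense TSV/CSV — gene symbol in the first column, one column per sample/cell
* MatrixMarket triplet directory — ``matrix.mtx`` + ``features.tsv`` (or
  ``genes.tsv``) + ``barcodes.tsv``, 1-based indices per the standard
* annotation TSV with a header and the column ID in the first field
* 2-column ortholog map TSV (human_symbol, mouse_symbol)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    Annotation,
    ExpressionMatrix,
    GeneSignature,
    MatrixKind,
    ValidationError,
    canonical_symbols,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> tuple[list[GeneSignature], int]:
    """Parse a GMT file into signatures (up lists only).

    Returns (signatures, n_duplicates_removed). Duplicate genes within a
    line are removed keeping first occurrence.
    """
    sigs: list[GeneSignature] = []
    n_dups = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            genes = [g for g in canonical_symbols(fields[2:]) if g]
            deduped = list(dict.fromkeys(genes))
            n_dups += len(genes) - len(deduped)
            sigs.append(GeneSignature(name=name, up=deduped))
    if n_dups:
        logger.warning("read_gmt(%s): removed %d duplicate genes", path, n_dups)
    return sigs, n_dups


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    """Write up lists as GMT; a non-empty down list goes out as NAME_DN."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.up]) + "\n")
            if sig.down:
                fh.write("\t".join([f"{sig.name}_DN", "na", *sig.down]) + "\n")


def _read_gene_list(source: str | Path | Sequence[str]) -> list[str]:
    if isinstance(source, (str, Path)) and Path(source).exists():
        lines = Path(source).read_text().splitlines()
        return [g for g in canonical_symbols(lines) if g]
    if isinstance(source, (list, tuple)):
        return [g for g in canonical_symbols(source) if g]
    raise ParseError(f"cannot resolve gene list source {source!r}")


def read_signature_pair(
    up: str | Path | Sequence[str],
    down: str | Path | Sequence[str] | None = None,
    name: str = "signature",
    species: str = "human",
) -> GeneSignature:
    """Combine an up list and an optional down list into one signature.

    Overlapping symbols are a hard error: a gene cannot be evidence for and
    against the same program.
    """
    up_genes = _read_gene_list(up)
    down_genes = _read_gene_list(down) if down is not None else []
    return GeneSignature(name=name, up=up_genes, down=down_genes, species=species)  # validates


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def collapse_duplicate_genes(values: pd.DataFrame, kind: MatrixKind) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate gene rows: sum for counts/tpm, max for log scale."""
    values.index = pd.Index(canonical_symbols(values.index), name="gene")
    n_dup = int(values.index.duplicated().sum())
    if n_dup:
        how = "sum" if kind in ("counts", "tpm") else "max"
        values = values.groupby(level=0, sort=False).agg(how)
        logger.info("collapsed %d duplicate gene rows by %s", n_dup, how)
    return values, n_dup


def read_expression(
    path: str | Path,
    format: Literal["tsv", "csv", "mtx_dir"] = "tsv",
    kind: MatrixKind = "tpm",
) -> ExpressionMatrix:
    """Read a genes x columns matrix from dense text or an MTX triplet dir."""
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.columns = df.columns.astype(str)
    elif format == "mtx_dir":
        df = _read_mtx_dir(path)
    else:
        raise ParseError(f"unknown expression format {format!r}")
    df, _ = collapse_duplicate_genes(df, kind)
    return ExpressionMatrix(df.astype(float), kind)


def _find_one(directory: Path, candidates: Sequence[str]) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise ParseError(f"{directory}: none of {candidates} found")


def _read_mtx_dir(directory: Path) -> pd.DataFrame:
    mtx = _find_one(directory, ["matrix.mtx"])
    feats = _find_one(directory, ["features.tsv", "genes.tsv"])
    bcs = _find_one(directory, ["barcodes.tsv"])
    mat = scipy.io.mmread(mtx)  # 1-based on disk, 0-based in memory
    genes = [ln.split("\t")[0].strip() for ln in feats.read_text().splitlines() if ln.strip()]
    barcodes = [ln.strip() for ln in bcs.read_text().splitlines() if ln.strip()]
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise ParseError(
            f"{directory}: matrix is {mat.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    return pd.DataFrame(mat.toarray(), index=genes, columns=barcodes)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    sep = "\t" if format == "tsv" else ","
    expr.values.to_csv(path, sep=sep, index_label="gene")


def write_mtx_dir(expr: ExpressionMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.coo_matrix(expr.values.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp)
    (directory / "features.tsv").write_text("".join(f"{g}\n" for g in expr.genes))
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in expr.columns))


# ---------------------------------------------------------------------------
# annotations / ortholog maps
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> Annotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Annotation(df)


def write_annotation(ann: Annotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="id")


def read_ortholog_table(path: str | Path) -> dict[str, str]:
    """2-column TSV (human_symbol, mouse_symbol) -> mapping dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog table needs 2 columns")
    return dict(zip(canonical_symbols(df.iloc[:, 0]), canonical_symbols(df.iloc[:, 1])))


def _heuristic_ortholog(symbol: str, to_species: str) -> str:
    # human symbols are ALL-CAPS, mouse are Title-case (Chga <-> CHGA)
    return symbol.upper() if to_species == "human" else symbol.capitalize()


def map_orthologs(
    sig: GeneSignature,
    to_species: str,
    table: Mapping[str, str] | None = None,
) -> GeneSignature:
    """Translate a signature across species.

    With a table (keyed by source symbols), unmapped genes are dropped and
    counted; without one the capitalization heuristic is applied to every
    gene. More than 50% of the up list unmapped is a hard error — the
    signature would no longer measure what it was built to measure.
    """
    if to_species == sig.species:
        return sig

    def translate(genes: list[str]) -> tuple[list[str], int]:
        out, dropped = [], 0
        for g in genes:
            if table is not None:
                if g in table:
                    out.append(table[g])
                else:
                    dropped += 1
            else:
                out.append(_heuristic_ortholog(g, to_species))
        return list(dict.fromkeys(out)), dropped

    up, up_dropped = translate(sig.up)
    down, down_dropped = translate(sig.down)
    if len(sig.up) and up_dropped / len(sig.up) > 0.5:
        raise ValidationError(
            f"ortholog mapping dropped {up_dropped}/{len(sig.up)} up genes "
            "(>50%); signature unusable for the target species"
        )
    if up_dropped or down_dropped:
        logger.warning(
            "map_orthologs(%s): dropped %d up / %d down unmapped genes",
            sig.name, up_dropped, down_dropped,
        )
    mapped = GeneSignature(name=sig.name, up=up, down=down, species=to_species)  # type: ignore[arg-type]
    mapped.metadata["unmapped_up"] = up_dropped
    mapped.metadata["unmapped_down"] = down_dropped
    return mapped


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def tpm_from_counts(
    counts: ExpressionMatrix, gene_lengths_kb: Mapping[str, float]
) -> ExpressionMatrix:
    """Counts -> transcripts per million given effective lengths in kb.

    TPM_g = 1e6 * (c_g / len_g) / sum_g'(c_g' / len_g'); genes without a
    length are dropped with a warning, every output column sums to 1e6.
    """
    if counts.kind != "counts":
        raise ValidationError(f"tpm_from_counts needs kind=counts, got {counts.kind}")
    have = [g for g in counts.genes if g in gene_lengths_kb]
    dropped = counts.shape[0] - len(have)
    if dropped:
        logger.warning("tpm_from_counts: dropped %d genes without a length", dropped)
    if not have:
        raise ValidationError("no gene has a supplied length")
    lengths = np.array([gene_lengths_kb[g] for g in have], dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    rate = counts.values.loc[have].to_numpy() / lengths[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = [c for c, s in zip(counts.columns, colsum) if s == 0]
        raise ValidationError(f"all-zero columns after length scaling: {bad[:5]}")
    tpm = 1e6 * rate / colsum
    return ExpressionMatrix(pd.DataFrame(tpm, index=have, columns=counts.columns), "tpm")
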