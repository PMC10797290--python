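"""Core in-memory containers: gene signatures, expression matrices, annotations.

Gene symbols are matched case-sensitively after whitespace trimming;
cross-species use goes through :func:`nescore.io.map_orthologs` rather than
case-folding, so human/mouse symbols never collide silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Species = Literal["human", "mouse"]
MatrixKind = Literal["counts", "tpm", "log"]


class ValidationError(ValueError):
    """Input data violates a contract (bad values, inconsistent dims, ...)."""


def canonical_symbols(symbols: Iterable[str]) -> list[str]:
    """Trim whitespace, preserve case, preserve order."""
    return [str(s).strip() for s in symbols]


def _dedupe_ordered(symbols: Iterable[str]) -> tuple[list[str], int]:
    seen: set[str] = set()
    out: list[str] = []
    dups = 0
    for s in symbols:
        if s in seen:
            dups += 1
        else:
            seen.add(s)
            out.append(s)
    return out, dups


@dataclass
class GeneSignature:
    """A named up/down gene list pair.

    ``up`` must be non-empty and disjoint from ``down``; ``down`` may be
    empty, in which case downstream risk scores reduce to the up-score alone.
    """

    name: str
    up: list[str]
    down: list[str] = field(default_factory=list)
    species: Species = "human"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up, _ = _dedupe_ordered(canonical_symbols(self.up))
        self.down, _ = _dedupe_ordered(canonical_symbols(self.down))
        if not self.up:
            raise ValidationError(f"signature {self.name!r}: up gene list is empty")
        overlap = sorted(set(self.up) & set(self.down))
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: genes in both up and down lists: "
                + ", ".join(overlap)
            )

    def swapped(self) -> "GeneSignature":
        """Signature with up and down lists exchanged (down must be non-empty)."""
        return GeneSignature(
            name=f"{self.name}_swapped", up=list(self.down), down=list(self.up),
            species=self.species,
        )


@dataclass
class ExpressionMatrix:
    """Dense genes x columns expression values with a declared scale.

    ``kind`` is declared by the caller, never auto-detected: 'counts' and
    'tpm' must be non-negative; 'log' means log2(x+1) of TPM or normalized
    counts. A declared-tpm matrix whose maximum is < 50 is rejected as
    probably already logged.
    """

    values: pd.DataFrame  # index = gene symbols, columns = sample/cell IDs
    kind: MatrixKind

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "tpm", "log"):
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = pd.Index(canonical_symbols(self.values.index), name="gene")
        if self.values.index.has_duplicates:
            raise ValidationError(
                "duplicate gene symbols after canonicalization; collapse first "
                "(see nescore.io.collapse_duplicate_genes)"
            )
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.kind in ("counts", "tpm") and arr.size and arr.min() < 0:
            raise ValidationError(f"negative values in a kind={self.kind} matrix")
        if self.kind == "tpm" and arr.size and arr.max() < 50:
            raise ValidationError(
                "declared kind=tpm but max value < 50 — matrix looks already "
                "log-transformed; declare kind='log' if so"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(columns)].copy(), self.kind)

    def to_log(self) -> "ExpressionMatrix":
        """log2(x+1) transform; identity if already log-scale."""
        if self.kind == "log":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), "log")


@dataclass
class Annotation:
    """Per-column attributes (cell type, sample, labels, survival)."""

    table: pd.DataFrame  # index = column IDs

    TIME_COL = "time"
    EVENT_COL = "event"

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        self.table.index = self.table.index.astype(str)
        if self.EVENT_COL in self.table.columns:
            ev = self.table[self.EVENT_COL].dropna()
            if not ev.isin([0, 1]).all():
                raise ValidationError("event flag must be 0 or 1")
            if self.TIME_COL in self.table.columns:
                t = self.table.loc[ev.index, self.TIME_COL]
                if (t <= 0).any():
                    raise ValidationError("survival time must be > 0 where event is recorded")

    def ids(self) -> list[str]:
        return list(self.table.index)

    def check_covers(self, expr: ExpressionMatrix) -> None:
        missing = set(expr.columns) - set(self.table.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} matrix columns missing from annotation, "
                f"e.g. {sorted(missing)[:5]}"
            )

    def column(self, name: str, ids: Sequence[str] | None = None) -> pd.Series:
        s = self.table[name]
        return s.loc[list(ids)] if ids is not None else s
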