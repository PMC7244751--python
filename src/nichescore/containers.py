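"""In-memory containers for counts, annotations, gene sets and interactions.

Gene and cell identifiers are opaque strings throughout: the package does
no species mapping or symbol/accession conversion, so all resources handed
to it must already share one namespace with the expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """An input artifact violated a container invariant."""


# required CellMetadata columns; alignment_pct is optional (its QC filter
# is skipped with a warning when absent)
METADATA_REQUIRED = ("cell_id", "time_point", "cell_type", "subtype",
                     "n_genes_detected", "n_umi")
METADATA_OPTIONAL = ("alignment_pct",)


def _check_unique(ids: np.ndarray, kind: str) -> None:
    values, counts = np.unique(ids, return_counts=True)
    dup = values[counts > 1]
    if dup.size:
        raise ValidationError(f"duplicate {kind} id(s): {', '.join(map(str, dup[:5]))}")


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer UMI counts."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.validate()

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        coo = self.counts.tocoo()
        bad = np.flatnonzero((coo.data < 0) | (coo.data != np.floor(coo.data)))
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"negative or non-integer count {coo.data[i]} at "
                f"(row {coo.row[i]}, col {coo.col[i]}) "
                f"[gene {self.gene_ids[coo.row[i]]}, cell {self.cell_ids[coo.col[i]]}]"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def total(self) -> int:
        return int(self.counts.sum())

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_detected_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix with genes selected by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(self.gene_ids[keep], self.cell_ids, self.counts[keep, :])

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(self.gene_ids, self.cell_ids[keep], self.counts[:, keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.gene_ids,
                            columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Gene x cell matrix of natural-log normalized expression values.

    Values are ln(1 + count/total * size_factor); back-transforming with
    expm1 and summing over genes recovers the size factor for every cell.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csr_matrix
    size_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        if not np.all(np.isfinite(self.values.data)):
            raise ValidationError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)


class GeneSetCollection:
    """Named gene sets (GMT semantics): set_id -> (description, members)."""

    def __init__(self, sets: Mapping[str, tuple[str, Iterable[str]]] | None = None):
        self._sets: dict[str, tuple[str, tuple[str, ...]]] = {}
        if sets:
            for sid, (desc, members) in sets.items():
                self.add(sid, desc, members)

    def add(self, set_id: str, description: str, members: Iterable[str]) -> None:
        if set_id in self._sets:
            raise ValidationError(f"duplicate set id: {set_id}")
        seen: dict[str, None] = dict.fromkeys(members)  # order-preserving dedup
        if not seen:
            raise ValidationError(f"gene set {set_id} has no members")
        self._sets[set_id] = (description, tuple(seen))

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)

    def description(self, set_id: str) -> str:
        return self._sets[set_id][0]

    def members(self, set_id: str) -> tuple[str, ...]:
        return self._sets[set_id][1]

    def sets_containing(self, gene: str) -> list[str]:
        return [sid for sid in self._sets if gene in self._sets[sid][1]]

    def all_member_genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self._sets.values():
            out.update(members)
        return out


@dataclass
class AnnotationLists:
    """Curated gene lists: secretome, membrane proteome, mitochondrial genes
    and housekeeping controls (gene -> category label)."""

    secreted: set = field(default_factory=set)
    membrane: set = field(default_factory=set)
    mitochondrial: set = field(default_factory=set)
    housekeeping: dict = field(default_factory=dict)

    def housekeeping_category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cat in self.housekeeping.values():
            sizes[cat] = sizes.get(cat, 0) + 1
        return sizes


class InteractionLibrary:
    """Unordered protein-protein interaction pairs with evidence scores.

    Lookup is symmetric: contains(a, b) == contains(b, a).
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = (),
                 allow_self: bool = False):
        self._scores: dict[tuple[str, str], float] = {}
        self.allow_self = allow_self
        for a, b, score in pairs:
            self.add(a, b, score)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float) -> None:
        if a == b and not self.allow_self:
            raise ValidationError(f"self-interaction not allowed: {a}")
        if score < 0:
            raise ValidationError(f"negative evidence score for ({a}, {b})")
        key = self._key(a, b)
        self._scores[key] = max(score, self._scores.get(key, 0.0))

    def contains(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._scores

    __contains__ = lambda self, pair: self.contains(*pair)  # noqa: E731

    def score(self, a: str, b: str) -> float:
        return self._scores[self._key(a, b)]

    def __len__(self) -> int:
        return len(self._scores)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._scores)

    def partners(self, gene: str) -> set[str]:
        out = set()
        for a, b in self._scores:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


def validate_metadata(metadata: pd.DataFrame,
                      counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check the per-cell metadata table against its invariants.

    One row per cell_id; alignment_pct (if present) within [0, 100]; when a
    CountMatrix is given, its cells must all be covered by the table.
    """
    missing = [c for c in METADATA_REQUIRED if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
    dup = metadata["cell_id"][metadata["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell_id in metadata: {dup.iloc[0]}")
    if "alignment_pct" in metadata.columns:
        a = metadata["alignment_pct"].astype(float)
        if ((a < 0) | (a > 100)).any():
            bad = metadata.loc[(a < 0) | (a > 100), "cell_id"].iloc[0]
            raise ValidationError(f"alignment_pct outside [0, 100] for cell {bad}")
    if counts is not None:
        uncovered = set(counts.cell_ids) - set(metadata["cell_id"])
        if uncovered:
            raise ValidationError(
                f"metadata does not cover cell(s): {sorted(uncovered)[:5]}")
    return metadata
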