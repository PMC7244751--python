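"""Count-matrix quality control and TPM-like log normalization.

Cell filters, applied in order to the metadata QC covariates:

1. at least 500 genes detected (inclusive),
2. genome alignment percentage strictly over 50,
3. distinct UMI count strictly below 1e6,
4. UMI count within mean +/- 2 sample SD, the window being computed over
   the cells that survive filters 1-3 (extreme cells would otherwise
   distort the very window meant to exclude them).

Gene filters: mitochondrial genes are dropped outright; remaining genes
must be detected (count > 0) in at least 10 cells.

Normalization: each count is divided by the cell's total UMIs, scaled by
a fixed size factor (10,000) and transformed with the natural logarithm
as ln(1 + x), so zeros stay finite and the back-transformed per-cell sum
equals the size factor exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from nichescore.containers import CountMatrix, NormalizedMatrix, validate_metadata

log = logging.getLogger(__name__)


@dataclass
class QCParams:
    min_genes_per_cell: int = 500        # inclusive
    min_cells_per_gene: int = 10         # inclusive
    min_alignment_pct: float = 50.0      # strict >
    max_umi: float = 1e6                 # strict <
    umi_sd_window: float = 2.0           # mean +/- k * sample SD
    size_factor: float = 10_000.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"QCParams.{name} must be > 0, got {value}")


@dataclass
class QCReport:
    """Per-rule removal bookkeeping for one filter_cells run."""

    n_cells_in: int = 0
    n_cells_out: int = 0
    removed: dict = field(default_factory=dict)
    boundary_conventions: tuple = (
        "min_genes inclusive (>= threshold kept)",
        "alignment strict (> threshold kept)",
        "max_umi strict (< threshold kept)",
        "UMI window mean +/- k * sample SD over cells surviving rules 1-3",
    )
    warnings: list = field(default_factory=list)

    def total_removed(self) -> int:
        return sum(self.removed.values())


def filter_cells(counts: CountMatrix, metadata: pd.DataFrame,
                 params: QCParams | None = None
                 ) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Apply the four cell-level QC rules in order.

    Returns the filtered matrix, the filtered metadata (same row order)
    and a QCReport with per-rule removal counts. Raises if no cell
    survives. When ``alignment_pct`` is absent from the metadata that
    rule is skipped with a logged warning.
    """
    params = params or QCParams()
    metadata = validate_metadata(metadata, counts)
    meta = metadata.set_index("cell_id").loc[list(counts.cell_ids)].reset_index()
    report = QCReport(n_cells_in=counts.n_cells)

    keep = np.ones(counts.n_cells, dtype=bool)

    n_genes = meta["n_genes_detected"].to_numpy(dtype=float)
    fail = keep & (n_genes < params.min_genes_per_cell)
    report.removed["min_genes"] = int(fail.sum())
    keep &= ~fail

    if "alignment_pct" in meta.columns:
        align = meta["alignment_pct"].to_numpy(dtype=float)
        fail = keep & ~(align > params.min_alignment_pct)
        report.removed["alignment"] = int(fail.sum())
        keep &= ~fail
    else:
        report.removed["alignment"] = 0
        report.warnings.append("alignment_pct absent; alignment filter skipped")
        log.warning("alignment_pct absent from metadata; alignment filter skipped")

    umi = meta["n_umi"].to_numpy(dtype=float)
    fail = keep & ~(umi < params.max_umi)
    report.removed["max_umi"] = int(fail.sum())
    keep &= ~fail

    # window over survivors of rules 1-3, sample SD (n-1)
    surviving_umi = umi[keep]
    if surviving_umi.size >= 2:
        mean = surviving_umi.mean()
        sd = surviving_umi.std(ddof=1)
        lo = mean - params.umi_sd_window * sd
        hi = mean + params.umi_sd_window * sd
        fail = keep & ((umi < lo) | (umi > hi))
        report.removed["umi_window"] = int(fail.sum())
        keep &= ~fail
    else:
        report.removed["umi_window"] = 0

    if not keep.any():
        raise ValueError("empty after QC: no cell survived the cell filters")

    report.n_cells_out = int(keep.sum())
    return counts.subset_cells(keep), meta.loc[keep].reset_index(drop=True), report


def filter_genes(counts: CountMatrix, mito_list=(),
                 min_cells: int = 10) -> CountMatrix:
    """Drop mitochondrial genes and genes detected in fewer than
    ``min_cells`` cells (inclusive keep at the boundary)."""
    mito = set(mito_list)
    detected = counts.cells_detected_per_gene()
    keep = np.array([g not in mito for g in counts.gene_ids]) & (detected >= min_cells)
    if not keep.any():
        log.warning("gene filtering removed every gene")
    return counts.subset_genes(keep)


def normalize(counts: CountMatrix, size_factor: float = 10_000.0) -> NormalizedMatrix:
    """TPM-like normalization: value = ln(1 + count/total * size_factor)."""
    totals = counts.cell_totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {counts.cell_ids[zero[0]]} has zero total UMIs; "
            "cannot normalize")
    mat = counts.counts.tocsc().astype(float)
    scale = size_factor / totals
    mat = mat.multiply(sp.csr_matrix(scale.reshape(1, -1))).tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(counts.gene_ids, counts.cell_ids, mat,
                            size_factor=size_factor)
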