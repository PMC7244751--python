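"""One-vs-rest (or cluster-vs-cluster) Wilcoxon marker detection.

Semantics follow the common single-cell convention the thresholds were
defined in: detection-fraction screen ``max(pct_in, pct_out) >= min_pct``,
log-fold-change screen on natural-log units computed as
``ln(mean(expm1(x)) + 1) - ln(mean(expm1(y)) + 1)`` over normalized
values, a two-sided Wilcoxon rank-sum test with midranks, tie-corrected
variance and continuity correction, and BH (default) or Bonferroni
adjustment over the genes actually tested within one contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nichescore.containers import NormalizedMatrix


@dataclass
class MarkerParams:
    min_pct: float = 0.2
    logfc_threshold: float = 0.2      # natural-log units
    only_positive: bool = True
    q_cutoff: float = 0.05
    adjust_method: str = "BH"         # "BH" or "bonferroni"

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValueError(f"min_pct must be in [0, 1], got {self.min_pct}")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be >= 0")
        if self.adjust_method not in ("BH", "bonferroni"):
            raise ValueError(f"unknown adjust_method: {self.adjust_method}")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of ``x`` (midranks for ties) and the
    two-sided p-value from the normal approximation with tie-corrected
    variance and continuity correction. Degenerate data (all pooled
    values identical) yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    n1 = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    if np.ptp(np.concatenate([x, y])) == 0:
        return w, 1.0
    u1 = w - n1 * (n1 + 1) / 2.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    assert np.isclose(res.statistic, u1)
    return w, float(res.pvalue)


def _wilcoxon_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Wilcoxon p-values for x (n1, G) vs y (n2, G)."""
    pooled = np.concatenate([x, y], axis=0)
    degenerate = np.ptp(pooled, axis=0) == 0
    p = np.ones(x.shape[1])
    if (~degenerate).any():
        res = stats.mannwhitneyu(x[:, ~degenerate], y[:, ~degenerate],
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True, axis=0)
        p[~degenerate] = res.pvalue
    return p


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError(f"unknown adjustment method: {method}")


def _log_mean_expm1(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(values[:, mask]).mean(axis=1) + 1.0)


def find_markers(norm: NormalizedMatrix, labels, params: MarkerParams | None = None,
                 groups=None, reference: str = "rest") -> pd.DataFrame:
    """Marker table for each target cluster against the rest (or one
    reference cluster).

    Parameters
    ----------
    norm : normalized expression matrix.
    labels : cluster label per cell, aligned with ``norm.cell_ids``.
    groups : target cluster(s); default all clusters in ``labels``.
    reference : ``"rest"`` or a specific cluster label.

    Returns a MarkerTable DataFrame with columns gene, cluster, log_fc,
    pct_in, pct_out, p_value, q_value, significant. Only genes passing the
    detection-fraction and log-fold-change screens are tested and
    reported; q-values are adjusted per contrast over the tested genes.
    """
    params = params or MarkerParams()
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("labels length does not match number of cells")
    present = pd.unique(labels)
    if len(present) < 2:
        raise ValueError("at least two clusters are required")
    if groups is None:
        targets = list(present)
    elif isinstance(groups, str):
        targets = [groups]
    else:
        targets = list(groups)
    for g in targets:
        if (labels == g).sum() == 0:
            raise ValueError(f"cluster {g!r} has no cells")
    if reference != "rest" and (labels == reference).sum() == 0:
        raise ValueError(f"reference cluster {reference!r} has no cells")

    X = norm.dense()
    rows = []
    for g in targets:
        in_mask = labels == g
        out_mask = (labels != g) if reference == "rest" else (labels == reference)
        if not out_mask.any():
            raise ValueError(f"no reference cells for cluster {g!r}")
        pct_in = (X[:, in_mask] > 0).mean(axis=1)
        pct_out = (X[:, out_mask] > 0).mean(axis=1)
        log_fc = _log_mean_expm1(X, in_mask) - _log_mean_expm1(X, out_mask)
        screen = np.maximum(pct_in, pct_out) >= params.min_pct
        if params.only_positive:
            screen &= log_fc >= params.logfc_threshold
        else:
            screen &= np.abs(log_fc) >= params.logfc_threshold
        idx = np.flatnonzero(screen)
        if idx.size == 0:
            continue
        p = _wilcoxon_matrix(X[idx][:, in_mask].T, X[idx][:, out_mask].T)
        q = adjust_pvalues(p, params.adjust_method)
        for j, gi in enumerate(idx):
            rows.append((norm.gene_ids[gi], g, log_fc[gi], pct_in[gi],
                         pct_out[gi], p[j], q[j], q[j] < params.q_cutoff))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "log_fc", "pct_in",
                                        "pct_out", "p_value", "q_value",
                                        "significant"])
    if len(table):
        table = table.sort_values(["cluster", "q_value", "gene"],
                                  kind="stable").reset_index(drop=True)
    return table
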