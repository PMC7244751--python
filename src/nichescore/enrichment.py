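"""Hypergeometric over-representation of a gene list against gene sets.

For a universe of N genes, a set covering K of them and a query hitting n
of them with overlap k, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n). Sets disjoint from the universe are
omitted. Significance uses the raw p-value cutoff (default 0.05); BH
q-values are reported alongside.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from nichescore.containers import GeneSetCollection
from nichescore.markers import adjust_pvalues

log = logging.getLogger(__name__)


def hypergeom_enrich(query, sets: GeneSetCollection, universe,
                     p_cutoff: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    Query genes outside the universe are dropped with a warning. Returns
    rows of (set_id, k_overlap, n_query_in_universe, K_set_in_universe,
    N_universe, p_value, q_value, significant, overlap_genes), sorted by
    p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    dropped = query - universe
    if dropped:
        log.warning("%d query gene(s) outside the universe dropped", len(dropped))
    query &= universe
    if not query:
        log.warning("query empty after intersecting with the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for sid in sets.set_ids:
        members = set(sets.members(sid)) & universe
        K = len(members)
        if K == 0:
            continue  # enrichment undefined for sets disjoint from the universe
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sid, k, n, K, N, p, overlap))
    out = pd.DataFrame(rows, columns=["set_id", "k_overlap", "n_query_in_universe",
                                      "K_set_in_universe", "N_universe", "p_value",
                                      "overlap_genes"])
    if len(out):
        out["q_value"] = adjust_pvalues(out["p_value"].to_numpy(), "BH")
        out["significant"] = out["p_value"] < p_cutoff
        out = out.sort_values(["p_value", "set_id"]).reset_index(drop=True)
        out = out[["set_id", "k_overlap", "n_query_in_universe",
                   "K_set_in_universe", "N_universe", "p_value", "q_value",
                   "significant", "overlap_genes"]]
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def maturation_pathways(deg_genes, sets: GeneSetCollection, universe,
                        p_cutoff: float = 0.05) -> list[str]:
    """Gene sets significantly enriched in a maturation-trajectory DEG list.

    The returned set ids serve as the maturation-pathway list for the
    interactome stage; callers may instead supply a curated list directly
    and skip this step.
    """
    result = hypergeom_enrich(deg_genes, sets, universe, p_cutoff=p_cutoff)
    if not len(result):
        log.warning("no enrichable sets; maturation pathway list is empty")
        return []
    return result.loc[result["significant"], "set_id"].tolist()
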