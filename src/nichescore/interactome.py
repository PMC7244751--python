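"""Niche-to-target contribution analysis.

The procedure, given QC'd normalized expression, subtype labels, a marker
table, a composition ChangeTable and annotation resources:

1. restrict to subtypes whose composition changed between the immature
   and mature states;
2. take each changed subtype's specific markers (q below a stringent
   cutoff, default 1e-3) and intersect with the secretome to obtain its
   candidate ligands;
3. keep only ligands that are members of at least one maturation-related
   pathway (bipartite ligand-pathway network; ligands with no edge drop
   out of the "matched" set);
4. rank subtypes by the sum over their matched ligands of the per-gene
   z-score of subtype-mean expression, scaled across the ranked subtypes
   (sample SD; zero-SD genes contribute 0);
5. select target-cell receptors as target-specific markers intersected
   with the membrane list, and count ligand-receptor pairs per subtype
   through the evidence-filtered interaction library.

The z-sum and the pair count are the two contribution read-outs; both are
reported per direction (increased vs decreased subtypes) and jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nichescore.containers import GeneSetCollection, InteractionLibrary, NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class ReceptorSet:
    """Target-cell receptors: target-specific markers on the membrane list."""

    target: str
    genes: tuple
    contrast: str = "target-vs-rest"
    q_cutoff: float = 0.05


@dataclass
class ContributionReport:
    """Aggregated output of one contribution run."""

    ligands: dict                       # subtype -> DataFrame (gene, q_value, log_fc)
    network: pd.DataFrame               # ligand, pathway, subtype
    zsum: pd.DataFrame                  # subtype, direction, z_sum, rank
    receptors: ReceptorSet | None
    pairs: pd.DataFrame                 # subtype, ligand, receptor
    pair_counts: pd.Series              # subtype -> count
    directions: dict = field(default_factory=dict)  # subtype -> increased/decreased

    def matched_ligands(self) -> dict:
        """Subtype -> ligands retained after the pathway-overlap step."""
        out: dict[str, list[str]] = {s: [] for s in self.ligands}
        for _, row in self.network.iterrows():
            if row["ligand"] not in out.setdefault(row["subtype"], []):
                out[row["subtype"]].append(row["ligand"])
        return out

    def pathway_ids(self) -> set:
        return set(self.network["pathway"]) if len(self.network) else set()

    def ligand_ids(self) -> set:
        return set(self.network["ligand"]) if len(self.network) else set()


def select_secreted_ligands(marker_table: pd.DataFrame, secreted_list,
                            changed: pd.DataFrame, q_max: float = 1e-3) -> dict:
    """Candidate ligands per changed subtype.

    For every subtype flagged ``changed``, keep its marker genes with
    q < ``q_max`` that belong to the secretome, ordered by ascending q.
    Unchanged subtypes get no entry even if they carry secreted markers.
    """
    secreted = set(secreted_list)
    assignment: dict[str, pd.DataFrame] = {}
    for _, row in changed.loc[changed["changed"]].iterrows():
        subtype = row["subtype"]
        sub = marker_table[(marker_table["cluster"] == subtype)
                           & (marker_table["q_value"] < q_max)
                           & (marker_table["gene"].isin(secreted))]
        sub = sub.sort_values(["q_value", "gene"]).reset_index(drop=True)
        if not len(sub):
            log.warning("changed subtype %s has no secreted ligands below q=%g",
                        subtype, q_max)
        assignment[subtype] = sub[["gene", "q_value", "log_fc"]]
    return assignment


def build_ligand_pathway_network(assignment: dict, sets: GeneSetCollection,
                                 maturation) -> pd.DataFrame:
    """Bipartite ligand-pathway edges restricted to maturation pathways.

    Edge (ligand, pathway) exists iff the ligand is a member of the
    pathway's gene set and the pathway is on the maturation list. Ligands
    with no edge are thereby dropped from the matched set.
    """
    maturation = [m for m in maturation if m in sets]
    if not maturation:
        log.warning("maturation pathway list is empty; network has no edges")
    member_sets = {m: set(sets.members(m)) for m in maturation}
    rows = []
    for subtype, table in assignment.items():
        for gene in table["gene"]:
            for m in maturation:
                if gene in member_sets[m]:
                    rows.append((gene, m, subtype))
    return pd.DataFrame(rows, columns=["ligand", "pathway", "subtype"])


def contribution_zsum(norm: NormalizedMatrix, subtype_labels,
                      matched_ligands_by_subtype: dict) -> pd.DataFrame:
    """Rank subtypes by summed across-cluster scaled mean expression.

    For each matched ligand g, the subtype means m(g, s) over the ranked
    subtypes are standardized with the sample SD; z_sum(s) sums z(g, s)
    over the ligands attributed to s. Ordering is by descending z_sum,
    ties broken lexicographically by subtype id.
    """
    subtypes = sorted(matched_ligands_by_subtype)
    if len(subtypes) < 2:
        raise ValueError("z-score undefined across one cluster: "
                         "need at least two subtypes to rank")
    labels = np.asarray(subtype_labels, dtype=object)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("subtype labels length does not match number of cells")
    gene_index = pd.Index(norm.gene_ids)
    genes = sorted({g for gl in matched_ligands_by_subtype.values() for g in gl})
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise ValueError(f"matched ligand(s) absent from matrix: {missing[:5]}")

    X = norm.dense()
    means = np.zeros((len(genes), len(subtypes)))
    for j, s in enumerate(subtypes):
        mask = labels == s
        if not mask.any():
            raise ValueError(f"subtype {s!r} has no cells")
        rows = gene_index.get_indexer(genes)
        means[:, j] = X[rows][:, mask].mean(axis=1)

    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True)
    z = np.zeros_like(means)
    nonzero = sd[:, 0] > 0
    z[nonzero] = (means[nonzero] - mu[nonzero]) / sd[nonzero]
    if (~nonzero).any():
        log.info("%d matched ligand(s) constant across subtypes contribute 0",
                 int((~nonzero).sum()))

    zsum = {}
    for j, s in enumerate(subtypes):
        own = matched_ligands_by_subtype[s]
        idx = [genes.index(g) for g in own]
        zsum[s] = float(z[idx, j].sum()) if idx else 0.0

    out = pd.DataFrame({"subtype": subtypes,
                        "z_sum": [zsum[s] for s in subtypes]})
    out = out.sort_values(["z_sum", "subtype"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_receptors(marker_table_for_target: pd.DataFrame, membrane_list,
                     q_cutoff: float = 0.05, target: str = "target",
                     contrast: str = "target-vs-rest") -> ReceptorSet:
    """Target-specific membrane receptors from a target-vs-rest marker table."""
    membrane = set(membrane_list)
    if not membrane:
        raise ValueError("membrane list is empty")
    sub = marker_table_for_target[
        (marker_table_for_target["q_value"] < q_cutoff)
        & (marker_table_for_target["gene"].isin(membrane))]
    genes = tuple(sub.sort_values(["q_value", "gene"])["gene"])
    return ReceptorSet(target=target, genes=genes, contrast=contrast,
                       q_cutoff=q_cutoff)


def pair_ligand_receptor(assignment: dict, receptors: ReceptorSet,
                         library: InteractionLibrary
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Ligand-receptor pairs per subtype through the interaction library.

    Equivalent to the brute-force cross-join of each subtype's ligands
    with the receptor set, filtered by symmetric library membership.
    Returns the pair list and per-subtype pair counts.
    """
    rows = []
    for subtype in sorted(assignment):
        table = assignment[subtype]
        ligands = table["gene"] if isinstance(table, pd.DataFrame) else table
        for ligand in ligands:
            for receptor in receptors.genes:
                if library.contains(ligand, receptor):
                    rows.append((subtype, ligand, receptor))
    pairs = pd.DataFrame(rows, columns=["subtype", "ligand", "receptor"])
    counts = pd.Series({s: int((pairs["subtype"] == s).sum())
                        for s in sorted(assignment)}, dtype=int, name="n_pairs")
    return pairs, counts


def overlap_analyses(report_a: ContributionReport, report_b: ContributionReport
                     ) -> dict:
    """Shared pathways and ligands between two completed analyses
    (e.g. an in vivo and an in vitro run)."""
    paths_a, paths_b = report_a.pathway_ids(), report_b.pathway_ids()
    ligs_a, ligs_b = report_a.ligand_ids(), report_b.ligand_ids()
    shared_paths = sorted(paths_a & paths_b)
    shared_ligs = sorted(ligs_a & ligs_b)
    return {
        "shared_pathways": shared_paths,
        "shared_ligands": shared_ligs,
        "n_shared_pathways": len(shared_paths),
        "n_pathways_union": len(paths_a | paths_b),
        "n_shared_ligands": len(shared_ligs),
        "n_ligands_union": len(ligs_a | ligs_b),
    }


def contribution_report(norm: NormalizedMatrix, subtype_labels,
                        marker_table: pd.DataFrame, changed: pd.DataFrame,
                        sets: GeneSetCollection, maturation,
                        secreted_list, receptors: ReceptorSet | None,
                        library: InteractionLibrary | None,
                        q_secretome: float = 1e-3) -> ContributionReport:
    """Run steps 1-5 and assemble a ContributionReport.

    ``receptors``/``library`` may be None to skip the pairing stage.
    """
    assignment = select_secreted_ligands(marker_table, secreted_list, changed,
                                         q_max=q_secretome)
    network = build_ligand_pathway_network(assignment, sets, maturation)
    matched = {s: [] for s in assignment}
    for _, row in network.iterrows():
        if row["ligand"] not in matched[row["subtype"]]:
            matched[row["subtype"]].append(row["ligand"])
    directions = dict(zip(changed["subtype"], changed["direction"]))

    if len(matched) >= 2:
        zsum = contribution_zsum(norm, subtype_labels, matched)
    else:
        zsum = pd.DataFrame(columns=["subtype", "z_sum", "rank"])
        log.warning("fewer than two changed subtypes; z-sum ranking skipped")
    if len(zsum):
        zsum = zsum.assign(direction=[directions.get(s, "unchanged")
                                      for s in zsum["subtype"]])
        zsum = zsum[["subtype", "direction", "z_sum", "rank"]]

    if receptors is not None and library is not None:
        pairs, counts = pair_ligand_receptor(assignment, receptors, library)
    else:
        pairs = pd.DataFrame(columns=["subtype", "ligand", "receptor"])
        counts = pd.Series(dtype=int, name="n_pairs")

    return ContributionReport(ligands=assignment, network=network, zsum=zsum,
                              receptors=receptors, pairs=pairs,
                              pair_counts=counts, directions=directions)
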