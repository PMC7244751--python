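"""Synthetic single-cell data with planted, known ground truth.

The generator emulates a two-time-point (neonatal P1 vs adult P56)
cardiac single-cell experiment: five cell types (CM target plus FB, EC,
MP, SMC niche types) with 2-4 subtypes each, subtype proportion
switching between time points, subtype-specific secreted-ligand
programs, a target-cell receptor program, and QC failure modes (forced
low-gene cells, extreme-UMI cells, low-alignment cells, a mitochondrial
decoy gene block).

Counts are negative binomial with per-gene means drawn log-normally and
per-cell log-normal library-size factors; planted effects multiply the
NB mean in the carrier subtype only, with shared dispersion. QC failures
are injected by overwriting metadata fields post hoc so that every
filter branch is exercised deterministically.

Alongside the matrix the generator emits a matched ResourceBundle:
secretome and membrane lists covering the planted genes plus decoys, a
gene-set collection in which every planted ligand belongs to at least
one maturation set, an interaction library containing all planted
ligand-receptor pairs plus decoys (including zero-evidence decoys that
the evidence filter must drop), a mitochondrial decoy block, a
107-gene housekeeping list split into four categories (37 tRNA, 36
elongation factor, 19 RNA polymerase II subunit, 15 ribosomal), and a
maturation-trajectory DEG list from which the enrichment stage can
recover the maturation pathways.

Annotation resources are desk-scale stand-ins: tens of secreted/membrane
genes and on the order of a hundred interaction pairs rather than the
thousands a curated proteome-wide resource would carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from nichescore.containers import (
    AnnotationLists,
    CountMatrix,
    GeneSetCollection,
    InteractionLibrary,
)

HOUSEKEEPING_CATEGORIES = {
    "tRNA": 37,
    "elongation_factor": 36,
    "rna_pol_ii_subunit": 19,
    "ribosomal": 15,
}


@dataclass
class SimConfig:
    """Study-design parameters for one simulated experiment."""

    time_points: tuple = ("P1", "P56")
    n_cells_per_time: int = 600
    n_genes: int = 2000
    # cell_type -> subtypes
    cell_types: dict = field(default_factory=dict)
    # time_point -> cell_type -> mixture fraction (sums to 1 per time point)
    type_mixture: dict = field(default_factory=dict)
    # time_point -> cell_type -> subtype -> within-type proportion
    subtype_proportions: dict = field(default_factory=dict)
    target_cell_type: str = "CM"
    # subtype -> tuple of ligand gene names (planted up in that subtype)
    planted_ligands: dict = field(default_factory=dict)
    planted_receptors: tuple = ()
    marker_log_fold: float = math.e   # multiplicative factor on the NB mean
    baseline_log_mean: float = math.log(0.8)
    baseline_log_sigma: float = 1.0
    planted_baseline_mean: float = 1.0
    housekeeping_mean: float = 2.0
    mito_mean: float = 3.0
    dispersion: float = 2.0           # NB inverse-dispersion (size)
    libsize_sigma: float = 0.3
    n_decoy_secreted: int = 40
    n_decoy_membrane: int = 40
    n_mito: int = 12
    qc_fail_fractions: dict = field(default_factory=lambda: {
        "low_genes": 0.02, "high_umi": 0.01, "low_alignment": 0.02})
    seed: int = 0

    def validate(self) -> None:
        for tp in self.time_points:
            mix = self.type_mixture[tp]
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"cell-type mixture at {tp} does not sum to 1")
            for ct, subtypes in self.cell_types.items():
                props = self.subtype_proportions[tp][ct]
                if set(props) != set(subtypes):
                    raise ValueError(
                        f"subtype proportions at {tp}/{ct} do not match subtypes")
                if abs(sum(props.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"subtype proportions at {tp}/{ct} do not sum to 1")
        known = {s for subs in self.cell_types.values() for s in subs}
        unknown = set(self.planted_ligands) - known
        if unknown:
            raise ValueError(f"planted ligands for unknown subtype(s): {unknown}")


@dataclass
class ResourceBundle:
    """Annotation resources matched to one simulated matrix."""

    gene_sets: GeneSetCollection
    annotations: AnnotationLists
    interactions: InteractionLibrary
    maturation_deg_genes: tuple = ()


@dataclass
class GroundTruth:
    """Planted structure a correct analysis must recover."""

    changed_subtypes: dict              # subtype -> "increased"/"decreased"
    ligand_receptor_pairs: set          # planted (ligand, receptor) pairs
    expected_top_contributor: str
    planted_ligands: dict
    planted_receptors: tuple
    maturation_set_ids: tuple


def default_config(seed: int = 0) -> SimConfig:
    """The standard simulated study: 5 cell types, 13 subtypes, a planted
    20-point composition shift driven by FB_4 (the adult-enriched
    fibroblast subtype carrying the strongest secreted-ligand program)."""
    cell_types = {
        "CM": ["CM_1", "CM_2"],
        "FB": ["FB_1", "FB_2", "FB_3", "FB_4"],
        "EC": ["EC_1", "EC_2", "EC_3"],
        "MP": ["MP_1", "MP_2"],
        "SMC": ["SMC_1", "SMC_2"],
    }
    mixture = {"CM": 0.30, "FB": 0.30, "EC": 0.18, "MP": 0.14, "SMC": 0.08}
    props = {
        "P1": {
            "CM": {"CM_1": 0.5, "CM_2": 0.5},
            "FB": {"FB_1": 0.40, "FB_2": 0.225, "FB_3": 0.225, "FB_4": 0.15},
            "EC": {"EC_1": 0.40, "EC_2": 0.35, "EC_3": 0.25},
            "MP": {"MP_1": 0.40, "MP_2": 0.60},
            "SMC": {"SMC_1": 0.50, "SMC_2": 0.50},
        },
        "P56": {
            "CM": {"CM_1": 0.5, "CM_2": 0.5},
            "FB": {"FB_1": 0.20, "FB_2": 0.225, "FB_3": 0.225, "FB_4": 0.35},
            "EC": {"EC_1": 0.28, "EC_2": 0.35, "EC_3": 0.37},
            "MP": {"MP_1": 0.55, "MP_2": 0.45},
            "SMC": {"SMC_1": 0.55, "SMC_2": 0.45},
        },
    }
    planted_ligands = {
        "FB_4": tuple(f"Lig_FB_4_{i}" for i in range(1, 7)),
        "FB_1": ("Lig_FB_1_1", "Lig_FB_1_2"),
        "EC_1": ("Lig_EC_1_1", "Lig_EC_1_2"),
        "EC_3": ("Lig_EC_3_1", "Lig_EC_3_2"),
        "MP_1": ("Lig_MP_1_1", "Lig_MP_1_2"),
        "MP_2": ("Lig_MP_2_1", "Lig_MP_2_2"),
        # EC_2 keeps a ligand program but its proportion is stable, so the
        # changed-subtype rule must exclude it downstream
        "EC_2": ("Lig_EC_2_1", "Lig_EC_2_2"),
    }
    receptors = tuple(f"Rec_{i}" for i in range(1, 7))
    return SimConfig(cell_types=cell_types,
                     type_mixture={"P1": mixture, "P56": mixture},
                     subtype_proportions=props,
                     planted_ligands=planted_ligands,
                     planted_receptors=receptors,
                     seed=seed)


def null_calibration_config(seed: int = 0) -> SimConfig:
    """Symmetric no-signal configuration for ranking calibration.

    Every niche subtype has the same expected cell count and the same
    number of designated ligand genes, no proportion changes and no
    planted expression effect (marker_log_fold = 1), so the subtypes are
    exchangeable and the rank of any designated subtype in the z-sum
    ranking is uniform by symmetry.
    """
    cell_types = {ct: [f"{ct}_1", f"{ct}_2"]
                  for ct in ("CM", "FB", "EC", "MP", "SMC")}
    mixture = {ct: 0.2 for ct in cell_types}
    props = {ct: {f"{ct}_1": 0.5, f"{ct}_2": 0.5} for ct in cell_types}
    planted = {f"{ct}_{i}": tuple(f"Lig_{ct}_{i}_{j}" for j in range(1, 4))
               for ct in ("FB", "EC", "MP", "SMC") for i in (1, 2)}
    return SimConfig(cell_types=cell_types,
                     type_mixture={"P1": mixture, "P56": mixture},
                     subtype_proportions={"P1": props, "P56": props},
                     planted_ligands=planted,
                     planted_receptors=("Rec_1", "Rec_2"),
                     marker_log_fold=1.0,
                     n_cells_per_time=250,
                     qc_fail_fractions={},
                     seed=seed)


def _gene_panel(config: SimConfig) -> dict:
    """Assign names and roles to the gene panel. Returns name arrays per role."""
    ligands = [g for s in sorted(config.planted_ligands)
               for g in config.planted_ligands[s]]
    receptors = list(config.planted_receptors)
    decoy_sec = [f"SecDecoy_{i:02d}" for i in range(1, config.n_decoy_secreted + 1)]
    decoy_mem = [f"MemDecoy_{i:02d}" for i in range(1, config.n_decoy_membrane + 1)]
    mito = [f"mt-{i:02d}" for i in range(1, config.n_mito + 1)]
    housekeeping = {}
    for cat, size in HOUSEKEEPING_CATEGORIES.items():
        for i in range(1, size + 1):
            housekeeping[f"Hk_{cat}_{i:02d}"] = cat
    named = (ligands + receptors + decoy_sec + decoy_mem + mito
             + list(housekeeping))
    n_background = config.n_genes - len(named)
    if n_background < 200:
        raise ValueError(
            f"n_genes={config.n_genes} too small for the named panel "
            f"({len(named)} named genes + >=200 background)")
    background = [f"Gene_{i:04d}" for i in range(1, n_background + 1)]
    return {"ligands": ligands, "receptors": receptors,
            "decoy_secreted": decoy_sec, "decoy_membrane": decoy_mem,
            "mito": mito, "housekeeping": housekeeping,
            "background": background,
            "all": np.asarray(named + background, dtype=object)}


def _build_gene_sets(config: SimConfig, panel: dict
                     ) -> tuple[GeneSetCollection, tuple, tuple]:
    """Maturation sets (each planted ligand in >=1), decoy sets, and the
    maturation-trajectory DEG list that recovers them by enrichment."""
    background = panel["background"]
    ligands = panel["ligands"]
    n_mat, n_decoy = 5, 5
    per_set_bg, per_decoy_bg = 15, 20
    needed = n_mat * per_set_bg + n_decoy * per_decoy_bg
    bg_pool = background[:needed]
    sets = GeneSetCollection()
    deg: list[str] = []
    mat_ids = []
    for i in range(n_mat):
        sid = f"M_PATH_{i + 1}"
        mat_ids.append(sid)
        bg_members = bg_pool[i * per_set_bg:(i + 1) * per_set_bg]
        lig_members = [g for j, g in enumerate(ligands) if j % n_mat == i]
        sets.add(sid, f"maturation pathway {i + 1}", lig_members + bg_members)
        deg.extend(bg_members[:12])   # DEG list independent of the ligands
    offset = n_mat * per_set_bg
    for i in range(n_decoy):
        sid = f"D_PATH_{i + 1}"
        members = bg_pool[offset + i * per_decoy_bg:offset + (i + 1) * per_decoy_bg]
        sets.add(sid, f"decoy pathway {i + 1}", members)
    return sets, tuple(mat_ids), tuple(deg)


def _build_interactions(config: SimConfig, panel: dict, rng: np.random.Generator
                        ) -> tuple[InteractionLibrary, set]:
    lib = InteractionLibrary()
    planted_pairs: set[tuple[str, str]] = set()
    receptors = panel["receptors"]
    driver = max(config.planted_ligands,
                 key=lambda s: len(config.planted_ligands[s]))
    for subtype in sorted(config.planted_ligands):
        ligs = config.planted_ligands[subtype]
        if subtype == driver:
            for i, lig in enumerate(ligs):
                rec = receptors[i % len(receptors)]
                lib.add(lig, rec, float(rng.integers(400, 900)))
                planted_pairs.add((lig, rec))
        else:
            rec = receptors[0]
            lib.add(ligs[0], rec, float(rng.integers(300, 900)))
            planted_pairs.add((ligs[0], rec))
    # decoys: scored pairs among decoy genes plus zero-evidence pairs that
    # the strict evidence filter must exclude
    dsec, dmem = panel["decoy_secreted"], panel["decoy_membrane"]
    for i in range(min(30, len(dsec), len(dmem))):
        lib.add(dsec[i], dmem[i], float(rng.integers(150, 900)))
    zero_ev = InteractionLibrary()  # kept separate: written out, filtered on read
    for i in range(min(10, len(dsec) - 1, len(dmem) - 1)):
        zero_ev.add(dsec[i], dmem[i + 1], 0.0)
    return lib, planted_pairs


def _changed_from_config(config: SimConfig) -> dict:
    t0, t1 = config.time_points[0], config.time_points[-1]
    out = {}
    for ct, subtypes in config.cell_types.items():
        for s in subtypes:
            delta = 100.0 * (config.subtype_proportions[t1][ct][s]
                             - config.subtype_proportions[t0][ct][s])
            if abs(delta) > 10.0:
                out[s] = "increased" if delta > 0 else "decreased"
    return out


def simulate(config: SimConfig | None = None
             ) -> tuple[CountMatrix, pd.DataFrame, ResourceBundle, GroundTruth]:
    """Draw one experiment from the configured study design.

    Returns (CountMatrix, CellMetadata DataFrame, ResourceBundle,
    GroundTruth). Identical config (including seed) gives bit-identical
    outputs.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = _gene_panel(config)
    genes = panel["all"]
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # cell assignment per time point
    cell_ids, tps, ctypes, subs = [], [], [], []
    for tp in config.time_points:
        combos = []
        probs = []
        for ct in sorted(config.cell_types):
            for s in config.cell_types[ct]:
                combos.append((ct, s))
                probs.append(config.type_mixture[tp][ct]
                             * config.subtype_proportions[tp][ct][s])
        draws = rng.multinomial(config.n_cells_per_time, np.asarray(probs))
        i = 0
        for (ct, s), n in zip(combos, draws):
            for _ in range(n):
                cell_ids.append(f"{tp}_c{i:05d}")
                tps.append(tp)
                ctypes.append(ct)
                subs.append(s)
                i += 1
    n_cells = len(cell_ids)
    subs_arr = np.asarray(subs, dtype=object)
    ctypes_arr = np.asarray(ctypes, dtype=object)

    # per-gene baseline NB means
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma,
                         size=n_genes)
    for g in panel["ligands"] + panel["receptors"]:
        base[gene_pos[g]] = config.planted_baseline_mean
    for g in panel["housekeeping"]:
        base[gene_pos[g]] = config.housekeeping_mean
    for g in panel["mito"]:
        base[gene_pos[g]] = config.mito_mean

    lib_factor = rng.lognormal(-config.libsize_sigma ** 2 / 2.0,
                               config.libsize_sigma, size=n_cells)
    mu = np.outer(base, lib_factor)

    # planted effects: multiplicative on the NB mean in the carrier cells only
    for subtype, ligs in config.planted_ligands.items():
        mask = subs_arr == subtype
        if mask.any():
            rows = [gene_pos[g] for g in ligs]
            mu[np.ix_(rows, np.flatnonzero(mask))] *= config.marker_log_fold
    target_mask = ctypes_arr == config.target_cell_type
    if config.planted_receptors and target_mask.any():
        rows = [gene_pos[g] for g in config.planted_receptors]
        mu[np.ix_(rows, np.flatnonzero(target_mask))] *= config.marker_log_fold

    r = config.dispersion
    counts_dense = rng.negative_binomial(r, r / (r + mu))
    counts = CountMatrix(genes, np.asarray(cell_ids, dtype=object),
                         sp.csr_matrix(counts_dense))

    metadata = pd.DataFrame({
        "cell_id": cell_ids,
        "time_point": tps,
        "cell_type": ctypes,
        "subtype": subs,
        "n_genes_detected": counts.genes_detected_per_cell(),
        "n_umi": counts.cell_totals().astype(int),
        "alignment_pct": np.round(rng.uniform(75, 95, size=n_cells), 2),
    })

    # QC failure injection: overwrite metadata fields post hoc; each cell
    # fails at most one mode (first mode in fixed order wins)
    taken = np.zeros(n_cells, dtype=bool)
    for mode in ("low_genes", "high_umi", "low_alignment"):
        frac = config.qc_fail_fractions.get(mode, 0.0)
        hit = (rng.random(n_cells) < frac) & ~taken
        taken |= hit
        idx = np.flatnonzero(hit)
        if mode == "low_genes":
            metadata.loc[idx, "n_genes_detected"] = rng.integers(50, 500,
                                                                 size=idx.size)
        elif mode == "high_umi":
            metadata.loc[idx, "n_umi"] = rng.integers(1_000_000, 2_000_000,
                                                      size=idx.size)
        else:
            metadata.loc[idx, "alignment_pct"] = np.round(
                rng.uniform(20, 50, size=idx.size), 2)

    gene_sets, mat_ids, deg = _build_gene_sets(config, panel)
    interactions, planted_pairs = _build_interactions(config, panel, rng)
    annotations = AnnotationLists(
        secreted=set(panel["ligands"]) | set(panel["decoy_secreted"]),
        membrane=set(panel["receptors"]) | set(panel["decoy_membrane"]),
        mitochondrial=set(panel["mito"]),
        housekeeping=dict(panel["housekeeping"]),
    )
    bundle = ResourceBundle(gene_sets=gene_sets, annotations=annotations,
                            interactions=interactions,
                            maturation_deg_genes=deg)

    changed = _changed_from_config(config)
    driver = max(config.planted_ligands,
                 key=lambda s: len(config.planted_ligands[s]))
    truth = GroundTruth(changed_subtypes=changed,
                        ligand_receptor_pairs=planted_pairs,
                        expected_top_contributor=driver,
                        planted_ligands=dict(config.planted_ligands),
                        planted_receptors=tuple(config.planted_receptors),
                        maturation_set_ids=mat_ids)
    return counts, metadata, bundle, truth


def config_with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# worked fixture: a tiny hand-written dataset with hand-computable results
# ---------------------------------------------------------------------------

def worked_fixture() -> tuple[CountMatrix, pd.DataFrame, ResourceBundle, GroundTruth]:
    """Fixed 20-gene x 30-cell dataset with hand-computable results.

    Structure (intended to be analyzed with min_cells_per_gene = 5 and
    otherwise-default QC, pooled-across-time receptor contrast):

    * 27 analysis cells: 12 FB_neo, 8 FB_adult, 7 CM (CM_1/CM_2);
      FB_adult is 2/10 of fibroblasts at P1 and 6/10 at P56 (delta +40
      points). The CM subtypes move by exactly 10 points (CM_1 3/5 -> 1/2,
      CM_2 2/5 -> 1/2), sitting on the strict composition boundary.
    * 3 QC-boundary cells: alignment exactly 50.0 (strict rule), UMI
      exactly 1e6 (strict rule), UMI 60000 (outside the 2-SD window).
      Analysis cells sit at exactly 500 detected genes (inclusive keep
      side of the minimum-gene rule).
    * LIG_A/LIG_B: FB_adult-only ligands, in the maturation pathway and
      paired to CM receptors REC_X/REC_Y; LIG_C: FB_neo-only ligand whose
      only pathway is a decoy, so it drops out of the matched set.
    * MT_DECOY (mitochondrial) and RARE_GENE (detected in 4 < 5 cells)
      are removed by gene filtering; EDGE_GENE (exactly 5 cells) stays.
    * The interaction table carries a zero-evidence decoy pair that the
      strict evidence filter must exclude.
    """
    genes = ["LIG_A", "LIG_B", "LIG_C", "REC_X", "REC_Y", "DECOY_SEC",
             "DECOY_MEM", "MT_DECOY", "RARE_GENE", "EDGE_GENE", "HK_ALPHA",
             "HK_BETA"] + [f"BG_{i:02d}" for i in range(1, 9)]
    gi = {g: i for i, g in enumerate(genes)}

    cells, tps, ctype, sub = [], [], [], []

    def add(cid, tp, ct, s):
        cells.append(cid)
        tps.append(tp)
        ctype.append(ct)
        sub.append(s)

    for i in range(1, 9):
        add(f"P1_FBn_{i:02d}", "P1", "FB", "FB_neo")
    for i in range(1, 3):
        add(f"P1_FBa_{i:02d}", "P1", "FB", "FB_adult")
    for i in range(1, 4):
        add(f"P1_CM_{i:02d}", "P1", "CM", "CM_1")
    for i in range(4, 6):
        add(f"P1_CM_{i:02d}", "P1", "CM", "CM_2")
    for i in range(1, 5):
        add(f"P56_FBn_{i:02d}", "P56", "FB", "FB_neo")
    for i in range(1, 7):
        add(f"P56_FBa_{i:02d}", "P56", "FB", "FB_adult")
    add("P56_CM_01", "P56", "CM", "CM_1")
    add("P56_CM_02", "P56", "CM", "CM_2")
    add("QF_ALIGN", "P1", "FB", "FB_neo")
    add("QF_UMI", "P56", "FB", "FB_neo")
    add("QF_SD", "P56", "FB", "FB_neo")

    X = np.zeros((len(genes), len(cells)), dtype=int)
    for j, (cid, s) in enumerate(zip(cells, sub)):
        for bg in range(1, 9):
            X[gi[f"BG_{bg:02d}"], j] = 3
        X[gi["HK_ALPHA"], j] = 6
        X[gi["HK_BETA"], j] = 2
        X[gi["DECOY_SEC"], j] = 2
        X[gi["DECOY_MEM"], j] = 2
        X[gi["MT_DECOY"], j] = 1
        if s == "FB_neo":
            X[gi["LIG_C"], j] = 5
        elif s == "FB_adult":
            X[gi["LIG_A"], j] = 5
            X[gi["LIG_B"], j] = 4
        elif s in ("CM_1", "CM_2"):
            X[gi["REC_X"], j] = 6
            X[gi["REC_Y"], j] = 3
    for cid in ["P1_FBn_01", "P1_FBn_02", "P1_FBn_03", "P1_FBn_04"]:
        X[gi["RARE_GENE"], cells.index(cid)] = 1
    for cid in ["P56_FBn_01", "P56_FBn_02", "P56_FBn_03", "P56_FBn_04",
                "P56_FBa_01"]:
        X[gi["EDGE_GENE"], cells.index(cid)] = 1

    counts = CountMatrix(np.asarray(genes, dtype=object),
                         np.asarray(cells, dtype=object), sp.csr_matrix(X))

    n_genes_meta = np.full(len(cells), 500)
    n_umi = 5000 + np.arange(len(cells))
    align = np.full(len(cells), 90.0)
    qf = {c: cells.index(c) for c in ("QF_ALIGN", "QF_UMI", "QF_SD")}
    align[qf["QF_ALIGN"]] = 50.0
    n_umi[qf["QF_UMI"]] = 1_000_000
    n_umi[qf["QF_SD"]] = 60_000
    metadata = pd.DataFrame({
        "cell_id": cells, "time_point": tps, "cell_type": ctype, "subtype": sub,
        "n_genes_detected": n_genes_meta, "n_umi": n_umi, "alignment_pct": align,
    })

    sets = GeneSetCollection()
    sets.add("M_SIG", "maturation signaling", ["LIG_A", "LIG_B", "BG_01",
                                              "BG_02", "BG_03"])
    sets.add("D_SIG", "decoy signaling", ["LIG_C", "BG_04", "BG_05"])
    annotations = AnnotationLists(
        secreted={"LIG_A", "LIG_B", "LIG_C", "DECOY_SEC"},
        membrane={"REC_X", "REC_Y", "DECOY_MEM"},
        mitochondrial={"MT_DECOY"},
        housekeeping={"HK_ALPHA": "ribosomal", "HK_BETA": "tRNA"},
    )
    interactions = InteractionLibrary([
        ("LIG_A", "REC_X", 700.0),
        ("LIG_B", "REC_Y", 400.0),
        ("DECOY_SEC", "REC_X", 300.0),
    ])
    # a zero-evidence row for the strict ">" filter is part of the written
    # table, not of the in-memory library
    bundle = ResourceBundle(gene_sets=sets, annotations=annotations,
                            interactions=interactions,
                            maturation_deg_genes=("LIG_A", "LIG_B", "BG_01",
                                                  "BG_02", "BG_03"))
    truth = GroundTruth(
        changed_subtypes={"FB_adult": "increased", "FB_neo": "decreased"},
        ligand_receptor_pairs={("LIG_A", "REC_X"), ("LIG_B", "REC_Y")},
        expected_top_contributor="FB_adult",
        planted_ligands={"FB_adult": ("LIG_A", "LIG_B"),
                         "FB_neo": ("LIG_C",)},
        planted_receptors=("REC_X", "REC_Y"),
        maturation_set_ids=("M_SIG",),
    )
    return counts, metadata, bundle, truth
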