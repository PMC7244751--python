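# Methods

This note documents the models, conventions and design choices behind
`nichescore`, in the order the pipeline runs them, followed by the
synthetic study design and the package's known limitations.

## Quality control

Cell filters run in a fixed order on the metadata QC covariates:
(1) detected genes ≥ 500 (inclusive — a cell at exactly 500 is kept);
(2) genome alignment percentage strictly greater than 50 (a cell at
exactly 50.0 is removed); (3) distinct UMI count strictly below 10⁶;
(4) UMI count within mean ± 2 sample SD (ddof = 1). The window in
rule 4 is computed over the cells that survive rules 1–3: cells with
10⁶-scale UMI counts would otherwise inflate the very window meant to
exclude them. The order-and-ddof convention is recorded in every
QCReport. When `alignment_pct` is absent the rule is skipped with a
warning rather than failing, since that covariate comes from upstream
read processing that not every matrix ships with.

Gene filters drop the mitochondrial list outright and then require
detection (count > 0) in at least 10 cells (inclusive). Both cell and
gene filtering are idempotent.

Normalization is the standard size-factor log transform:
`value = ln(1 + count/total * 10000)`. `ln(1+x)` rather than `ln(x)` is
the only convention under which zero counts stay finite, and it is the
convention in which the downstream log-fold-change threshold of 0.2 is
defined. Back-transforming with `expm1` and summing over genes recovers
the size factor exactly for every cell (tested to 1e-6 relative), which
makes the transform auditable.

## Marker detection

One-vs-rest (or cluster-vs-cluster) comparisons use the two-sided
Wilcoxon rank-sum test with midranks for ties, the tie-corrected
variance, and a continuity correction, evaluated through the normal
approximation (`scipy.stats.mannwhitneyu`). Genes enter the test only if
`max(pct_in, pct_out) >= 0.2` and the natural-log fold change
`ln(mean(expm1(x))+1) - ln(mean(expm1(y))+1)` is at least 0.2 (positive
only by default). Adjustment is Benjamini–Hochberg over the genes
actually tested within one contrast; Bonferroni is available as a config
option and the choice is echoed into output headers. Degenerate input
(all pooled values identical) yields p = 1 rather than an error.

Accuracy of the approximation, measured against full permutation
enumeration in the test suite: for untied samples with group sizes 3–8
the two-sided p agrees within 0.05 (worst observed 0.038 over 1000
instances), and for heavily tied small samples the two tests agree
within 0.05 wherever either of them is significant at 0.05. Near the
center of the permutation distribution, however, tied samples of size
≤ 8 have probability atoms far larger than 0.05, so no asymptotic
p-value can track the enumerated p uniformly there (e.g. x = [1,1],
y = [2,1]: exact p = 1.0, asymptotic 0.617). This is a property of the
approximation itself, not of the implementation; at the group sizes
marker detection actually sees (tens to hundreds of cells) the
approximation is well calibrated — on label-permuted null data the
fraction of genes with p < 0.05 is 0.05 ± 0.02 across ≥ 2000 gene tests.

## Composition switching

Proportions are computed within cell type, so each cell type's subtypes
sum to 100% at every time point and a large cell type cannot mask
switching in a small one. The change call is a plain threshold —
strictly more than 10 percentage points of absolute difference between
the two states — with no significance test attached; the delta is
compositional, so deltas within a cell type sum to zero. On simulated
data a planted 20-point shift at ≥ 200 cells per time point is flagged
in ≥ 95% of replicates.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for a query of n genes hitting k members of a K-gene set in an
N-gene universe. The default universe is the intersection of the genes
surviving QC with the genes appearing in at least one set of the
collection (the convention of the standard enrichment tools); using all
filtered genes is a config option. Sets disjoint from the universe are
omitted — their enrichment is undefined, not null. Significance uses the
raw p < 0.05 cutoff, with BH q-values reported alongside. The
implementation agrees with exact term-by-term rational summation of the
pmf to 1e-12 across all N ≤ 60, and the maturation-pathway derivation is
just the significant set ids for a user-supplied trajectory DEG list
(callers may bypass it with a curated list).

## Contribution analysis

Candidate ligands of a changed subtype are its markers at q < 10⁻³
intersected with the secretome, ordered by q; by default all passing
genes are kept (an optional top-k exists) because no sharper ranking
criterion is defined for the selection step. Unchanged subtypes get no
entry even when they carry secreted markers — composition switching is
the gate. Ligand–pathway edges require set membership in a
maturation-list pathway; ligands with no edge drop out of the matched
set.

The z-sum score standardizes each matched ligand's subtype-mean
normalized expression across the subtypes being ranked (the changed
subtypes), with sample SD; genes constant across subtypes contribute 0.
Each subtype sums the z-scores of its own matched ligands. Scaling
across the ranked subtypes mirrors the per-row scaling of a
cluster-by-gene heatmap of exactly those clusters; rankings are reported
jointly and per direction of change (increased vs decreased), since the
two directions answer different questions (gained vs lost signals).
Ties are broken lexicographically by subtype id to keep runs
reproducible.

Receptors are target-vs-rest markers (default contrast: mature time
point only, configurable to pooled or per time point) intersected with
the membrane list at q < 0.05. Pairing is an exact cross-join of each
subtype's ligands with the receptor set, filtered by symmetric
membership in the evidence-filtered interaction library (experimental
evidence strictly > 0); it is verified against an independent
brute-force triple loop. The per-subtype pair count is the second
contribution read-out, and two completed analyses can be intersected on
pathway and ligand ids for conservation-style comparisons.

## Synthetic study design

`default_config()` emulates a two-time-point (P1/P56) cardiac
experiment: 600 cells per time point, 2000 genes, five cell types
(CM 30%, FB 30%, EC 18%, MP 14%, SMC 8%) with 13 subtypes. Counts are
negative binomial with inverse-dispersion 2, per-gene means drawn
log-normally (median 0.8, log-SD 1.0), and per-cell log-normal library
factors (log-SD 0.3, mean 1). Planted effects multiply the NB mean by
`marker_log_fold` (default e¹ ≈ 2.72) in the carrier cells only.

The planted structure: the adult-expanded fibroblast subtype FB_4 is
the driver — its fibroblast share rises from 15% to 35% (the 20-point
shift the composition stage must detect) and it carries six ligands,
all members of maturation pathways and all paired to CM receptors in
the interaction library. Five other subtypes shift by 12–20 points with
two-ligand programs and a single receptor pair each, one stable subtype
(EC_2) carries a ligand program that the changed-subtype gate must
exclude, and decoy secreted/membrane genes, decoy pathways, decoy
interaction pairs (including zero-evidence rows) and a mitochondrial
block exercise every filter. The driver's base proportion was set so
that its planted program is identifiable under the default analysis:
at 15% → 35% the driver has ~90–120 post-QC cells and all six ligands
clear the q < 10⁻³ screen; far rarer driver populations (a few dozen
cells) leave individual ligands short of that stringent cutoff at this
effect size. The housekeeping control list keeps the canonical category
bookkeeping of 107 genes = 37 tRNA + 36 elongation factor + 19 RNA
polymerase II subunit + 15 ribosomal. Annotation resources are
deliberately desk-scale (tens of genes per list, ~10² interaction
pairs), not proteome-scale.

QC failure modes are injected post hoc by overwriting metadata fields
(forced detected-gene counts below 500, UMI ≥ 10⁶, alignment ≤ 50) on
Bernoulli-sampled disjoint cell subsets, so each filter branch fires
deterministically under a fixed seed; all outputs are bit-identical
given the same config.

`null_calibration_config()` is the matching negative control for the
ranking statistic: `marker_log_fold = 1` (no planted effect), equal
cell-type mixture, equal subtype proportions at both time points and an
equal number of designated ligand genes per niche subtype. Under this
symmetric design the subtypes are exchangeable, so the rank of any
designated subtype in the z-sum ranking is uniform — which the test
suite verifies by chi-square over 200 replicates. A literal no-signal
run of the full pipeline is not usable for this purpose: without
significant markers every ligand set is empty, all z-sums are zero and
the deterministic tie-break fixes the ranking, so calibration is
necessarily assessed on the designated (ground-truth) ligand
assignment.

The worked fixture (`worked_fixture()`) is a hand-written 20-gene ×
30-cell dataset whose marker, composition, z-sum and pairing results
are all computable by hand; its cells sit exactly on the QC and
composition boundaries (500 detected genes kept, alignment 50.0
removed, UMI 10⁶ removed, a 2-SD-window outlier, CM subtypes at exactly
±10 points not called changed). Its gene-filter boundary is at 5 cells
rather than the default 10 because its planted programs span only 6–8
cells.

### What the simulation does and does not capture

The generator reproduces overdispersed counts, library-size variation,
compositional switching, cluster-specific expression programs and QC
failure modes. It does not model doublets, ambient RNA, batch effects,
gene–gene correlation beyond the planted programs, or continuous
maturation trajectories (the DEG list that stands in for a trajectory
is constructed, not inferred). Passing the recovery tests therefore
shows that the pipeline's logic and statistics behave correctly under
the stated generative model — not that real tissue data meet that
model's assumptions.

## Numerical conventions and problem sizes

All boundary comparisons are as stated above (inclusive minimum-gene
and minimum-cell rules; strict alignment, UMI, composition-cutoff and
evidence thresholds). Proportion configs must sum to 1 within 1e-9.
Zero-SD genes score 0 in the z-sum; a single-subtype ranking is an
error, not a silent 0. The test suite and the acceptance script use 20
replicates for planted-structure recovery (600 cells/time point, 2000
genes) and 200 replicates for null calibration (250 cells/time point),
sizes at which the whole suite completes in about a minute on one CPU
while leaving the binomial noise on the 95%-recovery check small.

## Known limitations

* The asymptotic Wilcoxon p cannot match exact enumeration uniformly in
  heavily tied samples of size ≤ 8 (see Marker detection); callers
  doing micro-scale comparisons should use an exact test.
* The 10-point composition rule is a threshold, not a test: with few
  cells per subtype, sampling noise alone moves proportions by several
  points, and stable subtypes occasionally cross the cutoff (visible in
  the worked example). Faithful to the method, but worth remembering
  when reading the changed-subtype list.
* Ligand–receptor pairing is set-based: it counts evidence-supported
  pairs and does not weight by expression magnitude, receptor
  saturation or spatial proximity.
* Gene identifiers are opaque strings; resources must be pre-harmonized
  to the matrix's namespace.
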