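# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic data does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

Counts are sparse cells × genes matrices with per-cell metadata (species,
sample/replicate, cell class, cell type) and per-gene metadata. Orthogroup
tables map an orthogroup id to per-species gene lists (one-to-one through
many-to-many). Regulons are a regulator plus signed targets: mode
`mod ∈ {−1, +1}` (activating/repressing) and weight `w ∈ (0, 1]`
(regulatory strength). All containers validate their invariants on
construction (unique ids, non-negative counts, a gene in at most one
orthogroup per species, weights in range).

## Synthetic two-species generator

The generator emulates the statistical structure the downstream statistics
assume, at desk scale (defaults: 2 × 6 types × 330 cells, 2,000
orthogroups, 2 samples per species, 20 regulators):

- **Counts** are negative binomial via a Gamma–Poisson mixture with
  dispersion θ = 2 (variance μ + μ²/θ), per-cell library sizes log-normal
  (σ = 0.3) around an expected depth of 2,000 counts, per-gene base rates
  log-normal (σ = 1) normalized to that depth.
- **Type identity**: each type has a disjoint program of 40 marker
  orthogroups up-regulated by fold change 4. Homologous types (an
  injective partial map from species-B types to species-A types; by
  default 5 of 6 types are matched, the last type of each species is
  species-specific) share marker programs through their orthogroups.
  A per-gene log-normal cross-species scale (σ = 0.3) keeps the mapping
  nontrivial but signal-preserving; a milder per-sample scale (σ = 0.1)
  creates the replicate structure the Stouffer combination integrates over.
- **Duplications**: a fraction (default 0.2) of orthogroups carries a
  second species-B copy. One copy — chosen at random — carries the full
  type-dependent rate; the other is flat low-level noise (5% of base),
  uninformative by construction. This is the ground truth MIOG selection
  must recover.
- **Regulators**: each of 20 regulators gets 40 signed targets (weights
  uniform on (0.25, 1], modes ± at random) and one active class (classes
  cycle over types, 3 by default). In cells of the active class every
  target rate is multiplied by `exp(effect · mod · w)` with effect = 1.
  With effect = 0 the generator is an exact null for the activity stage.
- **QC artifacts**: low-depth cells are binomially thinned real cells
  (≈ 200 expected counts — below both low-quality thresholds); doublets
  are sums of two random cells amplified until their detected-feature
  count exceeds the doublet threshold. Labels are recorded in cell
  metadata and ground truth.

**Doublet threshold at desk scale.** The real-data doublet rule (detected
features > 8,950) cannot fire when only 2,000 genes exist, so the
simulator carries its own feature threshold (default 1,450; singlets at
the default depth detect ≈ 850 ± 120 genes, injected doublets ≥ 1,600).
The 8,950 boundary itself is exercised on dedicated spanning inputs with
> 9,000 genes. The pipeline uses the simulator's threshold whenever the
configured one exceeds the gene count.

Not emulated: ambient RNA, batch chemistry, cell-cycle structure, gene
length or GC effects, or realistic gene-gene correlation beyond the
programmed type/regulator structure. Passing recovery tests therefore
shows the statistics behave as designed under their own assumptions, not
that they are robust to every artifact of real data.

## QC, normalization, HVGs

A cell is removed as low-quality when it fails **either** minimum (total
counts < 500 or detected features < 330); the literal both-minima reading
is available behind `low_quality_rule="both"`. Cells with features above
the doublet threshold are removed in both modes. Filtering is idempotent.
Normalization is `log2(1 + CPM)`; zero-total cells are an error (they
belong to QC). HVGs are the top-k genes by standard deviation (ddof = 1)
of log-normalized expression, ties broken by gene id. This replaces a
variance-stabilizing-model ranking deliberately: same role, deterministic,
desk-scale.

## Type trees

Type profiles are per-type means of log-normalized expression. The
correlation distance is `Dist = (1 − r)/2` with Pearson r, hence in
[0, 1] and invariant to positive affine rescaling of profiles.

- **Centroid dendrogram**: Lance–Williams centroid update on squared
  distances (treating Dist as Euclidean). Merge heights are centroid
  distances and may invert, as is characteristic of centroid linkage;
  negative branch lengths are clamped to 0 in the Newick output, and ties
  in the closest pair break toward the lexicographically smallest label
  pair (a cluster is labeled by its smallest leaf). The merge sequence
  matches scipy's centroid linkage whenever no ties occur.
- **Neighbor joining** with bootstrap: replicates resample gene columns
  with replacement, rebuild the distance and the NJ tree, and each
  internal edge of the main tree gets the percentage (0–100) of replicates
  containing its bipartition. 100 replicates by default. Fewer than 4
  leaves degrade to a cherry/star without supports.

## MIOG selection and the feature table

Within each orthogroup and species, the member gene with the highest
standard deviation of log-normalized expression across **all** of that
species' cells wins (ddof = 1; ties break toward the smaller gene id).
All-cells SD was chosen over per-subset SD as the simplest reading
consistent with the selection's purpose; duplication of every cell leaves
the choice unchanged. Orthogroup members absent from the matrix score 0
and are skipped with a warning; orthogroups with no expressed member in a
species get no entry there. The aligned feature table keeps orthogroups
with representatives in both species (`miog` mode), optionally restricted
to representatives that are HVGs in both species (`intersection` mode).
Every aligned pair maps through exactly one orthogroup.

## Cross-species mapping

Per type, `min(floor(0.67·n), 300)` cells train and the rest evaluate
(floor by convention; the cap applies after the fraction; types with < 3
cells go entirely to training with a warning). The classifier is XGBoost
`multi:softprob` over the log-normalized aligned features, with fixed
defaults (80 rounds, depth 4, learning rate 0.3, `hist`, single thread)
— none are tuned per dataset, and the seed fixes the split and the fit.
Cells are assigned by hard argmax of class scores; `P[j, i]` is the
fraction of test-type-j cells assigned train type i, so rows sum to 1.
A test type is conserved when its best matched percentage is ≥ 50%
(exactly 50% counts as conserved); best-match ties break toward the
lexicographically first training label. Across several reference species,
a type is conserved if it passes the rule against any reference, with
unique-vs-shared bookkeeping. The normalized entropy uses base e and the
`0·ln 0 = 0` convention; it is 0 exactly for one-hot rows and 1 for
uniform rows, and requires at least two training types (a single training
type is reported as 0: the forced mapping has no uncertainty).

## Conserved markers

Per sample, genes are tested one-vs-rest with the two-sided Wilcoxon
rank-sum test (asymptotic, tie-corrected); the direction is the sign of
the mean log-normalized difference. Each two-sided p becomes a signed
normal score `Z_i = sign · Φ⁻¹(1 − p/2)`, combined as `Z = Σ Z_i / √n`,
with a two-sided combined p and Benjamini–Hochberg adjustment across
genes. Zero p-values are replaced by the smallest positive *normalized*
double (2.2e-308), bounding |Z_i| at ≈ 38.5; the subnormal minimum
(5e-324) is available behind a flag and is guarded against underflow when
halved. Groups absent from a sample, or with fewer than 2 cells on either
side, are skipped with a warning. No minimum-expression gene prefilter is
applied; with the BH step this only costs power, never validity.

## ROSA protein activity

Regulons are pruned before scoring: more than 50 targets → keep the 50
largest-weight targets (ties by target id; weight is the only per-target
strength available here), fewer than 20 → drop the regulon. Expression Z
scores are per-gene standardizations of log-normalized expression (or of
an externally supplied residual matrix); constant genes get Z ≡ 0. The
coarse-grained adjustment snaps each Z toward zero onto the grid of
standard-normal q-quantiles `Φ⁻¹(i/q)`, i = 1..q−1: negative Z maps to
the smallest grid point ≥ Z, non-negative Z to the largest grid point
≤ Z. Grid points are fixed points (the adjustment is idempotent), values
beyond the grid clamp to the extreme points, and for odd q (no zero
point) Z = 0 maps to the largest negative grid point. q defaults to 100 —
fine enough that shrinkage is mild, coarse enough to bound |Z| at
`Φ⁻¹(0.99) ≈ 2.33`.

`ES = Σ mod·w·Z` over the regulon's targets and `NES = ES/√(Σ(mod·w)²)`;
targets absent from the matrix are dropped and the null SD recomputed over
the targets actually used, which keeps the analytic null exact (a regulon
with no present targets is removed). NES is invariant to global positive
rescaling of the weights and antisymmetric under flipping every mode.
Downstream, regulators are ranked by activity SD (top 700 by default,
capped at availability) and class-specific regulators read off one-vs-rest
Student's t-tests of NES.

## Conservation GSEA

A class signature is the per-regulator mean NES difference between one
class and all others; its rank transform (average ranks on ties) is the
reference ranking. The query is the top-k most activated regulators of the
same class in the other species, translated through orthology (regulators
without orthologs are dropped with a warning; k = 50 by default, capped in
the pipeline at the positively scored regulators and at one less than the
regulator count, since the running-sum statistic is undefined when the
query covers everything). The enrichment score is the GSEA-style weighted
Kolmogorov–Smirnov running sum (weight exponent 1, weights |score|,
signed maximum deviation). The null permutes cell class labels uniformly
at random, recomputing signature and ES each time; `NES = ES/mean|ES_null|`
and the two-sided `p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm)`, so p is
never below the permutation floor `1/(n_perm+1)`. Fewer than 100
permutations are refused.

**Choice of permutation unit.** With few regulators the cell-label null is
degenerate: regulator activities are strongly correlated through the class
structure, so a label permutation that merely enriches the in-group for
the target class reproduces the observed ordering, and with ~20 regulators
a few percent of permutations tie the saturated ES — the p-value plateaus
well above the floor however strong the signal. Cell permutation remains
the default (it is the conservative, structure-respecting null), and
`perm_unit="regulators"` provides the standard gene-set permutation, which
is exactly calibrated for random queries and resolves the floor; the test
suite exercises the positive control under the regulator null and the
significance (p < 0.05) of true programs under the cell null. With
hundreds of regulators, as in real applications, the distinction fades.

## Pipeline and reproducibility

One global seed fans out to per-stage seeds by hashing the stage name, so
stages can be rerun in isolation. Every run writes a manifest naming the
config hash, stage parameters and SHA-256 of each artifact; identical
configs give byte-identical artifacts. YAML configs reject unknown keys.

## Problem sizes used by the tests

Unit tests run on toy matrices and a reduced simulation (4 types × 90
cells, 600 genes); parameter-recovery acceptance checks run at the
generator defaults (6 types × 330 cells × 2 species, 2,000 orthogroups,
20 regulators) with 10,000-permutation GSEA; the Monte-Carlo ES null uses
100,000 draws. These sizes were chosen as the smallest at which each
statistic's behavior is unambiguous.

## Known limitations

- Network inference is out of scope: regulons are inputs (or synthetic),
  never inferred from expression, and modes are taken as given.
- The simulator's homology map is injective; one-to-many type splits are
  not generated (the mapping statistics support them — several test types
  may match one training type — but recovery of splits is untested).
- Sample-permutation GSEA p-values saturate at small regulator counts
  (above), and the bootstrap NJ supports are over genes, not cells.
- HVG selection by plain SD favors highly expressed genes more than a
  variance-stabilized ranking would.
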