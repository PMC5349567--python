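# Methods

## Model

Observations are sequencing reads assigned to OTUs that sit at the
leaves of a rooted phylogenetic tree `T` with nonnegative branch
lengths `L_i` (arbitrary units; all results are invariant to rescaling
all lengths by a constant). For every node `i`, `p_i` is the frequency
of observations descending from `i`; at the root `p = 1`, and at any
internal node `p_i` equals the sum of its children's values. The
abundance-weighted mean depth `T_bar = sum_i L_i p_i` normalizes all
entropies, so the framework applies to non-ultrametric trees.

The phylogenetic Shannon entropy is

    Hp = - sum_i (L_i / T_bar) p_i ln p_i        (natural log; 0 ln 0 = 0)

`exp(Hp)` counts *equivalent lineages*: `n` equally abundant leaves on
a unit star tree give exactly `exp(Hp) = n`, which is the property that
fixes the `1/T_bar` scaling (no other scaling makes the star identity
exact). Natural log is paired with `exp` so the equivalent-number units
come out right.

### Partition

Observations carry a group label `g` with weight `w_g`. Writing
`a_ig` for the within-group frequency of branch `i` and
`p_ig = w_g a_ig`:

* `H_gamma`: `Hp` of the pooled marginal `p_i = sum_g p_ig`.
* `H_alpha = sum_g w_g Hp(g)`, where `Hp(g)` uses `a_ig` but the
  *pooled* `T_bar`. Using per-group depths would break additivity;
  with the pooled depth, `H_gamma = H_alpha + H_beta` is an algebraic
  identity (verified to 1e-9 on randomized instances and to 1e-12
  against a brute-force oracle on small trees).
* `H_beta = sum_i (L_i/T_bar) sum_g p_ig ln(p_ig / (p_i w_g))` — the
  mutual information between lineage and grouping. Each branch's term
  is `(L_i/T_bar) p_i KL(p_ig/p_i || w)`, hence nonnegative; the terms
  localize between-group structure on the tree and sum to `H_beta`.
* Turnover `= H_beta / H(G)` with `H(G) = -sum_g w_g ln w_g`, the
  maximum mutual information the design permits. For two equal-weight
  groups it equals the unshared observation fraction, which the test
  suite checks over a grid of planted fractions.

### Weighting choices

* **Group weights** default to `w_g = 1/G` so each group contributes
  equally rather than proportionally to its read depth — sequencing
  effort routinely differs by orders of magnitude between environments
  and would otherwise dominate the pooled frequencies. The
  read-proportional estimator is available via `weighting="proportional"`.
* **Within a group**, reads of all replicate samples are pooled before
  normalizing; equalizing samples inside a group is an opt-in flag
  (`equalize_samples=True`) because replicates of one compartment are
  treated as repeated draws of the same community.
* Pairwise sample turnover treats each sample as a group with weight
  1/2, making the distance matrix independent of per-sample depth.

### Numerical conventions

`0 ln 0 = 0` throughout; branches with `p_i = 0` contribute nothing.
The root has no branch (`L = 0`) and any node with `p_i = 1`
contributes 0 automatically. Per-branch β terms are mathematically
nonnegative, but floating-point cancellation can produce residues
around −1e−17; these are clipped to zero (values below −1e−9 raise, as
they would indicate a real defect). Lineages are addressed by internal
node label when the newick provides one and by the deterministic
preorder name `L<i>` always.

## Permutation test

Null: group labels carry no information about lineages. Labels are
re-assigned to individual reads without replacement, preserving each
group's read total — per OTU this is a multivariate-hypergeometric
split of its pooled count. The implementation permutes an expanded
read-label vector (provably the same distribution) so hundreds of
permutations reduce to array shuffles and bincounts. One-sided
p-value with the +1 Monte-Carlo correction; default 999 permutations.
Calibration is verified empirically: over 200 null datasets the
rejection rate at α = 0.05 stays inside the 99% binomial band.
Permuting whole samples instead of reads (`unit="sample"`) is offered
for sensitivity analysis; it is far more conservative with few
replicates.

## Ordination

Pairwise turnover is not guaranteed Euclidean-embeddable. PCoA uses
classical metric scaling (via scikit-bio); negative eigenvalues are
dropped and their share of total inertia reported as
`negative_inertia`. No Lingoes/Cailliez correction is applied by
default — the interest is in relative placement, not exact embedding.

## OTU filters

`filter_min_count` drops OTUs below a total read count (default 75)
across all samples, the customary guard against spurious
amplicon-error OTUs. `subset_by_taxa` keeps OTUs whose classifier
lineage string mentions any target rank name (case-insensitive
substring); the default target list is the eight candidate-phyla /
CPR names (Parcubacteria, Microgenomates, Saccharibacteria,
Dependentiae, OP3, OP1, BRC1, WS3). Both filters are row predicates on
the same totals, so their order does not change the surviving set.

## Synthetic data generator

The generator exists so every stage is testable with known ground
truth. `simulate_tree` produces unit star trees or pure-birth (Yule)
trees with exponential waiting-time branch lengths (a final waiting
time is appended after the last birth so no pendant edge has zero
length). A `SyntheticScenario` plants named clades with exact per-group
abundance shares; within a clade the share is split equally among its
leaves, and the leftover mass is spread uniformly over shared
background leaves, identically in every group. Reads are multinomial
per sample (Dirichlet-multinomial with an `overdispersion` parameter
for stress tests; pure multinomial is the default because no explicit
biological noise model is assumed).

The `dwtp` preset emulates a three-compartment drinking-water
treatment plant: groups GW, CF, CHL with 4 replicate samples each at
depth 10,000 reads (GW sampled 3× deeper, exercising the
equal-weighting estimator); a 12-leaf clade `L1372` enriched in treated
water with per-group shares 4% / 68% / 58%, a 10-leaf clade `L420`
typical of groundwater with shares 58% / 7% / 10%, and 18 shared
background leaves; clade sizes, replicate count and depth are package
choices documented in `truth.json`. Taxonomy strings reuse the
candidate-phyla names (plus a Proteobacteria background fraction) so
the taxonomy subset is exercised end to end.

What the generator does **not** emulate: sequencing error and chimeras,
OTU-clustering artefacts, compositional biases of extraction/PCR,
phylogenetic uncertainty in the tree, or temporal autocorrelation
between samples. Passing tests therefore demonstrate correctness of
the estimators and their sampling behaviour under clean multinomial
noise, not robustness to real amplicon pipelines.

## Problem sizes used in checks

Randomized invariant checks use 500 instances of 4–24-leaf trees with
2–4 groups; oracle equivalence uses 200 instances with ≤8 leaves;
permutation calibration uses 200 null datasets of 150 reads × 2 groups
on a 16-leaf tree with 999 permutations each; parameter recovery uses
100 preset replicates at default size. The acceptance script runs the
preset at default size with 999 permutations.

## Known limitations

* Only the Shannon (order-1) member of the Hill family is implemented;
  no rarefaction (the permutation framework deliberately avoids
  subsampling) and no UniFrac-style metrics.
* The β in "equivalent-sample" units (`exp(H_beta)`) is reported but
  hard to interpret when group depths differ; turnover is the
  recommended summary.
* `lineage_contribution` is undefined when `H_beta = 0` and raises.
* With a single group, β and turnover are undefined; α and γ are still
  computed.
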