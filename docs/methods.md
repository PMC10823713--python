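# Methods

This note documents the statistical procedures implemented in
`nichecompare`, the modeling assumptions behind the synthetic cohort
generator, the defaults that matter, and the numerical choices made where a
convention had to be fixed.

## Normalization convention

Everywhere "normalized expression" appears — signature scores,
ligand–receptor means, marker tests, pseudobulk profiles — it means
per-cell (or per-pseudobulk) library-size scaling to 10,000 counts followed
by log(1 + x). This is the dominant convention in the field and is fixed
package-wide so that thresholds (e.g. the 10% detection ratio) have a single
meaning. No other transformation (scaling to unit variance, HVG selection
before scoring) is applied.

Gene identity is by symbol, case-sensitive. Signature or ligand–receptor
genes absent from a matrix are dropped with a logged warning; an operation
that would be left with zero genes raises instead.

## QC gating

A cell is retained iff `total_umi >= 700` and `mito_frac <= 0.20` and
`doublet_score <= 0.40`. The removal rules are strict inequalities ("fewer
than", "more than", "above"), so boundary cells pass — this matters for
reproducibility across implementations. Mitochondrial fraction and doublet
score are consumed from the cell metadata; they are measurements of the
upstream pipeline, not something this package re-derives. For reporting,
a cell failing several rules is attributed to the first failing rule in the
fixed order (UMI, mito, doublet); retention itself is the conjunction.

## Marker Z score

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests per cluster
(asymptotic, tie-corrected). The ranking statistic is the signed probit
transform z = sign(µ_in − µ_out) · Φ⁻¹(1 − p/2). The transform is the
natural "p-value determined Z"; it is monotone in p, zero at p = 1, and is
capped at |z| ≤ 37 because a two-sided p below ~1e-300 underflows double
precision. The marker filter is strict: z > 3. Clusters with fewer than 3
cells are skipped. BH correction is applied across genes within each
cluster; the filter itself uses z (i.e. raw p), matching the screening role
the statistic plays.

## Signature scores

Per-cell score = unweighted mean of normalized expression over the present
signature genes (duplicates removed on construction, so scores are invariant
to repeated genes). Per-sample score = arithmetic mean over the sample's
cells, optionally restricted to one cell type. Condition contrasts are
two-sided Wilcoxon rank-sum tests on sample-level scores — cells are not
treated as independent replicates — with BH correction across the condition
pairs tested in one call. Pairs with fewer than 2 qualifying samples per
side are reported untested.

## Composition analysis

Cluster-based: cell-type fractions are computed within a major population
(e.g. T-cell subtypes within the T lineage), because whole-sample
denominators confound subtype shifts with lineage shifts. Samples
contributing fewer than 50 cells of the major population are excluded for
that population's subtypes — a small-sample guard. A gated sample with zero
cells of a particular subtype counts as fraction 0, not missing. Testing is
two-sided Wilcoxon rank-sum on per-sample fractions, BH across cell types
within each condition pair.

Cluster-free: per-sample Gaussian KDE on the provided 2D embedding,
evaluated on a shared grid (default 400×400) spanning the global bounding
box plus 2% padding per side; each sample's map is renormalized to sum 1 so
samples with different cell counts are comparable, and condition maps are
unweighted means over samples. Bandwidth is Silverman's rule per sample
(scipy's covariance-based factor); the grid follows the bounding box, so the
whole pipeline is invariant to affine rescaling of the embedding. Degenerate
samples (zero variance in an axis, or < 3 points) fall back to a normalized
2D histogram, preserving point-mass behaviour; samples with fewer than 10
cells are excluded. The per-bin difference statistic is the standardized
two-sided Wilcoxon rank-sum statistic across per-sample densities (positive
= enriched in the first condition); fully tied bins (e.g. all-zero) get 0.
How to threshold or color this map is left to the user.

## Expression distance

Pseudobulk profiles: per (sample, subpopulation) sum of raw counts over
cells (pairs with < 10 cells dropped), normalized and log1p'd. Distances are
computed on the 2,000 most variable genes across all pseudobulks
(configurable); Pearson correlation distance d_s = 1 − r_s per shared
subpopulation; the sample-pair distance is Σ w_s d_s with w_s equal to the
mean of the two samples' subpopulation proportions, renormalized to sum 1
over the subpopulations present in both samples. The mean (rather than min)
weighting was chosen because it is continuous in the proportions. Distances
therefore live in [0, 2]; pairs sharing no subpopulation are undefined
(NaN) and excluded from the projection with a warning.

Projection is classical (Torgerson) MDS: double-center −D²/2, take the top
two eigenvectors scaled by the root eigenvalues (negative eigenvalues
clipped). Classical MDS reproduces Euclidean-embeddable distance matrices
exactly, which gives the module a sharp correctness oracle; coordinates are
deterministic up to sign/rotation, so consumers should compare embedded
pairwise distances, not raw coordinates.

## Pseudobulk differential expression

Aggregation: per sample, cells of the target type are counted; samples with
< 10 cells are excluded and samples with > 320 cells are downsampled to 320
uniformly without replacement (seeded). Counts are summed per gene.

Test: a negative-binomial Wald test authored here (no external DE package
is called):

* size factors by median-of-ratios over genes positive in every sample,
  falling back to library-size ratios when fewer than 10 such genes exist;
* gene-wise dispersion α (variance µ + αµ²) by method-of-moments on
  normalized counts, pooled across the two groups and floored at 1e-8 —
  no shrinkage toward a trend, which keeps the estimator simple and the
  test's calibration a matter of direct simulation rather than equality
  with any particular reference implementation;
* per-group means fitted by Newton iteration on the NB score equation with
  size-factor offsets; Wald z = log₂FC / SE with SE from the Fisher
  information of both groups.

Genes with all-zero counts are untested. Genes expressed in only one group
get a large finite log₂FC (±30) and p = 1 — with no information in the
other group the Wald contrast is undefined, and reporting a conservative
p avoids spurious discoveries from single-group dropouts. An
independent-filtering analogue excludes genes with mean normalized count
< 1 from the BH family. Significance: p_adj < 0.05 and |log₂FC| > 1.5
(both configurable; some applications tighten p_adj to 0.01).

Under null NB simulations (θ = 10, 8 vs 8 samples, 2,000 genes) the Wald
p-value attains type-I error ≈ 0.07 at α = 0.05 — slightly anticonservative,
as expected without dispersion shrinkage at n = 8, and bounded in the test
suite to [0.03, 0.08].

Leave-one-out resampling: each of 100 rounds removes one uniformly chosen
sample (seeded), re-runs aggregation (fresh downsampling) and the test, and
BH within the round. Per-gene outputs are the median p and median log₂FC
across rounds, the BH adjustment of the median p, and the *support*: the
fraction of rounds in which the gene was significant. Median aggregation
was chosen for robustness; with one round the procedure reduces exactly to
a direct test on the reduced design. Rounds that violate the 2-samples-per-
group minimum are skipped; fewer than half successful rounds is an error.

## Ligand–receptor permutation test

Candidates are ordered cluster pairs (A, B) × LR pairs where the ligand is
detected (normalized value > 0) in ≥ 10% of A's cells and the receptor in
≥ 10% of B's cells; autocrine pairs (A = B) are allowed. The score is the
product of mean normalized expressions. The null shuffles all cluster
labels jointly, once per round, reusing the shuffle across candidates —
valid under exchangeability, vectorizable, and the standard practice of
permutation CCC tools; p = (1 + #{perm ≥ obs}) / (B + 1) with B = 1000, so
p is never 0 and is valid (P(p ≤ α) ≤ α up to the permutation granularity).
The marker screen then requires ligand z > 4 in the sender and receptor
z > 0 in the receiver (strict, from the marker table on the same
clustering; a missing marker entry counts as z = 0 and fails). Reported
interactions must pass the permutation test *and* the screen — the screen
is a conjunction, not an alternative route. Multi-subunit complexes are out
of scope; rows are single-gene pairs.

## Survival analysis

Patients are scored by the mean bulk expression of the signature's present
genes and stratified into the top and bottom floor(0.25 n); ties at a
boundary are broken by stable patient-id order so the strata are
deterministic. The strata are compared by a two-sided log-rank test with
Kaplan–Meier curves (lifelines), and by a Cox proportional-hazards model
with age and one-hot-encoded stage (first sorted level as reference);
non-convergence is returned as a flagged result rather than an exception.

Gene-subset bootstrap: 200 rounds each draw max(2, round(0.8 · |signature|))
genes without replacement, re-stratify (the score changes with the subset,
so strata are recomputed per round rather than frozen), and re-run the
log-rank test. The reported statistic is the 0.90 empirical quantile of the
200 p-values under linear (type-7) interpolation — both the subset fraction
(80%) and the quantile level are configurable, since conventions for this
"reproducibility p-value" vary between 0.90 and 0.95.

## Synthetic cohort generator

The generator emulates a bone-metastasis case/control design: by default 9
BoneMet, 4 Involved, 4 Distal and 9 Benign samples, six cell types with
marrow-like base proportions, and per-sample type proportions drawn from a
Dirichlet (concentration 60) around condition-specific targets. Planted
effects, all recorded in a truth record:

* composition multipliers (default: TAM ×3, Treg ×2, NaiveT ×0.4 in
  BoneMet), renormalized to proper proportions;
* 5 marker genes per type at 8× elevation;
* an 8-gene signature module at 2× in BoneMet CTL cells (an
  exhaustion-module analogue);
* 20 DE genes at |log₂FC| = 2 (alternating sign) in one type between two
  conditions;
* one ligand–receptor coupling (ligand ×5 in TAM, receptor ×5 in Treg —
  a CCL18→CCR8-style axis);
* QC nuisance cells: 5% low-UMI (binomially thinned below 700 counts),
  3% high-mito, 2% high-doublet, flagged disjointly. Baseline cells are
  guaranteed to pass every gate (bounded baseline mito/doublet scores, a
  700-count floor) so the planted flags are the exact expected removals.

Counts are gamma-Poisson: NB with mean = type profile × lognormal cell size
factor and variance µ + µ²/θ, θ = 2 at the cell level (overdispersed, as
real UMI data are); gene means are lognormal, scaled to ~3,000 expected
counts per cell. The embedding is synthetic Gaussian blobs (per-type
centers on a circle, sd 1) — the density analysis operates on a *given*
embedding, so any layout with known geometry suffices. The generator does
not emulate batch effects, ambient RNA, realistic doublet transcriptomes
(scores are planted directly), or gene–gene correlation beyond the planted
modules; passing tests therefore demonstrate calibration and recovery under
a clean generative model, not robustness to those artifacts.

The survival generator draws a latent activity per patient, loads it on the
signature genes with unit loading plus unit Gaussian noise, and assigns
exponential event times with hazard multipliers 1 / √HR / HR for the
bottom / middle / top activity quartiles, so the planted top-vs-bottom
hazard ratio is exactly HR. Censoring is independent exponential, tuned to
the requested marginal rate; age is N(60, 10) with an optional
activity-confounding term, stage categorical.

A sample-level generator (`simulate_nb_pseudobulk`) produces aggregated NB
counts directly (lognormal gene means, lognormal library sizes, planted
log₂ fold changes) for testing the DE stage at the scale it actually
operates on.

## Simulation sizes and determinism

Tests and the acceptance script run cohorts of 16–26 samples × 80–250 cells
× 30–120 genes, DE simulations of 2,000 genes × 16 samples, 1,000-round
permutations, 100-round LOO resampling, and 200-round bootstraps; these
sizes give each check adequate power while keeping the full suite in the
minutes range on one CPU. All randomness flows from explicit seeds
(numpy `default_rng` / `SeedSequence`); identical seeds give byte-identical
outputs, including every CLI subcommand's files.

## Known limitations

* The NB Wald test omits dispersion/fold-change shrinkage, so at small
  sample numbers it is mildly anticonservative (≈0.07 at nominal 0.05) and
  its fold-change estimates are unshrunken; its operating characteristics
  are established by simulation, not by equivalence to any reference tool.
* The survival design has an intrinsic power ceiling: with a top-vs-bottom
  quartile hazard ratio of 2.0, n = 200 (50 vs 50 strata) and ~30%
  censoring, per-seed log-rank power is ~0.8 under perfect stratification
  and lower under score-based stratification; detection rates reported at
  these sizes reflect that ceiling, not an implementation defect. Larger
  cohorts (n ≥ 400–600) reach ≥90% power.
* Cluster labels, embeddings, and doublet scores are consumed as given;
  errors in them propagate. Compositional tests treat samples as
  exchangeable within condition (no patient-level pairing).
* Ligand–receptor analysis has no complex (multi-subunit) semantics and no
  spatial component; "interaction" means co-elevated expression, not
  demonstrated signaling.
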