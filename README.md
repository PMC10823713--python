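# nichecompare

Comparative statistics for multi-sample, multi-condition single-cell RNA-seq
cohorts — the kind of case/control design used to study how a tissue niche
(for example, bone marrow invaded by metastatic carcinoma) differs from
healthy or benign controls across several sample fractions.

The package takes raw UMI count matrices plus per-cell and per-sample
metadata (cluster labels and 2D embeddings are consumed as inputs, not
computed) and provides:

* **QC gating** — remove cells with < 700 total UMI, > 20% mitochondrial
  counts, or doublet score > 0.40 (strict inequalities; boundary cells kept).
* **Marker detection** — one-vs-rest two-sided Wilcoxon rank-sum per
  cluster, ranked by the signed probit transform of the p-value,
  z = sign(µ_in − µ_out) · Φ⁻¹(1 − p/2), filtered at z > 3.
* **Signature scoring** — per-cell mean of log-normalized expression over a
  gene set; sample-level means contrasted across conditions by Wilcoxon
  rank-sum with Benjamini–Hochberg correction.
* **Composition testing** — cluster-based: per-sample cell-type fractions
  within a major population (samples with < 50 cells of that population
  excluded), Wilcoxon + BH; cluster-free: per-sample Gaussian KDE on a
  shared 400×400 embedding grid, condition-averaged, differenced per bin
  with a standardized Wilcoxon statistic.
* **Expression distance** — per (sample, subpopulation) pseudobulk profiles;
  D(i,j) = Σ_s w_s (1 − r_s) with r_s the Pearson correlation of the shared
  subpopulation profiles and w_s the mean subpopulation proportion,
  renormalized over shared subpopulations; projected by classical MDS.
* **Pseudobulk differential expression** — per-sample aggregation with a
  10-cell minimum / 320-cell downsampling cap, negative-binomial Wald test
  (median-of-ratios size factors, method-of-moments dispersion), BH
  correction, significance at p_adj < 0.05 and |log₂FC| > 1.5, and a
  100-round leave-one-out sample resampling reporting per-gene support.
* **Ligand–receptor analysis** — CellPhoneDB-style score
  s = mean(ligand in A) · mean(receptor in B) for genes detected in ≥ 10%
  of the respective cluster, a 1000-round cluster-label permutation p-value,
  and a marker screen (ligand z > 4 in the sender, receptor z > 0 in the
  receiver); reported interactions pass both.
* **Survival analysis** — bulk-cohort signature scores, top vs bottom
  quartile stratification, two-sided log-rank + Kaplan–Meier, Cox PH
  adjustment for age and stage, and a 200-round gene-subset bootstrap
  reporting the 0.90 quantile of the resampled p-values.

A first-class synthetic cohort generator (`nichecompare.simulate`) plants
every effect the pipeline is meant to detect — composition shifts, markers,
signature modules, DE genes, ligand–receptor couplings, QC failures, and a
signature-linked hazard — and reports them in a truth record, so each stage
can be tested for calibration and recovery against known ground truth.

## Worked example

```python
from nichecompare.simulate import CohortSpec, simulate_cohort
from nichecompare.qc import apply_qc
from nichecompare.composition import composition_test
from nichecompare.markers import score_signature, compare_signature_across_conditions
from nichecompare.datatypes import AnalysisConfig, GeneSignature

spec = CohortSpec(seed=0, cells_per_sample=(200, 300))   # 9 BoneMet / 4 Involved / 4 Distal / 9 Benign samples
counts, cells, samples, truth = simulate_cohort(spec)

filtered, cells, report = apply_qc(counts, cells, AnalysisConfig())
print(f"QC: {counts.n_cells} cells -> {report.total_retained()} retained")

major = {t: "All" for t in spec.cell_types}
res = composition_test(cells, samples, major, [("BoneMet", "Benign")])
print(res[["cell_type", "frac_a_median", "frac_b_median", "p", "padj"]].round(4))
```

prints

```
QC: 6337 cells -> 5703 retained
cell_type  frac_a_median  frac_b_median      p   padj
      CTL         0.1700         0.1629 1.0000 1.0000
      MSC         0.0863         0.1414 0.0192 0.0384
     Mono         0.2129         0.2670 0.0934 0.1401
   NaiveT         0.1019         0.2165 0.0008 0.0024
      TAM         0.2990         0.1082 0.0006 0.0024
     Treg         0.1152         0.0681 0.3096 0.3716
```

The generator plants a 3× proportion increase of the TAM-like type (and a
compensatory NaiveT decrease) in the BoneMet condition; the composition test
recovers exactly those shifts at p_adj < 0.05 (the MSC hit at 0.038 reflects
the renormalization of the remaining types). Scoring the planted signature
module in CTL cells and contrasting BoneMet against Benign sample means
gives `median 3.16 vs 2.45, padj 4e-4` — the analogue of an exhaustion-score
comparison between disease fractions.

Every stage is also available from the shell via `nichecompare <subcommand>`
(`simulate`, `qc`, `markers`, `score`, `composition`, `density`, `distance`,
`de`, `lr`, `survival`); outputs are TSV and byte-reproducible for a fixed
config seed.

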