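# Methods

## Data model

The pipeline operates on the classic 27K-style promoter methylation design:
a manifest of CpG markers (chromosome in {1..22, X, Y}, nearest gene symbol,
signed offset to the transcription start site), a markers × samples matrix
of beta values β ∈ [0, 1] (fraction methylated, NaN = missing, never
imputed), and a sample sheet assigning each sample to one of three clinical
groups — FC (febrile controls, n = 4), KD1 (acute Kawasaki disease before
IVIG, n = 7), KD3 (three weeks after IVIG, n = 7). All analyses reduce to
three pairwise contrasts: KD1 vs FC (disease onset), KD3 vs FC and
KD3 vs KD1 (treatment effect).

## Differential testing

Each marker is tested with a two-sided two-sample *t*-test on its beta
values; significance is the strict inequality p < α with α = 0.05 and no
multiple-testing correction by default, because the downstream statistics
(per-chromosome rates, union, filter) are defined on raw-p calls. The
default flavor is the **pooled-variance (Student) test**, with Welch
selectable per call. Rationale: the two-group nulls this pipeline is
validated against have equal group variances by construction, where the
pooled test is exact under normality, and at the design's small unequal
sizes (4 vs 7) the Welch–Satterthwaite approximation is measurably
conservative (simulated null level ≈ 0.048 rather than 0.050), which
distorts the calibration of the significance-rate statistic. Missing
entries are dropped marker-wise; a marker with fewer than two observations
in either group is *untestable* (p undefined, never significant, excluded
from rate denominators), and a marker with zero variance in both groups and
equal means likewise yields an undefined p. The sign convention is
Δβ = mean(test) − mean(reference), with the t statistic oriented the same
way.

The per-chromosome **significance rate** is #significant / #tested per
chromosome, summarized by the mean and sample SD (ddof = 1) across the
chromosomes present. Denominators count the markers that actually entered
testing, the reading of "all markers on the chromosome" that keeps the
counts conserved: Σ per-chromosome totals = #testable markers.

−log10(p) values are provided for Manhattan-style displays; p = 0 (possible
only for degenerate zero-variance separations) maps to a configurable cap
(default 300) and is logged. Plot rendering itself is out of scope.

## Alteration filter

A marker is *altered* when it satisfies, in at least `min_comparisons` = 2
of the three comparisons, the joint criterion p < 0.05 **and** alteration
\> 10% (both strict). "10% alteration" is ambiguous between two scales, so
both are implemented and the choice is recorded in every run manifest:

- `absolute` (default): |Δβ| > 0.10, i.e. ten percentage points of
  methylation — the standard effect-size measure for array EWAS;
- `relative`: |mean β(test)/mean β(reference) − 1| > 0.10, i.e. a 10% shift
  on the scale where the comparison's reference group is 100%.

Selected markers are labelled **hyper-** or **hypo-methylated** from the
sign of Δβ in the first FC-referenced comparison; exact ties are left
unclassified rather than forced. Group methylation is also reported on the
FC = 100% scale (rel_KD1, rel_KD3 = 100 · mean β(group)/mean β(FC)); markers
whose FC mean is zero are flagged undefined and logged. Tightening any
threshold can only shrink the selected set; this monotonicity and exact
agreement with a naive double-loop evaluation of the rule are enforced by
tests.

## Gene-set enrichment

Significant markers are mapped to their manifest genes (a gene with several
markers counts once; unannotated markers are dropped with a warning). Each
gene set is scored with the upper-tail hypergeometric probability
P(X ≥ k) for X ~ Hypergeom(N, K, n) — N universe genes, K set members in
the universe, n query genes in the universe, k the overlap — with
P(X ≥ 0) ≡ 1 and no mid-p adjustment. The universe is a policy choice the
run records: `intersect` (default; genes present in both the manifest and
the gene-set collection, standard over-representation practice), `gmt`, or
`manifest`. Raw p < α defines a significant pathway, and the pipeline
intersects the pathway lists of the two post-treatment contrasts
(KD3 vs FC ∩ KD3 vs KD1); the onset contrast can be added by flag but is
excluded from the intersection by default. No multiple-testing correction
is applied to pathway p-values by default.

## Methylation–expression bootstrap

For one gene, the inputs are per-group *unpaired* pools: methylation assays
(β) and qPCR ΔCt assays of different sizes (defaults 4/7/7 β assays and
26/24/10 ΔCt assays for FC/KD1/KD3), with no per-sample correspondence.
Each group is resampled B times (default 10,000) and each run contributes
one (β, ΔCt) point; the 3B pooled points are summarized by one Pearson
correlation. Because the pools are unpaired and unequal in size, what "one
run" draws is a genuine modelling choice; both options are implemented and
the mode is recorded in the output:

- `draw` (default): one β and one ΔCt drawn independently, with
  replacement, from the group's pools. As B → ∞ the pooled cloud converges
  to the equal-weight group mixture of within-group product distributions,
  whose correlation has a closed form used as a test oracle.
- `resample_mean`: each pool is resampled to its own size and the run emits
  the pair of resample means (a bootstrap of the group means; tighter
  clouds, more weight on between-group structure).

Under `draw`, within-group independence means any nonzero pooled r is
carried by the between-group co-movement of the two modalities — exactly
the association of interest. Groups are always processed in the fixed order
FC, KD1, KD3 from one seeded generator, so results are reproducible. The
reported interpretation flips the sign for expression: ΔCt rises as
expression falls, so r > 0 reads "methylation negatively associated with
expression".

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the assay chemistry:

- **Manifest** — 27,578 markers by default, placed on chromosomes by a
  single multinomial draw with weights proportional to approximate
  per-chromosome protein-coding gene counts (a promoter array tracks gene
  density); synthetic gene symbols with ~1.9 markers per gene; TSS offsets
  uniform on [−1500, 200].
- **Beta values** — per-marker baseline means from a bimodal mixture
  (70% Beta(2, 18), mean 0.10; 30% Beta(17, 3), mean 0.85 — the marginal
  shape typical of promoter arrays), clipped to [0.02, 0.98]; observations
  are Beta(μ·φ, (1−μ)·φ) with precision φ = 200 by default, giving
  within-group SD ≈ 0.02–0.035 as seen between replicate array probes.
  Missingness is optional (default 0) and flagged as NaN.
- **Planted effects** — (markers, group, Δβ) triples added to the group's
  true means. Count-based selectors draw only among markers whose shifted
  mean stays strictly inside (0, 1) — a hyper-methylating effect lands on
  markers that can still gain methylation; explicit marker lists are taken
  literally and error if they leave (0, 1). On a null configuration all
  three groups share every marker's distribution by construction.
- **Expression pools** — ΔCt ~ Normal(intercept + coupling · μ_g, σ) with
  defaults intercept 6, coupling +8 cycles per unit β (positive coupling =
  methylation represses expression), σ = 0.5.
- **Gene sets** — random sets over manifest genes; optionally the first set
  is stocked from a supplied gene pool so enrichment recovery is testable
  by construction.

Reproducibility: every product (manifest, baselines, beta matrix, pools,
gene sets) consumes its own seed stream derived from the config seed, so
identical configs are bit-identical and regenerating one product does not
perturb another.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real arrays: probe-level two-channel intensities and
normalization, bisulfite-conversion efficiency, batch/chip effects,
spatial/neighbor correlation between CpGs, cell-type composition
heterogeneity of whole blood, and heavy-tailed or multimodal within-group
deviations from the Beta noise family. Results on real data additionally
depend on QC and normalization upstream of this pipeline.

## Numerical and design choices

- Strict inequalities throughout ("p < 0.05", "more than 10%"), matching
  how the thresholds are stated.
- Baseline means clipped to [0.02, 0.98]; planted means validated strictly
  inside (0, 1).
- Zero-variance and under-observed markers yield undefined p, never
  significance; undefined values propagate as NaN in transforms.
- Enrichment p-values computed via the scipy hypergeometric survival
  function; verified against exhaustive enumeration of all C(N, n) draws
  for every N ≤ 20 to 1e-12.
- Byte-level determinism of a full run: no timestamps in outputs, relative
  paths in the run manifest, fixed float formatting in TSVs.
- CLI exit codes: 0 success, 2 configuration error, 3 data error.

## Problem sizes used in validation

The test suite validates calibration on 200 null replicates of 20,000
markers (4/7/7), planted-effect recovery on 2,000 shifted + 20,000 null
markers at Δβ = 0.15 (7 vs 7), bootstrap convergence at B = 200,000 on
≤10-element pools, and full-pipeline determinism at 3,000 markers; the
acceptance script runs the complete pipeline at the full 27,578-marker
design with 800 onset-planted and 1,700 treatment-planted markers
(treatment predominantly hyper-methylating, mirroring the biology the
design targets). These sizes give Monte-Carlo error comfortably below every
asserted tolerance.

## Known limitations

- The paper-scale headline counts from the original clinical dataset are
  not reproducible here: the underlying microarray and qPCR data were never
  deposited, so the pipeline demonstrates the *procedures* on synthetic
  data with known ground truth instead.
- Raw-p significance (no FDR) is the faithful default for this analysis
  style; Benjamini–Hochberg-adjusted workflows should treat the per-marker
  tables as input and recompute calls.
- The alteration filter's two magnitude scales can disagree near the
  threshold; runs record which was used.
- ANOVA across all three groups simultaneously is not implemented; the
  pipeline's significance calls are pairwise *t*-tests.
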