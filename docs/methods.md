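# Methods

## The analysis model

`lightmask` reimplements, on synthetic data, an analysis strategy for
separating primary light-quality transcriptome responses from
development-driven changes in a 3-genotype x 2-light-source design. Its
core assumption is that developmental stage, not light quality, drives a
large share of within-genotype M-vs-F differential expression, because the
fluorescent treatment delays development by a genotype-dependent amount.
The disentangling device is purely set-algebraic: genes DE between the
developmentally most advanced genotype and each of the two slower ones
*under the control light* carry a development signal with no light-quality
involvement; their intersection (by gene id, ignoring direction of change)
defines the development set, which is subtracted from every genotype's
within-genotype DE set. The same operation is applied to enriched GO
terms. No causal model is fitted — the procedure's validity rests on the
control-light contrasts being light-free, which holds by construction here
and by design in the motivating experiment.

## The generative model

Counts follow a log-linear negative binomial:

```
count[g, s] ~ NB(mean = exp(b_g + slope_g * stage_s + ln2 * lfc_{g, geno(s)} * [cond(s) = F]),
                 var  = mean + dispersion * mean^2)
```

with gene classes *null* (83% of genes; `slope = lfc = 0`), *development*
(10%; `slope != 0`, `lfc = 0`), *light_shared* (5%; `lfc != 0` in every
genotype, magnitudes graded by sensitivity), and *light_specific* (2% per
genotype; `lfc != 0` in one genotype). Developmental stage is a latent
per-design-cell covariate; because the two light cells of a genotype sit
at different stages, development genes show M-vs-F differences within every
genotype — the confound the masking must remove — while their control-light
between-genotype differences make them identifiable.

### Default study conditions and why

All defaults live in `SimulationParams`; the notable ones:

* **Design** — 3 genotypes x 2 conditions x 3 replicates (18 samples), the
  size of the motivating experiment.
* **Stage layout** — `G_insensitive`: M 1.2 / F 0.6; `G_intermediate`:
  M 0.5 / F 0.1; `G_sensitive`: M 0.5 / −0.15 (arbitrary units). The
  insensitive line under control light is far ahead of every other cell
  (it has crossed the reproductive transition), giving it both the largest
  within-genotype stage gap — so its M-vs-F DE set is dominated by
  development — and a wide between-genotype gap (0.7) that powers the
  mask. Fluorescent light delays all genotypes; in absolute stage the
  delay is largest for the sensitive line.
* **Abundance** — null genes draw ln-baseline from N(8, 1); development
  and light genes from N(6.6, 0.4), and development trajectories are
  centred on the design's mean stage. Two constraints force this split.
  First, TPM is compositional: with ~20% of 2000 genes carrying planted
  effects, strong responders at bulk abundance shift every null gene's
  TPM and generate wholesale false positives; keeping effect genes ~4x
  below the bulk caps their library-mass share at a few percent. Second,
  the Poisson noise floor `1/mean` must stay small at every point of a
  development trajectory, which deep libraries guarantee.
* **Noise** — NB dispersion 0.005 (biological CV ~7%), appropriate for
  pooled leaf samples of inbred lines in controlled chambers, and chosen
  together with the effect sizes so that planted effects are detectable by
  a 3-vs-3 Welch test. That test has only 2–4 degrees of freedom, which
  caps attainable p-values; BH at q < 0.01 over 2000 genes needs typical
  |t| of 15–25, i.e. effects of ~2–4 log2 units at residual sd ~0.1.
* **Effect sizes** — development slopes |U(3, 4)| per stage unit (natural
  log); shared light effects |log2FC| ~ U(2.5, 4) in the sensitive
  genotype, scaled by (0.3, 0.7, 1.0) across (insensitive, intermediate,
  sensitive); genotype-specific effects unscaled. The insensitive scale
  0.3 places its shared responses near the detection threshold, which is
  what reproduces the qualitative headline that the insensitive genotype
  retains the smallest light/total fraction after masking.
* **Promoters** — gene lengths U(500, 5000) bp; every gene gets a 1700 bp
  clear flank so the widest window ([−1500, +200]) fits; the consensus
  `AAATACAT` is planted, promoter-sense, at a uniform offset in
  [−450, −60] in 70% of light-responsive genes (exact copies, no
  per-site mutation).
* **GO** — three planted development terms and three light terms annotate
  90% of their class and 2% of other genes; ten background terms annotate
  5% of all genes; the DAG is a small single-root `is_a` hierarchy.

With these conditions, averaged over five seeds, the retained sets recover
planted light genes at precision ≈ 0.85 and recall ≈ 0.97, the development
set covers ≈ 0.89 of planted development genes, and the retained-fraction
ordering holds in every seed. Per-seed values fluctuate by a few points:
the variance estimate of a 3-vs-3 Welch test is itself 2-df noisy, so a
small, irreducible fraction of strong effects lands above any fixed BH
threshold in any one contrast.

## Statistical choices

* **DE test** — Welch two-sample t on log2(TPM + 0.5). Pseudocount 0.5;
  two-sided; direction from the sign of the mean difference. Zero-variance
  rows are deterministic: equal means → p = 1, unequal → machine-floor p.
  No variance moderation or bootstrap uncertainty is modelled; downstream
  logic consumes only (direction, q) per gene.
* **Multiplicity** — Benjamini–Hochberg step-up, validated against an
  exhaustive min-over-tails oracle. Primary cutoff q < 0.01; q < 0.05 is
  the relaxed tier used for GO significance labelling ("\*" vs "\*\*").
* **Replicate QC** — Pearson r on log2(TPM+1) within genotype x condition
  groups; per-sample statistic = mean of its within-group r. The lower
  boxplot fence (Q1 − 1.5·IQR) is computed over the statistics of all
  samples pooled across groups, and flagging is iterative: the worst
  sample below the fence is removed, partners' statistics are recomputed,
  and the rule repeats. Pooling + iteration is deliberate: within a single
  group of three, the lowest of three statistics can *never* fall below
  its own group's Tukey fence (for sorted values b ≤ g1 ≤ g2 the condition
  requires b > g2 + 2(g2−g1)), so a per-group rule would be vacuous at
  this design size, and non-iterative pooling would also flag the
  flagged sample's partners, whose means are dragged down by it. A sample
  is only flaggable while its group keeps ≥3 unflagged replicates.
* **GO enrichment** — classic per-term upper-tail hypergeometric test
  after true-path (`is_a`) propagation, terms with <3 annotated universe
  genes untested; no decorrelation across the DAG (parent and child terms
  are tested independently). Universe = all genes with nonzero TPM in ≥1
  retained sample.
* **Motifs** — order-0 background (word frequencies over the whole
  promoter universe, both strands); upper-tail binomial word p-values, BH
  over words; greedy assembly around the most significant word (shift ≤ 2,
  ≤ 1 mismatch in the overlap, either strand), each aligned-word
  occurrence contributing a full-width site so column sums equal the site
  count; consensus uppercase where the plurality base reaches 75% of
  sites. Motif score = −log10 of the seed word's q-value. Significance is
  empirical: the identical chain runs on `n_null = 50` random same-size
  promoter clusters and `empirical_p = (1 + #null ≥ observed) / (1 + 50)`,
  so the smallest attainable value is 1/51 ≈ 0.0196.

## Numerical and degenerate-input conventions

Machine-floor p-values use `np.finfo(float).tiny`. All-zero samples give
all-zero TPM, not NaN. Zero-variance correlation pairs are reported as
missing, never as 0. Quartiles use linear interpolation (`np.percentile`
default). Venn regions are keyed by gene id; direction concordance is an
annotation, not a partition key, and discordant genes are always reported,
never dropped. Promoter windows clipped at contig edges record the
clipping; windows entirely off-contig yield an empty sequence with a
warning. Every generator and every resampling routine is a pure function
of its parameters and a seed.

## Problem sizes

The default study is 2000 genes x 18 samples, sized so the full test suite
runs in well under a minute and a complete pipeline run in seconds to a
couple of minutes depending on the motif-window grid. Motif experiments
use a 300-gene universe with 50-gene clusters and 50 null clusters, the
cluster scale of the procedure being emulated.

## What the synthetic data does and does not show

The generator reproduces the *structure* that makes masking necessary —
a stage-by-light confound with genotype-graded light sensitivity — under
idealised conditions: independent genes, a shared known dispersion,
log-linear effects, exact motif copies, and annotation noise that is
independent across genes. It does not emulate gene-gene correlation,
isoform structure, mapping ambiguity, GC or length biases, batch effects,
or compositional effects beyond those TPM itself induces. Passing the
recovery suites therefore shows the set algebra, the statistics, and the
calibration machinery are correct and well-powered under the stated model;
it does not certify performance on real reads. Results at other design
points (e.g. shallower libraries, weaker effects, higher dispersion) will
degrade smoothly and can be explored by overriding `SimulationParams`.

## Known limitations

* The per-gene Welch test at n = 3 is the power bottleneck; a
  moderated-variance test would recover more marginal effects but is
  deliberately out of scope.
* The development mask is binary; genes with mixed development and light
  signal are removed outright (a small recall cost for shared-signal
  genes, visible as precision/recall trade-off in the planted metrics).
* The motif assembler reports a single motif per (window, k) run — the
  best-seeded one — rather than an exhaustive motif census.
* GO masking compares term sets at a fixed significance tier; terms
  hovering at the threshold can flip tiers between runs of different
  seeds.
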