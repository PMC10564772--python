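# lightmask

Separating **primary light-quality responses** from **development-driven
expression changes** in multi-genotype, two-light-source RNA-seq designs —
as a fully tested pipeline on synthetic data with known ground truth.

## The problem

Expose three barley genotypes — insensitive, intermediate, and sensitive to
light quality — to two light sources of equal intensity and duration:
metal halide (M, the control) and fluorescent (F). Fluorescent light delays
development, and the delay differs by genotype, so at a common sampling
time the plants sit at different developmental stages. Any within-genotype
M-vs-F differential-expression (DE) contrast therefore mixes two signals:

* genes responding **directly to light quality**, and
* genes whose expression simply **tracks developmental stage** — a
  confound created by the light-induced delay, not a primary response.

The pipeline isolates the first class with a *development mask*: genes DE
between the developmentally most advanced genotype and **each** of the two
slower genotypes **under control light only** (so light quality plays no
role) are declared development-related and removed from every genotype's
M-vs-F DE set. Formally, with `DE(a, b | cond)` the set of genes passing a
BH q-value cutoff in a two-group contrast,

```
development = DE(ins, int | M)  ∩  DE(ins, sen | M)        (by gene id)
light(g)    = DE(g·M, g·F)  \  development                  (per genotype g)
```

The same masking is applied at the level of enriched GO terms, and the
retained gene sets feed a promoter motif search whose significance is
calibrated against 50 random same-size promoter clusters.

## What is in the box

| module | what it does |
|---|---|
| `lightmask.synthetic_data` | generates complete toy studies: design (3 genotypes x 2 lights x n replicates), negative-binomial counts with planted development/light/null genes, a genome + GFF3 gene models with a motif planted in light-responsive promoters, and a gene→GO map with an OBO-lite DAG |
| `lightmask.expression_qc` | TPM, replicate Pearson-correlation QC with boxplot-fence outlier discard, unigene→reference id mapping (1-to-many aware) |
| `lightmask.diffexpr` | Welch t per gene on log2(TPM+0.5), BH q-values, directional DE calls at q < 0.01 / 0.05 |
| `lightmask.contrast_masking` | development-set algebra, masking reports, three-way Venn regions with direction-concordance annotation |
| `lightmask.go_enrichment` | true-path propagation, upper-tail hypergeometric enrichment, development-GO masking |
| `lightmask.motif_discovery` | strand-aware TSS-window promoter extraction, k-mer binomial scoring, greedy motif assembly with cased consensus, empirical p against null clusters |
| `lightmask.pipeline` / `lightmask.cli` | YAML-config orchestration and the `lightmask` command |

## Worked example

```python
from lightmask.evaluate import run_masking_analysis, light_precision_recall, dev_mask_coverage
from lightmask.contrast_masking import masking_summary

analysis = run_masking_analysis(seed=1)
print(masking_summary(analysis.rows)[["genotype", "total", "development", "light", "light_pct"]].to_string(index=False))
precision, recall = light_precision_recall(analysis.truth, analysis.retained.values())
coverage = dev_mask_coverage(analysis.truth, analysis.dev_set)
print(f"planted light genes: precision={precision:.2f} recall={recall:.2f}; development coverage={coverage:.2f}")
```

prints

```
      genotype  total  development  light  light_pct
 G_insensitive    277          171    106       38.3
G_intermediate    310          157    153       49.4
   G_sensitive    335          175    160       47.8
planted light genes: precision=0.85 recall=0.98; development coverage=0.89
```

Reading the table: of the 277 genes DE between the two lights in the
insensitive genotype, 171 are attributed to development by the mask and 106
are retained as candidate primary light responses — the smallest retained
fraction of the three genotypes, as expected for a line whose development
reacts strongly to the sampling-stage confound but whose transcriptome
barely responds to light quality itself. Against the generator's ground
truth, the retained sets recover planted light-responsive genes with
precision 0.85 and recall 0.98, and the mask captures 89% of planted
development genes.

The full pipeline (simulation → QC → DE → masking → GO → motifs) runs from
a config:

```sh
lightmask all --outdir run --seed 1 --quiet > run_report.json
```

## Notes

* The study conditions (sample sizes, stage layout, effect sizes, noise)
  are fixed defaults of `SimulationParams`; see `docs/methods.md` for the
  model, the reasoning behind each default, and known limitations.
* Everything is deterministic given a seed; every generator is a pure
  function of `(params, seed)`.
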