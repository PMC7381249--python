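# cd8mir

Analysis toolkit linking smoking/nicotine exposure to a naïve-memory CD8+
T-cell program: miRNA microarray QC and cyclic-loess normalization,
moderated two-group differential expression, ΔΔCT qPCR quantification,
median-threshold phenotype scoring, the mRNA/miR ratio classifier with its
paired nicotine-shift analysis, exact small-sample statistics, and
Ward/Spearman clustering — exercised end-to-end on seeded synthetic cohort
generators so no data download is required.

## Library layout

| module | what it does |
| --- | --- |
| `cd8mir.io_core` | `ExpressionMatrix` (features × samples with a value-kind tag), `SampleTable`, `NoiseStats`, `AnalytePanel`; TSV/CSV readers/writers, GEO series-matrix reader, YAML config, logging |
| `cd8mir.microarray` | detection calling (noise mean + k·SD), background subtraction, sample QC, 80-AU mean filter / top-n, log2, cyclic loess |
| `cd8mir.de` | per-feature OLS, empirical-Bayes variance moderation (method-of-moments prior, moderated t), BH adjustment, strict logFC/p selection |
| `cd8mir.qpcr` | ΔCT/ΔΔCT fold changes, 2^(−ΔCT) quantities, relative quantity to the cohort median (RQ) |
| `cd8mir.phenotype` | naïve-memory point scoring (variant A: CD27 freq + IL7R/FOXO1/TCF7, ≥2 points; variant B: IL7R/FOXO1/BCL6/TCF7, ≥3 points) and the 2×2 smoking association |
| `cd8mir.ratio` | per-sample median-RQ mRNA/miR ratio, high/intermediate/low classification (cutoffs 1.5 and exactly 2/3), paired nicotine response shift |
| `cd8mir.stats_tests` | exact odds ratio (rational), Fisher exact by hypergeometric enumeration, Mann-Whitney U and Wilcoxon signed-rank with full-enumeration exact paths |
| `cd8mir.cluster` | pairwise-complete Spearman distances, Ward linkage, purity reports, Newick export |
| `cd8mir.simulate` | seeded generators for microarray cohorts (planted smoker effects, optional bad samples), paired qPCR CT tables (planted ratio groups + nicotine inversion), and phenotype marker tables — each with a truth record |
| `cd8mir.pipeline` | end-to-end orchestration with a digest-bearing run manifest |

## CLI

```bash
cd8mir simulate microarray --seed 1 --out-dir sim/
cd8mir normalize --raw sim/raw_intensities.tsv --noise sim/noise_stats.tsv \
    --out-dir norm/ --mean-threshold 80 --span 0.7 --iterations 3
cd8mir de --matrix norm/normalized.tsv --meta sim/samples.csv --out de.tsv \
    --lfc 0.5 --p 0.05
cd8mir cluster --matrix norm/normalized.tsv --meta sim/samples.csv \
    --k 2 --attribute smoker --out-dir clust/
cd8mir stats 9 4 5 11                 # odds ratio + Fisher p for a 2x2
cd8mir pipeline run --config run.yaml --out-dir out/ --seed 1
```

A minimal pipeline config:

```yaml
microarray: {}
qpcr: {}
phenotype: {smoker_counts: [9, 5]}
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

## Conventions worth knowing

- Stage order detection → QC → filter → log2 → loess is enforced through
  the matrix value-kind tag; stages reject inputs of the wrong kind.
- "Above the median" is strictly greater everywhere; ties score zero.
- The low ratio cutoff is exactly 2/3, not a rounded 0.667.
- Exact rank-test p-values double the smaller enumerated tail (capped at
  1); Fisher sums all tables whose point probability is at most the
  observed one.
- All randomness flows from explicit seeds; generators are pure functions
  of (config, seed).
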