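# cecofec

Paired cecum-vs-feces microbiota comparison for 16S amplicon studies.

In many animal studies — rabbits, pigs, poultry — feces are sampled as a
convenient proxy for the gut microbiota, while the cecum is the actual
fermentation organ. Deciding whether the proxy is adequate requires a
*paired* comparison: one cecal and one fecal sample from each animal, with
the animal itself treated as a block so that between-animal variation does
not masquerade as a compartment effect. `cecofec` implements that
comparison end to end for a processed OTU table:

- **Filtering** at sample level (minimum sequencing depth, default 5,000
  reads), OTU level (minimum 0.01% of total counts), prevalence level
  (detected in ≥ 5% of samples), and the pairing rule that drops animals
  missing either compartment.
- **Cumulative sum scaling (CSS)** normalization: per sample *j*,
  abundances are `count / s_j × N` where `s_j` sums the counts up to a
  data-chosen quantile of the sample's nonzero count distribution.
- **Alpha diversity** (Shannon in bits, observed OTUs) after rarefaction
  to a common depth (default 15,000 reads), analysed with a paired ANOVA
  over sampling origin, feeding regime, their interaction and the animal
  block.
- **Paired bootstrap-F differential abundance**: per feature, with
  within-animal differences `d_i = cecum_i − feces_i`, the statistic
  `F = n·mean(d)² / var(d)` (identical to the extra-sum-of-squares F for
  origin in the `animal + origin` linear model) is referred to an
  empirical null built by resampling the centered differences, with
  Benjamini–Hochberg FDR across features. Runs on CSS abundances at OTU
  level and on relative abundances at genus and phylum level.
- **Ordination**: weighted UniFrac distances
  `d(A,B) = Σ_i b_i·|p_A(i) − p_B(i)|` over the branches of a rooted
  phylogeny, embedded by classical PCoA; and a multilevel (paired) PCA of
  the within-animal deviation matrix.
- **Multilevel sparse PLS-DA**: partial least squares against the
  origin-indicator response on within-animal deviations, with an
  L1-style penalty keeping exactly `keepX` OTU loadings per component.
- A **synthetic-data generator** that emulates the paired design (animal
  random effects, planted origin effects, realistic depths and
  rank-abundance skew), so the whole pipeline is testable with known
  ground truth.

## Worked example

```python
from cecofec import (SyntheticParams, generate_dataset, build_paired_design,
                     css_normalize, run_diff_abundance, BootstrapConfig,
                     within_animal_deviations, fit_splsda)

params = SyntheticParams(n_animals=21, n_otus=100, frac_differential=0.2,
                         origin_effect_size=0.7, seed=42)
table, meta, taxonomy, tree, truth = generate_dataset(params)
design = build_paired_design(meta, table)
norm = css_normalize(table)

result = run_diff_abundance(norm, design, BootstrapConfig(B=1000, seed=42))
sig = result.table[result.table["significant"]].sort_values("q")
print(sig[["difference", "se", "F", "p_boot", "q"]].head(5).round(3))
```

```
         difference     se       F  p_boot    q
feature
OTU0008      40.775  5.549  53.995     0.0  0.0
OTU0010       8.654  1.856  21.734     0.0  0.0
OTU0013     -31.668  5.971  28.130     0.0  0.0
OTU0021      51.297  9.201  31.082     0.0  0.0
OTU0022      -8.046  0.931  74.628     0.0  0.0
```

`difference` is the mean cecum − feces abundance in CSS units (positive =
overrepresented in cecum), `se` its standard error over the 21 pairs,
`p_boot` the proportion of 1,000 bootstrap resamples with an F at least as
large as observed, and `q` the BH-adjusted value. On this dataset 21 of
100 OTUs are called differential at FDR 0.05, 20 of which are planted
effects; the multilevel sPLS-DA then concentrates the discrimination:

```python
W = within_animal_deviations(norm, design)
model = fit_splsda(W, [meta[s].origin for s in W.sample_ids], keepx=(20, 10))
```

selects 20 OTUs on component 1 — all of them also bootstrap-significant —
explaining 16% of the within-animal variance.

The same analyses are available from the shell:

```sh
cecofec simulate --n-animals 21 --n-otus 596 --seed 1 --outdir data/
cecofec all --outdir report/            # full pipeline on the default design
cecofec diffabund --otu-table data/otu_table.tsv --metadata data/metadata.tsv \
        --level otu --b 1000 --fdr 0.05 --seed 1 --out diffabund.tsv
```

`cecofec all` writes a report bundle: filter summary, CSS factors and
abundances, per-sample alpha indices with the paired-ANOVA summary,
OTU/genus/phylum differential-abundance tables, PCoA and paired-PCA
coordinates with eigenvalues, sPLS-DA loadings/variates/selections, and a
deterministic JSON-lines run log. The same config and seed reproduce the
bundle byte for byte.

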