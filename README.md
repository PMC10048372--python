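# rohkit

Within-breed genomic diversity analysis from multi-sample VCFs: detection of
runs of homozygosity (ROH), genomic inbreeding coefficients, ROH islands,
identity-by-state population structure and breed-relevant variant reporting.
Written for population geneticists studying closed populations — dog breeds
being the motivating case — where high autozygosity, selection signatures and
fixed trait alleles are the quantities of interest, and bundled with a
synthetic-cohort generator so every stage can be validated against planted
ground truth.

## What it computes

**ROH detection** uses the PLINK-style scanning window: a window of
`window_snp` consecutive SNVs is homozygous if it contains at most
`window_het` heterozygous and `window_missing` missing calls; a SNV is
eligible when the fraction of homozygous windows covering it reaches
`hit_threshold` and its own call is not heterozygous; maximal eligible runs,
split at gaps above `max_gap_kb`, become segments when they satisfy the
minimum SNV count, minimum length and SNV-density bounds. The minimum SNV
count can be calibrated so fewer than a fraction α of ROH arise by chance:

    min_snv = ceil( ln(α / (n_samples · n_SNVs)) / ln(1 − het̄) )

with het̄ the mean marker heterozygosity. With α = 0.05, 33 genomes,
6,344,366 markers and het̄ = 0.268 this gives 72 SNVs.

**Genomic inbreeding** is F_ROH = Σ ROH length / autosomal bp covered by SNV
positions, decomposed over six ROH length classes (<1, 1–2, 2–4, 4–8, 8–10,
>10 Mb); group means are compared by one-way ANOVA.

**ROH islands** are maximal runs of consecutive SNVs whose ROH incidence
(fraction of samples in a ROH at that SNV) reaches 90%, with no minimum
size; they are annotated against GFF3/BED gene intervals and audited for a
shared underlying haplotype, reporting sub-regions where samples carry
consecutive heterozygous calls.

**Population structure** follows LD pruning (1000-marker windows, step 100,
r² > 0.8 over pairwise-complete dosages) with raw Hamming (allele-mismatch)
distances and classical multidimensional scaling, extracting the first three
coordinates.

**Trait variants** ship as a definition table (degenerative-myelopathy
*SOD1*/*SP110* alleles, *GFAP*, *IGF1*, *MSRB3*, *FGF5*, *ASIP*, and the four
multi-SNV histiocytic-sarcoma risk loci on chr5, chr11 and chr14): genotype
class counts, allele/haplotype frequencies, a configurable monotone A/B/C
risk index, Fisher-exact group comparisons and mtDNA haplotype assignment.

## Worked example

```python
from rohkit import (SimConfig, simulate, detect_roh, compute_denominator,
                    sample_diversity_table, group_anova)

res = simulate(SimConfig(seed=1))          # 33 samples, 240 Mb, planted F
segments = detect_roh(res.matrix)          # auto-calibrated min_snv
denom = compute_denominator(res.matrix)
table = sample_diversity_table(res.matrix, segments, denom,
                               groups=res.truth.populations.to_dict())
print(table["froh"].mean(), res.truth.froh.mean())
print(group_anova(table["froh"], table["group"]))
```

prints a recovered cohort mean F_ROH of 0.393 against a planted mean of
0.402 — the caller loses only sub-resolution segment mass — and an ANOVA of
F = 0.00, p = 0.967 between the two simulated subpopulations, which share
the same inbreeding model. The scripts in `examples/` walk through each
capability (simulation, ROH + F_ROH, islands, MDS, trait variants) and
print the numbers they compute.

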