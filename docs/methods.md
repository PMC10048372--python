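# Methods

This note documents the models, conventions and numerical choices behind
`rohkit`, in the order data flows through the pipeline.

## Genotype model and site filtering

Genotypes are diploid dosage codes per sample and site: 0 (hom-ref), 1
(het), 2 (hom-alt), −1 (missing). Any genotype with at least one missing
allele — `./.` as well as half-calls like `0/.` — is coded missing; this is
the conservative reading, since a half-call carries no evidence of
homozygosity. Phase is ignored. A genotype whose two alleles differ is
heterozygous regardless of which alleles they are, so `1/2` at a
multi-allelic site codes 1. Coordinates are 1-based inclusive internally
(VCF convention); BED output converts to 0-based half-open.

The site filter retains PASS, biallelic SNVs on a caller-supplied chromosome
set whose call rate is *strictly greater than* `min_call_rate` (default
0.90): with 33 samples, 30 called genotypes (0.909) pass and 29 (0.879) do
not. Chromosome labels are opaque strings — the autosome set is
configuration, never inferred from names. Variant type is determined purely
by allele lengths (SNV iff ref and every alt are single bases); biallelicity
is a separate predicate, so multi-allelic SNV sites are still removed by the
biallelic policy. Filtering is idempotent and order-preserving.

## ROH detection

The scan mirrors the PLINK `--homozyg` scheme. Defaults: 50-SNV windows, at
most 3 heterozygous and 5 missing calls per homozygous window, hit-fraction
threshold 0.05, 300 kb minimum length, 1 Mb maximum inter-SNV gap, 50 kb/SNV
maximum density. The window het limit of 3 and the 300 kb minimum are the
operating point for dense WGS data of a highly inbred population; the rest
are the PLINK v1.9 defaults, all overridable.

Two conventions are deliberate and testable where the upstream tool's fine
print is obscure:

- **Heterozygous calls break runs.** A SNV is eligible only if its hit
  fraction reaches the threshold *and* its own call is not heterozygous, so
  no called segment starts, ends or contains a het call and recorded `n_het`
  is zero under default semantics (it is still reported for audit, and
  becomes informative if eligibility is relaxed). This matches the
  observation that a stretch of heterozygous genotypes splits a shared
  homozygous region in two rather than being smoothed over.
- **Missing calls are neutral.** They are counted against the window
  missing limit but neither break runs nor count toward `n_snvs`, and
  segments never start or end on one. Segment coordinates are the positions
  of the first and last member SNVs; length = end − start + 1.

Chromosomes shorter than the window are scanned with one truncated window.
An exhaustive window-enumeration oracle in the test suite defines the
reference semantics; the vectorised implementation must match it exactly on
fixtures up to 300 SNVs across a parameter grid.

**Minimum-SNV calibration.** The minimum SNVs per ROH such that fewer than a
fraction α of ROH arise by chance is ceil(ln(α/(n_samples·n_SNVs))/ln(1−het̄)).
The heterozygosity entering the formula is the *mean marker heterozygosity*
2p(1−p) from allele frequencies, not the observed het-call fraction: the
null hypothesis is "no autozygosity", and the observed fraction is itself
depressed by real ROH, which would inflate the threshold in exactly the
cohorts where ROH are abundant. In an outbred cohort the two coincide. The
pipeline default computes this threshold from the scanned matrix at α = 0.05
and logs it; an explicit value can be supplied instead.

## Inbreeding coefficients

F_ROH = Σ segment lengths / genome denominator. The denominator is the
autosomal bp covered by SNV positions, computed as Σ over chromosomes of
(max SNV position − min SNV position + 1); because published analyses
sometimes fix this constant by other means, a verbatim override is
supported. Length classes use cut points 1, 2, 4, 8, 10 Mb with [lower,
upper) binning, so every segment falls in exactly one class and the class
F_ROH values re-add to total F_ROH exactly. The country/group comparison is
a classical one-way ANOVA on untransformed F_ROH (scipy); groups need at
least two members each.

## ROH islands

Incidence at a SNV is the fraction of samples with a ROH covering it.
Islands are maximal runs of *consecutive* SNVs at incidence ≥ 90% —
consecutive in SNV-index space, since incidence is defined only at SNVs; the
largest internal bp gap is reported for audit instead of breaking islands.
There is no minimum size (a single SNV can be an island) and no merging
across sub-threshold dips. With 33 samples the 90% rule triggers at exactly
30 covered samples. Gene annotation lists any feature overlapping an island
by ≥1 bp — the most inclusive reading of "genes in the region". The
haplotype audit declares an island `identical` only when every member SNV is
the same homozygous genotype in all non-missing samples, and reports maximal
sub-intervals where any sample carries ≥k consecutive het calls (default
k = 2) together with the affected sample count.

## Population structure

LD pruning slides a `window_size`-marker window advancing by `step` within
each chromosome; markers are processed in ascending order and a marker is
removed when a still-retained earlier marker in the window shows squared
Pearson correlation of dosages above `r2_max`. Correlations use
pairwise-complete observations (composite LD on unphased dosages); pairs
with fewer than two complete observations or zero variance count as r² = 0.
Removing the *later* marker makes the retained set deterministic —
tie-breaking by allele frequency, as some tools do, is not reproducible
from parameter settings alone.

Distances are raw allele-mismatch counts (opposite homozygotes 2, het vs hom
1) over sites called in both samples, with the pairwise complete-site count
reported alongside; no normalisation is applied, matching the "raw" scale.
A pair sharing no called site is an error rather than a silent zero.

Classical MDS double-centres −½D², eigendecomposes, and scales the top-k
nonnegative eigenvectors by √λ; components with non-positive eigenvalues are
zero. The sign convention (first nonzero loading positive) makes coordinates
reproducible across runs and libraries.

## Trait variants and risk haplotypes

Variant definitions are exact-coordinate records; indel and structural
alleles are matched by coordinates plus a symbolic descriptor with no local
realignment, so a record that is absent is reported "not genotyped", never
as zero counts. Allele frequency is (het + 2·hom-alt)/(2·called), rounded to
three decimals for reporting only.

The dose of a multi-SNV risk haplotype is the rounded (half-up) median of
the dosages at the locus's defining SNVs, missing when fewer than half are
genotyped; the per-SNV discordance fraction is always reported because the
aggregation rule used by the originating risk test is not public — the
median is an auditable consensus stand-in, not a claim about that assay. The
A/B/C index maps the total risk-allele count over the four loci through a
configurable banded rule (default 0–2 → A, 3–5 → B, 6–8 → C); the rule is
validated to partition 0–8 monotonically, which guarantees that raising any
single dose never lowers the index. The default cut points are explicitly
non-authoritative. Group frequency contrasts use the two-sided Fisher exact
test on allele-count tables. mtDNA haplotypes are assigned when a
haplotype's full defining variant set is present; ties report all matches,
variants outside every definition are listed as unexplained, and the
shipped A2/A22 table is a synthetic stand-in (see its file header) since the
authoritative defining sets are not redistributed here.

## Synthetic cohorts

The generator emulates a WGS cohort of a closed breed population at desk
scale: by default 33 diploid samples on three autosomes of 100/80/60 Mb at
100 SNVs/Mb (24,000 markers — small enough for sub-second simulation and
second-scale analysis on one core, dense enough that a 300 kb segment holds
~30 SNVs), site frequencies from a symmetric Beta whose shape α =
h/(1−2h) yields E[2p(1−p)] = h with h = 0.268 outside ROH, two
subpopulations obtained by perturbing ancestral frequencies on the logit
scale with σ = 0.3 (delta-method F_ST ≈ 0.03–0.05, the order observed
between continental subpopulations of one breed), genotyping error turning
a true-ROH genotype heterozygous at rate 10⁻³, and 5% missingness.

Per-sample autozygosity targets default to Uniform(0.32, 0.52), the
F_ROH range of the motivating cohort. Segment lengths come from a
six-class truncated-exponential mixture (class weights 0.350/0.270/0.213/
0.090/0.035/0.042) chosen so ~83% of segments are shorter than 4 Mb and ~4%
longer than 10 Mb; the shortest plantable segment is 0.3 Mb. Segments are
placed without overlap by sampling uniformly among all feasible start
positions (exact gap bookkeeping, no rejection stall at high occupancy), and
the last segment is trimmed so the realised autozygous fraction equals the
target up to the SNV grid. Island regions plant one shared haplotype —
identical homozygous alleles — into a chosen fraction of samples, each
carrier's segment extended by a random 0.2–0.8 Mb flank.

What the generator does **not** model: linkage disequilibrium outside
planted segments (sites are independent given frequencies), recombination
maps, mutation-age structure relating ROH length to coalescence time,
pedigree relationships, allele-frequency spectra distorted by variant
calling, or reference bias. Tests passing on this generator therefore
demonstrate correctness of the detection and summary machinery under known
truth — not calling performance on real sequencing artefacts.

## Numerical and degenerate-input conventions

- A sample with zero called genotypes has undefined heterozygosity (NaN),
  excluded from cohort means.
- Overlapping ROH segments within one sample are a caller-contract
  violation and raise, rather than silently double-counting F_ROH.
- Empty filter results warn and return an empty matrix; empty chromosomes
  contribute zero to the denominator.
- The calibration formula requires 0 < α < 1 and 0 < het̄ < 1 (log
  domain); α near 1 degenerates to a threshold of 1 SNV.
- Fisher tables with an empty margin return p = 1 with a warning.
- MDS of an all-zero distance matrix returns all-zero coordinates.

## Known limitations

Desk-scale SNV density (100/Mb versus ~2,850/Mb for real WGS) makes the
minimum-SNV threshold the binding constraint near 300–550 kb, so the
shortest real-scale ROH class is only partially recoverable in simulation;
recovery metrics are therefore quoted for segments ≥600 kb, and total-F
recovery absorbs a ~1–2% shortfall from sub-resolution mass. The ROH caller
is not bit-compatible with any external tool on edge cases (window
truncation at chromosome ends, missing-call handling at run boundaries);
its semantics are fixed by the enumeration oracle in the test suite. The
X chromosome, phasing-aware IBD and likelihood/HMM ROH models are out of
scope.
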