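# Methods

`sweepscan` detects selection signatures in SNP-chip panels by comparing an
"object" population suspected of recent positive selection (here, cashmere-type
goat breeds) against a reference population, combining an allele-frequency
statistic (per-SNP Fst) with a haplotype statistic (XP-EHH), and calling
candidates from the empirical tails. This note records the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## Quality control

A SNP enters the scan only if it passes four filters: exact Hardy–Weinberg
p ≥ 10⁻⁶, call rate > 0.90, minor-allele frequency > 0.01, and autosomal
location (chromosome name not in a configurable list, default X/Y/MT). The
pass rules are strict inequalities: a SNP exactly at 0.90 call rate or 0.01
MAF fails. Setting a threshold to exactly 0 disables its rule, so
`QcThresholds(0, 0, 0, autosomes_only=False)` is the identity filter.

The HWE test is the exact conditional test: conditioning on the total genotype
count and the minor-allele count, it sums the probabilities of all
heterozygote counts whose conditional probability does not exceed the observed
one (no mid-p correction). It is computed by the standard log-space recurrence
over heterozygote counts, which is stable for the sample sizes chips see. HWE
is tested on all samples pooled by default — common chip-QC practice; a
per-population mode (fail if any population fails) is available via
`hwe_per_population`. Missing genotypes are excluded from the HWE and MAF
denominators.

## Per-SNP Fst

The two-population estimator works on allele frequencies with allele-unit
sample sizes mᵢ = 2 × (genotyped individuals):

    p̄   = Σ mᵢ pᵢ / Σ mᵢ
    MSP = Σ mᵢ (pᵢ − p̄)² / (r − 1)          (among populations, r = 2)
    MSG = Σ mᵢ pᵢ (1 − pᵢ) / Σ (mᵢ − 1)     (within populations)
    n_c = (Σ mᵢ − Σ mᵢ² / Σ mᵢ) / (r − 1)
    Fst = (MSP − MSG) / (MSP + (n_c − 1) MSG)

Fixed differences give exactly 1; identical frequencies give the forced
negative value −1/(n_c − 1). Negative values are reported as computed — the
top-5% rule is unaffected by truncation, and clamping would bias multi-locus
sums. Fst is undefined (NaN) when both populations are monomorphic for the
same allele.

For multi-locus summaries (the pairwise population matrix, and parameter
recovery on simulated panels) SNPs are combined as a ratio of sums,
Σ(MSP − MSG) / Σ(MSP + (n_c − 1)MSG), not as a mean of per-SNP ratios. The
ratio-of-sums form is the standard choice and is unbiased enough to recover a
simulated differentiation of 0.05–0.4 to within ±0.005 in our tests; the mean
of per-SNP ratios is biased low by ~25% at F = 0.4 because low-information
SNPs contribute noisy, often negative, ratios.

## EHH and XP-EHH

For a core SNP with allele counts n_a and n_A, haplotypes are partitioned by
their full allele vector over the closed interval from the core out to marker
x. With class sizes n_i,

    EHH(x) = Σᵢ C(n_i, 2) / (C(n_a, 2) + C(n_A, 2)).

The denominator pools both core-allele classes; because the partition at the
core is exactly the two allele classes, EHH(core) = 1, and refinement makes
the curve non-increasing outward (asserted in tests). This pooled form is the
package default (`ehh_mode="pooled"`); the classical single-core-allele
definition, EHH restricted to one allele class with denominator C(n_allele, 2),
is available as `ehh_mode="per_allele"` (defaulting to the major core allele)
for comparison. Haplotypes with a missing allele are dropped from the
partition at the first missing site outward; the denominator stays fixed at
the core.

XP-EHH at a core is the ratio of integrated EHH between object and reference:

    XP-EHH = ∫_D EHH_obj(x) dx / ∫_D EHH_ref(x) dx.

The domain D extends outward in each direction until max(EHH_obj, EHH_ref)
drops below ε (default ε = 0.05 — "sufficiently small"; no canonical value
exists) or the chromosome ends; the first sub-ε marker is kept as the
endpoint so the integral covers the decay. Both curves are integrated with
the trapezoid rule over physical bp, with the core contributing EHH = 1 at
offset 0, over the same D — which makes ln XP-EHH exactly antisymmetric under
swapping the populations. The plain ratio is the primary output; ln-ratio and
a genome-wide z-standardized ln-ratio are emitted alongside. When the
reference integral is zero the ratio is reported missing, never infinite.

## Candidate calling and gene annotation

Thresholds are per statistic and per population pair: the nearest-rank upper
5% point of the non-missing values (sort descending, take rank
⌈0.05·n⌉ = n − ⌊0.95·n⌋, computed in integer arithmetic to avoid float
round-off). The threshold is always attained, candidates are values ≥
threshold, and ties can only add candidates. Candidate regions are ±50 kb
around each candidate SNP (clipped at position 1); a gene is a candidate gene
when its 1-based inclusive span intersects at least one region. Per pair, the
merged set is the intersection of the Fst and XP-EHH gene sets — genes
supported by both an allele-frequency and a haplotype signal; across pairs,
the overlap is the intersection of merged sets. A per-SNP best gene (nearest
within the flank, ties to smallest start) is also reported for table output.

## Population structure

The pairwise-Fst distance matrix (negative entries floored at 0) feeds a
Saitou–Nei neighbor-joining implementation: Q-matrix selection with
deterministic tie-breaking by label order, standard branch-length formulas,
and negative branch lengths clamped to 0 with the deficit transferred to the
sibling edge. On additive matrices the reconstruction is exact (verified
against path-length recomputation and against scikit-bio's NJ). PCA
mean-imputes missing dosages per SNP, centers by 2p̂ and scales by
√(2p̂(1−p̂)) (dropping monomorphic SNPs), and takes coordinates U·S from the
SVD, fixing each component's sign so its largest-magnitude SNP loading is
positive.

## Enrichment

Over-representation of a candidate gene set uses the plain hypergeometric
upper tail P(X ≥ k) for k pathway members among n candidates drawn from N
background genes of which K are in the pathway, with Benjamini–Hochberg
control and significance at q < 0.05. The background defaults to all genes in
the annotation. A modified Fisher/EASE score was deliberately not used: its
behaviour depends on a web service's database snapshot and is not
reproducible; only the q < 0.05 rule is consumed downstream.

## Synthetic panels

The generator emulates a 50K-chip-like design at desk scale: by default 17 +
20 + 16 diploid samples in three populations (two object breeds, one
reference), 5,000 SNPs uniformly placed on one 50 Mb chromosome, ancestral
allele frequencies uniform on (0.05, 0.95), and Balding–Nichols population
frequencies p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F). Under this model F equals the
expected Fst, giving a closed-form target for parameter recovery without a
coalescent simulator. The default F = 0.1 is a typical between-breed chip
value for Chinese goat breeds; no published pairwise estimate exists for
these populations.

A sweep is planted, not evolved: one donor haplotype is chosen in the target
population, and a carrier fraction (default 0.8) of that population's
haplotypes receives the donor allele at each site with probability
exp(−d/λ), d the distance to the core and λ the decay length (default 2 Mb).
This directly produces the long shared-haplotype signature XP-EHH targets,
with a tunable spatial scale, while leaving other populations bitwise
untouched. All randomness flows from one integer seed; replicate k uses
seed + k.

What the generator does **not** emulate: background linkage disequilibrium
(sites are independent, so the only haplotype structure is the sweep),
recombination-rate variation, demography beyond a star split, genotyping
error, and sex chromosomes. A green sweep-power test therefore establishes
that the statistics detect extended haplotype homozygosity against an
LD-free background — an easier background than real chip data, where
baseline EHH decays more slowly and thresholds sit higher. Conversely, the
QC, estimator-vs-oracle, NJ and enrichment guarantees are
distribution-free.

In the bundled analysis, sweeps are planted at nearby cores (20.0 Mb in one
breed, 20.5 Mb in the other) to emulate selection on a shared genomic region
in both object populations, which is what makes the cross-pair overlap set
non-empty.

## Known limitations

* XP-EHH values across cores are not independent (overlapping domains); the
  empirical top-5% rule treats them marker-wise, as scan practice does.
* The EHH partition drops haplotypes at missing sites without renormalizing
  the core denominator, so heavy missingness deflates EHH symmetrically in
  both populations.
* iHS and multi-population (r > 2) Fst are out of scope; haplotype phasing is
  consumed, not performed.
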