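# Methods

This note documents the models, rules, and numerical choices behind each
stage, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Genotype calling

Calls are made from per-allele read counts with the two largest counts
`c1 >= c2`:

* heterozygous iff `c2 > 10` **and** `c2/c1 > 0.20` (the allele coverage
  ratio, ACR);
* otherwise homozygous for the top allele iff `c1 > 30` **and** the
  minor-signal fraction `c2/(c1+c2) <= 0.10`;
* otherwise no-call, flagged `low_coverage`, `imbalanced` (a credible but
  unbalanced second allele), or `high_noise`.

All comparisons are strict inequalities: exactly 30 reads is not enough for
a homozygote, an ACR of exactly 0.20 is not enough for a heterozygote. The
region where the minor allele exceeds the noise bound but misses the
heterozygote criteria is deliberately a no-call rather than a forced
homozygote — a conservative choice that avoids manufacturing false
homozygotes from imbalanced heterozygotes. Alleles beyond the top two are
treated as noise; when their pooled fraction exceeds the ACR bound the call
is still attempted from the top two but flagged `high_noise`. The
`noise_max_fraction` of 0.10 is the one tunable in this block without a
field-standard value; it is configurable on `CallingThresholds`.

Mean ACR in summaries is the mean of per-sample ratios, not the ratio of
mean per-allele coverages; both styles appear in practice, and the two
differ, so per-allele mean coverages are reported separately when raw
counts are available.

## Concordance

Two call sets over the same sample × locus grid are compared as unordered
allele pairs. A dual no-call is concordant (neither pipeline produced
evidence of disagreement); a one-sided no-call is discordant with reason
`a_no_call`/`b_no_call`; a genotype mismatch is `genotype_mismatch`.
Swapping the call sets preserves the concordant count and transposes the
one-sided reasons, which is property-tested.

## Microhaplotype extraction

Observed sequences are globally aligned to the amplicon reference with
match +1, mismatch −1, linear gap −2 (Biopython `PairwiseAligner`).
Differences become variants; indels are left-aligned to the first base of
their homopolymer run so the same molecule always yields the same variant
set. The base at the target offset is carried separately as the target
allele; flanking variants plus target compose a canonical allele string
(`target;offset:ref>alt;...`, variants sorted by offset).

Two numerical choices matter here:

* **Target-aware disambiguation.** When the target SNP heads a homopolymer
  run, a read carrying the alternate target base plus a one-base run
  deletion aligns ambiguously, and plain left-alignment drags the deletion
  onto the target base — the exact mechanism by which such reads get
  mis-scored as deletions of the target and a heterozygote collapses into a
  false homozygote. `classify_read` re-aligns such reads against the
  reference with each candidate base substituted at the target and keeps the
  interpretation with the fewest flanking edits; a deletion that can sit
  entirely after the target is re-placed at `target_offset + 1`. This
  recovers the correct (alt target, flank deletion) reading.
* **Artifact indicator.** Independently of the rescue, any call where more
  than 50% of reads carry a deletion at or adjacent to the target is flagged
  `deletion_artifact` for reviewer attention (strictly greater than the
  `deletion_flag_fraction` threshold; exactly half does not fire).

Reads needing more than 4 edits are counted as noise for that sample-locus,
mirroring pipelines that exclude error-bearing reads from allele counts.
Microhaplotype calling reuses the same thresholds as target-SNP calling,
applied to microhaplotype-allele read counts.

ΔH_obs per locus compares the fraction of heterozygous samples under the
two encodings over the samples called under **both**, so the proportions
share a denominator and refinement can only increase H_obs. Categories:
high ≥ 0.15, moderate [0.05, 0.15), low < 0.05.

## Forensic statistics

The standard forensic definitions are used: Nei's unbiased gene diversity
`GD = n/(n−1)(1 − Σp²)` with `n` the number of typed gene copies (no-calls
leave the denominator, so `n` varies by locus); Botstein's
`PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²`; `PM = Σ_g f_g²` over **observed**
genotype proportions (not HWE expectations) and `PD = 1 − PM`; Fisher's
`PE = h²(1 − 2hH²)` and `TPI = 1/(2H)` with `h` observed heterozygosity and
`H = 1 − h` (TPI is reported as infinite when no homozygote is observed);
`A_e = 1/(p² + q²)`. The low-A_e reference line is `Q1 − 1.5·IQR` with
linear interpolation between order statistics — quartile conventions differ
across software, so the convention is fixed and tested explicitly.
Frequencies are written to 4 decimal places; all internal arithmetic is at
full precision.

## Hardy–Weinberg and linkage disequilibrium

For a biallelic locus the distribution of the heterozygote count
conditional on the allele counts is

    P(n_Aa | n, n_A) = 2^{n_Aa} n! n_A! n_a! / (n_AA! n_Aa! n_aa! (2n)!)

and the two-sided p-value sums all configurations no more probable than the
observed one. The enumeration is exact and deterministic, so no
Markov-chain approximation is needed; probabilities are computed through
log-gamma and renormalized, and the p-value is clamped to 1. Monomorphic
loci return p = 1 with a flag.

LD uses `LR = 2[lnL(EM haplotype frequencies) − lnL(allele-frequency
product)]`. The EM algorithm resolves only the double-heterozygote phase
ambiguity; it iterates to a max frequency change below 1e−8 (cap 1000
iterations) from two starts — uniform and the linkage-equilibrium product —
keeping the better likelihood, and its per-iteration likelihood ascent is
asserted in tests. The null distribution comes from permuting one locus's
genotype column across individuals, which preserves both genotype margins
while destroying gametic association;
`p = (1 + #{LR_perm ≥ LR_obs}) / (n_perm + 1)`, so the attainable floor is
`1/(n_perm + 1)`. Permutations are batched: the 3×3 genotype-pair tables of
all permutations are built at once and the EM update runs vectorized across
the batch, which keeps 10,000 permutations per pair tractable. Bonferroni
uses the number of tests actually performed in the batch (per-population by
default, matching per-population significance reporting); synteny is
same-chromosome membership with base-pair distance.

## Random-match probabilities

Per locus, `p²` for homozygotes and `2pq` for heterozygotes; the profile
RMP is the product across loci under independence. All accumulation is in
log10 space — a 94-locus product reaches ~10⁻³⁸ and would degrade in naive
linear accumulation — and linear-scale means/SDs are recovered through
log-sum-exp. No-call loci are skipped and counted (`n_loci_skipped`); a
called allele with no frequency entry, or zero frequency, is an error
rather than silently substituted with a minimum allele frequency. No
θ/subpopulation correction is applied. Marker-set comparisons report
`round(log10(mean_A / mean_B))`.

## Synthetic data

The generator emulates the four-population, 94-locus study design and is
the source of every test fixture. Defaults, with rationale:

| knob | default | why |
| --- | --- | --- |
| populations | 342 / 97 / 361 / 236 | the study's group sizes (1036 total) |
| base alt frequency | U(0.2, 0.8) | identity SNPs are chosen for balanced frequencies |
| divergence (Balding–Nichols) | F_st = 0.05 | typical inter-continental human value; F_st = 0 collapses populations exactly |
| coverage scale | lognormal, median 553×, σ_ln = 1.0 | spans roughly 50×–5000× (two orders of magnitude) across 94 loci |
| per-sample depth | negative binomial, size 8 | overdispersed sample-to-sample depth |
| het read split | beta-binomial, concentration 150 | panel mean ACR ≈ 0.86 for balanced loci |
| skewed loci | indices 1, 2 with bias 0.30 / 0.35 | emulates the two loci with mean ACR below 0.6 |
| error rate | 0.003 per base | each error-bearing read realized as one random substitution; with a 60 bp amplicon, P(≥2 errors per read | ≥1) ≈ 8%, and multi-error reads would be handled identically (rare noise alleles filtered by thresholds) |
| flanking variants | ~13% of loci a common phased SNV (freq 0.25–0.5), ~50% a rare one (0.005–0.05) | produces a spread of ΔH_obs categories |
| rare homopolymer deletion | 1e−4, locus 0, phased to the alt allele | ~0–1 carriers per 1036 samples; locus 0 is built with a 4-base T run heading at the target to exercise the alignment artifact |

All randomness flows from one integer seed through `SeedSequence` spawning
with fixed stream keys for panel, genotypes, and reads, so each stage is
independently regenerable and byte-identical across runs.

What the generator does **not** emulate: read-level quality scores, PCR
stutter, mixtures, primer-binding-site mutations (allelic skew is imposed
directly via the bias knob, not mechanistically), insert-size variation, or
strand-specific error profiles. Passing recovery tests therefore
demonstrates correctness of the analysis logic under the stated generative
model, not robustness to every artifact of real sequencing chemistry.

## Test and verification scales

The default test dataset is 4 populations × 20 loci × 50 samples (the
package's standard desk-scale configuration); calibration checks use 1000
simulated loci for the HWE type-I error, 50 random 50-sample instances for
EM-vs-grid-search accuracy, and 1000 tests × 1000 permutations for the LD
null. Noiseless-recovery runs use 150 samples × 10 loci at fixed 200×
depth. These sizes make the binomial error bands (3 SE) tight enough to be
informative while keeping the whole suite fast.

## Known limitations

* The HWE exact enumeration is biallelic-only; multiallelic
  microhaplotype encodings are not HWE-tested.
* The LD permutation test treats each pair independently; no attempt is
  made to exploit shared permutations across pairs, and p-values at the
  permutation floor are ties, not exact values.
* The concordance module compares exactly two call sets; adjudication of
  discordances is left to the analyst.
* VCF export covers target SNPs only — composite microhaplotype alleles
  have no natural single-position VCF representation and are exported as
  TSV allele strings instead.
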