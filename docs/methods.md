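# Methods

## Problem and model

GNE myopathy is autosomal recessive: an individual is affected when both
*GNE* alleles carry a pathogenic variant (homozygous or compound
heterozygous). Given per-variant allele frequencies q₁, …, qₙ in a
reference population and random mating (Hardy–Weinberg equilibrium), the
frequency of disease genotypes is the square of the total pathogenic allele
frequency,

    q² = (Σᵢ qᵢ)² = Σᵢ Σⱼ qᵢ qⱼ,

a sum over ordered allele pairs. All estimators in this package are
evaluations of this quadratic form with different plug-ins for qᵢ and an
optional 0/1 weight per pair.

**Frequency plug-ins.** `ml` uses the maximum-likelihood ratio AC/AN.
The Bayesian plug-ins model the observed allele count as
AC ~ Binomial(AN, qᵢ) with a conjugate Beta(α, β) prior, giving the
posterior Beta(α + AC, β + AN − AC); `bayes_mean` substitutes the posterior
mean, and `bayes_var` reports the full posterior expectation of q²,
E[q²] = Σᵢ Var(qᵢ) + (Σᵢ E[qᵢ])², under posterior independence across
variants (no linkage or haplotype structure is modelled — consistent with
the additive treatment of q). The default prior is the uniform Beta(1, 1);
it is configurable per call because informative priors for rare-variant
frequencies are study-specific. With AN in the 10⁵–10⁶ range typical of
population databases the posterior mean differs from AC/AN by at most
~1/AN, so the three estimators agree closely on real catalogs; `bayes_var`
exceeds `bayes_mean` by exactly the summed posterior variances and matters
for variants observed only a handful of times.

**Severity adjustment.** Some genotype combinations cannot appear in living
patients. The compatibility policy assigns each variant a severity class —
`null` (nonsense, frameshift, canonical splice, start-loss; the standard
loss-of-function definition), `mild_hom_excluded` (designated founder or
common alleles that are non-penetrant in homozygosity: p.Asp207Val,
p.Val727Met, p.Asp239Glu by default, supplied as canonical keys and fully
configurable), `synonymous`, or `standard` — and induces a symmetric matrix
A with Aᵢⱼ = 0 exactly when both alleles are null (embryonic lethality) or
when i = j and the allele is mild or synonymous (non-penetrant
homozygotes). The adjusted estimate is Σᵢⱼ Aᵢⱼ mᵢⱼ where mᵢⱼ is the
method's pair term (for `bayes_var` the diagonal uses Var(qᵢ) + E[qᵢ]²).
Compound heterozygotes of two *distinct* mild alleles, and of two distinct
synonymous alleles, remain allowed: only homozygosity is excluded for these
classes. Mild-list membership takes precedence over the consequence-derived
classes (the designated alleles are missense, so the order only matters for
misconfigured inputs).

**Confidence intervals.** A parametric bootstrap: each replicate redraws
every variant's count AC\* ~ Binomial(AN, AC/AN) independently per variant
and population, re-evaluates the estimate, and the 2.5th/97.5th percentiles
over replicates (default 1000, seeded NumPy generator) form the 95%
interval. These intervals capture only binomial sampling noise, not
uncertainty in which variants are truly pathogenic or in database
composition. Variants with AC = 0 never resample above zero, so coverage
degrades for catalogs dominated by unobserved alleles; the coverage study
below operates in the regime where the pooled expected count is large.

**Burden.** `burden(v, N, f)` = v × N / 10⁶ × f converts a per-million
prevalence into a case count for a population of size N; the affected
fraction f discounts pre-symptomatic carriers of disease genotypes
(adult-onset disease), e.g. f = 0.5 for the half of the world population
under typical onset age. The product is rounded to a configurable number
of decimals (default: whole individuals).

## Triage of unreported variants

Variants present in the population database without a clinical
classification are candidate unreported pathogenic alleles. The triage
cascade:

1. **MAF prefilter** (default cutoff 0.001 on global AC/AN). Removal is on
   strict `AF > cutoff` by default, with an inclusive `AF ≥ cutoff` mode;
   both conventions exist in practice and the choice is exposed because the
   cutoff is typically anchored to the highest frequency among known
   pathogenic alleles, which may itself sit at the boundary. Records with
   no usable global AN are dropped with a warning.
2. **CADD cutoffs.** Normal distributions are fitted (mean, sample sd with
   n−1 denominator; configurable `ddof`) to the CADD scores of known
   pathogenic and known benign variants. The lower cutoff is the pathogenic
   mean minus k·sd, the upper cutoff the benign mean plus k·sd (k = 3
   default). Cutoffs are used unrounded; `round_cutoffs` reproduces
   integer-reporting conventions (e.g. the 13/23 pair used for *GNE*).
   Scores above the upper cutoff → likely pathogenic; below the lower →
   likely benign; between the cutoffs, or missing → gray zone. Boundary
   scores equal to a cutoff fall in the gray zone. When the two score
   distributions are so well separated that lower ≥ upper, the unified rule
   (`pathogenic iff score > upper and score ≥ lower`; `benign iff
   score < lower and score ≤ upper`; else gray) keeps the three-way
   partition consistent and a warning is emitted.
3. **Gray-zone vote.** A gray-zone variant is called pathogenic when HSF
   predicts a big impact on splicing, or when at least two of three
   categories are positive: splicing (HSF important impact or
   SpliceAI > 0.5), protein impact (SIFT deleterious or PolyPhen
   probably-damaging/damaging), primate constraint (PrimateAI > 0.805).
   Absent tools count as non-positive rather than missing data, so the
   vote is monotone in available evidence; variants with no annotations at
   all stay in the gray zone (and hence in S4).

The four nested sets are S1 = known pathogenic; S2 = S1 ∪ likely
pathogenic; S3 = S2 ∪ gray-zone vote passes; S4 = S2 ∪ all gray zone.

Precomputed pathogenicity scores from missense predictors (MAVERICK,
AlphaMissense) are consumed as [0, 1] score tables and thresholded three
ways (benign < 0.4, pathogenic > 0.8 by default, both boundaries in the
closed ambiguous interval); running those models is out of scope.

## Catalog plumbing

HGVS identity is handled at string level only: keys are canonical tokens
(`<transcript>:c.<body>` with uppercased nucleotides and lowercase edit
keywords), with no sequence validation or transcript lifting — curation
pipelines convert notation to the reference transcript upstream.
Protein-only (p.) records are quarantined with a reason rather than fuzzily
matched, avoiding many-to-one c./p. ambiguity. Merging unions provenance
and resolves clinical-class conflicts by the precedence known_pathogenic >
other_disease > vus > benign (every conflict is logged); merging is
idempotent. Cross-referencing a curated list against a population export
partitions it into matched records (which inherit the export's counts) and
unmatched keys; duplicate keys inside an export are an error because their
counts would be ambiguous. Delimited input is UTF-8 with tab/comma
auto-detection; malformed annotation numerics are warned about and treated
as absent, malformed counts are hard errors naming the row.

## Synthetic data generator

The generator emulates a gnomAD-style export with known truth. Defaults —
which are the conditions under which the package's statistical claims are
validated — are: 60 variants; eight ancestry groups with diploid sample
sizes matching a v2.1.1-scale exome release (8,128 African/African
American … 56,885 non-Finnish European; ~125k individuals, global
AN ≈ 251k); true frequencies log-uniform on [10⁻⁶, 10⁻³] (the rare-variant
regime left after the MAF prefilter); consequence mix 70% missense, 8%
nonsense, 7% frameshift, 5% canonical splice, 10% synonymous; half the
variants truly pathogenic; CADD drawn from N(28, 5) for pathogenic-like and
N(8, 5) for benign-like variants (these fits place 3-sd cutoffs near the
13/23 pair used for *GNE*); binary tool outputs flipped at 5% false-positive
and false-negative rates. Counts are produced by sampling AN/2 diploid
genotypes from the multinomial (q², 2q(1−q), (1−q)²), so ac ≤ an and
2·nhomalt ≤ ac hold by construction and nhomalt is consistent with random
mating. All draws flow through one seeded generator: identical seeds give
identical catalogs.

What the generator does *not* emulate: demographic structure and founder
effects (frequencies are drawn independently per variant, not elevated in
one ancestry group), linkage, site-frequency-spectrum realism,
ascertainment and coverage bias in real databases, and misclassification in
curated lists. Passing tests therefore demonstrate the correctness of the
estimators and triage logic under the stated sampling model, not robustness
to the biases of real population databases.

## Numerical and design choices

- The quadratic form is evaluated with dense float64 linear algebra; the
  all-allowed ml value equals (Σqᵢ)² to ~1e-16 relative, and the
  severity-adjusted value matches exhaustive ordered-pair enumeration to
  the same precision (verified up to 20 variants in the acceptance suite).
- Empty variant sets estimate zero prevalence; populations for which a
  variant has no counts skip that variant with a warning rather than
  imputing zero frequency.
- Per-population estimates recompute AC/AN from that population's own
  counts; the global "all" estimate uses the explicit global entry when
  present, otherwise the sum of per-population counts.
- Reporting rounds per-million values to two decimals in tabular output;
  internal computation is unrounded.
- Problem sizes in the validation suite (one million simulated diploids for
  the Monte-Carlo genotype oracle; 100 catalogs × 1000 bootstrap replicates
  for the coverage study; AN = 10⁷ for the consistency check) were chosen
  so each statistical check has comfortable resolution while the whole
  suite runs in seconds.

## Known limitations

- Structural variants and CNVs are not representable (tables only, no VCF).
- The Hardy–Weinberg assumption ignores consanguinity, which inflates
  homozygote frequencies relative to q²; founder populations violate the
  worldwide pooling implicitly.
- Bootstrap intervals reflect sampling noise only; intervals for different
  variant sets or methods need not overlap.
- The Bayesian default prior is uninformative; per-consequence-class priors
  must be supplied by the user.
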