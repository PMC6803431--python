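# Methods

## Study design being modelled

Two purebred tilapia lines — Nile tilapia (NN), always the dam, and blue
tilapia (BB), always the sire — and their F1 hybrid (NB). GH is
pituitary-restricted; expression is measured there by qPCR in cohorts of
five fish per group and sex, allele-specific expression (ASE) by
pyrosequencing in six adult hybrids per sex plus five juvenile hybrids
per feeding condition (fed/fasted), and growth in a 120-day trial of 20
males per group. Because the parental lines are fixed for different
bases at four GH coding positions, every hybrid is heterozygous at the
assayed site and its two alleles can be attributed to parents.

## Coordinate convention

All positions are signed, 1-based CDS coordinates: +1 is the first CDS
base, negative values count 5'-ward from it and position 0 does not
exist. Spans are inclusive; a span crossing the CDS start therefore has
length `end - start` rather than `end - start + 1`. This convention is
forced by the primer table itself: the cloning pair spans -26..751 and
its printed product is 777 bp, which only the zero-skipping rule
reproduces (a naive convention with a zero position gives 778). The same
rule reproduces the other three amplicon sizes (150, 78, 113 bp).
Sequences are stored with a 26-base 5' segment ahead of the CDS so the
cloning forward primer (-26..-8) is placeable.

## Relative expression and inheritance mode

Per sample, dCt = mean Ct(GH) - mean Ct(beta-actin) over technical
replicates; ddCt subtracts the mean dCt of the calibrator group and
RQ = 2^-ddCt. The calibrator defaults to BB, the lowest-expressing
group, so parental and hybrid RQs are interpretable as fold change over
the blue parent; the choice is configurable and cancels out of every
downstream ratio. No amplification-efficiency correction is applied
(efficiency 2 assumed for both genes).

The midparent value is the arithmetic mean of the two parental cohort
mean RQs. Classification is two-stage:

1. one-sample t of the hybrid RQs against the MPV point estimate —
   nonsignificant means additive;
2. Welch two-sample t against each parent refines a nonadditive call:
   above (below) both parents means overdominant (underdominant);
   indistinguishable from exactly one parent while the parents differ
   means that parent's dominance; otherwise the direction-only call
   (above-MPV nonadditive is reported as "predominant").

Treating the MPV as a known constant ignores parental sampling error and
inflates the stage-1 type-I rate above nominal (measured ~0.08 at
alpha = 0.05 with n = 5 per cohort; the test suite bounds it at 0.10).
This is a deliberate simplification matching how MPV comparisons are
usually drawn (a dashed line at the parental average), and it is why the
classifier's null behaviour is tested against the 0.10 bound rather than
alpha itself.

Pairwise cohort comparisons default to Welch's t because the fish are
independent biological replicates; a paired variant is available where a
pairing actually exists. Multi-group comparisons use one-way ANOVA with
Tukey HSD, gated by Levene's test (median-centred, alpha 0.05) with a
log10 fallback transform when variances are heterogeneous.

## ASE model

Pyrosequencing reports the fraction of reads carrying the maternal (C)
allele at CDS position 501. Per individual, the imbalance test is the
exact two-sided binomial against 0.5, summing all outcomes whose
probability does not exceed the observed outcome's; counts are the
natural sampling unit, and instruments that report percentages are
converted back at the configured depth. No multiplicity correction is
applied by default (cohorts of 5-6); Benjamini-Hochberg is available
behind a flag. Cohort bias is the one-sample t of maternal percentages
against 50, which is identical to a paired t of maternal vs paternal
percentages since they sum to 100 per individual. Zero-variance cohorts
are reported with a degenerate flag instead of a p-value. Feeding
conditions are compared with Welch's t on the maternal percentages.

## Cis/trans decomposition

A = log2(mean RQ of NN / mean RQ of BB) is the total parental
divergence; B = log2(maternal % / paternal %) in the hybrid isolates the
cis component because both alleles share one trans-acting environment;
the trans component is the remainder A - B. Sign agreement of B and
A - B means enhancing, opposition means compensating. The sign rules are
undefined on the axes, so an epsilon dead-zone (default 0.1 log2 units,
about a 7% expression difference) adds conserved / cis-only / trans-only
as explicitly flagged extended categories. B is computed from
cohort-mean percentages (paternal = 100 - maternal); a per-individual
option exists, and no statistical uncertainty is propagated into the
category — the decomposition is a point classification, as it is
normally reported.

## Synthetic-data generator

One global seed is split into fixed per-table substreams (sequences, Ct,
allele counts, growth; allele-count streams are further keyed by preset
name), so regenerating one table never perturbs another and identical
configs are byte-identical. The generator emulates:

- **Sequences**: a random 777-base cDNA (26-base 5' segment + 751 CDS
  positions) duplicated with substitutions at 53/327/501/603; the 501
  pair is C (Nile) / G (blue), the others fixed transversions/
  transitions. Real codon structure, UTR biology and indels are not
  modelled — the fixture exists to exercise alignment, SNP calling and
  coordinate arithmetic.
- **Ct tables**: Ct ~ Normal(group mean, 0.25 cycles), five biological
  samples per group x sex, technical triplicates, reference gene flat at
  Ct 18. The GH means (males NN 24 / BB 26 / NB 22.5; females NN 23.2 /
  BB 26 / NB 23.2) encode the qualitative expression ordering of the
  study — male overdominance, female maternal dominance, hybrid above
  MPV in both sexes — because the underlying bar heights are not printed
  anywhere; only the ordering and significance pattern is reproducible.
- **Allele counts**: maternal count ~ beta-binomial(depth, p_i, rho)
  with per-individual true fractions p_i, depth 2000 and rho = 0.02 by
  default (pyrosequencing replicates are overdispersed relative to
  binomial; rho = 0 recovers the binomial exactly). The adult preset
  fractions are calibrated so cohort means equal the reported 87.10%
  (males) and 82.33% (females) exactly, with one paternal-biased
  individual per sex; per-individual values are otherwise invented,
  since the study reports them only graphically. The fed/fasted presets
  share their mean to first order, so the condition comparison is null
  by construction.
- **Growth**: final weights lognormal with arithmetic means 399.31 /
  378.95 / 305.25 g (NB/NN/BB) and sd 45 g (SEM ~10 g at n = 20);
  initial means 25.84 / 25.81 / 26.15 g back-solved from the reported
  weight-gain percentages. SGR = 100 x (ln W_final - ln W_initial)/days
  and the weight-gain rate 100 x (W_final - W_initial)/W_initial are
  both reported and always labelled, because the two are often conflated
  and cannot be interconverted without the initial weights.

Passing tests on these fixtures demonstrate that the arithmetic,
statistics and classifications behave correctly under the study's
design; they do not validate instrument-level noise models, and any
conclusion specific to real pyrograms, amplification efficiencies or
pond conditions is out of scope.

## Numerical and engineering choices

- Alignment: Needleman-Wunsch with match 1 / mismatch -1 / linear gap
  -2 and a fixed traceback tie-break (diagonal > up > left), so SNP
  coordinates are bit-reproducible; the parental fixtures are
  equal-length substitution-only pairs, for which any sane scheme gives
  the ungapped alignment. Scores are cross-checked in tests against an
  exhaustive enumeration (short sequences) and an independent library
  aligner (long sequences).
- Sanger evidence at a site may arrive as a base, an unordered base
  pair, or an IUPAC two-base ambiguity letter; all normalise to a base
  set, and bases outside the two parental alleles raise an error rather
  than being silently dropped.
- Extreme allele counts (e.g. 1000:0) produce finite, tiny p-values via
  scipy's exact binomial; nothing downstream divides by them.
- All intermediate artifacts are plain TSV/JSON so each stage can be
  re-run and audited independently; the pipeline report is a single
  JSON document keyed by stage.

## Known limitations

- The MPV test ignores parental sampling error (see above).
- Absolute RQ levels depend on the calibrator; only ratios and
  categories are comparable across runs.
- The cis/trans category carries no confidence statement; bootstrap
  intervals for A and B exist behind a flag but do not alter the class.
- The generator draws technical replicates independently; real qPCR
  replicates share pipetting structure, so fixture Ct variance is
  slightly optimistic.
- Per-individual ASE presets are calibrated to cohort means only; the
  individual-level values are plausible inventions, not data.
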