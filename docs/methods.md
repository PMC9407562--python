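# Methods

## Locus thresholds and genotype calling

Calling operates on per-marker, per-strand base counts over the tokens
A/C/G/T plus INS/DEL for the panel's single InDel (rs796296176). The
decision sequence per marker:

1. total coverage < `min_total_cov` (default 20, inclusive) → NN with
   LOW_COVERAGE;
2. otherwise, either strand at or below `min_strand_cov` (default 10;
   "more than 10×" is read strictly, so a strand needs ≥ 11 reads) → NN
   with STRAND_FAIL;
3. otherwise alleles are ranked by combined-strand coverage. A second
   allele strictly above `het_min_minor_pct` (10.0%) of *total marker
   coverage* makes a heterozygote of the top two; within the closed band
   1.0–10.0% it leaves a homozygote of the top allele carrying
   HOM_SECOND_ALLELE_ALERT; below that, a clean homozygote.

NN holds exactly when one of the two gate flags is present. Strand
information is used only by the strand gate; the genotype decision uses
combined counts, because the thresholds are stated at marker level. Ties
in coverage rank break alphabetically on the token — deterministic, and
irrelevant above the coverage gates in practice.

For heterozygotes the **variant-allele fraction** of the two called
alleles' reads is tested against the closed imbalance bands
[10.1, 35.0]% and [65.0, 89.1]%; inside either the MAF_IMBALANCE flag is
raised. Two open choices are made explicit here: the designated allele of
the fraction is the panel's variant allele (falling back to the minor
called allele when the variant allele is not among the called pair), and
the printed bands are applied literally, leaving the (10.0, 10.1)% and
(89.1, 90.0)% slivers unflagged. Both bands and the designated-allele
convention sit in the serializable `Thresholds` object, so per-locus
overrides can be swapped in via configuration.

**Drop-in records.** Every allele token outside the called genotype with
at least `dropin_min_reads` (10) reads and at least `dropin_min_pct`
(1.0%) of total marker coverage is recorded with its percentage of total
coverage (all tokens, both strands) rounded half away from zero to one
decimal. Both conventions — the denominator and the rounding — were fixed
by verifying that they reproduce all eight percentages of the reference
tri-allelic event set carried in `mpspheno.experiments` exactly. The
read floor guards against flagging single-read noise near the coverage
gate; the smallest reference event has 199 reads, so it has no effect on
the reference re-analysis. Note that the detector takes the called
genotype as an argument: in one reference event (C 2943 / A 296 / T 707)
the threshold rules alone would rank the damage product T above the true
second allele A, which is precisely why tri-allelic patterns get expert
re-analysis rather than automated acceptance.

**rDoC.** The relative depth of coverage of a marker is its total reads
divided by the library's summed on-panel reads; vectors sum to one by
construction and an all-zero library is a distinct error, not NN. The
denominator is on-panel coverage because off-target reads are outside the
count-table data model.

## Consensus clauses

Usable calls are the non-NN calls of a skeleton's retained libraries
(libraries with no marker above the coverage gates are discarded first).
Clauses apply in precedence order: single source; two-sample discordance
→ NA; unanimity of homozygotes; replicated heterozygote; heterozygote
plus homozygotes for different alleles; homozygotes for two different
alleles alone (requires ≥ 3 usable calls — with exactly two calls the
discordance clause takes precedence, the only reading under which both
clauses can hold simultaneously); one heterozygote against ≥ 2 identical
homozygotes → NA. More than two distinct alleles across calls at a
bi-allelic marker is a data-integrity condition: warning plus NA, under
the distinct rule id DATA_INTEGRITY; a marker with no usable call at all
is NA under NO_USABLE_CALLS. These two ids extend the seven clause ids so
that no NA is mislabelled with a clause that did not fire.

The clause set is verified two ways: an exhaustive scan of all 55
multisets of size 1–5 over {A/A, G/G, A/G} against a hand-enumerated
truth table written directly from the clause definitions, and a
permutation-invariance property test.

**Drop-out enumeration.** At each marker with heterozygous consensus
(X, Y), every library called homozygous X or Y is one drop-out event,
carrying the library's coverage of the surviving allele. Surviving
coverages are binned into [0, 1000), [1000, 5000), [5000, 10000) and
[10000, ∞) reads.

## Phenotype coding and AUC-loss bookkeeping

Input codes count the copies of a per-marker *counted allele* (0/1/2; NA
propagates). The counted-allele convention belongs to the external
webtool's conversion script, so the coding table is mandatory
configuration; `CodingTable.variant_counted` provides the common
count-the-variant default, and the InDel codes like any bi-allelic marker.
In single-test mode (no replicates available) heterozygotes flagged for
imbalance are conservatively masked to NA before coding. Eye colour is
undetermined whenever rs12913832 is NA; hair colour has no single gating
marker. AUC loss is the sum of configured per-trait, per-marker
contributions over a profile's NA markers — additive and monotone by
construction. The external model's actual loss values are not shipped:
they are properties of that model, not of this workflow; the analysis
driver uses a synthetic, clearly-labelled illustrative table.

## Synthetic degraded-DNA generator

Per marker, total depth is negative-binomial with mean
`base_depth · exp(−lambda_decay · amplicon_len)` and shape `dispersion`.
The exponential length decay is the simplest model of the degradation
gradient — longer amplicons lose template availability faster — and the
negative binomial the standard overdispersed count model for amplicon
depth. Heterozygote reads split by a fraction drawn from
N(0.5, `imbalance_sd`) (clipped to [0.02, 0.98]) and then binomially;
each allele of a genotype independently fails to amplify with
`p_dropout`, a dropped heterozygote allele ceding the full depth to its
sister (surviving-allele coverage stays high, as drop-out events show);
each read of a C allele flips to T (G to A) with `deam_rate`, logged as an
injected drop-in; reads split between strands with `strand_bias`. The
InDel marker is exempt from deamination. One all-zero negative-control
library is appended per cohort. All randomness flows from a single
`numpy.random.Generator` seeded by `SimulationParams.seed`; equal
parameters give byte-identical output tables.

Defaults: 11 skeletons × 4 libraries (the multi-element replicate
design); `base_depth` 8000, `lambda_decay` 0.004/bp and `dispersion` 3,
putting per-marker totals in the few-thousand to tens-of-thousands range
typical of these libraries; `p_dropout` 0.05 (observed drop-out
frequencies in such material run up to about 5–6%, with unresolved
markers making the true rate uncertain — the default is illustrative, not
calibrated); `deam_rate` 0.08, placing detected drop-in percentages
within the 1–18%-of-coverage band of the reference events (≈ 4% on a
balanced C-carrying heterozygote); `imbalance_sd` 0.06; `strand_bias` 0.5.

What the generator does *not* emulate: per-read damage patterns and
fragment-length structure (it is count-level, not read-level),
contamination mixtures, library-wide failure modes such as off-target
bacterial cloning, and between-library variation of the deamination rate
— the constant rate makes simulated drop-ins far more *prevalent* than in
real data even though their *sizes* are realistic. Passing tests
therefore demonstrate the correctness and statistical calibration of the
calling/consensus/coding rules under the stated noise model, not
performance on real aged-bone libraries.

## Validation experiments

* **Calling oracle.** An independent restatement of the locus rules in
  exact rational arithmetic (`fractions.Fraction`) is compared with the
  caller on every count vector over three alleles with total ≤ 60 (39 711
  vectors, under both balanced and skewed strand splits), plus
  hypothesis-driven random vectors up to 40 000 reads per cell.
* **Drop-out recovery.** 15 skeletons × 4 libraries with all-heterozygous
  truth and `p_dropout` = 0.10. A usable call is homozygous iff exactly
  one allele dropped, so conditional on usability events occur with
  probability 2p/(1+p); inverting the observed event fraction f gives
  p̂ = f/(2−f), with a delta-method standard error. The estimate is
  required to land within 3 SE of the simulated rate (observed across
  seeds: well inside; replication keeps consensus-NA selection bias small
  against the SE at ~1400 opportunities).
* **Deamination recovery.** On a het(A, C) marker at depth 10⁴, the mean
  detected T drop-in percentage must match the analytic expectation
  100·d/2 within Monte-Carlo error (200 libraries).
* **Noiseless identity.** With all noise off, simulate → call → consensus
  → codes reproduces the truth codes with zero NA and zero mismatches.

## Numerical choices and degenerate inputs

Percentages are compared as floats against the literal closed bounds; at
the denominators involved no representable value collides with a bound
(the oracle's exact-rational comparison confirms this over the exhaustive
grid). Rounding is half away from zero to one decimal everywhere a
percentage is reported. Degenerate inputs fail loudly: empty call lists,
skeletons without libraries or without a single usable call, all-zero
libraries in rDoC, non-positive template mass in the cycle rule, alleles
outside a marker's token pair in truth genotypes or profiles.

## Problem sizes

The shipped analyses use the default cohort (11 × 4 libraries), a
15 × 4-library recovery cohort (~1400 heterozygous library-markers), 200
libraries for the deamination study and the full ≤ 60-read enumeration
for the oracle scan; together they complete in seconds while keeping
every standard error small against its 3-SE acceptance band.
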