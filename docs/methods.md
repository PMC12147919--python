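# Methods

This note documents the models behind `orievolve`: what each simulator
emulates, the analysis definitions, the numerical choices, and what the
package's passing tests do and do not establish about real data.

## Reference frame

Everything operates on one amplicon: a rep-initiator ORF plus fixed-length
flanks (defaults 966 nt + 2 x 150 nt, matching a typical *repA* sequencing
amplicon). Coordinates are 0-based half-open internally; every file and
report uses 1-based positions and 1-based residue indices. Generated
references start with ATG, contain no internal stop codons (internal codons
drawn uniformly from the 61 sense codons) and end with a random stop.

## Synthetic data: what is modelled, what is not

**epPCR library.** Each clone carries a Poisson(lambda_mut) number of
substitutions, truncated at 10, with positions uniform over the ORF (the
flanks come from the vector and are never mutagenized) and alternate bases
drawn from a 4x4 spectrum. The default spectrum is transition-biased
(65% transitions, transversions split evenly), reflecting Mn2+ /
unbalanced-dNTP Taq behaviour; lambda_mut defaults to 2, the midpoint of
the usual 1-3 substitutions-per-molecule target of a low-cycle epPCR. The
realized per-molecule rate of any actual reaction is unknown, so both are
calibration choices, user-overridable. No indels, chimeras or
recombination are modelled.

**Phenotypes.** A clone whose protein differs from wild type at a causal
residue receives `wt_copy_number x multiplier` (max over causal residues
hit); defaults plant 5 causal residues at x5. Clones acquiring a premature
stop are removed at library construction: a replication-dead plasmid
cannot be maintained under marker selection. With the default spectrum and
lambda, ~5-6% of clones are removed, consistent with the enumerated
per-substitution stop-gain probability (~2.8%) compounded over the
mutation load.

**Selection.** The copy-number -> survival coupling is an invented
parametric stand-in (no quantitative dose-response was ever measured for
this system): Hill induction `I(s) = I_min + (I_max - I_min) s^h /
(K_s^h + s^h)` of the resistance gene by salicylic acid, resistance dose
`R = copies * I(s)`, and a log-logistic per-generation growth weight
`w(g, R) = 1 / (1 + (g / (alpha R))^beta)`, compounded over G = 10
generations and realized by multinomial resampling to the output culture
size. Defaults (I_min = 0.02, I_max = 1, K_s = 0.25 uM, h = 1, alpha = 20
mg/L per dose unit, beta = 2) were set so that a wild type at 9.5
copies/cell shows a lethality frontier inside the standard checkerboard;
with them the strongest auto-selected well is 750 mg/L gentamicin +
5 uM salicylic acid. The weight is exactly 1 at zero gentamicin,
non-decreasing in dose and non-increasing in drug; expected post-selection
frequencies have the closed form `f_i w_i^G / sum_j f_j w_j^G`, which the
tests use as an oracle. The default output culture size is 10^6 cells:
selection cultures are bulk (many orders of magnitude above library
complexity), so the resampling bottleneck should be far below read-sampling
noise, not an artificial 10^4-cell founder effect.

**Checkerboard.** 8 rows x 12 columns; gentamicin halves row-wise from
3,000 mg/L (row A) to 23.4 mg/L (row H), salicylic acid halves column-wise
from 5 uM (column 12) to 2.44 nM (column 1). Overnight well ODs are
modelled as saturating outgrowth: a clone with weight w expands
2^(D w)-fold (D = 24 doublings in the window), summed over the population,
capped at od_max = 1 from an inoculum of 0.002. Selection wells are those
with `od_wt < threshold <= od_mut` (threshold 0.2).

**Sequencing.** Fragments emulate tagmentation of the amplicon: uniform
start, length ~ Normal(600, 60) truncated to the amplicon, no insertion
bias. R1 is the first 300 bases of the fragment, R2 the reverse complement
of the last 300 (shorter fragments give shorter reads). Errors are i.i.d.
substitutions at 0.3% per base with a uniform wrong base; qualities are a
constant Phred score (default 35). No instrument error profiles, no
quality decay along the read, and no PhiX spike-in (that only aided
base-calling diversity on the instrument).

**dPCR and growth curves.** A dPCR channel with mean load lambda per
partition yields positives ~ Binomial(8500, 1 - e^-lambda). Growth curves
are a three-parameter logistic sampled every 6 min for 24 h (241 points)
with additive Gaussian OD noise (default sd 0.005), clipped at zero.

Because the generator omits indels, context-dependent error, alignment
artefacts and culture-to-culture biological variance, passing tests
demonstrate the correctness and calibration of the *analysis* under the
stated generative model — not that real libraries will reach the same
recall.

## Read mapping and pileup

The mapper is gapless and substitution-only: a 20-mer seed looked up in a
two-strand exact k-mer index, slid by 10 nt when it misses, then gapless
extension; a placement is accepted iff it is the unique minimal-mismatch
placement with mismatch fraction <= 0.10. When every seed window misses,
the mapper falls back to an exhaustive scan over all offsets and strands,
so accept/reject behaviour is identical to a brute-force aligner (the
batch path verifies this is so in the tests). Reads shorter than the seed
are unmappable. Indel-bearing reads fail the mismatch threshold and drop
out — appropriate here because epPCR produces substitutions; externally
aligned (gapped) data can enter through the SAM reader instead, which
walks CIGARs, counts M/=/X bases, skips insertions and soft clips, tallies
deletion-spanned positions under `other`, and ignores
secondary/supplementary/duplicate records.

The pileup masks bases below Q20 rather than trimming reads. Overlapping
mates contribute one observation per template position: agreeing unmasked
bases count once; a disagreement, or an overlap where either base is
masked, counts as masked. This conservative rule keeps every A/C/G/T
counter monotone non-increasing in the quality threshold. Consequently
total depth equals the summed aligned length minus the summed overlap;
depth conservation holds exactly for non-overlapping templates.

Performance: reads are processed in 50,000-pair chunks; uniform-length
chunks take a sparse path that counts coverage from read intervals and
handles only deviant bases explicitly (identical output to the dense
tally, which remains as the general path and as a cross-check).

## Enrichment

Allele frequency is `alt / (A+C+G+T)` per position (masked and `other`
excluded); positions under 100x usable depth are flagged and excluded from
residue ranking. Fold change uses a 0.5 pseudocount on counts (not
frequencies), making FC finite, exactly reciprocal under sample swap, and
insensitive (<1%) to doubling both depths. Significance is a two-sided
Fisher exact test per allele on `[[alt_sel, ref_sel], [alt_unsel,
ref_unsel]]` — computed by a vectorized log-gamma enumeration of the
hypergeometric support, equal to the classic sum-of-smaller-probabilities
definition (1e-12 log-space tie tolerance) — with Benjamini-Hochberg
correction across all alleles. Residue scores take the maximum FC over
nonsynonymous alleles of the codon; synonymous and flank alleles never
enter ranking. Top-k selection (default k = 20) breaks ties by ascending
residue index and reports the realized FC threshold.

A known property of the max-aggregation rule: under a true null the
residue-level median FC sits above 1 by roughly `exp(1.35 * sd(ln FC))`
(the expected maximum of ~7 unit-median alleles), e.g. ~1.3 at ~50 reads
per allele. The allele-level FC distribution is the calibrated quantity
(median 1.00 in the null runs); residue scores are a ranking device, not
an unbiased effect estimate.

## Copy number

`lambda = -ln(1 - k/n)` per channel (computed with `log1p` for small
fractions); a saturated plate (k = n) is an error, never a clipped
estimate, and a reference channel with zero positives is an explicit
no-signal error. Copies/cell is lambda_target / lambda_reference — equal
reaction volumes assumed, so partition volume cancels. The 95% CI applies
the delta method on the log-ratio: `Var(lambda-hat) ~= p / (n (1 - p))`
per channel, summed as squared coefficients of variation; coverage is
94-95% in simulation and the interval matches a 10^4-resample bootstrap to
~2%. Biological replicates are combined as the mean of per-replicate
ratios (not the ratio of pooled lambdas), with its SE.

## Growth kinetics

The three-parameter logistic `N(t) = K / (1 + ((K - N0)/N0) e^{-rt})` is
fitted by bounded trust-region least squares. Initialization: K0 = max OD,
N0_0 = first positive OD, r0 = slope of ln(OD) over the earliest quarter
of above-baseline points, with a small ladder of rate restarts
(0.1/0.3/1/3 per hour) guarding against a bad initial slope. Bounds:
K in [max(1e-6, 0.5 max OD), 10 max OD], N0 in [1e-8, max OD], r in
[1e-4, 50] per hour. A fit is `converged` only if the optimizer succeeded,
K > N0 > 0, r is off its lower bound, and the fit explains at least 10% of
the variance; flat series return `converged = False`, never an exception.
Blank handling is opt-in (`blank="first"` subtracts the first reading,
flooring at 1e-4) because simulated curves are true ODs with no medium
blank, and unconditional subtraction would erase N0 and bias r; real
plate data with a blank offset should enable it. Rates are reported as
doublings per hour = r / ln 2, identically 60 / doubling-time-in-minutes.
Across K in [0.5, 1.5], N0 in [0.005, 0.05], r in [0.2, 1.0] at noise
0.005, 100% of fits converge with r within 5%.

Growth comparisons use the equal-variance Student t per mutant against WT
with BH correction across the mutants of a panel (the unequal-variance
Welch test is used for transformation colony counts instead, where group
spreads differ structurally).

## Panel statistics

Regressions are polynomial OLS (degree 1 by default, degree 2 available
because copy-number/output relationships often plateau), reporting
adjusted `R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)` and the overall F-test
p. Tukey HSD uses the studentized-range distribution (scipy); letters come
from the insert-and-absorb compact-letter-display algorithm over groups
sorted by mean — groups share a letter iff no significant pairwise
difference separates them. Fisher exact 2x2 (zero-margin tables get p = 1),
Welch t with Welch-Satterthwaite df, and Pearson correlations with
t-approximation p and BH across the tested pairs complete the set. The
interface-enrichment test builds the candidate x interface membership 2x2
and applies the Fisher test; it is a pragmatic stand-in for whatever
spatial statistic one might prefer with full structures in hand. All of
these are pure functions: no seeds, no state.

## Problem sizes and reproducibility

All simulators are bit-reproducible from (configuration, integer seed);
per-stage streams are derived with `numpy.random.SeedSequence` spawn keys,
so each stage can be regenerated independently. The acceptance script runs
the full screen at study scale (10,000 clones, 200,000 read pairs per
population, 20 seeds) and the no-selection calibration at 50 seeds with
60,000 read pairs per population — the null statistics (discovery rate,
median fold change) are depth-limited only through sampling noise, so the
smaller read budget changes their spread, not their location. The dPCR
block uses 1,000 plates; the growth block 90 grid fits.

## Known limitations

- Short-read pileups cannot phase multi-substitution haplotypes; the
  analysis is strictly per-allele, and hitch-hiking passengers of true
  causal clones enrich alongside them (they are diluted by recurrence:
  a causal residue is hit in many independent clones, a passenger in few).
- No selection-coefficient inference; FC is a ranking statistic.
- The survival model's parameters are not identifiable from the screen's
  outputs and are not meant to be fitted.
- The residue-level max-aggregate is upward-biased under the null (see
  Enrichment above); compare residues against each other, not against 1.
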