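# Methods

## Conversion chemistry model

Bisulfite conversion is modelled per cytosine with two error parameters:
the under-conversion probability `u` (an unmethylated C fails to convert
and is read as C; default 0.05) and the over-conversion probability `v` (a
methylated C is erroneously read as T; default 0). An unmethylated C
converts with probability `1 − u`, a methylated C with probability `v`;
only C→T changes are possible, so A and G counts on the converted strand
are conserved. The reverse strand is converted as the reverse complement
(its cytosines are the plus-strand guanines), which reproduces the
strand symmetry real libraries show: C/T drift on the plus strand mirrors
G/A drift on the minus strand.

Under this model, the expected per-site methylation percentage at CpG
cytosines with methylation probability `p` is `100·(p + (1−p)·u −
p·v)`, and the spike-in estimator below is unbiased for `u`.

## Spike-in conversion QC

A fully unmethylated reference stands in for the lambda spike-in. The
under-conversion rate is the number of C−C matches divided by the total
read coverage of reference-C positions, counted only on the strand a read
derives from (conversion is strand-specific chemistry); efficiency is
`100·(1 − rate)`. Reads are placed by their recorded truth intervals —
the generator's lossless substitute for alignment, which is out of scope.
Zero covered C positions is an error rather than a silent zero. The QC
verdict passes at efficiency ≥ 95% (boundary inclusive); note that with
`u = 0.05` exactly, the true efficiency sits on the boundary and the
verdict of any finite run is a coin flip — the report always carries the
numeric estimate.

## Read simulation: two modes

`bisulfite_convert`/`convert_genome` + `simulate_genomic_reads` convert a
genome **once** and slice reads from it. This is simple and exactly
self-consistent (a read equals the converted genome at its truth
interval), but every read overlapping a site shows the same base there, so
per-site counts are all-or-nothing.

`simulate_bisulfite_reads` instead draws methylation states **and**
conversion outcomes per read, treating each read as an independent
molecule from a cell population — per-site C/T counts across reads are
then binomial, as in a real library. The pipelines and all per-site
statistics use this mode; the genome-level mode remains for conversion
bookkeeping and invariant checks. Both modes place read starts uniformly
and sample strands 50/50. Paired-end fragments are supported in the
genome-level mode (the `simulate` subcommand writes them); the analysis
pipelines run single-end, which loses nothing at these scales because
mates are statistically identical to two single reads.

Sequencing error beyond conversion events, quality-score simulation and
indels are intentionally not modelled.

## Methylome and context model

Every cytosine on both strands gets a context by the standard 3-base rule
(CpG, CHG, CHH with H ∈ {A,C,T}) on its own strand's 5'→3' reading;
a context window running off the sequence end falls through to CHH, and
cytosines with N in the window are excluded from every count. States are
independent Bernoulli draws with per-context probabilities (defaults:
CpG 0.75–0.85 by arm, CHG/CHH 0.01), optionally overridden per site. Real
methylomes are spatially correlated; this generator is deliberately
i.i.d. within context, so tests verify calling and testing machinery, not
segmentation behaviour.

## Differential methylation

Sites shared by both samples are tested with a two-sided Fisher exact test
(minimum-likelihood two-sided rule) on the 2×2 (n_meth, n_unmeth) table at
per-site α = 0.01, with no multiple-testing correction by default
(Benjamini–Hochberg available behind a flag). Before testing, a site's
methylation must be distinguishable from conversion noise in at least one
sample: a one-sided binomial test of n_meth against retention probability
equal to the conversion error rate (default 0.05) at p < α. This "reality
screen" is the simplest defensible use of an externally calibrated error
rate as a gate before differential testing. Orphan sites (covered in only
one sample) are dropped by default — random coverage guarantees some —
and `strict=True` raises with the orphan list instead.

## Repeat-amplicon analysis

**Primer location.** The left primer is matched directly, the right as its
reverse complement downstream; both primer→side assignments are tried
because a printed consensus may be written in either product orientation
(the shipped LINE-1 consensus is reverse-primer oriented). In bisulfite
space, a primer T additionally pairs with a consensus C (a C that
converted; primer C demands a retained C), reverse-complementing to G/A
degeneracy on the right primer — this matches primers designed against
converted DNA, as the shipped Alu pair is. Primers may overhang a
consensus edge by up to 3 bases with mismatches counted over the overlap
(the shipped Alu consensus is one base shorter than its nominal product,
so the reverse primer overhangs by one); best hit = fewest mismatches,
ties to the leftmost, >3 mismatches = not found. The located Alu amplicon
is [0, 219) and LINE-1 [0, 429).

**Alignment.** A semi-global affine-gap aligner (match +1, mismatch −1,
gap open −2, gap extend −0.5; a gap of length g costs open + (g−1)·extend;
consensus end gaps free) reports consensus span and identity for QC.
Dinucleotide counting uses reads as sequenced, not alignment-projected
coordinates, matching the per-sequence frequency measure.

**Per-read measure.** `cg_pct = 100·n_cg/(L−1)` over all overlapping
dinucleotide windows (N-containing windows excluded from the denominator),
with `100·n_cg/(n_cg+n_tg)` reported alongside. The distribution-shift
thresholds (8/12 low/high, 7.5 split) are applied to per-read CG *counts*
by default (`tail_metric` configurable): on the shipped consensi the
count scale is the one those thresholds bracket — the Alu amplicon has 16
CpGs (so full-length cg_pct tops out at 7.3%) and LINE-1 has 10 — and for
fixed-length products counts and length-normalised frequencies are the
same measure up to a constant.

**Tail-shift test.** Control category proportions define expected treated
counts, reported with a goodness-of-fit statistic; the p-value comes from
the 2×k homogeneity chi-square on both samples' counts, because treating
the control proportions as known inflates the false-positive rate
roughly (1 + n_t/n_c)-fold at comparable arm sizes, at any depth.

**Mixture detection.** `gaussian_em` fits univariate Gaussian mixtures by
EM: k=1 closed form; k=2 from 10 seeded restarts (sorted-split
initialisation at a random quantile), relative log-likelihood tolerance
1e-8, at most 500 iterations, SDs floored at 1e-4 of the data range.
Because the unconstrained likelihood is unbounded, a k=2 solution must
give every component an effective count ≥ 5. Selection: the
likelihood-ratio statistic with Wolfe's degrees-of-freedom adjustment for
mixtures (χ², df = 2 × extra parameters = 6, α = 0.05). AICc is computed
and reported for every fit and available as `selection="aicc"`, but it
admits spurious narrow shoulder components on plainly unimodal samples
(the mixture LRT null is not χ²₃, and information criteria inherit the
problem); the uncorrected 3-df LRT is also available. With n < 20 only
k=1 is fitted. Fits are deterministic for a fixed seed.

A caveat either way: for any fixed non-Gaussian shape the k=2 fit wins
asymptotically, so the one- vs two-population verdict on skewed or
strongly discrete data is meaningful at moderate n (hundreds of reads),
not a consistency statement.

## Generator defaults for the amplicon study

Defaults describe the Alu study conditions: control is a single molecule
population whose mean CG retention centres the per-read count at ~10 of
the 16 consensus CpGs (level 0.60; retention = level + (1−level)·u),
i.e. squarely between the 8/12 tail thresholds; treated is a minor (25%)
hypomethylated population at level 0.30 plus a major (75%)
hypermethylated population at level 0.85, whose centres sit ≥1 SD below 8
and above 12 respectively. Per-molecule levels are beta-distributed
(concentration 40) with conditionally independent per-CpG Bernoulli
states — the simplest model producing unimodal/bimodal per-read CG
distributions; no claim is made that real per-molecule levels are beta.
Molecules default to full length (`p_truncate = 0`), modelling
gel-purified products; truncation to a random window (optionally down to
`min_observed_len`) exercises the ≥100 b length filter when enabled. PCR
bias against molecules with unmethylated CpGs in the priming region is
available (`priming_bias`) but off by default; concatemer artifacts are
not generated.

Because every consensus CpG reads CG or TG when conversion is exact,
`n_cg + n_tg` is constant across full-length reads, and the within-arm
CG/TG regression slope is exactly −1 under defaults — the inverse
correlation is structural, real data only blurs it.

## Problem sizes

Default runs and the test suite use desk-scale sizes chosen to keep every
check statistically decisive: 20 kb genomes, 3,000–20,000 reads of 100 b
(≈15–100× strand coverage), 5 kb spike-in with 800–10,000 reads, 600
amplicon molecules per arm, 200-replicate null batches for size checks,
and 20-seed batches for recovery checks. The original study's scales
(human genome, >7,000 Alu / >10,000 LINE-1 products) are emulated in
structure, not in volume.

## Numerical and convention choices

- Coordinates are 0-based half-open everywhere; 1-based appears only in
  rendered text.
- The C-count denominator is all sequenced bases (not covered bases).
- Methylation-percent bins are [0,10) … [90,100] with the last bin closed.
- Flank windows are [pos−100, pos+101) clipped at chromosome ends; greedy
  left-to-right emission skips any window overlapping the previous one,
  preserving fixed 201 b windows.
- Gene distance is the gap to the nearest included gene base (half-open
  arithmetic), "proximal" at ≤5 kb inclusive; reports also carry the
  dichotomous >5 kb intergenic split.
- The ratio-paired t-test is a paired t on log10 ratios (natural log gives
  the identical p); Welch is the default two-sample t; the two-sided
  Fisher p uses the minimum-likelihood rule (other tools' doubling rule
  differs in ties).
- Yates' correction is floored so |O−E|−0.5 never goes negative.
- EM ties in model selection resolve to k=1; mixture components are
  reported sorted by mean.

## Known limitations

- Truth sidecars substitute for alignment; there is no mapper, and
  mapping ambiguity (a large effect in real repeat analysis) is absent.
- The i.i.d. methylome has no regional structure, so bin-profile and
  annotation results demonstrate correctness of the bookkeeping, not
  biological realism of where methylation changes fall.
- Gaussian mixture verdicts on strongly discrete/skewed data are
  n-sensitive (see above).
- The amplicon generator draws molecules from one consensus; real repeat
  families carry sequence and CpG-position diversity between elements,
  which widens real per-read CG distributions beyond what the generator
  produces.
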