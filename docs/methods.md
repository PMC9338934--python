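# Methods

This note documents the model behind `strsift`, the defaults it ships
with and why, the numerical conventions that matter for reproducibility,
and what the simulation-based validation does and does not establish.

## Complexity filter

Each read's nucleotide string (uppercased, non-ACGT characters mapped to
N) is compressed and the ratio C = output bytes / input bytes computed.
The container convention is pinned: **raw DEFLATE stream** (`wbits=-15`,
no zlib/gzip header or trailer) at compression level 1 (fastest). Wrapper
headers would shift C additively by several bytes — material at short
read lengths — so the convention is recorded in every threshold table and
output file. Input bytes are the sequence characters only; quality
strings never enter the ratio. C is bit-deterministic for a given
sequence.

A read of length L is a repeat candidate iff C ≤ t_L. The boundary is
inclusive: filter false positives are cheap (they merely reach the exact
repeat detector, which cannot produce spurious runs), so the convention
favours sensitivity. Thresholds for absent read lengths fail loudly
rather than interpolate, because C's scale changes nonlinearly with L
(fixed DEFLATE block overhead occupies a growing fraction of short
reads).

### Threshold calibration

`calibrate_thresholds` simulates, per read length, N labelled
repeat-informative reads (tract ≥ 45 nt of a random primitive motif of
1–15 nt, tract length uniform in [45, L]) and N background reads, then
picks the threshold maximising Youden's J = sensitivity + specificity − 1
over the observed C values (ties broken toward higher sensitivity, then
the smaller threshold). N defaults to 2,000 per class; the built-in table
(read lengths 50, 75, 100, 124, 125, 150, uniform background, error-free,
N = 5,000, seed 20260928) was produced by this exact routine and records
the calibration sensitivity/specificity alongside each threshold.
Degenerate calibrations (J ≤ 0 everywhere, i.e. inseparable classes)
raise rather than return a meaningless threshold.

The 45 nt informativeness floor follows the convention that a read must
contain at least 45 nucleotides of repetitive sequence to be useful
evidence for an expansion.

### Two evaluation protocols

`evaluate_classifier` measures the filter against the 45-nt labelling
under two designs, and the distinction is deliberate:

* **informative**: positives have tract ≥ 45 nt, negatives are pure
  background. This measures raw separability of the two C distributions
  and is the design the thresholds are calibrated on. Under error-free
  uniform background it is near-perfect (sensitivity and specificity
  ≥ 0.99 at 150 nt and at 50 nt).
* **full** (default): repeat-carrying reads are simulated at *all* tract
  lengths 1..L, so reads with 1–44 repetitive nt are genuine negatives,
  alongside background reads. Tracts just below 45 nt are intrinsically
  confusable with tracts just above — no threshold on C can split a 44 nt
  tract from a 45 nt one — and this confusable band makes up a growing
  share of the negative class as L shrinks (44/L of repeat draws). This
  is why specificity degrades at short read lengths (measured ≈ 0.87 at
  50 nt vs ≈ 0.96 at 150 nt with calibrated thresholds), while
  sensitivity stays near 1.

## Exact maximal repetitions

The detector reports every run — substring with minimal period p, at
least two full copies (fractional trailing copies extend the tract, e.g.
`AGCAGCA` is one run of tract 7, period 3), not extensible in either
direction under p — with tract length ≥ `min_tract` (default 9 nt, which
suppresses ubiquitous short dinucleotide noise; scoring windows make the
choice immaterial for expansion detection). Runs never span an N.

The implementation scans each candidate period for maximal match blocks
at that lag and keeps a block iff the substring's minimal period (via its
failure function) equals the scanned period, which reports each run
exactly once. For read-scale inputs (≤ a few hundred nt) this quadratic
detector is faster than the constant overhead of asymptotically better
algorithms. Correctness is defined by the run definition itself: the
suite checks exact agreement with an independent definition-level
enumerator, exhaustively over all two-letter strings up to length 12 and
on 10⁴ random four-letter strings, and asserts the runs-theorem bound
(number of runs ≤ string length). Purity is 1.0 by construction under
exact detection; the field is kept for format compatibility.

Motif canonicalisation reduces a motif to its primitive root, then takes
the lexicographic minimum over all rotations of the root and of its
reverse complement. Class counts per canonical length are 2, 4, 10, 33,
102, 350 for lengths 1–6 (145 classes for lengths 3–5). Runs of any
period are detected, but summarisation keeps canonical motifs of at most
6 nt by default (`max_motif_len`), the STR range.

## Information scores

Per sample and canonical motif, v_l counts runs of tract length l; the
score is s_m = (Σ_{i≤l≤j} v_l·l)/n with n the library size (every read
counts, candidate or not), j the read length and i = ⌊0.75·j⌋ (the
bracket is implemented as floor; at j = 150, i = 112). Counts are stored
raw and divided by n exactly once — normalising the stored vector *and*
dividing in the score would scale s_m by 1/n², making it depth-dependent.
With the single division s_m is invariant under exact duplication of the
library and linear under concatenation of read files, both asserted in
the suite. The window [i, j] ranges over *tract lengths*; motif length is
capped separately. Every run in a read counts (a read holding an AT run
and a CG run increments both motifs).

Mixed-read-length cohorts must be harmonised before scoring: the trim
length is the minimum of per-sample modal read lengths, longer reads are
truncated to their first L nt (analogous to downsampling the longer
experiment), shorter reads are kept untrimmed rather than discarded.
Score vectors with different windows refuse to assemble into one cohort.

## Screening statistics

Per motif with a nonzero score in ≥ 1 sample, a one-sided Mann–Whitney U
(cases > background; midranks for ties) is referred to its permutation
null over label shuffles. When C(n₁+n₂, n₁) ≤ n_perm all labelings are
enumerated and the p-value is exact; otherwise n_perm (default 10,000)
random shuffles give the add-one estimator (1 + #{U* ≥ U})/(1 + n_perm),
which is positive and seed-reproducible. Identical pooled scores short-
circuit to p = 1. BH step-up correction (via statsmodels) is applied
across exactly the tested motif set; the suite verifies it against a
direct implementation of the step-up definition on 10⁴ random p-vectors,
and verifies the permutation p against exhaustive pairwise-win
enumeration on small groups. The null type-I error at nominal 0.05 is
checked to sit inside its 99% binomial envelope over 400 null screens
(slightly conservative values are expected from the discreteness of the
exact null).

## Outlier detection

One-versus-many: for each motif the upper end of the 95% BCa bootstrap
confidence interval for the 95th percentile of the information score is
estimated from **background-labelled samples only** (n ≥ 20 enforced),
and a query sample is flagged iff its score strictly exceeds that bound.
Using only unascertained/control backgrounds avoids the false negatives
that case-resampling schemes with an assumed outlier fraction produce
when expansions are common at a locus. Quantiles use linear interpolation
between order statistics (the numpy default), pinned because quantile-
type ambiguity shifts bounds materially at background sizes in the tens.
n_boot defaults to 9,999. The BCa machinery is scipy's
(`scipy.stats.bootstrap`); when the bias-correction or acceleration is
undefined (degenerate bootstrap distributions, zero jackknife variance —
e.g. an all-zero background) the estimator falls back to the percentile
bootstrap and says so in the output. Coverage of the true 95th percentile
on normal and exponential backgrounds (n = 500) is measured at ≈ 0.92–
0.95 over 200 replicates, consistent with the nominal 95% level within
Monte-Carlo and quantile-bootstrap error.

## Simulation subsystem

Background reads draw i.i.d. bases from single-nucleotide composition
models: `uniform` (0.25 each), `human` (~41% GC), `gc_rich` (~72% GC, a
GC-rich actinobacterium), `at_rich` (~86% AT, protozoan intergenic
sequence). These are parameter presets, not genome-derived k-mer models.
Repeat reads overwrite a window of a background read with a periodic
tract; impurity is modelled per motif copy (one random substitution
within a copy with probability `motif_change_prob`), sequencing error as
a per-base substitution (no indels) applied afterwards. Synthetic
expansion loci place a tract between flanks rejection-sampled until the
package's own detector finds no run ≥ 15 nt, standing in for
repeat-masked genomic flanks; locus reads sample start positions
uniformly and are labelled informative at ≥ 45 nt overlap with the
tract. Cohort fixtures write controls as pure background and cases with
25 expansion-derived reads per 10⁴ reads by default — a deliberately
clear signal used for end-to-end validation, not an estimate of any
particular disorder's read yield.

What passing simulations do **not** show: performance on real libraries
with indels, quality-dependent error, GC bias, PCR duplicates, k-mer
structure in the background (real genomes are more repetitive than any
i.i.d. model, so real false-positive rates at the filter are higher and
thresholds should be recalibrated per dataset), or power at expansion
sizes that shed few fully-repetitive reads.

## Problem sizes

Default validation sizes were chosen to give stable estimates at
interactive runtimes on a single CPU: 2,000 reads per class for
calibration, 20,000 per class for classifier evaluation, 25 samples ×
10⁴ reads for the end-to-end cohort, 400 null screens, 200 bootstrap
replicates (n_boot = 999 inside replicated coverage studies, 9,999 for
single analyses). All generators and tests derive their randomness from
explicit seeds; identical seeds give byte-identical outputs.
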