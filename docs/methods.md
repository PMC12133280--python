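# Methods

## Model

cfDNA sequencing over- or under-represents fragments as a smooth, nonlinear
function of their GC content, and the shape of that function drifts with
fragment length. `fraggc` models the bias at single-position resolution:
for fragment length *l* and GC bin *g* (0–100, integer percent,
round-half-up), the bias value is

    b(l, g) ∝ O(l, g) / E(l, g)

where O counts observed fragments and E counts all possible fragment
placements in the valid regions of the reference. Because E enumerates
every position exactly (no sampling), b is an unbiased estimate of the
sample's length-specific acceptance curve up to a scale; the per-length
mean normalization removes the scale. The correction factor c(l, g) =
1/b(l, g) is applied as a per-fragment weight.

Assumptions: bias depends on (l, g) only — not on chromosome, copy-number
state, or position; fragments are counted once from the forward read of a
proper pair with the fragment interval [POS, POS+TLEN); GC content is read
from the reference under the fragment, not from read bases, so sequencing
errors do not perturb the bin.

## GC context window

The first and last 10 bp of a fragment are excluded from the GC window
(`clip`, default 10): base composition at fragment ends reflects cleavage
preference, not amplification bias, and contaminates the GC signal. For a
150 bp fragment the window is therefore the central 130 bp.

## Estimation chain and numerical choices

1. **Gap interpolation.** An integer window of size w can only realize w+1
   GC fractions, so for w < 100 some of the 101 bins are unattainable and
   systematically zero. Those bins — and only those — are filled by linear
   interpolation between the nearest non-zero neighbors, in both matrices.
   Zero counts at *attainable* bins are genuine observations; filling them
   too would invent mass exactly where data are sparse and systematically
   depress the normalized center of the curve (we measured factor errors
   of 20–40% on sparse lengths before restricting the fill rule).
   The bare `interpolate_gaps(row)` call without a support argument fills
   every interior zero, for callers that do not know the window size.
2. **Neighbor merging.** Counts are pooled across fragment lengths within
   ±2 bp (identically for O and E); adjacent lengths share near-identical
   curves and pooling is what keeps per-length estimation workable at
   ultra-low coverage.
3. **Estimability.** b(l, g) is defined only on GC bins 10–90 where
   (a) E(l, g) is at least 10⁻³ of the row's maximum expected count and
   (b) E(l, g) times the row's average sampling rate O·/E· is ≥ 2 — i.e.
   at least two fragments would be expected in the bin even without bias.
   Below either threshold the ratio is shot noise: a single stray fragment
   at the edge of the support otherwise acquires enough leverage to bend
   the local-linear smoother and, through the mean normalization, shift
   the whole row. Undefined bins surface as correction factor 0, the same
   convention the method uses outside the 20–80% range.
4. **Winsorization.** Within each length row, defined values are clamped
   to that row's 3rd/97th percentiles (linear interpolation between order
   statistics). The clamp is per length because raw rates scale with the
   fragment-length distribution: mono-nucleosomal rows sit an order of
   magnitude above rare lengths before normalization, so a joint clamp
   across the table would shear the peaks of well-populated curves instead
   of removing outliers (measured: recovery r dropped from ≥0.97 to 0.84
   with a global clamp under a bell-shaped injected bias).
5. **Smoothing.** Each row is mean-normalized and smoothed with a
   tricube-weighted local-linear fit (span = max(3, ⌈0.1·n⌉) of the n
   defined points, single pass, no robustness iterations), evaluated on
   bins 20–80. The kernel is additionally multiplied by precision weights
   proportional to the expected counts: Var(O/E) ∝ 1/E, and at desk scale
   the edges of the GC range have orders of magnitude less support than
   the center. The smoother is implemented in-package because the common
   library implementation accepts no observation weights; in the
   unweighted case the two agree (covered by a test). Smoothed values are
   floored at 0, and rows with fewer than 3 defined points pass through
   unsmoothed with a warning.
6. **Retention and final normalization.** Only 20–80% GC is kept (the
   10–90 margin exists to give the smoother context at the retained
   edges); each row is mean-normalized once more, so every defined row
   averages exactly 1 (enforced to 1e-9; re-applying the normalization is
   a no-op).
7. **Inversion and capping.** c = 1/b where b > 0, else 0 (never
   infinity); c = 0 outside 20–80% GC; c is capped at 20, or at the 99th
   percentile of the positive factors when that percentile exceeds 20
   (a sample with genuinely extreme bias is allowed stronger correction).

A length-agnostic variant estimates a single curve from a fixed 400 bp
window anchored at the fragment start and broadcasts it to all lengths; it
exists as a comparison configuration and is measurably worse under
length-dependent bias (and even under length-invariant bias, because the
fixed window only weakly reflects each fragment's own context).

## Outputs

Factors are written as a CSV grid (rows = length 51–400, columns = GC
0–100, 6 decimals). BAM tagging writes every read's fragment-level factor
as a float `GC` tag (both mates carry the same value; ineligible fragments
get 0.0); tagging can run per contig and concatenate, which produces
byte-identical tags. Binned coverage assigns each eligible fragment to the
bin containing its midpoint (raw +1, corrected +c); factors are rounded to
single precision before accumulation so that summing `GC` tags from the
tagged BAM reproduces the corrected track exactly. Bins without any
valid-region overlap are reported as missing, not zero. WIG output is
1-based fixedStep with step = span = bin size, the convention expected by
HMM-based copy-number callers.

## Metrics

*Divergence*: fragment counts per GC bin (optionally factor-weighted) are
summed over a length group and sum-normalized; the Jensen–Shannon
divergence against the expected density uses base-2 logarithms, so it is
symmetric and bounded in [0, 1], with 0·log 0 := 0. *Variation*: bins are
filtered to high-confidence copy-number calls (neutral keeps 1.5 < CN <
2.5, gain CN > 2.5, loss CN < 1.5); runs of 50 consecutive, coordinate-
contiguous, same-label bins are selected greedily left-to-right per
contig, skipping 25 bins after each run (10 and 5 at 1 Mb bins); the
sample COV is the mean over runs of the population SD / mean of
mean-normalized coverage. Coverage is normalized by the genome-wide mean
over labeled bins; COV itself is scale-invariant, so any consistent
normalization gives the same value.

## Applications

Fetal-fraction mixing merges a seeded X% of male fragments (selected by
query name, so mates are never orphaned; names are prefixed per source to
prevent collisions) into a full female sample; the ground truth is the
exact rational 100·X/(X+100) percent. The per-autosome diagnostic is the
population SD of the 22 mean-normalized count/length ratios (0 for
perfectly even coverage); with a correction table, counts are
factor-weighted. The NDR score divides mean fragment coverage in the
strand-oriented −150..+50 bp window around a TSS by the pooled mean over
the ±1000–2000 bp flanks; zero flank coverage yields NaN with a warning,
and the score is invariant to global coverage scaling.

## Synthetic data

The simulator generates what the estimator assumes, with known truth:

* **Genomes** are built from 5 kb blocks whose GC target follows a
  triangle wave between 30% and 70% (per-contig phase offsets), so GC bias
  expresses itself as coverage waves along the contig. Default 3 contigs ×
  300 kb; 2 kb stretches every 150 kb are masked from the valid-regions
  BED to exercise region handling while leaving ≥ 50-bin contiguous runs
  at 2 kb bins. Bases are drawn independently per position.
* **Fragments** are rejection-sampled: uniform start in a length-weighted
  valid interval, length from a mixture of normals — 166±10 bp (85%),
  320±15 bp (10%), 80±8 bp (5%), the mono-/di-/sub-nucleosomal structure
  of plasma cfDNA — accepted with probability a(l, g) from a configurable
  acceptance curve (flat, bell, increasing, or length-banded regimes),
  floored at 10⁻³. Rejection sampling makes O/E equal a(l, g) in
  expectation, which is what makes recovery testable. Optional
  copy-number segments scale placement density by CN/2. Each accepted
  fragment is written as one proper pair (50 bp reads copied from the
  reference, TLEN ±l), coordinate-sorted and indexed.
* **Not modeled**: sequencing error, base qualities, adapters, mappability
  structure, chimeras, duplicate reads. Passing tests therefore
  demonstrate correctness of the estimation machinery under the stated
  bias model, not robustness to alignment artifacts in real data.

## Problem sizes used in the test suite

The statistical checks run on 500 000 fragments over the 900 kb synthetic
genome (a per-position sampling depth comparable to deep WGS, with the
per-bin count sparsity of low-pass data), with COV evaluated on 2 kb bins
as a scaled stand-in for 100 kb bins — the 50-bin run length and 25-bin
gap are kept. Smaller samples (8k–60k fragments) back the mechanical and
application tests.

## Known limitations

* Fragment lengths with almost no data even after ±2 bp merging produce
  noisy curves; their factors may be extreme (within the cap) or zero.
  They affect few fragments by construction, but per-bin coverage in very
  small bins can be visibly perturbed by a single heavily-weighted rare
  fragment.
* The correction zeroes fragments outside 20–80% GC (about 1% of mass in
  realistic genomes), so corrected totals are slightly below raw totals.
* Single-end data, CRAM, and reads without a valid TLEN are unsupported;
  duplicate marking is assumed done upstream.
* The per-autosome fetal-fraction *estimator* is not included — only the
  mixing simulator, its exact ground-truth arithmetic, and the
  autosome-ratio SD diagnostic.
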