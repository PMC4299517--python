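# Methods

## Sequence space and conventions

A TIS context is the 11-mer spanning positions −6..−1, +1..+5 around a
fixed AUG (+1..+3); there is no position 0.  Sequences are RNA internally;
DNA input is accepted and converted (T→U) on entry.  Enumeration order is
lexicographic with A < C < G < U, so rank r of a context is its base-4
digit expansion over the eight variable positions.  An *upstream AUG* is an
AUG window lying entirely within −6..−1 (window starts −6..−3); a window
straddling −1/+1 is impossible because +1 is fixed to A.  Of the 65,536
contexts, 4,080 contain an upstream AUG (4·4³ six-mers minus the single
AUGAUG double-count, times 16 downstream combinations).  The
high-efficiency motif RYMRMVAUGGC matches 96 contexts, none of which
contains an upstream AUG.

## Synthetic FACS-seq generator

The generator emulates the sort-seq measurement with a known truth so that
every estimation step can be checked by parameter recovery.

**Ground truth.** ln E is log-linear in the context: an intercept plus
zero-sum mononucleotide effects per position and doubly centered pairwise
effect tables per position pair — the same functional family the fitting
module estimates, which is what makes generator coefficients directly
comparable with fitted ones.  Defaults: mono effects N(0, 0.10²), pairwise
effects N(0, (0.5·0.10)²), intercept ln 76.9 (a typical exp-scale baseline
for a reference-normalized reporter).  The effect scale was set so the
efficiency span across the space is of the order of the ~12-fold range
reported for real AUG contexts (measured ~7–15-fold across generator
seeds); the pairwise fraction makes interaction structure strong enough
that a pairwise fit clearly beats a mononucleotide one, mirroring the real
measurement.  `pair_fraction=0` yields a purely mononucleotide truth for
exact order-1 recovery tests.

**Cells.** Each of the 65,536 contexts receives `cells_per_tis` cells
(default 300, giving a ~2×10⁷-cell sort); each cell's GFP/RFP ratio is the
true efficiency times exp(ε), ε ~ N(0, σ²) with σ = 0.25 by default.  A
single multiplicative log-normal term is the simplest noise law consistent
with a strictly positive ratio; real data would add heavier tails,
autofluorescence floors and sorter impurity, none of which is modeled, so
passing recovery tests demonstrate correctness of the estimation chain, not
robustness to every cytometry artifact.

**Gating.** The 20 gates each hold exactly 5% of cells.  Gating is
rank-based — sort by ratio, cut into contiguous blocks differing by at most
one cell — rather than thresholding, so equal occupancy is exact; reported
boundaries are the ratio values at block edges.  All ratios identical is a
degenerate-gates error.  The bottom and top gates are open-ended (off-scale
cells land there), which matters for quantification (below).

**Sequencing.** Per gate, `reads_per_gate` reads (default 50,000, i.e. 10⁶
total across 20 barcodes) are drawn multinomially with probabilities
proportional to per-context cell counts.  Reads can be rendered as
error-free barcoded FASTQ (6-mer gate barcode + fixed anchors + 11-mer) for
demultiplexer testing; PCR bias and sequencing errors are out of scope.
One root seed drives all stages through independently spawned child
streams, so identical seeds reproduce outputs exactly.

## Quantification

Counts are depth-normalized per gate column so each barcode represents an
equal fraction of the sorted population (columns rescaled to the mean raw
total; row proportions unchanged).  Each context's median GFP/RFP is read
off its cumulative per-gate weight curve at 0.5, interpolating linearly in
ln(ratio) within the gate (cytometer gates are approximately log-spaced);
the open-ended extreme gates are assigned synthetic edges one median
ln-gate-width beyond the extreme boundaries.  Efficiencies are
E = 100·median/median(GCCACCAUGGG), making the reference exactly 100.

Row flags: `missing` (zero reads — never zero-filled; the PWM later
predicts these contexts), `low_reads` (fewer than 20 normalized reads;
configurable), and `off_scale` (median falling in an open-ended extreme
gate).  The `off_scale` flag exists because those medians depend on the
synthetic-edge convention rather than on data — the cells there were
censored by the sorter scale — and including them in training measurably
biases coefficient estimates; flagged rows keep their values but are
excluded from fitting.  At the default depth (~15 reads per context on
average) most rows are `low_reads`; the ~8–9k high-confidence rows are
ample for the order-2 fit (10× rows-per-predictor required).

The 20-bin quantization bounds the per-context resolution: with exact gate
weights and no expression noise, every interior reconstructed median lies
within half its gate's ln-width of the truth (asserted in the tests).

## PWM fitting

Ordinary least squares of ln(E) on a sum-to-zero ("effects") contrast
encoding: 3 columns per position (24 for order 1), 9 per position pair
(+252 for order 2), 27 per triple (+1,512 for order 3), plus an intercept
ln k.  The contrast basis makes the decoded per-(base, position) effects
satisfy the sum-to-zero normalization exactly, with the intercept absorbing
the overall level; fitted values are identical to any other identifiable
parameterization.  Upstream-AUG contexts and flagged rows are excluded from
training by default; weighted least squares by read count is available but
off by default.  Normal equations are solved by Cholesky factorization;
OLS standard errors of the decoded mono and pair effects are retained on
the model.

Two degeneracy behaviors are deliberate.  A base never observed at some
position raises an error naming the missing (position, base) levels.  For
order 3 only, the upstream-AUG exclusion structurally empties the (A,U,G)
cell of each consecutive upstream position-triple, making the full
trinucleotide interaction unidentifiable; the fit then uses the
minimum-norm (pseudoinverse) solution and records `solver: pseudoinverse`
in the metadata.  Coefficient magnitudes of affected triples are therefore
convention-dependent, but fitted values on observable contexts are not.

Parameter recovery behaves as follows (asserted by the acceptance tests):
from a noiseless efficiency table the order-1 and order-2 fits reproduce
generator coefficients to ~1e-14 (tolerance 1e-6); through the full
pipeline at default depth with σ = 0.25 the deviations are consistent with
the OLS standard errors.  "Within 3 SE" is checked per coefficient with
the binomially expected number of exceedances allowed (a calibrated
estimator leaves each coefficient inside 3 SE with probability ≈ 99.7%, so
over m coefficients up to ⌈0.0027·m + 3·√(0.0027·m)⌉ exceedances are
statistically expected); at the canonical seed the observed exceedances are
zero.  On pairwise truth with noise, held-out R² of the order-2 fit exceeds
the order-1 fit, and the order-3 fit does not beat order-2 (over-fitting),
reproducing the qualitative model ranking of real TIS data; the exact R²
values depend on the generator's signal-to-noise and are not meaningful
constants.

## Descriptive statistics

Cooperativity summaries group contexts by their bases at a chosen position
pair (e.g. +4/+5) and report group medians with percentile-bootstrap 95%
CIs (default 1,000 resamples, seeded).  Quartile composition ranks the
table by efficiency with deterministic lexicographic tie-breaking, and
reports per-quartile fractions lacking −3R or +4G, the max/min fold-range,
and the mean uplift of full motif matches over contexts carrying only the
−3R/+4G rule of thumb.  A table of identical efficiencies has no quartiles
and raises a degenerate-ties error.

## Genome scanning and leaky scanning

Transcript I/O is 1-based inclusive (GenBank CDS convention); internals are
0-based half-open.  The annotated context is the 11-mer around `cds_start`;
records whose start is not AUG, whose CDS is not a codon multiple, or whose
bounds are inconsistent are skipped with a reason.  Starts lacking 6
upstream or 2 downstream bases are flagged insufficient-context and
excluded from distribution summaries (counted in the skip report).  uORF
TISs are AUGs lying entirely within the 5′ UTR (codon end ≤ cds_start − 1);
AUGs overlapping the CDS boundary are not uORFs.  Category summaries
(mean uplift vs the full-space mean, top/bottom-quartile shares) weight
per transcript.

The truncation TIS is the smallest in-frame AUG position p > cds_start with
the codon strictly before the stop codon; only this nearest site is
considered (multi-site cascades are not modeled).  The initiation ratio is
X = (1 − p₁)·p₂/p₁ with pᵢ = min(1, k·Eᵢ/100) and k = 0.86; predicted
efficiencies can exceed 100/k, in which case the probability clamps to 1
and the event is logged.  Classes are X ≥ 1.0, 0.50 ≤ X < 1.0, X < 0.50
(upper boundaries inclusive).  Ribosome-footprint support is filtered from
a user-supplied per-transcript count table: reads at the annotated TIS
≥ 50, TIS separation ≥ 20 bases, no annotated alternative 5′ isoform —
boundaries inclusive, each dropped row attributed to the first failing
filter in that order, and prediction ids missing from the count table
listed rather than silently dropped.  Footprint read mapping and peak
calling are out of scope.

## Variant effects

A TIS SNV substitutes one base at −6..−1, +4 or +5 (start-codon positions
are rejected as out of scope); the effect is
100·(E_mut − E_wt)/E_wt, negative meaning reduced translation, computed
from either a fitted model or a full reference-table lookup — the two paths
agree exactly when the table was built from the same model.  The screening
helper only flags sign-consistency with a user-supplied expression
direction; it makes no statistical claims (tumor-database intersection and
expression statistics are outside the package).

## Problem sizes and limitations

Default study conditions: 65,536 contexts × 300 cells, 20 gates, 10⁶ reads
total, σ = 0.25.  Tests use the same pipeline at reduced cell and read
depth where exactness is not the point.  Known limitations: the noise model
is a single log-normal term; reads are error-free (the demultiplexer's
anchor/barcode rejection paths are exercised with synthetic corrupt reads,
not a sequencing-error model); the generator's truth is exactly log-linear,
so model-misspecification behavior beyond order mismatch is not probed; and
genome scans treat each transcript independently, without resolving
alternative 5′ isoforms.
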