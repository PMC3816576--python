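# Methods

This note documents the models, the statistics and the design choices made
where the underlying protocol left the design open, together with what the
synthetic benchmarks do and do not establish.

## qPCR processing

**Ct calling.** A linear baseline is fitted by least squares over the
baseline window (default cycles 3–15, 1-based) and subtracted; the Ct is
the linearly interpolated fractional cycle at which corrected fluorescence
first rises through the threshold (default 0.2, on the reporter/passive-dye
scale).  Two consequences are worth knowing.  First, the baseline window
must precede the amplification rise: fitting through rising signal drags
the baseline up and biases the Ct (the window default matches instruments
where real Cts sit well above cycle 15; `baseline_cycles=None` skips the
correction for already-corrected curves).  Second, linear interpolation
chords the convex exponential, so a curve crossing between integer cycles
reads slightly early — for F = 1e-4·2^c and threshold 0.2 the interpolated
Ct is 10.9531 against the exact crossing log2(2000) = 10.9658, a bias of
about 0.013 cycles, far below replicate noise.  A curve that never crosses
is "not detected" (NaN); the genomic-DNA check treats non-detection as a
pass since no amplification implies no contaminating template.

**Efficiency estimation.** Per-cycle amplification efficiency is estimated
from log10(F) regressed on cycle number over the best contiguous
window-of-linearity (default length 5) among windows with positive,
strictly rising fluorescence, and reported as (10^slope − 1)·100.  The
regression weights each point by F² — the inverse-variance weighting when
fluorescence noise is additive, which stops the noisiest low-signal cycles
from dominating after the log transform.  Window selection maximizes the
(weighted) R² of the fit, with ties going to the steeper, earlier window;
plain OLS and steepest-window selection remain available as switches.  On
noiseless curves every variant recovers the planted efficiency exactly; at
1%-of-plateau additive noise the median estimate over 100 curves stays
within 2 percentage points of truth, while individual estimates scatter
more (the log of an additively noisy exponential is intrinsically
ill-conditioned at low signal).  Gene-level QC excludes a gene iff the
fraction of its reactions with efficiency < 95% is strictly greater than
0.25 — a fail fraction of exactly 1/4 is retained.

**Quantile normalization.** Each sample's sorted Ct vector is replaced by
the across-sample mean of sorted vectors (rank ties broken stably), making
every sample's distribution identical while preserving within-sample order;
the operation is idempotent.  Genes with a missing value in any sample are
excluded from the rank computation and restored as missing.  Joint
normalization across all samples is the default; a per-condition switch
exists.  A caveat documented here because it matters for synthetic
benchmarks: when *most* genes genuinely change (as in a small simulated
panel where every gene responds), forcing equal distributions compresses
true fold changes — the fold-change exactness checks therefore run on the
un-normalized ΔΔCt path, and the normalization is validated on its own
contract.

**Relative quantification.** ΔCt is the median of normalized Ct across
biological replicates (even counts use the midpoint mean), ΔΔCt contrasts
the low-CO2 sample at each timepoint against the high-CO2 reference at
t = 0, and FC = 2^−ΔΔCt, so FC(ΔΔCt)·FC(−ΔΔCt) = 1 identically.  The
marker-gene path normalizes a target to a reference gene (e.g. actin)
within each sample before the condition contrast, reporting replicate
means ± SD.  For clustering, profiles are log2-transformed, min–max scaled
to [0, 1] per gene and mean-centred; constant profiles have no defined
scaling and are excluded with a flag.

## QT clustering

Distance is d(a, b) = 1 − r(a, b) (Pearson), so the diameter threshold 0.5
keeps all intra-cluster pairs at r ≥ 0.5.  The alternative (1 − r)/2
convention would halve the effective threshold; the choice is exposed by
simply passing a different diameter.  The algorithm is the classic
quality-threshold procedure: grow a candidate cluster from every remaining
gene as seed, at each step adding the gene that least increases the
diameter (the maximum pairwise distance) while it stays within the
threshold; extract the largest candidate (ties: earliest seed; growth ties:
input order — both fixed for determinism), repeat, and stop when the best
candidate falls below the minimum size (default 4).  Remaining genes are
unassigned, never forced.  The implementation maintains incremental
max-distances; the test suite checks it against an exhaustive
re-computation oracle on random instances up to 12 genes, and asserts the
diameter bound on every output.  Because Pearson distance is invariant to
positive affine maps per gene, clustering scaled profiles or raw fold
changes yields identical partitions.

## Inner composition alignment (IOTA)

For regulator series x and target series y of length m ≥ 3, let π be the
stable ascending sort permutation of x and ỹ = y∘π.  A crossing is a pair
(i, j), 1 ≤ i < j ≤ m−1, with (ỹ_j − ỹ_i)(ỹ_{j+1} − ỹ_i) < 0 — the segment
ỹ_j → ỹ_{j+1} strictly crosses the level of the earlier point ỹ_i.  Then

    ι(x → y) = 1 − C / ((m−1)(m−2)/2).

Properties relied on by the tests: ι ∈ [0, 1]; ι = 1 for every strictly
monotone relation y = f(x), increasing or decreasing, which is what lets
one score activation and repression alike; ι depends only on orderings, so
it is invariant under strictly increasing transforms of either series (the
network stage therefore feeds −ΔCt, i.e. log2 relative expression,
directly); exact ties count as non-crossings, a zero-measure event for
continuous data that keeps the statistic deterministic.  The implementation
is vectorized over the (m−1)(m−2)/2 index pairs and is checked for exact
agreement against a naive triple-loop enumerator on 1,000 random instances.

**Significance.** The permutation test shuffles the *target* series
uniformly at random with replacement from the m! permutations (the only
tractable reading for large m), recomputes ι, and reports
p = (1 + #{ι* ≥ ι_obs}) / (1 + n_perm) — add-one corrected so p > 0.
Because reordering a uniform shuffle by any fixed permutation is again a
uniform shuffle, the null draws for a given target are shared across all
candidate regulators inside `reconstruct_network`, reducing the cost from
n²·n_perm to n·n_perm ι evaluations without changing any distribution.
Default n_perm = 10,000 and α = 0.01 per pair, with no multiple-testing
correction by default (a Benjamini–Hochberg switch exists).  With m = 4
points the exact null has only 24 atoms, so p < 0.01 is unattainable by
permutation of one series; the generator therefore defaults to m = 12
observations, which also matches the package's calibration suites.

**Calibration caveat.** ι at m = 12 has a discrete support of 56 values, so
permutation p-values form a lumpy, slightly conservative mixture smoothed
only by Monte-Carlo jitter.  They are approximately — not exactly —
continuous-uniform under independence: a KS test on 500 draws usually
passes at the 0.01 level but can reject for unlucky RNG streams.  The
zero-coupling false-edge rate matches α within binomial error.

**What edge recovery does and does not show.**  A pairwise monotonicity
measure has two structural blind spots, and the benchmarks are split
accordingly.  (i) A target driven by several regulators is not monotone in
any single one, so multi-parent edges score low; (ii) conversely, an
*invertible* monotone coupling is symmetric (x = f⁻¹(y)), and monotone
compositions along chains or between siblings sharing a regulator are
themselves monotone, so reverse, indirect and confounded pairs score high.
The edge-detectability suite therefore uses planted one-regulator→one-target
topologies (median true-edge ι exceeds the 95th percentile of all other
ordered pairs across 20 seeds at noise 0.05), while the density-sampled
benchmark exercises only the reconstruction contract and reports
precision/recall descriptively.  On real data the same caveats apply to any
IOTA-derived network: an arrow means "monotone association aligned with
this ordering", not a causal claim.

## Synthetic data

The generator reproduces the study design rather than the organism:
unregulated genes follow smooth gene-specific transient response curves (a
seeded low-order Fourier series on log2 scale, amplitude 1–3 log2 units —
2- to 8-fold swings, matching the fold-change range qPCR panels report); a
regulated gene's log2 expression is the signed average of saturating tanh
drives from its regulators (averaging keeps amplitudes within the per-edge
coupling strength; sign −1 models repression; ~30% of edges are
repressive).  Coupling is evaluated within the recorded timepoint — the
fast-equilibration reading of a first-order update, appropriate when the
transcriptional response is fast relative to the 60-min sampling interval —
with cycle-closing edges falling back to the previous timepoint.  This
makes a noiseless single-edge system *exactly* monotone in the aligned
series (ι = 1) for every source shape.  Measurement noise is additive
Gaussian on log2 expression (default SD 0.05, i.e. ~3.5% CV), independent
per replicate (default 5 biological replicates), and expression is
exponentiated so it stays positive.  Ct encoding inverts relative
quantification: Ct = offset − log2(expression) + technical noise, with the
t = 0 sample labelled HC and later samples LC.

Amplification curves are saturated exponentials — exactly f0·(1 + E/100)^c
below the plateau, capped there, plus additive noise — so the log-slope of
the exponential phase encodes the planted efficiency exactly.

The toy genome places fixed-length genes without overlap on one chromosome,
marks a fraction as differentially expressed, and plants a summit near the
coding start or stop of each gene with probability P(peak|DE) = 0.9 vs
P(peak|non-DE) = 0.1 (the defaults), jittered by a configurable Gaussian
offset.  What these simulations do *not* emulate: genuine qPCR artefacts
(primer-dimer melting behaviour, plate effects), chromatin biophysics,
fragment-size effects, sequencing noise, overlapping gene models, or any
linkage between the expression simulator and the genome simulator's DE
labels — so passing tests certify the statistics and the code paths, not
biological fidelity.

## FAIRE enrichment and peak annotation

Per amplicon, ΔCt subtracts the reference amplicon within sample type,
ΔΔCt = ΔCt(FAIRE) − ΔCt(control), enrichment = 2^−ΔΔCt; the reference has
enrichment exactly 1 and the profile is invariant to constant Ct shifts of
either sample type.  Technical-replicate Cts enter as means, with SDs
propagated in quadrature onto ΔΔCt.  Two reference-selection rules are
implemented: the published rule — the amplicon minimizing the raw
Ct(FAIRE)/Ct(control) *ratio* — and a least-enriched rule (largest
Ct(FAIRE) − Ct(control)).  The ratio rule is kept as the default for
fidelity, but note it selects the *most* FAIRE-enriched region (enriched
regions have low FAIRE Ct), which then normalizes true enrichment away;
the synthetic demo uses the least-enriched rule so planted openness reads
out as enrichment > 1.

Summits are assigned to the gene minimizing min(|summit − coding start|,
|summit − coding end|) on the same chromosome (ties by gene id; strand
recorded but irrelevant to the unsigned distance), unassigned beyond
`max_distance` (default 1 kb; pass infinity for histograms so the tail is
not clipped).  GFF3 is 1-based inclusive, BED 0-based half-open; both are
converted to 1-based positions internally and an even-width peak's summit
takes the lower-middle base.  The association tests are Pearson chi-square
on 2×2 tables (1 df, no continuity correction by default, Yates behind a
flag), with zero margins rejected; the implementation is checked against
the closed-form 2×2 formula.

## Motif scanning and promoters

IUPAC consensus scanning reports every (overlapping) offset where each
pattern position's base set contains the sequence base, single-strand by
default (enhancer elements are defined on the promoter strand) with an
optional reverse-complement scan; Biopython's ambiguity table supplies the
base sets, restricted to the fifteen IUPAC codes.  Promoter extraction
takes the strand-aware window of `upstream_bp` bases ending just before the
coding start (reverse-complemented for minus-strand genes), truncating and
flagging at chromosome edges.  Note the base-rate: a 7-letter pattern with
five informative positions hits a random 500-bp window with probability
~0.38, so motif-presence counts need a background comparison, which the
analysis script provides by planting the consensus only upstream of DE
genes.

## Pipeline defaults and problem sizes

All stage defaults are the protocol's parameters (Ct threshold 0.2,
baseline 3–15, efficiency QC 95%/25%, QT diameter 0.5/min size 4, n_perm
10,000, α 0.01, 2-fold cutoff, 500-bp histogram bins, 1-kb assignment
window).  The analysis scripts run a 60-gene, 12-timepoint, 5-replicate
time course over a network of ~77 edges (edge density 0.02, close to the
sparsity of published regulator networks), and a 300-gene toy genome with
600-bp summit jitter; the calibration suites use 10-gene networks, 500
permutation-null draws at n_perm 2,000, and 100 genomes of 300 genes.
These sizes keep the full test-and-acceptance cycle in the tens of seconds
while leaving every statistic well away from small-sample degeneracy.
Every random routine takes an explicit seed, and a pipeline run writes its
resolved configuration and a JSON summary next to its outputs, so any run
is reproducible byte-for-byte.

## Known limitations

- Pairwise IOTA cannot separate direct from indirect/confounded monotone
  relations, cannot see multi-regulator integration, and retains both
  directions of near-invertible couplings; reported precision against
  planted dense networks is correspondingly low.
- Quantile normalization assumes most genes are unchanged; on panels where
  everything responds it compresses fold changes.
- Efficiency estimates from single noisy curves scatter by several
  percentage points; gene-level QC decisions should rest on many reactions,
  as the 25% rule implies.
- The deposited genome-scale network summary (node count, mean out-degree)
  can only be checked when the published supplementary edge list is
  supplied by the user; it is not redistributable here.
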