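# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions a user relying on the outputs should
know.

## Coordinates

All genomic coordinates are 0-based half-open in memory and 1-based
inclusive in every TSV interface. TSS-relative coordinates put 0 on
the first transcribed base; −1 is the base immediately 5′ of the TSS.
Minus-strand promoters are analyzed on the sense (transcribed) strand:
the window is the reverse complement of the corresponding genomic
slice. This choice is made because σ-factor contacts and the open
transcription bubble are defined on the sense strand; a tool that had
analyzed the reference strand instead would see AT2 (which is not a
strand-symmetric set: AT↔AT, AA↔TT, but TA maps to itself) with a
different composition on half the promoters. TUs whose window overruns
a contig end are excluded and counted, never padded or truncated —
padding with N would dilute positional frequencies asymmetrically.

## Time-series clustering

The chain arcsinh → DFT → component normalization → Gaussian mixture
is designed so that a gene's response *shape*, not its expression
level, drives the clustering. arcsinh(x) = ln(x + √(x²+1)) behaves
like ln(2x) for large x and like x near 0, so multiplicative noise
becomes approximately additive while zeros stay finite. The DFT is
taken over the sample index of the (unevenly spaced) series; this
matches common practice for feature extraction from designed time
courses, where the components act as smooth shape descriptors rather
than literal frequencies. Each non-DC component is normalized by the
mean amplitude of the other non-DC components,
X′_k = X_k / mean{|X_j| : j ≥ 1, j ≠ k}; the denominator deliberately
excludes component k itself so that a series dominated by a single
component keeps a large normalized value at that component. Genes
whose spectrum has fewer than two non-zero components (the denominator
would vanish) and genes with summed TPM below a low-signal threshold
(default 1 TPM over the series) are excluded and reported.

Clustering uses an EM-fitted Gaussian mixture with full covariances,
ridge-regularized by 1e−6·trace/dim of the data covariance, best of
n_restarts (default 20) seeded restarts. A t-mixture with a Box–Cox
stage could be substituted; after arcsinh stabilization and amplitude
normalization the features are close enough to elliptical that the
Gaussian family recovers the planted structure exactly (see the
acceptance tests), and the mixture family is not itself exploited
downstream — only the labels and centers are. Model selection
maximizes BIC = 2·log L − p·ln n over K = 2..10, ties toward smaller
K. With the default synthetic scenario the BIC curve has a clear
interior maximum at the planted cohort count.

Cluster ids are arbitrary, so for display they are relabeled against a
reference classification (in practice: diurnal co-expression cohorts)
by greedily assigning the (cluster, class) pair with the smallest
hypergeometric enrichment p-value; leftover clusters append in
decreasing size order.

## TU statistics

TU expression is the unweighted mean over member coding genes. The
gene clustering is transferred to TUs by Lloyd's k-means started
exactly at the gene-cluster centers (tolerance 1e−8, ≤300 iterations)
with K fixed; a cluster that captures no TU keeps its center and is
reported empty rather than reseeded, because reseeding would break the
correspondence with the gene clustering. k-means is implemented
directly here (not via a library call) precisely to preserve these
empty-cluster semantics.

Immediate-response labels use r = log2((mean_post + δ)/(mean_pre + δ))
with pseudocount δ = 0.5 TPM shared across all log-ratio utilities;
label boundaries are strict (|r| exactly at θ is "nc"). Defaults
θ = 0.01 at gene level (a permissive directionality census) and
θ = 0.15 at TU level (only confident movers feed the promoter
analysis).

The 5′→3′ gradient is Δ = log2FC(first) − log2FC(last); positive Δ
means the downstream gene responds less (or more negatively) than the
promoter-proximal gene, the pattern expected when transcription
attenuates along the unit. The sign convention is documented here
because only relative statements constrain it; the quantity is
antisymmetric under reversing the gene order, so consumers can flip it
trivially.

ΔΔCt is returned both raw and negated; the negated value is the log2
fold change (a drop in target Ct means more transcript).

## Enrichment tables

Cell tests are cumulative hypergeometric: enrichment is the upper tail
P(X ≥ x), deprivation the lower tail P(X ≤ x), on the universe of
items shared by the two classifications. P-values are reported raw —
the display contract caps intensity at p_min, which serves the same
practical purpose as correction for the table plots — and a
Benjamini–Hochberg column is emitted alongside for users who need
error control.

Row sorting walks the table columns in order: rows enriched at
p ≤ p_sort in the current column move to the top (ascending p), and
rows never placed stay below the "red line" (or are dropped). Sorting
keys on p_enrich only; using min(p_enrich, p_deplete) would mix
directions within a block.

The rendering contract emits, per cell: the count (or rounded Welch
t), background intensity min(1, log2 p / log2 p_min), hue (black for
categorical tests; red t < 0, blue t > 0), and white text iff
p ≤ p_txt. It is a TSV style sheet, not a drawing routine, so any
plotting toolkit can consume it.

## Promoter structure

Motif occurrences are recorded at the position of the k-mer's first
base; all overlapping occurrences count (the indicator is literally a
0/1 vector over start positions). Windowed frequencies use windows of
w positions centered as [p − ⌈w/2⌉ + 1, p + ⌊w/2⌋] (so the even 66 bp
window covers −32..+33 around p), truncated at profile edges with the
effective slot count in the denominator. Positional tests treat the
window slots of all TUs as the universe and the cluster's slots as the
draw; for single-base motifs on an i.i.d. background this sampling
model is exact, while for k ≥ 2 motifs the within-window
autocorrelation of overlapping k-mers makes it an approximation (the
null-calibration test covers the regime actually used).

The autocorrelation of upstream regions (default −100..−1 for the
pipeline; configurable) is computed on the concatenated indicator with
cross-promoter products masked out — naive concatenation would
generate spurious boundary products between unrelated promoters. The
dominant period is the argmax of r(ℓ) over ℓ ∈ [6, 15] refined by
parabolic interpolation through the three surrounding lags, which
resolves non-integer pitches from integer-lag ACFs.

PWMs use a pseudocount of 0.5 per base. Jensen–Shannon divergence is
computed per position in bits (log base 2), so it lies in [0, 1].
Significance of PWM differences uses a label-permutation test
(default B = 1000): group labels of the pooled sequences are permuted
preserving group sizes and p = (1 + #{JSD_perm ≥ JSD_obs})/(B + 1).
The permutation scheme is chosen over parametric PWM-difference
statistics because it is exact under exchangeability and needs no
distributional assumptions about column counts.

Discriminator statistics summarize the mean G+C fraction over
positions −6..−3 and the fraction of promoters with T at −7; cluster
vs all comparisons reuse the hypergeometric machinery on base counts.

## Synthetic generators

`simulate_timeseries` draws TPM(t) = baseline · 2^w(t) · e^ε with
gene baselines lognormal(ln 100, 1), cohort waveform w(t) in log2
units (0 before induction), and ε ~ N(0, 0.2²) — multiplicative
lognormal noise, the simplest generative model consistent with
strictly positive expression and the arcsinh/log analysis chain. The
default scenario has six cohorts of 150 genes over 15 time points
(−24 h and −35 min pre-induction, 5 and 20 min immediately after,
then out to 72 h): a damped 24 h oscillation peaking at induction, a
sustained down-step, an antiphase oscillation, a weak residual
oscillation, a delayed ramp and a delayed ramp with overshoot. These
templates emulate the qualitative shapes of induction-response groups;
they do not emulate count noise, library-size artifacts, or
overlapping/ambiguous gene-to-cohort membership, so recovery of the
planted labels shows the feature chain and model selection work — not
that six groups would be found in any real transcriptome.

`simulate_genome` tiles non-overlapping TUs on alternating strands of
an i.i.d. background chromosome (default GC 0.48, near the
*Synechocystis* genome average). `plant_promoter_motifs` writes
A-tract(4) tetramers at sense positions round(anchor − j·pitch)
(rounding half away from zero), defaults anchor −10, pitch 10.5 bp,
3 repeats, into 80% of TUs. The j-th upstream repeat is present with
probability 0.75^j (the anchor always, when a TU carries the pattern):
real promoter sets show their strongest phased enrichment at the
anchor with decaying upstream coherence, and without attenuation every
planted position would tie for the profile maximum. Because planting
offsets round to integers, a 10.5 bp pitch realizes as alternating
10/11 bp lags; the ACF consequently peaks between lags 10 and 11 and
the parabolic refinement lands near 10.5–10.8 depending on the
attenuation-weighted lag mix.

`simulate_foldchanges` gives gene k of m the value
fc_first − Δ·(k−1)/(m−1) + noise with per-TU fc_first ~ N(0, 1);
at zero noise the gradient estimator returns Δ up to floating-point
rounding (the generator and estimator share no code).

## Problem sizes and determinism

The validation suite runs the full default clustering scenario (900
genes, 15 time points, K = 2..10) in seconds and repeats it over 20
seeds with 3 restarts per fit; promoter recovery uses 200–300
synthetic TUs. These sizes were chosen as the smallest at which the
recovery statistics are stable from seed to seed. Every stochastic
stage takes an explicit integer seed and is bit-reproducible; the
pipeline writes its config hash and all stage seeds to the run log,
and a rerun with the same config produces byte-identical outputs.

## Known limitations

* The DFT treats samples as equally spaced; strongly uneven designs
  change what the components mean (shape descriptors, not
  frequencies).
* Positional hypergeometric tests for k ≥ 2 motifs ignore
  within-window occurrence autocorrelation (see above).
* The AT2 set is analyzed on the sense strand only; a both-strand scan
  would double-count AA/TT and needs a different null.
* Immediate-response labeling assumes exactly two pre- and two
  post-induction samples by default; other designs must pass explicit
  index sets.
* The enrichment display contract reports raw p-values by design; use
  the emitted BH column when inference rather than display is the
  goal.
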