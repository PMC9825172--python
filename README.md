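# coilscape

Analysis pipeline for transcriptome responses to perturbations of DNA
supercoiling in bacteria, built around the kind of experiment in which
topoisomerase activity is genetically manipulated (topoisomerase I
overexpression, gyrase knockdown) in a cyanobacterium such as
*Synechocystis* and the transcriptome is followed over an induction
time course. It is aimed at computational biologists who have
expression tables, fold-change tables and a TSS-annotated genome, and
who want to ask: which co-expression groups respond, how does the
response propagate along transcription units, and what distinguishes
the promoters of the responding groups?

The package covers four analysis stages plus a synthetic-data module
that emulates the statistical structure of all inputs, so every stage
can be exercised and validated without external downloads.

## What it computes

**Fourier-feature time-series clustering.** A gene's TPM series
x(t) is variance-stabilized with arcsinh, transformed by the DFT
(X_k = Σ_t x_t e^(−2πikt/N)), and each non-DC component is normalized
by the mean amplitude of the other non-DC components:
X′_k = X_k / mean{|X_j| : j ≥ 1, j ≠ k}. The real and imaginary parts
of X′_1..X′_6 are clustered with a full-covariance Gaussian mixture
over K = 2..10; the K maximizing BIC = 2·log L − p·ln n is selected.
Clusters are then sorted and relabeled against a reference
classification (e.g. diurnal co-expression cohorts) by greedy
hypergeometric matching.

**TU-level response.** Gene expression is averaged over the coding
genes of each transcription unit; the gene clustering is transferred
to TUs by k-means seeded exactly at the gene-cluster centers; the
immediate response is labeled up/down/nc from
r = log2(mean(post)/mean(pre)) against a threshold θ (0.01 for genes,
0.15 for TUs); and the 5′→3′ gradient of a TU is
Δ = log2FC(first gene) − log2FC(last gene). TPM normalization and the
qPCR ΔΔCt quantity (−ΔΔCt = log2 fold change) are included.

**Enrichment profiles.** Any two classifications are cross-tabulated
and each cell is tested with cumulative hypergeometric tests
(P(X ≥ x) for enrichment, P(X ≤ x) for deprivation); numeric values
are profiled per cluster with two-sided Welch t-tests against the
complement. An iterative column-wise sorting procedure arranges rows
for display, and a style-sheet contract (intensity ∝ log2 p, hue by
t-sign) is emitted as TSV for any plotting layer.

**Promoter structure.** Motif occurrence vectors (G+C, AT2 = {AA, AT,
TT}, the TpA step, A-tracts of length 4 = {AAAA, AAAT, AATT, ATTT,
TTTT}) are aligned at the TSS (position 0 = first transcribed base),
summarized as windowed frequency profiles (5 or 66 bp windows) with
per-position hypergeometric tests of each cluster vs all TUs, and
probed for helical phasing by the autocorrelation of concatenated
upstream indicators. Promoter sets are compared by per-position
Jensen–Shannon divergence between their PWMs with a label-permutation
test, and the discriminator region (−6..−3) is summarized by its G+C
content and the conserved T at −7.

## Worked example

```python
from coilscape import simulate, fourier, promoter

# six-cohort induction time series (900 genes, 15 time points)
matrix, cohorts = simulate.simulate_timeseries(
    simulate.default_induction_scenario(seed=1))
features = fourier.build_features(matrix)
result = fourier.select_k(features, range(2, 11), n_restarts=5, seed=1)
print(f"chosen K = {result.chosen_k}")

# promoters with helically phased A-tracts anchored at -10
sc = simulate.PromoterScenario(n_tu=300, seed=7)
genome, tus = simulate.simulate_genome(sc)
genome, planted = simulate.plant_promoter_motifs(genome, tus, sc)
aligned = promoter.align_at_tss(genome, tus, promoter.ATRACT4,
                                sc.upstream, sc.downstream)
planted_ids = [t for t, l in planted.labels.items() if l == "planted"]
freq = promoter.windowed_frequency(aligned, planted_ids, w=5)
print(f"A-tract(4) profile peak at {freq.idxmax()} bp "
      f"({freq.max():.1f}% in 5 bp windows)")
_, period = promoter.acf_periodicity(genome, tus, promoter.AT2,
                                     region=(-100, -1))
print(f"dominant AT2 period = {period:.2f} bp")
```

prints

```
chosen K = 6
A-tract(4) profile peak at -10 bp (35.6% in 5 bp windows)
dominant AT2 period = 10.72 bp
```

The mixture model recovers the six planted response cohorts; the
A-tract frequency profile peaks exactly at the planted −10 anchor; and
the autocorrelation period recovers the planted helical pitch of
10.5 bp within half a base.

A full end-to-end run (simulate → cluster → tu → enrich → promoter)
is available from the command line:

```
coilscape all --seed 42 --outdir run/
```

which writes TSV/FASTA/JSON artifacts under `run/inputs/`,
`run/clustering/`, `run/tu/`, `run/enrichment/`, `run/promoter/` and a
provenance log under `run/logs/`. Individual stages are exposed as the
subcommands `simulate`, `cluster`, `tu`, `enrich` and `promoter`.

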