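"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three analysis axes:

* :func:`simulate_timeseries` — cohort-structured induction time series
  (multiplicative lognormal noise on TPM) with a known cohort truth.
* :func:`simulate_genome` / :func:`plant_promoter_motifs` — an i.i.d.
  background genome with TSS-annotated TUs carrying helically phased
  A-tract motifs upstream of the TSS.
* :func:`simulate_foldchanges` — strain fold-change tables with planted
  5'->3' gradients along multi-gene TUs.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    Classification,
    ExpressionMatrix,
    FoldChangeTable,
    Genome,
    SampleSeries,
    TranscriptionUnit,
    reverse_complement,
)
import pandas as pd

ATRACT4_SET = ("AAAA", "AAAT", "AATT", "ATTT", "TTTT")


# ---------------------------------------------------------------------------
# time series


def _damped_cos(t, amplitude=1.5, period=24.0, damping=60.0, phase=0.0):
    return amplitude * np.exp(-t / damping) * np.cos(2 * np.pi * (t - phase) / period)


def _down_step(t, depth=2.0, tau=2.0):
    return -depth * (1.0 - np.exp(-t / tau))


def _late_ramp(t, amplitude=2.0, onset=24.0, rise=48.0):
    return amplitude * np.clip((t - onset) / rise, 0.0, 1.0)


def _late_overshoot(t, amplitude=3.0, onset=24.0, tau=14.0):
    s = np.clip(t - onset, 0.0, None) / tau
    return amplitude * s * np.exp(1.0 - s)


def waveform_templates() -> dict[str, Callable]:
    """Closed-form log2 response templates, all 0 for t < 0."""

    def gate(f):
        return lambda t, **kw: np.where(np.asarray(t, float) < 0, 0.0, f(np.asarray(t, float), **kw))

    return {
        # dawn-like damped 24 h oscillation, peaks right after induction
        "dawn_damped_cos": gate(_damped_cos),
        # sustained shut-down
        "down_step": gate(_down_step),
        # initial dip, antiphase oscillation
        "dusk_inverted_cos": gate(lambda t, **kw: -_damped_cos(t, **kw)),
        # weak residual oscillation
        "near_flat": gate(lambda t, **kw: _damped_cos(t, amplitude=kw.get("amplitude", 0.3), phase=kw.get("phase", 6.0))),
        # delayed adaptive ramp-up
        "late_ramp": gate(_late_ramp),
        # delayed ramp with plasmid-like overshoot
        "late_overshoot": gate(_late_overshoot),
    }


@dataclass(frozen=True)
class CohortSpec:
    name: str
    waveform: Callable
    n_genes: int
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("each cohort needs at least one gene")


@dataclass(frozen=True)
class TimeSeriesScenario:
    cohorts: tuple[CohortSpec, ...]
    times_h: tuple[float, ...]
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        t = self.times_h
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if sum(x < 0 for x in t) < 2:
            raise ValueError("scenario needs at least two pre-induction times")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Sampling grid of the default induction experiment: two pre-induction
#: samples (-24 h and -35 min), two immediate post-induction samples
#: (5 and 20 min) and a follow-up out to 72 h; 15 samples total.
DEFAULT_TIMES = (-24.0, -0.58, 0.083, 0.33, 1.0, 2.0, 4.0, 8.0, 12.0,
                 16.0, 24.0, 32.0, 48.0, 60.0, 72.0)


def default_induction_scenario(
    n_genes_per_cohort: int = 150, noise_sd: float = 0.2, seed: int = 0
) -> TimeSeriesScenario:
    """Six-cohort induction scenario mirroring the observed response groups.

    The six waveforms model: (1) an immediately upregulated dawn-like
    oscillating group, (2) a sustained down-step, (3) an antiphase
    oscillation with an initial dip, (4) a weakly responding group,
    (5) a delayed ramp-up and (6) a delayed ramp with overshoot.
    """
    wf = waveform_templates()
    cohorts = tuple(
        CohortSpec(name=f"cohort{i + 1}", waveform=wf[key], n_genes=n_genes_per_cohort)
        for i, key in enumerate(
            ["dawn_damped_cos", "down_step", "dusk_inverted_cos",
             "near_flat", "late_ramp", "late_overshoot"]
        )
    )
    return TimeSeriesScenario(cohorts=cohorts, times_h=DEFAULT_TIMES,
                              noise_sd=noise_sd, seed=seed)


def simulate_timeseries(scenario: TimeSeriesScenario) -> tuple[ExpressionMatrix, Classification]:
    """Draw TPM(t) = baseline * 2**w(t) * exp(eps), eps ~ N(0, noise_sd^2)."""
    rng = np.random.default_rng(scenario.seed)
    t = np.asarray(scenario.times_h, float)
    gene_ids, rows, truth = [], [], {}
    for cohort in scenario.cohorts:
        w = np.asarray(cohort.waveform(t), float)
        baselines = rng.lognormal(cohort.baseline_log_mean, cohort.baseline_log_sd,
                                  size=cohort.n_genes)
        eps = rng.normal(0.0, scenario.noise_sd, size=(cohort.n_genes, len(t)))
        block = baselines[:, None] * np.exp2(w)[None, :] * np.exp(eps)
        for i in range(cohort.n_genes):
            gid = f"{cohort.name}_g{i + 1:04d}"
            gene_ids.append(gid)
            truth[gid] = cohort.name
        rows.append(block)
    samples = SampleSeries(
        tuple(f"s{i + 1:02d}" for i in range(len(t))), tuple(scenario.times_h)
    )
    matrix = ExpressionMatrix(gene_ids, samples, np.vstack(rows), unit="TPM")
    return matrix, Classification(truth)


# ---------------------------------------------------------------------------
# genome / promoters


@dataclass(frozen=True)
class PromoterScenario:
    """Promoter grammar: phased A-tracts anchored just upstream of the TSS.

    ``anchor`` is the sense-strand relative position of the most
    downstream planted tract (default -10, the core promoter element);
    further tracts are planted every ``pitch`` bp upstream (default
    10.5, the DNA helical pitch), with the j-th repeat present with
    probability ``upstream_attenuation**j`` so the anchor carries the
    maximal peak and upstream phasing decays, as real promoter sets do.
    """

    n_tu: int = 300
    upstream: int = 100
    downstream: int = 50
    gc: float = 0.48
    anchor: int = -10
    pitch: float = 10.5
    n_repeats: int = 3
    plant_prob: float = 0.8
    upstream_attenuation: float = 0.75
    spacer: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.plant_prob <= 1:
            raise ValueError("plant_prob must be in [0, 1]")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not (-self.upstream <= self.anchor < self.downstream):
            raise ValueError("anchor must lie inside the window")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def simulate_genome(
    pscenario: PromoterScenario, genes_per_tu: int = 1
) -> tuple[Genome, list[TranscriptionUnit]]:
    """I.i.d. background genome with TUs tiled on alternating strands."""
    rng = np.random.default_rng(pscenario.seed)
    slot = pscenario.upstream + pscenario.downstream + pscenario.spacer
    n = pscenario.n_tu * slot + slot
    p = np.array([(1 - pscenario.gc) / 2, pscenario.gc / 2,
                  pscenario.gc / 2, (1 - pscenario.gc) / 2])
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    tus = []
    for i in range(pscenario.n_tu):
        s = i * slot + pscenario.spacer // 2
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            # window [tss-U, tss+D) == [s, s+U+D)
            tss = s + pscenario.upstream
        else:
            # window [tss-D+1, tss+U+1) == [s, s+U+D)
            tss = s + pscenario.downstream - 1
        tus.append(
            TranscriptionUnit(
                tu_id=f"TU{i + 1:04d}",
                replicon="chr",
                replicon_class="chromosome",
                strand=strand,
                tss=tss,
                genes=tuple(f"TU{i + 1:04d}_g{k + 1}" for k in range(genes_per_tu)),
            )
        )
    return Genome({"chr": seq}), tus


def planting_offsets(pscenario: PromoterScenario) -> list[int]:
    """Sense-strand start positions of the planted tracts (rounded half away from zero)."""
    return [
        _round_half_away(pscenario.anchor - j * pscenario.pitch)
        for j in range(pscenario.n_repeats)
    ]


def plant_promoter_motifs(
    genome: Genome, tus: Sequence[TranscriptionUnit], pscenario: PromoterScenario
) -> tuple[Genome, Classification]:
    """Write phased A-tract(4) tetramers into selected promoters.

    Returns the edited genome and a truth classification of each TU as
    ``planted`` or ``background``. Minus-strand promoters are edited via
    the reverse complement at the corresponding genomic coordinates.
    """
    rng = np.random.default_rng(pscenario.seed + 1)
    offsets = planting_offsets(pscenario)
    k = 4
    for off in offsets:
        if off < -pscenario.upstream or off + k > pscenario.downstream:
            raise ValueError(
                f"planting position {off} outside window "
                f"[-{pscenario.upstream}, {pscenario.downstream})"
            )
    chars = {name: list(seq) for name, seq in genome.items()}
    truth = {}
    for tu in tus:
        carry = rng.random() < pscenario.plant_prob
        truth[tu.tu_id] = "planted" if carry else "background"
        if not carry:
            continue
        for j, off in enumerate(offsets):
            if j > 0 and rng.random() >= pscenario.upstream_attenuation**j:
                continue
            motif = ATRACT4_SET[rng.integers(len(ATRACT4_SET))]
            if tu.strand == "+":
                start = tu.tss + off
                chars[tu.replicon][start : start + k] = list(motif)
            else:
                # sense relative positions off..off+3 map to genomic
                # tss-off-3..tss-off; write the reverse complement
                start = tu.tss - off - (k - 1)
                chars[tu.replicon][start : start + k] = list(reverse_complement(motif))
    return Genome({n: "".join(c) for n, c in chars.items()}), Classification(truth)


def annotate_tus_with_genes(
    tus: Sequence[TranscriptionUnit], gene_ids: Sequence[str]
) -> list[TranscriptionUnit]:
    """Re-annotate simulated TUs with consecutive genes from another source.

    The time-series and genome generators are independent; this links
    them by assigning expression genes to TUs in order (TU sizes
    preserved). TUs left without genes are dropped.
    """
    out = []
    i = 0
    for tu in tus:
        if i >= len(gene_ids):
            break
        members = tuple(gene_ids[i : i + len(tu.genes)])
        i += len(members)
        out.append(
            TranscriptionUnit(tu.tu_id, tu.replicon, tu.replicon_class, tu.strand,
                              tu.tss, members)
        )
    return out


# ---------------------------------------------------------------------------
# fold-change gradients


@dataclass(frozen=True)
class GradientScenario:
    """Linear 5'->3' log2 fold-change gradients within multi-gene TUs."""

    delta: float = 1.5  # log2fc(first gene) - log2fc(last gene)
    noise_sd: float = 0.1
    fc_first_sd: float = 1.0
    contrast: str = "strain_vs_control"
    seed: int = 0

    def __post_init__(self):
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.noise_sd < 0 or self.fc_first_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def simulate_foldchanges(
    tus: Sequence[TranscriptionUnit], gscenario: GradientScenario
) -> FoldChangeTable:
    """Gene k of m in a TU gets log2fc = fc_first - delta*(k-1)/(m-1) + noise."""
    rng = np.random.default_rng(gscenario.seed)
    genes, values = [], []
    for tu in tus:
        m = len(tu.genes)
        fc_first = rng.normal(0.0, gscenario.fc_first_sd)
        for k, gid in enumerate(tu.genes):
            frac = 0.0 if m == 1 else k / (m - 1)
            noise = rng.normal(0.0, gscenario.noise_sd) if gscenario.noise_sd else 0.0
            genes.append(gid)
            values.append(fc_first - gscenario.delta * frac + noise)
    df = pd.DataFrame({gscenario.contrast: values}, index=genes)
    return FoldChangeTable([gscenario.contrast], df)
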