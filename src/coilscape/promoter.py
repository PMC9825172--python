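"""TSS-anchored promoter structural analysis.

The genome is scanned into binary motif occurrence vectors (GC base,
AT2 dinucleotides {AA, AT, TT}, the TpA step, A-tracts of length four),
aligned at transcription start sites into an occurrence matrix, and
summarized as windowed positional frequency profiles with per-position
hypergeometric enrichment/deprivation tests of a cluster against all
TUs. Helical phasing is quantified by the autocorrelation of
concatenated upstream indicators, and promoter sets are compared by
per-position Jensen-Shannon divergence between their position weight
matrices with a label-permutation significance test. Only TUs on the
main chromosome enter these analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, TranscriptionUnit, WindowOutOfBounds, tss_window

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class MotifDef:
    name: str
    k: int
    matcher: Callable[[str], bool]

    def matches(self, kmer: str) -> bool:
        if "N" in kmer:
            return False
        return self.matcher(kmer)


AT2_SET = frozenset({"AA", "AT", "TT"})
ATRACT4_SET = frozenset({"AAAA", "AAAT", "AATT", "ATTT", "TTTT"})

GC = MotifDef("GC", 1, lambda s: s in "GC")
AT2 = MotifDef("AT2", 2, lambda s: s in AT2_SET)
TPA = MotifDef("TpA", 2, lambda s: s == "TA")
ATRACT4 = MotifDef("ATRACT4", 4, lambda s: s in ATRACT4_SET)

MOTIFS = {m.name: m for m in (GC, AT2, TPA, ATRACT4)}


def motif_indicator(sequence: str, motif: MotifDef) -> np.ndarray:
    """Binary vector: 1 where a motif occurrence starts (all overlaps counted)."""
    n = len(sequence) - motif.k + 1
    if n < 1:
        return np.zeros(0, dtype=np.int8)
    return np.fromiter(
        (motif.matches(sequence[i : i + motif.k]) for i in range(n)),
        dtype=np.int8,
        count=n,
    )


@dataclass
class AlignedOccurrence:
    """TU x TSS-relative-position indicator matrix for one motif.

    Column ``positions[j]`` is the relative position of the first base
    of a k-mer; position 0 is the TSS.
    """

    motif: MotifDef
    tu_ids: list[str]
    positions: np.ndarray  # relative positions, length U+D-k+1
    matrix: np.ndarray  # binary, len(tu_ids) x len(positions)
    n_excluded: int  # TUs dropped: off-chromosome or window out of bounds

    def subset(self, tu_ids: Sequence[str]) -> np.ndarray:
        wanted = set(tu_ids)
        mask = np.array([t in wanted for t in self.tu_ids])
        if not mask.any():
            raise ValueError("none of the requested TUs are in the alignment")
        return self.matrix[mask]


def align_at_tss(
    genome: Genome,
    tus: Sequence[TranscriptionUnit],
    motif: MotifDef,
    upstream: int,
    downstream: int,
) -> AlignedOccurrence:
    """Align motif indicators of chromosome TUs at their TSS.

    TUs on plasmids, and TUs whose window overruns the replicon, are
    excluded and counted (never truncated or padded).
    """
    rows, ids = [], []
    n_excluded = 0
    for tu in tus:
        if tu.replicon_class != "chromosome":
            n_excluded += 1
            continue
        try:
            seq = tss_window(genome, tu, upstream, downstream)
        except WindowOutOfBounds:
            n_excluded += 1
            continue
        rows.append(motif_indicator(seq, motif))
        ids.append(tu.tu_id)
    if not rows:
        raise ValueError("no usable chromosome TUs for TSS alignment")
    if n_excluded:
        logger.info("align_at_tss: excluded %d TUs", n_excluded)
    positions = np.arange(-upstream, downstream - motif.k + 1)
    return AlignedOccurrence(motif, ids, positions, np.vstack(rows), n_excluded)


def _window_bounds(w: int):
    # window [p - ceil(w/2) + 1, p + floor(w/2)] inclusive; 66 -> -32..+33
    return -(math.ceil(w / 2) - 1), math.floor(w / 2)


def windowed_frequency(
    aligned: AlignedOccurrence, tu_ids: Sequence[str] | None = None, w: int = 5
) -> pd.Series:
    """Mean motif occurrence (%) in a w-bp window around each position.

    freq(p) = 100 * (occurrences in window across TUs) / (slots), where
    the window is truncated at the profile edges (slots = effective
    window size * number of TUs).
    """
    sub = aligned.matrix if tu_ids is None else aligned.subset(tu_ids)
    lo, hi = _window_bounds(w)
    npos = len(aligned.positions)
    colsum = sub.sum(axis=0)
    out = np.empty(npos)
    n = sub.shape[0]
    for j in range(npos):
        a, b = max(0, j + lo), min(npos, j + hi + 1)
        out[j] = 100.0 * colsum[a:b].sum() / ((b - a) * n)
    return pd.Series(out, index=aligned.positions, name=f"freq_{aligned.motif.name}")


def positional_tests(
    aligned: AlignedOccurrence, tu_ids: Sequence[str], w: int = 5
) -> pd.DataFrame:
    """Windowed hypergeometric enrichment/deprivation of a cluster vs all TUs.

    Per position: universe = all-TU slots in the window, successes =
    all-TU occurrences there, draws = cluster slots, observed = cluster
    occurrences. Glyph sizes are -log2(p) for the smaller tail, with the
    significance glyph shown every 3rd (w=5) or 10th (w=66) position to
    avoid overplotting.
    """
    sub = aligned.subset(tu_ids)
    allm = aligned.matrix
    lo, hi = _window_bounds(w)
    npos = len(aligned.positions)
    n_all, n_cl = allm.shape[0], sub.shape[0]
    all_colsum, cl_colsum = allm.sum(axis=0), sub.sum(axis=0)
    stride = 3 if w <= 5 else 10
    rows = []
    for j in range(npos):
        a, b = max(0, j + lo), min(npos, j + hi + 1)
        w_eff = b - a
        universe = n_all * w_eff
        k_succ = int(all_colsum[a:b].sum())
        draws = n_cl * w_eff
        x = int(cl_colsum[a:b].sum())
        p_en = float(stats.hypergeom.sf(x - 1, universe, k_succ, draws))
        p_de = float(stats.hypergeom.cdf(x, universe, k_succ, draws))
        rows.append(
            {
                "position": int(aligned.positions[j]),
                "p_enrich": min(p_en, 1.0),
                "p_deplete": min(p_de, 1.0),
                "direction": "enriched" if p_en <= p_de else "deprived",
                "glyph_size": -np.log2(max(min(p_en, p_de), 1e-300)),
                "show_glyph": (j % stride) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("position")


def positional_profile(
    aligned: AlignedOccurrence, tu_ids: Sequence[str], w: int = 5
) -> pd.DataFrame:
    """Frequency profile and per-position tests for one cluster, combined."""
    freq = windowed_frequency(aligned, tu_ids, w=w)
    tests = positional_tests(aligned, tu_ids, w=w)
    out = tests.copy()
    out.insert(0, "frequency_pct", freq.values)
    return out


def acf_periodicity(
    genome: Genome,
    tus: Sequence[TranscriptionUnit],
    motif: MotifDef = AT2,
    region: tuple[int, int] = (-200, -1),
    max_lag: int = 30,
    period_lags: tuple[int, int] = (6, 15),
) -> tuple[np.ndarray, float]:
    """Autocorrelation of concatenated promoter motif indicators.

    Sense-strand sequences over ``region`` (inclusive TSS-relative
    bounds) are extracted per TU and their indicator vectors
    concatenated; products straddling a promoter boundary are masked
    out. Returns (r[0..max_lag], dominant period), where the dominant
    period is the argmax of r over ``period_lags`` refined by parabolic
    interpolation of the three surrounding lags.
    """
    start, end = region
    if start > end:
        raise ValueError("invalid region: start > end")
    upstream, downstream = -start, end + 1
    if upstream < 0 or downstream < 0:
        raise ValueError("region must start upstream (start <= end <= ... <= 0 allowed)")
    vectors = []
    for tu in tus:
        if tu.replicon_class != "chromosome":
            continue
        try:
            seq = tss_window(genome, tu, upstream, downstream)
        except WindowOutOfBounds:
            continue
        vectors.append(motif_indicator(seq, motif).astype(float))
    if not vectors:
        raise ValueError("no usable TUs in region")
    concat = np.concatenate(vectors)
    if concat.sum() == 0:
        raise ValueError("no occurrences of the motif in the region")
    mu, var = concat.mean(), concat.var()
    n_total = len(concat)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for lag in range(1, max_lag + 1):
        num, cnt = 0.0, 0
        for v in vectors:
            if len(v) > lag:
                num += ((v[:-lag] - mu) * (v[lag:] - mu)).sum()
                cnt += len(v) - lag
        acf[lag] = num / (cnt * var) if cnt else np.nan
    lo, hi = period_lags
    if hi + 1 > max_lag:
        raise ValueError("max_lag too small for the period search range")
    seg = acf[lo : hi + 1]
    ell = lo + int(np.nanargmax(seg))
    y0, y1, y2 = acf[ell - 1], acf[ell], acf[ell + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return acf, float(ell + offset)


@dataclass
class PWM:
    """Position weight matrix with pseudocounts; columns sum to 1."""

    probs: pd.DataFrame  # positions x ACGT
    n_sequences: int


def build_pwm(sequences: Sequence[str], positions=None, pseudocount: float = 0.5) -> PWM:
    """prob(base, pos) = (count + pseudocount) / (n + 4*pseudocount)."""
    if not sequences:
        raise ValueError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((L, 4))
    for seq in sequences:
        for i, b in enumerate(seq):
            j = BASES.find(b)
            if j >= 0:
                counts[i, j] += 1
    n_valid = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (n_valid + 4 * pseudocount)
    index = positions if positions is not None else np.arange(L)
    return PWM(pd.DataFrame(probs, index=index, columns=list(BASES)), len(sequences))


def js_divergence(pwm1: PWM, pwm2: PWM) -> pd.Series:
    """Per-position Jensen-Shannon divergence in bits, in [0, 1].

    JSD(P, Q) = 0.5*KL(P||M) + 0.5*KL(Q||M) with M = (P+Q)/2, log base 2.
    """
    if pwm1.probs.shape != pwm2.probs.shape:
        raise ValueError("PWMs must cover the same positions")
    p = pwm1.probs.values
    q = pwm2.probs.values
    m = 0.5 * (p + q)

    def kl(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(a > 0, a * np.log2(np.where(a > 0, a / b, 1.0)), 0.0)
        return terms.sum(axis=1)

    jsd = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return pd.Series(jsd, index=pwm1.probs.index, name="jsd_bits")


def jsd_permutation_test(
    seqs1: Sequence[str],
    seqs2: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    positions=None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Label-permutation significance of the per-position JSD.

    The pooled sequences are reassigned to the two groups (preserving
    sizes) B times; p = (1 + #{JSD_perm >= JSD_obs}) / (B + 1) per
    position.
    """
    n1 = len(seqs1)
    pool = list(seqs1) + list(seqs2)
    obs = js_divergence(
        build_pwm(seqs1, positions, pseudocount), build_pwm(seqs2, positions, pseudocount)
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs))
    pool_arr = np.array(pool, dtype=object)
    for _ in range(B):
        perm = rng.permutation(len(pool_arr))
        g1 = list(pool_arr[perm[:n1]])
        g2 = list(pool_arr[perm[n1:]])
        jsd = js_divergence(
            build_pwm(g1, positions, pseudocount), build_pwm(g2, positions, pseudocount)
        )
        exceed += jsd.values >= obs.values
    p = (1.0 + exceed) / (B + 1.0)
    return pd.DataFrame({"jsd_bits": obs.values, "p": p}, index=obs.index)


DISCRIMINATOR_RANGE = (-6, -3)  # GC content here modulates supercoiling response
CONSERVED_T_POS = -7


@dataclass
class DiscriminatorStats:
    n_tus: int
    gc_fraction: float  # mean G+C over positions -6..-3
    gc_count: int  # G/C bases observed in the discriminator slots
    n_slots: int  # 4 * n_tus
    t_at_minus7_fraction: float
    t_at_minus7_count: int


def discriminator_stats(
    genome: Genome, tus: Sequence[TranscriptionUnit]
) -> DiscriminatorStats:
    """G+C content of the discriminator (-6..-3) and the conserved T at -7."""
    lo, hi = DISCRIMINATOR_RANGE
    upstream = -min(lo, CONSERVED_T_POS)
    gc_count = t_count = n = 0
    for tu in tus:
        if tu.replicon_class != "chromosome":
            continue
        try:
            seq = tss_window(genome, tu, upstream, 0)
        except WindowOutOfBounds:
            continue
        n += 1
        disc = seq[lo + upstream : hi + upstream + 1]
        gc_count += sum(b in "GC" for b in disc)
        if seq[CONSERVED_T_POS + upstream] == "T":
            t_count += 1
    if n == 0:
        raise ValueError("no usable TUs for discriminator statistics")
    width = hi - lo + 1
    return DiscriminatorStats(
        n_tus=n,
        gc_fraction=gc_count / (width * n),
        gc_count=gc_count,
        n_slots=width * n,
        t_at_minus7_fraction=t_count / n,
        t_at_minus7_count=t_count,
    )


def discriminator_enrichment(
    cluster: DiscriminatorStats, all_tus: DiscriminatorStats
) -> tuple[float, float]:
    """Hypergeometric enrichment/deprivation of discriminator G+C in a cluster."""
    from .enrichment import hypergeom_tests

    return hypergeom_tests(
        cluster.gc_count, cluster.n_slots, all_tus.gc_count, all_tus.n_slots
    )
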