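"""TSS-anchored motif profiles, periodicity, PWM divergence, discriminator."""

import numpy as np
import pandas as pd
import pytest

from coilscape.core import Genome, TranscriptionUnit
from coilscape.promoter import (
    AT2,
    ATRACT4,
    GC,
    TPA,
    AlignedOccurrence,
    MotifDef,
    acf_periodicity,
    align_at_tss,
    build_pwm,
    discriminator_enrichment,
    discriminator_stats,
    js_divergence,
    jsd_permutation_test,
    motif_indicator,
    positional_tests,
    windowed_frequency,
)
from coilscape.simulate import (
    PromoterScenario,
    plant_promoter_motifs,
    simulate_genome,
)


class TestMotifIndicator:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("AATT", ATRACT4, [1]),
            ("ATAT", ATRACT4, [0]),  # contains the TpA step
            ("GATAC", TPA, [0, 0, 1, 0]),  # TA starts at 0-based position 2
            ("GCAT", GC, [1, 1, 0, 0]),
            ("AATA", AT2, [1, 1, 0]),
            ("ANAT", AT2, [0, 0, 1]),  # N never matches
        ],
    )
    def test_definitions(self, seq, motif, expected):
        np.testing.assert_array_equal(motif_indicator(seq, motif), expected)

    def test_atract4_set_is_the_five_tpa_free_words(self):
        words = ["".join(w) for w in __import__("itertools").product("AT", repeat=4)]
        hits = [w for w in words if motif_indicator(w, ATRACT4)[0]]
        assert hits == ["AAAA", "AAAT", "AATT", "ATTT", "TTTT"]

    def test_short_sequence_empty(self):
        assert len(motif_indicator("AC", ATRACT4)) == 0


def _tu(i, strand="+", tss=20, cls="chromosome"):
    return TranscriptionUnit(f"TU{i}", "chr", cls, strand, tss, (f"g{i}",))


class TestAlignAtTss:
    def test_planted_site_lands_at_its_relative_position(self):
        sc = PromoterScenario(n_tu=20, plant_prob=1.0, n_repeats=1, seed=0)
        g, tus = simulate_genome(sc)
        g2, _ = plant_promoter_motifs(g, tus, sc)
        aligned = align_at_tss(g2, tus, ATRACT4, sc.upstream, sc.downstream)
        col = list(aligned.positions).index(sc.anchor)
        assert (aligned.matrix[:, col] == 1).all()

    def test_minus_strand_same_sense_sequence_identical_row(self):
        # build a genome where a + and a - TU expose the same sense window
        sense = "GGAAAATTGGCCAAGG"
        from coilscape.core import reverse_complement

        seq = "C" * 10 + sense + "C" * 10 + reverse_complement(sense) + "C" * 10
        g = Genome({"chr": seq})
        plus = TranscriptionUnit("P", "chr", "chromosome", "+", 18, ("a",))
        # sense window of the minus TU must read the same: tss at the
        # mirrored position inside the revcomp block
        minus = TranscriptionUnit("M", "chr", "chromosome", "-", 43, ("b",))
        aligned = align_at_tss(g, [plus, minus], ATRACT4, 8, 8)
        np.testing.assert_array_equal(aligned.matrix[0], aligned.matrix[1])
        assert aligned.matrix[0].sum() > 0

    def test_plasmid_tus_excluded(self):
        g = Genome({"chr": "A" * 100})
        tus = [_tu(1), _tu(2, cls="plasmid")]
        aligned = align_at_tss(g, tus, AT2, 5, 5)
        assert aligned.tu_ids == ["TU1"]
        assert aligned.n_excluded == 1

    def test_out_of_bounds_excluded_not_truncated(self):
        g = Genome({"chr": "A" * 100})
        aligned = align_at_tss(g, [_tu(1, tss=2), _tu(2, tss=50)], AT2, 5, 5)
        assert aligned.tu_ids == ["TU2"]

    def test_empty_tu_set_rejected(self):
        g = Genome({"chr": "A" * 100})
        with pytest.raises(ValueError):
            align_at_tss(g, [_tu(1, cls="plasmid")], AT2, 5, 5)


def _aligned(matrix, k=1, upstream=None):
    matrix = np.asarray(matrix)
    n = matrix.shape[1]
    upstream = n // 2 if upstream is None else upstream
    return AlignedOccurrence(
        MotifDef("unit", k, lambda s: True),
        [f"TU{i}" for i in range(matrix.shape[0])],
        np.arange(-upstream, n - upstream),
        matrix,
        0,
    )


class TestWindowedFrequency:
    def test_all_ones_everywhere_100(self):
        freq = windowed_frequency(_aligned(np.ones((4, 11), dtype=int)), w=5)
        np.testing.assert_allclose(freq.values, 100.0)

    def test_single_occurrence_smeared_over_window(self):
        m = np.zeros((2, 11), dtype=int)
        m[0, 5] = 1
        freq = windowed_frequency(_aligned(m), w=5)
        center = freq.loc[-2:2]
        np.testing.assert_allclose(center.values, 100 / (5 * 2))
        assert freq.loc[3] == 0.0

    def test_w1_is_raw_column_mean(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(7, 9))
        freq = windowed_frequency(_aligned(m), w=1)
        np.testing.assert_allclose(freq.values, 100 * m.mean(axis=0))

    def test_even_window_is_centered_asymmetrically(self):
        # w=66 covers [-32, +33]: an occurrence 33 right of p still counts
        m = np.zeros((1, 80), dtype=int)
        m[0, 73] = 1
        freq = windowed_frequency(_aligned(m, upstream=40), w=66)
        assert freq.loc[0] > 0  # position 0 + 33 = 33 = column 73
        assert freq.loc[-1] == 0.0


class TestPositionalTests:
    def test_whole_set_as_cluster_has_no_signal(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(10, 21))
        aligned = _aligned(m)
        out = positional_tests(aligned, aligned.tu_ids, w=5)
        assert (out["p_enrich"] + out["p_deplete"] >= 1.0).all()
        assert (out["p_enrich"] > 0.3).all()

    def test_planted_cluster_most_enriched_at_plant_position(self):
        m = np.zeros((40, 21), dtype=int)
        m[:10, 4] = 1  # cluster TUs carry the motif at relative position -6
        aligned = _aligned(m)
        out = positional_tests(aligned, aligned.tu_ids[:10], w=5)
        # every window containing the planted column attains the minimum
        assert out.loc[-6, "p_enrich"] == out["p_enrich"].min()
        assert out.loc[-6, "p_enrich"] < 1e-6
        assert out.loc[5, "p_enrich"] > 0.5

    def test_glyph_thinning_strides(self):
        m = np.ones((4, 30), dtype=int)
        out5 = positional_tests(_aligned(m), [f"TU{i}" for i in range(2)], w=5)
        assert out5["show_glyph"].sum() == len(out5[::3])
        out66 = positional_tests(_aligned(m), [f"TU{i}" for i in range(2)], w=66)
        assert out66["show_glyph"].sum() == len(out66[::10])


class TestAcfPeriodicity:
    def test_strict_period_10_recovered_exactly(self):
        seq = ("TAGGCCGGCC" * 30)  # TA every 10 bp
        g = Genome({"chr": seq + "G" * 10})
        tus = [TranscriptionUnit("T1", "chr", "chromosome", "+", 290, ("g1",))]
        _, period = acf_periodicity(g, tus, TPA, region=(-280, -1), max_lag=30)
        assert np.isclose(period, 10.0, atol=0.05)

    @pytest.mark.parametrize("pitch", [10.0, 10.5, 11.0])
    def test_planted_pitch_recovered(self, pitch):
        sc = PromoterScenario(n_tu=200, upstream=150, downstream=0, pitch=pitch,
                              n_repeats=8, plant_prob=0.9, seed=3)
        g, tus = simulate_genome(sc)
        g2, _ = plant_promoter_motifs(g, tus, sc)
        _, period = acf_periodicity(g2, tus, AT2, region=(-150, -1), max_lag=30)
        assert abs(period - pitch) <= 0.5

    def test_no_occurrences_rejected(self):
        g = Genome({"chr": "G" * 400})
        tus = [TranscriptionUnit("T1", "chr", "chromosome", "+", 300, ("g1",))]
        with pytest.raises(ValueError, match="no occurrences"):
            acf_periodicity(g, tus, AT2, region=(-200, -1))

    def test_boundary_masking_blocks_cross_promoter_products(self):
        """With per-promoter vectors shorter than the lag, the ACF is undefined
        (NaN) instead of borrowing products across promoters."""
        g = Genome({"chr": "ATATATAT" * 50})
        tus = [TranscriptionUnit(f"T{i}", "chr", "chromosome", "+", 100 + 8 * i, ("g",))
               for i in range(10)]
        acf, _ = acf_periodicity(g, [tus[0]], AT2, region=(-6, -1), max_lag=30,
                                 period_lags=(1, 2))
        assert np.isnan(acf[10])


class TestPwmAndJsd:
    def test_single_sequence_pseudocount(self):
        pwm = build_pwm(["A"])
        assert np.isclose(pwm.probs.at[0, "A"], 1.5 / 3)
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0)

    def test_large_sample_uniform(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(4000)]
        pwm = build_pwm(seqs)
        np.testing.assert_allclose(pwm.probs.values, 0.25, atol=0.03)

    def test_jsd_identity_and_symmetry(self):
        rng = np.random.default_rng(1)
        seqs1 = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
        seqs2 = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
        p1, p2 = build_pwm(seqs1), build_pwm(seqs2)
        np.testing.assert_allclose(js_divergence(p1, p1).values, 0.0, atol=1e-14)
        np.testing.assert_allclose(
            js_divergence(p1, p2).values, js_divergence(p2, p1).values
        )

    def test_disjoint_supports_give_one_bit(self):
        from coilscape.promoter import PWM

        p = PWM(pd.DataFrame([[1.0, 0, 0, 0]], columns=list("ACGT")), 1)
        q = PWM(pd.DataFrame([[0, 1.0, 0, 0]], columns=list("ACGT")), 1)
        assert np.isclose(js_divergence(p, q).iloc[0], 1.0)

    def test_matches_entropy_formula_oracle(self):
        """JSD(P,Q) = H(M) - (H(P) + H(Q))/2 with Shannon entropies in bits."""
        rng = np.random.default_rng(2)
        from coilscape.promoter import PWM

        a = rng.dirichlet(np.ones(4), size=8)
        b = rng.dirichlet(np.ones(4), size=8)
        p = PWM(pd.DataFrame(a, columns=list("ACGT")), 10)
        q = PWM(pd.DataFrame(b, columns=list("ACGT")), 10)

        def H(mat):
            return -(mat * np.log2(mat)).sum(axis=1)

        oracle = H((a + b) / 2) - (H(a) + H(b)) / 2
        np.testing.assert_allclose(js_divergence(p, q).values, oracle, atol=1e-12)


class TestJsdPermutation:
    def test_duplicated_groups_not_significant(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(15)]
        out = jsd_permutation_test(seqs, list(seqs), B=99, seed=0)
        assert (out["p"] > 0.5).all()

    def test_fixed_disjoint_letters_extreme_p(self):
        out = jsd_permutation_test(["A"] * 10, ["C"] * 10, B=199, seed=0)
        # only permutations recreating the exact split (or its mirror) tie
        assert out["p"].iloc[0] < 0.05


class TestDiscriminator:
    def test_all_t_promoters(self):
        g = Genome({"chr": "T" * 200})
        tus = [TranscriptionUnit(f"T{i}", "chr", "chromosome", "+", 100 + i, ("g",))
               for i in range(5)]
        stats = discriminator_stats(g, tus)
        assert stats.gc_fraction == 0.0
        assert stats.t_at_minus7_fraction == 1.0

    def test_uniform_background_matches_gc(self):
        sc = PromoterScenario(n_tu=400, gc=0.48, plant_prob=0.0, seed=4)
        g, tus = simulate_genome(sc)
        stats = discriminator_stats(g, tus)
        assert abs(stats.gc_fraction - 0.48) < 0.03

    def test_at_rich_cluster_depleted_in_gc(self):
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), 3000)))
        tus = []
        for i in range(30):
            tss = 50 + i * 90
            tus.append(TranscriptionUnit(f"T{i}", "chr", "chromosome", "+", tss, ("g",)))
            if i < 15:  # make the first half AT-rich in the discriminator
                for pos in range(tss - 6, tss - 2):
                    seq[pos] = "AT"[rng.integers(2)]
        g = Genome({"chr": "".join(seq)})
        up = discriminator_stats(g, tus[:15])
        allstats = discriminator_stats(g, tus)
        assert up.gc_fraction < allstats.gc_fraction
        p_en, p_de = discriminator_enrichment(up, allstats)
        assert p_de < 0.05
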