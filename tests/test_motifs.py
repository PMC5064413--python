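"""PWM loading, log-odds scanning, exact score distribution and enrichment."""

import numpy as np
import pytest
from scipy import stats

from circuitscan import motifs as mo


def _uniform_pwm(L=6):
    return mo.PWM("uniform", "", np.full((L, 4), 0.25), 0.0)


def _sharp_pwm(consensus="ACGTAC", eps=0.01):
    L = len(consensus)
    probs = np.full((L, 4), eps)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = 1 - 3 * eps
    return mo.PWM("sharp", "", probs, 0.0)


class TestLoadPwms:
    def test_uniform_counts(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m1\n" + "\n".join(["25 25 25 25"] * 8) + "\n")
        (pwm,) = mo.load_pwms(p, pseudocount=1.0)
        assert np.allclose(pwm.probs, 0.25)
        assert len(pwm) == 8

    def test_pseudocount_arithmetic(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m1\n" + "\n".join(["0 0 0 100"] * 4) + "\n")
        (pwm,) = mo.load_pwms(p, pseudocount=1.0)
        assert np.allclose(pwm.probs[0], [1 / 104, 1 / 104, 1 / 104, 101 / 104])

    def test_position_sums_and_mapping(self, tmp_path):
        p = tmp_path / "p.txt"
        rng = np.random.default_rng(0)
        lines = [">m1"] + [
            " ".join(str(int(x)) for x in rng.integers(0, 200, 4)) for _ in range(10)
        ]
        p.write_text("\n".join(lines) + "\n")
        m = tmp_path / "map.tsv"
        m.write_text("motif_id\ttf_symbol\nm1\tFOXA1\n")
        (pwm,) = mo.load_pwms(p, m, pseudocount=0.8)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-6)
        assert pwm.tf_symbol == "FOXA1"

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(">m1\n1 2 3 4\n1 2 3\n1 2 3 4\n1 2 3 4\n")
        with pytest.raises(ValueError, match="ragged|4-column"):
            mo.load_pwms(p)


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm, bg = _uniform_pwm(), mo.BackgroundModel.uniform()
        for seq in ("ACGTAC", "TTTTTT", "GGGGGG"):
            assert mo.log_odds_score(pwm, bg, seq) == pytest.approx(0.0)

    def test_sharp_position_closed_form(self):
        eps = 0.01
        probs = np.tile([1 - 3 * eps, eps, eps, eps], (4, 1))
        pwm = mo.PWM("m", "", probs, 0.0)
        bg = mo.BackgroundModel.uniform()
        expected = 4 * round(np.log2((1 - 3 * eps) / 0.25), 3)
        assert mo.log_odds_score(pwm, bg, "AAAA") == pytest.approx(expected, abs=1e-9)

    def test_matches_position_by_position_summation(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet([1.0] * 4, size=7)
        pwm = mo.PWM("m", "", probs, 0.0)
        bg = mo.BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]), "custom")
        seq = "ACGTTGA"
        lo = np.round(np.log2(pwm.probs / bg.freqs), 3)
        expected = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(seq))
        assert mo.log_odds_score(pwm, bg, seq) == pytest.approx(expected, abs=1e-9)

    def test_invalid_characters_rejected(self):
        pwm, bg = _uniform_pwm(), mo.BackgroundModel.uniform()
        with pytest.raises(mo.InvalidSequenceError):
            mo.log_odds_score(pwm, bg, "ACGNAC")
        with pytest.raises(mo.InvalidSequenceError):
            mo.log_odds_score(pwm, bg, "ACGT")  # wrong length

    def test_consensus_scores_maximum(self):
        rng = np.random.default_rng(2)
        pwm = mo.PWM("m", "", rng.dirichlet([0.5] * 4, size=5), 0.0)
        bg = mo.BackgroundModel.uniform()
        best = mo.log_odds_score(pwm, bg, pwm.consensus)
        from itertools import product

        for word in product("ACGT", repeat=5):
            assert mo.log_odds_score(pwm, bg, "".join(word)) <= best + 1e-9


class TestScoreDistribution:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_probability_one(self, seed):
        rng = np.random.default_rng(seed)
        pwm = mo.PWM("m", "", rng.dirichlet([0.7] * 4, size=9), 0.0)
        bg = mo.BackgroundModel(np.array([0.295, 0.205, 0.205, 0.295]), "genome")
        _, probs = mo.score_distribution(pwm, bg)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        pwm = mo.PWM("m", "", rng.dirichlet([1.0] * 4, size=5), 0.0)
        bg = mo.BackgroundModel.uniform()
        scores, probs = mo.score_distribution(pwm, bg)
        from itertools import product

        lo = mo.log_odds_matrix(pwm, bg)
        acc = {}
        for word in product(range(4), repeat=5):
            s = round(sum(lo[i, b] for i, b in enumerate(word)), 3)
            acc[s] = acc.get(s, 0.0) + 0.25**5
        for s, p in zip(scores, probs):
            assert p == pytest.approx(acc[round(float(s), 3)], abs=1e-12)

    def test_threshold_matches_empirical_quantile(self):
        rng = np.random.default_rng(4)
        pwm = mo.PWM("m", "", rng.dirichlet([2.0] * 4, size=8), 0.0)
        bg = mo.BackgroundModel.uniform()
        q = 0.99
        thr = mo.score_threshold(pwm, bg, q)
        lo = mo.log_odds_matrix(pwm, bg)
        draws = rng.integers(0, 4, size=(1_000_000, 8))
        samples = lo[np.arange(8)[None, :], draws].sum(axis=1)
        emp = np.quantile(samples, q)
        assert thr == pytest.approx(emp, abs=0.05)


class TestScan:
    def test_consensus_always_hits(self):
        pwm = _sharp_pwm("ACGTAC")
        bg = mo.BackgroundModel.uniform()
        thr = mo.score_threshold(pwm, bg, 0.99)
        assert mo.scan_sequence(pwm, bg, "TTTTACGTACTTTT", thr) >= 1

    def test_all_n_sequence_has_no_hits(self):
        pwm = _sharp_pwm()
        bg = mo.BackgroundModel.uniform()
        assert mo.scan_sequence(pwm, bg, "N" * 30, -100.0) == 0

    def test_short_region_is_zero_hits(self):
        pwm = _sharp_pwm("ACGTAC")
        bg = mo.BackgroundModel.uniform()
        assert mo.scan_sequence(pwm, bg, "ACG", 0.0) == 0

    def test_reverse_strand_detects_reverse_complement(self):
        pwm = _sharp_pwm("AACGTT"[:6])
        bg = mo.BackgroundModel.uniform()
        thr = mo.score_threshold(pwm, bg, 0.99)
        site = mo.reverse_complement(pwm.consensus)
        assert mo.scan_sequence(pwm, bg, "GG" + site + "GG", thr) >= 1

    def test_hit_counts_match_exhaustive_window_oracle(self):
        rng = np.random.default_rng(5)
        pwm = mo.PWM("m", "", rng.dirichlet([0.8] * 4, size=5), 0.0)
        bg = mo.BackgroundModel.uniform()
        thr = mo.score_threshold(pwm, bg, 0.95)
        seqs = [
            "".join(rng.choice(list("ACGT"), 30)) for _ in range(50)
        ]
        got = mo.scan_regions(pwm, bg, seqs, threshold_quantile=0.95)
        for seq, n_hits in zip(seqs, got):
            expected = 0
            for i in range(len(seq) - 4):
                w = seq[i : i + 5]
                if mo.log_odds_score(pwm, bg, w) >= thr - 5e-4:
                    expected += 1
                if mo.log_odds_score(pwm, bg, mo.reverse_complement(w)) >= thr - 5e-4:
                    expected += 1
            assert n_hits == expected


class TestEnrichment:
    def test_zero_hits_gives_p_one(self):
        pwm = _sharp_pwm("ACGTAC")
        bg = mo.BackgroundModel.uniform()
        res = mo.motif_enrichment(pwm, bg, ["TTTTTTTTTT"] * 5, ["TTTTTTTTTT"] * 5)
        assert res.target_hits == 0
        assert res.p == pytest.approx(1.0)

    def test_binomial_tail_matches_direct_summation(self):
        from math import comb

        n, hits, rate = 10, 8, 0.1
        p_direct = sum(
            comb(n, k) * rate**k * (1 - rate) ** (n - k) for k in range(hits, n + 1)
        )
        assert float(stats.binom.sf(hits - 1, n, rate)) == pytest.approx(p_direct)
        # through the public API: 8 of 10 target regions hit, bg rate 0.1 (2/20)
        pwm = _sharp_pwm("ACGTAC")
        bg = mo.BackgroundModel.uniform()
        cons = pwm.consensus
        targets = ["TT" + cons + "TT"] * 8 + ["T" * 10] * 2
        bgs = ["TT" + cons + "TT"] * 2 + ["T" * 10] * 18
        res = mo.motif_enrichment(pwm, bg, targets, bgs)
        assert res.target_hits == 8 and res.bg_rate == pytest.approx(0.1)
        assert res.p == pytest.approx(p_direct, rel=1e-9)

    def test_bg_rate_floor(self):
        pwm = _sharp_pwm("ACGTAC")
        bg = mo.BackgroundModel.uniform()
        res = mo.motif_enrichment(
            pwm, bg, ["TT" + pwm.consensus + "TT"] * 4, ["T" * 10] * 8
        )
        assert res.bg_rate == pytest.approx(1 / 16)

    def test_identical_target_and_background_not_enriched(self):
        rng = np.random.default_rng(6)
        bg = mo.BackgroundModel.uniform()
        ps = []
        for trial in range(10):
            pwm = mo.PWM("m", "", rng.dirichlet([0.5] * 4, size=5), 0.0)
            seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(30)]
            ps.append(mo.motif_enrichment(pwm, bg, seqs, seqs, 0.99).p)
        assert np.mean(ps) > 0.4


class TestRankMotifs:
    def _res(self, mid, p, hits=0):
        return mo.MotifEnrichmentResult(mid, "", hits, 100, 0.1, p)

    def test_orders_by_p(self):
        ranked = mo.rank_motifs(
            [self._res("m1", 0.5), self._res("m2", 0.001), self._res("m3", 0.01)]
        )
        assert [r.motif_id for r in ranked] == ["m2", "m3", "m1"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_ties_break_by_hits_then_id(self):
        ranked = mo.rank_motifs(
            [
                self._res("b", 0.01, hits=5),
                self._res("a", 0.01, hits=5),
                self._res("c", 0.01, hits=9),
            ]
        )
        assert [r.motif_id for r in ranked] == ["c", "a", "b"]

    def test_topk_is_prefix_of_full_sort(self):
        rng = np.random.default_rng(7)
        results = [self._res(f"m{i:02d}", float(p)) for i, p in enumerate(rng.random(50))]
        full = mo.rank_motifs(results, k=50)
        top = mo.rank_motifs(results, k=20)
        assert [r.motif_id for r in top] == [r.motif_id for r in full[:20]]
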