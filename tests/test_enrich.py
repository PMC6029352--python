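"""Cognate-set construction, minHG statistics, correction, pruning, PPI pairs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kmerfact.enrich import (
    EnrichmentRecord,
    MotifCognateSet,
    correct_and_call,
    min_hypergeometric,
    pair_interaction_enrichment,
    pbm_cognate_set,
    prune_redundant,
    pwm_cognate_set,
    pwm_pattern_score,
    pwm_score_patterns,
    read_cisbp_pwm,
    write_cisbp_pwm,
)
from kmerfact.kmers import enumerate_patterns, reverse_complement


def sharp_pwm(consensus: str, p: float = 0.97) -> np.ndarray:
    pwm = np.full((len(consensus), 4), (1 - p) / 3)
    for i, c in enumerate(consensus):
        pwm[i, "ACGT".index(c)] = p
    return pwm


class TestPwmScoring:
    def test_single_base_log_odds(self):
        # a lone "A" against p(A)=0.97: log((0.97+eps)/0.25) with pseudocount
        pwm = sharp_pwm("A")
        expected = math.log(((0.97 + 0.01) / 1.04) / 0.25)
        assert pwm_pattern_score(pwm, "A") == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.335, abs=0.03)

    def test_gap_positions_contribute_zero(self):
        # against consensus ATC the pattern ANC aligns A..C at offset 0, so
        # its score is exactly the sum of the two specified positions
        pwm = sharp_pwm("ATC")
        assert pwm_pattern_score(pwm, "ANC") == pytest.approx(
            pwm_pattern_score(pwm, "A") + pwm_pattern_score(pwm, "C"), rel=1e-6
        )

    def test_reverse_complement_scores_equal(self, rng):
        pwm = sharp_pwm("ATGCGT", p=0.8)
        pats = [p.pattern for p in enumerate_patterns(4, canonicalize=False)][:200]
        scores = pwm_score_patterns(pwm, pats)
        rc_scores = pwm_score_patterns(pwm, [reverse_complement(p) for p in pats])
        np.testing.assert_allclose(scores, rc_scores, atol=1e-10)

    def test_overhanging_offsets_allowed(self):
        # pattern longer than the PWM still scores its best overlap
        pwm = sharp_pwm("AC")
        assert pwm_pattern_score(pwm, "ACGT") > 0

    def test_roundtrip_cisbp_format(self, tmp_path):
        pwm = sharp_pwm("ACGT", p=0.7)
        write_cisbp_pwm(pwm, tmp_path / "m.txt")
        np.testing.assert_allclose(read_cisbp_pwm(tmp_path / "m.txt"), pwm, atol=1e-9)


class TestPwmCognate:
    PATTERNS = [p.pattern for p in enumerate_patterns(4, canonicalize=True)]

    def test_consensus_patterns_get_high_z(self):
        pwm = sharp_pwm("ACGTACGT")
        cset = pwm_cognate_set(pwm, self.PATTERNS, tf_name="t")
        z = pd.Series(cset.z, index=cset.patterns)
        assert z["ACGT"] > 2
        assert cset.cognate.sum() < 0.35 * len(self.PATTERNS)

    def test_scale_invariance_of_cognate_set(self):
        pwm = sharp_pwm("ACGTACGT")
        cset = pwm_cognate_set(pwm, self.PATTERNS)
        scaled = pwm_cognate_set(pwm, self.PATTERNS, scores=cset.scores * 7.3)
        np.testing.assert_array_equal(cset.cognate, scaled.cognate)

    def test_requires_enough_patterns(self):
        with pytest.raises(ValueError):
            pwm_cognate_set(sharp_pwm("ACGT"), ["AC", "GT"])


class TestPbmCognate:
    def test_single_experiment_identity(self):
        table = pd.Series({"AAAAAAAC": 4.0, "AAAAAACC": 1.0})
        cset = pbm_cognate_set([table], tf_name="t")
        assert dict(zip(cset.patterns, cset.z))["AAAAAAAC"] == pytest.approx(4.0)

    def test_stouffer_combination(self):
        t = {"AAAAAAAC": 3.0, "AAAAAACC": 3.0}
        u = {"AAAAAAAC": 3.0, "AAAAAACC": -3.0}
        cset = pbm_cognate_set([t, u], tf_name="t")
        z = dict(zip(cset.patterns, cset.z))
        assert z["AAAAAAAC"] == pytest.approx(6 / math.sqrt(2))
        assert z["AAAAAACC"] == pytest.approx(0.0)
        assert list(cset.cognate) == [z[p] > 3 for p in cset.patterns]

    def test_mismatched_universes_raise(self):
        with pytest.raises(ValueError, match="universe"):
            pbm_cognate_set([{"AAAAAAAC": 1.0}, {"AAAAAACC": 1.0}])

    def test_reverse_complement_keys_collapse(self):
        table = {"AAAAAAAA": 2.0, "TTTTTTTT": 5.0}
        cset = pbm_cognate_set([table])
        assert cset.patterns == ["AAAAAAAA"]
        assert cset.z[0] == 5.0


def brute_force_minhg(flags: np.ndarray, max_prefix: int) -> tuple[float, int]:
    """Independent oracle: explicit prefix loop with exact hypergeometric."""
    M, K = len(flags), int(flags.sum())
    best_p, best_n = 1.0, 0
    x = 0
    for n in range(1, max_prefix + 1):
        x += int(flags[n - 1])
        p = float(stats.hypergeom.sf(x - 1, M, K, n))
        if p < best_p:
            best_p, best_n = p, n
    return best_p, best_n


class TestMinHypergeometric:
    def test_hand_computed_1_over_45(self):
        # 10 patterns, 2 cognate, both leading: p at N=2 is 1/C(10,2) = 1/45
        flags = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=bool)
        log10p, best_n = min_hypergeometric(flags, max_prefix=10)
        assert 10 ** log10p == pytest.approx(1 / 45, rel=1e-9)
        assert best_n == 2

    def test_zero_cognates_returns_one(self):
        assert min_hypergeometric(np.zeros(8, dtype=bool), 8) == (0.0, 0)

    def test_all_cognate_is_uninformative(self):
        log10p, _ = min_hypergeometric(np.ones(9, dtype=bool), 9)
        assert log10p == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            m = int(rng.integers(5, 400))
            k = int(rng.integers(1, m))
            flags = np.zeros(m, dtype=bool)
            flags[rng.choice(m, size=k, replace=False)] = True
            cap = int(rng.integers(1, m + 1))
            log10p, best_n = min_hypergeometric(flags, cap)
            exp_p, exp_n = brute_force_minhg(flags, cap)
            assert 10 ** log10p == pytest.approx(exp_p, rel=1e-8)
            assert best_n == exp_n

    def test_invariant_to_noncognate_relabeling(self, rng):
        flags = np.array([0, 1, 0, 1, 0, 0, 1, 0, 0, 0], dtype=bool)
        base = min_hypergeometric(flags, 10)
        assert min_hypergeometric(flags.copy(), 10) == base

    def test_scattered_cognates_not_significant(self, rng):
        hits = 0
        for _ in range(40):
            flags = np.zeros(200, dtype=bool)
            flags[rng.choice(200, size=20, replace=False)] = True
            log10p, _ = min_hypergeometric(flags, 200)
            hits += 10 ** log10p > 0.05 / 200  # vs Bonferroni scale
        assert hits >= 38


class TestCorrectAndCall:
    def _rec(self, log10p, n_prefixes, source="PBM"):
        return EnrichmentRecord("t", 0, "top", source, log10p,
                                log10p + math.log10(n_prefixes), 1, n_prefixes)

    def test_bonferroni_multiplier(self):
        rec = self._rec(math.log10(1 / 45), 2)
        assert rec.corrected_p == pytest.approx(2 / 45)

    def test_corrected_p_capped_at_one(self):
        rec = self._rec(-0.01, 1000)
        assert rec.corrected_p == 1.0

    def test_source_specific_thresholds(self):
        pbm = self._rec(math.log10(5e-3) - 3, 1000, "PBM")   # corrected 5e-3
        pwm = self._rec(math.log10(5e-3) - 3, 1000, "PWM")
        out = correct_and_call([pbm, pwm])
        assert pbm.significant and not pwm.significant
        assert out == [pbm]


class TestPruneRedundant:
    def _rec(self, tf, logp, pc=0, tail="top"):
        r = EnrichmentRecord(tf, pc, tail, "PWM", logp, logp, 1, 100)
        r.significant = True
        return r

    def test_identical_motifs_collapse(self, rng):
        v = pd.Series(rng.normal(size=50), index=[f"p{i}" for i in range(50)])
        recs = [self._rec("a", -20.0), self._rec("b", -10.0)]
        kept = prune_redundant(recs, {"a": v, "b": v * 2 + 1})
        assert [r.tf_name for r in kept] == ["a"]

    def test_orthogonal_motifs_both_kept(self, rng):
        idx = [f"p{i}" for i in range(200)]
        va = pd.Series(rng.normal(size=200), index=idx)
        vb = pd.Series(rng.normal(size=200), index=idx)
        kept = prune_redundant([self._rec("a", -20.0), self._rec("b", -10.0)],
                               {"a": va, "b": vb})
        assert [r.tf_name for r in kept] == ["a", "b"]

    def test_tie_broken_by_name(self, rng):
        idx = [f"p{i}" for i in range(50)]
        v = pd.Series(rng.normal(size=50), index=idx)
        recs = [self._rec("zeta", -10.0), self._rec("alpha", -10.0)]
        kept = prune_redundant(recs, {"zeta": v, "alpha": v})
        assert [r.tf_name for r in kept] == ["alpha"]


class TestPairInteractionEnrichment:
    def test_constructed_enrichment(self):
        universe = {f"t{i}" for i in range(10)}  # 45 possible pairs
        interactions = [("t0", "t1"), ("t2", "t3")]
        fold, p = pair_interaction_enrichment(
            [{"t0", "t1"}], interactions, universe
        )
        # 1 drawn pair, 2/45 success rate -> fold = 1 / (2/45) = 22.5
        assert fold == pytest.approx(22.5)
        assert p == pytest.approx(2 / 45)

    def test_all_pairs_interacting_is_null(self):
        universe = {"a", "b", "c"}
        inter = [("a", "b"), ("a", "c"), ("b", "c")]
        fold, p = pair_interaction_enrichment([{"a", "b", "c"}], inter, universe)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_no_coenriched_pairs(self):
        fold, p = pair_interaction_enrichment([set()], [("a", "b")], {"a", "b", "c"})
        assert math.isnan(fold) and p == 1.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            pair_interaction_enrichment([set()], [], set())
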