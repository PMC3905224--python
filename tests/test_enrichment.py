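"""Tests of the competitive enrichment stage: the running-sum score against
a brute-force oracle, the permutation null, GSEA-style FDR, empirical
validation, and leave-one-out sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_ranking
from gwaspath.enrichment import (
    EnrichmentResult,
    empirical_validation,
    enrichment_score,
    fdr_q,
    gsea,
    leave_one_out,
    permutation_p,
)
from gwaspath.types import EnrichmentConfig


def brute_force_es(weights, hit_mask, w):
    """Oracle: walk the ranking position by position, track the maximum."""
    weights = np.asarray(weights, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N, k = len(weights), int(hit_mask.sum())
    rw = weights**w if w != 0 else np.ones(N)
    denom = rw[hit_mask].sum()
    running, best = 0.0, -np.inf
    for j in range(N):
        if hit_mask[j]:
            running += rw[j] / denom if denom > 0 else 1.0 / k
        else:
            running -= 1.0 / (N - k)
        best = max(best, running)
    return best


def ranking_from_weights(weights):
    n = len(weights)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:03d}" for i in range(n)],
            "p": 10.0 ** (-np.asarray(weights, dtype=float)),
            "weight": np.asarray(weights, dtype=float),
        }
    )


class TestEnrichmentScore:
    def test_unit_weight_top_gene(self):
        ranked = ranking_from_weights([4.0, 3.0, 2.0, 1.0])
        es, profile = enrichment_score(ranked, ["G001"], w=0)
        np.testing.assert_allclose(profile, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert es == pytest.approx(1.0)

    def test_unit_weight_second_gene(self):
        ranked = ranking_from_weights([4.0, 3.0, 2.0, 1.0])
        es, _ = enrichment_score(ranked, ["G002"], w=0)
        assert es == pytest.approx(2 / 3)

    def test_weighted_top_two(self):
        ranked = ranking_from_weights([3.0, 2.0, 1.0, 0.5])
        es, profile = enrichment_score(ranked, ["G001", "G002"], w=1)
        np.testing.assert_allclose(profile, [3 / 5, 1.0, 1 / 2, 0.0], atol=1e-12)
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("w", [0, 1])
    def test_matches_brute_force_on_random_sets(self, w, rng):
        for _ in range(30):
            N = int(rng.integers(5, 40))
            weights = np.sort(rng.uniform(0, 6, N))[::-1]
            ranked = ranking_from_weights(weights)
            k = int(rng.integers(1, N))
            members = list(rng.choice(ranked["gene_id"], size=k, replace=False))
            hit_mask = ranked["gene_id"].isin(members).to_numpy()
            es, _ = enrichment_score(ranked, members, w=w)
            assert es == pytest.approx(brute_force_es(weights, hit_mask, w),
                                       abs=1e-12)

    def test_profile_conserves_to_zero(self, rng):
        ranked = ranking_from_weights(np.sort(rng.uniform(0, 5, 30))[::-1])
        _, profile = enrichment_score(ranked, ["G003", "G010", "G020"], w=1)
        assert abs(profile[-1]) < 1e-10

    def test_scale_invariance_weighted(self, rng):
        weights = np.sort(rng.uniform(0.1, 5, 25))[::-1]
        members = ["G002", "G007", "G015"]
        es1, _ = enrichment_score(ranking_from_weights(weights), members, w=1)
        es2, _ = enrichment_score(ranking_from_weights(weights * 7.3), members, w=1)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_weight_blindness_unit_mode(self, rng):
        w1 = np.sort(rng.uniform(0.1, 5, 25))[::-1]
        w2 = np.sort(rng.uniform(0.1, 5, 25))[::-1]
        members = ["G002", "G007", "G015"]
        es1, _ = enrichment_score(ranking_from_weights(w1), members, w=0)
        es2, _ = enrichment_score(ranking_from_weights(w2), members, w=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_absent_members_dropped(self):
        ranked = ranking_from_weights([3.0, 2.0, 1.0, 0.5])
        es_with, _ = enrichment_score(ranked, ["G001", "NOT_THERE"], w=0)
        es_alone, _ = enrichment_score(ranked, ["G001"], w=0)
        assert es_with == pytest.approx(es_alone)

    def test_degenerate_sets_rejected(self):
        ranked = ranking_from_weights([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, ["X"], w=0)
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, ["G001", "G002", "G003"], w=0)


class TestPermutationP:
    def test_add_one_counting(self, rng):
        ranked = ranking_from_weights(np.sort(rng.uniform(0, 4, 50))[::-1])
        config = EnrichmentConfig(n_perm=200, seed=3)
        es, _ = enrichment_score(ranked, ["G001", "G004", "G009"], w=1)
        p, null_es = permutation_p(ranked, 3, es, config)
        assert len(null_es) == 200
        assert p == (1 + (null_es >= es).sum()) / 201

    def test_beats_all_permutations_hits_floor(self, rng):
        # an impossible ES exceeds every permuted one
        ranked = ranking_from_weights(np.sort(rng.uniform(0, 4, 50))[::-1])
        config = EnrichmentConfig(n_perm=100, seed=4)
        p, _ = permutation_p(ranked, 3, 2.0, config)
        assert p == pytest.approx(1 / 101)

    def test_reproducible_at_fixed_seed(self, rng):
        ranked = ranking_from_weights(np.sort(rng.uniform(0, 4, 60))[::-1])
        config = EnrichmentConfig(n_perm=300, seed=11)
        es, _ = enrichment_score(ranked, ["G001", "G030"], w=1)
        p1, n1 = permutation_p(ranked, 2, es, config)
        p2, n2 = permutation_p(ranked, 2, es, config)
        assert p1 == p2
        np.testing.assert_array_equal(n1, n2)

    def test_self_consistency_null_p_uniform(self, rng):
        # a set drawn from the null has a uniform permutation P
        weights = np.sort(rng.uniform(0, 4, 60))[::-1]
        ranked = ranking_from_weights(weights)
        ps = []
        for i in range(150):
            members = list(rng.choice(ranked["gene_id"], 6, replace=False))
            es, _ = enrichment_score(ranked, members, w=1)
            p, _ = permutation_p(
                ranked, 6, es, EnrichmentConfig(n_perm=199, seed=i)
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_type_one_error_nominal(self, rng):
        # random sets on a null ranking are rejected at ~5%
        rejections = 0
        reps = 200
        for i in range(reps):
            local = np.random.default_rng(1000 + i)
            ranked = make_ranking(local.uniform(0, 1, 120))
            members = list(local.choice(ranked["gene_id"], 10, replace=False))
            es, _ = enrichment_score(ranked, members, w=1)
            p, _ = permutation_p(
                ranked, 10, es, EnrichmentConfig(n_perm=399, seed=i)
            )
            rejections += p <= 0.05
        half_ci = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= half_ci


class TestFdr:
    def test_single_set_collapses_to_p(self, rng):
        null = rng.uniform(0, 1, 500)
        nes, q = fdr_q(np.array([0.8]), [null], np.array([0.0123]))
        assert q[0] == pytest.approx(0.0123)

    def test_identical_sets_equal_q(self, rng):
        null = rng.uniform(0, 1, 500)
        nes, q = fdr_q(
            np.array([0.7, 0.7]), [null, null.copy()], np.array([0.1, 0.1])
        )
        assert q[0] == pytest.approx(q[1])

    def test_matches_brute_force_estimator(self, rng):
        m = 5
        es = rng.uniform(0.2, 0.9, m)
        nulls = [rng.uniform(0, 1, 400) for _ in range(m)]
        nes, q = fdr_q(es, nulls, rng.uniform(0, 1, m))
        # independent reimplementation of the ratio estimator
        norms = np.array([n[n > 0].mean() for n in nulls])
        nes_o = es / norms
        pooled = np.concatenate([n / c for n, c in zip(nulls, norms)])
        raw = np.array(
            [
                min(1.0, (pooled >= v).mean() / max((nes_o >= v).mean(), 1e-300))
                for v in nes_o
            ]
        )
        order = np.argsort(-nes_o, kind="mergesort")
        mono = raw[order]
        mono = np.minimum.accumulate(mono[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = mono
        np.testing.assert_allclose(q, expected, atol=1e-12)
        np.testing.assert_allclose(nes, nes_o, atol=1e-12)

    def test_q_monotone_in_nes(self, rng):
        m = 8
        es = rng.uniform(0.1, 1.0, m)
        nulls = [rng.uniform(0, 1, 300) for _ in range(m)]
        nes, q = fdr_q(es, nulls, rng.uniform(0, 1, m))
        order = np.argsort(-nes)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestValidation:
    def test_dominant_set_validates(self, rng):
        # causal-like ranking: set members occupy the top of the list
        p_vals = np.concatenate([rng.uniform(0, 0.001, 8),
                                 rng.uniform(0.2, 1.0, 72)])
        ranked = make_ranking(p_vals)
        members = ranked["gene_id"].iloc[:8].tolist()
        config = EnrichmentConfig(
            n_perm=500, n_random_sets=100, n_perm_validation=99, seed=2
        )
        results = gsea(ranked, {"top": members}, config)
        v = empirical_validation(ranked, members, results[0], config)
        assert v.fraction_exceeding_p == pytest.approx(1.0)
        assert v.validated

    def test_null_set_validates_at_criterion_rate(self):
        # calibration: an unremarkable set should validate ~5% of the time
        hits = 0
        reps = 60
        for i in range(reps):
            local = np.random.default_rng(3000 + i)
            ranked = make_ranking(local.uniform(0, 1, 60))
            members = list(local.choice(ranked["gene_id"], 6, replace=False))
            config = EnrichmentConfig(
                n_perm=199, n_random_sets=60, n_perm_validation=99, seed=i
            )
            results = gsea(ranked, {"s": members}, config)
            v = empirical_validation(ranked, members, results[0], config)
            hits += v.validated
        # binomial(60, 0.05): P(X > 9) < 1e-4
        assert hits <= 9


class TestLeaveOneOut:
    def test_pair_reduces_to_weaker_member(self, rng):
        ranked = make_ranking(np.linspace(0.01, 0.99, 40))
        members = [ranked["gene_id"].iloc[10], ranked["gene_id"].iloc[25]]
        config = EnrichmentConfig(n_perm=300, seed=5)
        out = leave_one_out(ranked, members, config)
        assert out.removed_gene == ranked["gene_id"].iloc[10]
        es_single, _ = enrichment_score(
            ranked, [ranked["gene_id"].iloc[25]], config.weight_exponent
        )
        assert out.es == pytest.approx(es_single)

    def test_single_driver_signal_collapses(self, rng):
        # one extreme gene at the top, the rest of the set unremarkable
        p_vals = np.concatenate([[1e-8], rng.uniform(0.3, 1.0, 99)])
        ranked = make_ranking(p_vals)
        top = ranked["gene_id"].iloc[0]
        others = list(rng.choice(ranked["gene_id"].iloc[40:], 9, replace=False))
        members = [top] + others
        config = EnrichmentConfig(n_perm=999, seed=6)
        results = gsea(ranked, {"s": members}, config)
        out = leave_one_out(ranked, members, config, set_name="s")
        assert results[0].p_perm < 0.05
        assert out.removed_gene == top
        assert out.p_perm > 0.05

    def test_spread_signal_survives(self, rng):
        # twenty moderately strong genes: no single member carries the signal
        p_vals = np.concatenate([rng.uniform(1e-6, 1e-3, 20),
                                 rng.uniform(0.05, 1.0, 180)])
        ranked = make_ranking(p_vals)
        members = ranked["gene_id"].iloc[:20].tolist()
        config = EnrichmentConfig(n_perm=999, seed=7)
        out = leave_one_out(ranked, members, config, set_name="s")
        assert out.p_perm < 0.05

    def test_requires_two_ranked_members(self):
        ranked = make_ranking([0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="2"):
            leave_one_out(ranked, [ranked["gene_id"].iloc[0]],
                          EnrichmentConfig(n_perm=10))


class TestRunningSumProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        data=st.data(),
        n=st.integers(min_value=2, max_value=25),
        w=st.sampled_from([0, 1]),
    )
    def test_walk_conservation_and_bounds(self, data, n, w):
        """For any ranking and proper subset: the walk ends at exactly zero,
        the score is its maximum, and it lies in [0, 1]."""
        raw = data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=8.0, allow_nan=False),
                min_size=n, max_size=n,
            )
        )
        weights = np.sort(np.asarray(raw))[::-1]
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        subset = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=n - 1),
                min_size=k, max_size=k, unique=True,
            )
        )
        ranked = ranking_from_weights(weights)
        members = [ranked["gene_id"].iloc[i] for i in subset]
        es, profile = enrichment_score(ranked, members, w=w)
        assert abs(profile[-1]) < 1e-10
        assert es == pytest.approx(profile.max(), abs=1e-12)
        assert 0.0 <= es <= 1.0 + 1e-12


class TestEnumeratedOracle:
    def test_all_subsets_small_rankings(self, rng):
        # exhaustive check on every proper non-empty subset, N <= 6 here
        # (the N <= 8 sweep lives in the acceptance suite)
        for N in (2, 4, 6):
            weights = np.sort(rng.uniform(0, 5, N))[::-1]
            ranked = ranking_from_weights(weights)
            ids = ranked["gene_id"].tolist()
            for r in range(1, N):
                for subset in itertools.combinations(range(N), r):
                    mask = np.zeros(N, dtype=bool)
                    mask[list(subset)] = True
                    members = [ids[i] for i in subset]
                    for w in (0, 1):
                        es, _ = enrichment_score(ranked, members, w=w)
                        assert es == pytest.approx(
                            brute_force_es(weights, mask, w), abs=1e-12
                        )
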