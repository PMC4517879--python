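"""Fleiss kappa against independent oracles, repeatability statistics,
bootstrap, interpretation bands."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripkit.agreement import (
    UndefinedAgreementError,
    accuracy_kappa,
    bootstrap_sd,
    consistency_kappa,
    fleiss_kappa,
    inter_scorer_kappa,
    intra_scorer_kappa,
    kappa_band,
)
from ripkit.patterns import PATTERNS
from ripkit.records import EvaluationPairing


def fleiss_oracle(matrix):
    """Brute-force Fleiss formula: pairwise agreement per sample, pooled
    category proportions for chance agreement. Written independently of the
    implementation (loops, no shared code)."""
    n, r = matrix.shape
    cats = sorted({int(v) for v in matrix.ravel()})
    p_sum = 0.0
    for row in matrix:
        agree = 0
        for i in range(r):
            for j in range(r):
                if i != j and row[i] == row[j]:
                    agree += 1
        p_sum += agree / (r * (r - 1))
    p_bar = p_sum / n
    p_e = 0.0
    for c in cats:
        frac = sum(1 for v in matrix.ravel() if int(v) == c) / (n * r)
        p_e += frac * frac
    if 1.0 - p_e < 1e-14:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


class TestFleissKappa:
    def test_perfect_agreement(self):
        m = np.repeat(np.array([[1], [2], [3], [4]]), 3, axis=1)
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_degenerate_single_category(self):
        m = np.ones((10, 3), dtype=int)
        assert fleiss_kappa(m) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        r = int(rng.integers(2, 5))
        m = rng.integers(1, 7, size=(n, r))
        assert fleiss_kappa(m) == pytest.approx(fleiss_oracle(m), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(99)
        m = rng.integers(1, 7, size=(500, 3))
        table, _ = aggregate_raters(m)
        assert fleiss_kappa(m) == pytest.approx(sm_fleiss(table), abs=1e-12)

    def test_chance_limit_two_uniform_raters(self):
        rng = np.random.default_rng(0)
        m = rng.integers(1, 7, size=(100_000, 2))
        assert abs(fleiss_kappa(m)) < 0.01

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 7, size=(15, 4))
        k = fleiss_kappa(m)
        rows = rng.permutation(15)
        cols = rng.permutation(4)
        assert fleiss_kappa(m[rows][:, cols]) == pytest.approx(k, abs=1e-12)

    def test_out_of_category_values_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[1, 99], [2, 2]]))


class TestAccuracy:
    def test_identity(self):
        v = np.array([1, 2, 3, 4, 5, 6] * 20)
        res = accuracy_kappa(v, v, seed=0)
        assert res.kappa == 1.0 and res.band == "almost perfect"

    def test_equals_two_rater_oracle(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(1, 7, size=400)
        assigned = truth.copy()
        flip = (truth == 4) & (rng.random(400) < 0.5)
        assigned[flip] = 6
        res = accuracy_kappa(assigned, truth, seed=0)
        m = np.column_stack([assigned, truth])
        assert res.kappa == pytest.approx(fleiss_oracle(m), abs=1e-12)

    def test_none_samples_excluded(self):
        truth = np.array([1, 2, 3, 0, 0])
        assigned = np.array([1, 2, 3, 4, 5])
        res = accuracy_kappa(assigned, truth, seed=0)
        assert res.n_samples == 3 and res.kappa == 1.0

    def test_disjoint_scored_regions_undefined(self):
        with pytest.raises(UndefinedAgreementError):
            accuracy_kappa(np.array([1, 0]), np.array([0, 2]))


class TestConsistency:
    def test_identical_copies(self):
        labels = np.array([1] * 50 + [2] * 50 + [1] * 50 + [2] * 50,
                          dtype=np.int8)
        pairing = EvaluationPairing(pairs=[((0, 50), (100, 150)),
                                           ((50, 100), (150, 200))])
        res = consistency_kappa(labels, pairing, seed=0)
        assert res.kappa == 1.0

    def test_symmetric_error_channel_expectation(self):
        # independent symmetric label noise per copy: closed-form kappa
        rng = np.random.default_rng(2)
        n = 60_000
        eps = 0.10
        truth = rng.integers(1, 7, size=n)

        def corrupt(v):
            out = v.copy()
            hit = rng.random(n) < eps
            shift = rng.integers(1, 6, size=n)
            out[hit] = ((v[hit] - 1 + shift[hit]) % 6) + 1
            return out

        labels = np.concatenate([corrupt(truth), corrupt(truth)]).astype(np.int8)
        pairing = EvaluationPairing(pairs=[((0, n), (n, 2 * n))])
        res = consistency_kappa(labels, pairing, n_resamples=10, seed=0)
        # P(agree) = (1-eps)^2 + eps^2/5; chance = 1/6 for uniform truth
        p_agree = (1 - eps) ** 2 + eps**2 / 5
        expected = (p_agree - 1 / 6) / (1 - 1 / 6)
        assert res.kappa == pytest.approx(expected, abs=0.01)

    def test_mismatched_pairing_rejected(self):
        pairing = EvaluationPairing(pairs=[((0, 50), (100, 150))])
        with pytest.raises(ValueError):
            consistency_kappa(np.ones(60, dtype=np.int8), pairing)


class TestIntraInter:
    def test_identical_iterations(self):
        v = np.array([1, 2, 3, 4, 5, 6] * 10, dtype=np.int8)
        overall, per_pattern = intra_scorer_kappa(v, v, n_resamples=10, seed=0)
        assert overall.kappa == 1.0
        assert all(r.kappa == 1.0 for r in per_pattern.values())

    def test_absent_pattern_reported_missing(self):
        v = np.array([1, 2] * 20, dtype=np.int8)
        _, per_pattern = intra_scorer_kappa(v, v, n_resamples=10, seed=0)
        from ripkit.patterns import PatternLabel

        assert per_pattern[PatternLabel.MVT] is None
        assert per_pattern[PatternLabel.SYB].kappa == 1.0

    def test_binarized_equals_two_category_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 7, size=300)
        b = rng.integers(1, 7, size=300)
        _, per_pattern = intra_scorer_kappa(a, b, n_resamples=10, seed=0)
        for pattern in PATTERNS:
            res = per_pattern[pattern]
            if res is None:
                continue
            binary = np.column_stack([(a == int(pattern)).astype(int),
                                      (b == int(pattern)).astype(int)])
            assert res.kappa == pytest.approx(fleiss_oracle(binary), abs=1e-12)

    def test_inter_scorer_combination_count(self):
        rng = np.random.default_rng(4)
        iterations = [[rng.integers(1, 7, size=100) for _ in range(2)]
                      for _ in range(3)]
        res = inter_scorer_kappa(iterations)
        assert res.n_combinations == 8
        # spot-check one combination against the oracle
        combo = [iterations[0][0], iterations[1][0], iterations[2][0]]
        assert res.kappas[0] == pytest.approx(
            fleiss_oracle(np.column_stack(combo)), abs=1e-12
        )

    def test_identical_scorers_mean_one_sd_zero(self):
        v = np.array([1, 2, 3] * 30, dtype=np.int8)
        res = inter_scorer_kappa([[v, v], [v, v], [v, v]])
        assert res.mean == 1.0 and res.sd == 0.0

    def test_single_combination_sd_zero(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(1, 7, size=(2, 80))
        res = inter_scorer_kappa([[a], [b]])
        assert res.n_combinations == 1 and res.sd == 0.0


class TestBootstrap:
    def test_constant_statistic_sd_zero(self):
        m = np.repeat(np.array([[1], [2], [3]]), 2, axis=1)
        assert bootstrap_sd(m, n_resamples=50, seed=0) == 0.0

    def test_reproducible(self):
        rng = np.random.default_rng(6)
        m = rng.integers(1, 7, size=(200, 2))
        assert bootstrap_sd(m, seed=3) == bootstrap_sd(m, seed=3)

    def test_matches_large_sample_variance_scale(self):
        # 2-rater agreement with symmetric noise: bootstrap SD should agree
        # with the asymptotic SD of kappa within a factor of 2
        rng = np.random.default_rng(7)
        n = 4000
        truth = rng.integers(1, 7, size=n)
        noisy = truth.copy()
        hit = rng.random(n) < 0.2
        noisy[hit] = rng.integers(1, 7, size=int(hit.sum()))
        m = np.column_stack([truth, noisy])
        sd = bootstrap_sd(m, n_resamples=100, seed=1)
        # delta-method scale: sd(kappa) ~ sd(agreement)/(1-Pe)/sqrt(n)
        agree = (m[:, 0] == m[:, 1]).astype(float)
        p_j = np.array([(m == c).mean() for c in range(1, 7)])
        p_e = (p_j**2).sum()
        approx = agree.std() / (1 - p_e) / np.sqrt(n)
        assert approx / 2 < sd < approx * 2


class TestKappaBand:
    @pytest.mark.parametrize(
        "value,band",
        [(-0.1, "poor"), (0.0, "slight"), (0.2, "slight"), (0.21, "fair"),
         (0.4, "fair"), (0.5, "moderate"), (0.6, "moderate"),
         (0.7, "substantial"), (0.8, "substantial"), (0.81, "almost perfect"),
         (1.0, "almost perfect")],
    )
    def test_boundaries_closed_above(self, value, band):
        assert kappa_band(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.5)
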