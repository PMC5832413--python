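import itertools

import numpy as np
import pytest
from scipy import stats

from rsapipe.inference import (bonferroni, critical_alpha, fisher_z,
                               group_model_fit, kendall_tau_a,
                               kendall_tau_a_batch, randomization_test,
                               rm_anova_2x2, tau_to_r,
                               wilcoxon_signed_rank_one_sided)
from rsapipe.rdm import RDM, squareform_from_vector
from tests.conftest import tau_a_oracle


class TestKendallTauA:
    def test_identity_and_reversal(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert kendall_tau_a(x, x) == pytest.approx(1.0)
        assert kendall_tau_a(x, x[::-1]) == pytest.approx(-1.0)

    def test_spec_tied_example(self):
        # 6 pairs, C - D = 2
        assert kendall_tau_a([1, 2, 2, 3], [1, 3, 2, 2]) == pytest.approx(2 / 6)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(30):
            m = int(rng.integers(5, 60))
            x = rng.integers(0, 6, m).astype(float)
            y = rng.integers(0, 6, m).astype(float)
            assert kendall_tau_a(x, y) == pytest.approx(tau_a_oracle(x, y),
                                                        abs=1e-12)

    def test_constant_vector_gives_zero(self):
        assert kendall_tau_a([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kendall_tau_a([1, 2], [1, 2, 3])

    def test_batch_equals_scalar(self, rng):
        y = rng.integers(0, 5, 20).astype(float)
        X = rng.integers(0, 5, size=(15, 20)).astype(float)
        batch = kendall_tau_a_batch(X, y)
        for row, got in zip(X, batch):
            assert got == pytest.approx(kendall_tau_a(row, y), abs=1e-12)

    def test_batch_nan_propagation(self):
        X = np.array([[1.0, 2, 3], [np.nan, 2, 3]])
        out = kendall_tau_a_batch(X, np.array([1.0, 2, 3]))
        assert out[0] == pytest.approx(1.0)
        assert np.isnan(out[1])


def exact_label_permutation_p(a: RDM, b: RDM) -> float:
    """Full enumeration over all n! simultaneous relabelings of b."""
    xa = a.vector()
    obs = kendall_tau_a(xa, b.vector())
    taus = [kendall_tau_a(xa, b.permute(list(p)))
            for p in itertools.permutations(range(a.n))]
    return np.mean([t >= obs - 1e-12 for t in taus])


class TestRandomizationTest:
    def test_self_comparison_small_p(self, rng):
        vec = rng.permutation(np.arange(6) + 1.0)
        a = squareform_from_vector(vec, list("abcd"))
        res = randomization_test(a, a, n_iter=999, seed=0)
        exact = exact_label_permutation_p(a, a)
        # +1-corrected p can exceed the exact p by at most the correction
        assert res.p <= exact + 2 / (1 + 999)

    def test_matches_exact_enumeration_n4(self, rng):
        for seed in range(5):
            g = np.random.default_rng(seed)
            a = squareform_from_vector(g.random(6), list("abcd"))
            b = squareform_from_vector(g.random(6), list("abcd"))
            exact = exact_label_permutation_p(a, b)
            res = randomization_test(a, b, n_iter=2000, seed=seed)
            assert res.p == pytest.approx(exact, abs=0.05)

    def test_deterministic_under_seed(self, toy_rdm, rng):
        b = squareform_from_vector(rng.random(6), toy_rdm.labels)
        r1 = randomization_test(toy_rdm, b, n_iter=200, seed=42)
        r2 = randomization_test(toy_rdm, b, n_iter=200, seed=42)
        assert r1.p == r2.p and r1.null_mean == r2.null_mean

    def test_invariant_to_consistent_relabeling(self, rng):
        labels = list("abcdef")
        a = squareform_from_vector(rng.random(15), labels)
        b = squareform_from_vector(rng.random(15), labels)
        r1 = randomization_test(a, b, n_iter=500, seed=7)
        order = ["d", "a", "f", "b", "e", "c"]
        r2 = randomization_test(a.reorder(order), b.reorder(order),
                                n_iter=500, seed=7)
        assert r1.tau_a == pytest.approx(r2.tau_a)
        assert r1.p == pytest.approx(r2.p)

    def test_constant_triangle_rejected(self):
        a = squareform_from_vector(np.ones(6), list("abcd"))
        b = squareform_from_vector(np.arange(6.0), list("abcd"))
        with pytest.raises(ValueError, match="tau undefined"):
            randomization_test(a, b, n_iter=10)

    def test_too_few_conditions_rejected(self):
        a = squareform_from_vector(np.arange(3.0), list("abc"))
        with pytest.raises(ValueError, match="4"):
            randomization_test(a, a, n_iter=10)


def wilcoxon_enumeration_oracle(v):
    """Exact one-sided p by enumerating all 2^n sign assignments."""
    v = np.asarray(v, float)
    v = v[v != 0]
    n = len(v)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = signs @ ranks
    return np.mean(w_all >= w_obs - 1e-9)


class TestWilcoxon:
    def test_all_positive_n6(self):
        p = wilcoxon_signed_rank_one_sided(np.arange(1.0, 7.0))
        assert p == pytest.approx(1 / 64)

    def test_antisymmetric_near_half(self):
        v = np.array([-3.0, 3.0, -1.0, 1.0, -2.0, 2.0])
        p = wilcoxon_signed_rank_one_sided(v)
        assert 0.4 < p < 0.65

    def test_exact_matches_enumeration_n16(self, rng):
        for _ in range(5):
            v = rng.standard_normal(16)
            v = v[v != 0]
            got = wilcoxon_signed_rank_one_sided(v)
            assert got == pytest.approx(wilcoxon_enumeration_oracle(v),
                                        abs=1e-6)

    def test_exact_with_tied_magnitudes(self):
        v = np.array([1.0, -1.0, 2.0, 2.0, 3.0, -2.0, 1.0])
        assert wilcoxon_signed_rank_one_sided(v) == pytest.approx(
            wilcoxon_enumeration_oracle(v), abs=1e-9)

    def test_zeros_dropped(self):
        v = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert wilcoxon_signed_rank_one_sided(v) == pytest.approx(1 / 64)

    def test_large_n_approximation_close_to_exact_at_25(self, rng):
        v = rng.standard_normal(25) + 0.4
        exact = wilcoxon_signed_rank_one_sided(v)  # n=25 uses the DP
        approx = wilcoxon_signed_rank_one_sided(np.r_[v, 0.35])  # n=26: normal
        assert np.isfinite(approx) and 0 < approx <= 1
        assert abs(np.log10(max(approx, 1e-12)) -
                   np.log10(max(exact, 1e-12))) < 1.0

    def test_error_cases(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_one_sided(np.zeros(6))
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank_one_sided(np.array([1.0, 2, 3, 0]))


class TestTransforms:
    def test_fixed_points(self):
        assert tau_to_r(0.0) == 0.0
        assert tau_to_r(1.0) == pytest.approx(1.0)
        assert tau_to_r(-1.0) == pytest.approx(-1.0)
        assert fisher_z(0.0) == 0.0

    def test_half_tau(self):
        assert tau_to_r(0.5) == pytest.approx(np.sin(np.pi / 4))
        assert tau_to_r(0.5) == pytest.approx(0.70711, abs=1e-5)

    def test_odd_and_strictly_increasing(self):
        taus = np.linspace(-1, 1, 41)
        rs = tau_to_r(taus)
        assert np.allclose(rs, -tau_to_r(-taus))
        assert np.all(np.diff(rs) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tau_to_r(1.5)
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestRmAnova:
    def test_additive_table_no_interaction(self, rng):
        # additive subject + column effects, tiny jitter to keep the
        # contrast variance nonzero
        subj = rng.standard_normal(8)
        table = subj[:, None] + np.array([0.0, 1.0, 2.0, 3.0])
        table += 1e-6 * rng.standard_normal(table.shape)
        eff = rm_anova_2x2(table)["interaction"]
        assert eff.p > 0.05
        d = (table[:, 0] - table[:, 1]) - (table[:, 2] - table[:, 3])
        assert np.allclose(d, 0.0, atol=1e-5)

    def test_interaction_equals_paired_t_squared(self, rng):
        table = rng.standard_normal((10, 4))
        table[:, 0] += 1.0  # crossed interaction
        eff = rm_anova_2x2(table)["interaction"]
        d = (table[:, 0] - table[:, 1]) - (table[:, 2] - table[:, 3])
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert eff.F == pytest.approx(t**2)
        assert eff.df == (1, 9)

    def test_against_statsmodels_anova_rm(self, rng):
        pd = pytest.importorskip("pandas")
        sm = pytest.importorskip("statsmodels.stats.anova")
        table = rng.standard_normal((12, 4))
        rows = []
        for s in range(12):
            for k, (m, c) in enumerate([("A", "1"), ("B", "1"),
                                        ("A", "2"), ("B", "2")]):
                rows.append({"subject": s, "model": m, "context": c,
                             "y": table[s, k]})
        df = pd.DataFrame(rows)
        res = sm.AnovaRM(df, "y", "subject",
                         within=["model", "context"]).fit()
        mine = rm_anova_2x2(table)
        aov = res.anova_table
        assert mine["interaction"].F == pytest.approx(
            aov.loc["model:context", "F Value"])
        assert mine["model"].F == pytest.approx(aov.loc["model", "F Value"])
        assert mine["context"].F == pytest.approx(
            aov.loc["context", "F Value"])
        assert mine["interaction"].p == pytest.approx(
            aov.loc["model:context", "Pr > F"])

    def test_missing_cells_rejected(self):
        t = np.ones((5, 4))
        t[0, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x2(t)
        with pytest.raises(ValueError):
            rm_anova_2x2(np.ones((5, 3)))


class TestBonferroni:
    def test_critical_alpha_16(self):
        assert critical_alpha(16) == pytest.approx(0.003125)

    def test_identity_m1(self):
        assert bonferroni([0.2], 1)[0] == pytest.approx(0.2)

    def test_clipping(self):
        assert bonferroni([0.4], 4)[0] == 1.0

    def test_default_m_is_length(self):
        out = bonferroni([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 1)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestGroupModelFit:
    def test_perfect_agreement(self, rng):
        model = squareform_from_vector(rng.permutation(np.arange(10.0)),
                                       list("abcde"))
        subs = [model for _ in range(6)]
        fit = group_model_fit(subs, model)
        assert np.allclose(fit.tau_per_subject, 1.0)
        assert fit.mean_tau == pytest.approx(1.0)
        assert fit.p == pytest.approx(1 / 64)

    def test_label_alignment(self, rng):
        model = squareform_from_vector(rng.random(10), list("abcde"))
        shuffled = model.reorder(["c", "e", "a", "b", "d"])
        fit = group_model_fit([shuffled] * 6, model)
        assert np.allclose(fit.tau_per_subject, 1.0)

    def test_too_few_subjects_propagates(self, rng):
        model = squareform_from_vector(rng.random(10), list("abcde"))
        with pytest.raises(ValueError):
            group_model_fit([model] * 3, model)
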