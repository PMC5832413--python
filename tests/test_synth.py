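import numpy as np
import pandas as pd
import pytest

from rsapipe import behavior, rsa, synth
from rsapipe.glm import build_design, estimate_patterns
from rsapipe.inference import (kendall_tau_a, wilcoxon_signed_rank_one_sided)
from rsapipe.rdm import aligned_vectors


class TestMakeModelRdms:
    def test_invariants_and_orthogonality(self):
        v, c = synth.make_model_rdms(16, tol=0.02, seed=0)
        for m in (v, c):
            assert np.allclose(m.values, m.values.T)
            assert np.all(np.diag(m.values) == 0)
            assert 0 <= m.values.min() and m.values.max() <= 1
        assert abs(kendall_tau_a(v.vector(), c.vector())) < 0.02

    def test_every_object_has_distinct_partners(self):
        v, c = synth.make_model_rdms(16, seed=0)
        v10 = np.percentile(v.vector(), 10)
        c10 = np.percentile(c.vector(), 10)
        for i in range(16):
            vrow = v.values[i].copy()
            crow = c.values[i].copy()
            vrow[i] = crow[i] = np.inf
            vp, cp = np.argmin(vrow), np.argmin(crow)
            assert vrow[vp] <= v10
            assert crow[cp] <= c10
            assert vp != cp  # different partner per model

    def test_deterministic_under_seed(self):
        a = synth.make_model_rdms(12, seed=9)
        b = synth.make_model_rdms(12, seed=9)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_odd_or_small_n_rejected(self):
        with pytest.raises(ValueError):
            synth.make_model_rdms(13)
        with pytest.raises(ValueError):
            synth.make_model_rdms(6)

    def test_unreachable_tolerance_reports_best(self):
        with pytest.raises(RuntimeError, match="best"):
            synth.make_model_rdms(8, tol=1e-9, seed=1, max_tries=3)


class TestSimulatePatterns:
    def test_ceiling_recovery(self, model_rdms):
        V, C = model_rdms
        cfg = synth.SyntheticConfig(
            n_objects=12, n_subjects=1, n_runs=1, grid=(8, 8, 8),
            regions={"r": synth.RegionSpec(
                (slice(0, 8),) * 3,
                {"visual": (1.0, 0.0), "conceptual": (1.0, 0.0)})},
            noise_sd=1e-3, exact_geometry=True, seed=5)
        sim = synth.simulate_patterns(V, C, cfg)
        rdm = rsa.pattern_rdm(sim.averaged(0, "visual", region="r"))
        tau = kendall_tau_a(*aligned_vectors(rdm, V))
        assert tau > 0.95

    def test_zero_weights_no_structure(self, model_rdms):
        V, C = model_rdms
        taus_v, taus_c = [], []
        for seed in range(8):
            cfg = synth.SyntheticConfig(
                n_objects=12, n_subjects=1, n_runs=1, grid=(6, 6, 6),
                regions={"r": synth.RegionSpec(
                    (slice(0, 6),) * 3,
                    {"visual": (0.0, 0.0), "conceptual": (0.0, 0.0)})},
                noise_sd=0.5, seed=seed)
            sim = synth.simulate_patterns(V, C, cfg)
            rdm = rsa.pattern_rdm(sim.averaged(0, "visual", region="r"))
            taus_v.append(kendall_tau_a(*aligned_vectors(rdm, V)))
            taus_c.append(kendall_tau_a(*aligned_vectors(rdm, C)))
        assert abs(np.mean(taus_v)) < 0.05
        assert abs(np.mean(taus_c)) < 0.05

    def test_integrative_region_fits_both_models(self, model_rdms,
                                                 small_config):
        V, C = model_rdms
        sim = synth.simulate_patterns(V, C, small_config)
        taus_v, taus_c = [], []
        for s in range(small_config.n_subjects):
            rdm = rsa.pattern_rdm(sim.averaged(s, "visual",
                                               region="prc_like"))
            taus_v.append(kendall_tau_a(*aligned_vectors(rdm, V)))
            taus_c.append(kendall_tau_a(*aligned_vectors(rdm, C)))
        assert wilcoxon_signed_rank_one_sided(np.array(taus_v)) < 0.05
        assert wilcoxon_signed_rank_one_sided(np.array(taus_c)) < 0.05

    def test_bit_reproducible(self, model_rdms, small_config):
        V, C = model_rdms
        a = synth.simulate_patterns(V, C, small_config).run_patterns(2)
        b = synth.simulate_patterns(V, C, small_config).run_patterns(2)
        for ctx in a:
            for ra, rb in zip(a[ctx], b[ctx]):
                assert np.array_equal(ra, rb)

    def test_run_noise_independent_across_runs(self, model_rdms,
                                               small_config):
        V, C = model_rdms
        runs = synth.simulate_patterns(V, C, small_config).run_patterns(0)
        assert not np.array_equal(runs["visual"][0], runs["visual"][1])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            synth.RegionSpec((slice(0, 2),) * 3, {"visual": (0.7, 0.7)})


class TestSimulateRatings:
    def test_round_trip_recovers_visual_model(self, model_rdms):
        V, _ = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12, n_raters=75,
                                    rating_noise_sd=0.0)
        ratings = synth.simulate_ratings(V, cfg, seed=3)
        rdm = behavior.visual_rdm(behavior.filter_raters(ratings))
        tau = kendall_tau_a(*aligned_vectors(rdm, V))
        assert tau > 0.95

    def test_failing_rater_removed_and_rdm_unchanged(self, model_rdms):
        V, _ = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12, n_raters=20)
        clean = synth.simulate_ratings(V, cfg, n_failing_raters=0, seed=4)
        planted = synth.simulate_ratings(V, cfg, n_failing_raters=2, seed=4)
        kept = behavior.filter_raters(planted)
        assert not kept["rater_id"].str.startswith("fail").any()
        a = behavior.visual_rdm(behavior.filter_raters(clean))
        b = behavior.visual_rdm(kept)
        assert np.allclose(a.values, b.reorder(a.labels).values)

    def test_catch_trials_present_per_rater(self, model_rdms):
        V, _ = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12, n_raters=5)
        ratings = synth.simulate_ratings(V, cfg, seed=0)
        catches = ratings[ratings["is_catch"]]
        assert (catches.groupby("rater_id").size() == 4).all()
        assert (catches["concept_a"] == catches["concept_b"]).all()

    def test_deterministic(self, model_rdms):
        V, _ = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12)
        a = synth.simulate_ratings(V, cfg, seed=5)
        b = synth.simulate_ratings(V, cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateNorms:
    def test_round_trip_recovers_conceptual_model(self, model_rdms):
        V, C = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12)
        norms = synth.simulate_norms(C, cfg, visual=V, seed=4)
        cfm = behavior.filter_features(norms)
        rdm = behavior.conceptual_rdm(cfm)
        tau = kendall_tau_a(*aligned_vectors(rdm, C))
        assert tau > 0.9

    def test_tagged_and_unreliable_features_filtered(self, model_rdms):
        V, C = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12)
        norms = synth.simulate_norms(C, cfg, visual=V, seed=4)
        assert (norms["tags"] != "none").any()
        assert (norms["producer_count"] < 4).any()
        cfm = behavior.filter_features(norms, min_count=4,
                                       exclude_tags={"visual_form", "color"})
        surviving = set(cfm.features)
        tagged = set(norms.loc[norms["tags"] != "none", "feature"].map(
            behavior.canonicalize_feature))
        assert not (surviving & tagged)

    def test_counts_within_producer_bounds(self, model_rdms):
        _, C = model_rdms
        cfg = synth.SyntheticConfig(n_objects=12, n_producers=20)
        norms = synth.simulate_norms(C, cfg, seed=1)
        assert norms["producer_count"].between(1, 20).all()


class TestSimulateEmbeddings:
    def test_leak_monotonicity(self, model_rdms):
        V, C = model_rdms
        taus = []
        for leak in [0.0, 0.3, 0.6]:
            emb = synth.simulate_embeddings(C, V, leak=leak, dim=64, seed=5)
            rdm = behavior.embedding_rdm(emb)
            taus.append(kendall_tau_a(*aligned_vectors(rdm, V)))
        assert taus[0] < taus[1] < taus[2]
        assert abs(taus[0]) < 0.1

    def test_no_leak_tracks_conceptual(self, model_rdms):
        V, C = model_rdms
        emb = synth.simulate_embeddings(C, V, leak=0.0, dim=64, seed=5)
        rdm = behavior.embedding_rdm(emb)
        assert kendall_tau_a(*aligned_vectors(rdm, C)) > 0.5

    def test_invalid_leak_rejected(self, model_rdms):
        V, C = model_rdms
        with pytest.raises(ValueError):
            synth.simulate_embeddings(C, V, leak=1.5)


class TestSimulateBold:
    def events(self):
        rows = [(0, "visual", f"o{i}", 6.0 + 8.0 * i, 2.0) for i in range(5)]
        return pd.DataFrame(rows, columns=["run", "context", "object",
                                           "onset", "duration"])

    def test_noise_free_exact_recovery(self, rng):
        amp = rng.standard_normal((5, 7))
        bs = synth.simulate_bold(self.events(), amp, noise_sd=0.0, seed=0)
        res = estimate_patterns(bs.data, bs.design, bs.design_columns)
        objects = [n for n in bs.design_columns if n != "intercept"]
        assert np.allclose(res.object_beta(objects), amp, atol=1e-9)

    def test_unbiased_across_seeds(self, rng):
        amp = rng.standard_normal((5, 3))
        errs = []
        for seed in range(30):
            bs = synth.simulate_bold(self.events(), amp, noise_sd=1.0,
                                     seed=seed)
            res = estimate_patterns(bs.data, bs.design, bs.design_columns)
            objects = [n for n in bs.design_columns if n != "intercept"]
            errs.append(res.object_beta(objects) - amp)
        assert abs(np.mean(errs)) < 0.1

    def test_drift_absorbed_by_nuisance(self, rng):
        amp = rng.standard_normal((5, 3))
        bs = synth.simulate_bold(self.events(), amp, noise_sd=0.0,
                                 drift=True, seed=0)
        res = estimate_patterns(bs.data, bs.design, bs.design_columns,
                                nuisance=bs.nuisance)
        objects = [n for n in bs.design_columns if n != "intercept"]
        assert np.allclose(res.object_beta(objects), amp, atol=1e-8)

    def test_negative_noise_rejected(self, rng):
        with pytest.raises(ValueError, match="noise"):
            synth.simulate_bold(self.events(), np.ones((5, 1)), noise_sd=-1)
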