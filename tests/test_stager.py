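import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mztstage as mz
from mztstage import ValidationError


class TestNormalizeToReference:
    def test_scaled_first_stage_column_recovers_factor(self, ref0, ruler0):
        reference, _ = ref0
        col = reference.matrix.values.iloc[:, 0]
        query = mz.ExpressionMatrix((2.0 * col).to_frame("q"))
        normalized, factors = mz.normalize_to_reference(query, reference, ruler0)
        assert factors["q"] == pytest.approx(0.5)
        ruler_genes = list(ruler0.genes)
        assert np.allclose(
            normalized.values.loc[ruler_genes, "q"], col.loc[ruler_genes]
        )

    def test_identity_query_gives_unit_factor(self, ref0, ruler0):
        reference, _ = ref0
        query = mz.ExpressionMatrix(reference.matrix.values.iloc[:, [0]].copy())
        _, factors = mz.normalize_to_reference(query, reference, ruler0)
        assert factors.iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("planted", [0.25, 0.5, 2.0, 4.0])
    def test_planted_library_size_factor_recovered(self, cfg0, ref0, ruler0, planted):
        reference, _ = ref0
        query, _ = mz.simulate_query(cfg0, reference.stage_times[0], 1, seed=1)
        scaled = mz.ExpressionMatrix(query.values * planted)
        _, factors = mz.normalize_to_reference(scaled, reference, ruler0)
        assert factors.iloc[0] == pytest.approx(1.0 / planted, rel=0.02)

    def test_too_few_shared_ruler_genes_error(self, ref0, ruler0):
        reference, _ = ref0
        small = mz.ExpressionMatrix(
            reference.matrix.values.loc[list(ruler0.genes[:5])].iloc[:, [0]].copy()
        )
        with pytest.raises(ValidationError, match="ruler genes"):
            mz.normalize_to_reference(small, reference, ruler0)


class TestStageSimilarity:
    def test_self_similarity_is_one(self, ref0, ruler0):
        reference, _ = ref0
        for k, stage in enumerate(reference.stage_labels):
            sims = mz.stage_similarity(
                reference.matrix.values[stage], reference, ruler0
            )
            assert sims[k] == pytest.approx(1.0)
            assert np.argmax(sims) == k

    def test_reversed_ranks_give_minus_one(self, ref0, ruler0):
        reference, _ = ref0
        col = reference.matrix.values["c12"]
        genes = list(ruler0.genes)
        vals = col.loc[genes].to_numpy()
        flipped = np.empty_like(vals)
        flipped[np.argsort(vals)] = np.sort(vals)[::-1]  # rank-reversing permutation
        reversed_profile = col.copy()
        reversed_profile.loc[genes] = flipped
        sims = mz.stage_similarity(reversed_profile, reference, ruler0)
        assert sims[list(reference.stage_labels).index("c12")] == pytest.approx(-1.0)

    def test_midpoint_query_argmax_flanks_truth(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        times = reference.stage_times
        for k in range(len(times) - 1):
            mid = (times[k] + times[k + 1]) / 2
            query, _ = mz.simulate_query(cfg0, mid, 1, seed=1)
            sims = mz.stage_similarity(query.values.iloc[:, 0], reference, ruler0)
            assert np.argmax(sims) in (k, k + 1)

    def test_constant_profile_is_error(self, ref0, ruler0):
        reference, _ = ref0
        flat = pd.Series(1.0, index=reference.gene_ids)
        with pytest.raises(ValidationError, match="constant"):
            mz.stage_similarity(flat, reference, ruler0)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_of_spearman(self, ref0, ruler0, scale):
        reference, _ = ref0
        col = reference.matrix.values["c13"]
        base = mz.stage_similarity(col, reference, ruler0)
        scaled = mz.stage_similarity(col * scale, reference, ruler0, pseudocount=1e-9)
        unscaled = mz.stage_similarity(col, reference, ruler0, pseudocount=1e-9)
        assert np.allclose(scaled, unscaled, atol=1e-9)
        assert np.argmax(base) == np.argmax(scaled)

    def test_overlap_metric_maximal_at_own_stage(self, ref0, ruler0):
        reference, _ = ref0
        for k, stage in enumerate(reference.stage_labels):
            sims = mz.stage_similarity(
                reference.matrix.values[stage], reference, ruler0, metric="overlap"
            )
            assert sims[k] == pytest.approx(1.0)
            assert sims[k] == sims.max()

    def test_overlap_invariant_to_scalar(self, ref0, ruler0):
        reference, _ = ref0
        col = reference.matrix.values["c12"]
        a = mz.stage_similarity(col, reference, ruler0, metric="overlap",
                                pseudocount=1e-9)
        b = mz.stage_similarity(col * 3.0, reference, ruler0, metric="overlap",
                                pseudocount=1e-9)
        assert np.allclose(a, b)


class TestEstimateStage:
    def test_reference_column_maps_to_own_stage(self, ref0, ruler0):
        reference, _ = ref0
        est = mz.estimate_stage(reference.matrix.values["c13"], reference, ruler0)
        assert est.best_stage == "c13"
        assert est.interp_time == reference.stage_times[3]

    def test_noise_free_interpolated_recovery_within_local_spacing(
        self, cfg0, ref0, ruler0
    ):
        reference, _ = ref0
        query, _ = mz.simulate_query(cfg0, 132.0, 1, seed=1)
        est = mz.estimate_stage(
            query.values.iloc[:, 0], reference, ruler0, interpolate=True
        )
        assert abs(est.interp_time - 132.0) <= 10.0  # half the local spacing
        assert abs(est.interp_time - 132.0) <= 2.0  # dense grid is near-exact

    def test_monotone_recovery_in_true_time(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        estimates = []
        for t in np.linspace(65, 168, 12):
            query, _ = mz.simulate_query(cfg0, t, 1, seed=1)
            est = mz.estimate_stage(
                query.values.iloc[:, 0], reference, ruler0, interpolate=True
            )
            estimates.append(est.interp_time)
        assert (np.diff(estimates) >= 0).all()

    def test_replicates_summarized_by_median(self, cfg, refn, rulern):
        reference, _ = refn
        query, _ = mz.simulate_query(cfg, 120.0, 3, seed=5)
        est = mz.estimate_stage(query, reference, rulern, interpolate=True)
        assert est.replicates is not None and len(est.replicates) == 3
        assert est.interp_time == pytest.approx(
            np.median([r.interp_time for r in est.replicates])
        )

    def test_parabola_mode_stays_within_flanking_stages(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        query, _ = mz.simulate_query(cfg0, 120.0, 1, seed=1)
        est = mz.estimate_stage(
            query.values.iloc[:, 0], reference, ruler0,
            interpolate=True, interp_method="parabola",
        )
        k = est.best_index
        lo = reference.stage_times[max(k - 1, 0)]
        hi = reference.stage_times[min(k + 1, len(reference.stage_times) - 1)]
        assert lo <= est.interp_time <= hi

    def test_noisy_recovery_within_one_interstage_spacing(self, cfg, refn, rulern):
        reference, _ = refn
        spacing = np.diff(reference.stage_times).mean()
        errors = []
        for i in range(30):
            t = 100.0
            query, _ = mz.simulate_query(cfg, t, 1, seed=3000 + i)
            est = mz.estimate_stage(
                query.values.iloc[:, 0], reference, rulern, interpolate=True
            )
            errors.append(abs(est.interp_time - t))
        assert np.median(errors) <= spacing


class TestDeltaTime:
    def test_identical_estimates_give_zero(self, ref0, ruler0):
        reference, _ = ref0
        est = mz.estimate_stage(reference.matrix.values["c12"], reference, ruler0)
        assert mz.delta_time(est, est).delta_t == 0.0

    def test_antisymmetry_exact(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        qa, _ = mz.simulate_query(cfg0, 100.0, 1, seed=1)
        qb, _ = mz.simulate_query(cfg0, 135.0, 1, seed=2)
        ea = mz.estimate_stage(qa.values.iloc[:, 0], reference, ruler0, True)
        eb = mz.estimate_stage(qb.values.iloc[:, 0], reference, ruler0, True)
        assert mz.delta_time(ea, eb).delta_t == -mz.delta_time(eb, ea).delta_t

    def test_planted_offset_recovered_noise_free(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        qa, _ = mz.simulate_query(cfg0, 100.0, 1, seed=1)
        qb, _ = mz.simulate_query(cfg0, 135.0, 1, seed=2)
        ea = mz.estimate_stage(qa.values.iloc[:, 0], reference, ruler0, True)
        eb = mz.estimate_stage(qb.values.iloc[:, 0], reference, ruler0, True)
        assert mz.delta_time(ea, eb).delta_t == pytest.approx(35.0, abs=2.0)

    def test_mismatched_references_error(self, ref0, ruler0):
        reference, _ = ref0
        est = mz.estimate_stage(reference.matrix.values["c12"], reference, ruler0)
        shorter = mz.ReferenceTimecourse(
            mz.ExpressionMatrix(reference.matrix.values.iloc[:, :4].copy()),
            reference.stage_labels[:4],
            reference.stage_times[:4],
        )
        other = mz.estimate_stage(
            shorter.matrix.values["c12"], shorter, ruler0
        )
        with pytest.raises(ValidationError, match="different references"):
            mz.delta_time(est, other)


class TestStageMatchedProfile:
    def test_exact_stage_returns_column_verbatim(self, ref0, ruler0):
        reference, _ = ref0
        est = mz.estimate_stage(reference.matrix.values["c13"], reference, ruler0)
        profile = mz.stage_matched_profile(reference, est)
        pd.testing.assert_series_equal(
            profile, reference.matrix.values["c13"], check_names=False
        )

    def test_midway_log_linear_interpolation_is_geometric_mean(self):
        df = pd.DataFrame({"a": [100.0, 16.0], "b": [25.0, 4.0]}, index=["g1", "g2"])
        reference = mz.ReferenceTimecourse(
            mz.ExpressionMatrix(df), ("a", "b"), np.array([0.0, 20.0])
        )
        est = mz.StageEstimate(
            similarities=np.array([0.5, 0.5]),
            stage_labels=("a", "b"),
            stage_times=np.array([0.0, 20.0]),
            best_index=0,
            interp_time=10.0,
            method_params={"interpolate": True},
        )
        profile = mz.stage_matched_profile(reference, est)
        assert profile["g1"] == pytest.approx(50.0)  # sqrt(100 * 25)
        assert profile["g2"] == pytest.approx(8.0)  # sqrt(16 * 4)

    def test_out_of_span_time_clamped_with_warning(self, ref0, ruler0):
        reference, _ = ref0
        est = mz.estimate_stage(reference.matrix.values["c10"], reference, ruler0)
        est.interp_time = 10.0
        with pytest.warns(UserWarning, match="clamp"):
            profile = mz.stage_matched_profile(reference, est)
        pd.testing.assert_series_equal(
            profile, reference.matrix.values["c10"], check_names=False
        )

    def test_noise_free_query_self_consistent_on_ruler_genes(
        self, cfg0, ref0, ruler0
    ):
        reference, _ = ref0
        query, _ = mz.simulate_query(cfg0, 140.0, 1, seed=1)
        est = mz.estimate_stage(
            query.values.iloc[:, 0], reference, ruler0, interpolate=True
        )
        profile = mz.stage_matched_profile(reference, est)
        genes = list(ruler0.genes)
        ratio = np.log2(
            (query.values.loc[genes].iloc[:, 0] + 0.5) / (profile.loc[genes] + 0.5)
        )
        assert np.median(np.abs(ratio)) <= 0.15


class TestBootstrapStage:
    def test_noise_free_exact_stage_sd_zero(self, cfg0, ref0, ruler0):
        reference, _ = ref0
        query, _ = mz.simulate_query(cfg0, 115.0, 1, seed=1)
        sd, _ = mz.bootstrap_stage(
            query.values.iloc[:, 0], reference, ruler0,
            n_boot=100, seed=2, interpolate=False,
        )
        assert sd == 0.0

    def test_seed_determinism(self, cfg, refn, rulern):
        reference, _ = refn
        query, _ = mz.simulate_query(cfg, 120.0, 1, seed=3)
        sd1, t1 = mz.bootstrap_stage(
            query.values.iloc[:, 0], reference, rulern, n_boot=100, seed=5
        )
        sd2, t2 = mz.bootstrap_stage(
            query.values.iloc[:, 0], reference, rulern, n_boot=100, seed=5
        )
        assert sd1 == sd2
        assert np.array_equal(t1, t2)

    def test_requires_at_least_100_replicates(self, cfg, refn, rulern):
        reference, _ = refn
        query, _ = mz.simulate_query(cfg, 120.0, 1, seed=3)
        with pytest.raises(ValueError, match="100"):
            mz.bootstrap_stage(query.values.iloc[:, 0], reference, rulern, n_boot=10)

    def test_sd_shrinks_with_ruler_size(self, cfg, refn, rulern):
        reference, _ = refn
        small = mz.RulerSet(rulern.genes[:20], rulern.params)
        large = mz.RulerSet(rulern.genes[:160], rulern.params)
        sd_small, sd_large = [], []
        for i in range(5):
            query, _ = mz.simulate_query(cfg, 120.0, 1, seed=7000 + i)
            profile = query.values.iloc[:, 0]
            s, _ = mz.bootstrap_stage(profile, reference, small, n_boot=100, seed=i)
            l, _ = mz.bootstrap_stage(profile, reference, large, n_boot=100, seed=i)
            sd_small.append(s)
            sd_large.append(l)
        assert np.mean(sd_small) > 1.5 * np.mean(sd_large)
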