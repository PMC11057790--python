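"""Assimilation tests: blending schedule, similarity transfer, pipeline."""

import numpy as np
import pytest

from tumorcast import (
    DensityMap,
    DomainError,
    GridSpec,
    SolverConfig,
    TreatmentParameterGrid,
    blend_parameters,
    build_training_prior,
    generate_dose_replicates,
    omega,
    predict_week,
    rank_similar_pixels,
    run_pipeline,
    sample_prediction_band,
    selection_size,
    transfer_parameters,
)
from tumorcast.assimilation import PARAM_NAMES, SimilarityRanking
from tumorcast.calibration import calibrate_posttreatment, calibrate_pretreatment


def _uniform_grid_params(grid, **kw):
    vals = dict(gs=0.01, fs=0.3, gd=0.005, kd=0.007, gamma_d=0.03, theta=89000.0)
    vals.update(kw)
    stacked = np.stack([np.full(grid.shape, vals[n]) for n in PARAM_NAMES], axis=-1)
    return TreatmentParameterGrid(stacked, grid)


class TestOmega:
    def test_anchors_and_midpoint(self):
        assert omega(0.0) == pytest.approx(1.0, abs=1e-15)
        assert omega(1.0) == pytest.approx(0.4, abs=1e-15)
        assert omega(0.5) == pytest.approx(0.55, abs=1e-15)

    def test_strictly_decreasing_with_bounded_range(self):
        ts = np.linspace(0, 1, 101)
        vals = np.array([omega(t) for t in ts])
        assert np.all(np.diff(vals) < 0)
        assert vals.min() >= 0.4 and vals.max() <= 1.0

    def test_domain_enforced(self):
        with pytest.raises(DomainError):
            omega(1.2)


class TestBlend:
    def test_start_of_experiment_returns_training_prior(self, grid5):
        pt = _uniform_grid_params(grid5, gs=0.02)
        pm = _uniform_grid_params(grid5, gs=0.005)
        out = blend_parameters(pt, pm, 0.0)
        assert np.array_equal(out.values, pt.values)

    def test_identical_grids_are_fixed_points(self, grid5, rng):
        vals = rng.uniform(0.2, 0.8, grid5.shape + (6,))
        p = TreatmentParameterGrid(vals, grid5)
        for t_hat in (0.0, 0.3, 1.0):
            assert np.allclose(blend_parameters(p, p, t_hat).values, vals)

    def test_scalar_example(self):
        g1 = GridSpec(1, 1, 430.0, 430.0)
        pt = TreatmentParameterGrid(np.full((1, 1, 6), 2.0), g1)
        pm = TreatmentParameterGrid(np.full((1, 1, 6), 4.0), g1)
        out = blend_parameters(pt, pm, 0.5)  # omega = 0.55
        assert np.allclose(out.values, 0.55 * 2.0 + 0.45 * 4.0)  # 2.9

    def test_convexity_keeps_values_in_span(self, grid5, rng):
        a = rng.uniform(0, 1, grid5.shape + (6,))
        b = rng.uniform(0, 1, grid5.shape + (6,))
        out = blend_parameters(TreatmentParameterGrid(a, grid5),
                               TreatmentParameterGrid(b, grid5), 0.7)
        assert np.all(out.values >= np.minimum(a, b) - 1e-12)
        assert np.all(out.values <= np.maximum(a, b) + 1e-12)


class TestSimilaritySelection:
    def test_full_training_set_selects_282(self):
        assert selection_size(5 * 15 * 15) == 282

    def test_ceiling_rule(self):
        assert selection_size(5 * 5 * 5) == 32   # ceil(31.25)
        assert selection_size(4) == 1

    def test_identical_course_ranks_first_with_unit_score(self, rng):
        courses = rng.uniform(0, 50, (40, 12))
        test = courses[17].copy()
        ranking = rank_similar_pixels(test, courses)
        assert ranking.order[0] == 17
        assert ranking.scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_weights_sum_to_one(self, rng):
        ranking = rank_similar_pixels(rng.uniform(0, 9, 10),
                                      rng.uniform(0, 9, (33, 10)))
        assert ranking.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(ranking.selected) == selection_size(33)

    def test_flat_test_course_falls_back_to_uniform_weights(self, rng):
        ranking = rank_similar_pixels(np.full(10, 3.0),
                                      rng.uniform(0, 9, (20, 10)))
        assert ranking.degenerate
        assert np.allclose(ranking.weights, 1.0 / len(ranking.selected))


class TestTransfer:
    def _ranking(self, ids, sccs):
        ids = np.asarray(ids)
        sccs = np.asarray(sccs, dtype=float)
        return SimilarityRanking(order=ids, scores=sccs, selected=ids,
                                 weights=sccs / sccs.sum())

    def test_shared_parameter_set_is_returned_unchanged(self):
        g1 = GridSpec(1, 1, 430.0, 430.0)
        params = np.tile([0.01, 0.3, 0.005, 0.007, 0.03, 89000.0], (5, 1))
        out = transfer_parameters([self._ranking([0, 2, 4], [0.9, 0.5, 0.2])],
                                  params, g1)
        assert np.allclose(out.values[0, 0], params[0])

    def test_equal_scores_give_plain_mean(self):
        g1 = GridSpec(1, 1, 430.0, 430.0)
        params = np.zeros((2, 6))
        params[0, 0], params[1, 0] = 0.01, 0.03
        out = transfer_parameters([self._ranking([0, 1], [0.7, 0.7])], params, g1)
        assert out.values[0, 0, 0] == pytest.approx(0.02, rel=1e-12)

    def test_three_pixel_weighted_example(self):
        # CCCs (0.9, 0.6, 0.3) -> weights (1/2, 1/3, 1/6)
        g1 = GridSpec(1, 1, 430.0, 430.0)
        params = np.zeros((3, 6))
        params[:, 0] = [0.012, 0.024, 0.036]
        r = self._ranking([0, 1, 2], [0.9, 0.6, 0.3])
        assert np.allclose(r.weights, [0.5, 1 / 3, 1 / 6])
        out = transfer_parameters([r], params, g1)
        expected = 0.5 * 0.012 + (1 / 3) * 0.024 + (1 / 6) * 0.036
        assert out.values[0, 0, 0] == pytest.approx(expected, rel=1e-12)


class TestTrainingPrior:
    def _cal(self, design, dose, seed):
        w = generate_dose_replicates(dose, design, master_seed=seed,
                                     n_replicates=1, noise_rel=0.0, noise_floor=0.0)[0]
        pre = calibrate_pretreatment(w).params
        return calibrate_posttreatment(w, frozen=pre, max_nfev=15)

    def test_identical_inputs_average_to_themselves(self, design5):
        cal = self._cal(design5, 75.0, 3)
        prior = build_training_prior([cal] * 5)
        single = TreatmentParameterGrid.from_calibration(cal)
        assert np.allclose(prior.values, single.values)

    def test_pixelwise_mean_matches_arithmetic_oracle(self, rng):
        from tumorcast.calibration import CalibrationResult
        from tumorcast.model_core import PretreatmentParams, TreatmentParams

        g2 = GridSpec(2, 2, 430.0, 860.0)
        cals = []
        for _ in range(5):
            post = TreatmentParams(
                gs=rng.uniform(0.001, 0.03, g2.shape), fs=rng.uniform(0, 1),
                gd=rng.uniform(0.001, 0.05), kd=rng.uniform(1e-4, 0.01),
                gamma_d=rng.uniform(1 / 120, 0.1), theta=rng.uniform(88000, 90000),
            )
            cals.append(CalibrationResult(
                pre=PretreatmentParams(), post=post, residuals=np.zeros(1),
                ccc_well=1.0, ccc_pixel=1.0, converged=True, n_iter=1,
                ic_map=DensityMap(np.ones(g2.shape), 48.0, g2),
            ))
        prior = build_training_prior(cals)
        stacked = np.stack(
            [TreatmentParameterGrid.from_calibration(c).values for c in cals])
        assert np.allclose(prior.values, stacked.mean(axis=0))
        # convexity: mean of bounded values respects the bounds
        assert prior.values[..., 1].min() >= 0.0 and prior.values[..., 1].max() <= 1.0


class TestPredictWeek:
    def test_matches_single_phase_simulation_for_uniform_grid(self, grid5, rng):
        from tumorcast.model_core import TreatmentParams, integrate_post

        params = _uniform_grid_params(grid5, gs=0.012, fs=0.2)
        cfg = SolverConfig(t_dox=48.0)
        ic = DensityMap(rng.uniform(5, 20, grid5.shape), 48.0, grid5)
        times = [100.0, 200.0]
        t, ns, nd = predict_week(ic, params, cfg, 0.003, times)
        p = TreatmentParams(gs=0.012, fs=0.2, gd=0.005, kd=0.007, gamma_d=0.03,
                            theta=89000.0, ds=0.003, dd=0.003)
        _, ns_ref, nd_ref = integrate_post(0.2 * ic.values, 0.8 * ic.values,
                                           p, cfg, grid5, 48.0, times)
        assert np.allclose(ns, ns_ref, rtol=1e-12)
        assert np.allclose(nd, nd_ref, rtol=1e-12)

    def test_empty_well_stays_empty(self, grid5):
        params = _uniform_grid_params(grid5)
        ic = DensityMap(np.zeros(grid5.shape), 48.0, grid5)
        _, ns, nd = predict_week(ic, params, SolverConfig(), 0.0, [200.0])
        assert np.all(ns == 0) and np.all(nd == 0)

    def test_fastest_pixel_wins_without_diffusion(self, grid5):
        gs = np.full(grid5.shape, 0.004)
        gs[3, 1] = 0.03
        params = _uniform_grid_params(grid5, fs=1.0)
        params.values[..., 0] = gs
        ic = DensityMap(np.full(grid5.shape, 5.0), 48.0, grid5)
        _, ns, nd = predict_week(ic, params, SolverConfig(), 0.0, [400.0])
        tot = ns[0] + nd[0]
        assert tot[3, 1] == tot.max()


class TestPredictionBand:
    def test_degenerate_distributions_collapse_to_point_forecast(self, grid5, rng):
        params = _uniform_grid_params(grid5, gs=0.012)
        samples = np.repeat(params.values[None], 6, axis=0)
        ic = DensityMap(rng.uniform(5, 20, grid5.shape), 48.0, grid5)
        cfg = SolverConfig(t_dox=48.0)
        band = sample_prediction_band(samples, samples, 0.3, ic, cfg, 0.003,
                                      [100.0, 150.0], n_samples=8, rng_seed=0)
        _, ns, nd = predict_week(ic, params, cfg, 0.003, [100.0, 150.0])
        assert np.allclose(band.mean, ns + nd, rtol=1e-12)
        assert np.allclose(band.upper - band.lower, 0.0, atol=1e-9)

    def test_seeded_reproducibility(self, grid5, rng):
        base = _uniform_grid_params(grid5).values
        samples = base[None] * rng.uniform(0.9, 1.1, (10, 1, 1, 1))
        ic = DensityMap(rng.uniform(5, 20, grid5.shape), 48.0, grid5)
        cfg = SolverConfig(t_dox=48.0)
        b1 = sample_prediction_band(samples, None, 0.0, ic, cfg, 0.003,
                                    [100.0], n_samples=16, rng_seed=5)
        b2 = sample_prediction_band(samples, None, 0.0, ic, cfg, 0.003,
                                    [100.0], n_samples=16, rng_seed=5)
        assert np.array_equal(b1.mean, b2.mean)
        assert np.array_equal(b1.lower, b2.lower)

    def test_too_few_samples_rejected(self, grid5):
        params = _uniform_grid_params(grid5)
        samples = np.repeat(params.values[None], 4, axis=0)
        ic = DensityMap(np.ones(grid5.shape), 48.0, grid5)
        with pytest.raises(DomainError):
            sample_prediction_band(samples, None, 0.0, ic, SolverConfig(),
                                   0.003, [100.0], n_samples=2)


class TestPipeline:
    def test_requires_six_replicates(self, design5):
        reps = generate_dose_replicates(75.0, design5, master_seed=1,
                                        n_replicates=4)
        with pytest.raises(DomainError):
            run_pipeline(reps, test_index=0)

    def test_rerun_with_same_seed_is_identical(self, design5):
        reps = generate_dose_replicates(
            35.0, design5, master_seed=7, n_replicates=6, shared_truth=True,
            noise_rel=0.0, noise_floor=0.0)
        r1 = run_pipeline(reps, test_index=2, rng_seed=9, n_boot=0, max_nfev=15)
        r2 = run_pipeline(reps, test_index=2, rng_seed=9, n_boot=0, max_nfev=15)
        for s1, s2 in zip(r1.trace.segments, r2.trace.segments):
            assert np.array_equal(s1.ntot, s2.ntot)

    def test_training_order_invariance(self, design5):
        """Leave-one-out symmetry: permuting the training replicates leaves
        the forecast unchanged (averaging and ranking are order-invariant)."""
        reps = generate_dose_replicates(
            35.0, design5, master_seed=7, n_replicates=6, shared_truth=True,
            noise_rel=0.0, noise_floor=0.0)
        r1 = run_pipeline(reps, test_index=5, rng_seed=0, n_boot=0, max_nfev=15)
        permuted = [reps[3], reps[1], reps[4], reps[0], reps[2], reps[5]]
        r2 = run_pipeline(permuted, test_index=5, rng_seed=0, n_boot=0, max_nfev=15)
        for s1, s2 in zip(r1.trace.segments, r2.trace.segments):
            assert np.allclose(s1.ntot, s2.ntot, rtol=1e-9)

    def test_forecast_quality_non_decreasing_on_self_consistent_design(self, design5):
        reps = generate_dose_replicates(
            35.0, design5, master_seed=7, n_replicates=6, shared_truth=True,
            noise_rel=0.0, noise_floor=0.0)
        res = run_pipeline(reps, test_index=5, rng_seed=0, n_boot=0)
        ccc = res.trace.ccc_well_by_week
        assert np.all(ccc >= ccc[0] - 1e-6)

    def test_bands_cover_point_forecast_on_shared_truth(self, design5):
        reps = generate_dose_replicates(
            35.0, design5, master_seed=7, n_replicates=6, shared_truth=True,
            noise_rel=0.02, noise_floor=0.0)
        res = run_pipeline(reps, test_index=0, rng_seed=3, n_boot=4,
                           n_band_samples=8)
        for seg in res.trace.segments:
            assert seg.band is not None
            assert np.all(seg.band.lower <= seg.band.upper + 1e-9)
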