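"""Synthetic cohort generator: roster, time series, voxel grids, responses."""

import numpy as np
import pytest

from gradconn.cohort import (CohortConfig, make_block_label_map, make_cohort,
                             simulate_gradcpt_responses, simulate_parcel_timeseries,
                             simulate_voxel_grid)
from gradconn.connectivity import TimeSeriesBundle, nuisance_residualize
from gradconn.gradcpt import assign_presses, build_trial_sequence, summarize_performance
from gradconn.stats import mann_whitney_z

from conftest import small_config


class TestMakeCohort:
    def test_default_roster_counts(self, default_cohort):
        groups = [r.group for r in default_cohort]
        assert sum(groups) == 18 and len(groups) - sum(groups) == 48

    def test_degenerate_all_controls(self):
        cfg = small_config(n_pos=0, n_neg=10)
        recs = make_cohort(cfg, seed=0)
        assert all(r.group == 0 for r in recs)

    def test_seeded_determinism(self):
        cfg = small_config()
        a, b = make_cohort(cfg, seed=3), make_cohort(cfg, seed=3)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id and ra.age == rb.age
            assert np.array_equal(ra.truth.corr, rb.truth.corr)

    def test_truth_matrix_symmetric_unit_diagonal(self):
        recs = make_cohort(small_config(), seed=1)
        for r in recs[:3]:
            C = r.truth.corr
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)

    def test_planted_effect_in_truth(self):
        cfg = small_config(jitter_z=0.0)
        recs = make_cohort(cfg, seed=2)
        ls, _ = cfg.seed_parcels
        pos = next(r for r in recs if r.group == 1)
        neg = next(r for r in recs if r.group == 0)
        z_pos = np.arctanh(pos.truth.corr[ls, cfg.mfg_parcel])
        z_neg = np.arctanh(neg.truth.corr[ls, cfg.mfg_parcel])
        assert z_pos - z_neg == pytest.approx(cfg.effect_mfg, abs=1e-9)

    def test_non_positive_definite_raises_with_subject(self):
        cfg = small_config(jitter_z=0.0, base_background_r=0.0,
                           base_seed_target_r=0.9, effect_mfg=1.5, effect_phg=0.0,
                           seed_seed_r=0.0)
        with pytest.raises(ValueError, match="sub-"):
            make_cohort(cfg, seed=0)


class TestParcelTimeseries:
    def test_identity_truth_near_zero_correlations(self):
        cfg = small_config(base_background_r=0.0, base_seed_target_r=0.0,
                           seed_seed_r=0.0, jitter_z=0.0, effect_mfg=0.0,
                           effect_phg=0.0, nuisance_amp=0.0, n_volumes=248)
        offdiags = []
        for s in range(40):
            recs = make_cohort(cfg, seed=s)
            ts, _ = simulate_parcel_timeseries(recs[0], cfg, seed=s)
            C = np.corrcoef(ts.to_numpy().T)
            offdiags.append(C[np.triu_indices_from(C, 1)].mean())
        assert abs(np.mean(offdiags)) < 0.02

    def test_planted_correlation_recovered_at_long_T(self):
        cfg = small_config(n_volumes=10000, nuisance_amp=0.0, jitter_z=0.0,
                           base_seed_target_r=0.5, effect_mfg=0.0, effect_phg=0.0)
        recs = make_cohort(cfg, seed=4)
        sub = next(r for r in recs if r.group == 0)
        ts, _ = simulate_parcel_timeseries(sub, cfg, seed=4)
        X = ts.to_numpy()
        ls, _ = cfg.seed_parcels
        r = np.corrcoef(X[:, ls], X[:, cfg.mfg_parcel])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_bit_identical_given_seed(self):
        cfg = small_config()
        rec = make_cohort(cfg, seed=5)[0]
        a, _ = simulate_parcel_timeseries(rec, cfg, seed=9)
        b, _ = simulate_parcel_timeseries(rec, cfg, seed=9)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_short_run_warns(self):
        cfg = small_config(n_volumes=20)
        rec = make_cohort(cfg, seed=6)[0]
        with pytest.warns(UserWarning, match="n_volumes"):
            simulate_parcel_timeseries(rec, cfg, seed=0)

    def test_residualized_correlations_converge_despite_nuisance(self):
        cfg = small_config(n_volumes=4000, nuisance_amp=0.5, jitter_z=0.0,
                           base_seed_target_r=0.4, effect_mfg=0.0, effect_phg=0.0)
        rec = make_cohort(cfg, seed=7)[0]
        ts, nuis = simulate_parcel_timeseries(rec, cfg, seed=7)
        resid = nuisance_residualize(TimeSeriesBundle(ts.to_numpy(), nuis.to_numpy()))
        ls, _ = cfg.seed_parcels
        r = np.corrcoef(resid[:, ls], resid[:, cfg.mfg_parcel])[0, 1]
        assert r == pytest.approx(0.4, abs=0.07)


class TestVoxelGrid:
    def test_zero_noise_replicates_parcel_series(self):
        cfg = small_config(voxel_noise_sd=0.0, n_volumes=40)
        rec = make_cohort(cfg, seed=8)[0]
        grid = (8, 6, 4)
        lm = make_block_label_map(grid, cfg.n_parcels)
        vol, _, _ = simulate_voxel_grid(rec, cfg, grid, lm, 0.0, seed=8)
        ts, _ = simulate_parcel_timeseries(rec, cfg, seed=8)
        X = ts.to_numpy()
        for pid in (1, cfg.n_parcels):
            vox = vol[lm == pid]
            assert np.allclose(vox, X[:, pid - 1][None, :])

    def test_parcel_mean_tracks_parcel_series(self):
        cfg = small_config(n_volumes=60, voxel_noise_sd=0.5)
        rec = make_cohort(cfg, seed=9)[0]
        grid = (12, 9, 6)
        lm = make_block_label_map(grid, cfg.n_parcels)
        ts, _ = simulate_parcel_timeseries(rec, cfg, seed=9)
        vol, _, _ = simulate_voxel_grid(rec, cfg, grid, lm, 0.0, seed=9,
                                        parcel_ts=ts.to_numpy())
        X = ts.to_numpy()
        for pid in (1, 5):
            mean_series = vol[lm == pid].mean(axis=0)
            r = np.corrcoef(mean_series, X[:, pid - 1])[0, 1]
            assert r > 0.9

    def test_grid_too_small_raises(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="too small|missing"):
            lm = make_block_label_map((2, 2, 2), 8)
            simulate_voxel_grid(make_cohort(cfg, seed=0)[0], cfg, (2, 2, 2), lm,
                                0.0, seed=0)

    def test_deterministic(self):
        cfg = small_config(n_volumes=30)
        rec = make_cohort(cfg, seed=10)[0]
        grid = (8, 6, 4)
        lm = make_block_label_map(grid, cfg.n_parcels)
        a, _, _ = simulate_voxel_grid(rec, cfg, grid, lm, 4.0, seed=3)
        b, _, _ = simulate_voxel_grid(rec, cfg, grid, lm, 4.0, seed=3)
        assert np.array_equal(a, b)

    def test_label_map_contains_all_parcels(self):
        lm = make_block_label_map((15, 15, 10), 116)
        assert set(range(1, 117)) <= set(np.unique(lm))


class TestGradcptResponses:
    def _subject_with(self, cfg, **truth_overrides):
        rec = make_cohort(cfg, seed=11)[0]
        from dataclasses import replace
        rec.truth = replace(rec.truth, **truth_overrides)
        return rec

    def test_degenerate_parameters_perfect_performance(self):
        cfg = small_config()
        rec = self._subject_with(cfg, p_lapse=0.0, p_ce=0.0, rt_sd_ms=1e-6,
                                 rt_mean_ms=750.0)
        seq = build_trial_sequence(300, 0.1, seed=12)
        log = simulate_gradcpt_responses(rec, seq, cfg, seed=12)
        s = summarize_performance(assign_presses(seq, log))
        assert s.oe_rate == 0.0 and s.ce_rate == 0.0
        assert s.rt_mean_s == pytest.approx(0.750, abs=0.005)

    def test_certain_commission_errors(self):
        cfg = small_config()
        rec = self._subject_with(cfg, p_lapse=0.0, p_ce=1.0)
        seq = build_trial_sequence(300, 0.1, seed=13)
        log = simulate_gradcpt_responses(rec, seq, cfg, seed=13)
        s = summarize_performance(assign_presses(seq, log))
        assert s.ce_rate == 1.0

    def test_press_times_strictly_increasing(self):
        cfg = small_config()
        rec = make_cohort(cfg, seed=14)[0]
        seq = build_trial_sequence(600, 0.1, seed=14)
        log = simulate_gradcpt_responses(rec, seq, cfg, seed=14)
        assert np.all(np.diff(log.press_time_ms) > 0)

    def test_group_direction_of_oe_and_cv(self):
        """Monte-Carlo under the default group parameters: the positive group
        shows higher omission rates and RT variability."""
        cfg = CohortConfig(n_pos=60, n_neg=60)
        recs = make_cohort(cfg, seed=15)
        oe = {0: [], 1: []}
        cv = {0: [], 1: []}
        for k, rec in enumerate(recs):
            seq = build_trial_sequence(300, 0.1, seed=600 + k)
            log = simulate_gradcpt_responses(rec, seq, cfg, seed=900 + k)
            s = summarize_performance(assign_presses(seq, log))
            oe[rec.group].append(s.oe_rate)
            cv[rec.group].append(s.rt_cv)
        assert np.mean(oe[1]) > np.mean(oe[0])
        assert np.mean(cv[1]) > np.mean(cv[0])


class TestCalibrationAndCoupling:
    def test_null_effects_calibrated_group_test(self):
        """With no planted effect the parcel-level group comparison rejects at
        the nominal rate."""
        cfg = small_config(effect_mfg=0.0, effect_phg=0.0, n_volumes=100,
                           n_parcels=12, seed_parcels=(0, 1), mfg_parcel=4,
                           phg_parcel=7, nuisance_amp=0.0)
        n_sim, rej = 200, 0
        for s in range(n_sim):
            recs = make_cohort(cfg, seed=s)
            y = np.array([r.group for r in recs])
            vals = []
            for k, rec in enumerate(recs):
                ts, _ = simulate_parcel_timeseries(rec, cfg, seed=s * 100 + k)
                X = ts.to_numpy()
                r = np.corrcoef(X[:, [0, 1]].mean(1), X[:, cfg.mfg_parcel])[0, 1]
                vals.append(np.arctanh(r))
            vals = np.array(vals)
            rej += mann_whitney_z(vals[y == 1], vals[y == 0]).p < 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01
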