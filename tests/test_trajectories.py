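import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from saprosucc import (
    ModelSpec,
    fit_trajectory,
    interaction_lrt,
    residual_time_diagnostics,
    specialist_generalist_model,
    within_time_contrasts,
)
from saprosucc.trajectories import FactorialDesign, FitResult


def nb_frame(rng, cell_means, n_traps_per_env=30, theta=5.0, years=(1, 2, 3, 4)):
    """Simulate an NB2 count model frame with given (env, year) cell means."""
    rows = []
    trap_id = 0
    for env in ("exposed", "shaded"):
        for _ in range(n_traps_per_env):
            trap_id += 1
            lsc = "A" if trap_id % 2 else "B"
            for y in years:
                mu = cell_means[env][y - 1]
                p = theta / (theta + mu)
                rows.append(dict(
                    trap=f"t{trap_id}", time=y, environment=env,
                    landscape=lsc, y=float(rng.negative_binomial(theta, p)),
                ))
    return pd.DataFrame(rows)


def gaussian_frame(rng, cell_means, n_traps_per_env=30, sd=0.3,
                   times=("1-2", "2-3", "3-4")):
    rows = []
    trap_id = 0
    for env in ("exposed", "shaded"):
        for _ in range(n_traps_per_env):
            trap_id += 1
            lsc = "A" if trap_id % 2 else "B"
            for i, t in enumerate(times):
                rows.append(dict(
                    trap=f"t{trap_id}", time=t, environment=env,
                    landscape=lsc,
                    y=cell_means[env][i] + rng.normal(0, sd),
                ))
    return pd.DataFrame(rows)


class TestFitTrajectory:
    def test_nb_cell_mean_recovery(self):
        # mean prediction over replicates recovers every cell mean within 15%
        rng = np.random.default_rng(0)
        truth = {"exposed": [2, 8, 8, 8], "shaded": [2, 4, 6, 8]}
        preds = []
        for _ in range(5):
            frame = nb_frame(rng, truth)
            fit = fit_trajectory(frame, ModelSpec.for_response("richness"))
            preds.append(fit.predictions.set_index(["environment", "time"])
                         ["predicted"])
        mean_pred = pd.concat(preds, axis=1).mean(axis=1)
        for (env, time), got in mean_pred.items():
            assert got == pytest.approx(truth[env][int(time) - 1], rel=0.15)

    def test_gaussian_constant_response_degenerates_cleanly(self):
        rng = np.random.default_rng(1)
        frame = gaussian_frame(rng, {"exposed": [0, 0, 0], "shaded": [0, 0, 0]},
                               sd=0.0)
        frame["y"] = 1.7
        fit = fit_trajectory(frame, ModelSpec.for_response("Gp"))
        assert np.allclose(fit.predictions["predicted"], 1.7, atol=1e-8)
        for c in within_time_contrasts(fit):
            assert c.estimate == pytest.approx(0.0, abs=1e-8)

    def test_single_environment_errors(self):
        rng = np.random.default_rng(2)
        frame = gaussian_frame(rng, {"exposed": [0, 0, 0], "shaded": [0, 0, 0]})
        frame = frame[frame["environment"] == "exposed"]
        with pytest.raises(ValueError, match="environments"):
            fit_trajectory(frame, ModelSpec.for_response("Gp"))

    def test_nb_matches_poisson_when_equidispersed(self):
        # as overdispersion vanishes the NB2 fit collapses onto Poisson
        rng = np.random.default_rng(3)
        rows = []
        for trap in range(60):
            env = "exposed" if trap < 30 else "shaded"
            for y in (1, 2, 3, 4):
                mu = 5.0 if env == "exposed" else 3.0
                rows.append(dict(trap=f"t{trap}", time=y, environment=env,
                                 landscape="A" if trap % 2 else "B",
                                 y=float(rng.poisson(mu))))
        frame = pd.DataFrame(rows)
        fit = fit_trajectory(frame, ModelSpec.for_response("abundance"))
        X = fit.design.matrix(frame)
        pois = sm.GLM(frame["y"].to_numpy(), X,
                      family=sm.families.Poisson()).fit()
        eta = X @ fit.params.to_numpy()
        np.testing.assert_allclose(np.exp(eta), pois.fittedvalues, rtol=0.02)

    def test_predictions_invariant_to_time_relabeling(self):
        rng = np.random.default_rng(4)
        truth = {"exposed": [2, 8, 8, 8], "shaded": [2, 4, 6, 8]}
        frame = nb_frame(rng, truth)
        fit1 = fit_trajectory(frame, ModelSpec.for_response("richness"))
        relabel = {1: "y1", 2: "y2", 3: "y3", 4: "y4"}
        frame2 = frame.assign(time=frame["time"].map(relabel))
        fit2 = fit_trajectory(frame2, ModelSpec.for_response("richness"))
        np.testing.assert_allclose(
            fit1.predictions["predicted"], fit2.predictions["predicted"],
            rtol=1e-6,
        )


class TestInteractionLRT:
    def test_df_counts_interaction_cells(self):
        rng = np.random.default_rng(5)
        truth = {"exposed": [2, 8, 8, 8], "shaded": [2, 4, 6, 8]}
        frame = nb_frame(rng, truth, n_traps_per_env=15)
        full = fit_trajectory(frame, ModelSpec.for_response("richness"))
        red = fit_trajectory(frame, ModelSpec.for_response("richness"),
                             interaction=False)
        chi2, df, p = interaction_lrt(full, red)
        assert df == 3  # (4-1) x (2-1)
        assert chi2 >= 0 and 0 < p <= 1

    def test_identical_loglik_gives_null_result(self):
        design = FactorialDesign({"time": [1, 2], "environment": ["e", "s"]})
        spec = ModelSpec.for_response("Gp")
        kw = dict(spec=spec, design=design,
                  cov=pd.DataFrame(np.eye(2)), n_obs=10,
                  data=pd.DataFrame(), predictions=pd.DataFrame(),
                  structure="test", llf=-12.0)
        full = FitResult(params=pd.Series([0.0, 0.0], index=["a", "b"]), **kw)
        red = FitResult(params=pd.Series([0.0], index=["a"]), **kw)
        chi2, df, p = interaction_lrt(full, red)
        assert chi2 == 0.0 and p == 1.0 and df == 1

    def test_non_nested_errors(self):
        rng = np.random.default_rng(6)
        truth = {"exposed": [2, 2, 2, 2], "shaded": [2, 2, 2, 2]}
        frame = nb_frame(rng, truth, n_traps_per_env=10)
        full = fit_trajectory(frame, ModelSpec.for_response("richness"))
        with pytest.raises(ValueError):
            interaction_lrt(full, full)  # no reduction
        red = fit_trajectory(frame.iloc[:-4],
                             ModelSpec.for_response("richness"),
                             interaction=False)
        with pytest.raises(ValueError):
            interaction_lrt(full, red)  # different data

    def test_power_under_strong_interaction(self):
        # exposed jumps year 1 -> 2, shaded rises linearly
        rng = np.random.default_rng(7)
        truth = {"exposed": [2, 8, 8, 8], "shaded": [2, 4, 6, 8]}
        rejections = 0
        n_rep = 25
        for _ in range(n_rep):
            frame = nb_frame(rng, truth, n_traps_per_env=30)
            full = fit_trajectory(frame, ModelSpec.for_response("richness"))
            red = fit_trajectory(frame, ModelSpec.for_response("richness"),
                                 interaction=False)
            _, _, p = interaction_lrt(full, red)
            rejections += p < 0.05
        # the noncentrality at this effect size / dispersion gives ~85% power
        assert rejections / n_rep >= 0.75

    def test_null_lrt_p_roughly_uniform(self):
        # no interaction in truth: p-values should not pile up near 0
        rng = np.random.default_rng(8)
        truth = {"exposed": [3, 4, 5, 6], "shaded": [2, 8 / 3, 10 / 3, 4]}
        ps = []
        for _ in range(40):
            frame = nb_frame(rng, truth, n_traps_per_env=20)
            full = fit_trajectory(frame, ModelSpec.for_response("richness"))
            red = fit_trajectory(frame, ModelSpec.for_response("richness"),
                                 interaction=False)
            ps.append(interaction_lrt(full, red)[2])
        # KS against uniform; permissive alpha for 40 replicates
        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestContrasts:
    def test_contrast_centering_tracks_cell_differences(self):
        rng = np.random.default_rng(9)
        truth = {"exposed": [2, 6, 6, 6], "shaded": [2, 3, 3, 3]}
        frame = nb_frame(rng, truth, n_traps_per_env=40)
        fit = fit_trajectory(frame, ModelSpec.for_response("richness"))
        con = {c.time: c for c in within_time_contrasts(fit)}
        assert abs(con[1].estimate) < 0.4  # equal cell means at year 1
        for t in (2, 3, 4):
            assert con[t].estimate == pytest.approx(np.log(2), abs=0.3)
            assert con[t].p < 0.01

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(10)
        truth = {"exposed": [3, 3, 3], "shaded": [3, 3, 3]}
        ps = []
        for _ in range(40):
            frame = gaussian_frame(rng, truth, n_traps_per_env=20, sd=1.0)
            fit = fit_trajectory(frame, ModelSpec.for_response("Gp"))
            ps.extend(c.p for c in within_time_contrasts(fit))
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(11)
        truth = {"exposed": [2, 6, 6, 6], "shaded": [2, 3, 3, 3]}
        frame = nb_frame(rng, truth)
        fit = fit_trajectory(frame, ModelSpec.for_response("richness"))
        raw = {c.time: c.p for c in within_time_contrasts(fit)}
        adj = {c.time: c.p for c in within_time_contrasts(fit, adjust="holm")}
        for t in raw:
            assert adj[t] >= raw[t] - 1e-15


class TestSpecialistGeneralist:
    def _frames(self, rng, spec_fold=8.0, gen_fold=2.0, n=30):
        frames = {}
        for g, fold in (("specialist", spec_fold), ("generalist", gen_fold)):
            truth = {"exposed": [3, 3 * fold], "shaded": [2, 2 * 1.2]}
            frames[g] = nb_frame(rng, truth, n_traps_per_env=n, years=(1, 2))
        return frames

    def test_fold_change_recovery_and_three_way_power(self):
        rng = np.random.default_rng(12)
        hits = 0
        spec_folds, gen_folds = [], []
        n_rep = 10
        for _ in range(n_rep):
            fit, tw, folds = specialist_generalist_model(self._frames(rng))
            fe = folds.set_index(["group", "environment"])["fold"]
            spec_folds.append(fe[("specialist", "exposed")])
            gen_folds.append(fe[("generalist", "exposed")])
            hits += tw.p < 0.05
        assert np.median(spec_folds) == pytest.approx(8.0, rel=0.25)
        assert np.median(gen_folds) == pytest.approx(2.0, rel=0.25)
        assert hits >= 0.8 * n_rep

    def test_identical_dynamics_gives_null_three_way(self):
        rng = np.random.default_rng(13)
        zs = []
        for _ in range(10):
            _, tw, _ = specialist_generalist_model(
                self._frames(rng, spec_fold=2.0, gen_fold=2.0))
            zs.append(tw.z)
        assert abs(np.mean(zs)) < 1.0

    def test_constant_counts_give_unit_fold(self):
        rng = np.random.default_rng(14)
        _, _, folds = specialist_generalist_model(
            self._frames(rng, spec_fold=1.0, gen_fold=1.0, n=40))
        fe = folds.set_index(["group", "environment"])["fold"]
        assert fe[("specialist", "exposed")] == pytest.approx(1.0, abs=0.35)

    def test_missing_group_errors(self):
        rng = np.random.default_rng(15)
        frames = self._frames(rng)
        del frames["generalist"]
        with pytest.raises(ValueError, match="generalist"):
            specialist_generalist_model(frames)


class TestResidualDiagnostics:
    def _fit_with_resid(self, resid_by_trap, times=(1, 2, 3, 4)):
        rows = []
        for trap, resids in resid_by_trap.items():
            for t, r in zip(times, resids):
                rows.append(dict(trap=trap, time=t, resid=r,
                                 environment="exposed", landscape="A", y=r))
        design = FactorialDesign({"time": list(times),
                                  "environment": ["exposed", "shaded"]})
        return FitResult(
            spec=ModelSpec.for_response("Gp"), design=design,
            params=pd.Series(dtype=float), cov=pd.DataFrame(),
            llf=0.0, n_obs=len(rows), data=pd.DataFrame(rows),
            predictions=pd.DataFrame(), structure="test",
        )

    def test_white_noise_residuals_uncorrelated(self):
        rng = np.random.default_rng(16)
        fit = self._fit_with_resid(
            {f"t{i}": rng.normal(0, 1, 4) for i in range(200)})
        _, summary = residual_time_diagnostics(fit)
        assert abs(summary["lag1_pooled"]) < 0.1

    def test_ar1_residuals_detected(self):
        rng = np.random.default_rng(17)
        resids = {}
        for i in range(200):
            r = np.empty(4)
            r[0] = rng.normal()
            for t in range(1, 4):
                r[t] = 0.8 * r[t - 1] + rng.normal(0, 0.6)
            resids[f"t{i}"] = r
        fit = self._fit_with_resid(resids)
        _, summary = residual_time_diagnostics(fit)
        assert summary["lag1_pooled"] > 0.4

    def test_two_time_points_error(self):
        rng = np.random.default_rng(18)
        fit = self._fit_with_resid(
            {f"t{i}": rng.normal(0, 1, 2) for i in range(5)}, times=(1, 2))
        with pytest.raises(ValueError, match="3 time points"):
            residual_time_diagnostics(fit)
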