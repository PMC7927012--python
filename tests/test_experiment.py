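"""End-to-end crossed experiment: design shape, determinism, reductions."""

import warnings

import numpy as np
import pytest

import mortcomp as mc
from mortcomp import experiment as ex
from mortcomp.blockboot import BlockSpec


@pytest.fixture(scope="module")
def small_surface():
    spec = mc.ScenarioSpec(ages=40, years=14, exposure=1e5, seed=21)
    surf, _ = mc.make_scenario_surface(spec)
    return surf


@pytest.fixture(scope="module")
def small_result(small_surface):
    cfg = mc.ExperimentConfig(n_replicates=3, horizon=8, seed=77,
                              n_projections=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return mc.run_experiment(small_surface, cfg)


class TestDefaultBlocks:
    def test_reference_shape_unscaled(self):
        assert ex.default_block_sizes(100, 22) == {
            "LC1": (3, 9), "LC2": (3, 9), "H1": (3, 14)}

    def test_scaled_down_proportionally(self):
        blocks = ex.default_block_sizes(50, 11)
        assert blocks["LC1"] == (2, 5)
        assert blocks["H1"] == (2, 7)

    def test_never_smaller_than_one_cell(self):
        blocks = ex.default_block_sizes(10, 3)
        for h, w in blocks.values():
            assert h >= 1 and w >= 1


class TestRunExperiment:
    def test_nine_cells_per_indicator(self, small_result):
        for cs in small_result.curvesets.values():
            assert len(cs.cells) == 9
            assert {m for m, _ in cs.cells} == {"LC1", "LC2", "H1"}
            assert {s for _, s in cs.cells} == {"RLC1", "RLC2", "RH1"}

    def test_horizon_year_count(self, small_result):
        for cs in small_result.curvesets.values():
            assert len(cs.horizon_years) == 8
            for arr in cs.cells.values():
                assert arr.shape == (3, 8)

    def test_e65_dropped_on_short_age_range(self, small_result):
        assert "e65" not in small_result.curvesets
        assert set(small_result.curvesets) == {"e0", "modal", "gini"}

    def test_intervals_ordered(self, small_result):
        iv = small_result.intervals
        assert (iv.lower <= iv.upper + 1e-12).all()

    def test_determinism_same_seed(self, small_surface, tmp_path):
        frames = []
        for run in range(2):
            cfg = mc.ExperimentConfig(n_replicates=2, horizon=5, seed=123,
                                      n_projections=5,
                                      out_dir=str(tmp_path / f"run{run}"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mc.run_experiment(small_surface, cfg)
            frames.append((tmp_path / f"run{run}" / "indicator_curves.csv")
                          .read_bytes())
        assert frames[0] == frames[1]

    def test_failure_fraction_guard(self, small_surface, monkeypatch):
        real = ex._fit_model
        calls = {"n": 0}

        def flaky(surface, family):
            calls["n"] += 1
            if calls["n"] > 3:  # fail every bootstrap refit
                raise RuntimeError("synthetic failure")
            return real(surface, family)

        monkeypatch.setattr(ex, "_fit_model", flaky)
        cfg = mc.ExperimentConfig(n_replicates=2, horizon=5, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(RuntimeError, match="replicates failed"):
                mc.run_experiment(small_surface, cfg)


class TestConfigFile:
    def test_round_trip(self, tmp_path):
        text = """
        # comment
        models = LC1, H1
        sources = LC1
        n_replicates = 4
        horizon = 6
        alpha = 0.01
        seed = 9
        block_sizes = LC1:2x5, H1:2x7
        k1_order = 0,1,0
        k1_drift = true
        indicators = e0, gini
        """
        path = tmp_path / "exp.cfg"
        path.write_text(text)
        cfg = mc.ExperimentConfig.from_file(path)
        assert cfg.models == ("LC1", "H1")
        assert cfg.sources == ("LC1",)
        assert cfg.n_replicates == 4
        assert cfg.alpha == 0.01
        assert cfg.block_sizes == {"LC1": (2, 5), "H1": (2, 7)}
        assert cfg.indicators == ("e0", "gini")

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("banana = 3\n")
        with pytest.raises(ValueError, match="banana"):
            mc.ExperimentConfig.from_file(path)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            mc.ExperimentConfig(n_replicates=1)
        with pytest.raises(ValueError):
            mc.ExperimentConfig(models=("LC7",))


class TestIidReduction:
    def test_unit_blocks_match_direct_iid_bootstrap(self, small_surface):
        """A 1x1-block experiment on one model/source must match a hand-rolled
        iid residual bootstrap in distribution (location/scale of the
        final-year e0 across replicates)."""
        N = 15
        cfg = mc.ExperimentConfig(models=("LC1",), sources=("LC1",),
                                  n_replicates=N, horizon=6, seed=5,
                                  indicators=("e0",),
                                  block_sizes={"LC1": (1, 1)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mc.run_experiment(small_surface, cfg)
        pipeline_e0 = res.curvesets["e0"].cells[("LC1", "RLC1")][:, -1]

        # direct implementation: iid resample of residual cells
        fit = mc.fit_lc(small_surface, r=1)
        dhat = mc.fitted_deaths(fit, small_surface)
        resid = mc.deviance_residuals(small_surface.d, dhat, small_surface.E)
        rng = np.random.default_rng(999)
        direct = []
        for _ in range(N):
            flat = resid.r.ravel()
            draw = rng.choice(flat, size=flat.size).reshape(resid.shape)
            rhat = mc.ResidualMatrix(r=draw, mask=np.isfinite(draw))
            d_new = mc.invert_to_deaths(rhat, dhat, small_surface.E)
            refit = mc.fit_lc(small_surface.with_deaths(d_new), r=1)
            from mortcomp.forecast import fit_arima, forecast_index
            spec = fit_arima(refit.K[0], 0, 1, 0, drift=True)
            k_fut = forecast_index(spec, refit.K[0], 6)[None, :]
            q_fut = mc.project_probabilities(refit, k_fut,
                                             small_surface.years[-1] + 1 + np.arange(6),
                                             small_surface.ages)
            direct.append(mc.indicator_curves(q_fut, indicators=("e0",))["e0"][-1])
        direct = np.asarray(direct)
        # same location and comparable spread
        pooled_sd = np.sqrt((pipeline_e0.var() + direct.var()) / 2)
        assert abs(pipeline_e0.mean() - direct.mean()) < 4 * pooled_sd
        assert 0.2 < pipeline_e0.std() / direct.std() < 5.0


class TestFullCircleNullCalibration:
    def test_same_model_design_keeps_nominal_level(self):
        """Simulate, fit, bootstrap and forecast with one model, split the
        replicates into nine pseudo-cells: the functional ANOVA must reject
        at no more than the nominal rate."""
        n_seeds = 40
        cells_n = 4
        rejections = 0
        from mortcomp.forecast import fit_arima, forecast_index
        for seed in range(n_seeds):
            truth = mc.make_params(24, 15, "LC1", seed=seed)
            surf = mc.simulate_deaths(truth, 1e5, seed=seed + 7000)
            fit = mc.fit_lc(surf, r=1)
            dhat = mc.fitted_deaths(fit, surf)
            resid = mc.deviance_residuals(surf.d, dhat, surf.E)
            rng = np.random.default_rng(seed + 3000)
            curves = []
            for _ in range(9 * cells_n):
                rhat = mc.resample_blocks(resid, BlockSpec(2, 3), rng=rng)
                d_new = mc.invert_to_deaths(rhat, dhat, surf.E)
                refit = mc.fit_lc(surf.with_deaths(d_new), r=1)
                spec = fit_arima(refit.K[0], 0, 1, 0, drift=True)
                k_fut = forecast_index(spec, refit.K[0], 8)[None, :]
                q_fut = mc.project_probabilities(
                    refit, k_fut, surf.years[-1] + 1 + np.arange(8), surf.ages)
                curves.append(mc.indicator_curves(q_fut,
                                                  indicators=("e0",))["e0"])
            curves = np.asarray(curves)
            cells = {}
            i = 0
            for m in ("LC1", "LC2", "H1"):
                for s in ("R1", "R2", "R3"):
                    cells[(m, s)] = curves[i * cells_n:(i + 1) * cells_n]
                    i += 1
            cs = mc.IndicatorCurveSet(indicator="e0",
                                      horizon_years=np.arange(8),
                                      cells=cells, N=cells_n)
            res = mc.fanova_test(cs, K=30, alpha=0.05, seed=seed + 11,
                                 with_pairwise=False)
            rejections += int(res.reject_model)
        assert rejections / n_seeds <= 0.10
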