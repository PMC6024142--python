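"""The penalized-spline backend: closed-form oracles, cyclic constraint,
failure capture, determinism and an independent-library cross-check."""

import math

import numpy as np
import pandas as pd
import pytest

from fullsubsets import FullSubsetsGAM
from fullsubsets.backend import (PenalizedSplineBackend, _pirls, fit_all)
from fullsubsets.basis import build_design
from fullsubsets.candidates import ModelSpec, TermSpec
from fullsubsets.formula import FitSpec, build_fit_spec
from fullsubsets.predictors import PredictorSpec

S = lambda v: TermSpec(kind="smooth", vars=(v,))
FM = lambda f: TermSpec(kind="factor_main", factors=(f,))


def _null_spec(family="gaussian"):
    return FitSpec(model=ModelSpec(terms=()), response="y", family=family)


class TestClosedFormOracles:
    def test_intercept_only_fits_the_mean(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        rec = PenalizedSplineBackend().fit(_null_spec(), data)
        assert rec.status == "ok"
        assert np.allclose(rec.fitted, 3.0)

    def test_intercept_only_gaussian_loglik(self):
        # closed-form normal loglik at the MLE: mean 3, variance 2
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s2 = ((y - y.mean()) ** 2).mean()
        expected = -0.5 * len(y) * (math.log(2 * math.pi * s2) + 1)
        assert expected == pytest.approx(-8.8275606, abs=1e-6)
        rec = PenalizedSplineBackend().fit(_null_spec(), pd.DataFrame({"y": y}))
        assert rec.loglik == pytest.approx(expected, abs=1e-8)
        assert rec.n_params == pytest.approx(2.0)  # intercept + scale

    def test_poisson_loglik_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        y = rng.poisson(4.0, 50).astype(float)
        rec = PenalizedSplineBackend().fit(
            _null_spec("poisson"), pd.DataFrame({"y": y}))
        assert np.allclose(rec.fitted, y.mean(), atol=1e-6)
        expected = stats.poisson.logpmf(y, y.mean()).sum()
        assert rec.loglik == pytest.approx(expected, abs=1e-6)


class TestSmoothFits:
    def test_linear_signal_fully_explained_by_smooth(self, rng):
        x = rng.uniform(0, 1, 100)
        data = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        spec = build_fit_spec(ModelSpec(terms=(S("x"),)),
                              [PredictorSpec("x")], "y")
        rec = PenalizedSplineBackend().fit(spec, data)
        assert rec.status == "ok"
        assert rec.deviance_explained >= 0.999

    def test_cyclic_smooth_is_periodic(self, rng):
        period = 24.0
        d = rng.uniform(0, period, 200)
        y = np.sin(2 * np.pi * d / period) + rng.normal(0, 0.1, 200)
        data = pd.DataFrame({"d": d, "y": y})
        spec = build_fit_spec(
            ModelSpec(terms=(S("d"),)),
            [PredictorSpec("d", cyclic=True, period=period)], "y")
        rec = PenalizedSplineBackend().fit(spec, data)
        f0 = rec.fit.predict(pd.DataFrame({"d": [0.0]}))[0]
        fP = rec.fit.predict(pd.DataFrame({"d": [period]}))[0]
        assert abs(f0 - fP) < 1e-6
        # and it actually tracks the sine
        grid = pd.DataFrame({"d": np.linspace(0, period, 50)})
        pred = rec.fit.predict(grid)
        assert np.corrcoef(pred, np.sin(2 * np.pi * grid.d / period))[0, 1] > 0.95

    def test_noise_smooth_edf_shrinks_toward_one(self):
        # under penalization a pure-noise cr smooth keeps only its
        # unpenalized slope: total edf ~ intercept + ~1
        edfs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = pd.DataFrame({"x": rng.normal(size=120),
                                 "y": rng.normal(size=120)})
            spec = build_fit_spec(ModelSpec(terms=(S("x"),)),
                                  [PredictorSpec("x")], "y")
            rec = PenalizedSplineBackend().fit(spec, data)
            edfs.append(rec.edf - 1.0)  # subtract the intercept
        assert 0.8 < float(np.mean(edfs)) < 1.6

    def test_unpenalized_nested_deviance_monotone(self, rng):
        # sanity oracle with penalties disabled: adding a term never
        # increases in-sample deviance
        n = 80
        data = pd.DataFrame({"x1": rng.uniform(0, 1, n),
                             "x2": rng.uniform(0, 1, n),
                             "y": rng.normal(size=n)})
        preds = [PredictorSpec("x1"), PredictorSpec("x2")]
        devs = []
        for terms in [(S("x1"),), (S("x1"), S("x2"))]:
            spec = build_fit_spec(ModelSpec(terms=terms), preds, "y")
            design = build_design(spec, data)
            lam = np.zeros(len(design.penalties))
            from fullsubsets.backend import _FAMILIES
            _, mu, _, dev = _pirls(design.X, data["y"].to_numpy(),
                                   design.penalties, lam, _FAMILIES["gaussian"])
            devs.append(dev)
        assert devs[1] <= devs[0] + 1e-8


class TestFailureCapture:
    def test_single_level_factor_is_failed_record_naming_it(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=30),
                             "f": ["only"] * 30,
                             "y": rng.normal(size=30)})
        spec = FitSpec(model=ModelSpec(terms=(FM("f"),)), response="y",
                       factor_levels={"f": ("only", "gone")})
        rec = PenalizedSplineBackend().fit(spec, data)
        assert rec.status == "failed"
        assert "'f'" in rec.error_message

    def test_random_terms_rejected_as_capability_failure(self):
        spec = FitSpec(model=ModelSpec(terms=()), response="y",
                       random_terms=("(1|site)",))
        rec = PenalizedSplineBackend().fit(
            spec, pd.DataFrame({"y": [1.0, 2.0, 3.0]}))
        assert rec.status == "failed"
        assert "random" in rec.error_message

    def test_driver_never_raises_and_keeps_order(self, simple_gaussian_data):
        preds = [PredictorSpec("x1"), PredictorSpec("x2")]
        good = build_fit_spec(ModelSpec(terms=(S("x1"),)), preds, "y")
        bad = FitSpec(model=ModelSpec(terms=(FM("nope"),)), response="y",
                      factor_levels={"nope": ("a", "b")})
        records = fit_all([good, bad], simple_gaussian_data)
        assert [r.status for r in records] == ["ok", "failed"]


class TestDeterminismAndParallel:
    def test_identical_runs_are_identical(self, simple_gaussian_data):
        gam = FullSubsetsGAM(simple_gaussian_data, "y",
                             continuous=["x1", "x2"], factors=["f"])
        t1 = gam.fit().table
        t2 = FullSubsetsGAM(simple_gaussian_data, "y",
                            continuous=["x1", "x2"], factors=["f"]).fit().table
        pd.testing.assert_frame_equal(t1, t2)

    def test_parallel_equals_sequential(self, simple_gaussian_data):
        gam = FullSubsetsGAM(simple_gaussian_data, "y",
                             continuous=["x1", "x2"], factors=["f"])
        seq = gam.fit(parallel=False)
        par = gam.fit(parallel=True, n_jobs=2)
        pd.testing.assert_frame_equal(seq.table, par.table)
        for a, b in zip(seq.records, par.records):
            assert a.model_id == b.model_id and a.status == b.status
            if a.status == "ok":
                assert a.loglik == b.loglik
                np.testing.assert_array_equal(a.fitted, b.fitted)


class TestCrossCheckAgainstStatsmodels:
    def test_single_smooth_agrees_with_glmgam(self):
        # independent penalized-spline implementation (different basis and
        # penalty-selection code path) must give near-identical curves
        from statsmodels.gam.api import BSplines, GLMGam
        rng = np.random.default_rng(42)
        n = 250
        x = rng.uniform(-2, 2, n)
        y = np.sin(1.5 * x) + rng.normal(0, 0.3, n)
        data = pd.DataFrame({"x": x, "y": y})
        res = FullSubsetsGAM(data, "y", continuous=["x"],
                             max_predictors=1, k=8).fit()
        rec = res.record("s(x)")

        bs = BSplines(data[["x"]], df=[8], degree=[3])
        gam = GLMGam(data["y"], np.ones((n, 1)), smoother=bs)
        gam.fit()
        alpha = gam.select_penweight()[0]
        ref = GLMGam(data["y"], np.ones((n, 1)), smoother=bs,
                     alpha=alpha).fit()
        rmse = float(np.sqrt(np.mean((rec.fitted - ref.fittedvalues) ** 2)))
        assert rmse < 0.08  # well under the residual sd of 0.3
        ref_devexp = 1 - ref.deviance / ((y - y.mean()) ** 2).sum()
        assert rec.deviance_explained == pytest.approx(ref_devexp, abs=0.02)
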