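"""Clock application, training (MLR / PCA / KDM) and normalisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioage import (
    ClockDefinition,
    batch_center,
    fit_kdm,
    fit_mlr_clock,
    fit_pca_clock,
    impute_missing,
    inverse_age_transform,
    predict_clock,
    predict_kdm,
    read_clock,
    write_clock,
)
from bioage.errors import (
    DegenerateDataError,
    MissingFeatureError,
    SingularDesignError,
    UntrainableModelError,
)


def _meta(sample_ids, ca=50.0):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"S{i}" for i in range(n)],
            "visit": 1,
            "replicate_id": 0,
            "ca_years": ca,
        }
    )


class TestPredictClock:
    def test_linear_evaluation(self):
        clock = ClockDefinition("toy", "clinical", {"f1": 0.5, "f2": -1.0}, intercept=10.0)
        feats = pd.DataFrame({"f1": [4.0], "f2": [1.0]}, index=["s1"])
        out = predict_clock(clock, feats, _meta(["s1"]))
        assert out["ba_pred"].iloc[0] == pytest.approx(11.0)
        assert out["age_accel"].iloc[0] == pytest.approx(11.0 - 50.0)

    def test_constant_clock(self):
        clock = ClockDefinition("const", "clinical", {"f1": 0.0}, intercept=42.0)
        feats = pd.DataFrame({"f1": np.arange(5.0)}, index=[f"s{i}" for i in range(5)])
        out = predict_clock(clock, feats, _meta(feats.index))
        assert (out["ba_pred"] == 42.0).all()

    def test_log_linear_fixed_point(self):
        clock = ClockDefinition(
            "epi", "epigenetic", {"f1": 0.0}, intercept=0.0,
            transform="log_linear_age", adult_age=20.0,
        )
        feats = pd.DataFrame({"f1": [1.0]}, index=["s1"])
        out = predict_clock(clock, feats, _meta(["s1"]))
        assert out["ba_pred"].iloc[0] == pytest.approx(20.0)

    def test_affine_in_coefficients(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"],
                             index=[f"s{i}" for i in range(6)])
        w = {"a": 0.3, "b": -0.7, "c": 1.1}
        one = predict_clock(ClockDefinition("c1", "clinical", w, intercept=5.0),
                            feats, _meta(feats.index))
        two = predict_clock(
            ClockDefinition("c2", "clinical", {k: 2 * v for k, v in w.items()}, intercept=10.0),
            feats, _meta(feats.index),
        )
        assert np.allclose(two["ba_pred"], 2 * one["ba_pred"])


class TestInverseAgeTransform:
    @pytest.mark.parametrize(
        "score,adult_age,expected",
        [(0.0, 20.0, 20.0), (1.0, 20.0, 41.0), (-math.log(21), 20.0, 0.0)],
    )
    def test_known_values(self, score, adult_age, expected):
        assert inverse_age_transform(score, adult_age) == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        s1=st.floats(-5, 5), s2=st.floats(-5, 5),
        adult_age=st.floats(1.0, 90.0),
    )
    def test_strictly_monotone(self, s1, s2, adult_age):
        if abs(s1 - s2) < 1e-9:  # below float resolution of the transform
            return
        lo, hi = sorted([s1, s2])
        assert inverse_age_transform(lo, adult_age) < inverse_age_transform(hi, adult_age)

    def test_continuous_at_zero(self):
        for aa in (5.0, 20.0, 65.0):
            left = inverse_age_transform(-1e-9, aa)
            right = inverse_age_transform(1e-9, aa)
            assert right - left < 1e-6


class TestImputation:
    clock = ClockDefinition(
        "c", "clinical", {"f1": 1.0, "f2": 1.0, "f3": 1.0},
        reference_medians={"f3": 2.1, "f2": 0.5},
    )

    def test_fills_absent_column_with_median(self):
        feats = pd.DataFrame({"f1": [1.0], "f2": [1.0]}, index=["s"])
        out, n = impute_missing(feats, self.clock)
        assert out.loc["s", "f3"] == 2.1
        assert out.loc["s", "f1"] == 1.0
        assert n == 1

    def test_complete_vector_untouched(self):
        feats = pd.DataFrame({"f1": [1.0], "f2": [2.0], "f3": [3.0]}, index=["s"])
        out, n = impute_missing(feats, self.clock)
        assert n == 0
        pd.testing.assert_frame_equal(out, feats[["f1", "f2", "f3"]])

    def test_counts_two_imputations(self):
        feats = pd.DataFrame({"f1": [1.0]}, index=["s"])
        out, n = impute_missing(feats, self.clock)
        assert n == 2 and out.loc["s", "f2"] == 0.5 and out.loc["s", "f3"] == 2.1

    def test_uncovered_feature_raises_with_ids(self):
        clock = ClockDefinition("c", "clinical", {"f1": 1.0, "f9": 1.0})
        feats = pd.DataFrame({"f1": [1.0]}, index=["s"])
        with pytest.raises(MissingFeatureError) as err:
            impute_missing(feats, clock)
        assert "f9" in str(err.value)


class TestMLRClock:
    def test_noiseless_recovery(self):
        x1 = np.linspace(5, 15, 30)
        x2 = np.sin(x1)
        feats = pd.DataFrame({"x1": x1, "x2": x2}, index=[f"s{i}" for i in range(30)])
        ca = 2 * x1 + 30
        clock = fit_mlr_clock(feats, ca)
        assert clock.coefficients["x1"] == pytest.approx(2.0, abs=1e-8)
        assert clock.coefficients["x2"] == pytest.approx(0.0, abs=1e-8)
        assert clock.intercept == pytest.approx(30.0, abs=1e-8)
        assert clock.train_r2 == pytest.approx(1.0)

    def test_pure_noise_feature_near_zero_weight(self):
        rng = np.random.default_rng(4)
        n = 2000
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        ca = 50 + 3 * x1 + rng.normal(scale=0.5, size=n)
        feats = pd.DataFrame({"x1": x1, "junk": noise}, index=[f"s{i}" for i in range(n)])
        clock = fit_mlr_clock(feats, ca)
        # 3 SE of the junk coefficient ~ 3 * sigma/sqrt(n)
        assert abs(clock.coefficients["junk"]) < 3 * 0.5 / np.sqrt(n) * 1.5

    def test_idempotent_on_fitted_values(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"),
                             index=[f"s{i}" for i in range(40)])
        ca = rng.normal(50, 5, size=40)
        clock = fit_mlr_clock(feats, ca)
        fitted = predict_clock(clock, feats, _meta(feats.index))["ba_pred"]
        clock2 = fit_mlr_clock(feats, fitted)
        refit = predict_clock(clock2, feats, _meta(feats.index))["ba_pred"]
        assert np.allclose(fitted, refit, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        x = np.linspace(0, 1, 20)
        feats = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"s{i}" for i in range(20)])
        with pytest.raises(SingularDesignError):
            fit_mlr_clock(feats, x + 40)


class TestPCAClock:
    def test_single_feature_matches_age_moments(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        ca = 50 + 4 * x + rng.normal(scale=0.1, size=50)
        feats = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(50)])
        clock = fit_pca_clock(feats, ca)
        ba = predict_clock(clock, feats, _meta(feats.index))["ba_pred"]
        assert abs(np.corrcoef(ba, x)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert ba.mean() == pytest.approx(np.mean(ca), abs=1e-8)
        assert ba.std(ddof=1) == pytest.approx(np.std(ca, ddof=1), abs=1e-8)

    def test_training_mean_matches_ca_mean(self, clinical_training):
        x, ca = clinical_training
        clock = fit_pca_clock(x, ca)
        meta = _meta(x.index)
        ba = predict_clock(clock, x, meta)["ba_pred"]
        assert ba.mean() == pytest.approx(ca.mean(), abs=1e-8)

    def test_duplicated_feature_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        ca = 50 + 2 * x + rng.normal(scale=0.2, size=40)
        ids = [f"s{i}" for i in range(40)]
        solo = pd.DataFrame({"x": x}, index=ids)
        dup = pd.DataFrame({"x": x, "x2": x.copy()}, index=ids)
        ba1 = predict_clock(fit_pca_clock(solo, ca), solo, _meta(ids))["ba_pred"]
        ba2 = predict_clock(fit_pca_clock(dup, ca), dup, _meta(ids))["ba_pred"]
        assert np.allclose(ba1, ba2, atol=1e-8)

    def test_zero_variance_feature_rejected(self):
        feats = pd.DataFrame({"x": np.ones(10)}, index=[f"s{i}" for i in range(10)])
        with pytest.raises(DegenerateDataError):
            fit_pca_clock(feats, np.arange(10.0))


class TestKDM:
    def test_noiseless_parameters(self):
        ca = np.linspace(40, 60, 30)
        feats = pd.DataFrame({"x1": 0.5 * ca + 10}, index=[f"s{i}" for i in range(30)])
        model = fit_kdm(feats, ca)
        assert model.params.loc["x1", "k"] == pytest.approx(0.5, abs=1e-10)
        assert model.params.loc["x1", "q"] == pytest.approx(10.0, abs=1e-8)
        assert model.params.loc["x1", "s"] <= 1e-6

    def test_uninformative_biomarker_dropped(self):
        rng = np.random.default_rng(8)
        ca = np.linspace(40, 60, 200)
        feats = pd.DataFrame(
            {"good": 0.8 * ca + rng.normal(scale=1, size=200),
             "flat": rng.normal(scale=1, size=200)},
            index=[f"s{i}" for i in range(200)],
        )
        with pytest.warns(UserWarning, match="dropped"):
            model = fit_kdm(feats, ca)
        assert list(model.params.index) == ["good"]

    def test_all_uninformative_raises(self):
        rng = np.random.default_rng(9)
        ca = np.linspace(40, 60, 100)
        feats = pd.DataFrame({"flat": rng.normal(size=100)},
                             index=[f"s{i}" for i in range(100)])
        with pytest.raises(UntrainableModelError), pytest.warns(UserWarning):
            fit_kdm(feats, ca)

    def test_residual_sd_recovery(self):
        rng = np.random.default_rng(10)
        n = 500
        ca = rng.uniform(40, 60, size=n)
        s_true = {"a": 2.0, "b": 4.0}
        feats = pd.DataFrame(
            {"a": 1.0 * ca + rng.normal(scale=s_true["a"], size=n),
             "b": -0.7 * ca + 80 + rng.normal(scale=s_true["b"], size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        model = fit_kdm(feats, ca)
        for f, s in s_true.items():
            assert model.params.loc[f, "s"] == pytest.approx(s, rel=0.15)

    def test_hand_case_ba_ec(self):
        # two biomarkers k=1, q=0, s=1; x = (52, 48); CA = 49; s_BA = 2
        model_params = pd.DataFrame({"k": [1.0, 1.0], "q": [0.0, 0.0], "s": [1.0, 1.0]},
                                    index=["x1", "x2"])
        from bioage.clock_engine import KDMModel

        model = KDMModel("kdm", "clinical", model_params, s_ba=2.0, ca_range_train=(40, 60))
        feats = pd.DataFrame({"x1": [52.0], "x2": [48.0]}, index=["s"])
        out = predict_kdm(model, feats, _meta(["s"], ca=49.0))
        assert out["ba_pred"].iloc[0] == pytest.approx((52 + 48 + 49 / 4) / (2 + 0.25))
        assert round(out["ba_pred"].iloc[0], 2) == 49.89
        assert out["ba_e"].iloc[0] == pytest.approx(50.0)

    def test_noiseless_single_biomarker_returns_ca(self):
        ca = np.linspace(40, 60, 30)
        ids = [f"s{i}" for i in range(30)]
        feats = pd.DataFrame({"x1": 0.5 * ca + 10}, index=ids)
        model = fit_kdm(feats, ca)
        meta = _meta(ids)
        meta["ca_years"] = ca
        out = predict_kdm(model, feats, meta)
        assert np.allclose(out["ba_pred"], ca, atol=1e-5)

    def test_tight_anchor_pulls_to_ca(self):
        from bioage.clock_engine import KDMModel

        params = pd.DataFrame({"k": [1.0], "q": [0.0], "s": [1.0]}, index=["x"])
        model = KDMModel("kdm", "clinical", params, s_ba=1e-6, ca_range_train=(40, 60))
        feats = pd.DataFrame({"x": [90.0]}, index=["s"])
        out = predict_kdm(model, feats, _meta(["s"], ca=49.0))
        assert out["ba_pred"].iloc[0] == pytest.approx(49.0, abs=1e-6)

    def test_kdm_adds_information_beyond_ca(self):
        # features generated from latent BA = CA + offset: the anchored KDM
        # estimate should track latent BA at least as well as CA does
        rng = np.random.default_rng(11)
        n, p = 200, 10
        ca = rng.uniform(45, 60, size=n)
        latent = ca + rng.normal(scale=4.0, size=n)
        k = rng.uniform(0.5, 1.2, size=p)
        q = rng.uniform(10, 50, size=p)
        s = rng.uniform(1.0, 3.0, size=p)
        x = q + np.outer(latent, k) + rng.normal(scale=s, size=(n, p))
        feats = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)],
                             index=[f"s{i}" for i in range(n)])
        model = fit_kdm(feats, ca)
        meta = _meta(feats.index)
        meta["ca_years"] = ca
        out = predict_kdm(model, feats, meta)
        r_kdm = np.corrcoef(out["ba_pred"], latent)[0, 1]
        r_ca = np.corrcoef(ca, latent)[0, 1]
        assert r_kdm >= r_ca


class TestBatchCenter:
    def test_additive_shift_removed(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(10, 3))
        feats = pd.DataFrame(np.vstack([base, base + 5.0]), columns=list("abc"),
                             index=[f"s{i}" for i in range(20)])
        batches = np.repeat([1, 2], 10)
        out = batch_center(feats, batches)
        for col in "abc":
            m1 = out[col].iloc[:10].median()
            m2 = out[col].iloc[10:].median()
            assert m1 == pytest.approx(m2, abs=1e-10)

    def test_single_batch_noop(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=list("xyz"))
        out = batch_center(feats, [1, 1, 1])
        pd.testing.assert_frame_equal(out, feats)

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        feats = pd.DataFrame(rng.normal(size=(21, 2)), columns=list("ab"),
                             index=[f"s{i}" for i in range(21)])
        batches = np.repeat([1, 2, 3], 7)
        once = batch_center(feats, batches)
        twice = batch_center(once, batches)
        pd.testing.assert_frame_equal(once, twice)

    def test_rank_preserved_within_batch(self):
        rng = np.random.default_rng(14)
        feats = pd.DataFrame({"a": rng.normal(size=12)}, index=[f"s{i}" for i in range(12)])
        batches = np.repeat([1, 2], 6)
        out = batch_center(feats, batches)
        for b in (1, 2):
            idx = feats.index[batches == b]
            assert (feats.loc[idx, "a"].rank() == out.loc[idx, "a"].rank()).all()

    def test_tiny_batch_left_uncentered(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0, 10.0]}, index=list("wxyz"))
        with pytest.warns(UserWarning, match="< 2 samples"):
            out = batch_center(feats, [1, 1, 1, 2])
        assert out.loc["z", "a"] == 10.0


class TestClockIO:
    def _clock(self):
        return ClockDefinition(
            "demo", "proteomic", {"p1": 0.25, "p2": -1.5}, intercept=12.5,
            transform="log_linear_age", adult_age=20.0,
            reference_medians={"p2": 3.25},
        )

    @pytest.mark.parametrize("suffix", [".tsv", ".json"])
    def test_round_trip(self, tmp_path, suffix):
        clock = self._clock()
        path = tmp_path / f"demo{suffix}"
        write_clock(clock, path)
        back = read_clock(path)
        assert back.name == clock.name
        assert back.category == clock.category
        assert back.transform == clock.transform
        assert back.coefficients == pytest.approx(clock.coefficients)
        assert back.intercept == pytest.approx(clock.intercept)
        assert back.reference_medians == pytest.approx(clock.reference_medians)
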