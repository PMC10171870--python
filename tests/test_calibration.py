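"""Ratio calibration, tag-drug fitting and toxicity-normalizer tests."""

import numpy as np
import pandas as pd
import pytest

import stochmix as sx
from stochmix.calibration import (
    DEFAULT_CONTROL_CONC_UM,
    DEFAULT_PARTITION_SIZE,
    CalibrationUndefinedError,
)
from stochmix.experiments import codelivery_experiment, toxicity_control_experiment


def cells_with(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame({"cell_id": range(n), **cols})


class TestComputeRatios:
    def test_simple_ratio(self):
        c = cells_with(tag=[2.0], aux=[4.0])
        out = sx.compute_ratios(c, ["tag"], "aux")
        assert out["R_tag"].iloc[0] == 0.5

    def test_global_gain_invariance(self, rng):
        c = cells_with(tag=rng.lognormal(0, 1, 100), aux=rng.lognormal(0, 1, 100))
        base = sx.compute_ratios(c, ["tag"], "aux")
        scaled = c.copy()
        scaled[["tag", "aux"]] *= 10.0
        gained = sx.compute_ratios(scaled, ["tag"], "aux")
        np.testing.assert_allclose(base["R_tag"], gained["R_tag"])

    def test_nonpositive_auxiliary_excluded_with_count(self):
        c = cells_with(tag=[1.0, 2.0, 3.0], aux=[1.0, 0.0, 2.0])
        out = sx.compute_ratios(c, ["tag"], "aux")
        assert len(out) == 2
        assert out.attrs["n_aux_excluded"] == 1

    def test_shared_volume_factor_cancels_in_ratio(self, rng):
        # uptake proportional to cell volume for aux and tag: the ratio
        # removes the volume variability, so CV(R) << CV(raw tag)
        n = 10_000
        volume = rng.lognormal(0, 0.5, n)
        tag = volume * rng.lognormal(0, 0.1, n)
        aux = volume * rng.lognormal(0, 0.1, n)
        out = sx.compute_ratios(cells_with(tag=tag, aux=aux), ["tag"], "aux")
        cv_ratio = out["R_tag"].std() / out["R_tag"].mean()
        cv_raw = tag.std() / tag.mean()
        assert cv_ratio < 0.5 * cv_raw

    def test_missing_auxiliary_rejected(self):
        with pytest.raises(ValueError, match="auxiliary"):
            sx.compute_ratios(cells_with(tag=[1.0]), ["tag"], "aux")


class TestCalibrateToControl:
    def make_sample(self, rng, n=2000, factor=1.0):
        aux = rng.lognormal(0, 0.2, n)
        tag = factor * 0.5 * aux * rng.lognormal(0, 0.1, n)
        return cells_with(NC=tag, aux=aux)

    def test_self_calibration_mean_is_one(self, rng):
        control = self.make_sample(rng)
        ratios = sx.compute_ratios(control, ["NC"], "aux")
        out, cal = sx.calibrate_to_control(ratios, control, ["NC"], "aux")
        assert out["rel_NC"].mean() == pytest.approx(1.0, abs=0.01)

    def test_default_control_concentrations(self):
        assert DEFAULT_CONTROL_CONC_UM == {"NC": 1.0, "CP": 1.0, "TXT": 0.1}

    def test_twofold_sample_recovers_factor_two(self, rng):
        control = self.make_sample(rng, n=10_000)
        sample = self.make_sample(rng, n=10_000, factor=2.0)
        ratios = sx.compute_ratios(sample, ["NC"], "aux")
        out, _ = sx.calibrate_to_control(ratios, control, ["NC"], "aux")
        assert out["rel_NC"].mean() == pytest.approx(2.0, rel=0.05)
        assert out["conc_NC"].mean() == pytest.approx(2.0, rel=0.05)  # NC control 1 uM

    def test_small_control_rejected(self, rng):
        control = self.make_sample(rng, n=50)
        ratios = sx.compute_ratios(control, ["NC"], "aux")
        with pytest.raises(ValueError, match="control"):
            sx.calibrate_to_control(ratios, control, ["NC"], "aux")

    def test_zero_control_ratio_is_calibration_undefined(self, rng):
        control = cells_with(NC=np.zeros(200), aux=np.ones(200))
        ratios = sx.compute_ratios(control, ["NC"], "aux")
        with pytest.raises(CalibrationUndefinedError):
            sx.calibrate_to_control(ratios, control, ["NC"], "aux")


class TestFitTagDrug:
    def bins_from(self, x, y):
        table = pd.DataFrame(
            {
                "bin_id": range(len(x)),
                "count": [50] * len(x),
                "tag_mean": x,
                "tag_sd": 0.0,
                "drug_mean": y,
                "drug_sd": 0.0,
            }
        )
        return sx.BinnedData(table=table, total_n=50 * len(x), channels=["tag", "drug"])

    def test_exact_line_recovered(self):
        x = np.array([1.0, 2, 3, 4, 5])
        fit = sx.fit_tag_drug(self.bins_from(x, 2 * x + 1), "tag", "drug")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_loglog_slope_recovers_proportionality(self):
        cells = codelivery_experiment(seed=21)
        binned = sx.ordered_binning(cells, "tag", r=50)
        fit = sx.fit_tag_drug(binned, "tag", "drug", scale="log")
        assert fit.slope == pytest.approx(1.0, rel=0.05)

    def test_homogeneous_mean_point_inside_prediction_band(self):
        # the well-mixed sample's mean (tag, drug) point must sit in the
        # point-injection fit's 95% prediction band
        cells = codelivery_experiment(seed=22)
        binned = sx.ordered_binning(cells, "tag", r=50)
        fit = sx.fit_tag_drug(binned, "tag", "drug", scale="log")
        geom = sx.Geometry(2000.0, 2000.0, "adherent", 10.0)
        homog_cells = sx.seed_cells(5000, geom, seed=23)
        dose = float(cells["tag"].mean())
        fields = sx.homogeneous_field(["tag", "drug"], dose, geom)
        homog = sx.simulate_uptake(
            homog_cells, fields, geom, sx.UptakeModel(0.3, 0.0), 24
        )
        x0, y0 = homog["tag"].mean(), homog["drug"].mean()
        lo, hi = fit.bands(x0, kind="prediction")
        assert lo[0] <= y0 <= hi[0]

    def test_fit_predict_round_trip_reproduces_coefficients(self):
        x = np.array([1.0, 2, 4, 8, 16])
        fit = sx.fit_tag_drug(self.bins_from(x, 3 * x + 2), "tag", "drug")
        refit = sx.fit_tag_drug(
            self.bins_from(x, fit.predict(x)), "tag", "drug"
        )
        assert refit.slope == pytest.approx(fit.slope, rel=1e-9)
        assert refit.intercept == pytest.approx(fit.intercept, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        x = np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            sx.fit_tag_drug(self.bins_from(x, x), "tag", "drug")
        xc = np.ones(5)
        with pytest.raises(ValueError, match="variance"):
            sx.fit_tag_drug(self.bins_from(xc, xc), "tag", "drug")

    def test_confidence_band_covers_true_line(self):
        # repeated refits on noisy lines: 95% confidence band should cover
        # the true line at >= 90% of interior points
        rng = np.random.default_rng(99)
        x = np.linspace(1, 10, 20)
        trials = 500
        interior = x[5:15]
        truth = 2 * interior + 1
        covered = 0
        for _ in range(trials):
            y = 2 * x + 1 + rng.normal(0, 0.5, x.size)
            fit = sx.fit_tag_drug(self.bins_from(x, y), "tag", "drug")
            lo, hi = fit.bands(interior, kind="confidence")
            covered += int(((lo <= truth) & (truth <= hi)).sum())
        assert covered / (trials * interior.size) >= 0.90


class TestToxicityNormalizer:
    def test_constant_control_surface_recovered(self, rng):
        table = pd.DataFrame(
            {
                "bin_id": range(16),
                "count": [40] * 16,
                "t1_mean": np.repeat([1.0, 3, 10, 30], 4),
                "t1_sd": 0.0,
                "t2_mean": np.tile([1.0, 3, 10, 30], 4),
                "t2_sd": 0.0,
                "phenotype_mean": np.full(16, 5.0),
                "phenotype_sd": 0.0,
            }
        )
        bins = sx.BinnedData(table=table, total_n=640, channels=["t1", "t2", "phenotype"])
        norm = sx.fit_toxicity_normalizer(bins, "t1", "t2")
        pred = norm.predict(bins.mean("t1"), bins.mean("t2"))
        assert np.abs(pred / 5.0 - 1).max() < 0.02

    def test_known_toxicity_surface_recovered_within_5pct_rmse(self):
        ctrl = toxicity_control_experiment(seed=31)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        t1, t2 = bins.mean("QD605"), bins.mean("QD655")
        truth = 1 / (1 + (t1 / 0.3) ** 2) / (1 + (t2 / 0.3) ** 2)
        rmse = np.sqrt(np.mean((norm.predict(t1, t2) - truth) ** 2))
        assert rmse < 0.05

    def test_cross_validated_r2_on_control(self):
        ctrl = toxicity_control_experiment(seed=32)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        assert norm.cv_r_squared >= 0.9

    def test_json_round_trip_reproduces_predictions(self, tmp_path):
        ctrl = toxicity_control_experiment(seed=33, n=5000)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        path = tmp_path / "normalizer.json"
        norm.to_json(path)
        loaded = sx.ToxicityNormalizer.from_json(path)
        t1, t2 = bins.mean("QD605"), bins.mean("QD655")
        np.testing.assert_allclose(
            loaded.predict(t1, t2), norm.predict(t1, t2), rtol=1e-10
        )

    def test_too_few_bins_rejected(self):
        table = pd.DataFrame(
            {
                "bin_id": range(4),
                "count": [40] * 4,
                "t1_mean": [1.0, 2, 3, 4],
                "t1_sd": 0.0,
                "t2_mean": [1.0, 2, 3, 4],
                "t2_sd": 0.0,
                "phenotype_mean": [1.0] * 4,
                "phenotype_sd": 0.0,
            }
        )
        bins = sx.BinnedData(table=table, total_n=160, channels=[])
        with pytest.raises(ValueError):
            sx.fit_toxicity_normalizer(bins, "t1", "t2")


class TestNormalizePhenotype:
    def test_self_normalization_is_unity(self):
        ctrl = toxicity_control_experiment(seed=41)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        out = sx.normalize_phenotype(bins, norm)
        vals = out.table.loc[~out.table["extrapolated"], "phenotype_norm"]
        assert np.abs(vals - 1).max() < 0.1

    def test_null_effect_treated_sample_normalizes_to_one(self):
        ctrl = toxicity_control_experiment(seed=42)
        treated = toxicity_control_experiment(seed=1042)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        tb = sx.mesh_binning_2d(treated, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        out = sx.normalize_phenotype(tb, norm)
        vals = out.table.loc[~out.table["extrapolated"], "phenotype_norm"]
        assert np.abs(vals - 1).max() < 0.1

    def test_known_repression_factor_recovered(self):
        # treated = control phenotype scaled by 0.4: normalization returns 0.4
        ctrl = toxicity_control_experiment(seed=43)
        bins = sx.mesh_binning_2d(ctrl, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        norm = sx.fit_toxicity_normalizer(bins, "QD605", "QD655")
        treated = toxicity_control_experiment(seed=1043)
        treated["phenotype"] *= 0.4
        tb = sx.mesh_binning_2d(treated, "QD605", "QD655", sx.BinScheme(sparse="drop"))
        out = sx.normalize_phenotype(tb, norm)
        vals = out.table.loc[~out.table["extrapolated"], "phenotype_norm"]
        assert np.abs(vals / 0.4 - 1).max() < 0.1


class TestPopulationMeanWithError:
    def test_constant_data_zero_sd(self):
        c = cells_with(a=np.full(500, 3.0))
        mean, sd = sx.population_mean_with_error(c, "a", seed=0)
        assert mean == 3.0
        assert sd == 0.0

    def test_default_partition_size_is_100(self):
        assert DEFAULT_PARTITION_SIZE == 100

    def test_group_mean_sd_matches_clt(self, rng):
        c = cells_with(a=rng.normal(10.0, 2.0, 10_000))
        _, sd = sx.population_mean_with_error(c, "a", partition_size=100, seed=1)
        assert sd == pytest.approx(2.0 / 10.0, rel=0.20)

    def test_k_groups_mode(self, rng):
        c = cells_with(a=rng.normal(0.0, 1.0, 900))
        mean, sd = sx.population_mean_with_error(c, "a", n_groups=3, seed=2)
        assert np.isfinite(sd) and sd > 0

    def test_insufficient_cells_rejected(self):
        c = cells_with(a=np.arange(50.0))
        with pytest.raises(ValueError):
            sx.population_mean_with_error(c, "a", partition_size=100)
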