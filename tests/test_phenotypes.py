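"""Tests for the feed-efficiency phenotype derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedquant import phenotypes as ph
from feedquant import simulate as sm


def _records(bird, dots, bws, fis=None, sex="M", pen="M1"):
    fis = fis if fis is not None else [50.0] * len(dots)
    return pd.DataFrame(
        {
            "bird_id": bird,
            "sex": sex,
            "pen": pen,
            "dot": dots,
            "bw_g": bws,
            "fi_g": fis,
        }
    )


class TestGrowthLine:
    def test_exact_line(self):
        fit = ph.fit_growth_line(_records(1, [1, 2, 3], [100, 110, 120]), 1)
        assert fit.intercept == pytest.approx(90.0)
        assert fit.slope == pytest.approx(10.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_ols(self):
        # Sxy = 18, Sxx = 2 -> slope 9, intercept 110 - 9*2 = 92
        fit = ph.fit_growth_line(_records(1, [1, 2, 3], [100, 112, 118]), 1)
        assert fit.slope == pytest.approx(9.0)
        assert fit.intercept == pytest.approx(92.0)

    def test_repeated_single_dot_rejected(self):
        with pytest.raises(ph.DegenerateGrowthData):
            ph.fit_growth_line(_records(1, [5, 5, 5], [100, 101, 99]), 1)


class TestMidtestWeights:
    def test_linear_prediction(self):
        fit = ph.GrowthFit(1, 90.0, 10.0, 0.0, 10)
        mbw, mmbw = ph.midtest_weights(fit, mid_dot=25)
        assert mbw == pytest.approx(340.0)
        assert mmbw == pytest.approx(340.0**0.75)
        assert mmbw == pytest.approx(79.18, abs=0.01)

    def test_unit_weight_fixed_point(self):
        fit = ph.GrowthFit(1, 1.0, 0.0, 0.0, 10)
        assert ph.midtest_weights(fit)[1] == pytest.approx(1.0)

    def test_nonphysical_trajectory_rejected(self):
        fit = ph.GrowthFit(1, 10.0, -5.0, 0.0, 10)
        with pytest.raises(ValueError, match="nonphysical"):
            ph.midtest_weights(fit, mid_dot=25)


class TestADFIandFCR:
    @pytest.mark.parametrize(
        "fis, expected",
        [([10.0, 20.0, 30.0], 20.0), ([0.0, 0.0, 0.0], 0.0)],
    )
    def test_adfi_is_mean_daily_intake(self, fis, expected):
        rec = _records(1, [1, 2, 3], [100, 110, 120], fis)
        assert ph.compute_adfi(rec, 1) == pytest.approx(expected)

    def test_fcr_examples(self):
        assert ph.compute_fcr(3000, 500, 1500) == pytest.approx(3.0)
        assert ph.compute_fcr(0, 500, 1500) == pytest.approx(0.0)
        # female start/end mean body weights, 671 -> 1632 g
        assert ph.compute_fcr(3780, 671, 1632) == pytest.approx(3.93, abs=0.005)

    def test_fcr_nonpositive_gain_flagged_missing(self):
        assert np.isnan(ph.compute_fcr(3000, 1500, 1500))
        assert np.isnan(ph.compute_fcr(3000, 1500, 1400))

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_fcr_scales_linearly_with_intake(self, fi, gain):
        one = ph.compute_fcr(fi, 0.0, gain)
        two = ph.compute_fcr(2 * fi, 0.0, gain)
        assert two == pytest.approx(2 * one, rel=1e-9)


def _factorial_phenotypes():
    # 2x2 factorial in MMBW and ADG; residual (+1,-1,-1,+1) is orthogonal to
    # both regressors and the intercept, so OLS recovers (1, 0.4, 1.0) exactly
    mmbw = np.array([100.0, 100.0, 120.0, 120.0])
    adg = np.array([10.0, 14.0, 10.0, 14.0])
    resid = np.array([1.0, -1.0, -1.0, 1.0])
    adfi = 1.0 + 0.4 * mmbw + 1.0 * adg + resid
    return (
        pd.DataFrame(
            {"sex": "M", "MMBW": mmbw, "ADG": adg, "ADFI": adfi},
            index=pd.Index([1, 2, 3, 4], name="bird_id"),
        ),
        resid,
    )


class TestEFIModel:
    def test_factorial_design_recovers_coefficients_exactly(self):
        pheno, resid = _factorial_phenotypes()
        model = ph.fit_efi_model(pheno, "M")
        assert model.b0 == pytest.approx(1.0)
        assert model.b1 == pytest.approx(0.4)
        assert model.b2 == pytest.approx(1.0)
        out = ph.compute_rfi(pheno, model)
        np.testing.assert_allclose(out["RFI"], resid, atol=1e-9)
        np.testing.assert_allclose(out["ADFI"], out["EFI"] + out["RFI"])

    def test_exact_plane_gives_r2_one_and_zero_rfi(self):
        pheno, _ = _factorial_phenotypes()
        pheno["ADFI"] = 2.0 + 0.3 * pheno["MMBW"] + 0.9 * pheno["ADG"]
        model = ph.fit_efi_model(pheno, "M")
        assert model.r_squared == pytest.approx(1.0)
        out = ph.compute_rfi(pheno, model)
        np.testing.assert_allclose(out["RFI"], 0.0, atol=1e-9)

    def test_underdetermined_and_collinear_rejected(self):
        pheno, _ = _factorial_phenotypes()
        with pytest.raises(ValueError, match=">= 4 birds"):
            ph.fit_efi_model(pheno.iloc[:3], "M")
        collinear = pheno.copy()
        collinear["ADG"] = 2.0 * collinear["MMBW"]
        with pytest.raises(ValueError, match="condition number"):
            ph.fit_efi_model(collinear, "M")

    def test_published_coefficient_arithmetic(self):
        # male expected-intake coefficients: EFI = 0.381*MMBW + 1.09*ADG - 5.14
        model = ph.EFIModel("M", -5.14, 0.381, 1.09, 0.41, 100)
        pheno = pd.DataFrame(
            {"sex": ["M"], "MMBW": [100.0], "ADG": [20.0], "ADFI": [60.0]},
            index=pd.Index([1], name="bird_id"),
        )
        out = ph.compute_rfi(pheno, model)
        assert out.loc[1, "EFI"] == pytest.approx(54.76)
        assert out.loc[1, "RFI"] == pytest.approx(5.24)

    def test_wrong_sex_rejected(self):
        pheno, _ = _factorial_phenotypes()
        model = ph.fit_efi_model(pheno, "M")
        with pytest.raises(ValueError, match="sex"):
            ph.compute_rfi(pheno.assign(sex="F"), ph.EFIModel(
                "X", model.b0, model.b1, model.b2, model.r_squared, model.n_birds
            ))


class TestDerivedInvariants:
    def test_identity_and_orthogonality(self, small_phenotypes):
        pheno, _ = small_phenotypes
        np.testing.assert_allclose(
            pheno["ADFI"], pheno["EFI"] + pheno["RFI"], rtol=0, atol=1e-9
        )
        for sex, sub in pheno.groupby("sex"):
            assert abs(sub["RFI"].mean()) < 1e-8
            assert abs(np.corrcoef(sub["RFI"], sub["MMBW"])[0, 1]) < 1e-8
            assert abs(np.corrcoef(sub["RFI"], sub["ADG"])[0, 1]) < 1e-8

    def test_zero_noise_closure(self):
        cfg = sm.default_config(seed=11)
        cfg.n_birds_target = 200
        cfg.bw_noise_sd = 0.0
        cfg.fi_noise_sd = 0.0
        cfg.loci = []
        pop = sm.simulate_population(cfg)
        pheno, models = ph.derive_phenotypes(pop.records)
        latent = pop.true_values.latent.loc[pheno.index]
        np.testing.assert_allclose(pheno["ADG"], latent["ADG"], atol=1e-9)
        np.testing.assert_allclose(pheno["BW8"], latent["BW8"], atol=1e-8)
        # derived RFI differs from latent RFI only through the refitted
        # regression absorbing the finite-sample mean of the latent RFI
        for sex, sub in pheno.groupby("sex"):
            r = np.corrcoef(sub["RFI"], latent.loc[sub.index, "RFI"])[0, 1]
            assert r > 0.99

    def test_short_records_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        good = _records(1, [1, 2, 3, 4], [100, 110, 120, 130])
        bad = _records(2, [1, 2], [100, 110])
        # varied slopes/intercepts/intakes keep the EFI regression well posed
        more = pd.concat(
            [good, bad]
            + [
                _records(
                    i,
                    [1, 2, 3, 4],
                    list(100 + 3 * i + (8 + i + rng.normal(0, 0.5)) * np.arange(1, 5)),
                    fis=list(rng.normal(50 + i, 2, 4)),
                )
                for i in range(3, 9)
            ]
        )
        with pytest.warns(UserWarning, match="skipping bird"):
            pheno, _ = ph.derive_phenotypes(more)
        assert 2 not in pheno.index


class TestDecileContrast:
    def _pheno(self, n=100, rng=None):
        rng = rng or np.random.default_rng(0)
        rfi = np.arange(1.0, n + 1)
        return pd.DataFrame(
            {"sex": "M", "RFI": rfi, "trait": rfi.copy()},
            index=pd.Index(range(n), name="bird_id"),
        )

    def test_groups_and_difference(self):
        contrast = ph.decile_contrast(self._pheno(), traits=["RFI", "trait"])
        row = contrast.loc["trait"]
        assert row["n_per_group"] == 10
        assert row["mean_high"] == pytest.approx(95.5)
        assert row["mean_low"] == pytest.approx(5.5)
        assert row["difference"] == pytest.approx(90.0)

    def test_identical_trait_p_near_one(self):
        pheno = self._pheno()
        pheno["flat"] = 1.0
        contrast = ph.decile_contrast(pheno, traits=["flat"])
        assert contrast.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        pheno = self._pheno()
        noise = rng.normal(0, 1.0, len(pheno))
        pheno["shifted"] = noise + np.where(pheno["RFI"] > 90, 10.0, 0.0)
        contrast = ph.decile_contrast(pheno, traits=["shifted"])
        assert contrast.loc["shifted", "p_value"] < 0.01

    def test_too_few_birds_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            ph.decile_contrast(self._pheno(n=15))
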