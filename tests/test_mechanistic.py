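"""Gill-diffusion, partitioning and hepatic clearance layer against the
published ten-surfactant dataset."""

import numpy as np
import pytest

from surfbcf import (
    ChemicalProperties,
    FishPhysiology,
    baseline_screening_bcf,
    clearance_dataset,
    diffusion_coefficient,
    fish_water_ratio,
    fit_clearance_model,
    gill_area_allometric,
    gill_elimination_k2,
    kb_from_kinetics,
    loglog_ols,
    mechanistic_result,
    predict_kb,
    reference_table,
)

PHYS = FishPhysiology()


class TestDiffusionCoefficient:
    def test_tridecylsulfonate_matches_published(self):
        d = diffusion_coefficient(0.25, 4.46, PHYS)
        assert d == pytest.approx(3.5e-8, rel=0.05)

    def test_doubling_area_halves_d(self):
        big = FishPhysiology(gill_area_m2=2 * PHYS.gill_area_m2)
        assert diffusion_coefficient(0.25, 4.46, big) == pytest.approx(
            diffusion_coefficient(0.25, 4.46, PHYS) / 2
        )

    def test_d_ratio_independent_of_area_matches_published(self):
        """D(DOSS)/D(C13SO3) from printed k_U and logD eliminates A."""
        ratio = (0.090 / 10**4.58) / (0.25 / 10**4.46)
        assert ratio == pytest.approx(9.3e-9 / 3.5e-8, rel=0.05)
        for area in (3e-3, 5.9e-3, 9e-3):
            phys = FishPhysiology(gill_area_m2=area)
            r = diffusion_coefficient(0.090, 4.58, phys) / \
                diffusion_coefficient(0.25, 4.46, phys)
            assert r == pytest.approx(ratio, rel=1e-12)

    def test_all_published_d_within_10_percent(self):
        ref = reference_table().dropna(subset=["k_u"])
        for cid, row in ref.iterrows():
            d = diffusion_coefficient(row["k_u"], row["log_dmlw"], PHYS)
            assert d == pytest.approx(row["d"], rel=0.10), cid


class TestPartitioning:
    def test_fish_water_ratio_arithmetic(self):
        assert fish_water_ratio(4.0, 0.0125) == pytest.approx(125.0)
        assert fish_water_ratio(4.0, 0.0) == 0.0

    def test_monotone_in_log_dmlw(self):
        vals = [fish_water_ratio(x) for x in np.linspace(3, 7, 9)]
        assert np.all(np.diff(vals) > 0)

    def test_baseline_bcf_equals_fish_water_ratio(self):
        assert baseline_screening_bcf(6.19) == fish_water_ratio(6.19)
        assert baseline_screening_bcf(6.19) == pytest.approx(1.94e4, rel=0.01)

    def test_baseline_exceeds_measured_by_1_to_2p5_orders(self):
        """Every measured BCF lies 1-2.5 orders below its partitioning
        ceiling, the signature of biotransformation-dominated loss."""
        ref = reference_table()
        excess = np.log10(
            np.array([baseline_screening_bcf(x) for x in ref["log_dmlw"]])
            / ref["bcf"].to_numpy()
        )
        assert excess.min() >= 1.0
        assert excess.max() <= 2.55  # printed-precision bound


class TestGillElimination:
    def test_published_spot_values(self):
        assert gill_elimination_k2(0.25, 4.46) == pytest.approx(
            0.00071, rel=0.03
        )
        assert gill_elimination_k2(6.3, 6.19) == pytest.approx(
            0.00033, rel=0.03
        )

    def test_doubling_f_mlf_halves_k2(self):
        assert gill_elimination_k2(0.25, 4.46, 0.025) == pytest.approx(
            gill_elimination_k2(0.25, 4.46, 0.0125) / 2
        )

    def test_k2_identical_to_diffusion_form(self):
        """k_U/(f_MLF·D_MLW) equals the gill-equation first term
        D·ρ_M·A·1000/(M·f_MLF) computed through D."""
        for k_u, logd in [(0.25, 4.46), (6.3, 6.19), (0.090, 4.58)]:
            d = diffusion_coefficient(k_u, logd, PHYS)
            via_d = (
                d * PHYS.membrane_density * PHYS.gill_area_m2 * 1000
                / (PHYS.mass_kg * PHYS.f_mlf)
            )
            assert gill_elimination_k2(k_u, logd, PHYS.f_mlf) == \
                pytest.approx(via_d, rel=1e-12)

    def test_kb_from_kinetics(self):
        kb, clamped = kb_from_kinetics(0.178, 0.00076)
        assert kb == pytest.approx(0.177, rel=0.005) and not clamped
        assert kb_from_kinetics(0.05, 0.0) == (0.05, False)
        with pytest.warns(UserWarning):
            kb, clamped = kb_from_kinetics(0.001, 0.002)
        assert kb == 0.0 and clamped

    def test_biotransformation_dominates_gill_elimination(self):
        """k_B-BCF is at least an order of magnitude above k_2 for every
        kinetically quantifiable chemical."""
        ref = reference_table().dropna(subset=["kb_bcf"])
        assert (ref["kb_bcf"] >= 10 * ref["k2"]).all()


class TestRegressions:
    def test_bcf_dmlw_regression_matches_published(self):
        ref = reference_table()
        slope, _, r2 = loglog_ols(ref["log_dmlw"], np.log10(ref["bcf"]))
        assert r2 == pytest.approx(0.96, abs=0.01)
        assert 10**slope == pytest.approx(25.0, rel=0.10)

    def test_ku_dmlw_slope_excluding_doss(self):
        ref = reference_table()
        m = ref["k_u"].notna() & (ref.index != "DOSS")
        slope, _, _ = loglog_ols(
            ref.loc[m, "log_dmlw"], np.log10(ref.loc[m, "k_u"])
        )
        assert slope == pytest.approx(0.89, abs=0.02)

    def test_collinear_input_r2_one(self):
        x = np.array([1.0, 2, 3, 4])
        slope, icpt, r2 = loglog_ols(x, 2.0 * x + 1.0)
        assert (slope, icpt, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            loglog_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClearanceModel:
    def test_self_consistency_on_exact_model_data(self):
        a, b = 4.0, 2e-4
        dmlw = 10 ** np.linspace(3, 6.5, 12)
        kb = 1 / (a + b * dmlw)
        fit = fit_clearance_model(dmlw, kb)
        assert fit.rmse_log == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(a, rel=1e-3)
        assert fit.b == pytest.approx(b, rel=1e-3)

    def test_published_dataset_rmse(self):
        cd = clearance_dataset()
        fit = fit_clearance_model(10 ** cd["log_dmlw"], cd["kb"])
        assert fit.rmse_log == pytest.approx(0.18, abs=0.05)

    def test_asymptotic_regimes(self):
        cd = clearance_dataset()
        fit = fit_clearance_model(10 ** cd["log_dmlw"], cd["kb"])
        # low D_MLW: constant at 1/a
        assert predict_kb(-10.0, fit) == pytest.approx(1 / fit.a, rel=1e-6)
        # high D_MLW: kb ∝ 1/D_MLW (slope -1 on the log-log scale)
        hi = np.array([9.0, 10.0])
        lk = np.log10(predict_kb(hi, fit))
        assert (lk[1] - lk[0]) == pytest.approx(-1.0, abs=1e-3)

    def test_predict_kb_strictly_decreasing(self):
        cd = clearance_dataset()
        fit = fit_clearance_model(10 ** cd["log_dmlw"], cd["kb"])
        vals = predict_kb(np.linspace(2, 7, 21), fit)
        assert np.all(np.diff(vals) < 0)

    def test_fit_invariant_to_input_order(self):
        cd = clearance_dataset()
        fit1 = fit_clearance_model(10 ** cd["log_dmlw"], cd["kb"])
        perm = np.random.default_rng(1).permutation(len(cd))
        fit2 = fit_clearance_model(
            10 ** cd["log_dmlw"].to_numpy()[perm], cd["kb"].to_numpy()[perm]
        )
        assert fit1.a == pytest.approx(fit2.a, rel=1e-6)
        assert fit1.b == pytest.approx(fit2.b, rel=1e-6)

    def test_leave_one_out_predictions_within_half_log_unit(self):
        cd = clearance_dataset()
        dmlw = 10 ** cd["log_dmlw"].to_numpy()
        kb = cd["kb"].to_numpy()
        for i in range(len(cd)):
            mask = np.arange(len(cd)) != i
            fit = fit_clearance_model(dmlw[mask], kb[mask])
            pred = predict_kb(np.log10(dmlw[i]), fit)
            assert abs(np.log10(pred / kb[i])) < 0.5


def test_mechanistic_result_bundles_consistently():
    chem = ChemicalProperties(chem_id="C13SO3", log_dmlw=4.46)
    res = mechanistic_result(chem, 0.25, 0.057, PHYS)
    assert res.kb_bcf == pytest.approx(0.056, rel=0.02)
    assert res.baseline_bcf == res.d_fw
    assert not res.kb_clamped


def test_gill_area_allometric_matches_default_at_reference_mass():
    assert gill_area_allometric(0.024) == pytest.approx(5.9e-3, rel=0.02)
    assert gill_area_allometric(0.048) > gill_area_allometric(0.024)
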