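"""S9 depletion fitting, detection-floor rule, IVIVE scaling."""

import numpy as np
import pytest

from surfbcf import (
    DepletionAssay,
    IviveParams,
    apply_ll_rule,
    compare_conditions,
    estimate_ll_s9,
    fit_depletion,
    ivive,
)

TIMES6 = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)


def _assay(times, concs, chem_id="X", condition="single"):
    return DepletionAssay(
        chem_id=chem_id, times=tuple(times), concs=tuple(concs),
        condition=condition,
    )


class TestFitDepletion:
    def test_exact_exponential_recovered(self):
        t = np.array(TIMES6)
        c = 100.0 * np.exp(-0.1 * t)
        fit = fit_depletion(_assay(t, c))
        assert fit.k_dep == pytest.approx(0.1, rel=1e-9)
        assert fit.p_value < 1e-6
        assert fit.significant

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_depletion(_assay(TIMES6, (1.0, 0.9, 0.0, 0.7, 0.6, 0.5)))

    def test_type_I_error_near_alpha(self, rng):
        """Flat series with noise is called non-significant >=90% of reps."""
        t = np.tile(TIMES6, 2)
        false_pos = 0
        for _ in range(200):
            c = 100.0 * np.exp(0.05 * rng.standard_normal(t.size))
            false_pos += fit_depletion(_assay(t, c)).significant
        assert false_pos / 200 <= 0.10

    def test_power_k005_cv10_recovered_within_20_percent(self, rng):
        t = np.tile(np.array(TIMES6) * 8, 2)  # 0-24 h incubation
        hits = 0
        for _ in range(200):
            c = 100.0 * np.exp(-0.05 * t) * np.exp(
                0.1 * rng.standard_normal(t.size)
            )
            fit = fit_depletion(_assay(t, c))
            hits += abs(fit.k_dep / 0.05 - 1) < 0.20
        assert hits / 200 >= 0.90


class TestLlRule:
    params = IviveParams(ll_s9=0.006)

    def test_significant_fit_unchanged(self):
        fit = fit_depletion(
            _assay(TIMES6, 100.0 * np.exp(-0.5 * np.array(TIMES6)))
        )
        fit.kb_s9 = 0.123
        assert apply_ll_rule(fit, self.params).kb_s9 == 0.123

    def test_nonsignificant_reported_at_ll_over_3(self, rng):
        c = 100.0 * np.exp(0.05 * rng.standard_normal(len(TIMES6)))
        fit = fit_depletion(_assay(TIMES6, c))
        assert not fit.significant
        out = apply_ll_rule(fit, self.params)
        assert out.kb_s9 == pytest.approx(0.002)
        assert out.ll_applied

    def test_ll_value_independent_of_fitted_slope(self, rng):
        outs = []
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            c = 100.0 * np.exp(0.05 * r.standard_normal(len(TIMES6)))
            fit = fit_depletion(_assay(TIMES6, c))
            if not fit.significant:
                outs.append(apply_ll_rule(fit, self.params).kb_s9)
        assert all(v == pytest.approx(0.002) for v in outs)


class TestIvive:
    params = IviveParams()

    def test_zero_depletion_maps_to_zero(self):
        assert ivive(0.0, 1e4, self.params) == 0.0

    def test_closed_form_oracle_equivalence(self):
        """The pipeline equals the independently hand-composed formula to
        1e-12 relative."""
        p = IviveParams(
            s9_protein_assay=2.0, liver_s9_yield=120.0,
            liver_mass_frac=0.015, v_d=1.4, f_mlb=0.003, q_b=0.06,
            ll_s9=0.005,
        )
        k_dep, dmlw = 0.3, 10**4.5
        cl_int = (0.3 / 2.0) * 120.0 * 0.015
        fu = 1.0 / (0.003 * dmlw)
        cl_h = 0.06 * fu * cl_int / (0.06 + fu * cl_int)
        expected = cl_h / 1.4
        assert ivive(k_dep, dmlw, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_k_dep_and_flow_ceiling(self):
        ks = np.linspace(0.0, 50.0, 40)
        vals = np.array([ivive(k, 1e4, self.params) for k in ks])
        assert np.all(np.diff(vals) > 0)
        ceiling = self.params.q_b / self.params.v_d
        assert np.all(vals <= ceiling)
        # clearance-limited regime is linear in k_dep
        low = np.array([ivive(k, 1e4, self.params) for k in (1e-6, 2e-6)])
        assert low[1] / low[0] == pytest.approx(2.0, rel=1e-3)

    def test_nonincreasing_in_dmlw(self):
        vals = [
            ivive(0.3, d, self.params) for d in 10 ** np.linspace(3, 7, 9)
        ]
        assert np.all(np.diff(vals) <= 0)

    def test_binding_mode_requires_dmlw(self):
        with pytest.raises(ValueError):
            ivive(0.3, None, self.params)

    def test_audit_trail_records_every_factor(self):
        audit = []
        ivive(0.3, 1e4, self.params, audit=audit)
        assert set(audit[0]) == {
            "k_dep", "cl_per_mg_protein", "cl_int_L_h_kg", "free_fraction",
            "cl_hepatic_L_h_kg", "kb_s9",
        }


class TestCompareConditions:
    def test_identical_inputs_no_difference(self):
        t = np.array(TIMES6)
        c = 100.0 * np.exp(-0.2 * t)
        a = _assay(t, c)
        b = _assay(t, c, condition="mixture")
        diff, p = compare_conditions(a, b)
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_sign_flips_with_argument_order(self, rng):
        t = np.tile(TIMES6, 2)
        c1 = 100.0 * np.exp(-0.3 * t) * np.exp(
            0.05 * rng.standard_normal(t.size)
        )
        c2 = 100.0 * np.exp(-0.15 * t) * np.exp(
            0.05 * rng.standard_normal(t.size)
        )
        d12, p12 = compare_conditions(_assay(t, c1), _assay(t, c2))
        d21, p21 = compare_conditions(_assay(t, c2), _assay(t, c1))
        assert d12 == -d21
        assert p12 == p21

    def test_mismatched_chemicals_rejected(self):
        t = np.array(TIMES6)
        c = 100.0 * np.exp(-0.2 * t)
        with pytest.raises(ValueError):
            compare_conditions(_assay(t, c, "A"), _assay(t, c, "B"))

    def test_twofold_slower_mixture_detected(self, rng):
        """A halved depletion rate at CV 10% is detected in >=80% of reps."""
        t = np.tile(np.array(TIMES6) * 4, 2)
        detected = 0
        for _ in range(200):
            single = 100.0 * np.exp(-0.2 * t) * np.exp(
                0.1 * rng.standard_normal(t.size)
            )
            mixture = 100.0 * np.exp(-0.1 * t) * np.exp(
                0.1 * rng.standard_normal(t.size)
            )
            diff, p = compare_conditions(
                _assay(t, single), _assay(t, mixture, condition="mixture")
            )
            detected += (p < 0.05) and (diff > 0)
        assert detected / 200 >= 0.80


def test_estimate_ll_s9_scales_with_noise_and_design():
    t = np.array(TIMES6)
    low = estimate_ll_s9(0.05, t)
    high = estimate_ll_s9(0.10, t)
    assert high == pytest.approx(2 * low, rel=1e-9)
    denser = estimate_ll_s9(0.05, np.linspace(0, 3, 12))
    assert denser < low
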