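"""Chemical activity terms, crowding factor and the TPM<->CBM equivalence."""

import math

import numpy as np
import pytest

from crowdspt import (
    CBMParams,
    SolutionState,
    TPMParams,
    cbm_chem_log_activity,
    contact_value_g0max,
    crowding_factor,
    model_equivalence_K_of_epsilon,
    sphere_geometry,
    steric_log_activity,
    total_log_activity,
    tpm_chem_log_activity,
)

SIGMA = 3.6


def _tpm(eps):
    return TPMParams.for_crystallin(eps, SIGMA)


class TestTPMChemical:
    def test_no_attraction(self, state02):
        assert tpm_chem_log_activity(_tpm(0.0), state02) == 0.0

    def test_dilute_limit(self):
        assert tpm_chem_log_activity(_tpm(13.9), SolutionState(0.0)) == 0.0

    def test_scalar_product_oracle(self, state02):
        # each factor evaluated independently: -rho * eps * S * [dr + (g-1)theta]
        rho = 6 * 0.2 / (math.pi * SIGMA**3)
        eps = 13.9
        s_area = math.pi * SIGMA**2
        dr = 0.2 * SIGMA
        theta = (2 ** (1 / 6) - 1) * SIGMA / 2
        g = 0.9 / 0.512
        expected = -rho * eps * s_area * (dr + (g - 1) * theta)
        assert tpm_chem_log_activity(_tpm(eps), state02) == pytest.approx(expected, rel=1e-14)

    def test_bracket_grouping(self):
        # the attraction-range term dr and the correlation correction
        # (g0max-1)*theta add inside the bracket multiplying -rho*eps*S
        p = _tpm(1.0)
        for phi in (0.05, 0.2, 0.35):
            st = SolutionState(phi)
            val = tpm_chem_log_activity(p, st)
            bracket = -val / (st.number_density * p.epsilon * p.surface_area)
            assert bracket - p.attraction_range == pytest.approx(
                (contact_value_g0max(phi) - 1) * p.decay_range, rel=1e-12
            )

    def test_nonpositive_and_linear_in_epsilon(self, state02):
        vals = [tpm_chem_log_activity(_tpm(e), state02) for e in (0.0, 5.0, 10.0, 20.0)]
        assert all(v <= 0 for v in vals)
        assert np.all(np.diff(vals) < 0)
        assert vals[3] == pytest.approx(2 * vals[2], rel=1e-12)

    def test_default_ranges(self):
        p = _tpm(1.0)
        assert p.attraction_range == pytest.approx(0.2 * SIGMA, rel=1e-14)
        assert p.decay_range == pytest.approx((2 ** (1 / 6) - 1) * SIGMA / 2, rel=1e-14)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            _tpm(-1.0)


class TestCBMChemical:
    def test_zero_binding(self, state02, reactant, product):
        p = CBMParams.for_crystallin(2.0, 0.0)
        triplet = (1.0, 1.0, 1.5)
        assert cbm_chem_log_activity(p, 2.0, state02, triplet) == 0.0

    def test_dilute_limit(self):
        p = CBMParams.for_crystallin(2.0, 10.6)
        assert cbm_chem_log_activity(p, 2.0, SolutionState(0.0), (1.0, 1.0, 1.5)) == 0.0

    def test_chained_steric_oracle(self, state02, reactant, product):
        # chain the independently summed steric values through the binding term
        ln_r = steric_log_activity(reactant, state02)
        ln_p = steric_log_activity(product, state02)
        expected = -2.0 * math.log(1 + 10.6 * math.exp(2 * ln_r - ln_p) * 0.2)
        p = CBMParams.for_crystallin(2.0, 10.6)
        got = cbm_chem_log_activity(p, 2.0, state02, (ln_r, ln_r, ln_p))
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(-4.17499, abs=1e-5)

    def test_monotone_in_binding_constant(self, state02):
        triplet = (2.0, 2.0, 3.0)
        vals = [
            cbm_chem_log_activity(CBMParams.for_crystallin(2.0, k), 2.0, state02, triplet)
            for k in (0.0, 1.0, 10.0, 100.0)
        ]
        assert all(v <= 0 for v in vals)
        assert np.all(np.diff(vals) < 0)

    def test_site_rules(self, product):
        area = CBMParams.for_crystallin(2.0, 10.6, product_site_rule="area")
        conserved = CBMParams.for_crystallin(2.0, 10.6, product_site_rule="conserved")
        reactant = sphere_geometry(SIGMA, SIGMA)
        assert area.sites_for(reactant) == pytest.approx(2.0, rel=1e-12)
        assert conserved.sites_for(reactant) == pytest.approx(2.0, rel=1e-12)
        assert area.sites_for(product) == pytest.approx(2.0 * 2 ** (2 / 3), rel=1e-12)
        assert conserved.sites_for(product) == 2.0


class TestTotalActivity:
    def test_tpm_zero_reduces_to_steric(self, reactant, state02):
        assert total_log_activity(reactant, state02, _tpm(0.0)) == pytest.approx(
            steric_log_activity(reactant, state02), rel=1e-14
        )

    def test_cbm_zero_reduces_to_steric(self, reactant, state02):
        p = CBMParams.for_crystallin(2.0, 0.0)
        assert total_log_activity(reactant, state02, p) == pytest.approx(
            steric_log_activity(reactant, state02), rel=1e-14
        )

    def test_tpm_total_is_pointwise_sum(self, reactant):
        # the attraction lowers the activity by exactly the chemical term
        for phi in (0.05, 0.2, 0.35):
            st = SolutionState(phi)
            total = total_log_activity(reactant, st, _tpm(13.9))
            parts = steric_log_activity(reactant, st) + tpm_chem_log_activity(
                _tpm(13.9), st
            )
            assert total == pytest.approx(parts, rel=1e-12)
            assert total < steric_log_activity(reactant, st)


class TestCrowdingFactor:
    def test_no_crowders(self, reactant, product):
        res = crowding_factor(reactant, product, SolutionState(0.0))
        assert res.log_crowding_factor == 0.0

    def test_hard_sphere_depletion_promotes_association(self, reactant, product, state02):
        ln_r = steric_log_activity(reactant, state02)
        ln_p = steric_log_activity(product, state02)
        res = crowding_factor(reactant, product, state02)
        assert res.log_crowding_factor == pytest.approx(2 * ln_r - ln_p, rel=1e-14)
        assert res.log_crowding_factor == pytest.approx(1.20370, abs=1e-5)
        assert res.log_crowding_factor > 0

    def test_strong_attraction_suppresses_association(self, reactant, product, phi_grid):
        for phi in phi_grid:
            res = crowding_factor(reactant, product, SolutionState(phi), _tpm(13.9))
            assert res.log_crowding_factor < 0

    def test_continuity_at_dilute_limit(self, reactant, product):
        for model in (None, _tpm(13.9), CBMParams.for_crystallin(2.0, 10.6)):
            val = crowding_factor(
                reactant, product, SolutionState(1e-6), model
            ).log_crowding_factor
            assert abs(val) < 1e-4

    def test_linearity_in_epsilon_with_closed_form_slope(self, reactant, product, state02):
        # ln Gamma(eps) = Delta_st - rho*eps*(2S_r - S_p)*[dr + (g-1)theta]
        p = _tpm(1.0)
        rho = state02.number_density
        bracket = p.attraction_range + (contact_value_g0max(0.2) - 1) * p.decay_range
        slope = -rho * (2 * reactant.surface_area - product.surface_area) * bracket

        def ln_gamma(eps):
            return crowding_factor(reactant, product, state02, _tpm(eps)).log_crowding_factor

        for e1, e2 in [(0.0, 5.0), (5.0, 13.9), (13.9, 20.0)]:
            fd = (ln_gamma(e2) - ln_gamma(e1)) / (e2 - e1)
            assert fd == pytest.approx(slope, rel=1e-10)

    def test_cbm_single_strong_bond_changes_sign(self, reactant, product):
        # one strong bond: attraction wins when dilute, depletion when crowded
        p = CBMParams.for_crystallin(1.0, 100.0)

        def ln_gamma(phi):
            return crowding_factor(
                reactant, product, SolutionState(phi), p
            ).log_crowding_factor

        assert ln_gamma(0.05) < 0
        assert ln_gamma(0.4) > 0
        from scipy.optimize import brentq

        root = brentq(ln_gamma, 0.05, 0.4)
        assert 0.0 < root < 0.5


class TestModelEquivalence:
    def test_zero_maps_to_zero(self, state02):
        assert model_equivalence_K_of_epsilon(0.0, state02) == 0.0

    def test_defining_equation_residual(self, reactant, state02):
        eps = 13.9
        k = model_equivalence_K_of_epsilon(eps, state02, n_sites=2.0)
        target = tpm_chem_log_activity(_tpm(eps), state02)
        # evaluate the CBM side with the same companion construction
        from crowdspt.interactions import _cbm_companions

        crowder, complex_geom = _cbm_companions(reactant, state02)
        triplet = (
            steric_log_activity(reactant, state02),
            steric_log_activity(crowder, state02),
            steric_log_activity(complex_geom, state02),
        )
        cbm_val = cbm_chem_log_activity(
            CBMParams.for_crystallin(2.0, k), 2.0, state02, triplet
        )
        assert abs(cbm_val - target) < 1e-10

    def test_matches_closed_form_inversion(self, reactant, state02):
        # K = (exp(-lnGamma_tpm/n_s) - 1)/(exp(Delta) * phi), solved by hand
        eps, n_s, phi = 7.0, 2.0, 0.2
        target = tpm_chem_log_activity(_tpm(eps), state02)
        from crowdspt.interactions import _cbm_companions

        crowder, complex_geom = _cbm_companions(reactant, state02)
        delta = (
            steric_log_activity(reactant, state02)
            + steric_log_activity(crowder, state02)
            - steric_log_activity(complex_geom, state02)
        )
        closed = (math.exp(-target / n_s) - 1) / (math.exp(delta) * phi)
        assert model_equivalence_K_of_epsilon(eps, state02, n_s) == pytest.approx(
            closed, rel=1e-10
        )

    def test_linear_at_low_density(self):
        st = SolutionState(0.02)
        k1 = model_equivalence_K_of_epsilon(0.05, st)
        k2 = model_equivalence_K_of_epsilon(0.10, st)
        assert k2 / k1 == pytest.approx(2.0, rel=2e-2)
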