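"""Circuit-model unit tests: network structure, closed-form limits,
steady states against a hand-written algebraic oracle, dose response,
copy-number sweeps, and the Dox-influx fit."""

import numpy as np
import pandas as pd
import pytest

from linamp.circuit_model import (
    SPECIES,
    build_network,
    copy_number_sweep,
    dose_response,
    find_steady_state,
    fit_dox_influx,
    promoter_fractions,
    simulate_ode,
    simulate_ssa,
)
from linamp.params import CircuitParameters, ParameterError

from oracles import steady_state_handwritten

_IDX = {s: i for i, s in enumerate(SPECIES)}


def _ss(params, name):
    x = find_steady_state(build_network(params))
    return x[_IDX[name]]


class TestParameters:
    def test_negative_rate_names_field(self, defaults):
        with pytest.raises(ParameterError) as err:
            defaults.replace(k_off=-1.0)
        assert err.value.field == "k_off"

    def test_leak_ordering_enforced(self, defaults):
        with pytest.raises(ParameterError):
            defaults.replace(leak_r1=0.1, leak_r2=0.5)

    def test_non_integer_copy_number_rejected(self, defaults):
        with pytest.raises(ParameterError) as err:
            defaults.replace(copy_number=1.5)
        assert err.value.field == "copy_number"

    def test_copy_number_zero_allowed(self, defaults):
        assert defaults.replace(copy_number=0).copy_number == 0


class TestBuildNetwork:
    def test_reaction_families_and_elementary_count(self, defaults):
        """Two-operator binding ladder + sequestration are reversible, so
        the 14 reaction families expand to 17 elementary reactions."""
        net = build_network(defaults)
        assert len(net.reactions) == 17
        assert len(net.families) == 14

    def test_promoter_rows_conserve_total(self, defaults):
        _, _, net_stoich = build_network(defaults).arrays()
        d_rows = [_IDX["D_free"], _IDX["D_R1"], _IDX["D_R2"]]
        assert np.all(net_stoich[:, d_rows].sum(axis=1) == 0)

    def test_no_template_means_no_expression(self, defaults):
        """copy_number=0: only intracellular Dox can move."""
        net = build_network(defaults.replace(copy_number=0))
        result = simulate_ode(net, 100.0)
        for name in ("mRNA", "TetR_free", "TetR_Dox", "eGFP", "D_R1", "D_R2"):
            assert np.all(result.trajectory(name) == 0.0)
        assert result.final("Dox_int") > 0

    def test_r_zero_keeps_operators_empty(self, defaults):
        net = build_network(defaults.replace(r=0.0))
        result = simulate_ode(net, 200.0)
        assert np.all(np.abs(result.trajectory("D_R1")) < 1e-9)
        assert np.all(np.abs(result.trajectory("D_R2")) < 1e-9)


class TestOdeClosedForms:
    def test_binding_off_matches_closed_form(self):
        """r=0 decouples the promoter: mRNA -> n m/d_m, eGFP -> n m k_tl/(d_m d_gfp)."""
        p = CircuitParameters(
            m=10.0, leak_r1=0.5, leak_r2=0.1, r=0.0, k_off=1.0, f=0.0, g_dox=1.0,
            k_seq_on=1.0, k_seq_off=0.1, k_tl_tetr=1.0, k_tl_gfp=1.0,
            d_m=1.0, d_tetr=0.1, d_gfp=0.1, copy_number=1, d_complex=0.1,
        )
        assert _ss(p, "mRNA") == pytest.approx(10.0, rel=1e-6)
        assert _ss(p, "eGFP") == pytest.approx(100.0, rel=1e-6)

    def test_full_leak_equals_binding_off(self, defaults):
        """leak_r1 = leak_r2 = 1: repression has no transcriptional effect."""
        p_leak = defaults.replace(leak_r1=1.0, leak_r2=1.0)
        p_off = defaults.replace(r=0.0)
        for name in ("mRNA", "eGFP"):
            assert _ss(p_leak, name) == pytest.approx(_ss(p_off, name), rel=1e-6)

    def test_steady_state_matches_handwritten_algebra(self, defaults):
        """Default calibration, n=1, 0.05 ng/mL Dox: integrate-then-polish
        agrees with an independently written root-find to 1e-6 relative."""
        oracle = steady_state_handwritten(defaults)
        x = find_steady_state(build_network(defaults))
        for name, value in oracle.items():
            assert x[_IDX[name]] == pytest.approx(value, rel=1e-6, abs=1e-9)

    def test_steady_state_flag_and_derivative_criterion(self, defaults):
        net = build_network(defaults)
        result = simulate_ode(net, 2000.0)
        assert result.steady_state
        short = simulate_ode(net, 0.01)
        assert not short.steady_state

    def test_strong_binding_leak_limit_matches_oracle(self, defaults):
        """leak_r2=0, strong binding, high n: transcription is dominated by
        the singly bound leak plus residual unbound contribution."""
        p = defaults.replace(leak_r2=0.0, r=50.0, copy_number=10)
        oracle = steady_state_handwritten(p)
        assert _ss(p, "mRNA") == pytest.approx(oracle["mRNA"], rel=1e-6)


class TestPromoterFractions:
    def test_fractions_sum_to_one(self, defaults):
        net = build_network(defaults.replace(copy_number=3))
        result = simulate_ode(net, 500.0)
        p = promoter_fractions(result, 3)
        assert sum(p) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in p)

    def test_no_repressor_gives_all_free(self, defaults):
        net = build_network(defaults.replace(r=0.0, copy_number=2))
        result = simulate_ode(net, 200.0)
        assert promoter_fractions(result, 2) == pytest.approx((1.0, 0.0, 0.0))

    def test_zero_copies_is_an_error(self, defaults):
        result = simulate_ode(build_network(defaults), 1.0)
        with pytest.raises(ValueError):
            promoter_fractions(result, 0)

    def test_detailed_balance_of_isolated_binding_ladder(self):
        """With free TetR clamped at T, equilibrium occupancy obeys
        p_double/p_free = (2rT/k_off) * (rT/(2 k_off)) = (rT/k_off)^2."""
        from scipy.integrate import solve_ivp

        r, k_off, T, n = 0.8, 3.0, 2.5, 1.0

        def ladder(t, d):
            d0, d1, d2 = d
            bind1 = 2 * r * d0 * T
            unbind1 = k_off * d1
            bind2 = r * d1 * T
            unbind2 = 2 * k_off * d2
            return [-bind1 + unbind1, bind1 - unbind1 - bind2 + unbind2, bind2 - unbind2]

        sol = solve_ivp(ladder, (0, 200.0), [n, 0, 0], rtol=1e-10, atol=1e-12)
        d0, d1, d2 = sol.y[:, -1]
        assert d2 / d0 == pytest.approx((r * T / k_off) ** 2, rel=1e-6)


class TestDoseResponse:
    def test_repressor_dead_mutant_is_flat(self, defaults):
        """r=0 reproduces constant high expression at any inducer level."""
        table = dose_response(defaults.replace(r=0.0), [0.0, 0.02, 0.05, 0.1, 0.5, 1.0])
        egfp = table["egfp"].to_numpy()
        assert egfp.max() / egfp.min() <= 1.0 + 1e-6

    def test_repression_lowers_expression_at_zero_dox(self, defaults):
        p = defaults.replace(r=50.0, leak_r2=0.0)
        repressed = dose_response(p, [0.0])["egfp"].iloc[0]
        unrepressed = dose_response(defaults.replace(r=0.0), [0.0])["egfp"].iloc[0]
        assert repressed < unrepressed

    def test_wild_type_is_monotone_and_linear(self, defaults):
        """The designed linearizer behavior: eGFP rises ~linearly with Dox
        over the calibrated induction range."""
        grid = np.linspace(0.0, 0.1, 6)
        table = dose_response(defaults, grid)
        y = table["egfp"].to_numpy()
        assert np.all(np.diff(y) > 0)
        coef = np.polyfit(grid, y, 1)
        resid = y - np.polyval(coef, grid)
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 >= 0.95
        # more inducer -> fewer doubly repressed promoters
        assert np.all(np.diff(table["p_double"].to_numpy()) < 0)

    def test_negative_dose_rejected(self, defaults):
        with pytest.raises(ValueError):
            dose_response(defaults, [-0.1])


class TestCopyNumberSweep:
    def test_expression_and_repressed_fraction_rise_with_n(self, defaults):
        """Amplification raises every output while pushing promoters into
        the repressed state: leak-dominated transcription."""
        sweep = copy_number_sweep(defaults, range(1, 16), dox=0.05)
        for col in ("mrna", "tetr_protein", "egfp"):
            assert np.all(np.diff(sweep[col].to_numpy()) > 0), col
        assert sweep["p_double"].iloc[-1] > sweep["p_double"].iloc[0]

    def test_r_zero_outputs_proportional_to_n(self, defaults):
        """Without binding the system is linear in template count."""
        sweep = copy_number_sweep(defaults.replace(r=0.0), [1, 3, 7, 15], dox=0.05)
        for col in ("mrna", "egfp", "tetr_protein"):
            per_copy = sweep[col].to_numpy() / sweep["n"].to_numpy()
            assert per_copy == pytest.approx([per_copy[0]] * 4, rel=1e-6)

    def test_egfp_nondecreasing_in_leak(self, defaults):
        values = [
            _ss(defaults.replace(leak_r1=l1, leak_r2=l2), "eGFP")
            for l1, l2 in [(0.05, 0.01), (0.1, 0.02), (0.3, 0.1), (0.6, 0.4)]
        ]
        assert np.all(np.diff(values) > 0)

    def test_non_positive_n_rejected(self, defaults):
        with pytest.raises(ValueError):
            copy_number_sweep(defaults, [0, 1], dox=0.05)


class TestSsa:
    def test_empty_system_stays_empty(self, defaults):
        net = build_network(defaults.replace(copy_number=0, dox_ext=0.0))
        result = simulate_ssa(net, 50.0, seed=1)
        assert np.all(result.states == 0.0)

    def test_promoter_conservation_exact(self, defaults):
        net = build_network(defaults.replace(copy_number=4))
        result = simulate_ssa(net, 100.0, seed=42, n_samples=400)
        totals = (
            result.trajectory("D_free")
            + result.trajectory("D_R1")
            + result.trajectory("D_R2")
        )
        assert np.all(totals == 4.0)
        assert np.all(result.states >= 0.0)

    def test_same_seed_reproduces_trajectory(self, defaults):
        net = build_network(defaults)
        a = simulate_ssa(net, 50.0, seed=7, n_samples=51)
        b = simulate_ssa(net, 50.0, seed=7, n_samples=51)
        assert np.array_equal(a.states, b.states)
        c = simulate_ssa(net, 50.0, seed=8, n_samples=51)
        assert not np.array_equal(a.states, c.states)


class TestFitDoxInflux:
    DOSES = [0.0, 0.03, 0.06, 0.1]

    def test_identity_fit_recovers_f0(self, defaults):
        observed = dose_response(defaults, self.DOSES)[["dox", "egfp"]]
        fit = fit_dox_influx(defaults, observed)
        assert fit.converged
        assert fit.f == pytest.approx(defaults.f, rel=1e-3)
        assert fit.scale == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("factor", [1.7, 2.5])
    def test_influx_multiplier_recovered(self, defaults, factor):
        """Self-consistency: data generated at f0*factor (e.g. the 2.5x
        adjustment needed to match a different cell line) is recovered to
        within 2% relative."""
        truth = defaults.replace(f=defaults.f * factor)
        observed = dose_response(truth, self.DOSES)[["dox", "egfp"]]
        fit = fit_dox_influx(defaults, observed)
        assert fit.converged
        assert fit.f / defaults.f == pytest.approx(factor, rel=0.02)

    def test_flat_observations_flagged(self, defaults):
        observed = pd.DataFrame({"dox": self.DOSES, "egfp": [50.0] * 4})
        fit = fit_dox_influx(defaults, observed)
        assert not fit.converged

    def test_too_few_doses_rejected(self, defaults):
        observed = pd.DataFrame({"dox": [0.0, 0.1], "egfp": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_dox_influx(defaults, observed)
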