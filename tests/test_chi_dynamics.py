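"""Single-cell flux forms, gap-junction flux, and the coupled right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliawave as gw
from gliawave.chi_dynamics import (
    CellState,
    calcium_fluxes,
    gj_flux,
    h_kinetics,
    ip3_fluxes,
    network_rhs,
    resting_state,
    single_cell_rhs,
    up_state,
)
from gliawave.experiments import make_fixture
from gliawave.params import ChIParams, GJParams


class TestCalciumFluxes:
    def test_er_gradient_vanishes(self, chi):
        # C at the ER-cytosol equilibrium kills both release and leak
        C_eq = chi.C_T / (1 + chi.rho_A)
        J_C, J_L, _ = calcium_fluxes(CellState(C=C_eq, h=0.5, I=1.0), chi)
        assert J_C == pytest.approx(0.0, abs=1e-12)
        assert J_L == pytest.approx(0.0, abs=1e-12)

    def test_pump_half_saturation(self, chi):
        _, _, J_P = calcium_fluxes(CellState(C=chi.K_P, h=0.5, I=0.5), chi)
        assert J_P == pytest.approx(chi.O_P / 2)

    def test_release_regression_pin(self, chi):
        # frozen value from exact rational evaluation of the closed form
        J_C, _, _ = calcium_fluxes(CellState(C=0.1, h=0.8, I=0.5), chi)
        assert J_C == pytest.approx(0.4766152644356577, rel=1e-12)


class TestHKinetics:
    def test_no_calcium_fully_available(self, chi):
        for I in (0.0, 0.3, 2.0):
            h_inf, _ = h_kinetics(CellState(C=0.0, h=0.5, I=I), chi)
            assert h_inf == pytest.approx(1.0)

    def test_q2_at_zero_ip3(self, chi):
        # Q2(0) = d2*d1/d3, recovered through Omega_h = O2*(Q2+C) at C=0
        _, Omega_h = h_kinetics(CellState(C=0.0, h=0.5, I=0.0), chi)
        assert Omega_h / chi.O2 == pytest.approx(0.14455162179351283, rel=1e-12)

    def test_midpoint_symmetry(self, chi):
        I = 0.4
        Q2 = chi.d2 * (I + chi.d1) / (I + chi.d3)
        h_inf, Omega_h = h_kinetics(CellState(C=Q2, h=0.5, I=I), chi)
        assert h_inf == pytest.approx(0.5)
        assert Omega_h == pytest.approx(2 * chi.O2 * Q2)


class TestIP3Fluxes:
    def test_linear_5p_degradation(self, chi):
        _, _, J_5P = ip3_fluxes(CellState(C=0.1, h=0.5, I=1.0), chi)
        assert J_5P == pytest.approx(0.21)

    def test_calcium_gated_terms_vanish(self, chi):
        J_delta, J_3K, _ = ip3_fluxes(CellState(C=0.0, h=0.5, I=0.5), chi)
        assert J_delta == 0.0
        assert J_3K == 0.0

    def test_3k_double_half_saturation(self, chi):
        J_delta, J_3K, _ = ip3_fluxes(CellState(C=chi.K_D, h=0.5, I=chi.K_3K), chi)
        assert J_3K == pytest.approx(chi.O_3K / 4)


class TestGJFlux:
    def test_zero_gradient(self, gj):
        assert gj_flux(0.0, gj) == 0.0
        assert gj_flux(0.0, GJParams(mode="linear")) == 0.0

    def test_threshold_gives_half_max(self, gj):
        assert gj_flux(gj.I_theta, gj) == pytest.approx(-gj.F / 2)

    def test_saturation(self, gj):
        assert gj_flux(50.0, gj) == pytest.approx(-gj.F, rel=1e-6)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_odd_function(self, delta):
        for params in (GJParams(), GJParams(mode="linear")):
            assert gj_flux(-delta, params) == pytest.approx(-gj_flux(delta, params), abs=1e-12)

    def test_magnitude_nondecreasing(self, gj):
        grid = np.linspace(0, 3, 301)
        for params in (gj, GJParams(mode="linear")):
            mags = np.abs(gj_flux(grid, params))
            assert np.all(np.diff(mags) >= -1e-12)


class TestNetworkRHS:
    def test_identical_coupled_cells_match_isolated(self, chi, gj, rest):
        _, net = make_fixture("two_cell")
        states = np.tile([[rest.C * 2], [0.5], [rest.I * 3]], (1, 2))
        d = network_rhs(states, net, chi, gj)
        iso = np.array(single_cell_rhs(states[0, 0], states[1, 0], states[2, 0], chi))
        np.testing.assert_allclose(d[:, 0], iso, rtol=1e-12)
        np.testing.assert_allclose(d[:, 1], iso, rtol=1e-12)

    def test_exchange_is_conservative(self, chi, gj, rng):
        # GJC terms cancel pairwise: total dI equals the sum of isolated terms
        pos = gw.place_astrocytes(3, 50, 10, seed=5)
        net = gw.build_link_radius(pos, 60.0)
        assert net.n_edges > 0
        states = np.vstack([
            rng.uniform(0.01, 1.0, pos.n),
            rng.uniform(0.0, 1.0, pos.n),
            rng.uniform(0.01, 2.0, pos.n),
        ])
        coupled = network_rhs(states, net, chi, gj)
        iso = single_cell_rhs(states[0], states[1], states[2], chi)
        assert coupled[2].sum() == pytest.approx(np.asarray(iso[2]).sum(), abs=1e-10)

    def test_resting_state_is_fixed_point(self, chi, gj, rest):
        _, net = make_fixture("two_cell")
        states = np.tile([[rest.C], [rest.h], [rest.I]], (1, 2))
        d = network_rhs(states, net, chi, gj)
        assert np.abs(d).max() < 1e-8

    def test_dimension_mismatch_rejected(self, chi, gj):
        _, net = make_fixture("two_cell")
        with pytest.raises(ValueError):
            network_rhs(np.zeros((3, 5)), net, chi, gj)


class TestRestingState:
    def test_subthreshold(self, rest):
        assert 0 <= rest.C < 0.7
        assert 0 <= rest.h <= 1
        assert rest.I >= 0

    def test_stronger_pump_lowers_rest_calcium(self, chi, rest):
        stronger = ChIParams(**{**chi.__dict__, "O_P": 2 * chi.O_P})
        assert resting_state(stronger).C < rest.C

    def test_bistable_up_state_distinct(self, chi, rest):
        up = up_state(chi)
        assert up.I > rest.I + 0.5
        assert up.C > rest.C

    def test_invalid_cell_state_rejected(self):
        with pytest.raises(ValueError):
            CellState(C=-0.1, h=0.5, I=0.5)
        with pytest.raises(ValueError):
            CellState(C=0.1, h=1.5, I=0.5)


class TestSingleCellDynamics:
    def test_h_stays_in_unit_interval_and_freq_rises_with_ip3(self, chi):
        # clamped-IP3 oscillations: h bounded, period shrinking with clamp level
        from gliawave import SimulationSettings, StimulusProtocol, integrate
        from gliawave.topology import CouplingNetwork
        from scipy.signal import find_peaks

        net1 = CouplingNetwork(1, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        periods = []
        for I_clamp in (0.7, 0.9, 1.05):
            stim = StimulusProtocol(target_cell=0, t_off=200.0, I_bias=I_clamp, mode="clamp")
            rec = integrate(net1, chi, GJParams(F=0.0), stim,
                            SimulationSettings(T=200.0, record=True, record_stride=1))
            h = rec.traj_h[:, 0]
            assert h.min() >= 0.0 and h.max() <= 1.0
            trace = rec.traj_C[len(rec.traj_C) // 2:, 0]
            peaks, _ = find_peaks(trace, height=0.7, prominence=0.2)
            assert len(peaks) >= 3, f"no sustained oscillation at clamp {I_clamp}"
            periods.append(np.diff(peaks).mean() * 0.01)
        assert periods[0] > periods[1] > periods[2]


class TestParamValidation:
    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ChIParams(O_P=0.0)
        with pytest.raises(ValueError):
            GJParams(omega_I=0.0)
        with pytest.raises(ValueError):
            GJParams(mode="quadratic")

    def test_config_roundtrip_and_unknown_keys(self, tmp_path, chi, gj):
        from gliawave.params import dump_params, load_params

        path = tmp_path / "params.json"
        dump_params(chi, gj, path, I_bias=2.0, T=200)
        cfg = load_params(path)
        assert cfg["chi"] == chi
        assert cfg["gj"] == gj
        assert cfg["extra"]["I_bias"] == 2.0
        path.write_text('{"Omega_C": 6, "no_such_symbol": 1}')
        with pytest.raises(ValueError, match="no_such_symbol"):
            load_params(path)
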