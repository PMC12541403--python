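import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import trapezoid

from redoxfilm import (
    F,
    BoundaryConditions,
    EnzymeKinetics,
    FilmParameters,
    InactivationModel,
    PotentialValue,
    RedoxCouple,
    SpeciesProfile,
    current_from_profile,
    dump_config,
    electrode_boundary_ratio,
    enzyme_net_rate,
    equilibrated_profile,
    estimate_front_speed,
    front_position,
    inactivation_rate_pair,
    inactive_fraction,
    layer_potential,
    load_config,
    nernst_profile,
    rate_density,
    reaction_layer,
    read_profile,
    solve_steady_state,
    solve_transient,
    write_profile,
)
from redoxfilm.potentials import h2_equilibrium_potential


class TestEnzymeNetRate:
    def test_zero_exactly_at_equilibrium(self, dv2_params):
        """Detailed balance: no net turnover at the H+/H2 equilibrium."""
        rng = np.random.default_rng(0)
        p = dv2_params
        for _ in range(100):
            h2 = rng.uniform(0.01, 0.78)
            rho = math.sqrt(p.k_thermo() / (h2 / p.h2_solubility))
            v_ox = rng.uniform(1.0, 99.0)
            v_red = v_ox / rho
            rate = enzyme_net_rate(v_ox, v_red, h2, p)
            scale = p.e_total * p.kinetics.k_cat_ox
            assert abs(rate) < 1e-10 * scale

    def test_pure_forward_when_no_reduced_mediator(self, dv2_params):
        assert enzyme_net_rate(50.0, 0.0, 0.5, dv2_params) > 0

    def test_pure_reverse_when_no_oxidized_mediator(self, dv2_params):
        assert enzyme_net_rate(0.0, 50.0, 0.5, dv2_params) < 0

    def test_linear_in_active_enzyme(self, dv2_params):
        r1 = enzyme_net_rate(30.0, 70.0, 0.5, dv2_params, e_active=1.0)
        r2 = enzyme_net_rate(30.0, 70.0, 0.5, dv2_params, e_active=2.0)
        assert r2 == pytest.approx(2 * r1)

    def test_rejects_negative_concentrations(self, dv2_params):
        with pytest.raises(ValueError):
            enzyme_net_rate(-1.0, 50.0, 0.5, dv2_params)

    def test_sign_follows_nernst_potential(self, dv2_params):
        """Oxidation above equilibrium, evolution below (100 random states)."""
        rng = np.random.default_rng(1)
        p = dv2_params
        e_eq = p.e_eq()
        for _ in range(100):
            u = rng.uniform(0.01, 0.99)
            h2 = rng.uniform(0.05, 0.78)
            e_v = p.mediator.e0 + np.log(u / (1 - u)) / p.f
            e_eq_loc = e_eq + np.log(p.h2_solubility / h2) / (2 * p.f)
            rate = enzyme_net_rate(100 * u, 100 * (1 - u), h2, p)
            assert np.sign(rate) == np.sign(e_v - e_eq_loc)


class TestInactivationKinetics:
    def test_rates_equal_at_e_inact(self):
        m = InactivationModel()
        k_i, k_a = inactivation_rate_pair(m.e_inact, m)
        assert k_i == pytest.approx(k_a) == pytest.approx(m.k_x)

    def test_enzyme_stays_active_at_low_potential(self):
        m = InactivationModel()
        k_i, k_a = inactivation_rate_pair(m.e_inact - 0.3, m)
        assert k_i / k_a < 1e-6
        assert inactive_fraction(m.e_inact - 0.3, m) < 1e-6

    def test_half_inactive_at_e_inact(self):
        m = InactivationModel()
        assert inactive_fraction(m.e_inact, m) == pytest.approx(0.5)

    def test_ceiling_preserves_ratio(self):
        m = InactivationModel(k_cap=0.5)
        e_v = m.e_inact + 0.2
        k_i, k_a = inactivation_rate_pair(e_v, m)
        assert max(k_i, k_a) <= m.k_cap * (1 + 1e-12)
        assert k_i / k_a == pytest.approx(math.exp(m.alpha * 0.2), rel=1e-9)

    def test_o2_channel_shifts_steady_fraction(self):
        m = InactivationModel()
        low = inactive_fraction(m.e_inact - 0.2, m, o2=0.0)
        aerobic = inactive_fraction(m.e_inact - 0.2, m, o2=0.06)
        assert aerobic > 0.5 > low


class TestElectrodeBoundary:
    def test_midpoint_ratio_one(self):
        med = RedoxCouple(-0.40)
        assert electrode_boundary_ratio(
            PotentialValue(-0.40, "SHE"), med
        ) == pytest.approx(1.0)

    def test_decade_per_59mV(self):
        med = RedoxCouple(0.0)
        r = electrode_boundary_ratio(
            PotentialValue(0.05916, "SHE"), med, temperature=298.15
        )
        assert r == pytest.approx(10.0, rel=1e-3)

    def test_fully_reduced_limit(self):
        med = RedoxCouple(-0.2)
        assert electrode_boundary_ratio(PotentialValue(-0.9, "SHE"), med) < 1e-11


class TestSteadyState:
    def test_no_enzyme_at_midpoint_is_equilibrated_film(self):
        """Without catalysis and E = E0, the film sits at v_ox = v_red."""
        p = FilmParameters(e_total=1e-9)
        bc = BoundaryConditions(
            PotentialValue(p.mediator.e0, "SHE"), bulk_h2=0.78
        )
        prof, current = solve_steady_state(p, bc, n_nodes=60)
        assert np.allclose(prof.v_ox, p.v_total / 2, rtol=1e-6)
        assert abs(current) < 1e-6

    def test_conservation_invariants(self, dv2_params, dv2_steady):
        prof, _ = dv2_steady
        p = dv2_params
        assert np.allclose(prof.v_ox + prof.v_red, p.v_total, rtol=1e-8)
        total = prof.e_active + prof.e_inactive + prof.e_dead
        assert np.allclose(total, p.e_total, rtol=1e-8)
        for arr in (prof.v_ox, prof.v_red, prof.h2, prof.o2, prof.e_active):
            assert np.all(arr >= -1e-12)

    def test_current_sign_tracks_thermodynamic_drive(self, dv2_params):
        e_eq = dv2_params.e_eq()
        for dE, sign in ((0.15, 1), (-0.15, -1)):
            bc = BoundaryConditions(PotentialValue(e_eq + dE, "SHE"), bulk_h2=0.78)
            _, j = solve_steady_state(dv2_params, bc, n_nodes=60)
            assert np.sign(j) == sign
        bc = BoundaryConditions(PotentialValue(e_eq, "SHE"), bulk_h2=0.78)
        _, j0 = solve_steady_state(dv2_params, bc, n_nodes=60)
        assert abs(j0) < 1e-6

    def test_grid_too_coarse_rejected(self, dv2_params, anaerobic_bc):
        with pytest.raises(ValueError):
            solve_steady_state(dv2_params, anaerobic_bc, n_nodes=20)

    def test_oxidizing_steady_state_is_protected_for_dv2(self, dv2_params, dv2_steady):
        prof, j = dv2_steady
        assert j > 0
        mask = reaction_layer(prof, dv2_params)
        inact = (prof.e_inactive + prof.e_dead) / dv2_params.e_total
        assert inact[mask].max() < 0.05


class TestTransient:
    def test_relaxes_to_steady_state(self, dv2_params, anaerobic_bc):
        prof_ss, j_ss = solve_steady_state(dv2_params, anaerobic_bc, n_nodes=60)
        init = equilibrated_profile(dv2_params, anaerobic_bc, n_nodes=60)
        res = solve_transient(
            dv2_params, anaerobic_bc, t_end=120.0, snapshots=[120.0],
            initial=init, n_nodes=60,
        )
        p = res.profiles[-1]
        assert np.max(np.abs(p.v_ox - prof_ss.v_ox)) / dv2_params.v_total < 1e-6
        assert res.current[-1] == pytest.approx(j_ss, rel=1e-6)

    def test_snapshot_times_honored_exactly(self, dv2_params, anaerobic_bc):
        snaps = [0.37, 1.0, 2.5]
        res = solve_transient(
            dv2_params, anaerobic_bc, t_end=2.5, snapshots=snaps, n_nodes=60
        )
        assert np.allclose(res.times[1:], snaps)

    def test_per_node_conservation_over_time(self, dv2_params, anaerobic_bc):
        init = equilibrated_profile(dv2_params, anaerobic_bc, n_nodes=60)
        res = solve_transient(
            dv2_params, anaerobic_bc, t_end=5.0, snapshots=[1.0, 5.0],
            initial=init, n_nodes=60,
        )
        for p in res.profiles:
            assert np.allclose(p.v_ox + p.v_red, dv2_params.v_total, rtol=1e-8)
            total = p.e_active + p.e_inactive + p.e_dead
            assert np.allclose(total, dv2_params.e_total, rtol=1e-8)


@pytest.fixture(scope="module")
def exposure(dv1_params, dv2_params, anaerobic_bc):
    out = {}
    bc_o2 = replace(anaerobic_bc, bulk_o2=0.06)
    for name, p in (("DV1", dv1_params), ("DV2", dv2_params)):
        prof0, j0 = solve_steady_state(p, anaerobic_bc, n_nodes=120)
        res = solve_transient(
            p, bc_o2, t_end=1.0, snapshots=[0.3, 1.0],
            initial=prof0, n_nodes=120,
        )
        out[name] = (p, j0, res)
    return out


class TestOxygenExposure:

    def test_front_moves_inward_and_faster_for_dv2(self, exposure):
        for name, (p, _, res) in exposure.items():
            fronts = [front_position(prof, p) for prof in res.profiles[1:]]
            assert all(f is not None for f in fronts)
            assert fronts[1] <= fronts[0] + 1e-9  # moves inward
        f_dv2 = front_position(exposure["DV2"][2].profiles[-1], exposure["DV2"][0])
        f_dv1 = front_position(exposure["DV1"][2].profiles[-1], exposure["DV1"][0])
        assert f_dv2 < f_dv1

    def test_inner_region_stays_oxygen_free_and_carries_current(self, exposure):
        for name, (p, j0, res) in exposure.items():
            prof = res.profiles[-1]
            n = prof.n_nodes
            assert prof.o2[: n // 2].max() < 0.05 * prof.o2[-1]
            assert res.current[-1] > 0.8 * j0

    def test_full_recovery_after_o2_removal(self, exposure, anaerobic_bc):
        for name, (p, j0, res) in exposure.items():
            back = solve_transient(
                p, anaerobic_bc, t_end=60.0, snapshots=[60.0],
                initial=res.profiles[-1], n_nodes=120,
            )
            assert back.current[-1] == pytest.approx(j0, rel=0.01)

    @pytest.mark.parametrize("phi_irr, full_recovery", [(0.0, True), (0.5, False)])
    def test_air_exposure_without_h2_and_reactivation(
        self, anaerobic_bc, phi_irr, full_recovery
    ):
        """Storage in air (no H2) inactivates the whole film; a reductive
        reactivation step restores the activity fully only when no
        irreversible-damage branch is present."""
        p = replace(
            FilmParameters(), inactivation=InactivationModel(phi_irr=phi_irr)
        )
        prof0, j0 = solve_steady_state(p, anaerobic_bc, n_nodes=80)
        bc_air = BoundaryConditions(
            PotentialValue(0.2, "SHE"), bulk_h2=0.0, bulk_o2=0.25
        )
        exposed = solve_transient(p, bc_air, t_end=5.0, snapshots=[5.0],
                                  initial=prof0, n_nodes=80)
        # without H2 the protection collapses: O2 floods the film
        assert exposed.profiles[-1].o2.min() > 0.1
        bc_red = replace(anaerobic_bc,
                         electrode_potential=PotentialValue(-0.6, "SHE"))
        react = solve_transient(p, bc_red, t_end=30.0, snapshots=[30.0],
                                initial=exposed.profiles[-1], n_nodes=80)
        assay = solve_transient(p, anaerobic_bc, t_end=30.0, snapshots=[30.0],
                                initial=react.profiles[-1], n_nodes=80)
        ratio = assay.current[-1] / j0
        if full_recovery:
            assert exposed.profiles[-1].e_dead.max() == pytest.approx(0.0, abs=1e-9)
            assert ratio == pytest.approx(1.0, abs=0.01)
        else:
            assert exposed.profiles[-1].e_dead.max() > 0
            assert ratio < 0.9


class TestFrontSpeedEstimate:
    def test_zero_without_oxygen(self, dv2_params, anaerobic_bc):
        assert estimate_front_speed(dv2_params, anaerobic_bc) == 0.0

    def test_dv2_front_faster_than_dv1(self, dv1_params, dv2_params, anaerobic_bc):
        bc = replace(anaerobic_bc, bulk_o2=0.06)
        assert estimate_front_speed(dv2_params, bc) > estimate_front_speed(
            dv1_params, bc
        )

    def test_matches_simulated_displacement_within_factor_two(
        self, dv2_params, anaerobic_bc
    ):
        prof0, _ = solve_steady_state(dv2_params, anaerobic_bc, n_nodes=100)
        for bulk_o2 in (0.02, 0.2):  # 10x range
            bc = replace(anaerobic_bc, bulk_o2=bulk_o2)
            speed = estimate_front_speed(dv2_params, bc)
            t_star = 0.15 * dv2_params.thickness / speed
            res = solve_transient(
                dv2_params, bc, t_end=t_star, snapshots=[t_star],
                initial=prof0, n_nodes=100,
            )
            fr = front_position(res.profiles[-1], dv2_params)
            assert fr is not None
            ratio = (1.0 - fr) / 0.15
            assert 0.5 < ratio < 2.0


class TestDerivedQuantities:
    def test_nernst_profile_midpoint_and_flags(self, dv2_params):
        prof = SpeciesProfile(
            xi=np.linspace(0, 1, 5),
            v_ox=np.array([50.0, 50.0, 10.0, 0.0, 100.0]),
            v_red=np.array([50.0, 50.0, 90.0, 100.0, 0.0]),
            h2=np.zeros(5), o2=np.zeros(5),
            e_active=np.full(5, 10.0), e_inactive=np.zeros(5),
            e_dead=np.zeros(5), e_v=np.zeros(5),
        )
        e_v = nernst_profile(prof, dv2_params.mediator, dv2_params.temperature)
        assert e_v[0] == pytest.approx(dv2_params.mediator.e0)
        assert np.isnan(e_v[3]) and np.isnan(e_v[4])

    def test_nernst_profile_boundary_matches_applied_potential(self, dv2_steady):
        prof, _ = dv2_steady
        assert prof.e_v[0] == pytest.approx(0.2, abs=1e-6)

    def test_interface_potential_reaches_h2_equilibrium(
        self, dv2_params, dv2_steady
    ):
        prof, _ = dv2_steady
        e_rhe = prof.e_v[-1] - dv2_params.e_eq()
        assert abs(e_rhe) * 1000 < 10  # within 10 mV of 0 vs RHE

    def test_monotone_nernst_profile_under_oxidizing_bias(self, dv2_steady):
        prof, _ = dv2_steady
        assert np.all(np.diff(prof.e_v) <= 1e-9)

    def test_uniform_profile_has_zero_current(self, dv2_params):
        prof = equilibrated_profile(
            dv2_params,
            BoundaryConditions(PotentialValue(0.0, "SHE"), bulk_h2=0.78),
            n_nodes=60,
        )
        assert current_from_profile(prof, dv2_params) == pytest.approx(0.0)

    def test_current_needs_three_nodes(self, dv2_params):
        prof = SpeciesProfile(
            xi=np.array([0.0, 1.0]),
            v_ox=np.array([1.0, 2.0]), v_red=np.array([99.0, 98.0]),
            h2=np.zeros(2), o2=np.zeros(2),
            e_active=np.zeros(2), e_inactive=np.zeros(2),
            e_dead=np.zeros(2), e_v=np.zeros(2),
        )
        with pytest.raises(ValueError):
            current_from_profile(prof, dv2_params)

    def test_electron_balance_at_fine_grid(self, dv2_params, anaerobic_bc):
        """Electrode flux equals 2F x integrated enzyme rate (<0.5%)."""
        prof, j = solve_steady_state(dv2_params, anaerobic_bc, n_nodes=1600)
        integ = (
            2 * F * trapezoid(rate_density(prof, dv2_params), prof.xi)
            * dv2_params.thickness
        )
        assert j == pytest.approx(integ, rel=5e-3)

    def test_layer_potential_is_buffered_at_mediator_e0(
        self, dv2_params, dv2_steady
    ):
        prof, _ = dv2_steady
        assert abs(layer_potential(prof, dv2_params) - dv2_params.mediator.e0) < 0.03

    def test_front_position_none_when_active(self, dv2_steady, dv2_params):
        prof, _ = dv2_steady
        assert front_position(prof, dv2_params) is None


class TestIO:
    def test_profile_round_trip(self, dv2_params, dv2_steady, tmp_path):
        prof, j = dv2_steady
        path = tmp_path / "profile.csv"
        write_profile(prof, path, dv2_params, metadata={"current_A_m2": j})
        meta, df = read_profile(path)
        assert float(meta["pH"]) == dv2_params.pH
        assert np.allclose(df["v_ox"], prof.v_ox)
        assert np.allclose(df["e_v_rhe"], prof.e_v - dv2_params.e_eq(),
                           equal_nan=True)

    def test_config_round_trip(self, dv2_params, anaerobic_bc, tmp_path):
        path = tmp_path / "film.yaml"
        dump_config(dv2_params, anaerobic_bc, path)
        params, bc = load_config(path)
        assert params == dv2_params
        assert bc == anaerobic_bc
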