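"""Unit and property tests for the bistable sequestering switch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurite_switch import switch_model as sm
from neurite_switch.switch_model import (
    Perturbation,
    SubstrateCondition,
    SwitchParameters,
    SwitchState,
    apply_perturbation,
    ensemble,
    find_fixed_points,
    partition_paxillin,
    rhs,
    scan_bifurcation,
    simulate,
    stiffness_to_adhesion_drive,
)


# --------------------------------------------------------------------------
# stiffness -> adhesion drive
# --------------------------------------------------------------------------

class TestAdhesionDrive:
    def test_half_point_identity(self, ref_params):
        assert stiffness_to_adhesion_drive(ref_params.E_half, ref_params) == pytest.approx(0.5)

    def test_limits(self, ref_params):
        assert stiffness_to_adhesion_drive(1e-9, ref_params) < 1e-12
        assert stiffness_to_adhesion_drive(1e9, ref_params) > 1 - 1e-12

    @pytest.mark.parametrize("E, expected", [
        # independent recomputation for E_half = 5, h_E = 2:
        # a(E) = (E/5)^2 / (1 + (E/5)^2)
        (0.1, 0.0004 / 1.0004),
        (1.0, 0.04 / 1.04),
        (20.0, 16.0 / 17.0),
    ])
    def test_closed_form_values(self, E, expected):
        p = SwitchParameters(E_half=5.0, h_E=2.0)
        assert stiffness_to_adhesion_drive(E, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self, ref_params):
        Es = np.geomspace(0.01, 1000, 50)
        vals = [stiffness_to_adhesion_drive(E, ref_params) for E in Es]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_modulus(self, ref_params):
        with pytest.raises(ValueError):
            stiffness_to_adhesion_drive(0.0, ref_params)


# --------------------------------------------------------------------------
# paxillin partition
# --------------------------------------------------------------------------

def _bisection_partition(P_T, S_E, S_A, K_E, K_A, tol=1e-12):
    """Independent bisection oracle for the free-paxillin root."""
    def f(P_f):
        return P_f + S_E * P_f / (K_E + P_f) + S_A * P_f / (K_A + P_f) - P_T

    lo, hi = 0.0, P_T
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestPartition:
    def test_no_scaffolds_all_free(self, ref_params):
        part = partition_paxillin(ref_params.P_T, 0.0, 0.0, ref_params)
        assert (part.P_free, part.P_E, part.P_A) == (ref_params.P_T, 0.0, 0.0)

    def test_symmetric_scaffolds_split_equally(self):
        p = SwitchParameters(K_E=1.0, K_A=1.0, S_E_per_ME=1.0, S_A_per_MA=1.0)
        part = partition_paxillin(p.P_T, 3.0, 3.0, p)
        assert part.P_E == pytest.approx(part.P_A, rel=1e-12)

    def test_against_bisection_oracle_worked_example(self):
        # P_T=10, S_E=4, S_A=2, K_E=0.5, K_A=2 with unit capacities
        p = SwitchParameters(S_E_per_ME=1.0, S_A_per_MA=1.0, K_E=0.5, K_A=2.0)
        part = partition_paxillin(10.0, 4.0, 2.0, p)
        P_f_oracle = _bisection_partition(10.0, 4.0, 2.0, 0.5, 2.0)
        assert part.P_free == pytest.approx(P_f_oracle, rel=1e-9)

    def test_conservation_and_oracle_on_random_draws(self, rng):
        """1,000 random parameter draws: conservation to 1e-9 relative and
        agreement with the 1e-12 bisection oracle."""
        for _ in range(1000):
            P_T = rng.uniform(0.1, 50)
            M_E, M_A = rng.uniform(0, 20, 2)
            p = SwitchParameters(
                P_T=P_T,
                S_E_per_ME=rng.uniform(0.05, 5), S_A_per_MA=rng.uniform(0.05, 5),
                K_E=rng.uniform(0.05, 10), K_A=rng.uniform(0.05, 10))
            part = partition_paxillin(P_T, M_E, M_A, p)
            assert part.P_free >= 0 and part.P_E >= 0 and part.P_A >= 0
            assert part.total == pytest.approx(P_T, rel=1e-9)
            oracle = _bisection_partition(P_T, p.S_E_per_ME * M_E,
                                          p.S_A_per_MA * M_A, p.K_E, p.K_A)
            assert part.P_free == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_capacity_bounds(self, ref_params):
        part = partition_paxillin(ref_params.P_T, 4.0, 6.0, ref_params)
        assert part.P_E <= ref_params.S_E_per_ME * 4.0 + 1e-12
        assert part.P_A <= ref_params.S_A_per_MA * 6.0 + 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(M_E=st.floats(0.5, 15), M_A=st.floats(0.5, 15),
           bump=st.floats(0.1, 2.0))
    def test_competition_monotonicity(self, M_E, M_A, bump):
        """More endocytic capacity strictly steals paxillin from adhesions."""
        p = SwitchParameters()
        before = partition_paxillin(p.P_T, M_E, M_A, p)
        after = partition_paxillin(p.P_T, M_E + bump, M_A, p)
        assert after.P_E > before.P_E
        assert after.P_A < before.P_A

    def test_rejects_negative_inputs(self, ref_params):
        with pytest.raises(ValueError):
            partition_paxillin(ref_params.P_T, -1.0, 0.0, ref_params)


# --------------------------------------------------------------------------
# right-hand side
# --------------------------------------------------------------------------

class TestRhs:
    def test_zero_flux_limit_feedback_silent(self, soft):
        p = SwitchParameters(kappa=1e-12)  # J_E ~ 0
        for M_E in (0.5, 3.0, 9.0):
            dME, _ = rhs((M_E, 1.0), soft, p)
            assert dME == pytest.approx(p.alpha_E - p.delta_E * M_E, abs=1e-6)

    def test_vanishing_adhesion_drive(self, ref_params):
        cond = SubstrateCondition(1e-6)
        _, dMA = rhs((1.0, 2.0), cond, ref_params)
        # production ~ 0, pure decay
        assert dMA == pytest.approx(-ref_params.delta_A * 2.0, rel=1e-3)

    def test_saturated_feedback_steady_state(self, soft):
        # decoupled M_E equation at J_E >> K_fb settles at (alpha+beta)/delta
        p = SwitchParameters(K_fb=1e-6)
        M_star = (p.alpha_E + p.beta_E) / p.delta_E
        dME, _ = rhs((M_star, 0.0), soft, p)
        assert dME == pytest.approx(0.0, abs=1e-6)

    def test_nonnegativity_preserving_at_origin(self, ref_params, soft, stiff):
        for cond in (soft, stiff):
            dME, dMA = rhs((0.0, 0.0), cond, ref_params)
            assert dME >= ref_params.alpha_E > 0
            assert dMA >= 0


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

class TestSimulate:
    def test_stays_at_stable_fixed_point(self, ref_params, soft):
        fp = [f for f in find_fixed_points(ref_params, soft) if f.stable][0]
        x0 = (fp.state.M_E, fp.state.M_A)
        traj = simulate(ref_params, soft, (0.0, 20.0), initial=x0)
        end = traj.endpoint
        assert end.M_E == pytest.approx(fp.state.M_E, abs=1e-5)
        assert end.M_A == pytest.approx(fp.state.M_A, abs=1e-5)

    def test_deterministic_run_ignores_seed(self, ref_params, soft):
        a = simulate(ref_params, soft, (0.0, 5.0), seed=1)
        b = simulate(ref_params, soft, (0.0, 5.0), seed=999)
        assert np.array_equal([s.M_E for s in a.states], [s.M_E for s in b.states])

    def test_same_seed_bit_identical_with_noise(self, soft):
        p = SwitchParameters(sigma_dyn=0.05)
        a = simulate(p, soft, (0.0, 3.0), seed=7)
        b = simulate(p, soft, (0.0, 3.0), seed=7)
        assert np.array_equal([s.M_E for s in a.states], [s.M_E for s in b.states])
        assert np.array_equal([s.M_A for s in a.states], [s.M_A for s in b.states])

    def test_endpoint_matches_fixed_point(self, ref_params, stiff):
        traj = simulate(ref_params, stiff, (0.0, 400.0))
        end = traj.endpoint
        fps = find_fixed_points(ref_params, stiff)
        dists = [abs(end.M_E - f.state.M_E) + abs(end.M_A - f.state.M_A)
                 for f in fps if f.stable]
        assert min(dists) < 1e-6

    def test_state_invariants_along_trajectory(self, ref_params, soft):
        traj = simulate(ref_params, soft, (0.0, 16.0))
        assert np.all(np.diff(traj.times) > 0)
        for s in traj.states:
            assert s.M_E >= 0 and s.M_A >= 0
            assert s.partition.total == pytest.approx(ref_params.P_T, rel=1e-9)
            assert s.J_E == pytest.approx(ref_params.kappa * s.partition.P_E)
            assert s.R == pytest.approx(ref_params.R0 + ref_params.g_rac * s.J_E)


# --------------------------------------------------------------------------
# fixed points and bifurcation structure
# --------------------------------------------------------------------------

def _nullcline_root_count(params, condition, n_grid=400):
    """Independent oracle: count sign changes of dM_E/dt along the M_A
    nullcline, the latter solved per M_E by bisection."""
    a_E = stiffness_to_adhesion_drive(condition.E_kPa, params)
    MA_hi = 1.05 * params.alpha_A * a_E / params.delta_A + 1e-9

    def MA_star(M_E):
        def r(M_A):
            _, dMA = rhs((M_E, M_A), condition, params)
            return dMA
        lo, hi = 0.0, MA_hi
        assert r(lo) >= 0 and r(hi) <= 0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if r(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    ME_grid = np.linspace(1e-3, 1.05 * (params.alpha_E + params.beta_E) / params.delta_E,
                          n_grid)
    signs = []
    for M_E in ME_grid:
        dME, _ = rhs((M_E, MA_star(M_E)), condition, params)
        signs.append(np.sign(dME))
    signs = np.asarray(signs)
    return int(np.sum(signs[:-1] * signs[1:] < 0))


class TestFixedPoints:
    def test_linear_system_analytic(self, soft):
        # feedback off and no adhesion inhibition: unique analytic steady state
        p = SwitchParameters(beta_E=1e-12, K_i=1e9)
        fps = find_fixed_points(p, soft)
        assert len(fps) == 1
        a_E = stiffness_to_adhesion_drive(soft.E_kPa, p)
        assert fps[0].stable
        assert fps[0].state.M_E == pytest.approx(p.alpha_E / p.delta_E, rel=1e-6)
        assert fps[0].state.M_A == pytest.approx(p.alpha_A * a_E / p.delta_A, rel=1e-6)

    def test_three_fixed_points_inside_window(self, ref_params):
        cond = SubstrateCondition(9.0)  # inside the bistable stiffness window
        fps = find_fixed_points(ref_params, cond, grid_n=16)
        assert len(fps) == 3
        assert sum(f.stable for f in fps) == 2
        assert sum(not f.stable for f in fps) == 1
        # independent nullcline sign-analysis oracle agrees
        assert _nullcline_root_count(ref_params, cond) == 3

    def test_stability_labels_agree_with_simulation(self, ref_params):
        cond = SubstrateCondition(9.0)
        fps = find_fixed_points(ref_params, cond, grid_n=16)
        for fp in fps:
            x0 = np.array([fp.state.M_E, fp.state.M_A]) * 1.02 + 1e-3
            traj = simulate(ref_params, cond, (0.0, 60.0), initial=x0)
            end = np.array([traj.endpoint.M_E, traj.endpoint.M_A])
            ref = np.array([fp.state.M_E, fp.state.M_A])
            if fp.stable:
                assert np.linalg.norm(end - ref) < 1e-3
            else:
                assert np.linalg.norm(end - ref) > 0.1

    def test_residuals_small(self, ref_params, soft, stiff):
        for cond in (soft, stiff):
            for fp in find_fixed_points(ref_params, cond):
                assert fp.residual < 1e-8


@pytest.fixture(scope="module")
def diagram(ref_params):
    return scan_bifurcation(ref_params, np.geomspace(0.05, 50, 30))


class TestBifurcation:
    def test_monostable_when_feedback_off(self):
        p = SwitchParameters(beta_E=1e-12, K_i=1e9)
        d = scan_bifurcation(p, np.geomspace(0.05, 50, 12))
        assert d.bistable_interval is None
        for up, dn in zip(d.up_branch, d.down_branch):
            assert up.M_E == pytest.approx(dn.M_E, abs=1e-4)
            assert up.M_A == pytest.approx(dn.M_A, abs=1e-4)

    def test_bistable_interval_within_study_range(self, diagram):
        """The window separates brain-like from rigid substrates: it exists
        and lies strictly inside (1, 20) kPa."""
        assert diagram.bistable_interval is not None
        lo, hi = diagram.bistable_interval
        assert 1.0 < lo < hi < 20.0
        assert diagram.hysteresis_width > 0

    def test_soft_resolves_endocytic_stiff_resolves_adhesive(self, diagram, ref_params):
        E = diagram.E_grid
        frac_up = np.array([s.partition.P_E / ref_params.P_T for s in diagram.up_branch])
        assert frac_up[E <= 1.0].min() > 0.30     # endocytic-dominant
        assert frac_up[E >= 20.0].max() < 0.15    # adhesion-dominant

    def test_hysteresis_direction(self, diagram, ref_params):
        """Up-sweep leaves the endocytic branch at a higher E than the
        down-sweep re-enters it (fold geometry)."""
        frac_up = np.array([s.partition.P_E / ref_params.P_T for s in diagram.up_branch])
        frac_dn = np.array([s.partition.P_E / ref_params.P_T for s in diagram.down_branch])
        up_trans = diagram.E_grid[np.argmax(frac_up < 0.25)]
        dn_trans = diagram.E_grid[np.argmax(frac_dn < 0.25)]
        assert up_trans >= dn_trans

    def test_monotone_endocytic_fraction_along_branches(self, diagram, ref_params):
        for states in (diagram.up_branch, diagram.down_branch):
            frac = np.array([s.partition.P_E / ref_params.P_T for s in states])
            assert np.all(np.diff(frac) <= 1e-6)


# --------------------------------------------------------------------------
# perturbations
# --------------------------------------------------------------------------

class TestPerturbations:
    def test_none_returns_unchanged(self, ref_params):
        assert apply_perturbation(ref_params, Perturbation("none")) is ref_params

    def test_original_untouched(self, ref_params):
        before = ref_params.P_T
        apply_perturbation(ref_params, Perturbation("paxillin_kd"))
        assert ref_params.P_T == before

    def test_paxillin_kd_default_residual(self, ref_params):
        p = apply_perturbation(ref_params, Perturbation("paxillin_kd"))
        assert p.P_T == pytest.approx(0.2 * ref_params.P_T)

    def test_dynamin_inhibition_zeroes_flux(self, ref_params, soft):
        p = apply_perturbation(ref_params, Perturbation("dynamin_inhibition"))
        traj = simulate(p, soft, (0.0, 16.0))
        assert max(s.J_E for s in traj.states) < 1e-9

    def test_ld13_releases_all_paxillin(self, ref_params):
        p = apply_perturbation(ref_params, Perturbation("pxn_LD13"))
        part = partition_paxillin(p.P_T, 10.0, 10.0, p)
        assert part.P_E < 1e-6 * p.P_T
        assert part.P_A < 1e-6 * p.P_T
        assert part.P_free == pytest.approx(p.P_T, rel=1e-6)

    def test_strength_interpolates(self, ref_params):
        half = apply_perturbation(ref_params, Perturbation("paxillin_kd", 0.5))
        assert half.P_T == pytest.approx(0.5 * ref_params.P_T)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="valid kinds"):
            Perturbation("myosin_kd")


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

class TestEnsemble:
    def test_degenerate_no_variability(self, ref_params, soft):
        p = ref_params.replace(cv_cell=1e-12, sigma_dyn=0.0)
        recs = ensemble(p, soft, n_cells=12, seed=0)
        kinds = {r.phenotype for r in recs}
        assert len(kinds) == 1  # all identical -> fraction 0% or 100%

    def test_reproducible_and_counter_based(self, ref_params, soft):
        a = ensemble(ref_params, soft, n_cells=20, seed=42)
        b = ensemble(ref_params, soft, n_cells=20, seed=42)
        assert [r.multipliers for r in a] == [r.multipliers for r in b]
        assert [r.neurite_bearing for r in a] == [r.neurite_bearing for r in b]
        # growing the ensemble must not reshuffle earlier cells
        big = ensemble(ref_params, soft, n_cells=30, seed=42)
        assert [r.multipliers for r in big[:20]] == [r.multipliers for r in a]

    def test_soft_mostly_segmented_stiff_mostly_broad(self, ref_params, soft, stiff):
        fr_soft = sm.phenotype_fractions(ensemble(ref_params, soft, n_cells=60, seed=3))
        fr_stiff = sm.phenotype_fractions(ensemble(ref_params, stiff, n_cells=60, seed=3))
        assert fr_soft["pct_SL"] > 85.0
        assert fr_stiff["pct_BL"] > 55.0

    def test_stochastic_fractions_approach_deterministic_basin(self, ref_params, soft):
        """cv -> 0: phenotype fractions collapse to the 0/1 indicator of the
        deterministic attractor reached from the common initial condition."""
        p = ref_params.replace(cv_cell=1e-9)
        fr = sm.phenotype_fractions(ensemble(p, soft, n_cells=10, seed=1))
        assert fr["pct_SL"] in (0.0, 100.0)
        assert fr["pct_SL"] == 100.0  # soft resolves endocytic
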