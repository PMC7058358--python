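"""Admissible kinetics, simulation, steady states, Lyapunov decrease along
trajectories, safety levels and flux bounds."""

import numpy as np
import pytest

from crnlyap import core, fixtures, kinetics as kin, rlf


class TestRateLaws:
    def test_mass_action_bimolecular_value(self, ptm_full):
        K = kin.mass_action(ptm_full, 1.0)
        x = np.zeros(6)
        x[ptm_full.species_index("S")] = 2.0
        x[ptm_full.species_index("E")] = 3.0
        assert K(x)[0] == pytest.approx(6.0)

    @pytest.mark.parametrize("law", ["mass_action", "michaelis_menten",
                                     "hill"])
    def test_zero_reactant_gives_zero_rate(self, ptm_full, law):
        K = kin.make_kinetics(ptm_full, law)
        x = np.ones(6)
        x[ptm_full.species_index("E")] = 0.0
        assert K(x)[0] == 0.0

    def test_parameter_validation(self, ptm_full):
        with pytest.raises(ValueError):
            kin.make_kinetics(ptm_full, "mass_action",
                              {"k": -np.ones(6)})
        with pytest.raises(ValueError):
            kin.Kinetics(ptm_full, [kin.RateLaw("hill", hill=0.5)] * 6)

    @pytest.mark.parametrize("law", ["mass_action", "michaelis_menten",
                                     "hill"])
    def test_jacobian_sign_pattern_matches_pairs(self, ptm_full, law, rng):
        """Finite-difference dR/dx is positive exactly on the
        reaction-reactant pair set at random positive states."""
        K = kin.make_kinetics(ptm_full, law)
        pairs = set(ptm_full.reactant_pairs())
        for _ in range(100):
            x = rng.uniform(0.2, 4.0, 6)
            base = K(x)
            for i in range(6):
                xp = x.copy()
                xp[i] += 1e-6
                d = (K(xp) - base) / 1e-6
                for j in range(6):
                    if (j, i) in pairs:
                        assert d[j] > 0
                    else:
                        assert abs(d[j]) < 1e-9


class TestSimulate:
    def test_first_order_decay_closed_form(self):
        net = core.parse_network("A -> B")
        traj = kin.simulate(net, kin.mass_action(net, 1.0), [1.0, 0.0], 10.0)
        assert np.max(np.abs(traj.x[0] - np.exp(-traj.t))) < 1e-6
        assert traj.min_state > -1e-9

    def test_conservation_constant_along_ptm(self, ptm_full):
        K = kin.mass_action(ptm_full, 1.0)
        traj = kin.simulate(ptm_full, K, [10., 10., 0., 0., 10., 0.], 50.0)
        assert traj.conservation_drift < 1e-6

    def test_negative_start_rejected(self, ptm_full):
        with pytest.raises(ValueError):
            kin.simulate(ptm_full, kin.mass_action(ptm_full), -np.ones(6), 1.0)


class TestSteadyState:
    def test_ptm_printed_steady_state(self, ptm_full):
        """Unit kinetics, totals (10, 10, 10): free substrate and free
        enzymes converge to (-7 + sqrt(89)) / 2 and that value + 5."""
        K = kin.mass_action(ptm_full, 1.0)
        ss = kin.steady_state(ptm_full, K, x0=[10., 10., 0., 0., 10., 0.])
        assert ss.converged and ss.residual <= 1e-10
        ref = (-7 + np.sqrt(89)) / 2
        assert ss.x[ptm_full.species_index("S")] == pytest.approx(ref,
                                                                  abs=1e-6)
        assert ss.x[ptm_full.species_index("E")] == pytest.approx(ref + 5,
                                                                  abs=1e-6)
        assert round(ss.x[ptm_full.species_index("S")], 6) == 1.216991

    def test_symmetric_isomerization(self):
        net = core.parse_network("A <-> B")
        ss = kin.steady_state(net, kin.mass_action(net, 1.0), x0=[1.0, 0.0])
        assert np.allclose(ss.x, [0.5, 0.5], atol=1e-9)

    def test_residual_small_across_fixtures(self, rng):
        for name in ["ptm_full", "transcription", "enzymatic_motif",
                     "kinetic_proofreading", "erk_rkip"]:
            net = fixtures.fixture(name)
            k = rng.uniform(0.5, 2.0, net.n_reactions)
            K = kin.mass_action(net, k)
            x0 = rng.uniform(0.5, 3.0, net.n_species)
            ss = kin.steady_state(net, K, x0=x0)
            assert ss.residual <= 1e-8

    def test_class_values_start(self, ptm_full):
        K = kin.mass_action(ptm_full, 1.0)
        cons = core.conservation_analysis(ptm_full)
        vals = [10.0] * len(cons.nonneg_laws)
        ss = kin.steady_state(ptm_full, K, class_values=vals)
        assert ss.residual <= 1e-9


class TestDiniDecrease:
    def test_soc_decreases_along_random_trajectories(self, ptm_full, rng):
        soc = rlf.construct_soc(ptm_full)
        for _ in range(5):
            K = kin.mass_action(ptm_full, rng.uniform(0.3, 3.0, 6))
            x0 = rng.uniform(0.0, 5.0, 6)
            traj = kin.simulate(ptm_full, K, x0, 40.0, n_points=2000)
            assert kin.dini_decrease_check(traj, soc) <= \
                kin.dini_threshold(traj, soc)

    def test_constant_trajectory_at_steady_state(self, ptm_full):
        K = kin.mass_action(ptm_full, 1.0)
        ss = kin.steady_state(ptm_full, K, x0=[10., 10., 0., 0., 10., 0.])
        traj = kin.simulate(ptm_full, K, ss.x, 5.0)
        soc = rlf.construct_soc(ptm_full)
        assert np.max(soc.values(traj.r)) <= 1e-6

    def test_wrong_function_detected(self, ptm_full, rng):
        bad = rlf.PWLCandidate(np.array([[0., 0., 1., 0., 0., 0.],
                                         [0., 0., -1., 0., 0., 0.]]),
                               form="max")
        K = kin.mass_action(ptm_full, 1.0)
        traj = kin.simulate(ptm_full, K, [5., 3., 2., 1., 7., 3.], 30.0,
                            n_points=2000)
        assert kin.dini_decrease_check(traj, bad) > \
            kin.dini_threshold(traj, bad)


class TestSafety:
    def test_slice_minimum_protects_trajectories(self, ptm_full, rng):
        soc = rlf.construct_soc(ptm_full)
        K = kin.mass_action(ptm_full, 1.0)
        sl = kin.safety_level(soc, ptm_full, K, "S", 2.5, [10., 10., 10.])
        assert sl.alpha is not None and sl.alpha > 0
        # trajectories starting strictly inside the level set stay below
        from scipy.optimize import linprog
        cons = core.conservation_analysis(ptm_full)
        L = np.vstack([np.asarray(d, dtype=float) for d in cons.nonneg_laws])
        ss = kin.steady_state(ptm_full, K, x0=[10., 10., 0., 0., 10., 0.])
        checked = 0
        for _ in range(200):
            res = linprog(c=rng.standard_normal(6), A_eq=L,
                          b_eq=[10., 10., 10.], bounds=[(0, None)] * 6,
                          method="highs")
            # interpolate toward the steady state to sample the sublevel set
            t = rng.uniform(0.0, 1.0)
            x0 = ss.x + t * (res.x - ss.x)
            if soc.value(K(x0)) < 0.95 * sl.alpha:
                traj = kin.simulate(ptm_full, K, x0, 50.0, n_points=500)
                assert traj.x[ptm_full.species_index("S")].max() <= 2.5 + 1e-6
                checked += 1
            if checked >= 50:
                break
        assert checked >= 10

    def test_unreachable_bound_is_unbounded_safe(self, ptm_full):
        soc = rlf.construct_soc(ptm_full)
        K = kin.mass_action(ptm_full, 1.0)
        sl = kin.safety_level(soc, ptm_full, K, "S", 11.0, [10., 10., 10.])
        assert sl.unbounded_safe

    def test_monotone_in_bound(self, ptm_full):
        soc = rlf.construct_soc(ptm_full)
        K = kin.mass_action(ptm_full, 1.0)
        a25 = kin.safety_level(soc, ptm_full, K, "S", 2.5, [10.] * 3).alpha
        a30 = kin.safety_level(soc, ptm_full, K, "S", 3.0, [10.] * 3).alpha
        assert a25 <= a30 + 1e-9


class TestFluxBound:
    def _setup(self, proofreading2):
        soc = rlf.construct_soc(proofreading2)
        xi = np.array([float(x) for x in soc.xi])
        C = xi[:, None] * proofreading2.Gamma.astype(float)
        r_init = np.zeros(6)
        r_init[0] = 1.0
        obj = next(j for j, rx in enumerate(proofreading2.reactions)
                   if rx.reactants == {"C2": 1}
                   and rx.products == {"M": 1, "L": 1})
        return C, r_init, obj

    def test_terminal_flux_bound_is_three(self, proofreading2):
        """The weighted-currents flux LP for the N=2 proofreading chain:
        r6* = 3 r1*."""
        C, r_init, obj = self._setup(proofreading2)
        fb = kin.flux_bound(proofreading2, C, r_init, obj, 0, 1.0)
        assert fb.optimum == pytest.approx(3.0, abs=1e-8)

    def test_capped_flux_objective_returns_cap(self, proofreading2):
        C, r_init, _ = self._setup(proofreading2)
        fb = kin.flux_bound(proofreading2, C, r_init, 0, 0, 1.0)
        assert fb.optimum == pytest.approx(1.0, abs=1e-9)

    def test_zero_initial_flux_forces_zero(self, proofreading2):
        C, _, obj = self._setup(proofreading2)
        fb = kin.flux_bound(proofreading2, C, np.zeros(6), obj, 0, 0.0)
        assert fb.optimum == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_initial_flux(self, proofreading2):
        C, _, obj = self._setup(proofreading2)
        vals = []
        for r1 in (0.5, 1.0, 2.0):
            r_init = np.zeros(6)
            r_init[0] = r1
            vals.append(kin.flux_bound(proofreading2, C, r_init, obj,
                                       0, r1).optimum)
        assert vals == sorted(vals)

    def test_soc_infnorm_conversion_rows(self, proofreading2):
        soc = rlf.construct_soc(proofreading2)
        C = kin.soc_to_infnorm(soc.xi, proofreading2)
        assert C.shape == (16, 6)
        # the conversion reproduces the 1-norm
        rng = np.random.default_rng(0)
        xi = np.array([float(x) for x in soc.xi])
        G = proofreading2.Gamma.astype(float)
        for _ in range(50):
            r = rng.standard_normal(6)
            assert np.max(np.abs(C @ r)) == pytest.approx(
                np.sum(np.abs(xi * (G @ r))), rel=1e-9)


class TestRateLawInversion:
    def test_linear_law_is_identity(self):
        law = kin.RateLaw("mass_action", k=1.0)
        assert kin.invert_rate_law(law, 3.0) == pytest.approx(3.0)

    def test_michaelis_menten_printed_curve(self):
        law = kin.RateLaw("michaelis_menten", k=1.0, K={"b": 0.1})
        assert kin.invert_rate_law(law, 3.0) == pytest.approx(3 / 0.7,
                                                              rel=1e-9)

    def test_saturation_is_unreachable(self):
        law = kin.RateLaw("michaelis_menten", k=1.0, K={"b": 0.1})
        assert kin.invert_rate_law(law, 10.0) is None
        assert kin.invert_rate_law(law, 12.0) is None


class TestBistability:
    def test_distributive_double_cycle_witness(self, distributive):
        """Random parameter search finds two distinct stable steady states
        in one stoichiometric class (qualitative multistability witness)."""
        w = kin.find_bistability(distributive, ["X0", "X1", "X2"],
                                 ["E", "F"], seed=0, n_trials=25)
        assert w is not None
        assert w.separation > 5.0
        assert max(w.residuals) < 1e-6
        # both limits lie in the same stoichiometric class
        cons = core.conservation_analysis(distributive)
        for d in cons.nonneg_laws:
            df = np.asarray(d, dtype=float)
            assert df @ w.limit_a == pytest.approx(df @ w.limit_b, rel=1e-6)
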