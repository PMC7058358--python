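"""Robust-Lyapunov-function construction and verification."""

import numpy as np
import pytest

from crnlyap import core, fixtures, rlf
from crnlyap._exact import as_float
from crnlyap._sdp import sampled_pwq_check


def soc_candidate(net, xi, part=None):
    """Build the partition-form candidate for V = sum xi_i |xdot_i|."""
    part = part or rlf.build_partition(net)
    G = net.Gamma
    xi = np.asarray(xi, dtype=float)
    C = np.array([(sig * xi) @ G for sig in part.signatures])
    return rlf.PWLCandidate(C, form="abs", partition=part, xi=xi)


class TestPartition:
    def test_identity_two_dim(self):
        net = core.Network.from_matrices([[1, 0], [0, 1]], [[0, 0], [0, 0]])
        part = rlf.build_partition(net, H=np.eye(2))
        assert part.n_regions == 2      # 4 signatures, 2 kept up to sign

    def test_reversible_pair_collapses_regions(self):
        net = core.parse_network("A <-> B")
        part = rlf.build_partition(net)
        # rows (-1,1) and (1,-1): only (+,-) and (-,+) have interior
        assert part.n_regions == 1
        assert part.signatures[0].tolist() == [1, -1]

    def test_ptm_regions_match_sampling_oracle(self, ptm_full, rng):
        part = rlf.build_partition(ptm_full)
        Hf = ptm_full.Gamma.astype(float)
        seen = set()
        for _ in range(100_000):
            y = Hf @ rng.standard_normal(ptm_full.n_reactions)
            if np.all(np.abs(y) > 1e-9):
                sig = tuple(np.sign(y).astype(int))
                seen.add(sig if sig[0] > 0 else tuple(-s for s in sig))
        kept = {tuple(s) for s in part.signatures}
        assert kept == seen

    def test_rejects_rows_outside_row_space(self, ptm_full):
        with pytest.raises(ValueError):
            rlf.build_partition(ptm_full, extra_rows=[[1, 0, 0, 0, 0, 0]])

    def test_accepts_row_sums(self, ptm_full):
        G = ptm_full.Gamma
        part = rlf.build_partition(ptm_full, extra_rows=[G[0] + G[1]])
        assert part.p == ptm_full.n_species + 1


class TestVerify:
    def test_simple_binding_rate_difference(self):
        net = fixtures.simple_binding()
        part = rlf.build_partition(net, H=np.array([[1, -1], [-1, 1]]))
        cand = rlf.PWLCandidate(np.array([[1.0, -1.0]]), form="abs",
                                partition=part)
        assert rlf.verify_pwl(net, cand).passed

    def test_constructed_violation_fails_with_witness(self, ptm_full):
        # V = R2 alone cannot decrease for all kinetics
        bad = rlf.PWLCandidate(np.array([[0., 0., 1., 0., 0., 0.],
                                         [0., 0., -1., 0., 0., 0.]]),
                               form="max")
        v = rlf.verify_pwl(ptm_full, bad)
        assert not v.passed

    def test_kernel_mismatch_detected(self, ptm_full):
        part = rlf.build_partition(ptm_full)
        C = np.zeros((part.n_regions, 6))
        C[:, 0] = 1.0                      # rank 1 < rank Gamma
        cand = rlf.PWLCandidate(C, form="abs", partition=part)
        v = rlf.verify_pwl(ptm_full, cand)
        assert not v.passed and "kernel" in v.reason

    def test_ptm_four_term_current_sum(self, ptm_full, rng):
        """The 4-term absolute-current certificate for the PTM cycle
        (|SEdot| + |S+dot| + |S+Fdot| + |Sdot|, i.e. half the weight-(2,1,1,
        2,1,1) sum of currents), encoded in max form, passes the LP verifier
        and an independent finite-difference decrease check."""
        rows = np.array([[1, -1, -1, 0, 0, 0],     # R1-R-1-R2   (SE current)
                         [0, 0, 1, -1, 1, 0],      # R2-R3+R-3   (S+ current)
                         [0, 0, 0, 1, -1, -1],     # R3-R-3-R4   (S+F current)
                         [1, -1, 0, 0, 0, -1]],    # R1-R-1-R4   (-S current)
                        dtype=float)
        import itertools
        C = np.array([sg @ rows
                      for sg in [np.array(x, dtype=float) for x in
                                 itertools.product((1, -1), repeat=4)]])
        cand = rlf.PWLCandidate(C, form="max", convex=True)
        assert rlf.verify_pwl(ptm_full, cand).passed
        # it agrees with the computed SoC certificate up to the factor 2
        soc = rlf.construct_soc(ptm_full)
        assert [int(x) for x in soc.xi] == [2, 1, 1, 2, 1, 1]
        for _ in range(50):
            r = rng.standard_normal(6)
            assert 2 * cand.value(r) == pytest.approx(soc.value(r), rel=1e-9)
        ex = core.extremals(ptm_full)
        Qs = [Q.astype(float) for Q in ex.Qs]
        for _ in range(1000):
            rho = rng.exponential(1.0, ex.s)
            r = rng.standard_normal(6)
            v = sum(rl * (Q @ r) for rl, Q in zip(rho, Qs))
            h = 1e-7
            dv = (cand.value(r + h * v) - cand.value(r)) / h
            assert dv <= 1e-6 * (1 + np.linalg.norm(v))


class TestSoC:
    @pytest.mark.parametrize("make,printed", [
        (lambda: fixtures.kinetic_proofreading(2), [1, 1, 2, 2, 2]),
        (lambda: fixtures.multisite_distinct(2),
         [2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1]),
    ])
    def test_printed_weight_vectors(self, make, printed):
        net = make()
        cand = rlf.construct_soc(net)
        assert cand is not None
        assert [int(x) for x in cand.xi] == printed
        assert rlf.verify_pwl(net, cand).passed

    def test_transcription_printed_weights_verify(self):
        """The published diag(1,1,1,3) weighted sum-of-currents function is a
        valid certificate; the LP minimizer (1,1,1,1) is one as well."""
        net = fixtures.transcription()
        cand = rlf.construct_soc(net)
        assert cand is not None and [int(x) for x in cand.xi] == [1, 1, 1, 1]
        assert rlf.verify_pwl(net, cand).passed
        assert rlf.verify_pwl(net, soc_candidate(net, [1, 1, 1, 3])).passed

    def test_a_b_unit_weights(self):
        net = core.parse_network("A <-> B")
        cand = rlf.construct_soc(net)
        assert [int(x) for x in cand.xi] == [1, 1]
        assert rlf.verify_pwl(net, cand).passed

    def test_requires_positive_flux(self):
        assert rlf.construct_soc(core.parse_network("A -> B")) is None


class TestLP:
    def test_a_b_recovers_rate_difference(self):
        net = core.parse_network("A <-> B")
        cand, cert = rlf.construct_pwl_lp(net)
        C = cand.Cf
        assert C.shape[0] == 1
        # C = (1,-1) up to positive scaling (sign fixed by the region)
        ratio = C[0] / np.array([-1.0, 1.0])
        assert np.allclose(ratio, ratio[0]) and ratio[0] > 0
        assert rlf.verify_pwl(net, cand).passed

    def test_distributive_double_infeasible(self, distributive):
        assert rlf.construct_pwl_lp(distributive) is None

    def test_receptor_open_problem_stays_open(self):
        net = fixtures.receptor_ptm_open()
        assert rlf.construct_pwl_lp(net) is None

    def test_certificate_identities(self, ptm_full):
        part = rlf.build_partition(ptm_full)
        cand, cert = rlf.construct_pwl_lp(ptm_full, part)
        assert cand.kernel_ok
        H = as_float(part.H)
        ex = core.extremals(ptm_full)
        for k in range(part.n_regions):
            SkH = part.signatures[k][:, None] * H
            assert np.allclose(cand.Cf[k], cert.xi[k] @ SkH, atol=1e-7)
            assert cert.xi[k].min() > -1e-9
            for l, Q in enumerate(ex.Qs):
                lhs = cand.Cf[k] @ Q.astype(float)
                assert np.allclose(lhs, -cert.lam[(k, l)] @ H, atol=1e-7)
                assert (part.signatures[k] * cert.lam[(k, l)]).min() > -1e-7

    def test_force_convex_still_succeeds(self, ptm_full):
        out = rlf.construct_pwl_lp(ptm_full, force_convex=True)
        assert out is not None and rlf.verify_pwl(ptm_full, out[0]).passed


class TestIterate:
    def test_translation_three_piece_function(self):
        """The ribosome/mRNA subnetwork terminates with the published
        three-piece function (up to closure under negation)."""
        net = fixtures.translation_core()
        cand = rlf.iterate_convex(net)
        assert cand is not None
        rows = {tuple(r) for r in cand.C.tolist()}
        printed = {(0, 0, 0, 1),          # R4
                   (1, -1, -1, -1),       # R1-R2-R3-R4
                   (-1, 1, 1, 0)}         # -R1+R2+R3
        assert printed <= rows
        assert rows == printed | {tuple(-x for x in r) for r in printed}
        assert rlf.verify_pwl(net, cand).passed

    def test_enzymatic_motif_function(self):
        net = fixtures.enzymatic_motif()
        cand = rlf.iterate_convex(net)
        rows = {tuple(r) for r in cand.C.tolist()}
        assert {(1, -1, 0), (-1, 1, 0), (0, 0, 1)} <= rows
        assert rlf.verify_pwl(net, cand).passed

    def test_simple_irreversible_conversion(self):
        net = core.parse_network("A -> B")
        cand = rlf.iterate_convex(net)
        assert cand is not None and rlf.verify_pwl(net, cand).passed

    def test_cap_returns_none(self, distributive):
        assert rlf.iterate_convex(distributive, n_max=40) is None


class TestMaxMin:
    @pytest.mark.parametrize("make,labels", [
        (fixtures.ptm_full, ["R1-R-1", "R2", "R3-R-3", "R4"]),
        (lambda: fixtures.ribosome_flow(3), ["R1", "R2", "R3", "R4"]),
        (fixtures.erk_rkip,
         ["R1-R-1", "R2", "R3-R-3", "R4", "R5-R-5", "R6-R-6", "R7"]),
        (lambda: fixtures.phosphorelay(3),
         ["R1", "R2", "R3-R-3", "R4-R-4", "R5-R-5", "R6-R-6"]),
    ])
    def test_printed_rate_sets(self, make, labels):
        net = make()
        mm = rlf.graphical_maxmin(net)
        assert isinstance(mm, rlf.MaxMinRLF)
        assert mm.labels == labels
        assert rlf.verify_pwl(net, mm).passed

    def test_simple_binding_zero_appended(self):
        mm = rlf.graphical_maxmin(fixtures.simple_binding())
        assert mm.include_zero and mm.labels == ["R1-R-1", "0"]
        # V = |R1 - R-1|
        assert mm.value([2.0, 0.5]) == pytest.approx(1.5)

    def test_binding_inflow_printed_set(self):
        mm = rlf.graphical_maxmin(fixtures.binding_inflow())
        assert mm.labels == ["R1-R-1", "R2-R-2", "0"]

    def test_non_m_network_refused(self):
        out = rlf.graphical_maxmin(fixtures.multisite_distinct(2))
        assert not isinstance(out, rlf.MaxMinRLF)
        assert out.reason == "not-an-M-network"

    def test_autocatalytic_refused(self):
        net = core.parse_network("D -> D + M\nM -> 0")
        out = rlf.graphical_maxmin(net)
        assert not isinstance(out, rlf.MaxMinRLF)
        assert out.reason == "autocatalytic"

    def test_vanishes_exactly_on_kernel(self, ptm_full, rng):
        mm = rlf.graphical_maxmin(ptm_full)
        from crnlyap._exact import nullspace
        for v in nullspace(ptm_full.Gamma):
            assert mm.value(as_float(v)) == pytest.approx(0.0, abs=1e-12)
        G = ptm_full.Gamma.astype(float)
        for _ in range(1000):
            r = rng.standard_normal(6)
            if np.max(np.abs(G @ r)) > 1e-6:
                assert mm.value(r) > 1e-9


class TestPWQ:
    def test_a_b_rank_one_point(self):
        net = core.parse_network("A <-> B")
        cand = rlf.construct_pwq_sdp(net)
        assert cand is not None
        # P = c c^T with c = (1,-1) up to positive scaling
        P = cand.Ps[0]
        assert np.allclose(P / P[0, 0], [[1, -1], [-1, 1]])

    def test_ptm_feasible_via_pwl(self, ptm_full):
        cand = rlf.construct_pwq_sdp(ptm_full)
        assert cand is not None and cand.residual <= 1e-6
        dec, neg = sampled_pwq_check(ptm_full, cand, 4000, seed=3)
        assert dec <= 1e-6 and neg <= 1e-9

    def test_as1_required(self):
        assert rlf.construct_pwq_sdp(core.parse_network("A -> B")) is None


class TestCrossRouteConsistency:
    """Certificates from independent construction routes all pass the
    region-wise verification LPs and the randomized decrease oracle."""

    @pytest.mark.parametrize("name,builder", [
        ("graphical", lambda net: rlf.graphical_maxmin(net)),
        ("soc", lambda net: rlf.construct_soc(net)),
        ("lp", lambda net: rlf.construct_pwl_lp(net)[0]),
    ])
    def test_ptm_all_routes(self, ptm_full, name, builder):
        cand = builder(ptm_full)
        assert cand is not None and not isinstance(cand, rlf.MaxMinFailure)
        assert rlf.verify_pwl(ptm_full, cand).passed
        assert rlf.sampled_decrease_check(ptm_full, cand, 2000, seed=11) <= 1e-7

    def test_maxmin_and_soc_share_kernel(self, ptm_full):
        mm = rlf.graphical_maxmin(ptm_full)
        soc = rlf.construct_soc(ptm_full)
        from crnlyap._exact import nullspace
        for v in nullspace(ptm_full.Gamma):
            vf = as_float(v)
            assert mm.value(vf) == pytest.approx(0.0, abs=1e-12)
            assert soc.value(vf) == pytest.approx(0.0, abs=1e-12)
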