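"""Homotopy solve, branch tracing, fold detection and flow-state labels."""

import numpy as np
import pytest

from hemonet.continuation import (classify_flow_state, continuation_equilibria,
                                  continue_branch, dedup_folds, detect_folds,
                                  enumerate_equilibria, equilibria_at,
                                  homotopy_initial_solve, multistart_equilibria,
                                  parameter_handle, redundant_vessel_order)
from hemonet.fixtures import FixtureSpec, build_extended_triangle, build_triangle
from hemonet.steady_state import canonicalize, compile_network
from hemonet.topology import enumerate_feasible_orientations


class TestHomotopy:
    def test_triangle_default_lands_on_known_equilibrium(self, triangle_sys,
                                                         triangle_equilibria):
        st = homotopy_initial_solve(triangle_sys)
        assert st.residual_norm() < 1e-10
        x = canonicalize(triangle_sys, st.x)
        assert min(np.max(np.abs(x - e.x)) for e in triangle_equilibria) < 1e-8

    def test_zero_haematocrit_reduces_to_linear_solution(self):
        net = build_triangle(FixtureSpec(h_in=0.0))
        sysm = compile_network(net)
        from hemonet.steady_state import solve_zero_haematocrit
        st = homotopy_initial_solve(sysm)
        lin = solve_zero_haematocrit(sysm)
        assert np.max(np.abs(st.x - lin.x)) < 1e-9

    def test_extended_triangle_contract(self, extended_sys):
        st = homotopy_initial_solve(extended_sys)
        assert st.residual_norm() < 1e-10
        H = extended_sys.haematocrits(st.x)
        assert np.all(H >= -1e-12) and np.all(H < 1.0)


class TestBranches:
    def test_branch_points_are_equilibria(self, triangle_beta_sweep):
        for br in triangle_beta_sweep.branches:
            for i in range(0, len(br), 7):
                br.ps.handle.set(br.ps.sys, br.lams[i])
                assert np.max(np.abs(br.ps.sys.residual(br.xs[i]))) < 1e-10

    def test_triangle_fold_pair(self, triangle_beta_sweep):
        lams = sorted(triangle_beta_sweep.fold_lams)
        assert len(lams) == 2
        # near-mirror placement of the folds about the symmetric geometry
        assert lams[0] + lams[1] == pytest.approx(2.0, abs=0.01)

    def test_fold_jacobian_near_singular(self, triangle_beta_sweep):
        br = triangle_beta_sweep.branches[0]
        for f in triangle_beta_sweep.folds:
            br.ps.handle.set(br.ps.sys, f.lam)
            sv = np.linalg.svd(br.ps.sys.jacobian(f.x), compute_uv=False)
            assert sv[-1] < 1e-6 * sv[0]

    def test_linear_network_branch_is_fold_free(self):
        net = build_triangle(FixtureSpec(h_in=0.0))
        sysm = compile_network(net)
        from hemonet.steady_state import solve_zero_haematocrit
        st = solve_zero_haematocrit(sysm)
        br = continue_branch(sysm, "beta", (0.5, 1.5), st, start_lam=1.0)
        assert detect_folds(br) == []
        assert br.lams.min() == pytest.approx(0.5, abs=1e-9)
        assert br.lams.max() == pytest.approx(1.5, abs=1e-9)

    def test_start_outside_range_rejected(self, triangle_sys, triangle_equilibria):
        with pytest.raises(ValueError):
            continue_branch(triangle_sys, "beta", (1.2, 1.5),
                            triangle_equilibria[0], start_lam=1.0)


class TestEnumeration:
    def test_counts_at_defaults(self, triangle_equilibria, extended_equilibria):
        assert len(triangle_equilibria) == 3
        assert len(extended_equilibria) == 9

    def test_zero_inlet_haematocrit_unique(self):
        net = build_extended_triangle(FixtureSpec(h_in=0.0))
        eq = enumerate_equilibria(net, n_starts=100, seed=0, method="multistart")
        assert len(eq) == 1
        q = eq[0].flows()
        assert np.max(np.abs(q[[2, 5]])) < 1e-10  # cross vessels carry no flow

    def test_continuation_route_matches_multistart_at_defaults(self, triangle_sys,
                                                               triangle_equilibria):
        cont = continuation_equilibria(triangle_sys)
        assert len(cont) == len(triangle_equilibria)
        for c in cont:
            assert min(np.max(np.abs(c.x - e.x)) for e in triangle_equilibria) < 1e-7

    def test_induced_orientations_are_feasible(self, extended_net,
                                               extended_equilibria):
        feas = {o.directions for o in enumerate_feasible_orientations(extended_net)}
        for st in extended_equilibria:
            dirs = st.induced_directions()
            # vessels with exactly zero flow have undefined direction; any
            # completion must match some feasible orientation
            ok = any(all(d == 0 or d == f[i] for i, d in enumerate(dirs))
                     for f in feas)
            assert ok

    def test_equilibria_at_interpolates_branch_crossings(self, triangle_beta_sweep):
        xs = equilibria_at(triangle_beta_sweep.branches, 0.99)
        dedup = []
        for x in xs:
            if not any(np.max(np.abs(x - y)) < 1e-6 for y in dedup):
                dedup.append(x)
        assert len(dedup) == 3


class TestClassification:
    def test_triangle_labels(self, triangle_equilibria, triangle_labels):
        assert sorted(triangle_labels) == [("-",), ("0",), ("+",)] or \
            set(triangle_labels) == {("-",), ("0",), ("+",)}

    def test_intermediate_state_has_zero_cross_flow_at_symmetry(
            self, triangle_equilibria, triangle_labels):
        mid = triangle_equilibria[triangle_labels.index(("0",))]
        assert abs(mid.flow(4, 5)) < 1e-9
        assert mid.haematocrit(4, 5) < 1e-9

    def test_extended_labels_distinct_and_complete(self, extended_labels):
        assert len(set(extended_labels)) == 9
        assert set(extended_labels) == {(a, b) for a in "-0+" for b in "-0+"}

    def test_intermediate_cross_vessels_carry_no_cells(self, extended_equilibria,
                                                       extended_labels):
        for st, (l78, l45) in zip(extended_equilibria, extended_labels):
            if l78 == "0":
                assert st.haematocrit(7, 8) < 0.01
            if l45 == "0":
                assert st.haematocrit(4, 5) < 0.01

    def test_redundant_vessel_order_inlet_first(self, extended_net):
        assert redundant_vessel_order(extended_net) == [(7, 8), (4, 5)]


class TestUpperBound:
    @pytest.mark.parametrize("draw", range(4))
    def test_count_never_exceeds_three_to_the_r(self, draw):
        rng = np.random.default_rng(100 + draw)
        spec = FixtureSpec(alpha=float(rng.uniform(0.05, 0.8)),
                           beta=float(rng.uniform(0.5, 1.8)),
                           h_in=float(rng.uniform(0.1, 0.55)))
        net = build_triangle(spec) if draw % 2 == 0 else build_extended_triangle(spec)
        bound = 3 if draw % 2 == 0 else 9
        eq = enumerate_equilibria(net, n_starts=150, seed=draw, method="multistart")
        assert 1 <= len(eq) <= bound
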