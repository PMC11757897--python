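"""Network equation assembly, conservation laws and Newton solves."""

import numpy as np
import pytest

from hemonet.fixtures import (FixtureSpec, build_extended_triangle, build_triangle,
                              mirror_permutation)
from hemonet.rheology import RheologyParams, apparent_viscosity
from hemonet.steady_state import (compile_network, frozen_haematocrit_start,
                                  global_rbc_balance, newton_solve,
                                  solve_zero_haematocrit, signed_flows)
from hemonet.topology import relabel_network


def kirchhoff_oracle(net):
    """Independent dense Kirchhoff solve at zero haematocrit (plasma only)."""
    ids = [n.id for n in net.nodes]
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    G = np.zeros((n, n))
    for v in net.vessels:
        mu = apparent_viscosity(0.0, v.diameter)
        g = np.pi * v.diameter**4 / (128.0 * v.length * mu)
        a, b = idx[v.start], idx[v.end]
        G[a, a] += g; G[b, b] += g
        G[a, b] -= g; G[b, a] -= g
    interior = [idx[m.id] for m in net.interior_nodes]
    boundary = [i for i in range(n) if i not in interior]
    pb = np.array([net.node_map()[ids[i]].pressure for i in boundary])
    P = np.zeros(n)
    P[boundary] = pb
    P[interior] = np.linalg.solve(G[np.ix_(interior, interior)],
                                  -G[np.ix_(interior, boundary)] @ pb)
    flows = {}
    for v in net.vessels:
        mu = apparent_viscosity(0.0, v.diameter)
        R = 128.0 * v.length * mu / (np.pi * v.diameter**4)
        flows[v.key] = (P[idx[v.start]] - P[idx[v.end]]) / R
    qin = sum(flows[v.key] for v in net.inlet_vessels())
    return {k: q / qin for k, q in flows.items()}


class TestZeroHaematocrit:
    def test_symmetric_extended_triangle_has_no_cross_flow(self):
        net = build_extended_triangle(FixtureSpec(h_in=0.0))
        st = solve_zero_haematocrit(net)
        q = signed_flows(net, st)
        assert abs(q[(4, 5)]) < 1e-12
        assert abs(q[(7, 8)]) < 1e-12

    def test_against_independent_kirchhoff_solve(self):
        net = build_triangle(FixtureSpec(beta=2.0, h_in=0.0))
        st = solve_zero_haematocrit(net)
        expect = kirchhoff_oracle(net)
        got = signed_flows(net, st)
        for k in expect:
            assert got[k] == pytest.approx(expect[k], abs=1e-12)

    def test_residual_vanishes_when_inlets_carry_no_cells(self):
        net = build_triangle(FixtureSpec(h_in=0.0))
        sysm = compile_network(net)
        st = solve_zero_haematocrit(sysm)
        assert np.max(np.abs(sysm.residual(st.x))) < 1e-12


class TestFlows:
    def test_symmetric_state_flows(self, triangle_sys):
        # frozen uniform haematocrit at beta = 1 is the symmetric equilibrium:
        # no cross flow, half the inflow through each inlet
        x = frozen_haematocrit_start(triangle_sys)
        q = dict(zip(triangle_sys.vessel_keys, triangle_sys.flows(x)))
        assert abs(q[(4, 5)]) < 1e-12
        assert q[(1, 4)] == pytest.approx(0.5, abs=1e-12)
        assert q[(2, 5)] == pytest.approx(0.5, abs=1e-12)

    def test_inlet_flows_normalised_to_one(self, extended_sys):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.concatenate([rng.uniform(0.05, 0.45, extended_sys.n_interior),
                                rng.uniform(0.0, 0.6, extended_sys.n_unknowns
                                            - extended_sys.n_interior)])
            q = extended_sys.flows(x)
            assert q[extended_sys.inlet_mask].sum() == pytest.approx(1.0, abs=1e-12)


class TestJacobian:
    def test_directional_derivative(self, triangle_sys):
        # evaluated away from the symmetric state, where the assembly would
        # sit exactly on a junction-type switch and be non-smooth
        rng = np.random.default_rng(1)
        x = frozen_haematocrit_start(triangle_sys) + rng.uniform(0.01, 0.05, 7)
        J = triangle_sys.jacobian(x)
        d = rng.normal(size=len(x))
        d /= np.linalg.norm(d)
        h = 1e-6
        fd = (triangle_sys.residual(x + h * d) - triangle_sys.residual(x - h * d)) / (2 * h)
        assert np.max(np.abs(J @ d - fd)) < 1e-6

    def test_quadratic_calibration(self):
        # the central-difference formula recovers the derivative of a smooth
        # quadratic to high accuracy (step calibration check)
        A = np.array([[2.0, 0.5], [0.5, 1.0]])

        def f(x):
            return A @ x + np.array([x[0] ** 2, x[0] * x[1]])

        x = np.array([0.3, -0.2])
        J = np.empty((2, 2))
        for j in range(2):
            h = 1e-7 * (1 + abs(x[j]))
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            J[:, j] = (f(xp) - f(xm)) / (2 * h)
        exact = A + np.array([[2 * x[0], 0.0], [x[1], x[0]]])
        assert np.max(np.abs(J - exact)) < 1e-8

    def test_zero_haematocrit_raw_flows_linear_in_pressure(self):
        # with no red cells the resistances are constant, so the unnormalised
        # flows respond linearly to pressure changes
        net = build_triangle(FixtureSpec(h_in=0.0))
        sysm = compile_network(net)
        st = solve_zero_haematocrit(sysm)
        d = np.zeros_like(st.x)
        d[: sysm.n_interior] = [0.01, -0.02, 0.005]
        q0, q1, q2 = (sysm.raw_flows(st.x + t * d) for t in (0.0, 1.0, 2.0))
        assert np.max(np.abs((q2 - q1) - (q1 - q0))) < 1e-12


class TestNewton:
    def test_fixed_point_at_equilibrium(self, triangle_equilibria):
        st = triangle_equilibria[0]
        res = newton_solve(st.system, st.x)
        assert res.converged and res.iterations <= 2

    def test_nan_guess_fails_gracefully(self, triangle_sys):
        res = newton_solve(triangle_sys, np.full(triangle_sys.n_unknowns, np.nan))
        assert not res.converged and res.state is None

    def test_zero_h_start_reaches_known_equilibrium(self, triangle_sys,
                                                    triangle_equilibria):
        x0 = solve_zero_haematocrit(triangle_sys).x
        res = newton_solve(triangle_sys, x0)
        assert res.converged
        from hemonet.steady_state import canonicalize
        x = canonicalize(triangle_sys, res.state.x)
        assert min(np.max(np.abs(x - e.x)) for e in triangle_equilibria) < 1e-8


class TestConservation:
    def test_flow_and_rbc_conservation_at_equilibria(self, extended_equilibria):
        for st in extended_equilibria:
            sysm = st.system
            r = sysm.residual(st.x)
            assert np.max(np.abs(r[: sysm.n_interior])) < 1e-10
            assert abs(global_rbc_balance(st)) < 1e-10

    def test_residual_invariant_under_relabelling(self, triangle_net, triangle_sys):
        perm = {1: 11, 2: 22, 3: 33, 4: 44, 5: 55, 6: 66}
        mapped = relabel_network(triangle_net, perm)
        sys2 = compile_network(mapped)
        x = frozen_haematocrit_start(triangle_sys) + 0.013
        # map the unknown vector across the relabelling
        x2 = np.empty_like(x)
        for i, nid in enumerate(n.id for n in triangle_sys.network.interior_nodes):
            j = [m.id for m in sys2.network.interior_nodes].index(perm[nid])
            x2[j] = x[i]
        ni = triangle_sys.n_interior
        keys1 = [triangle_sys.vessel_keys[v] for v in triangle_sys.noninlet]
        keys2 = [sys2.vessel_keys[v] for v in sys2.noninlet]
        for k, key in enumerate(keys1):
            mapped_key = (perm[key[0]], perm[key[1]])
            x2[ni + keys2.index(mapped_key)] = x[ni + k]
        r1 = np.sort(np.abs(triangle_sys.residual(x)))
        r2 = np.sort(np.abs(sys2.residual(x2)))
        assert np.allclose(r1, r2, atol=1e-14)


class TestInvariances:
    """Dimensionless equilibria do not depend on the physical scales."""

    def test_plasma_viscosity(self, triangle_equilibria):
        net = build_triangle()
        sys2 = compile_network(net, params=RheologyParams(mu_p=7.3))
        for st in triangle_equilibria:
            res = newton_solve(sys2, st.x)
            assert res.converged
            assert np.max(np.abs(res.state.x - st.x)) < 1e-9

    def test_reference_length(self, triangle_equilibria):
        spec = FixtureSpec()
        net = build_triangle(spec)
        from hemonet.topology import VascularNetwork, Vessel
        scaled = VascularNetwork(
            net.nodes,
            [Vessel(v.start, v.end, 5.0 * v.length, v.diameter, v.inlet_haematocrit)
             for v in net.vessels])
        sys2 = compile_network(scaled)
        for st in triangle_equilibria:
            res = newton_solve(sys2, st.x)
            assert res.converged
            assert np.max(np.abs(res.state.x - st.x)) < 1e-9

    def test_pressure_rescaling(self, triangle_equilibria):
        c = 4.0
        net = build_triangle(FixtureSpec(p1=0.5 * c, p2=0.5 * c, p3=0.0))
        sys2 = compile_network(net)
        for st in triangle_equilibria:
            x0 = st.x.copy()
            x0[: sys2.n_interior] *= c
            res = newton_solve(sys2, x0)
            assert res.converged
            z = res.state.normalized()
            assert np.max(np.abs(z - st.normalized())) < 1e-9


class TestAsymmetricHaematocrit:
    def test_plus_state_enriches_the_beta_branch(self, triangle_equilibria,
                                                 triangle_labels):
        # with positive cross flow the left outlet branch carries more red
        # cells than the inlets supply, the right one fewer
        plus = triangle_equilibria[triangle_labels.index(("+",))]
        assert plus.haematocrit(4, 6) > 0.45 > plus.haematocrit(5, 6)
        minus = triangle_equilibria[triangle_labels.index(("-",))]
        assert minus.haematocrit(5, 6) > 0.45 > minus.haematocrit(4, 6)


class TestMirrorSymmetry:
    def test_equilibrium_set_closed_under_mirror(self, triangle_net,
                                                 triangle_equilibria):
        perm = mirror_permutation(triangle_net)
        sysm = triangle_equilibria[0].system
        for st in triangle_equilibria:
            # mirrored state: swap pressures of 4/5, haematocrits of the
            # mirrored vessels
            x = st.x
            x2 = np.empty_like(x)
            ids = [n.id for n in sysm.network.interior_nodes]
            for i, nid in enumerate(ids):
                x2[ids.index(perm[nid])] = x[i]
            ni = sysm.n_interior
            keys = [sysm.vessel_keys[v] for v in sysm.noninlet]
            for k, (a, b) in enumerate(keys):
                ma, mb = perm[a], perm[b]
                j = keys.index((ma, mb)) if (ma, mb) in keys else keys.index((mb, ma))
                x2[ni + j] = x[ni + k]
            dist = min(np.max(np.abs(x2 - e.x)) for e in triangle_equilibria)
            assert dist < 1e-8
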