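"""Sweep drivers and region maps."""

import numpy as np
import pytest

from hemonet.continuation import multistart_equilibria
from hemonet.experiments import (alpha_sweep, count_equilibria_at,
                                 inlet_pressure_sweep, region_map_alpha_beta,
                                 haematocrit_sweep)
from hemonet.fixtures import FixtureSpec, build_extended_triangle, build_triangle
from hemonet.steady_state import compile_network


@pytest.fixture(scope="module")
def asweep():
    net = build_extended_triangle(FixtureSpec(beta=1.025))
    return alpha_sweep(net, (0.05, 3.5), n_starts=600, seed=1)


class TestAlphaSweep:
    @pytest.fixture()
    def sweep(self, asweep):
        return asweep

    def test_count_drops_from_nine_to_one(self, sweep):
        assert count_equilibria_at(sweep, 0.06) == 9
        assert count_equilibria_at(sweep, 3.2) == 1

    def test_count_nonincreasing_between_folds(self, sweep):
        lams = sorted(sweep.fold_lams)
        probes = [0.06]
        for a, b in zip(lams, lams[1:]):
            if b - a > 1e-3:
                probes.append(0.5 * (a + b))
        probes.append(3.2)
        counts = [count_equilibria_at(sweep, p) for p in probes]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))
        assert all(c % 2 == 1 for c in counts)


class TestPressureSweep:
    def test_triangle_symmetric_point_and_fold_parity(self, triangle_net,
                                                      triangle_equilibria):
        res = inlet_pressure_sweep(triangle_net, 1, (0.45, 0.55),
                                   seeds=triangle_equilibria, seed=1)
        assert count_equilibria_at(res, 0.5) == 3
        lams = sorted(res.fold_lams)
        probes = [0.452] + [0.5 * (a + b) for a, b in zip(lams, lams[1:])
                            if b - a > 1e-4] + [0.548]
        counts = [count_equilibria_at(res, p) for p in probes]
        # equilibria appear and disappear in pairs at folds
        assert all(c % 2 == 1 for c in counts)
        assert all(abs(c1 - c2) in (0, 2) for c1, c2 in
                   zip(counts, counts[1:]))


class TestProportionalRule:
    def test_linear_rule_gives_unique_uniform_equilibrium(self):
        # psi = r forces every daughter haematocrit to equal its parent's, so
        # the haematocrit field is uniform and the flow problem is linear
        sysm = compile_network(build_extended_triangle(), rule="proportional")
        eq = multistart_equilibria(sysm, n_starts=200, seed=4)
        assert len(eq) == 1
        H = sysm.haematocrits(eq[0].x)
        q = eq[0].flows()
        # vessels that actually carry flow share the inlet haematocrit; the
        # idle cross vessels have an undetermined haematocrit (canonically 0)
        flowing = np.abs(q) > 1e-9
        assert np.max(np.abs(H[flowing] - 0.45)) < 1e-9


class TestHaematocritSweep:
    def test_first_emergence_labels(self, extended_net, extended_equilibria,
                                    extended_labels):
        res = haematocrit_sweep(extended_net, (0.0, 0.45),
                                seeds=extended_equilibria, seed=1)
        hmin = min(res.fold_lams)
        assert 0.25 < hmin < 0.40
        # the branch carrying the first fold joins the (+,+) and (-,-) states
        for br in res.branches:
            if any(abs(f.lam - hmin) < 1e-9 for f in br.folds):
                ends = []
                for x in (br.xs[0], br.xs[-1]):
                    d = [np.max(np.abs(x - e.x)) for e in extended_equilibria]
                    ends.append(extended_labels[int(np.argmin(d))])
                assert set(ends) == {("+", "+"), ("-", "-")}
                break
        else:
            pytest.fail("no branch carries the first fold")


@pytest.fixture(scope="module")
def region_maps():
    alphas = [0.05, 0.12, 0.25, 0.4]
    betas = np.linspace(0.75, 1.25, 8)  # avoids the degenerate beta = 1
    out = {}
    for h in (0.35, 0.40, 0.45):
        out[h] = region_map_alpha_beta(build_extended_triangle, alphas, betas,
                                       h_in=h, n_rand=25, seed=5)
    return out


class TestRegionMap:
    @pytest.fixture()
    def maps(self, region_maps):
        return region_maps

    def test_counts_odd_and_bounded(self, maps):
        for rm in maps.values():
            c = rm.counts.ravel()
            assert np.all(c % 2 == 1)
            assert np.all((c >= 1) & (c <= 9))

    def test_multi_area_grows_with_inlet_haematocrit(self, maps):
        a = [maps[h].multi_equilibria_area() for h in (0.35, 0.40, 0.45)]
        assert a[0] <= a[1] <= a[2]

    def test_asymmetric_geometry_is_unique(self, maps):
        rm = maps[0.45]
        # strongly asymmetric, long cross vessels: single equilibrium
        assert rm.counts[-1, 0] == 1
        assert rm.counts[-1, -1] == 1

    def test_triangle_region_narrower_than_extended(self, maps):
        alphas = [0.1]
        betas = np.linspace(0.75, 1.25, 8)
        tri = region_map_alpha_beta(build_triangle, alphas, betas, h_in=0.45,
                                    n_rand=25, seed=5)
        ext = maps[0.45]
        # at alpha ~ 0.1 the extended network's multi-equilibria beta-extent
        # contains the triangle's
        tri_multi = tri.counts[0] > 1
        ext_multi = ext.counts[1] > 1
        assert ext_multi.sum() >= tri_multi.sum()
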