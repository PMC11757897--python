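"""Canonical study networks and random small networks for property testing.

The two canonical geometries are the *triangle* network (one redundant
vessel) and the *extended-triangle* network (two redundant vessels), both
fed by two inlets at equal pressure and drained by a single outlet.  Their
free parameters are the vessel-length ratios α (redundant vessels) and β
(the (4,6) vessel, controlling left/right asymmetry), a common diameter D,
the boundary pressures and the inlet haematocrit.  Lengths are stored as
multiples of the reference length L, which is never given a numeric value
because the dimensionless equilibria do not depend on it.

Default parameter values: P1 = P2 = 0.5, P3 = 0 (already normalised),
D = 10 µm, α = 0.1, β = 1, H_in = 0.45.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .topology import Node, Vessel, VascularNetwork, NetworkValidationError

__all__ = ["FixtureSpec", "build_triangle", "build_extended_triangle",
           "random_network", "mirror_permutation"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the canonical networks (see module docstring for defaults)."""

    alpha: float = 0.1
    beta: float = 1.0
    diameter: float = 10.0
    p1: float = 0.5
    p2: float = 0.5
    p3: float = 0.0
    h_in: float = 0.45

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise NetworkValidationError("length ratios alpha, beta must be positive")
        if not self.diameter > 1.1:
            raise NetworkValidationError("diameter must exceed 1.1 µm")
        if not (self.p1 > self.p3 and self.p2 > self.p3):
            raise NetworkValidationError("inlet pressures must exceed the outlet pressure")
        if not 0.0 <= self.h_in < 1.0:
            raise NetworkValidationError("inlet haematocrit must lie in [0, 1)")


def build_triangle(spec: FixtureSpec | None = None) -> VascularNetwork:
    """Triangle network: inlets 1, 2 → interior 4, 5, 6 → outlet 3.

    Vessels (1,4), (2,5), <4,5>, (4,6), (5,6), (6,3); the cross vessel <4,5>
    (length αL) is the single redundant vessel and (4,6) has length βL.
    """
    s = spec or FixtureSpec()
    D, H = s.diameter, s.h_in
    nodes = [
        Node(1, "inlet", s.p1), Node(2, "inlet", s.p2), Node(3, "outlet", s.p3),
        Node(4, "interior"), Node(5, "interior"), Node(6, "interior"),
    ]
    vessels = [
        Vessel(1, 4, 1.0, D, inlet_haematocrit=H),
        Vessel(2, 5, 1.0, D, inlet_haematocrit=H),
        Vessel(4, 5, s.alpha, D),
        Vessel(4, 6, s.beta, D),
        Vessel(5, 6, 1.0, D),
        Vessel(6, 3, 1.0, D),
    ]
    return VascularNetwork(nodes, vessels, meta={"fixture": "triangle", "alpha": s.alpha,
                                                 "beta": s.beta})


def build_extended_triangle(spec: FixtureSpec | None = None) -> VascularNetwork:
    """Extended-triangle network: the triangle plus a second cross vessel.

    Inlets 1, 2 feed interior nodes 7, 8 joined by the redundant vessel <7,8>;
    vessels (7,4) and (8,5) lead into the triangle subnetwork {4, 5, 6} with
    redundant vessel <4,5>.  Both cross vessels have length αL and (4,6) has
    length βL; every other vessel has length L.
    """
    s = spec or FixtureSpec()
    D, H = s.diameter, s.h_in
    nodes = [
        Node(1, "inlet", s.p1), Node(2, "inlet", s.p2), Node(3, "outlet", s.p3),
        Node(4, "interior"), Node(5, "interior"), Node(6, "interior"),
        Node(7, "interior"), Node(8, "interior"),
    ]
    vessels = [
        Vessel(1, 7, 1.0, D, inlet_haematocrit=H),
        Vessel(2, 8, 1.0, D, inlet_haematocrit=H),
        Vessel(7, 8, s.alpha, D),
        Vessel(7, 4, 1.0, D),
        Vessel(8, 5, 1.0, D),
        Vessel(4, 5, s.alpha, D),
        Vessel(4, 6, s.beta, D),
        Vessel(5, 6, 1.0, D),
        Vessel(6, 3, 1.0, D),
    ]
    return VascularNetwork(nodes, vessels, meta={"fixture": "extended_triangle",
                                                 "alpha": s.alpha, "beta": s.beta})


def mirror_permutation(network: VascularNetwork) -> dict:
    """Node permutation of the left/right mirror symmetry of the fixtures.

    Valid as a network automorphism only when β = 1 and the two inlets share
    pressure and haematocrit.
    """
    fixture = network.meta.get("fixture")
    if fixture == "triangle":
        return {1: 2, 2: 1, 4: 5, 5: 4, 3: 3, 6: 6}
    if fixture == "extended_triangle":
        return {1: 2, 2: 1, 4: 5, 5: 4, 7: 8, 8: 7, 3: 3, 6: 6}
    raise ValueError("mirror permutation is only defined for the canonical fixtures")


def random_network(seed: int, node_budget: int = 10, max_tries: int = 50) -> VascularNetwork:
    """Random small degree-3 network for property tests.

    Grown from a Y junction by repeatedly (a) inserting a T junction with a
    new boundary node on a random vessel or (b) bridging two vessels with a
    new cross vessel (which creates a loop and hence potential redundancy).
    Lengths are drawn from [0.05, 3] L, diameters from [5, 50] µm, inlet
    haematocrits from [0, 0.6]; inlet pressures always exceed outlet
    pressures.  Deterministic for a given seed.
    """
    if node_budget > 12:
        raise ValueError("node budget capped at 12")
    if node_budget < 4:
        raise ValueError("need at least 4 nodes (a Y junction)")
    from .topology import enumerate_feasible_orientations, NoFeasibleOrientationError
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        net = _grow_random(rng, node_budget)
        if net is None:
            continue
        try:
            enumerate_feasible_orientations(net)
        except NoFeasibleOrientationError:
            continue
        return net
    raise RuntimeError(f"could not generate a feasible network from seed {seed}")


def _grow_random(rng, node_budget: int) -> VascularNetwork | None:
    # edges as [a, b] over integer node ids; boundary nodes tracked separately
    next_id = 5
    edges: list[list[int]] = [[1, 4], [2, 4], [3, 4]]
    boundary = [1, 2, 3]
    interior = [4]
    n_nodes = 4
    while n_nodes < node_budget:
        # bridging consumes 2 new nodes, T insertion 2 as well
        do_bridge = len(edges) >= 2 and rng.random() < 0.45 and n_nodes + 2 <= node_budget
        if do_bridge:
            i, j = rng.choice(len(edges), size=2, replace=False)
            m1, m2 = next_id, next_id + 1
            next_id += 2
            a1, b1 = edges[i]
            a2, b2 = edges[j]
            edges[i] = [a1, m1]
            edges[j] = [a2, m2]
            edges += [[m1, b1], [m2, b2], [m1, m2]]
            interior += [m1, m2]
            n_nodes += 2
        else:
            i = int(rng.integers(len(edges)))
            a, b = edges[i]
            m, t = next_id, next_id + 1
            next_id += 2
            edges[i] = [a, m]
            edges += [[m, b], [m, t]]
            interior.append(m)
            boundary.append(t)
            n_nodes += 2
    # duplicate-edge or self-loop check
    seen = set()
    for a, b in edges:
        k = frozenset((a, b))
        if a == b or k in seen:
            return None
        seen.add(k)
    # assign boundary roles: at least one inlet and one outlet
    n_b = len(boundary)
    n_in = int(rng.integers(1, n_b))
    roles = ["inlet"] * n_in + ["outlet"] * (n_b - n_in)
    rng.shuffle(roles)
    pressures = {}
    for node, role in zip(boundary, roles):
        if role == "inlet":
            pressures[node] = float(rng.uniform(0.6, 1.0))
        else:
            pressures[node] = float(rng.uniform(0.0, 0.4))
    inlets = {n for n, r in zip(boundary, roles) if r == "inlet"}
    nodes = [Node(n, "interior") for n in interior]
    nodes += [Node(n, "inlet" if n in inlets else "outlet", pressures[n]) for n in boundary]
    vessels = []
    for a, b in edges:
        h = float(rng.uniform(0.0, 0.6)) if (a in inlets or b in inlets) else None
        vessels.append(Vessel(a, b, length=float(rng.uniform(0.05, 3.0)),
                              diameter=float(rng.uniform(5.0, 50.0)),
                              inlet_haematocrit=h))
    try:
        return VascularNetwork(nodes, vessels)
    except NetworkValidationError:
        return None
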