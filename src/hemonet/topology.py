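"""Vascular networks as graphs: feasible flow orientations and redundant vessels.

A vascular network is an undirected graph whose boundary nodes (degree-1
inlets and outlets) carry prescribed pressures and whose interior nodes are
degree-3 junctions.  Because pressure-driven flow cannot loop, any steady
flow induces an acyclic orientation of the vessels with inlets as sources
and outlets as sinks.  Vessels whose direction differs between two feasible
orientations are *redundant*; they are the structural ingredient that allows
a network to support multiple flow equilibria, one for each combination of
negative/intermediate/positive flow across the redundant vessels (at most
3^r in total for r redundant vessels).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Node",
    "Vessel",
    "VascularNetwork",
    "Orientation",
    "enumerate_feasible_orientations",
    "find_redundant_vessels",
    "equilibrium_upper_bound",
    "NetworkValidationError",
    "EnumerationGuardError",
    "NoFeasibleOrientationError",
]

NODE_KINDS = ("inlet", "outlet", "interior")

#: Exhaustive orientation search is guarded to small networks.
MAX_VESSELS_FOR_ENUMERATION = 25


class NetworkValidationError(ValueError):
    """The network violates a structural invariant."""


class EnumerationGuardError(RuntimeError):
    """The network is too large for exhaustive orientation enumeration."""


class NoFeasibleOrientationError(RuntimeError):
    """No acyclic orientation satisfies the boundary constraints."""


@dataclass(frozen=True)
class Node:
    id: int | str
    kind: str  # inlet | outlet | interior
    pressure: float | None = None  # prescribed for boundary nodes, None for interior


@dataclass(frozen=True)
class Vessel:
    """A vessel between ``start`` and ``end``; the (start, end) order is the
    reference orientation used to sign flows.  ``length`` is a multiple of the
    reference length L, ``diameter`` is in µm.  Inlet vessels carry the
    prescribed inlet haematocrit."""

    start: int | str
    end: int | str
    length: float
    diameter: float
    inlet_haematocrit: float | None = None

    @property
    def key(self) -> tuple:
        return (self.start, self.end)


@dataclass(frozen=True)
class VascularNetwork:
    nodes: tuple[Node, ...]
    vessels: tuple[Vessel, ...]
    meta: Mapping = field(default_factory=dict)

    def __init__(self, nodes: Iterable[Node], vessels: Iterable[Vessel], meta=None,
                 validate: bool = True):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "vessels", tuple(vessels))
        object.__setattr__(self, "meta", dict(meta or {}))
        if validate:
            self.validate()

    # -- views -----------------------------------------------------------
    def node_map(self) -> dict:
        return {n.id: n for n in self.nodes}

    @property
    def inlet_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == "inlet")

    @property
    def outlet_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == "outlet")

    @property
    def interior_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == "interior")

    def inlet_vessels(self) -> tuple[Vessel, ...]:
        inlets = {n.id for n in self.inlet_nodes}
        return tuple(v for v in self.vessels if v.start in inlets or v.end in inlets)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind)
        for i, v in enumerate(self.vessels):
            g.add_edge(v.start, v.end, index=i)
        return g

    def degree(self, node_id) -> int:
        return sum(1 for v in self.vessels if node_id in (v.start, v.end))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate node ids")
        nmap = self.node_map()
        for n in self.nodes:
            if n.kind not in NODE_KINDS:
                raise NetworkValidationError(f"node {n.id}: unknown kind {n.kind!r}")
            if n.kind in ("inlet", "outlet") and n.pressure is None:
                raise NetworkValidationError(f"boundary node {n.id} lacks a pressure")
        if not self.inlet_nodes or not self.outlet_nodes:
            raise NetworkValidationError("need at least one inlet and one outlet")
        seen = set()
        for v in self.vessels:
            for end in (v.start, v.end):
                if end not in nmap:
                    raise NetworkValidationError(f"vessel {v.key} references unknown node {end}")
            if v.start == v.end:
                raise NetworkValidationError(f"vessel {v.key} is a self-loop")
            k = frozenset(v.key)
            if k in seen:
                raise NetworkValidationError(f"parallel vessels between {v.key}")
            seen.add(k)
            if not v.length > 0 or not v.diameter > 0:
                raise NetworkValidationError(f"vessel {v.key}: length and diameter must be positive")
        for n in self.nodes:
            d = self.degree(n.id)
            if n.kind in ("inlet", "outlet") and d != 1:
                raise NetworkValidationError(f"boundary node {n.id} must have degree 1, has {d}")
            if n.kind == "interior" and d != 3:
                raise NetworkValidationError(f"interior node {n.id} must have degree 3, has {d}")
        if not nx.is_connected(self.graph()):
            raise NetworkValidationError("network graph is not connected")
        in_p = [n.pressure for n in self.inlet_nodes]
        out_p = [n.pressure for n in self.outlet_nodes]
        if min(in_p) <= max(out_p):
            raise NetworkValidationError(
                "every inlet pressure must exceed every outlet pressure")
        inlets = {n.id for n in self.inlet_nodes}
        for v in self.vessels:
            touches_inlet = v.start in inlets or v.end in inlets
            if touches_inlet:
                h = v.inlet_haematocrit
                if h is None or not 0.0 <= h < 1.0:
                    raise NetworkValidationError(
                        f"inlet vessel {v.key} needs an inlet haematocrit in [0, 1)")
            elif v.inlet_haematocrit is not None:
                raise NetworkValidationError(
                    f"vessel {v.key} is not an inlet vessel but carries an inlet haematocrit")


@dataclass(frozen=True)
class Orientation:
    """Direction assignment for every vessel of a network.

    ``directions[i]`` is +1 if vessel i flows along its reference (start→end)
    orientation and -1 otherwise.
    """

    network: VascularNetwork
    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.directions) != len(self.network.vessels):
            raise ValueError("one direction per vessel required")

    def upstream(self, vessel_index: int):
        v = self.network.vessels[vessel_index]
        return v.start if self.directions[vessel_index] == 1 else v.end

    def as_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.id for n in self.network.nodes)
        for v, d in zip(self.network.vessels, self.directions):
            a, b = (v.start, v.end) if d == 1 else (v.end, v.start)
            g.add_edge(a, b)
        return g

    def __hash__(self):
        return hash(self.directions)

    def __eq__(self, other):
        return isinstance(other, Orientation) and self.directions == other.directions


def _satisfies_degree_constraints(net: VascularNetwork, dirs: Sequence[int]) -> bool:
    out_deg: dict = {n.id: 0 for n in net.nodes}
    in_deg: dict = {n.id: 0 for n in net.nodes}
    for v, d in zip(net.vessels, dirs):
        a, b = (v.start, v.end) if d == 1 else (v.end, v.start)
        out_deg[a] += 1
        in_deg[b] += 1
    for n in net.nodes:
        if n.kind == "inlet" and not (out_deg[n.id] == 1 and in_deg[n.id] == 0):
            return False
        if n.kind == "outlet" and not (in_deg[n.id] == 1 and out_deg[n.id] == 0):
            return False
        if n.kind == "interior" and not (in_deg[n.id] >= 1 and out_deg[n.id] >= 1):
            return False
    return True


def enumerate_feasible_orientations(network: VascularNetwork) -> set[Orientation]:
    """All acyclic orientations compatible with the boundary constraints.

    Inlet and outlet vessel directions are forced (away from inlets, toward
    outlets); the remaining vessels are searched exhaustively.  Guarded to
    networks with at most 25 vessels.
    """
    m = len(network.vessels)
    if m > MAX_VESSELS_FOR_ENUMERATION:
        raise EnumerationGuardError(
            f"{m} vessels exceeds the exhaustive-search guard of {MAX_VESSELS_FOR_ENUMERATION}")
    inlets = {n.id for n in network.inlet_nodes}
    outlets = {n.id for n in network.outlet_nodes}
    forced: list[int | None] = []
    free: list[int] = []
    for i, v in enumerate(network.vessels):
        if v.start in inlets or v.end in outlets:
            forced.append(1)
        elif v.end in inlets or v.start in outlets:
            forced.append(-1)
        else:
            forced.append(None)
            free.append(i)
    found: set[Orientation] = set()
    for combo in itertools.product((1, -1), repeat=len(free)):
        dirs = list(forced)
        for i, d in zip(free, combo):
            dirs[i] = d
        if not _satisfies_degree_constraints(network, dirs):
            continue
        o = Orientation(network, tuple(dirs))
        if nx.is_directed_acyclic_graph(o.as_digraph()):
            found.add(o)
    if not found:
        raise NoFeasibleOrientationError("no acyclic orientation satisfies the boundary constraints")
    return found


def find_redundant_vessels(network: VascularNetwork) -> set[tuple]:
    """Vessels (as reference (start, end) keys) whose direction differs between
    at least two feasible orientations; all other vessels are fixed."""
    orientations = enumerate_feasible_orientations(network)
    redundant: set[tuple] = set()
    for i, v in enumerate(network.vessels):
        dirs = {o.directions[i] for o in orientations}
        if len(dirs) > 1:
            redundant.add(v.key)
    return redundant


def equilibrium_upper_bound(network: VascularNetwork) -> int:
    """Upper bound 3^r on the number of equilibria, where r is the number of
    redundant vessels (one of negative/intermediate/positive flow each)."""
    return 3 ** len(find_redundant_vessels(network))


def relabel_network(network: VascularNetwork, mapping: Mapping) -> VascularNetwork:
    """Return an isomorphic copy with node ids renamed via ``mapping``."""
    nodes = tuple(Node(mapping.get(n.id, n.id), n.kind, n.pressure) for n in network.nodes)
    vessels = tuple(
        Vessel(mapping.get(v.start, v.start), mapping.get(v.end, v.end),
               v.length, v.diameter, v.inlet_haematocrit)
        for v in network.vessels)
    return VascularNetwork(nodes, vessels, meta=dict(network.meta))
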