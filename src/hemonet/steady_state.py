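"""Assembly and solution of the dimensionless steady-state network equations.

Unknowns are the interior nodal pressures and the haematocrits of every
non-inlet vessel; vessel flows are eliminated through Poiseuille's law with
the haematocrit- and diameter-dependent in-vivo viscosity, and are reported
normalised by the total network inflow so that every |Q| <= 1.

The residual carries one flow-conservation equation per interior node and
one red-blood-cell equation per non-inlet vessel.  The RBC equation takes
one of two forms depending on the junction type at the vessel's current
upstream node: at a convergence (two inflows) it is plain RBC conservation
in conservative product form; at a bifurcation (one inflow, two outflows)
it is the splitting-rule condition psi(r) Q_p H_p = Q_d H_d.  Junction
types are re-detected from the current flow signs at every residual
evaluation, so the equation structure follows the state through flow
reversals.

Equilibria are invariant to the plasma viscosity, the reference vessel
length and uniform rescaling of the boundary-pressure span, because every
equation is expressed in flow ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rheology import RheologyParams, _viscosity_unchecked
from .splitting import SplittingRule, get_rule, _psi_unchecked
from .topology import VascularNetwork

__all__ = [
    "CompiledSystem",
    "NetworkState",
    "NewtonResult",
    "compile_network",
    "signed_flows",
    "assemble_residual",
    "jacobian",
    "solve_zero_haematocrit",
    "newton_solve",
    "SingularNetworkError",
    "InvalidStateError",
]

#: Normalised-flow floor below which a flow is treated as zero for junction typing.
EPS_Q = 1e-14


class SingularNetworkError(RuntimeError):
    """The linear conductance system is singular (ill-posed network)."""


class InvalidStateError(ValueError):
    """A state violates the preconditions of an operation."""


class CompiledSystem:
    """Index-compiled form of a :class:`VascularNetwork` for fast residual evaluation.

    Parameter arrays (``lengths``, ``diameters``, ``inlet_h``, ``boundary_p``)
    are mutable so that continuation can sweep them without recompiling; the
    topology is fixed.
    """

    def __init__(self, network: VascularNetwork, rule: SplittingRule | str = "pries1990",
                 params: RheologyParams | None = None):
        self.network = network
        self.rule = get_rule(rule) if isinstance(rule, str) else rule
        self.params = params or RheologyParams()

        self.node_ids = [n.id for n in network.nodes]
        self.node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.kinds = [n.kind for n in network.nodes]
        self.interior_idx = np.array(
            [i for i, n in enumerate(network.nodes) if n.kind == "interior"], dtype=int)
        self.boundary_p = np.array(
            [n.pressure if n.pressure is not None else np.nan for n in network.nodes])
        self.outlet_idx = np.array(
            [i for i, n in enumerate(network.nodes) if n.kind == "outlet"], dtype=int)

        inlet_nodes = {n.id for n in network.inlet_nodes}
        outlet_nodes = {n.id for n in network.outlet_nodes}
        m = len(network.vessels)
        start = np.empty(m, dtype=int)
        end = np.empty(m, dtype=int)
        self.lengths = np.empty(m)
        self.diameters = np.empty(m)
        self.inlet_h = np.zeros(m)
        inlet_mask = np.zeros(m, dtype=bool)
        outlet_mask = np.zeros(m, dtype=bool)
        for i, v in enumerate(network.vessels):
            a, b = v.start, v.end
            # orient inlet vessels out of the inlet and outlet vessels into the outlet
            if b in inlet_nodes or a in outlet_nodes:
                a, b = b, a
            start[i], end[i] = self.node_index[a], self.node_index[b]
            self.lengths[i] = v.length
            self.diameters[i] = v.diameter
            if v.inlet_haematocrit is not None:
                self.inlet_h[i] = v.inlet_haematocrit
                inlet_mask[i] = True
            if v.start in outlet_nodes or v.end in outlet_nodes:
                outlet_mask[i] = True
        self.start, self.end = start, end
        self.inlet_mask = inlet_mask
        self.outlet_mask = outlet_mask
        self.vessel_keys = [(self.node_ids[start[i]], self.node_ids[end[i]]) for i in range(m)]

        self.noninlet = np.array([i for i in range(m) if not inlet_mask[i]], dtype=int)
        self.h_slot_of_vessel = {int(v): k for k, v in enumerate(self.noninlet)}
        self.n_interior = len(self.interior_idx)
        self.n_unknowns = self.n_interior + len(self.noninlet)

        # incidence: per node, tuple of (vessel index, +1 if node is the vessel end)
        incident: list[list[tuple[int, int]]] = [[] for _ in self.node_ids]
        for i in range(m):
            incident[start[i]].append((i, -1))
            incident[end[i]].append((i, +1))
        self.incident = [tuple(lst) for lst in incident]
        # interior-node incidence matrix over vessels (flow-into signs)
        A = np.zeros((self.n_interior, m))
        for r, ni in enumerate(self.interior_idx):
            for vi, s in self.incident[ni]:
                A[r, vi] = s
        self._A_int = A
        self._is_boundary = np.array([k != "interior" for k in self.kinds])
        self._is_boundary_l = [bool(b) for b in self._is_boundary]
        self._start_l = [int(s) for s in start]
        self._cache_key = None

    # -- parameter handles ------------------------------------------------
    def copy(self) -> "CompiledSystem":
        import copy as _copy
        new = _copy.copy(self)
        new.lengths = self.lengths.copy()
        new.diameters = self.diameters.copy()
        new.inlet_h = self.inlet_h.copy()
        new.boundary_p = self.boundary_p.copy()
        return new

    def vessel_indices(self, keys) -> list[int]:
        lookup = {}
        for i, (a, b) in enumerate(self.vessel_keys):
            lookup[(a, b)] = i
            lookup[(b, a)] = i
        return [lookup[tuple(k)] for k in keys]

    # -- core evaluation ---------------------------------------------------
    def full_pressures(self, x: np.ndarray) -> np.ndarray:
        P = self.boundary_p.copy()
        P[self.interior_idx] = x[: self.n_interior]
        return P

    def haematocrits(self, x: np.ndarray) -> np.ndarray:
        H = self.inlet_h.copy()
        H[self.noninlet] = x[self.n_interior:]
        return H

    def _rheo_cache(self):
        """Diameter/length-dependent constants of the viscosity law, recomputed
        only when the parameter arrays change (handles mutate them in place)."""
        key = (self.diameters.tobytes(), self.lengths.tobytes(), self.params.mu_p)
        if key != self._cache_key:
            D = self.diameters
            m45 = 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)
            t = 1.0 / (1.0 + 1e-11 * D**12)
            C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + t) + t
            wall = (D / (D - 1.1)) ** 2
            amp = (m45 - 1.0) / (0.55**C - 1.0) * wall
            kR = 128.0 * self.lengths / (math.pi * D**4)
            self._cache = (C, amp, wall, kR, self.params.mu_p, D.tolist())
            self._cache_key = key
        return self._cache

    def raw_flows(self, x: np.ndarray) -> np.ndarray:
        C, amp, wall, kR, mu_p, _ = self._rheo_cache()
        P = self.full_pressures(x)
        H = np.clip(self.haematocrits(x), 0.0, 0.999)
        mu = mu_p * (1.0 + amp * ((1.0 - H) ** C - 1.0)) * wall
        return (P[self.start] - P[self.end]) / (kR * mu)

    def flows(self, x: np.ndarray) -> np.ndarray:
        """Flows normalised by the total inflow Q_in; raises if Q_in <= 0."""
        Q = self.raw_flows(x)
        Qin = Q[self.inlet_mask].sum()
        if not Qin > 0:
            raise InvalidStateError("total inflow Q_in is not positive")
        return Q / Qin

    def residual(self, x: np.ndarray) -> np.ndarray:
        """Residual vector; NaN-filled if the state is degenerate (Q_in <= 0)."""
        Q = self.raw_flows(x)
        Qin = Q[self.inlet_mask].sum()
        if not (Qin > 0 and np.all(np.isfinite(Q))):
            return np.full(self.n_unknowns, np.nan)
        q_arr = Q / Qin
        res = np.empty(self.n_unknowns)
        res[: self.n_interior] = self._A_int @ q_arr
        ni = self.n_interior
        q = q_arr.tolist()
        H = self.haematocrits(x).tolist()
        Dv = self._rheo_cache()[5]
        fast_pries = self.rule.name == "pries1990"
        rule = self.rule
        incident = self.incident
        is_boundary = self._is_boundary_l
        start_l = self._start_l
        end_l = self.end
        for k, vi in enumerate(self.noninlet):
            qv = q[vi]
            # upstream node: by flow sign; reference orientation on ~zero flow
            if qv >= -EPS_Q:
                u = start_l[vi]
                out_mag = qv
            else:
                u = int(end_l[vi])
                out_mag = -qv
            if is_boundary[u]:
                # reversed outlet vessel (transient, off-equilibrium): pin H
                res[ni + k] = H[vi]
                continue
            inflows = []
            outflows = []
            for wi, s in incident[u]:
                qw = q[wi]
                if -EPS_Q <= qw <= EPS_Q:
                    # zero-flow convention: vessel directed along its reference
                    (inflows if s > 0 else outflows).append((wi, 0.0))
                    continue
                f = s * qw
                if f > 0:
                    inflows.append((wi, f))
                else:
                    outflows.append((wi, -f))
            if len(inflows) == 1 and len(outflows) == 2:
                pi, qp = inflows[0]
                sib = outflows[0][0] if outflows[0][0] != vi else outflows[1][0]
                r = out_mag / qp if qp > EPS_Q else 1.0
                if r < 0.0:
                    r = 0.0
                elif r > 1.0:
                    r = 1.0
                Hp = H[pi]
                if fast_pries:
                    Dp = Dv[pi]
                    X0 = 0.4 / Dp
                    if r < X0:
                        p = 0.0
                    elif r > 1.0 - X0:
                        p = 1.0
                    else:
                        # clamp the coefficient haematocrit: off-equilibrium
                        # iterates may wander outside [0, 1)
                        Hc = 0.0 if Hp < 0.0 else (1.0 if Hp > 1.0 else Hp)
                        rho = 1.0 + 6.98 * (1.0 - Hc) / Dp
                        hi = 1.0 - r - X0
                        if hi < 0.0:
                            hi = 0.0
                        num = math.exp(-(6.96 / Dp) * math.log(Dv[vi] / Dv[sib])) \
                            * (r - X0) ** rho
                        p = num / (num + hi**rho)
                else:
                    p = float(rule(r, Hp, Dv[pi], Dv[vi], Dv[sib]))
                res[ni + k] = p * qp * Hp - out_mag * H[vi]
            elif len(inflows) == 2:
                acc = -out_mag * H[vi]
                for wi, f in inflows:
                    acc += f * H[wi]
                res[ni + k] = acc
            else:
                # degenerate junction (no inflow): pin haematocrit
                res[ni + k] = H[vi]
        return res

    def jacobian(self, x: np.ndarray, step: float = 1e-7) -> np.ndarray:
        """Central finite-difference Jacobian with magnitude-scaled steps."""
        n = self.n_unknowns
        J = np.empty((n, n))
        for j in range(n):
            h = step * (1.0 + abs(x[j]))
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            J[:, j] = (self.residual(xp) - self.residual(xm)) / (2.0 * h)
        return J

    def make_state(self, x: np.ndarray) -> "NetworkState":
        return NetworkState(self, np.asarray(x, dtype=float).copy())


def compile_network(network: VascularNetwork, rule="pries1990",
                    params: RheologyParams | None = None) -> CompiledSystem:
    return CompiledSystem(network, rule=rule, params=params)


@dataclass
class NetworkState:
    """A point in unknown space: interior pressures then non-inlet haematocrits."""

    system: CompiledSystem
    x: np.ndarray

    @property
    def interior_pressures(self) -> np.ndarray:
        return self.x[: self.system.n_interior]

    @property
    def noninlet_haematocrits(self) -> np.ndarray:
        return self.x[self.system.n_interior:]

    def pressure(self, node_id) -> float:
        i = self.system.node_index[node_id]
        return float(self.system.full_pressures(self.x)[i])

    def haematocrit(self, a, b) -> float:
        vi = self.system.vessel_indices([(a, b)])[0]
        return float(self.system.haematocrits(self.x)[vi])

    def flow(self, a, b) -> float:
        """Normalised flow signed from a to b."""
        vi = self.system.vessel_indices([(a, b)])[0]
        q = float(self.system.flows(self.x)[vi])
        ka, _kb = self.system.vessel_keys[vi]
        return q if ka == a else -q

    def flows(self) -> np.ndarray:
        return self.system.flows(self.x)

    def residual_norm(self) -> float:
        return float(np.max(np.abs(self.system.residual(self.x))))

    def normalized(self) -> np.ndarray:
        """Unknown vector with pressures mapped to (P - P_out)/(sum of inlet P).

        Makes states comparable across uniform rescalings of the boundary
        pressures.
        """
        sysm = self.system
        p_out = np.nanmin(sysm.boundary_p[sysm.outlet_idx])
        span = sum(sysm.boundary_p[sysm.node_index[n.id]] - p_out
                   for n in sysm.network.inlet_nodes)
        z = self.x.copy()
        z[: sysm.n_interior] = (z[: sysm.n_interior] - p_out) / span
        return z

    def induced_directions(self, zero_tol: float = 1e-9) -> tuple:
        """Per-vessel +1/-1/0 signs of the normalised flows (0 within tolerance)."""
        q = self.flows()
        return tuple(0 if abs(v) < zero_tol else (1 if v > 0 else -1) for v in q)


def canonicalize(system: CompiledSystem, x: np.ndarray, zero_q: float = 1e-7) -> np.ndarray:
    """Zero out haematocrits that the equations leave undetermined.

    A bifurcation daughter whose flow ratio sits below the splitting threshold
    X0 receives no red cells; when its flow is itself ~0 the RBC equation
    degenerates to 0 = 0 and the haematocrit unknown is free.  The continuous
    limit along any branch is H = 0, so that value is the canonical
    representative (used before de-duplicating equilibria).
    """
    x = np.asarray(x, dtype=float).copy()
    try:
        q = system.flows(x)
    except InvalidStateError:
        return x
    H = system.haematocrits(x)
    ni = system.n_interior
    for k, vi in enumerate(system.noninlet):
        if abs(q[vi]) < zero_q and H[vi] > 0:
            xt = x.copy()
            xt[ni + k] = 0.0
            if np.nanmax(np.abs(system.residual(xt))) < 1e-9:
                x = xt
    return x


@dataclass
class NewtonResult:
    state: NetworkState | None
    converged: bool
    iterations: int
    residual_norm: float
    message: str = ""


def newton_solve(system: CompiledSystem | VascularNetwork, x0: np.ndarray,
                 tol: float = 1e-12, max_iter: int = 50,
                 max_backtracks: int = 20) -> NewtonResult:
    """Damped Newton iteration on the network residual.

    Haematocrit iterates are clipped to [0, 0.999] during the iteration;
    acceptance requires the unclipped residual to satisfy the tolerance.
    Returns a failed :class:`NewtonResult` (never raises) on non-convergence,
    NaN input or singular Jacobians.
    """
    sysm = system if isinstance(system, CompiledSystem) else compile_network(system)
    x = np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        return NewtonResult(None, False, 0, np.inf, "non-finite initial guess")
    ni = sysm.n_interior
    f = sysm.residual(x)
    if not np.all(np.isfinite(f)):
        return NewtonResult(None, False, 0, np.inf, "residual not finite at initial guess")
    fn = float(np.max(np.abs(f)))
    for it in range(1, max_iter + 1):
        if fn < tol:
            return NewtonResult(sysm.make_state(x), True, it - 1, fn)
        J = sysm.jacobian(x)
        if not np.all(np.isfinite(J)):
            return NewtonResult(None, False, it, fn, "non-finite Jacobian")
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            # exactly singular (e.g. a zero-flow vessel leaves a haematocrit
            # free): take the minimum-norm step, which ignores the null space
            dx = np.linalg.lstsq(J, -f, rcond=None)[0]
        if not np.all(np.isfinite(dx)):
            return NewtonResult(None, False, it, fn, "non-finite Newton step")
        t = 1.0
        for _ in range(max_backtracks + 1):
            xt = x + t * dx
            xt[ni:] = np.clip(xt[ni:], 0.0, 0.999)
            ft = sysm.residual(xt)
            ftn = float(np.max(np.abs(ft))) if np.all(np.isfinite(ft)) else np.inf
            if ftn < fn:
                break
            t *= 0.5
        else:
            return NewtonResult(None, False, it, fn, "line search failed")
        x, f, fn = xt, ft, ftn
    if fn < tol:
        return NewtonResult(sysm.make_state(x), True, max_iter, fn)
    return NewtonResult(None, False, max_iter, fn, "maximum iterations reached")


def solve_zero_haematocrit(network: VascularNetwork | CompiledSystem) -> NetworkState:
    """Unique equilibrium of the haematocrit-free (linear) network.

    With no red cells every vessel has the plasma viscosity value µ(0, D) and
    the pressure equations reduce to a linear conductance (Kirchhoff) system;
    all haematocrit unknowns are zero.  Serves as the homotopy start.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network)
    x = np.zeros(sysm.n_unknowns)
    P = _linear_pressure_solve(sysm, np.zeros(len(sysm.lengths)))
    x[: sysm.n_interior] = P[sysm.interior_idx]
    return sysm.make_state(x)


def _linear_pressure_solve(sysm: CompiledSystem, H: np.ndarray) -> np.ndarray:
    """Solve the conductance system for interior pressures at frozen haematocrit."""
    mu = _viscosity_unchecked(np.clip(H, 0.0, 0.999), sysm.diameters, sysm.params.mu_p)
    g = math.pi * sysm.diameters**4 / (128.0 * sysm.lengths * mu)  # conductances
    n = len(sysm.node_ids)
    L = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(len(g)):
        a, c = sysm.start[i], sysm.end[i]
        L[a, a] += g[i]; L[c, c] += g[i]
        L[a, c] -= g[i]; L[c, a] -= g[i]
    ii = sysm.interior_idx
    bb = np.where(sysm._is_boundary)[0]
    rhs = -L[np.ix_(ii, bb)] @ sysm.boundary_p[bb]
    try:
        p_int = np.linalg.solve(L[np.ix_(ii, ii)], rhs)
    except np.linalg.LinAlgError as e:
        raise SingularNetworkError("conductance system is singular") from e
    P = sysm.boundary_p.copy()
    P[ii] = p_int
    return P


def frozen_haematocrit_start(sysm: CompiledSystem, h_value: float | None = None) -> np.ndarray:
    """Start vector with every haematocrit frozen at ``h_value`` (default: mean
    inlet haematocrit) and pressures from the corresponding linear solve."""
    if h_value is None:
        h_value = float(sysm.inlet_h[sysm.inlet_mask].mean()) if sysm.inlet_mask.any() else 0.0
    H = np.full(len(sysm.lengths), h_value)
    P = _linear_pressure_solve(sysm, H)
    x = np.empty(sysm.n_unknowns)
    x[: sysm.n_interior] = P[sysm.interior_idx]
    x[sysm.n_interior:] = h_value
    return x


# -- spec-facing wrappers -------------------------------------------------

def signed_flows(network: VascularNetwork, state: NetworkState) -> dict:
    """Normalised signed flow per vessel key (positive along reference orientation)."""
    q = state.system.flows(state.x)
    return {k: float(v) for k, v in zip(state.system.vessel_keys, q)}


def assemble_residual(network: VascularNetwork | CompiledSystem,
                      state: NetworkState | np.ndarray) -> np.ndarray:
    """Residual vector (interior-node rows, then non-inlet vessel rows)."""
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network)
    x = state.x if isinstance(state, NetworkState) else np.asarray(state, dtype=float)
    H = sysm.haematocrits(x)
    if np.any((H < -1e-12) | (H >= 1.0)):
        raise InvalidStateError("haematocrits must lie in [0, 1)")
    return sysm.residual(x)


def jacobian(network: VascularNetwork | CompiledSystem,
             state: NetworkState | np.ndarray, step: float = 1e-7) -> np.ndarray:
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network)
    x = state.x if isinstance(state, NetworkState) else np.asarray(state, dtype=float)
    return sysm.jacobian(x, step=step)


def global_rbc_balance(state: NetworkState) -> float:
    """Outlet RBC flux minus inlet RBC flux (zero at any equilibrium)."""
    sysm = state.system
    q = sysm.flows(state.x)
    H = sysm.haematocrits(state.x)
    inflow = float(np.sum(np.abs(q[sysm.inlet_mask]) * H[sysm.inlet_mask]))
    outflow = float(np.sum(np.abs(q[sysm.outlet_mask]) * H[sysm.outlet_mask]))
    return outflow - inflow
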