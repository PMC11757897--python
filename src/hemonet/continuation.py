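"""Homotopy start, pseudo-arclength branch tracing, folds and flow-state labels.

The network equations are solved globally in two stages.  A first
equilibrium is found by homotopy: the target system F is deformed into a
starting system G with a known unique solution through
``h = (1-lam) F + lam G`` and the solution path is tracked from lam = 1 to
lam = 0 (equivalent to integrating the Davidenko ODE, but realised as a
pseudo-arclength predictor-corrector so the path may pass through folds).
Bifurcation diagrams are produced by the same tracker with lam a network
parameter (a length ratio, diameter, inlet haematocrit or boundary
pressure).  Folds are detected as sign changes of the tangent's parameter
component, bracketed by bisection along the branch and polished by a Newton
iteration on the extended fold system (residual + null-vector condition),
which leaves the Jacobian numerically singular at the reported point.

Equilibria at a fixed parameter point are enumerated by combining
continuation seeding with multistart damped Newton from a seeded
low-discrepancy grid, de-duplicated by state distance.  Coexisting
equilibria are labelled by the flow state (negative / intermediate /
positive) in each redundant vessel: a triple of flows straddling zero labels
its middle member intermediate, in line with the geometric picture of an
S-shaped branch between two folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import networkx as nx
from scipy.stats import qmc

from .steady_state import (CompiledSystem, NetworkState, compile_network,
                           canonicalize, frozen_haematocrit_start, newton_solve,
                           solve_zero_haematocrit, InvalidStateError)
from .topology import VascularNetwork, find_redundant_vessels

__all__ = [
    "ParameterHandle", "parameter_handle", "ParametricSystem",
    "Branch", "FoldPoint", "TrackingError",
    "homotopy_initial_solve", "continue_branch", "detect_folds", "dedup_folds",
    "enumerate_equilibria", "classify_flow_state", "redundant_vessel_order",
    "equilibria_at",
]

RESIDUAL_TOL = 1e-11


class TrackingError(RuntimeError):
    """Continuation failed before reaching the requested parameter range."""


# --------------------------------------------------------------------------
# parameter handles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterHandle:
    """Named scalar parameter of a compiled system (mutates parameter arrays)."""

    name: str
    setter: Callable[[CompiledSystem, float], None]
    getter: Callable[[CompiledSystem], float]

    def set(self, system: CompiledSystem, value: float) -> None:
        self.setter(system, value)

    def get(self, system: CompiledSystem) -> float:
        return self.getter(system)


def parameter_handle(network: VascularNetwork, name: str) -> ParameterHandle:
    """Build a handle for one of the sweepable parameters.

    Recognised names: ``beta`` (length of vessel (4,6)), ``alpha`` (common
    length of the redundant vessels), ``H_in`` (common inlet haematocrit),
    ``H_scale`` (scale factor on the as-built inlet haematocrits), ``D``
    (common diameter), ``P:<node>`` (boundary pressure of a node),
    ``L:<a>-<b>`` (length of one vessel).
    """
    if name == "beta":
        def _idx(sysm):
            i = sysm.__dict__.get("_beta_idx")
            if i is None:
                i = sysm.vessel_indices([(4, 6)])[0]
                sysm._beta_idx = i
            return i

        return ParameterHandle(
            "beta",
            lambda sysm, v: sysm.lengths.__setitem__(_idx(sysm), v),
            lambda sysm: float(sysm.lengths[_idx(sysm)]))
    if name == "alpha":
        keys = tuple(sorted(find_redundant_vessels(network)))
        if not keys:
            raise ValueError("network has no redundant vessels; alpha is undefined")

        def _aidx(sysm, _keys=keys):
            ii = sysm.__dict__.get("_alpha_idx")
            if ii is None:
                ii = tuple(sysm.vessel_indices(_keys))
                sysm._alpha_idx = ii
            return ii

        def setter(sysm, v):
            for i in _aidx(sysm):
                sysm.lengths[i] = v

        return ParameterHandle("alpha", setter,
                               lambda sysm: float(sysm.lengths[_aidx(sysm)[0]]))
    if name == "H_in":
        def setter(sysm, v):
            sysm.inlet_h[sysm.inlet_mask] = v

        def getter(sysm):
            return float(sysm.inlet_h[sysm.inlet_mask].mean())

        return ParameterHandle("H_in", setter, getter)
    if name == "H_scale":
        def setter(sysm, v):
            if "H_scale_base" not in sysm.__dict__:
                sysm.H_scale_base = sysm.inlet_h.copy()
            sysm.inlet_h[:] = v * sysm.H_scale_base

        def getter(sysm):
            return 1.0

        return ParameterHandle("H_scale", setter, getter)
    if name == "D":
        def setter(sysm, v):
            sysm.diameters[:] = v

        def getter(sysm):
            return float(sysm.diameters[0])

        return ParameterHandle("D", setter, getter)
    if name.startswith("P:"):
        node = _parse_id(name[2:])

        def setter(sysm, v, _node=node):
            sysm.boundary_p[sysm.node_index[_node]] = v

        def getter(sysm, _node=node):
            return float(sysm.boundary_p[sysm.node_index[_node]])

        return ParameterHandle(name, setter, getter)
    if name.startswith("L:"):
        a, b = (_parse_id(t) for t in name[2:].split("-"))

        def setter(sysm, v, _k=(a, b)):
            sysm.lengths[sysm.vessel_indices([_k])[0]] = v

        def getter(sysm, _k=(a, b)):
            return float(sysm.lengths[sysm.vessel_indices([_k])[0]])

        return ParameterHandle(name, setter, getter)
    raise ValueError(f"unknown parameter name {name!r}")


def _parse_id(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


class ParametricSystem:
    """Residual family F(x, lam) from a compiled system and a parameter handle."""

    def __init__(self, system: CompiledSystem, handle: ParameterHandle):
        self.sys = system.copy()
        self.handle = handle

    def F(self, x, lam):
        self.handle.set(self.sys, lam)
        return self.sys.residual(x)

    def Jx(self, x, lam):
        self.handle.set(self.sys, lam)
        return self.sys.jacobian(x)

    def Flam(self, x, lam, step: float = 1e-7):
        h = step * (1.0 + abs(lam))
        return (self.F(x, lam + h) - self.F(x, lam - h)) / (2.0 * h)

    def newton(self, x0, lam, tol: float = 1e-12, max_iter: int = 30):
        self.handle.set(self.sys, lam)
        return newton_solve(self.sys, x0, tol=tol, max_iter=max_iter)


class _CallableSystem:
    """Adapter giving arbitrary residual callables the ParametricSystem interface."""

    def __init__(self, fun, n, fd_step: float = 1e-7):
        self.fun = fun
        self.n = n
        self.fd_step = fd_step

    def F(self, x, lam):
        return self.fun(x, lam)

    def Jx(self, x, lam):
        J = np.empty((self.n, self.n))
        for j in range(self.n):
            h = self.fd_step * (1.0 + abs(x[j]))
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            J[:, j] = (self.fun(xp, lam) - self.fun(xm, lam)) / (2.0 * h)
        return J

    def Flam(self, x, lam):
        h = self.fd_step * (1.0 + abs(lam))
        return (self.fun(x, lam + h) - self.fun(x, lam - h)) / (2.0 * h)

    def newton(self, x0, lam, tol: float = 1e-12, max_iter: int = 30):
        x = np.asarray(x0, dtype=float).copy()
        f = self.fun(x, lam)
        fn = np.max(np.abs(f)) if np.all(np.isfinite(f)) else np.inf
        for _ in range(max_iter):
            if fn < tol:
                break
            try:
                dx = np.linalg.solve(self.Jx(x, lam), -f)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            for _bt in range(20):
                xt = x + t * dx
                ft = self.fun(xt, lam)
                ftn = np.max(np.abs(ft)) if np.all(np.isfinite(ft)) else np.inf
                if ftn < fn:
                    break
                t *= 0.5
            else:
                break
            x, f, fn = xt, ft, ftn

        class _R:
            pass

        r = _R()
        r.converged = fn < tol
        r.residual_norm = fn
        r.state = None
        r.x = x
        return r


# --------------------------------------------------------------------------
# branches and folds
# --------------------------------------------------------------------------

@dataclass
class FoldPoint:
    """A turning point of a branch: the tangent's parameter component vanishes."""

    lam: float
    x: np.ndarray
    tangent_lam: float
    index: int  # position in the branch point list after which the fold occurs


@dataclass
class Branch:
    """Ordered continuation curve of (state vector, parameter) points."""

    parameter: str
    lams: np.ndarray
    xs: np.ndarray          # shape (n_points, n_unknowns)
    tangent_lams: np.ndarray
    folds: list = field(default_factory=list)
    message: str = ""
    ps: ParametricSystem | None = field(default=None, repr=False)
    lam_range: tuple[float, float] | None = None  # requested sweep range

    def __len__(self) -> int:
        return len(self.lams)

    def state_at(self, i: int) -> NetworkState:
        if self.ps is None or not hasattr(self.ps, "sys"):
            raise ValueError("branch carries no compiled system")
        self.ps.handle.set(self.ps.sys, self.lams[i])
        return self.ps.sys.make_state(self.xs[i])

    def to_frame(self):
        import pandas as pd
        if self.ps is None or not hasattr(self.ps, "sys"):
            raise ValueError("branch carries no compiled system")
        sysm = self.ps.sys
        rows = []
        fold_idx = {f.index for f in self.folds}
        for i in range(len(self.lams)):
            self.ps.handle.set(sysm, self.lams[i])
            q = sysm.flows(self.xs[i])
            H = sysm.haematocrits(self.xs[i])
            P = sysm.full_pressures(self.xs[i])
            row = {self.parameter: self.lams[i], "fold": i in fold_idx}
            for k, (a, b) in enumerate(sysm.vessel_keys):
                row[f"Q_{a}_{b}"] = q[k]
                row[f"H_{a}_{b}"] = H[k]
            for nid in sysm.node_ids:
                row[f"P_{nid}"] = P[sysm.node_index[nid]]
            rows.append(row)
        return pd.DataFrame(rows)


def _tangent(ps, x, lam, t_prev):
    """Unit tangent of the solution curve from the bordered Jacobian."""
    n = len(x)
    M = np.empty((n + 1, n + 1))
    M[:n, :n] = ps.Jx(x, lam)
    M[:n, n] = ps.Flam(x, lam)
    M[n, :] = t_prev
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    try:
        t = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return None
    nrm = np.linalg.norm(t)
    if not np.isfinite(nrm) or nrm == 0:
        return None
    t = t / nrm
    if np.dot(t, t_prev) < 0:
        t = -t
    return t


def _corrector(ps, z_pred, t, tol: float = 1e-12, max_iter: int = 12):
    """Newton iteration orthogonal to the tangent; returns (z, n_iter) or None."""
    n = len(z_pred) - 1
    z = z_pred.copy()
    for it in range(1, max_iter + 1):
        f = ps.F(z[:n], z[n])
        if not np.all(np.isfinite(f)):
            return None
        fn = np.max(np.abs(f))
        if fn < tol:
            return z, it
        M = np.empty((n + 1, n + 1))
        M[:n, :n] = ps.Jx(z[:n], z[n])
        M[:n, n] = ps.Flam(z[:n], z[n])
        M[n, :] = t
        rhs = np.empty(n + 1)
        rhs[:n] = -f
        rhs[n] = -np.dot(t, z - z_pred)
        try:
            dz = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(dz)):
            return None
        z = z + dz
    f = ps.F(z[:n], z[n])
    if np.all(np.isfinite(f)) and np.max(np.abs(f)) < tol:
        return z, max_iter
    return None


def continue_branch(system: CompiledSystem | VascularNetwork,
                    parameter: str | ParameterHandle,
                    lam_range: tuple[float, float],
                    start: NetworkState | np.ndarray,
                    start_lam: float | None = None,
                    direction: int = 0,
                    step0: float = 1e-3, max_step: float = 2e-2,
                    min_step: float = 1e-8, max_points: int = 6000,
                    tol: float = 1e-12,
                    refine: bool = True) -> Branch:
    """Trace an equilibrium branch of F(x, parameter) = 0 through folds.

    ``start`` must be an equilibrium at ``start_lam`` (taken from the system
    if omitted) inside ``lam_range``.  ``direction`` +1/-1 picks the initial
    parameter direction; 0 traces both ways and concatenates.  The branch
    terminates at the range boundary (with a final point polished exactly on
    the boundary), on step underflow, or after ``max_points``.
    """
    if isinstance(system, VascularNetwork):
        system = compile_network(system)
    handle = parameter if isinstance(parameter, ParameterHandle) else \
        parameter_handle(system.network, parameter)
    ps = ParametricSystem(system, handle)
    x0 = start.x if isinstance(start, NetworkState) else np.asarray(start, dtype=float)
    lam0 = float(handle.get(ps.sys)) if start_lam is None else float(start_lam)
    lo, hi = min(lam_range), max(lam_range)
    if not lo <= lam0 <= hi:
        raise ValueError(f"start parameter {lam0} outside range [{lo}, {hi}]")
    res = ps.newton(x0, lam0, tol=tol)
    if not res.converged:
        raise TrackingError(f"start point is not an equilibrium (residual {res.residual_norm:.2e})")
    x0 = res.state.x if res.state is not None else res.x

    if direction == 0:
        b_up = _trace(ps, x0, lam0, lo, hi, +1, step0, max_step, min_step, max_points, tol)
        b_dn = _trace(ps, x0, lam0, lo, hi, -1, step0, max_step, min_step, max_points, tol)
        lams = np.concatenate([b_dn[0][::-1], b_up[0][1:]])
        xs = np.vstack([b_dn[1][::-1], b_up[1][1:]])
        tls = np.concatenate([-b_dn[2][::-1], b_up[2][1:]])
        msg = "; ".join(m for m in (b_dn[3], b_up[3]) if m)
    else:
        lams, xs, tls, msg = _trace(ps, x0, lam0, lo, hi, direction,
                                    step0, max_step, min_step, max_points, tol)
    branch = Branch(handle.name, np.asarray(lams), np.asarray(xs), np.asarray(tls),
                    message=msg, ps=ps, lam_range=(lo, hi))
    if refine:
        detect_folds(branch)
    return branch


def _trace(ps, x0, lam0, lo, hi, direction, step0, max_step, min_step, max_points, tol):
    n = len(x0)
    z = np.concatenate([x0, [lam0]])
    # initial tangent along increasing lam, then orient
    t_seed = np.zeros(n + 1)
    t_seed[n] = 1.0
    t = _tangent(ps, z[:n], z[n], t_seed)
    if t is None:
        # fall back to a secant tangent from a small fixed-lam-free perturbation
        t = t_seed
    if t[n] * direction < 0:
        t = -t
    elif t[n] == 0 and direction < 0:
        t = -t
    lams = [z[n]]
    xs = [z[:n].copy()]
    tls = [t[n]]
    h = step0
    msg = ""
    stall = 0
    side_stepped = False
    while len(lams) < max_points:
        z_pred = z + h * t
        out = _corrector(ps, z_pred, t, tol=tol)
        accept = False
        if out is not None:
            z_new, iters = out
            # reject wild corrector excursions (possible branch jumps)
            if np.linalg.norm(z_new - z_pred) <= max(4.0 * h, 1e-6):
                accept = True
        if not accept:
            h *= 0.4
            if h < min_step:
                if len(lams) == 1 and not side_stepped:
                    # the start may sit at a degenerate (symmetric) point where
                    # the arclength system is singular; restart from a nearby
                    # parameter value reached by a plain fixed-lam Newton solve
                    side_stepped = True
                    for off in (1e-4, 1e-3, 1e-2):
                        lam_try = min(hi, max(lo, lam0 + direction * off * max(1.0, hi - lo)))
                        if lam_try == lam0:
                            continue
                        res = ps.newton(x0, lam_try, tol=tol, max_iter=60)
                        if res.converged:
                            xr = res.state.x if res.state is not None else res.x
                            z = np.concatenate([xr, [lam_try]])
                            sec = z - np.concatenate([x0, [lam0]])
                            nrm = np.linalg.norm(sec)
                            t = sec / nrm if nrm > 0 else t
                            tn = _tangent(ps, z[:n], z[n], t)
                            if tn is not None:
                                t = tn
                            lams.append(z[n])
                            xs.append(z[:n].copy())
                            tls.append(t[n])
                            h = step0
                            break
                    else:
                        msg = "step underflow"
                        break
                    continue
                msg = "step underflow"
                break
            continue
        t_new = _tangent(ps, z_new[:n], z_new[n], t)
        if t_new is None:
            t_new = (z_new - z) / np.linalg.norm(z_new - z)
        moved = np.linalg.norm(z_new - z)
        z, t = z_new, t_new
        lams.append(z[n])
        xs.append(z[:n].copy())
        tls.append(t[n])
        # terminate when the path stops making progress (e.g. crawling into,
        # or drifting along, a symmetry-degenerate branch where the bordered
        # system is near-singular): no displacement, or no parameter motion
        # over a long window
        if moved < 1e-8:
            stall += 1
            if stall >= 25:
                msg = "stalled"
                break
        else:
            stall = 0
        if len(lams) >= 40 and abs(max(lams[-40:]) - min(lams[-40:])) < 1e-7:
            msg = "stalled"
            break
        if iters <= 3:
            h = min(h * 1.4, max_step)
        elif iters > 6:
            h = max(h * 0.5, min_step)
        if z[n] > hi + 1e-12 or z[n] < lo - 1e-12:
            # polish the final point exactly onto the boundary
            bound = hi if z[n] > hi else lo
            res = ps.newton(z[:n], bound, tol=tol)
            if res.converged:
                xb = res.state.x if res.state is not None else res.x
                lams[-1] = bound
                xs[-1] = xb
            break
    else:
        msg = "max points reached"
    return np.asarray(lams), np.asarray(xs), np.asarray(tls), msg


def detect_folds(branch: Branch, tol_tangent: float = 1e-8,
                 max_bisect: int = 70) -> list[FoldPoint]:
    """Locate folds on a branch as sign changes of the tangent's lam component.

    Each sign change is refined by bisection along the branch (halving
    pseudo-arclength steps) and then polished by Newton on the extended fold
    system F = 0, J v = 0, v_k = 1, so the Jacobian at the reported state is
    singular to near machine precision.
    """
    ps = branch.ps
    folds: list[FoldPoint] = []
    tls = branch.tangent_lams
    if branch.lam_range is not None:
        # filter on the requested sweep range: a fold just beyond the final
        # boundary-polished point belongs outside the sweep, while a fold at
        # a turning point legitimately sits slightly beyond the sampled range
        lam_lo, lam_hi = branch.lam_range
    else:
        lam_lo = float(np.min(branch.lams))
        lam_hi = float(np.max(branch.lams))
    for i in range(len(tls) - 1):
        if tls[i] == 0 or tls[i + 1] == 0:
            continue
        if np.sign(tls[i]) == np.sign(tls[i + 1]):
            continue
        fp = _refine_fold(ps, branch.xs[i], branch.lams[i],
                          branch.xs[i + 1], branch.lams[i + 1],
                          tol_tangent, max_bisect)
        if fp is None:
            continue
        # a sign change at the final (boundary-polished) point may belong to a
        # fold beyond the traced range; do not report it
        if not (lam_lo - 1e-9 <= fp.lam <= lam_hi + 1e-9):
            continue
        fp.index = i
        folds.append(fp)
    branch.folds = folds
    return folds


def _refine_fold(ps, x_a, lam_a, x_b, lam_b, tol_tangent, max_bisect):
    n = len(x_a)
    z_a = np.concatenate([x_a, [lam_a]])
    z_b = np.concatenate([x_b, [lam_b]])
    sec = (z_b - z_a)
    sec /= np.linalg.norm(sec)
    t_a = _tangent(ps, x_a, lam_a, sec)
    t_b = _tangent(ps, x_b, lam_b, sec)
    if t_a is None or t_b is None or np.sign(t_a[n]) == np.sign(t_b[n]):
        return None
    best = None
    for _ in range(max_bisect):
        gap = np.linalg.norm(z_b - z_a)
        if gap < 1e-13:
            break
        z_pred = z_a + 0.5 * gap * t_a
        out = _corrector(ps, z_pred, t_a, tol=1e-11)
        if out is None:
            break
        z_m = out[0]
        t_m = _tangent(ps, z_m[:n], z_m[n], t_a)
        if t_m is None:
            break
        best = (z_m, t_m)
        if abs(t_m[n]) < tol_tangent:
            break
        if np.sign(t_m[n]) == np.sign(t_a[n]):
            z_a, t_a = z_m, t_m
        else:
            z_b, t_b = z_m, t_m
    if best is None:
        z_m = 0.5 * (z_a + z_b)
        out = _corrector(ps, z_m, sec, tol=1e-10)
        if out is None:
            return None
        z_m = out[0]
        t_m = _tangent(ps, z_m[:n], z_m[n], sec)
        if t_m is None:
            return None
        best = (z_m, t_m)
    z_m, t_m = best
    z_p = _fold_newton(ps, z_m[:n], z_m[n])
    if z_p is not None:
        # accept the extended-system polish only if it stays near the bracket
        width = abs(lam_b - lam_a)
        if abs(z_p[n] - z_m[n]) <= max(2.0 * width, 1e-3) and \
                np.max(np.abs(z_p[:n] - z_m[:n])) <= max(10.0 * width, 0.05):
            z_m = z_p
            t_new = _tangent(ps, z_m[:n], z_m[n], t_m)
            if t_new is not None:
                t_m = t_new
    return FoldPoint(float(z_m[n]), z_m[:n].copy(), float(t_m[n]), -1)


def _fold_newton(ps, x, lam, max_iter: int = 8, tol: float = 1e-11):
    """Newton on the extended fold system (x, lam, v): F=0, Jv=0, v_k=1."""
    n = len(x)
    J = ps.Jx(x, lam)
    try:
        _, _, Vt = np.linalg.svd(J)
    except np.linalg.LinAlgError:
        return None
    v = Vt[-1]
    k = int(np.argmax(np.abs(v)))
    v = v / v[k]

    def G(y):
        xx, ll, vv = y[:n], y[n], y[n + 1:]
        Jm = ps.Jx(xx, ll)
        out = np.empty(2 * n + 1)
        out[:n] = ps.F(xx, ll)
        out[n:2 * n] = Jm @ vv
        out[2 * n] = vv[k] - 1.0
        return out

    y = np.concatenate([x, [lam], v])
    g = G(y)
    if not np.all(np.isfinite(g)):
        return None
    gn = np.max(np.abs(g))
    for _ in range(max_iter):
        if gn < tol:
            break
        m = 2 * n + 1
        Jg = np.empty((m, m))
        for j in range(m):
            h = 1e-6 * (1.0 + abs(y[j]))
            yp = y.copy(); yp[j] += h
            ym = y.copy(); ym[j] -= h
            gp, gm = G(yp), G(ym)
            if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
                return None
            Jg[:, j] = (gp - gm) / (2.0 * h)
        try:
            dy = np.linalg.solve(Jg, -g)
        except np.linalg.LinAlgError:
            return None
        y_new = y + dy
        g_new = G(y_new)
        if not np.all(np.isfinite(g_new)):
            return None
        gn_new = np.max(np.abs(g_new))
        if gn_new >= gn and gn < 1e-8:
            break
        y, g, gn = y_new, g_new, gn_new
    if gn > 1e-8:
        return None
    return np.concatenate([y[:n], [y[n]]])


def dedup_folds(folds: Sequence[FoldPoint], lam_tol: float = 1e-4,
                x_tol: float = 1e-4) -> list[FoldPoint]:
    """Merge folds found repeatedly when the same curve is traced from several seeds."""
    out: list[FoldPoint] = []
    for f in folds:
        dup = any(abs(f.lam - g.lam) < lam_tol and np.max(np.abs(f.x - g.x)) < x_tol
                  for g in out)
        if not dup:
            out.append(f)
    return sorted(out, key=lambda f: f.lam)


# --------------------------------------------------------------------------
# homotopy initial solve
# --------------------------------------------------------------------------

def homotopy_initial_solve(network: VascularNetwork | CompiledSystem,
                           rule="pries1990") -> NetworkState:
    """Find one equilibrium of the network equations by homotopy continuation.

    The starting system G freezes every vessel's viscosity at µ(H_in, D) and
    pins every unknown haematocrit to the mean inlet haematocrit, so it is
    linear in the pressures with a unique closed-form solution.  The convex
    homotopy h = (1-lam) F + lam G is tracked from lam = 1 to lam = 0 by
    pseudo-arclength continuation.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network, rule=rule)
    h_bar = float(sysm.inlet_h[sysm.inlet_mask].mean()) if sysm.inlet_mask.any() else 0.0
    x_start = frozen_haematocrit_start(sysm, h_bar)
    n = sysm.n_unknowns
    ni = sysm.n_interior

    frozen = sysm.copy()
    frozen_H = np.full(len(frozen.lengths), h_bar)

    def G(x):
        from .rheology import _viscosity_unchecked
        import math as _m
        mu = _viscosity_unchecked(np.clip(frozen_H, 0.0, 0.999), frozen.diameters,
                                  frozen.params.mu_p)
        R = 128.0 * frozen.lengths * mu / (_m.pi * frozen.diameters**4)
        P = frozen.full_pressures(x)
        Q = (P[frozen.start] - P[frozen.end]) / R
        Qin = Q[frozen.inlet_mask].sum()
        q = Q / Qin if Qin > 0 else np.full_like(Q, np.nan)
        out = np.empty(n)
        out[:ni] = frozen._A_int @ q
        out[ni:] = x[ni:] - h_bar
        return out

    def fun(x, lam):
        g = G(x)
        f = sysm.residual(x)
        return (1.0 - lam) * f + lam * g

    cs = _CallableSystem(fun, n)
    lams, xs, _tls, msg = _trace(cs, x_start, 1.0, 0.0, 1.0, -1,
                                 step0=5e-3, max_step=5e-2, min_step=1e-9,
                                 max_points=4000, tol=1e-11)
    if abs(lams[-1]) > 1e-12:
        raise TrackingError(f"homotopy tracking stalled at lambda = {lams[-1]:.4g} ({msg})")
    res = newton_solve(sysm, xs[-1], tol=1e-12)
    if not res.converged:
        raise TrackingError("final Newton polish at lambda = 0 failed")
    return sysm.make_state(canonicalize(sysm, res.state.x))


# --------------------------------------------------------------------------
# enumeration of equilibria
# --------------------------------------------------------------------------

def _is_valid_equilibrium(sysm: CompiledSystem, x: np.ndarray) -> bool:
    r = sysm.residual(x)
    if not (np.all(np.isfinite(r)) and np.max(np.abs(r)) < RESIDUAL_TOL):
        return False
    H = sysm.haematocrits(x)
    if np.any(H < -1e-10) or np.any(H >= 1.0):
        return False
    try:
        q = sysm.flows(x)
    except InvalidStateError:
        return False
    if np.any(np.abs(q) > 1.0 + 1e-6):
        return False
    return True


def _dedup_states(sysm: CompiledSystem, xs: list[np.ndarray],
                  tol: float = 1e-6) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for x in xs:
        if not any(np.max(np.abs(x - y)) < tol for y in out):
            out.append(x)
    return out


def multistart_equilibria(network: VascularNetwork | CompiledSystem,
                          n_starts: int = 400, seed: int = 0,
                          rule="pries1990") -> list[NetworkState]:
    """Equilibria found by damped Newton from a low-discrepancy grid of guesses.

    Independent of the continuation machinery; serves as its cross-check.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network, rule=rule)
    ni = sysm.n_interior
    n = sysm.n_unknowns
    p_lo = float(np.nanmin(sysm.boundary_p))
    p_hi = float(np.nanmax(sysm.boundary_p))
    h_hi = min(0.95, max(0.7, 1.6 * float(sysm.inlet_h.max(initial=0.0))))
    sampler = qmc.Sobol(d=n, scramble=True, seed=seed)
    m = max(1, int(np.ceil(np.log2(max(2, n_starts)))))
    pts = sampler.random_base2(m)[:n_starts]
    lo = np.concatenate([np.full(ni, p_lo), np.zeros(n - ni)])
    hi = np.concatenate([np.full(ni, p_hi), np.full(n - ni, h_hi)])
    guesses = [lo + p * (hi - lo) for p in pts]
    # structured guesses: linear solutions at frozen haematocrit patterns
    try:
        guesses.append(solve_zero_haematocrit(sysm).x)
        guesses.append(frozen_haematocrit_start(sysm))
    except Exception:
        pass
    found: list[np.ndarray] = []
    for g in guesses:
        res = newton_solve(sysm, g, tol=1e-12)
        if res.converged and res.state is not None:
            x = canonicalize(sysm, res.state.x)
            if _is_valid_equilibrium(sysm, x):
                found.append(x)
    return [sysm.make_state(x) for x in _dedup_states(sysm, found)]


def equilibria_at(branches: Sequence[Branch], lam_target: float,
                  tol: float = 1e-12) -> list[np.ndarray]:
    """All branch crossings of ``lam == lam_target``, polished by fixed-lam Newton."""
    xs: list[np.ndarray] = []
    for br in branches:
        ps = br.ps
        lams = br.lams
        for i in range(len(lams)):
            take = None
            if abs(lams[i] - lam_target) < 1e-9:
                take = br.xs[i]
            elif i + 1 < len(lams) and (lams[i] - lam_target) * (lams[i + 1] - lam_target) < 0:
                w = (lam_target - lams[i]) / (lams[i + 1] - lams[i])
                take = (1 - w) * br.xs[i] + w * br.xs[i + 1]
            if take is None:
                continue
            res = ps.newton(take, lam_target, tol=tol)
            if res.converged and res.state is not None:
                xs.append(canonicalize(ps.sys, res.state.x))
    return xs


def continuation_equilibria(network: VascularNetwork | CompiledSystem,
                            rule="pries1990",
                            handles: Sequence[str] | None = None,
                            rounds: int = 2,
                            sweep_span: float = 3.0) -> list[NetworkState]:
    """Equilibria found by continuation seeding only.

    Starts from the unique zero-haematocrit solution, continues the inlet
    haematocrit up to its as-built value, then repeatedly continues every
    known equilibrium through the geometric parameters (collecting all branch
    crossings of the target value), until no new equilibria appear.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network, rule=rule)
    if handles is None:
        handles = []
        try:
            parameter_handle(sysm.network, "beta")
            handles.append("beta")
        except Exception:
            pass
        try:
            parameter_handle(sysm.network, "alpha")
            handles.append("alpha")
        except Exception:
            pass
        if not handles:
            handles = ["H_scale"]
    # stage 1: bring the inlet haematocrit up from zero
    base = solve_zero_haematocrit(sysm)
    hs = parameter_handle(sysm.network, "H_scale")
    br = continue_branch(sysm, hs, (0.0, 1.0), base, start_lam=0.0, direction=+1,
                        max_step=5e-2, refine=False)
    xs = equilibria_at([br], 1.0)
    if not xs:
        res = newton_solve(sysm, homotopy_initial_solve(sysm).x)
        if res.converged:
            xs = [res.state.x]
    xs = _dedup_states(sysm, [canonicalize(sysm, x) for x in xs])
    # stage 2: sweep geometric parameters from every known equilibrium
    for _ in range(rounds):
        new: list[np.ndarray] = list(xs)
        for name in handles:
            handle = parameter_handle(sysm.network, name)
            target = handle.get(sysm)
            lo = target / sweep_span if target > 0 else -1.0
            hi = target * sweep_span if target > 0 else 1.0
            for x in xs:
                try:
                    b = continue_branch(sysm, handle, (lo, hi), sysm.make_state(x),
                                        start_lam=target, refine=False)
                except TrackingError:
                    continue
                new.extend(equilibria_at([b], target))
        new = _dedup_states(sysm, [canonicalize(sysm, x) for x in new])
        if len(new) == len(xs):
            xs = new
            break
        xs = new
    return [sysm.make_state(x) for x in xs if _is_valid_equilibrium(sysm, x)]


def enumerate_equilibria(network: VascularNetwork | CompiledSystem,
                         n_starts: int = 400, seed: int = 0,
                         rule="pries1990",
                         method: str = "both") -> list[NetworkState]:
    """All steady states at the network's current parameter point.

    Combines continuation seeding (from the unique zero-haematocrit solution)
    with multistart damped Newton, de-duplicating by state distance.  Raises
    if nothing is found.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network, rule=rule)
    xs: list[np.ndarray] = []
    if method in ("both", "multistart"):
        xs += [s.x for s in multistart_equilibria(sysm, n_starts=n_starts, seed=seed)]
    if method in ("both", "continuation"):
        try:
            xs += [s.x for s in continuation_equilibria(sysm)]
        except TrackingError:
            pass
    xs = _dedup_states(sysm, xs)
    if not xs:
        raise RuntimeError("no equilibrium found")
    return [sysm.make_state(x) for x in xs]


# --------------------------------------------------------------------------
# flow-state classification
# --------------------------------------------------------------------------

def redundant_vessel_order(network: VascularNetwork) -> list[tuple]:
    """Redundant vessels ordered by distance from the inlets (then by key)."""
    red = find_redundant_vessels(network)
    g = network.graph()
    dist = nx.multi_source_dijkstra_path_length(
        g, {n.id for n in network.inlet_nodes})
    return sorted(red, key=lambda k: (min(dist[k[0]], dist[k[1]]), str(k)))


def _cluster_1d(values: np.ndarray, max_k: int = 3, min_score: float = 3.0):
    """Split sorted 1-D values at their largest gaps into at most ``max_k`` groups."""
    order = np.argsort(values)
    v = values[order]
    nv = len(v)
    if nv == 1:
        return [list(order)], np.inf
    gaps = np.diff(v)
    best = ([list(order)], 0.0)
    for k in range(2, min(max_k, nv) + 1):
        cut_idx = np.sort(np.argsort(gaps)[-(k - 1):])
        groups = []
        startg = 0
        for c in cut_idx:
            groups.append(list(order[startg:c + 1]))
            startg = c + 1
        groups.append(list(order[startg:]))
        boundary = min(gaps[c] for c in cut_idx)
        within = 0.0
        for grp in groups:
            vv = values[grp]
            if len(vv) > 1:
                within = max(within, float(vv.max() - vv.min()))
        score = boundary / (within + 1e-12)
        if score >= min_score and score >= best[1]:
            best = (groups, score)
    return best


def classify_flow_state(equilibria: Sequence[NetworkState],
                        redundant: Sequence[tuple] | VascularNetwork | None = None,
                        zero_tol: float = 1e-9) -> list[tuple]:
    """Label each equilibrium by its flow state per redundant vessel.

    For every redundant vessel, coexisting equilibria are grouped by their
    flow value (conditioning recursively on the labels already assigned in
    the other vessels); a group triple straddling zero is labelled
    (-, 0, +) in flow order, otherwise groups are labelled by sign.  Flows
    within ``zero_tol`` of zero are labelled intermediate outright.
    """
    if not equilibria:
        return []
    sysm = equilibria[0].system
    if redundant is None or isinstance(redundant, VascularNetwork):
        net = redundant if isinstance(redundant, VascularNetwork) else sysm.network
        redundant = redundant_vessel_order(net)
    keys = list(redundant)
    flows = np.array([[s.flow(a, b) for (a, b) in keys] for s in equilibria])
    ns = len(equilibria)
    labels = [[None] * len(keys) for _ in range(ns)]

    def sign_label(val: float) -> str:
        if abs(val) < zero_tol:
            return "0"
        return "+" if val > 0 else "-"

    def assign(idxs: list[int], cols: list[int]) -> None:
        if not cols:
            return
        if len(idxs) == 1:
            for c in cols:
                labels[idxs[0]][c] = sign_label(flows[idxs[0], c])
            return
        # pick the vessel whose flows cluster most cleanly
        best_col, best_groups, best_score = cols[0], [list(range(len(idxs)))], -1.0
        for c in cols:
            groups, score = _cluster_1d(flows[idxs, c])
            if score > best_score:
                best_col, best_groups, best_score = c, groups, score
        c = best_col
        groups = [[idxs[i] for i in grp] for grp in best_groups]
        groups.sort(key=lambda grp: float(np.mean(flows[grp, c])))
        means = [float(np.mean(flows[grp, c])) for grp in groups]
        if len(groups) == 3 and means[0] < 0 < means[2]:
            tags = ["-", "0", "+"]
        else:
            tags = [sign_label(m) for m in means]
            if len(set(tags)) < len(tags):
                warnings.warn("ambiguous flow-state labelling: groups share a sign",
                              stacklevel=2)
        for grp, tag in zip(groups, tags):
            for i in grp:
                labels[i][c] = tag
            assign(grp, [cc for cc in cols if cc != c])

    assign(list(range(ns)), list(range(len(keys))))
    return [tuple(lab) for lab in labels]
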