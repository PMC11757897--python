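"""Sweep drivers for the bifurcation studies on the canonical networks.

Each driver enumerates the coexisting equilibria at a reference parameter
value, traces every equilibrium branch across the requested range by
pseudo-arclength continuation (skipping seeds that already lie on a traced
curve), de-duplicates the folds found on the way, and returns the branches,
folds and flow-state labels in machine-readable form.  Region maps count
equilibria on a parameter grid with warm-started Newton scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .continuation import (Branch, FoldPoint, TrackingError, classify_flow_state,
                           continue_branch, dedup_folds, enumerate_equilibria,
                           equilibria_at, multistart_equilibria, parameter_handle,
                           redundant_vessel_order)
from .fixtures import FixtureSpec, build_extended_triangle, build_triangle
from .steady_state import (CompiledSystem, NetworkState, canonicalize,
                           compile_network, frozen_haematocrit_start,
                           newton_solve, solve_zero_haematocrit)
from .topology import VascularNetwork

__all__ = [
    "SweepResult", "RegionMap", "sweep", "beta_sweep", "alpha_sweep",
    "haematocrit_sweep", "inlet_pressure_sweep", "count_equilibria_at",
    "region_map_alpha_beta", "critical_inlet_haematocrit", "region_map_D_H",
]


@dataclass
class SweepResult:
    """Branches and folds of a one-parameter bifurcation sweep."""

    parameter: str
    lam_range: tuple[float, float]
    branches: list[Branch]
    folds: list[FoldPoint]
    seed_states: list[NetworkState]
    seed_labels: list[tuple]

    @property
    def fold_lams(self) -> list[float]:
        return [f.lam for f in self.folds]

    def to_frame(self):
        import pandas as pd
        frames = []
        for i, br in enumerate(self.branches):
            df = br.to_frame()
            df.insert(0, "branch", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def sweep(network: VascularNetwork | CompiledSystem, parameter: str,
          lam_range: tuple[float, float], *, n_starts: int = 600, seed: int = 0,
          max_step: float = 6e-3, rule="pries1990",
          seeds: Sequence[NetworkState] | None = None,
          enumeration: str = "both") -> SweepResult:
    """Trace all equilibrium branches of ``parameter`` over ``lam_range``.

    Seeds default to the full equilibrium set at the system's as-built
    parameter value.  A seed already covered by a previously traced branch
    (within 1e-6 in state) is not re-traced.
    """
    sysm = network if isinstance(network, CompiledSystem) else compile_network(network, rule=rule)
    handle = parameter_handle(sysm.network, parameter)
    lam0 = handle.get(sysm)
    lo, hi = min(lam_range), max(lam_range)
    if not lo <= lam0 <= hi:
        lam0 = min(hi, max(lo, lam0))
        handle.set(sysm, lam0)
    if seeds is None:
        seeds = enumerate_equilibria(sysm, n_starts=n_starts, seed=seed, method=enumeration)
    labels = classify_flow_state(seeds) if seeds else []
    branches: list[Branch] = []
    covered: list[np.ndarray] = []
    for st in seeds:
        if any(np.max(np.abs(st.x - c)) < 1e-6 for c in covered):
            continue
        try:
            br = continue_branch(sysm, handle, (lo, hi), st, start_lam=lam0,
                                 max_step=max_step)
        except TrackingError:
            continue
        branches.append(br)
        covered.extend(equilibria_at([br], lam0))
    folds = dedup_folds([f for br in branches for f in br.folds])
    return SweepResult(handle.name, (lo, hi), branches, folds, list(seeds), labels)


def count_equilibria_at(result: SweepResult, lam: float) -> int:
    """Number of distinct equilibria where the traced branches cross ``lam``."""
    xs = equilibria_at(result.branches, lam)
    out: list[np.ndarray] = []
    for x in xs:
        if not any(np.max(np.abs(x - y)) < 1e-6 for y in out):
            out.append(x)
    return len(out)


def beta_sweep(network: VascularNetwork, beta_range: tuple[float, float] = (0.5, 1.5),
               **kw) -> SweepResult:
    """Vessel-length-asymmetry sweep: branches and folds versus β."""
    return sweep(network, "beta", beta_range, **kw)


def alpha_sweep(network: VascularNetwork, alpha_range: tuple[float, float] = (0.05, 2.0),
                **kw) -> SweepResult:
    """Redundant-vessel-length sweep: equilibria disappear pairwise as the
    cross vessels lengthen and their resistance grows."""
    return sweep(network, "alpha", alpha_range, **kw)


def haematocrit_sweep(network: VascularNetwork,
                      h_range: tuple[float, float] = (0.0, 0.45),
                      **kw) -> SweepResult:
    """Inlet-haematocrit sweep; fold locations are the critical values at
    which additional equilibria emerge from the unique H = 0 solution."""
    return sweep(network, "H_in", h_range, **kw)


def inlet_pressure_sweep(network: VascularNetwork, node=1,
                         p_range: tuple[float, float] = (0.35, 0.65),
                         **kw) -> SweepResult:
    """One inlet pressure varied with the other boundary conditions fixed."""
    return sweep(network, f"P:{node}", p_range, **kw)


# --------------------------------------------------------------------------
# region maps
# --------------------------------------------------------------------------

@dataclass
class RegionMap:
    """Equilibrium counts on a 2-D parameter grid (counts[i, j] at (rows[i], cols[j]))."""

    row_name: str
    col_name: str
    rows: np.ndarray
    cols: np.ndarray
    counts: np.ndarray

    def areas(self) -> dict[int, float]:
        """Area per count level, as cell count x cell area (uniform grids)."""
        dr = np.mean(np.diff(self.rows)) if len(self.rows) > 1 else 1.0
        dc = np.mean(np.diff(self.cols)) if len(self.cols) > 1 else 1.0
        cell = abs(dr * dc)
        out: dict[int, float] = {}
        for c in np.unique(self.counts):
            out[int(c)] = float(np.sum(self.counts == c) * cell)
        return out

    def multi_equilibria_area(self) -> float:
        return sum(a for c, a in self.areas().items() if c > 1)

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, r in enumerate(self.rows):
            for j, c in enumerate(self.cols):
                rows.append({self.row_name: r, self.col_name: c,
                             "n_equilibria": int(self.counts[i, j])})
        return pd.DataFrame(rows)


def _count_cell(sysm: CompiledSystem, carry: list[np.ndarray], rng,
                n_rand: int, p_lo: float, p_hi: float, h_hi: float,
                max_escalations: int = 3) -> list[np.ndarray]:
    """Equilibria of the current system from warm starts plus random guesses."""
    ni = sysm.n_interior
    n = sysm.n_unknowns
    guesses = list(carry)
    try:
        guesses.append(solve_zero_haematocrit(sysm).x)
        guesses.append(frozen_haematocrit_start(sysm))
    except Exception:
        pass
    found: list[np.ndarray] = []

    def run(batch):
        for g in batch:
            res = newton_solve(sysm, g, tol=1e-12)
            if res.converged and res.state is not None:
                x = canonicalize(sysm, res.state.x)
                from .continuation import _is_valid_equilibrium
                if _is_valid_equilibrium(sysm, x) and \
                        not any(np.max(np.abs(x - y)) < 1e-6 for y in found):
                    found.append(x)

    run(guesses)
    for _ in range(max_escalations + 1):
        batch = []
        for _k in range(n_rand):
            g = np.empty(n)
            g[:ni] = rng.uniform(p_lo, p_hi, ni)
            g[ni:] = rng.uniform(0.0, h_hi, n - ni)
            batch.append(g)
        # neighbouring equilibria often sit close in state space: perturbing
        # the ones already found is a cheap way to reach the rest of a cluster
        for x in list(found):
            for _k in range(3):
                batch.append(x + rng.normal(0.0, 0.03, n))
        run(batch)
        # equilibria appear in fold pairs above the unique base solution, so
        # an even count means at least one state is still missing
        if len(found) % 2 == 1:
            break
    else:
        # stubborn cell: one full low-discrepancy multistart pass
        extra = multistart_equilibria(sysm, n_starts=256,
                                      seed=int(rng.integers(2**31 - 1)))
        run([s.x for s in extra])
    return found


def region_map_alpha_beta(builder: Callable[[FixtureSpec], VascularNetwork],
                          alphas: Sequence[float], betas: Sequence[float],
                          h_in: float = 0.45, spec: FixtureSpec | None = None,
                          n_rand: int = 40, seed: int = 0,
                          rule="pries1990") -> RegionMap:
    """Equilibrium counts over an (α, β) grid at fixed inlet haematocrit.

    Scans each α row in β order, warm-starting the Newton solves from the
    neighbouring cell's equilibria; rows are additionally seeded from the
    row below.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    counts = np.zeros((len(alphas), len(betas)), dtype=int)
    base = builder(FixtureSpec(alpha=float(alphas[0]), beta=float(betas[0]),
                               diameter=spec.diameter, p1=spec.p1, p2=spec.p2,
                               p3=spec.p3, h_in=h_in))
    sysm = compile_network(base, rule=rule)
    ah = parameter_handle(base, "alpha")
    bh = parameter_handle(base, "beta")
    p_lo = float(np.nanmin(sysm.boundary_p))
    p_hi = float(np.nanmax(sysm.boundary_p))
    h_hi = min(0.95, max(0.7, 1.6 * h_in))
    prev_row: list[list[np.ndarray]] = [[] for _ in betas]
    for i, a in enumerate(alphas):
        ah.set(sysm, float(a))
        carry: list[np.ndarray] = []
        row_cache: list[list[np.ndarray]] = []
        for j, b in enumerate(betas):
            bh.set(sysm, float(b))
            found = _count_cell(sysm, carry + prev_row[j], rng, n_rand,
                                p_lo, p_hi, h_hi)
            counts[i, j] = len(found)
            carry = found
            row_cache.append(found)
        prev_row = row_cache
    return RegionMap("alpha", "beta", alphas, betas, counts)


# --------------------------------------------------------------------------
# critical inlet haematocrits versus diameter
# --------------------------------------------------------------------------

def _pick_state(states: list[NetworkState], labels: list[tuple], want: tuple):
    for s, l in zip(states, labels):
        if l == want:
            return s
    return None


def critical_inlet_haematocrit(D: float, *, which: tuple = ("+", "+"),
                               h_start: float = 0.6, alpha: float = 0.1,
                               beta: float = 1.0, n_starts: int = 300,
                               seed: int = 0, warm: np.ndarray | None = None,
                               max_step: float = 3e-3,
                               builder=build_extended_triangle):
    """Smallest inlet haematocrit at which the ``which``-labelled equilibrium
    of the symmetric extended-triangle network exists, at diameter ``D``.

    Located as the fold reached by continuing that equilibrium downward in
    the inlet haematocrit from ``h_start``.  Returns (fold value, state at
    ``h_start``); the state can warm-start the next diameter.
    """
    net = builder(FixtureSpec(alpha=alpha, beta=beta, diameter=D, h_in=h_start))
    sysm = compile_network(net)
    st = None
    if warm is not None:
        res = newton_solve(sysm, warm, tol=1e-12)
        if res.converged and res.state is not None:
            # verify the warm start still carries the wanted flow signs
            keys = redundant_vessel_order(net)
            signs = tuple("+" if res.state.flow(a, b) > 1e-9 else
                          ("-" if res.state.flow(a, b) < -1e-9 else "0")
                          for (a, b) in keys)
            if signs == which:
                st = res.state
    if st is None:
        eq = multistart_equilibria(sysm, n_starts=n_starts, seed=seed)
        labels = classify_flow_state(eq)
        st = _pick_state(eq, labels, which)
    if st is None:
        raise RuntimeError(f"no {which} equilibrium at D={D}, H_in={h_start}")
    br = continue_branch(sysm, "H_in", (0.0, h_start), st, start_lam=h_start,
                         max_step=max_step, max_points=1200)
    if br.folds:
        return min(f.lam for f in br.folds), st
    # at large diameters the branch ends on the symmetric base branch at a
    # symmetry-breaking branch point instead of a fold; the critical value is
    # then the lowest inlet haematocrit the branch reaches before stalling
    lam_min = float(np.min(br.lams))
    if lam_min > 5e-3 and br.message:
        return lam_min, st
    raise RuntimeError(f"no critical point found continuing H_in down at D={D}")


def region_map_D_H(D_values: Sequence[float] | None = None, *,
                   h_start: float = 0.6, seed: int = 0, refine: bool = True,
                   builder=build_extended_triangle) -> dict:
    """Critical curve H^(3)(D) of the symmetric extended-triangle network.

    ``H^(3)(D)`` is the inlet haematocrit at which the first pair of extra
    equilibria (the (+,+)/(-,-) pair) emerges.  Returns the curve on the
    diameter grid (default: 20 points log-spaced over [10, 200]) together
    with the diameter at which it attains its maximum, refined by a local
    quadratic fit when ``refine`` is set.
    """
    if D_values is None:
        D_values = np.geomspace(10.0, 200.0, 20)
    D_values = np.asarray(D_values, dtype=float)
    h3 = np.full(len(D_values), np.nan)
    warm = None
    for i, D in enumerate(D_values):
        try:
            h3[i], st = critical_inlet_haematocrit(D, h_start=h_start, seed=seed,
                                                   warm=warm, max_step=6e-3,
                                                   builder=builder)
            warm = st.x
        except RuntimeError:
            try:
                h3[i], st = critical_inlet_haematocrit(
                    D, h_start=h_start, seed=seed + 17, warm=None,
                    n_starts=600, max_step=3e-3, builder=builder)
                warm = st.x
            except RuntimeError:
                warm = None
    if np.all(np.isnan(h3)):
        raise RuntimeError("critical curve could not be computed on any grid point")
    i_max = int(np.nanargmax(h3))
    D_peak = float(D_values[i_max])
    if refine and 0 < i_max < len(D_values) - 1:
        # quadratic fit through the peak and refinement solves on extra points
        Ds = list(D_values[i_max - 1:i_max + 2])
        Hs = list(h3[i_max - 1:i_max + 2])
        extra = np.geomspace(Ds[0], Ds[-1], 7)[1:-1]
        for D in extra:
            try:
                v, st = critical_inlet_haematocrit(float(D), h_start=h_start,
                                                   seed=seed, warm=warm,
                                                   max_step=6e-3,
                                                   builder=builder)
                Ds.append(float(D))
                Hs.append(v)
            except RuntimeError:
                pass
        Ds = np.asarray(Ds)
        Hs = np.asarray(Hs)
        if len(Ds) >= 3 and np.ptp(Ds) > 0:
            c = np.polyfit(Ds, Hs, 2)
            if c[0] < 0:
                vertex = -c[1] / (2 * c[0])
                if Ds.min() <= vertex <= Ds.max():
                    D_peak = float(vertex)
                else:
                    D_peak = float(Ds[int(np.argmax(Hs))])
            else:
                D_peak = float(Ds[int(np.argmax(Hs))])
    return {"D": D_values, "H3": h3, "D_peak": D_peak,
            "H3_max": float(np.nanmax(h3))}
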