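"""In-vivo blood rheology: apparent viscosity and hydraulic resistance.

Blood in microvessels is modelled as a Poiseuille flow whose effective
viscosity depends on the tube haematocrit ``H`` (red-blood-cell volume
fraction) and the vessel diameter ``D`` (in µm) through the empirical
in-vivo law of Pries and co-workers.  The diameter dependence captures the
Fåhræus–Lindqvist effect: apparent viscosity falls steeply as the diameter
shrinks towards the red-cell size, then diverges again below ~1 µm.

All functions are pure and vectorised over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "mu_45",
    "coeff_C",
    "apparent_viscosity",
    "hydraulic_resistance",
    "poiseuille_flow",
]

#: Diameter (µm) at which the in-vivo law is singular; inputs must exceed it.
SINGULAR_DIAMETER = 1.1


@dataclass(frozen=True)
class RheologyParams:
    """Plasma viscosity ``mu_p`` in arbitrary consistent units.

    The network equations are formulated in flow ratios, so ``mu_p`` cancels
    from every dimensionless equilibrium; the default of 1 is therefore not a
    physical claim, merely a convenient normalisation.
    """

    mu_p: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu_p > 0:
            raise ValueError(f"plasma viscosity must be positive, got {self.mu_p}")


def mu_45(D):
    """Relative apparent viscosity of blood at H = 0.45 in a tube of diameter ``D`` µm.

    ``mu_45 = 6 exp(-0.085 D) + 3.2 - 2.44 exp(-0.06 D^0.645)``; tends to 3.2
    as D grows large.  Raises for ``D <= 1.1`` where the viscosity law it
    feeds into is singular.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= SINGULAR_DIAMETER):
        raise ValueError(f"diameter must exceed {SINGULAR_DIAMETER} µm")
    out = 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)
    return out if out.ndim else float(out)


def coeff_C(D):
    """Shape coefficient C(D) of the haematocrit dependence of the viscosity law.

    ``C = (0.8 + exp(-0.075 D)) (-1 + 1/(1 + 1e-11 D^12)) + 1/(1 + 1e-11 D^12)``.
    C → 1 as D → 0 and C → -0.8 as D → ∞.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    # 1e-11 D^12 overflows float for D ≳ 1e26; evaluate in log space guard-free
    with np.errstate(over="ignore"):
        t = 1.0 / (1.0 + 1e-11 * D**12)
    out = (0.8 + np.exp(-0.075 * D)) * (-1.0 + t) + t
    return out if out.ndim else float(out)


def apparent_viscosity(H, D, params: RheologyParams | None = None):
    """In-vivo apparent viscosity µ(H, D) for haematocrit ``H`` and diameter ``D`` µm.

    Reduces to ``mu_p (D/(D-1.1))^2`` at H = 0 and to ``mu_p mu_45(D)`` at
    H = 0.45 in wide tubes.
    """
    mu_p = (params or RheologyParams()).mu_p
    H = np.asarray(H, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any((H < 0) | (H >= 1)):
        raise ValueError("haematocrit must lie in [0, 1)")
    if np.any(D <= SINGULAR_DIAMETER):
        raise ValueError(f"diameter must exceed {SINGULAR_DIAMETER} µm")
    out = _viscosity_unchecked(H, D, mu_p)
    return out if out.ndim else float(out)


def _viscosity_unchecked(H, D, mu_p: float = 1.0):
    """Viscosity law without domain validation (solver-internal hot path)."""
    m45 = 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)
    t = 1.0 / (1.0 + 1e-11 * D**12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + t) + t
    wall = (D / (D - SINGULAR_DIAMETER)) ** 2
    hfac = ((1.0 - H) ** C - 1.0) / (0.55**C - 1.0)
    return mu_p * (1.0 + (m45 - 1.0) * hfac * wall) * wall


def hydraulic_resistance(H, D, L, params: RheologyParams | None = None):
    """Poiseuille resistance ``R = 128 L µ(H, D) / (π D^4)`` of a cylindrical vessel."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("vessel length must be positive")
    mu = apparent_viscosity(H, D, params)
    out = 128.0 * L * mu / (np.pi * np.asarray(D, dtype=float) ** 4)
    return out if np.ndim(out) else float(out)


def poiseuille_flow(P_upstream, P_downstream, R):
    """Signed volumetric flow ``Q = (P_up - P_down) / R`` through a vessel."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("resistance must be positive")
    out = (np.asarray(P_upstream, dtype=float) - np.asarray(P_downstream, dtype=float)) / R
    return out if np.ndim(out) else float(out)
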