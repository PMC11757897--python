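"""Plasma-skimming (phase-separation) splitting rules at flow bifurcations.

At a diverging junction red blood cells partition disproportionately between
the daughter vessels.  A splitting rule gives the fraction ψ of the parent
RBC flux entering a daughter as a function of the daughter's fractional
blood flow r = Q_daughter/Q_parent.  The default rule is the empirical
Pries-1990 logit form with diameter- and haematocrit-dependent coefficients.

Rules are pluggable: register alternatives with :func:`register_rule` and
select them by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

__all__ = [
    "SplitCoefficients",
    "SplittingRule",
    "pries1990_coefficients",
    "psi",
    "daughter_haematocrit_defect",
    "get_rule",
    "register_rule",
    "available_rules",
    "DegenerateJunctionError",
]

#: Normalised parent flow magnitude below which a junction is degenerate
#: (the flow ratio r is undefined at zero parent flow).
EPS_Q = 1e-14


class DegenerateJunctionError(ValueError):
    """Raised when a splitting rule is evaluated with (near-)zero parent flow."""


@dataclass(frozen=True)
class SplitCoefficients:
    """Coefficients of the Pries logit splitting rule.

    A skews the split towards the wider daughter, ρ ≥ 1 sharpens the logit,
    and X0 ∈ (0, 0.5) is the fractional-flow threshold below which a daughter
    receives no red cells at all.
    """

    A: float
    rho: float
    X0: float

    def __post_init__(self) -> None:
        if not self.rho >= 1.0:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if not 0.0 < self.X0 < 0.5:
            raise ValueError(f"X0 must lie in (0, 0.5), got {self.X0}")

    def sibling(self) -> "SplitCoefficients":
        """Coefficients seen by the other daughter (A changes sign)."""
        return SplitCoefficients(-self.A, self.rho, self.X0)


def pries1990_coefficients(D_parent: float, D_daughter: float, D_sibling: float,
                           H_parent: float) -> SplitCoefficients:
    """Pries-1990 coefficients for a given junction geometry.

    A = -(6.96/D_parent) ln(D_daughter/D_sibling), ρ = 1 + 6.98 (1-H)/D_parent,
    X0 = 0.4/D_parent.  Raises for parents too narrow for the rule (X0 ≥ 0.5).
    """
    for name, D in (("parent", D_parent), ("daughter", D_daughter), ("sibling", D_sibling)):
        if not D > 0.8:
            raise ValueError(f"{name} diameter must exceed 0.8 µm, got {D}")
    if not 0.0 <= H_parent < 1.0:
        raise ValueError(f"parent haematocrit must lie in [0, 1), got {H_parent}")
    A = -(6.96 / D_parent) * np.log(D_daughter / D_sibling)
    rho = 1.0 + 6.98 * (1.0 - H_parent) / D_parent
    X0 = 0.4 / D_parent
    return SplitCoefficients(float(A), float(rho), float(X0))


def psi(r, coeffs: SplitCoefficients):
    """RBC flux fraction ψ(r) received by a daughter with flow fraction ``r``.

    Piecewise: 0 below X0, 1 above 1-X0, and the logit form
    ``e^A (r-X0)^ρ / (e^A (r-X0)^ρ + (1-r-X0)^ρ)`` in between.  The powers are
    applied to ``max(·, 0)`` so round-off just outside the thresholds cannot
    produce complex values.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("flow ratio must lie in [0, 1]")
    out = _psi_unchecked(r, coeffs.A, coeffs.rho, coeffs.X0)
    return out if out.ndim else float(out)


def _psi_unchecked(r, A: float, rho: float, X0: float):
    r = np.asarray(r, dtype=float)
    lo = np.maximum(r - X0, 0.0)
    hi = np.maximum(1.0 - r - X0, 0.0)
    num = np.exp(A) * lo**rho
    den = num + hi**rho
    with np.errstate(invalid="ignore"):
        mid = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.5)
    return np.where(r < X0, 0.0, np.where(r > 1.0 - X0, 1.0, mid))


# --- pluggable rule interface -------------------------------------------------

@dataclass(frozen=True)
class SplittingRule:
    """A named splitting rule ψ(r, H_parent, D_parent, D_daughter, D_sibling)."""

    name: str
    fn: Callable[[float, float, float, float, float], float]

    def __call__(self, r, H_parent, D_parent, D_daughter, D_sibling):
        return self.fn(r, H_parent, D_parent, D_daughter, D_sibling)


def _pries1990(r, H_parent, D_parent, D_daughter, D_sibling):
    A = -(6.96 / D_parent) * np.log(D_daughter / D_sibling)
    rho = 1.0 + 6.98 * (1.0 - H_parent) / D_parent
    X0 = 0.4 / D_parent
    return _psi_unchecked(r, A, rho, X0)


def _proportional(r, H_parent, D_parent, D_daughter, D_sibling):
    # Degenerate reference rule: RBC flux split proportional to blood flow,
    # i.e. daughter haematocrits equal the parent's.  Useful as a linear
    # benchmark; not a physiological model.
    return np.asarray(r, dtype=float)


_REGISTRY: Dict[str, SplittingRule] = {}


def register_rule(name: str, fn) -> SplittingRule:
    """Register a splitting rule under ``name`` (overwrites any existing entry)."""
    rule = SplittingRule(name, fn)
    _REGISTRY[name] = rule
    return rule


def get_rule(name: str = "pries1990") -> SplittingRule:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown splitting rule {name!r}; available: {sorted(_REGISTRY)}")


def available_rules() -> list[str]:
    return sorted(_REGISTRY)


register_rule("pries1990", _pries1990)
register_rule("proportional", _proportional)


def daughter_haematocrit_defect(Q_parent, H_parent, Q_daughter, H_daughter,
                                D_parent, D_daughter, D_sibling,
                                rule: SplittingRule | str = "pries1990"):
    """Residual of the steady RBC-split condition at a diverging junction.

    Zero exactly when ψ(Q_d/Q_p) Q_p H_p = Q_d H_d.  Flows may be given in any
    common normalisation (the defect is invariant under uniform rescaling of
    both flows only up to the overall flux factor; at a root this does not
    matter).  Raises :class:`DegenerateJunctionError` when |Q_parent| < 1e-14.
    """
    if isinstance(rule, str):
        rule = get_rule(rule)
    if abs(Q_parent) < EPS_Q:
        raise DegenerateJunctionError("parent flow magnitude below 1e-14; flow ratio undefined")
    r = Q_daughter / Q_parent
    p = rule(r, H_parent, D_parent, D_daughter, D_sibling)
    return float(p * Q_parent * H_parent - Q_daughter * H_daughter)
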