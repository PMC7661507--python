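"""Coupled binding equilibria of the ProTα–H1 system.

The binding scheme comprises the 1:1 dimer PH and the two ternary
complexes PPH (a second ProTα bound to PH) and PHH (a second H1 bound to
PH):

    P + H   <-> PH    (K_D)
    P + PH  <-> PPH   (K_D_PPH)
    PH + H  <-> PHH   (K_D_PHH)

All isotherms and the general multi-species solver below work in molar
units.  A fluorescently labeled species P* is treated as strictly
infinitesimal — it reports on the equilibrium but never depletes the
unlabeled pools — except where an explicit ``c_Pstar_tot`` argument is
part of the isotherm (the direct H1 titration and the PHH titration,
which include ligand depletion of the labeled species itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RateSet",
    "ConcentrationState",
    "two_state_bound_fraction",
    "competition_bound_fraction",
    "phh_bound_fraction",
    "solve_species_concentrations",
    "population_fractions",
    "fit_titration_kd",
]


@dataclass(frozen=True)
class RateSet:
    """The six rate coefficients of the dimer + two-ternary-complex scheme.

    Units: association coefficients in M^-1 s^-1, dissociation rates in s^-1.
    Dissociation constants are derived, K_D = k_off / k_on per reaction.
    """

    k_on: float
    k_off: float
    k_on_PPH: float
    k_off_PPH: float
    k_on_PHH: float
    k_off_PHH: float

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_on_PPH", "k_off_PPH",
                     "k_on_PHH", "k_off_PHH"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on

    @property
    def K_D_PPH(self) -> float:
        return self.k_off_PPH / self.k_on_PPH

    @property
    def K_D_PHH(self) -> float:
        return self.k_off_PHH / self.k_on_PHH


#: Rate coefficients of the globally fitted kinetic scheme at 200 mM ionic
#: strength: dimer coefficients from the immobilized-molecule fit, ternary
#: PPH coefficients from the global concentration-dependent fit, and the
#: PHH branch from K_D_PHH = 12 µM with the trimer association rates assumed
#: equal (k_on_PHH = k_on_PPH).
GLOBAL_FIT_RATES = RateSet(
    k_on=1.45e9,
    k_off=1.7,
    k_on_PPH=0.53e9,
    k_off_PPH=1.9e3,
    k_on_PHH=0.53e9,
    k_off_PHH=0.53e9 * 12e-6,
)


@dataclass
class ConcentrationState:
    """Free and complex species concentrations at bulk equilibrium (molar)."""

    c_P: float
    c_H: float
    c_PH: float
    c_PPH: float
    c_PHH: float
    c_P_tot: float
    c_H_tot: float
    c_Pstar_tot: float = 0.0
    theta: float = field(default=np.nan)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check non-negativity and both mass-conservation identities."""
        for name in ("c_P", "c_H", "c_PH", "c_PPH", "c_PHH"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration {name}")
        p_sum = self.c_P + self.c_PH + 2 * self.c_PPH + self.c_PHH
        h_sum = self.c_H + self.c_PH + self.c_PPH + 2 * self.c_PHH
        scale_p = max(self.c_P_tot, 1e-300)
        scale_h = max(self.c_H_tot, 1e-300)
        if abs(p_sum - self.c_P_tot) > rtol * scale_p:
            raise ValueError("P mass conservation violated")
        if abs(h_sum - self.c_H_tot) > rtol * scale_h:
            raise ValueError("H mass conservation violated")


def _check_nonneg(**kwargs):
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be non-negative")


def two_state_bound_fraction(c_H_tot, c_Pstar_tot, K_D_star):
    """Bound fraction of labeled P* in a direct H1 titration.

    Exact quadratic-root solution of P* + H <-> P*H including depletion of
    the titrant by the labeled species.  Vectorized over ``c_H_tot``.
    """
    _check_nonneg(c_H_tot=c_H_tot, c_Pstar_tot=c_Pstar_tot)
    if K_D_star <= 0:
        raise ValueError("K_D_star must be positive")
    c_H_tot = np.asarray(c_H_tot, dtype=float)
    if c_Pstar_tot == 0:
        return c_H_tot / (c_H_tot + K_D_star)
    s = c_H_tot + K_D_star + c_Pstar_tot
    disc = s * s - 4.0 * c_H_tot * c_Pstar_tot
    theta = (s - np.sqrt(disc)) / (2.0 * c_Pstar_tot)
    return np.clip(theta, 0.0, 1.0)


def competition_bound_fraction(c_P_tot, c_H_tot, K_D_star, K_D):
    """Bound fraction of trace-labeled P* competed by unlabeled P.

    Closed form for the coupled equilibria P* + H <-> P*H and P + H <-> PH,
    valid in the limit where the labeled species is present in trace
    amounts relative to the unlabeled competitor (no explicit ``c_Pstar``
    argument; the labeled species does not deplete any pool).
    """
    _check_nonneg(c_P_tot=c_P_tot, c_H_tot=c_H_tot)
    if K_D_star <= 0 or K_D <= 0:
        raise ValueError("dissociation constants must be positive")
    c_P_tot = np.asarray(c_P_tot, dtype=float)
    root = np.sqrt((-c_H_tot + K_D + c_P_tot) ** 2 + 4.0 * c_H_tot * K_D)
    num = (c_H_tot * K_D_star - c_P_tot * K_D_star - 2.0 * c_H_tot * K_D
           - K_D_star * K_D + K_D_star * root)
    den = 2.0 * (c_H_tot * (K_D_star - K_D)
                 + K_D_star * (-c_P_tot - K_D + K_D_star))
    scale = 2.0 * K_D_star * (c_H_tot + c_P_tot + K_D)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(den) > 1e-10 * scale, num,
                         np.nan) / np.where(den != 0, den, 1.0)
    if np.any(~np.isfinite(theta)):
        # degenerate closed form (e.g. c_P_tot = 0 with equal affinities):
        # free H from the unlabeled dimer equilibrium, then the dilute-
        # labeled isotherm
        free_h = 0.5 * (c_H_tot - c_P_tot - K_D
                        + root)
        limit = free_h / (free_h + K_D_star)
        theta = np.where(np.isfinite(theta), theta, limit)
    return np.clip(theta, 0.0, 1.0)


def competition_midpoint(c_H_tot, K_D_star, K_D, bracket=(1e-15, 1e-3)):
    """Total competitor concentration at which the bound fraction of the
    labeled species is exactly 1/2 (absolute, not half of the plateau)."""
    f = lambda c: competition_bound_fraction(c, c_H_tot, K_D_star, K_D) - 0.5
    return brentq(f, *bracket, xtol=1e-18, rtol=1e-13)


def phh_bound_fraction(c_H_tot, c_Pstar_tot, K_D_PHH):
    """Fraction of labeled species present as P*HH in an H1 titration.

    At the relevant conditions the labeled species is fully saturated with
    one H1 (unbound P* is negligible), so the total labeled pool is
    c_P*H + c_P*HH and the reaction P*H + H <-> P*HH has the same
    quadratic-root isotherm as a simple 1:1 titration.
    """
    return two_state_bound_fraction(c_H_tot, c_Pstar_tot, K_D_PHH)


def _cp_given_ch(c_H, c_P_tot, K_D, K_D_PPH, K_D_PHH):
    """Free P from its conservation law at fixed free H (positive root of a
    quadratic; written to avoid cancellation)."""
    a = 2.0 * c_H / (K_D * K_D_PPH)
    b = 1.0 + c_H / K_D
    if K_D_PHH is not None:
        b += c_H * c_H / (K_D * K_D_PHH)
    if a == 0.0:
        return c_P_tot / b
    return 2.0 * c_P_tot / (b + np.sqrt(b * b + 4.0 * a * c_P_tot))


def solve_species_concentrations(c_P_tot, c_H_tot, rates: RateSet,
                                 include_PHH: bool = True,
                                 max_iter: int = 10_000,
                                 rtol: float = 1e-12) -> ConcentrationState:
    """Solve the coupled mass-action equilibrium for (P, H, PH, PPH[, PHH]).

    Strategy: damped fixed point alternating between the two analytic
    conservation quadratics for c_P(c_H) and c_H(c_P); if it has not
    converged within ``max_iter`` iterations, fall back to bracketed root
    finding on the scalar H-conservation residual, which is monotone in
    c_H and therefore always bracketed by [0, c_H_tot].
    """
    _check_nonneg(c_P_tot=c_P_tot, c_H_tot=c_H_tot)
    K_D, K_D_PPH = rates.K_D, rates.K_D_PPH
    K_D_PHH = rates.K_D_PHH if include_PHH else None

    def back_substitute(c_P, c_H):
        c_PH = c_P * c_H / K_D
        c_PPH = c_P * c_PH / K_D_PPH
        c_PHH = c_H * c_PH / K_D_PHH if include_PHH else 0.0
        return c_PH, c_PPH, c_PHH

    if c_P_tot == 0.0 or c_H_tot == 0.0:
        return ConcentrationState(c_P=c_P_tot, c_H=c_H_tot, c_PH=0.0,
                                  c_PPH=0.0, c_PHH=0.0,
                                  c_P_tot=c_P_tot, c_H_tot=c_H_tot)

    def _ch_given_cp(c_P):
        a = (2.0 * c_P / (K_D * K_D_PHH)) if include_PHH else 0.0
        b = 1.0 + c_P / K_D + c_P * c_P / (K_D * K_D_PPH)
        if a == 0.0:
            return c_H_tot / b
        return 2.0 * c_H_tot / (b + np.sqrt(b * b + 4.0 * a * c_H_tot))

    # damped alternating fixed point
    c_H = min(c_H_tot, K_D)
    c_P = _cp_given_ch(c_H, c_P_tot, K_D, K_D_PPH, K_D_PHH)
    damp = 0.5
    converged = False
    for _ in range(max_iter):
        c_P_new = _cp_given_ch(c_H, c_P_tot, K_D, K_D_PPH, K_D_PHH)
        c_H_new = _ch_given_cp(c_P_new)
        c_P_next = damp * c_P_new + (1 - damp) * c_P
        c_H_next = damp * c_H_new + (1 - damp) * c_H
        if (abs(c_P_next - c_P) <= rtol * max(c_P, 1e-300)
                and abs(c_H_next - c_H) <= rtol * max(c_H, 1e-300)):
            c_P, c_H = c_P_next, c_H_next
            converged = True
            break
        c_P, c_H = c_P_next, c_H_next

    if not converged:
        def resid(ch):
            cp = _cp_given_ch(ch, c_P_tot, K_D, K_D_PPH, K_D_PHH)
            c_PH, c_PPH, c_PHH = back_substitute(cp, ch)
            return ch + c_PH + c_PPH + 2.0 * c_PHH - c_H_tot
        try:
            c_H = brentq(resid, 0.0, c_H_tot, xtol=1e-30, rtol=1e-15, maxiter=300)
        except Exception as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"equilibrium solver failed for c_P_tot={c_P_tot}, "
                f"c_H_tot={c_H_tot}: {exc}") from exc
        c_P = _cp_given_ch(c_H, c_P_tot, K_D, K_D_PPH, K_D_PHH)

    # polish with one bracketed root solve for full precision
    def resid(ch):
        cp = _cp_given_ch(ch, c_P_tot, K_D, K_D_PPH, K_D_PHH)
        c_PH, c_PPH, c_PHH = back_substitute(cp, ch)
        return ch + c_PH + c_PPH + 2.0 * c_PHH - c_H_tot
    lo, hi = 0.5 * c_H, min(2.0 * c_H, c_H_tot)
    if not (resid(lo) < 0 < resid(hi)):
        lo, hi = 0.0, c_H_tot
    c_H = brentq(resid, lo, hi, xtol=1e-30, rtol=1e-15, maxiter=300)
    c_P = _cp_given_ch(c_H, c_P_tot, K_D, K_D_PPH, K_D_PHH)
    c_PH, c_PPH, c_PHH = back_substitute(c_P, c_H)

    state = ConcentrationState(c_P=c_P, c_H=c_H, c_PH=c_PH, c_PPH=c_PPH,
                               c_PHH=c_PHH, c_P_tot=c_P_tot, c_H_tot=c_H_tot)
    state.validate(rtol=1e-9)
    return state


def population_fractions(c_P_tot_grid, c_H_tot, rates: RateSet,
                         include_PHH: bool = True):
    """Species fractions along a competitor-concentration grid.

    The free-P fraction is normalized by the total P concentration; the
    H-containing species (H, PH, PPH, PHH) are normalized by the total H1
    concentration, in which the doubly H-loaded PHH counts twice.
    """
    import pandas as pd

    rows = []
    for c_P_tot in np.asarray(c_P_tot_grid, dtype=float):
        s = solve_species_concentrations(c_P_tot, c_H_tot, rates,
                                         include_PHH=include_PHH)
        rows.append({
            "c_P_tot": c_P_tot,
            "P": s.c_P / s.c_P_tot if s.c_P_tot > 0 else 1.0,
            "H": s.c_H / c_H_tot,
            "PH": s.c_PH / c_H_tot,
            "PPH": s.c_PPH / c_H_tot,
            "PHH": s.c_PHH / c_H_tot,
        })
    return pd.DataFrame(rows)


def fit_titration_kd(c_tot, theta, sd=None, model="two_state",
                     c_Pstar_tot=0.0, c_H_tot=None, K_D_star=None,
                     p0=1e-9):
    """Weighted least-squares fit of a titration curve for its K_D.

    model:
      'two_state'   — direct titration, Eq.-of-state two_state_bound_fraction
      'phh'         — second-H1 titration, phh_bound_fraction
      'competition' — competitor titration at fixed c_H_tot and K_D_star
    Returns (K_D, s.e.).
    """
    import lmfit

    c_tot = np.asarray(c_tot, float)
    theta = np.asarray(theta, float)
    w = 1.0 / np.asarray(sd, float) if sd is not None else None

    def residual(params):
        kd = params["kd"].value
        if model == "two_state":
            pred = two_state_bound_fraction(c_tot, c_Pstar_tot, kd)
        elif model == "phh":
            pred = phh_bound_fraction(c_tot, c_Pstar_tot, kd)
        elif model == "competition":
            pred = competition_bound_fraction(c_tot, c_H_tot, K_D_star, kd)
        else:
            raise ValueError(f"unknown model {model!r}")
        r = pred - theta
        return r * w if w is not None else r

    params = lmfit.Parameters()
    params.add("kd", value=p0, min=1e-15, max=1.0)
    out = lmfit.minimize(residual, params, method="leastsq")
    kd = out.params["kd"].value
    stderr = out.params["kd"].stderr
    return kd, (stderr if stderr is not None else np.nan)
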