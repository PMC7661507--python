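"""Continuous-time Markov generators for the multi-state binding kinetics.

The generators use the column convention dp/dt = K p: off-diagonal entry
K[i, j] is the rate from state j to state i, and every column sums to
zero.  The concentrations entering the pseudo-first-order entries are the
bulk-equilibrium concentrations of the *unlabeled* species; the observed
labeled molecule is infinitesimally dilute and never depletes them, which
makes the generator independent of the labeled concentrations.

The PPH ternary complex dissociates either to P* + PH or to P*H + P with
equal likelihood, producing the factors 1/2 on its dissociation entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .equilibria import ConcentrationState, RateSet, solve_species_concentrations

__all__ = [
    "GeneratorMatrix",
    "DwellResult",
    "build_K2",
    "build_K3P",
    "build_K4P",
    "build_K4H",
    "mean_dwell_times",
    "tau_high_3state",
    "exchange_rate",
    "global_fit_ternary",
]

#: branch weight for PPH -> (P* + PH) vs (P*H + P); both channels equally likely
PPH_SPLIT = 0.5


@dataclass
class GeneratorMatrix:
    """A CTMC generator (column convention) with labels and equilibrium."""

    K: np.ndarray
    state_labels: tuple

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n):
            raise ValueError("K must be square")
        off = K - np.diag(np.diag(K))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        colsums = K.sum(axis=0)
        scale = np.abs(K).max() or 1.0
        if np.any(np.abs(colsums) > 1e-10 * scale):
            raise ValueError("columns of a generator must sum to zero")
        self.K = K

    @property
    def n_states(self) -> int:
        return self.K.shape[0]

    @property
    def p_eq(self) -> np.ndarray:
        """Equilibrium distribution: K p = 0, sum(p) = 1, p >= 0."""
        ns = null_space(self.K)
        if ns.shape[1] == 0:
            # numerically empty null space: fall back to least squares
            A = np.vstack([self.K, np.ones(self.n_states)])
            b = np.zeros(self.n_states + 1)
            b[-1] = 1.0
            p, *_ = np.linalg.lstsq(A, b, rcond=None)
        elif ns.shape[1] > 1:
            raise ValueError(
                "generator is reducible (multiple stationary distributions); "
                f"states {self.state_labels}")
        else:
            p = ns[:, 0]
        p = p / p.sum()
        if np.any(p < -1e-12):
            raise ValueError("negative equilibrium probability")
        return np.clip(p, 0.0, None)


@dataclass
class DwellResult:
    """Mean dwell times of the low/high aggregates and derived rates."""

    tau_low: float
    tau_high: float

    @property
    def k_on_obs(self) -> float:
        return 1.0 / self.tau_low

    @property
    def k_off_obs(self) -> float:
        return 1.0 / self.tau_high

    @property
    def k_ex(self) -> float:
        return self.k_on_obs + self.k_off_obs


def build_K2(rates: RateSet, c_H: float) -> GeneratorMatrix:
    """Two-state generator (unbound, bound) with k_on_obs = k_on * c_H."""
    if c_H < 0:
        raise ValueError("c_H must be non-negative")
    kon_obs = rates.k_on * c_H
    K = np.array([[-kon_obs, rates.k_off],
                  [kon_obs, -rates.k_off]])
    return GeneratorMatrix(K, ("P*", "P*H"))


def _require_solved(conc: ConcentrationState):
    if conc.c_P < 0 or conc.c_H < 0 or conc.c_PH < 0:
        raise ValueError("concentration state has negative entries")


def build_K3P(rates: RateSet, conc: ConcentrationState) -> GeneratorMatrix:
    """Three-state generator (P*, P*H, P*PH) with the PHH branch neglected."""
    _require_solved(conc)
    kon, koff = rates.k_on, rates.k_off
    konT, koffT = rates.k_on_PPH, rates.k_off_PPH
    cP, cH, cPH = conc.c_P, conc.c_H, conc.c_PH
    K = np.array([
        [-(kon * cH + konT * cPH), koff, PPH_SPLIT * koffT],
        [kon * cH, -(koff + konT * cP), PPH_SPLIT * koffT],
        [konT * cPH, konT * cP, -koffT],
    ])
    return GeneratorMatrix(K, ("P*", "P*H", "P*PH"))


def build_K4P(rates: RateSet, conc: ConcentrationState) -> GeneratorMatrix:
    """Four-state generator (P*, P*H, P*PH, P*HH) for observation of labeled P.

    The 1/2 branch factors apply to PPH dissociation only; P*HH dissociates
    with the full k_off_PHH back to P*H (loss of the second H1).
    """
    _require_solved(conc)
    kon, koff = rates.k_on, rates.k_off
    konT, koffT = rates.k_on_PPH, rates.k_off_PPH
    konH, koffH = rates.k_on_PHH, rates.k_off_PHH
    cP, cH, cPH = conc.c_P, conc.c_H, conc.c_PH
    K = np.array([
        [-(kon * cH + konT * cPH), koff, PPH_SPLIT * koffT, 0.0],
        [kon * cH, -(koff + konT * cP + konH * cH), PPH_SPLIT * koffT, koffH],
        [konT * cPH, konT * cP, -koffT, 0.0],
        [0.0, konH * cH, 0.0, -koffH],
    ])
    return GeneratorMatrix(K, ("P*", "P*H", "P*PH", "P*HH"))


def build_K4H(rates: RateSet, conc: ConcentrationState) -> GeneratorMatrix:
    """Four-state generator (H*, PH*, PPH*, PH*H) for observation of labeled H.

    Mirror of the labeled-P case: here the doubly H1-loaded complex PH*H
    carries the 1/2 branch factors (it can release either H1 copy), while
    PPH* dissociates with the full k_off_PPH back to PH*.
    """
    _require_solved(conc)
    kon, koff = rates.k_on, rates.k_off
    konT, koffT = rates.k_on_PPH, rates.k_off_PPH
    konH, koffH = rates.k_on_PHH, rates.k_off_PHH
    cP, cH, cPH = conc.c_P, conc.c_H, conc.c_PH
    K = np.array([
        [-(kon * cP + konH * cPH), koff, 0.0, PPH_SPLIT * koffH],
        [kon * cP, -(koff + konT * cP + konH * cH), koffT, PPH_SPLIT * koffH],
        [0.0, konT * cP, -koffT, 0.0],
        [konH * cPH, konH * cH, 0.0, -koffH],
    ])
    return GeneratorMatrix(K, ("H*", "PH*", "PPH*", "PH*H"))


def mean_dwell_times(gen: GeneratorMatrix, low_states) -> DwellResult:
    """Mean dwell times of the low/high aggregates of a generator.

    Computed via the sub-generator fundamental matrix: the mean residence
    time in an aggregate A entered according to the steady-state entry
    distribution is eta^T (-(K_AA)^T)^{-1} 1, which equals the equilibrium
    occupancy of A divided by the probability flux leaving A.
    """
    labels = list(gen.state_labels)
    low = sorted(labels.index(s) if isinstance(s, str) else int(s)
                 for s in low_states)
    high = [i for i in range(gen.n_states) if i not in low]
    if not low or not high:
        raise ValueError("low/high partition must be a proper bipartition")
    p_eq = gen.p_eq

    def aggregate_dwell(A, B):
        K_AA = gen.K[np.ix_(A, A)]
        # entry distribution: flux from B into each state of A
        eta = np.array([gen.K[i, B] @ p_eq[B] for i in A])
        total = eta.sum()
        if total <= 0:
            raise ValueError(
                f"aggregate {[labels[i] for i in A]} is disconnected from "
                f"{[labels[i] for i in B]}")
        eta /= total
        # mean absorption times: -(K_AA)^T t = 1
        t = np.linalg.solve(-K_AA.T, np.ones(len(A)))
        return float(eta @ t)

    return DwellResult(tau_low=aggregate_dwell(low, high),
                       tau_high=aggregate_dwell(high, low))


def tau_high_3state(rates: RateSet, conc: ConcentrationState) -> float:
    """Closed-form mean bound-state dwell time of the three-state model.

    Rational expression in the free concentrations and rate coefficients;
    reduces to 1/k_off when no competitor is present (c_P = c_PH = 0).
    """
    kon, koff = rates.k_on, rates.k_off
    konT, koffT = rates.k_on_PPH, rates.k_off_PPH
    cP, cH, cPH = conc.c_P, conc.c_H, conc.c_PH
    num = (2.0 * cH * kon * (koffT + cP * konT)
           + cPH * konT * (2.0 * koff + koffT + 2.0 * cP * konT))
    den = koffT * (2.0 * koff + cP * konT) * (cH * kon + cPH * konT)
    if den == 0.0:
        raise ZeroDivisionError("degenerate rates/concentrations: zero denominator")
    return num / den


def exchange_rate(rates: RateSet, conc: ConcentrationState,
                  observed: str = "P", model: str = "4state") -> float:
    """Exchange rate k_ex = 1/tau_low + 1/tau_high for the chosen model.

    observed: 'P' (labeled ProTα) or 'H' (labeled H1).
    model: '2state', '3state' (labeled P only) or '4state'.
    """
    if model == "2state":
        c_partner = conc.c_H if observed == "P" else conc.c_P
        return rates.k_on * c_partner + rates.k_off
    if observed == "P":
        gen = build_K3P(rates, conc) if model == "3state" else build_K4P(rates, conc)
        low = ["P*"]
    elif observed == "H":
        if model == "3state":
            raise ValueError("3-state reduction applies to labeled P only")
        gen = build_K4H(rates, conc)
        low = ["H*"]
    else:
        raise ValueError(f"observed must be 'P' or 'H', got {observed!r}")
    return mean_dwell_times(gen, low).k_ex


def observed_rates_3state(rates: RateSet, c_P_tot: float, c_H_tot: float):
    """(k_on_obs, k_off_obs) of labeled P from the three-state model at the
    bulk equilibrium of the given totals (PHH excluded)."""
    conc = solve_species_concentrations(c_P_tot, c_H_tot, rates,
                                        include_PHH=False)
    k_on_obs = rates.k_on * conc.c_H + rates.k_on_PPH * conc.c_PH
    k_off_obs = 1.0 / tau_high_3state(rates, conc)
    return k_on_obs, k_off_obs


def global_fit_ternary(datasets, k_on: float, k_off: float,
                       K_D_PHH: float = 12e-6, p0=(1e9, 1e3)):
    """Global weighted least-squares fit of the ternary-complex coefficients.

    ``datasets`` is an iterable of records ``(c_P_tot, c_H_tot, observable,
    value, sd)`` with observable in {'k_on_obs', 'k_off_obs', 'k_ex'}.  The
    dimer coefficients ``k_on``/``k_off`` are fixed (determined at low
    concentration where ternary complexes are negligible) and the trimer
    association coefficients are shared, k_on_PHH = k_on_PPH.  Records
    without an s.d. are weighted as 10% relative errors.

    Returns (RateSet, report) where report carries standard errors, the
    reduced chi-square, the weights used, and a Jacobian condition number
    as an identifiability diagnostic.
    """
    import lmfit

    rows = [tuple(r) for r in datasets]
    if not rows:
        raise ValueError("no datasets")
    values = np.array([r[3] for r in rows], float)
    sds = np.array([r[4] if (len(r) > 4 and r[4] is not None and r[4] > 0)
                    else 0.1 * abs(r[3]) for r in rows], float)

    def predict(k_on_PPH, k_off_PPH):
        rs = RateSet(k_on=k_on, k_off=k_off,
                     k_on_PPH=k_on_PPH, k_off_PPH=k_off_PPH,
                     k_on_PHH=k_on_PPH, k_off_PHH=k_on_PPH * K_D_PHH)
        out = np.empty(len(rows))
        for i, (cPt, cHt, obs, _, *_rest) in enumerate(rows):
            kon_obs, koff_obs = observed_rates_3state(rs, cPt, cHt)
            if obs == "k_on_obs":
                out[i] = kon_obs
            elif obs == "k_off_obs":
                out[i] = koff_obs
            elif obs == "k_ex":
                out[i] = kon_obs + koff_obs
            else:
                raise ValueError(f"unknown observable {obs!r}")
        return out

    def residual(params):
        return (predict(np.exp(params["ln_kon_PPH"].value),
                        np.exp(params["ln_koff_PPH"].value)) - values) / sds

    params = lmfit.Parameters()
    params.add("ln_kon_PPH", value=np.log(p0[0]))
    params.add("ln_koff_PPH", value=np.log(p0[1]))
    result = lmfit.minimize(residual, params, method="leastsq")

    kon_PPH = np.exp(result.params["ln_kon_PPH"].value)
    koff_PPH = np.exp(result.params["ln_koff_PPH"].value)
    # delta-method standard errors on the natural scale
    se_ln_on = result.params["ln_kon_PPH"].stderr
    se_ln_off = result.params["ln_koff_PPH"].stderr
    se_on = kon_PPH * se_ln_on if se_ln_on is not None else np.nan
    se_off = koff_PPH * se_ln_off if se_ln_off is not None else np.nan

    # identifiability: condition number of the scaled Jacobian
    eps = 1e-6
    base = predict(kon_PPH, koff_PPH)
    J = np.column_stack([
        (predict(kon_PPH * (1 + eps), koff_PPH) - base) / eps,
        (predict(kon_PPH, koff_PPH * (1 + eps)) - base) / eps,
    ]) / sds[:, None]
    cond = float(np.linalg.cond(J))

    fitted = RateSet(k_on=k_on, k_off=k_off,
                     k_on_PPH=kon_PPH, k_off_PPH=koff_PPH,
                     k_on_PHH=kon_PPH, k_off_PHH=kon_PPH * K_D_PHH)
    report = {
        "k_on_PPH": kon_PPH, "k_on_PPH_se": se_on,
        "k_off_PPH": koff_PPH, "k_off_PPH_se": se_off,
        "redchi": float(result.redchi),
        "jacobian_condition_number": cond,
        "identifiable": cond < 1e8,
        "weights": "inverse-variance (10% relative where s.d. missing)",
        "n_data": len(rows),
    }
    return fitted, report


def slowest_relaxation_rate(gen: GeneratorMatrix) -> float:
    """Magnitude of the smallest nonzero eigenvalue of the generator.

    This is the rate at which bulk populations relax to equilibrium and
    hence what a single-exponential fit of an ensemble relaxation (e.g.
    stopped flow) measures.  It is generally smaller than the dwell-based
    exchange rate 1/tau_low + 1/tau_high, which also counts fast correlated
    recrossings through short-lived intermediates.
    """
    ev = np.sort(np.abs(np.linalg.eigvals(gen.K)))
    return float(ev[1])
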