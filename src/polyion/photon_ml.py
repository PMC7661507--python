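"""Photon-by-photon maximum-likelihood kinetics from smFRET time traces.

The likelihood of a photon trace under a hidden-Markov model with
continuous-time state switching (generator K) and state-dependent Poisson
photon emission in two detection channels is

    L = 1^T  prod_i  n_{c_i} exp[(K - n_D - n_A) tau_i]  p_eq,

where the product runs over photons in time order, c_i is the detection
channel of photon i, tau_i the preceding inter-photon interval
(tau_1 = 0), and n_D, n_A are diagonal matrices of per-state detection
rates.  The propagated vector is renormalized after every photon and the
log-norms accumulated, so the log-likelihood is exact and underflow-free.

For the two-state case the matrix exponential has a closed form
(the 2x2 matrix M = K - n_D - n_A always has real eigenvalues here, since
its off-diagonal product is non-negative); traces are processed by a
compiled kernel so that joint fits over tens of millions of photons remain
tractable.  A generic dense-expm route covers >= 3 states and serves as
the reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .rate_models import GeneratorMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


__all__ = [
    "PhotonTrace",
    "EmissionRates",
    "MLFit",
    "trace_likelihood",
    "fit_two_state",
    "viterbi_path",
    "bootstrap_rates",
    "select_traces",
]


@dataclass
class PhotonTrace:
    """Photon arrival times (s, strictly increasing) and channels (0=D, 1=A)."""

    arrival_times: np.ndarray
    colors: np.ndarray
    trace_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.arrival_times, dtype=float)
        c = np.asarray(self.colors)
        if c.dtype.kind in "US":
            c = np.where(np.char.upper(c.astype(str)) == "A", 1, 0)
        c = c.astype(np.int8)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and colors must be 1-D and equal length")
        if len(t) == 0:
            raise ValueError("a photon trace needs at least one photon")
        if np.any(np.diff(t) < 0):
            raise ValueError("arrival times must be non-decreasing")
        self.arrival_times, self.colors = t, c

    @property
    def n_photons(self) -> int:
        return len(self.arrival_times)

    @property
    def duration(self) -> float:
        return float(self.arrival_times[-1] - self.arrival_times[0])

    @classmethod
    def from_table(cls, path, trace_id=""):
        """Read a two-column delimited text file (time_seconds, channel D|A)."""
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         names=["time", "channel"], header=None)
        return cls(df["time"].to_numpy(float),
                   df["channel"].to_numpy(), trace_id=trace_id)


@dataclass
class EmissionRates:
    """Per-state photon detection rates (Hz): donor and acceptor channels."""

    n_D: np.ndarray  # per state
    n_A: np.ndarray

    def __post_init__(self):
        self.n_D = np.asarray(self.n_D, dtype=float)
        self.n_A = np.asarray(self.n_A, dtype=float)
        if self.n_D.shape != self.n_A.shape:
            raise ValueError("donor/acceptor rate vectors must match")
        if np.any(self.n_D < 0) or np.any(self.n_A < 0):
            raise ValueError("emission rates must be non-negative")


@dataclass
class MLFit:
    """Result of a joint maximum-likelihood fit over a trace ensemble."""

    k_on_obs: float
    k_off_obs: float
    emission_rates: list
    logL: float
    c_H: float | None = None
    bootstrap_sd: dict = field(default_factory=dict)

    @property
    def k_on(self) -> float | None:
        """Bimolecular association coefficient, if c_H was provided."""
        return self.k_on_obs / self.c_H if self.c_H else None


# ---------------------------------------------------------------------------
# likelihood kernels

@njit(cache=True, fastmath=True)
def _loglik_2state_kernel(dt, colors, kon, koff, nDU, nDB, nAU, nAB):
    """Sequential photon-by-photon log-likelihood for the 2-state model.

    The 2x2 propagator exp(M tau) is evaluated from the closed-form
    eigendecomposition (eigenvalues m +/- s are real and negative, so the
    two exponentials cannot overflow); the propagated vector is rescaled
    lazily, accumulating the log of the running norm only when it leaves
    a safe floating-point range.
    """
    a = -kon - nDU - nAU       # M[0,0]
    d = -koff - nDB - nAB      # M[1,1]
    b = koff                   # M[0,1]
    c = kon                    # M[1,0]
    m = 0.5 * (a + d)
    s = np.sqrt(0.25 * (a - d) * (a - d) + b * c)
    am_s = 0.25 * (a - d) / s if s > 0 else 0.0  # (a-m)/(2s); df carries 2 sinh
    b_s = 0.5 * b / s if s > 0 else 0.0
    c_s = 0.5 * c / s if s > 0 else 0.0
    p0 = koff / (kon + koff)
    p1 = kon / (kon + koff)
    logL = 0.0
    for i in range(dt.shape[0]):
        tau = dt[i]
        if tau > 0.0:
            e1 = np.exp((m + s) * tau)
            e2 = np.exp((m - s) * tau)
            sm = 0.5 * (e1 + e2)
            df = e1 - e2
            q0 = (sm + am_s * df) * p0 + b_s * df * p1
            q1 = c_s * df * p0 + (sm - am_s * df) * p1
        else:
            q0, q1 = p0, p1
        if colors[i] == 0:
            q0 *= nDU
            q1 *= nDB
        else:
            q0 *= nAU
            q1 *= nAB
        norm = q0 + q1
        if norm <= 0.0:
            return -np.inf
        if norm < 1e-120 or norm > 1e120:
            logL += np.log(norm)
            q0 /= norm
            q1 /= norm
            norm = 1.0
        p0, p1 = q0, q1
        if i & 63 == 63:
            sc = p0 + p1
            logL += np.log(sc)
            p0 /= sc
            p1 /= sc
    final = p0 + p1
    return logL + np.log(final)


def _loglik_2state(trace: PhotonTrace, kon_obs, koff_obs, rates: EmissionRates):
    dt = np.empty(trace.n_photons)
    dt[0] = 0.0
    dt[1:] = np.diff(trace.arrival_times)
    return float(_loglik_2state_kernel(
        dt, trace.colors, kon_obs, koff_obs,
        rates.n_D[0], rates.n_D[1], rates.n_A[0], rates.n_A[1]))


def trace_likelihood(trace: PhotonTrace, K: GeneratorMatrix,
                     rates: EmissionRates) -> float:
    """Log-likelihood of one trace (reference dense-expm implementation).

    Works for any number of states.  Returns -inf (not an exception) if a
    photon arrives in a channel whose rate is zero in every reachable
    state.
    """
    n = K.n_states
    if rates.n_D.shape[0] != n:
        raise ValueError("emission rates and generator dimension mismatch")
    M = K.K - np.diag(rates.n_D) - np.diag(rates.n_A)
    p = K.p_eq.copy()
    logL = 0.0
    prev_t = trace.arrival_times[0]
    for i in range(trace.n_photons):
        tau = trace.arrival_times[i] - prev_t if i > 0 else 0.0
        prev_t = trace.arrival_times[i]
        if tau > 0:
            p = expm(M * tau) @ p
        p = (rates.n_D if trace.colors[i] == 0 else rates.n_A) * p
        norm = p.sum()
        if norm <= 0:
            return -np.inf
        logL += np.log(norm)
        p = p / norm
    return logL


def ensemble_loglik(traces, kon_obs, koff_obs, emissions) -> float:
    """Total log-likelihood of an ensemble under shared kinetics."""
    return sum(_loglik_2state(tr, kon_obs, koff_obs, em)
               for tr, em in zip(traces, emissions))


# ---------------------------------------------------------------------------
# emission-rate initialization and per-trace refinement

def _init_emission_rates(trace: PhotonTrace, window: float = 0.05):
    """Crude per-trace emission rates from a sliding acceptor-fraction split.

    Windows are classified low/high FRET by thresholding the acceptor
    fraction at its midrange; per-class donor/acceptor rates follow by
    counting.  Only used to seed the optimizer.
    """
    t, c = trace.arrival_times, trace.colors
    edges = np.arange(t[0], t[-1] + window, window)
    idx = np.searchsorted(t, edges)
    nA = np.empty(len(edges) - 1)
    nT = np.empty(len(edges) - 1)
    for w in range(len(edges) - 1):
        seg = c[idx[w]:idx[w + 1]]
        nT[w] = len(seg)
        nA[w] = seg.sum()
    keep = nT > 0
    frac = nA[keep] / nT[keep]
    thr = 0.5 * (frac.min() + frac.max())
    lo = frac <= thr
    dur = window
    def _rates(sel):
        tot_t = max(sel.sum() * dur, dur)
        return (nT[keep][sel] - nA[keep][sel]).sum() / tot_t, nA[keep][sel].sum() / tot_t
    dU, aU = _rates(lo)
    dB, aB = _rates(~lo)
    floor = max(1.0, 0.01 * (len(t) / max(trace.duration, window)))
    return EmissionRates(n_D=np.array([max(dU, floor), max(dB, floor)]),
                         n_A=np.array([max(aU, floor), max(aB, floor)]))


def _refine_emission(trace, kon_obs, koff_obs, em: EmissionRates):
    """Maximize one trace's likelihood over its four emission rates."""
    x0 = np.log(np.array([em.n_D[0], em.n_D[1], em.n_A[0], em.n_A[1]]))

    def nll(x):
        r = np.exp(x)
        return -_loglik_2state(trace, kon_obs, koff_obs,
                               EmissionRates(n_D=r[:2], n_A=r[2:]))

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 0.05, "maxiter": 300})
    r = np.exp(res.x)
    return EmissionRates(n_D=r[:2], n_A=r[2:])


def fit_two_state(traces, c_H=None, refine_emissions: bool = True,
                  n_starts: int = 3, x0=None) -> MLFit:
    """Joint ML fit of shared (k_on_obs, k_off_obs) and per-trace emissions.

    Optimization runs in log-parameter space: per-trace emission rates are
    profiled (initialized from an intensity split, refined at the current
    kinetics), and the two shared rate coefficients are maximized by
    Nelder-Mead with multi-start to guard against local maxima.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    emissions = [_init_emission_rates(tr) for tr in traces]

    if x0 is None:
        starts = [(1.0, 1.0), (10.0, 3.0), (0.3, 0.3)][:max(1, n_starts)]
    else:
        starts = [x0]

    def nll(x):
        return -ensemble_loglik(traces, np.exp(x[0]), np.exp(x[1]), emissions)

    best = None
    for s in starts:
        res = minimize(nll, np.log(np.asarray(s, float)), method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 0.02, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res

    if refine_emissions:
        kon_obs, koff_obs = np.exp(best.x)
        emissions = [_refine_emission(tr, kon_obs, koff_obs, em)
                     for tr, em in zip(traces, emissions)]
        res = minimize(nll, best.x, method="Nelder-Mead",
                       options={"xatol": 2e-3, "fatol": 0.01, "maxiter": 200})
        if res.fun < best.fun:
            best = res

    kon_obs, koff_obs = np.exp(best.x)
    return MLFit(k_on_obs=float(kon_obs), k_off_obs=float(koff_obs),
                 emission_rates=emissions, logL=-float(best.fun), c_H=c_H)


@njit(cache=True, fastmath=True)
def _viterbi_2state_kernel(dt, colors, kon, koff, nDU, nDB, nAU, nAB):
    a = -kon - nDU - nAU
    d = -koff - nDB - nAB
    b = koff
    c = kon
    m = 0.5 * (a + d)
    s = np.sqrt(0.25 * (a - d) * (a - d) + b * c)
    n = dt.shape[0]
    back = np.zeros((n, 2), dtype=np.int8)
    lg0 = np.log(koff / (kon + koff))
    lg1 = np.log(kon / (kon + koff))
    for i in range(n):
        tau = dt[i]
        if tau > 0.0:
            st = s * tau
            ch = np.cosh(st)
            sh_s = np.sinh(st) / s if st > 1e-8 else tau
            e = m * tau
            lt00 = e + np.log(ch + (a - m) * sh_s)
            lt01 = e + np.log(b * sh_s)
            lt10 = e + np.log(c * sh_s)
            lt11 = e + np.log(ch + (d - m) * sh_s)
            c00 = lt00 + lg0
            c01 = lt01 + lg1
            c10 = lt10 + lg0
            c11 = lt11 + lg1
            if c00 >= c01:
                g0, back[i, 0] = c00, 0
            else:
                g0, back[i, 0] = c01, 1
            if c10 >= c11:
                g1, back[i, 1] = c10, 0
            else:
                g1, back[i, 1] = c11, 1
        else:
            g0, g1 = lg0, lg1
            back[i, 0] = 0
            back[i, 1] = 1
        if colors[i] == 0:
            g0 += np.log(nDU) if nDU > 0 else -np.inf
            g1 += np.log(nDB) if nDB > 0 else -np.inf
        else:
            g0 += np.log(nAU) if nAU > 0 else -np.inf
            g1 += np.log(nAB) if nAB > 0 else -np.inf
        # renormalize to avoid drift
        mx = max(g0, g1)
        lg0 = g0 - mx
        lg1 = g1 - mx
    states = np.empty(n, dtype=np.int8)
    states[n - 1] = 0 if lg0 >= lg1 else 1
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return states


def viterbi_path(trace: PhotonTrace, K: GeneratorMatrix,
                 rates: EmissionRates) -> np.ndarray:
    """Most likely per-photon state sequence (max-product over the same
    photon-interval propagators as the likelihood)."""
    if K.n_states != 2:
        raise NotImplementedError("Viterbi path implemented for 2 states")
    dt = np.empty(trace.n_photons)
    dt[0] = 0.0
    dt[1:] = np.diff(trace.arrival_times)
    kon_obs = K.K[1, 0]
    koff_obs = K.K[0, 1]
    return _viterbi_2state_kernel(dt, trace.colors, kon_obs, koff_obs,
                                  rates.n_D[0], rates.n_D[1],
                                  rates.n_A[0], rates.n_A[1])


def count_transitions(states: np.ndarray) -> int:
    return int(np.count_nonzero(np.diff(states.astype(np.int16))))


def select_traces(traces, fit: MLFit, min_transitions: int = 4):
    """Keep traces whose Viterbi path shows more than ``min_transitions``
    transitions; return (kept, report)."""
    kept, report = [], []
    gen = GeneratorMatrix(
        np.array([[-fit.k_on_obs, fit.k_off_obs],
                  [fit.k_on_obs, -fit.k_off_obs]]), ("U", "B"))
    for tr, em in zip(traces, fit.emission_rates):
        n_trans = count_transitions(viterbi_path(tr, gen, em))
        ok = n_trans > min_transitions
        report.append({"trace_id": tr.trace_id, "n_transitions": n_trans,
                       "kept": ok,
                       "reason": "" if ok else
                       f"only {n_trans} transitions (need > {min_transitions})"})
        if ok:
            kept.append(tr)
    return kept, report


def bootstrap_rates(traces, fit: MLFit, n_rounds: int = 20, seed: int = 0):
    """Standard deviations of (k_on_obs, k_off_obs) by resampling whole
    traces with replacement and refitting, warm-started at the fit optimum."""
    traces = list(traces)
    if len(traces) < 5:
        raise ValueError("bootstrap needs at least 5 traces")
    rng = np.random.default_rng(seed)
    kon_samples, koff_samples = [], []
    n_degenerate = 0
    em_by_id = {id(tr): em for tr, em in zip(traces, fit.emission_rates)}
    for _ in range(n_rounds):
        idx = rng.integers(0, len(traces), size=len(traces))
        if len(np.unique(idx)) == 1:
            n_degenerate += 1
        sample = [traces[i] for i in idx]
        ems = [em_by_id[id(tr)] for tr in sample]

        def nll(x):
            return -ensemble_loglik(sample, np.exp(x[0]), np.exp(x[1]), ems)

        res = minimize(nll, np.log([fit.k_on_obs, fit.k_off_obs]),
                       method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 0.02, "maxiter": 120})
        kon, koff = np.exp(res.x)
        kon_samples.append(kon)
        koff_samples.append(koff)
    sd = {"k_on_obs": float(np.std(kon_samples, ddof=1)),
          "k_off_obs": float(np.std(koff_samples, ddof=1)),
          "n_degenerate_resamples": n_degenerate}
    fit.bootstrap_sd = sd
    return sd
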