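"""Ensemble observables: FCS correlation fits, stopped-flow relaxations,
and pulsed-field-gradient NMR diffusion (Stejskal–Tanner) fits.

These are the bulk counterparts of the single-molecule kinetics: FCS
diffusion times report on hydrodynamic radii of the complexes, stopped-
flow relaxations report on the exchange rate k_ex after a concentration
jump, and gradient-strength decays of NMR signals yield translational
diffusion coefficients (and hence R_H against an internal dioxane
reference).
"""

from __future__ import annotations

import numpy as np

from .constants import GAMMA_PFG, RH_DIOXANE_ANGSTROM

__all__ = [
    "fcs_model",
    "fcs_fit",
    "rh_from_fcs",
    "stopped_flow_fit",
    "stejskal_tanner_model",
    "stejskal_tanner_fit",
    "rh_from_diffusion",
]


def fcs_model(tau, N, tau_D, c_T, tau_T, s):
    """Correlation function for translational diffusion through a 3-D
    Gaussian focus plus triplet blinking.

    G(tau) = 1 + (1/N) (1 + tau/tau_D)^-1 (1 + s^2 tau/tau_D)^-1/2
                  (1 + c_T exp(-tau/tau_T)),

    where N is the mean number of labeled molecules in the focus and s the
    lateral-to-axial radius ratio of the confocal volume.
    """
    tau = np.asarray(tau, dtype=float)
    diff = (1.0 + tau / tau_D) ** -1 * (1.0 + s**2 * tau / tau_D) ** -0.5
    trip = 1.0 + c_T * np.exp(-tau / tau_T)
    return 1.0 + diff * trip / N


def fcs_fit(tau, G, s=0.2, fit_s=False, p0=None):
    """Least-squares fit of the diffusion + triplet FCS model.

    ``s`` may be held fixed (the common practice when the focal geometry is
    calibrated) or fitted (``fit_s=True``).  Returns a dict of fitted
    parameters with standard errors.
    """
    import lmfit

    tau = np.asarray(tau, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(tau <= 0) or not np.all(np.isfinite(G)):
        raise ValueError("lag times must be positive and G finite")

    d = p0 or {}
    params = lmfit.Parameters()
    params.add("N", value=d.get("N", 1.0 / max(G.max() - 1.0, 1e-3)), min=1e-6)
    params.add("tau_D", value=d.get("tau_D", tau[np.argmin(np.abs(G - (1 + (G.max()-1)/2)))]),
               min=tau.min() / 10, max=tau.max() * 10)
    params.add("c_T", value=d.get("c_T", 0.1), min=0.0, max=5.0)
    params.add("tau_T", value=d.get("tau_T", tau.min() * 5), min=tau.min() / 100,
               max=tau.max())
    params.add("s", value=s, min=1e-3, max=1.0, vary=fit_s)

    def residual(pars):
        v = pars.valuesdict()
        return fcs_model(tau, v["N"], v["tau_D"], v["c_T"], v["tau_T"], v["s"]) - G

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"FCS fit did not converge: {out.message}")
    res = {k: out.params[k].value for k in ("N", "tau_D", "c_T", "tau_T", "s")}
    res.update({k + "_se": out.params[k].stderr for k in ("N", "tau_D", "c_T", "tau_T")})
    res["lmfit"] = out
    return res


def rh_from_fcs(tau_D, tau_D_ref, R_H_ref):
    """Hydrodynamic radius from a diffusion-time ratio against a reference
    species of known R_H: R_H = tau_D * R_H_ref / tau_D_ref."""
    if tau_D_ref <= 0 or R_H_ref <= 0:
        raise ValueError("reference values must be positive")
    return np.asarray(tau_D, dtype=float) * R_H_ref / tau_D_ref


def stopped_flow_fit(time, signal, dead_time=0.0, normalize=True):
    """Single-exponential relaxation fit of a stopped-flow trace.

    The post-mixing dead-time region ``t < dead_time`` is excluded.  The
    model is signal = amplitude * exp(-k_ex t) + offset; amplitude and
    offset remain free even when the trace is max–min normalized first.
    Returns a dict with k_ex, its standard error, amplitude and offset.
    Degenerate (offset-only) traces are flagged via ``identifiable=False``.
    """
    import lmfit

    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    keep = time >= dead_time
    t, y = time[keep], signal[keep]
    if len(t) < 4:
        raise ValueError("too few points after dead-time exclusion")
    if normalize:
        span = y.max() - y.min()
        if span > 0:
            y = (y - y.min()) / span

    span = y.max() - y.min()
    noise = np.std(np.diff(y)) / np.sqrt(2.0) if len(y) > 8 else 0.0
    if span <= 3.0 * noise or span == 0.0:
        return {"k_ex": np.nan, "k_ex_se": np.nan, "amplitude": 0.0,
                "offset": float(np.mean(y)), "identifiable": False}

    # crude rate guess from the 1/e crossing
    target = y[0] - (y[0] - y[-1]) * (1 - np.exp(-1.0))
    crossing = np.argmin(np.abs(y - target))
    k0 = 1.0 / max(t[crossing] - t[0], (t[1] - t[0]))

    params = lmfit.Parameters()
    params.add("amp", value=y[0] - y[-1])
    params.add("offset", value=y[-1])
    params.add("ln_k", value=np.log(k0))

    def residual(pars):
        v = pars.valuesdict()
        return v["amp"] * np.exp(-np.exp(v["ln_k"]) * (t - t[0])) + v["offset"] - y

    out = lmfit.minimize(residual, params, method="leastsq")
    k = float(np.exp(out.params["ln_k"].value))
    se = out.params["ln_k"].stderr
    return {"k_ex": k, "k_ex_se": k * se if se is not None else np.nan,
            "amplitude": float(out.params["amp"].value),
            "offset": float(out.params["offset"].value),
            "identifiable": True, "lmfit": out}


def stejskal_tanner_model(G_x, D, I_0, delta=3e-3, Delta=250e-3,
                          gamma=GAMMA_PFG):
    """Pulsed-field-gradient echo attenuation
    I = I_0 exp[-D G_x^2 gamma^2 delta^2 (Delta - delta/3)].

    Units: G_x in gauss/cm, D in cm^2/s, delta/Delta in s, gamma in
    rad gauss^-1 s^-1.
    """
    G_x = np.asarray(G_x, dtype=float)
    return I_0 * np.exp(-D * G_x**2 * gamma**2 * delta**2 * (Delta - delta / 3.0))


def stejskal_tanner_fit(G_x, I, delta=3e-3, Delta=250e-3, gamma=GAMMA_PFG,
                        method="nonlinear"):
    """Fit a gradient-strength decay for the diffusion coefficient D.

    ``method='loglinear'`` performs a weighted linear regression of
    ln I against G_x^2; ``'nonlinear'`` (default) a least-squares fit of the
    exponential itself.  Returns (D, D_se, I_0).  A negative fitted D is an
    error (non-physical decay).
    """
    G_x = np.asarray(G_x, dtype=float)
    I = np.asarray(I, dtype=float)
    b = G_x**2 * gamma**2 * delta**2 * (Delta - delta / 3.0)

    if method == "loglinear":
        if np.any(I <= 0):
            raise ValueError("log-linear fit requires positive intensities")
        coeffs, cov = np.polyfit(b, np.log(I), 1, cov=True)
        D = -coeffs[0]
        D_se = float(np.sqrt(cov[0, 0]))
        I_0 = float(np.exp(coeffs[1]))
    else:
        import lmfit

        params = lmfit.Parameters()
        slope0 = max((np.log(max(I[0], 1e-300)) - np.log(max(I[-1], 1e-300)))
                     / max(b[-1] - b[0], 1e-300), 1e-12)
        params.add("D", value=slope0)
        params.add("I_0", value=float(I.max()))

        def residual(pars):
            v = pars.valuesdict()
            return v["I_0"] * np.exp(-v["D"] * b) - I

        out = lmfit.minimize(residual, params, method="leastsq")
        D = float(out.params["D"].value)
        D_se = out.params["D"].stderr
        D_se = float(D_se) if D_se is not None else np.nan
        I_0 = float(out.params["I_0"].value)
    if D < 0:
        raise ValueError(f"fitted diffusion coefficient is negative: {D}")
    return D, D_se, I_0


def rh_from_diffusion(D_protein, D_dioxane,
                      R_H_ref_angstrom=RH_DIOXANE_ANGSTROM):
    """Hydrodynamic radius (Å) from the diffusion-coefficient ratio against
    the internal 1,4-dioxane reference: R_H = D_dioxane R_H_ref / D_protein."""
    if D_protein <= 0 or D_dioxane <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return D_dioxane * R_H_ref_angstrom / D_protein
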