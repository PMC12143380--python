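"""Kinetic reduction of population time series.

Inter-group energy transfer in these models is rate-like: the rise of an
acceptor group's population is summarized by a saturating exponential
P(t) = P_inf (1 - e^{-t/tau}) or, for multi-step funnels, by a
biexponential P(t) = P_inf - A1 e^{-t/tau1} - A2 e^{-t/tau2}.  The fitted
time constants (in ps) feed rate-constant ratios used to compare the
classical and polaron-quantized treatments of the high-frequency modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import PopulationTimeSeries

__all__ = ["KineticsFit", "FitError", "group_population", "fit_mono", "fit_biexp",
           "rate_ratio"]

FS_PER_PS = 1000.0


class FitError(RuntimeError):
    """Nonlinear fit failed or the input is kinetically degenerate."""


@dataclass(frozen=True)
class KineticsFit:
    """Result of a mono- or biexponential rise fit (times in ps)."""

    model: str
    p_inf: float
    tau: float | None = None
    tau1: float | None = None
    tau2: float | None = None
    amp1: float | None = None
    amp2: float | None = None
    residual_rms: float = 0.0
    covariance: np.ndarray | None = None
    degenerate: bool = False

    @property
    def rates(self):
        """Rate constants 1/tau (1/ps), slow-to-fast ordering for biexp."""
        if self.model == "mono":
            return (1.0 / self.tau,)
        return (1.0 / self.tau1, 1.0 / self.tau2)

    def to_json_dict(self):
        out = {"model": self.model, "p_inf": self.p_inf,
               "residual_rms": self.residual_rms, "degenerate": self.degenerate}
        for key in ("tau", "tau1", "tau2", "amp1", "amp2"):
            val = getattr(self, key)
            if val is not None:
                out[key + "_ps"] = val
        return out


def group_population(ts: PopulationTimeSeries, group):
    """Summed population of a site group and its SEM (from batch means)."""
    series, sem = ts.group_series(group)
    return ts.times, series, sem


def _mono(t, p_inf, tau):
    return p_inf * (1.0 - np.exp(-t / tau))


def fit_mono(times_fs, series, sem=None, fixed_p_inf=None) -> KineticsFit:
    """Fit P(t) = P_inf (1 - e^{-t/tau}) to a rising group population.

    Deterministic initial guess: P_inf from the final value, tau from the
    first crossing of P_inf (1 - 1/e).  Times in fs on input, tau in ps on
    output.  Uniform weights by default.  With ``fixed_p_inf`` the plateau
    is pinned (e.g. to a measured long-time average) and only tau is
    optimized — useful when the series has not fully plateaued, where the
    two-parameter fit is ill-conditioned.
    """
    t = np.asarray(times_fs, dtype=float) / FS_PER_PS
    y = np.asarray(series, dtype=float)
    p_inf0 = float(y[-1]) if fixed_p_inf is None else float(fixed_p_inf)
    if p_inf0 <= 0 or np.ptp(y) < 1e-12:
        raise FitError("series shows no rise; mono-exponential model is degenerate")
    target = p_inf0 * (1.0 - 1.0 / math.e)
    above = np.nonzero(y >= target)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(
        float(t[-1]) / 3.0, 1e-3)
    sigma = None
    if sem is not None and np.all(np.asarray(sem)[1:] > 0):
        sigma = np.asarray(sem, dtype=float)
        sigma[sigma == 0] = sigma[sigma > 0].min()
    try:
        if fixed_p_inf is not None:
            popt1, pcov1 = curve_fit(
                lambda tt, tau: _mono(tt, p_inf0, tau), t, y, p0=[tau0],
                bounds=([1e-6], [np.inf]), sigma=sigma, maxfev=10000,
            )
            popt = np.array([p_inf0, popt1[0]])
            pcov = np.zeros((2, 2))
            pcov[1, 1] = pcov1[0, 0]
        else:
            popt, pcov = curve_fit(
                _mono, t, y, p0=[min(max(p_inf0, 1e-3), 1.0), tau0],
                bounds=([0.0, 1e-6], [1.0, np.inf]), sigma=sigma, maxfev=10000,
            )
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    resid = y - _mono(t, *popt)
    return KineticsFit(
        model="mono", p_inf=float(popt[0]), tau=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))), covariance=pcov,
    )


def _biexp(t, p_inf, a1, tau1, a2, tau2):
    return p_inf - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)


def fit_biexp(times_fs, series, sem=None, degeneracy_ratio: float = 1.05) -> KineticsFit:
    """Fit P(t) = P_inf - A1 e^{-t/tau1} - A2 e^{-t/tau2}, tau1 <= tau2.

    Multi-start over five tau-ratio seeds around the mono-exponential
    solution; the best-residual fit is kept.  Amplitudes are constrained
    non-negative; tau1 ~ tau2 is flagged as degenerate.
    """
    t = np.asarray(times_fs, dtype=float) / FS_PER_PS
    y = np.asarray(series, dtype=float)
    mono = fit_mono(times_fs, series, sem)
    sigma = None
    if sem is not None and np.all(np.asarray(sem)[1:] > 0):
        sigma = np.asarray(sem, dtype=float)
        sigma[sigma == 0] = sigma[sigma > 0].min()
    best = None
    for ratio in (0.1, 0.3, 1.0, 3.0, 10.0):
        p0 = [mono.p_inf, 0.5 * mono.p_inf, mono.tau * min(1.0, ratio),
              0.5 * mono.p_inf, mono.tau * max(1.0, ratio)]
        try:
            popt, pcov = curve_fit(
                _biexp, t, y, p0=p0,
                bounds=([0.0, 0.0, 1e-6, 0.0, 1e-6], [1.0, 1.0, np.inf, 1.0, np.inf]),
                sigma=sigma, maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((y - _biexp(t, *popt)) ** 2)))
        if best is None or resid < best[1]:
            best = (popt, resid, pcov)
    if best is None:
        raise FitError("biexponential fit did not converge from any start")
    popt, resid, pcov = best
    p_inf, a1, tau1, a2, tau2 = popt
    if tau1 > tau2:
        a1, a2 = a2, a1
        tau1, tau2 = tau2, tau1
    degenerate = tau2 / max(tau1, 1e-30) < degeneracy_ratio
    return KineticsFit(
        model="biexp", p_inf=float(p_inf), tau1=float(tau1), tau2=float(tau2),
        amp1=float(a1), amp2=float(a2), residual_rms=resid, covariance=pcov,
        degenerate=degenerate,
    )


def rate_ratio(fit_a: KineticsFit, fit_b: KineticsFit):
    """Component-wise ratio of rate constants k_a / k_b = tau_b / tau_a.

    Returns a list of (ratio, stderr) pairs, with errors propagated from
    the fit covariances.
    """
    if fit_a.model != fit_b.model:
        raise ValueError("rate_ratio requires fits of the same model type")

    def tau_err(fit, which):
        if fit.covariance is None:
            return 0.0
        idx = {"mono": {"tau": 1}, "biexp": {"tau1": 2, "tau2": 4}}[fit.model][which]
        return math.sqrt(max(fit.covariance[idx, idx], 0.0))

    names = ("tau",) if fit_a.model == "mono" else ("tau1", "tau2")
    out = []
    for name in names:
        ta = getattr(fit_a, name)
        tb = getattr(fit_b, name)
        ratio = tb / ta
        ea, eb = tau_err(fit_a, name), tau_err(fit_b, name)
        err = abs(ratio) * math.sqrt((ea / ta) ** 2 + (eb / tb) ** 2)
        out.append((ratio, err))
    return out
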