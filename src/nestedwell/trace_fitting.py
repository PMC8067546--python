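"""Reduction of stepwise titration traces to per-step amplitudes and rates.

Each injection step is fitted with a single-exponential approach to an
extrapolated asymptote,

    σ(t) = σ_prev + (Σ(c) − σ_prev)·(1 − e^(−Γ(c)·(t − t0))),

yielding the absolute asymptote Σ(c), the growth rate Γ(c) and the initial
slope σ'(c) = Γ·(Σ − σ_prev).  For a single-well probe Γ(c) = kon·c + koff
exactly, so a linear fit of Γ against c returns both rates.  For a
nested-well probe the step kinetics is nearly exponential in the
fast-inner-exchange regime and the fitted Γ tracks the slow relaxation time
(1/Γ ≥ τ1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from ._errors import DataError, FitError, NoBindingSignalError
from .synthetic import BindingTrace

__all__ = ["StepFitResult", "GammaLineFit", "fit_step", "fit_all_steps",
           "gamma_line_fit", "initial_slope_fd"]

_TIGHT = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14)


@dataclass
class StepFitResult:
    """Single-injection-step exponential fit.

    ``Sigma`` is the *absolute* extrapolated asymptote at this step's
    concentration (the fitted increment is Sigma − sigma_prev), so Σ(c)
    values feed the Langmuir isotherm directly.
    """

    c: float                  # step concentration, nM
    Sigma: float              # extrapolated asymptote, instrument units
    Gamma: float              # growth rate, s⁻¹
    slope0: float             # initial slope Γ·(Σ − σ_prev), units/s
    sigma_prev: float         # plateau level before the step
    residual_rms: float
    se_Sigma: float = np.nan
    se_Gamma: float = np.nan
    c_prev: float = 0.0       # concentration before the step (for Δc regressors)
    usable: bool = True
    message: str = ""

    def plateau_at(self, t_elapsed: float) -> float:
        """Model value after ``t_elapsed`` seconds into the step."""
        if not np.isfinite(self.Gamma):
            return self.Sigma
        return self.sigma_prev + (self.Sigma - self.sigma_prev) * (
            1.0 - np.exp(-self.Gamma * t_elapsed)
        )


@dataclass
class GammaLineFit:
    """Linear fit Γ(c) = kon·c + koff across the titration ladder."""

    kon: float
    koff: float
    se_kon: float = np.nan
    se_koff: float = np.nan
    no_binding_signal: bool = False


def _exp_step(t, Sigma, Gamma, sigma_prev, t0):
    return sigma_prev + (Sigma - sigma_prev) * (1.0 - np.exp(-Gamma * (t - t0)))


def _noise_estimate(sigma: np.ndarray) -> float:
    # high-frequency residual: std of first differences of white noise is sd·√2
    if sigma.size < 3:
        return 0.0
    return float(np.std(np.diff(sigma)) / np.sqrt(2.0))


def fit_step(
    times: np.ndarray,
    sigma: np.ndarray,
    c: float,
    t0: float,
    sigma_prev: float,
    discard: float = 10.0,
    c_prev: float = 0.0,
) -> StepFitResult:
    """Least-squares exponential fit of one injection step.

    Samples with t < t0 + discard are dropped (mixing transient).  If the
    step rise is below three times the noise estimate the step is flagged
    unusable (Σ = σ_prev, Γ = NaN) rather than fitted.
    """
    times = np.asarray(times, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    keep = times >= t0 + discard
    t, y = times[keep], sigma[keep]
    if t.size < 10:
        raise DataError(f"only {t.size} samples after the discard window; need >= 10")

    noise = _noise_estimate(y)
    tail = max(1, t.size // 10)
    sigma0 = float(np.mean(y[-tail:]))  # last-decile mean
    rise = sigma0 - sigma_prev
    if abs(rise) < 3.0 * noise:
        return StepFitResult(
            c=c, Sigma=sigma_prev, Gamma=np.nan, slope0=0.0, sigma_prev=sigma_prev,
            residual_rms=float(np.sqrt(np.mean((y - sigma_prev) ** 2))),
            c_prev=c_prev, usable=False, message="step rise below 3x noise estimate",
        )

    # Γ init from the time to reach half of the step's total rise
    half = sigma_prev + 0.5 * rise
    above = np.nonzero(y >= half if rise > 0 else y <= half)[0]
    if above.size and t[above[0]] > t0:
        gamma0 = np.log(2.0) / (t[above[0]] - t0)
    else:
        gamma0 = 1.0 / (t[-1] - t0)

    model = Model(_exp_step, independent_vars=["t"])
    params = model.make_params(Sigma=sigma0, Gamma=gamma0)
    params["Gamma"].set(min=1e-12)
    params.add("sigma_prev", value=sigma_prev, vary=False)
    params.add("t0", value=t0, vary=False)
    try:
        res = model.fit(y, params, t=t, fit_kws=_TIGHT)
    except Exception as exc:  # pragma: no cover - lmfit raises rarely here
        raise FitError(f"step fit failed at c={c} nM: {exc}") from exc
    if not res.success:
        raise FitError(f"step fit did not converge at c={c} nM: {res.message}",
                       diagnostics={"lmfit_report": res.fit_report()})
    Sigma = float(res.params["Sigma"].value)
    Gamma = float(res.params["Gamma"].value)
    return StepFitResult(
        c=c, Sigma=Sigma, Gamma=Gamma,
        slope0=Gamma * (Sigma - sigma_prev),
        sigma_prev=sigma_prev,
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        se_Sigma=float(res.params["Sigma"].stderr or np.nan),
        se_Gamma=float(res.params["Gamma"].stderr or np.nan),
        c_prev=c_prev,
    )


def fit_all_steps(trace: BindingTrace, discard: float = 10.0) -> list[StepFitResult]:
    """Chain :func:`fit_step` over every injection of a titration trace.

    The baseline of each step is the previous step's fitted model evaluated
    at the next injection time, so incomplete saturation propagates
    correctly instead of biasing the next increment.
    """
    bounds = trace.schedule.step_bounds()
    results: list[StepFitResult] = []
    sigma_prev = 0.0
    c_prev = 0.0
    for i, c in enumerate(trace.schedule.concentrations):
        t0, t1 = bounds[i], bounds[i + 1]
        mask = (trace.times >= t0) & (trace.times < t1)
        res = fit_step(trace.times[mask], trace.sigma[mask], c=float(c), t0=float(t0),
                       sigma_prev=sigma_prev, discard=discard, c_prev=c_prev)
        results.append(res)
        sigma_prev = res.plateau_at(t1 - t0) if res.usable else sigma_prev
        c_prev = float(c)
    return results


def gamma_line_fit(results: list[StepFitResult]) -> GammaLineFit:
    """Weighted linear regression of Γ on c: slope kon, intercept koff.

    Weights are 1/se² where per-step standard errors are available.  A
    nonpositive slope is returned as kon = 0 with the no-binding-signal
    flag set.
    """
    usable = [r for r in results if r.usable and np.isfinite(r.Gamma)]
    cs = np.array([r.c for r in usable])
    if np.unique(cs).size < 2:
        raise DataError("gamma_line_fit needs at least two distinct concentrations")
    gs = np.array([r.Gamma for r in usable])
    ses = np.array([r.se_Gamma for r in usable])
    w = np.where(np.isfinite(ses) & (ses > 0), 1.0 / ses**2, np.nan)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(gs)
    X = np.column_stack([cs, np.ones_like(cs)])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ gs)
    resid = gs - X @ beta
    dof = max(len(gs) - 2, 1)
    s2 = float((w * resid**2).sum() / dof)
    se = np.sqrt(np.diag(cov) * s2)
    kon, koff = float(beta[0]), float(beta[1])
    # a slope indistinguishable from zero means Γ does not grow with c
    if kon <= 0 or kon < 2.0 * se[0]:
        return GammaLineFit(kon=0.0, koff=koff, se_kon=float(se[0]),
                            se_koff=float(se[1]), no_binding_signal=True)
    return GammaLineFit(kon=kon, koff=koff, se_kon=float(se[0]), se_koff=float(se[1]))


def initial_slope_fd(times: np.ndarray, sigma: np.ndarray, t0: float,
                     window: float = 60.0) -> float:
    """Finite-difference initial slope over ``window`` seconds after ``t0``.

    Diagnostic alternative to the model-based slope0; noisier but model-free.
    """
    times = np.asarray(times, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mask = (times >= t0) & (times <= t0 + window)
    if mask.sum() < 2:
        raise DataError("finite-difference slope needs at least two samples in the window")
    t, y = times[mask], sigma[mask]
    return float(np.polyfit(t - t0, y, 1)[0])
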