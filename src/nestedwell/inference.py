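"""Condition-level estimation: isotherms, rates, selectivity, thermodynamics.

The analysis chain for one experimental condition is

1. per-step exponential reduction (``trace_fitting``) of the paired
   specific/nonspecific traces;
2. global Langmuir fit of both Σ(c) sets, Σ(c) = Σ∞·c/(c+Kd), with a single
   shared saturation density Σ∞ and one Kd per probe class;
3. a pooled association rate kon from the initial slopes,
   σ'(c)/Σ∞ against a concentration regressor, with koff = Kd·kon per class;
4. the selectivity coefficient K2 = Kd_sp/(K1 − Kd_sp) where K1 is the
   nonspecific Kd (inverting Kd = K1·K2/(1+K2));
5. optionally a simultaneous nested-well kinetic fit of both raw traces;
6. across temperatures, the van't Hoff decomposition
   ln K2 = ΔH/(R·T) − ΔS/R.

Sign convention: K2 is a dissociation-like ratio (nonspecific over
specific), so ΔG = R·T·ln K2 is *negative* when the specific state is
favoured — the opposite of the common association convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from ._errors import (
    DataError,
    FitError,
    InvalidParameterError,
    NoBindingSignalError,
    NonphysicalSelectivityError,
)
from .nw_model import RateSet, k2_from_kd, piecewise_occupancy, relaxation_spectrum
from .synthetic import R_KCAL, BindingTrace
from .trace_fitting import StepFitResult, fit_all_steps, gamma_line_fit

__all__ = [
    "IsothermFit",
    "RateEstimate",
    "ThermoFit",
    "NWJointFit",
    "langmuir_pair_fit",
    "kon_from_slopes",
    "extract_k2",
    "nw_joint_fit",
    "vant_hoff_fit",
    "delta_g",
    "fraction_specific",
    "delta_delta_g",
    "analyze_pair",
]

_TIGHT = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14)


@dataclass
class IsothermFit:
    """Paired Langmuir fit with a shared saturation density.

    Keeps the per-step (c, Σ) data so downstream uncertainty can be
    re-estimated by residual bootstrap.
    """

    Sigma_inf: float
    Kd_specific: float
    Kd_nonspecific: float
    se_Sigma_inf: float = np.nan
    se_Kd_specific: float = np.nan
    se_Kd_nonspecific: float = np.nan
    cov: np.ndarray | None = None  # covariance of (Sigma_inf, Kd_sp, Kd_ns)
    temperature: float = 303.15
    ionic_strength: float = 150.0
    warning: str = ""
    c_specific: np.ndarray = field(default_factory=lambda: np.empty(0))
    Sigma_specific: np.ndarray = field(default_factory=lambda: np.empty(0))
    c_nonspecific: np.ndarray = field(default_factory=lambda: np.empty(0))
    Sigma_nonspecific: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def ordering_expected(self) -> bool:
        """True when Kd_specific < Kd_nonspecific (the physical ordering)."""
        return self.Kd_specific < self.Kd_nonspecific


@dataclass
class RateEstimate:
    """Pooled association rate and per-class dissociation rates."""

    kon: float                 # s⁻¹·nM⁻¹, common to both probe classes
    koff_specific: float       # s⁻¹, = Kd_specific · kon
    koff_nonspecific: float    # s⁻¹, = Kd_nonspecific · kon
    se_kon: float = np.nan
    se_koff_specific: float = np.nan
    se_koff_nonspecific: float = np.nan
    regressor: str = "c"


@dataclass
class ThermoFit:
    """Van't Hoff decomposition of K2(T).

    ``dH`` in kcal/mol, ``dS`` in cal/(mol·K); ``cov`` is the covariance of
    (dH [kcal/mol], dS [cal/(mol·K)]).
    """

    dH: float
    dS: float
    se_dH: float = np.nan
    se_dS: float = np.nan
    cov: np.ndarray | None = None
    R: float = R_KCAL

    def k2_model(self, T: float | np.ndarray) -> float | np.ndarray:
        return np.exp(self.dH / (self.R * np.asarray(T, dtype=float))
                      - (self.dS / 1000.0) / self.R)

    def dG_at(self, T: float) -> float:
        """ΔG(T) = ΔH − T·ΔS = R·T·ln K2_model(T), in kcal/mol."""
        return self.dH - T * self.dS / 1000.0


@dataclass
class NWJointFit:
    """Simultaneous nested-well fit of a specific/nonspecific trace pair."""

    rates: RateSet
    Sigma_inf: float
    se_log: dict = field(default_factory=dict)  # stderr of the log-parameters
    fast_exchange: bool = False   # τL within 5% of τL∞ at every step
    kon2_lower_bound: bool = False  # kon2 not identifiable; value is a lower bound
    single_well_collapse: bool = False  # fitted K2 so large the inner well vanishes
    residual_rms: float = np.nan

    @property
    def K2(self) -> float:
        return self.rates.K2


def _langmuir(c, Sigma_inf, Kd):
    return Sigma_inf * c / (c + Kd)


def langmuir_pair_fit(
    steps_specific: list[StepFitResult],
    steps_nonspecific: list[StepFitResult],
    temperature: float = 303.15,
    ionic_strength: float = 150.0,
) -> IsothermFit:
    """Simultaneous Langmuir fit of both Σ(c) sets with one shared Σ∞.

    The shared asymptote encodes the assumption that the probe accommodates
    the same maximal protein load with or without the specific site.
    """
    c_sp, S_sp = _usable_arrays(steps_specific)
    c_ns, S_ns = _usable_arrays(steps_nonspecific)
    if min(np.unique(c_sp).size, np.unique(c_ns).size) < 3:
        raise DataError("langmuir_pair_fit needs at least 3 concentrations per probe class")

    params = Parameters()
    smax = float(max(S_sp.max(), S_ns.max()))
    params.add("Sigma_inf", value=1.5 * smax, min=smax * 0.5)
    params.add("Kd_sp", value=float(np.median(c_sp)), min=1e-9)
    params.add("Kd_ns", value=float(4.0 * np.median(c_ns)), min=1e-9)

    def resid(p):
        return np.concatenate([
            _langmuir(c_sp, p["Sigma_inf"], p["Kd_sp"]) - S_sp,
            _langmuir(c_ns, p["Sigma_inf"], p["Kd_ns"]) - S_ns,
        ])

    out = minimize(resid, params, **_TIGHT)
    if not out.success:
        raise FitError(f"Langmuir pair fit did not converge: {out.message}")
    p = out.params
    ses = [p[k].stderr or np.nan for k in ("Sigma_inf", "Kd_sp", "Kd_ns")]
    warning = ""
    kd_min = min(p["Kd_sp"].value, p["Kd_ns"].value)
    if c_sp.max() < kd_min:
        warning = "all data below Kd: isotherm nearly linear, Sigma_inf weakly constrained"
    elif c_sp.min() > 10 * max(p["Kd_sp"].value, p["Kd_ns"].value):
        warning = "all data saturated: Kd weakly constrained"
    return IsothermFit(
        Sigma_inf=float(p["Sigma_inf"].value),
        Kd_specific=float(p["Kd_sp"].value),
        Kd_nonspecific=float(p["Kd_ns"].value),
        se_Sigma_inf=float(ses[0]), se_Kd_specific=float(ses[1]),
        se_Kd_nonspecific=float(ses[2]),
        cov=np.asarray(out.covar) if out.covar is not None else None,
        temperature=temperature, ionic_strength=ionic_strength, warning=warning,
        c_specific=c_sp, Sigma_specific=S_sp,
        c_nonspecific=c_ns, Sigma_nonspecific=S_ns,
    )


def _usable_arrays(steps: list[StepFitResult]) -> tuple[np.ndarray, np.ndarray]:
    usable = [s for s in steps if s.usable]
    if not usable:
        raise DataError("no usable steps")
    return (np.array([s.c for s in usable]), np.array([s.Sigma for s in usable]))


def kon_from_slopes(
    steps_specific: list[StepFitResult],
    steps_nonspecific: list[StepFitResult],
    isotherm: IsothermFit,
    regressor: str = "c",
) -> RateEstimate:
    """Pooled kon from initial slopes; koff per class as Kd·kon.

    σ'(c)/Σ∞ is regressed through the origin against a concentration
    regressor, pooling specific and nonspecific points (single common kon):

    - ``"c"`` — the step concentration itself.  Exact only for binding that
      starts from empty probes (the first step); later steps are biased low
      by the factor Kd/(c_prev + Kd).
    - ``"delta_c"`` — the concentration increment; removes part of the bias.
    - ``"corrected"`` — Kd·(c − c_eq)/(c_eq + Kd) with the class Kd from the
      isotherm fit and c_eq the concentration equivalent of the actual
      baseline, c_eq = Kd·σ_prev/(Σ∞ − σ_prev).  This is the exact
      closed-form per-step slope, unbiased across the full ladder even when
      a step is injected before the previous one has saturated.
    """
    if regressor not in ("c", "delta_c", "corrected"):
        raise InvalidParameterError(f"unknown regressor {regressor!r}")
    xs, ys = [], []
    for steps, kd in ((steps_specific, isotherm.Kd_specific),
                      (steps_nonspecific, isotherm.Kd_nonspecific)):
        for s in steps:
            if not s.usable:
                continue
            if regressor == "c":
                x = s.c
            elif regressor == "delta_c":
                x = s.c - s.c_prev
            else:
                if s.sigma_prev >= isotherm.Sigma_inf:
                    continue  # baseline above saturation: no information
                c_eq = kd * s.sigma_prev / (isotherm.Sigma_inf - s.sigma_prev)
                x = kd * (s.c - c_eq) / (c_eq + kd)
            xs.append(x)
            ys.append(s.slope0 / isotherm.Sigma_inf)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 2 or np.all(x == 0):
        raise DataError("kon_from_slopes needs at least two nonzero regressor points")
    sxx = float(np.sum(x * x))
    kon = float(np.sum(x * y) / sxx)
    resid = y - kon * x
    dof = max(x.size - 1, 1)
    se_kon = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    if kon <= 0:
        raise NoBindingSignalError(f"fitted kon = {kon:.3g} <= 0: no binding signal")
    koff_sp = isotherm.Kd_specific * kon
    koff_ns = isotherm.Kd_nonspecific * kon
    se_sp = np.sqrt((isotherm.Kd_specific * se_kon) ** 2
                    + (kon * _nan0(isotherm.se_Kd_specific)) ** 2)
    se_ns = np.sqrt((isotherm.Kd_nonspecific * se_kon) ** 2
                    + (kon * _nan0(isotherm.se_Kd_nonspecific)) ** 2)
    return RateEstimate(kon=kon, koff_specific=koff_sp, koff_nonspecific=koff_ns,
                        se_kon=se_kon, se_koff_specific=float(se_sp),
                        se_koff_nonspecific=float(se_ns), regressor=regressor)


def _nan0(x: float) -> float:
    return 0.0 if not np.isfinite(x) else x


def extract_k2(
    isotherm: IsothermFit,
    bootstrap: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Selectivity coefficient K2 = Kd_sp/(K1 − Kd_sp) with its uncertainty.

    By default the standard error comes from first-order (delta-method)
    propagation of the two Kd uncertainties including their covariance; with
    ``bootstrap=True`` it is the standard deviation of K2 over seeded
    residual-bootstrap refits of the paired isotherm — more honest near
    Kd → K1 where the first-order error diverges.
    """
    kd, k1 = isotherm.Kd_specific, isotherm.Kd_nonspecific
    if kd >= k1:
        raise NonphysicalSelectivityError(
            f"Kd_specific = {kd:.3g} nM >= Kd_nonspecific = {k1:.3g} nM"
        )
    k2 = k2_from_kd(kd, k1)
    if bootstrap:
        return k2, _bootstrap_k2_se(isotherm, n_boot, seed)
    d = k1 - kd
    g = np.array([k1 / d**2, -kd / d**2])  # (∂K2/∂Kd_sp, ∂K2/∂Kd_ns)
    if isotherm.cov is not None and isotherm.cov.shape == (3, 3):
        sub = isotherm.cov[1:, 1:]
        var = float(g @ sub @ g)
    else:
        var = float((g[0] * _nan0(isotherm.se_Kd_specific)) ** 2
                    + (g[1] * _nan0(isotherm.se_Kd_nonspecific)) ** 2)
    return k2, float(np.sqrt(max(var, 0.0)))


def _bootstrap_k2_se(isotherm: IsothermFit, n_boot: int, seed: int) -> float:
    from .trace_fitting import StepFitResult as SFR

    rng = np.random.default_rng([int(seed), 0x6B32])
    model_sp = _langmuir(isotherm.c_specific, isotherm.Sigma_inf, isotherm.Kd_specific)
    model_ns = _langmuir(isotherm.c_nonspecific, isotherm.Sigma_inf, isotherm.Kd_nonspecific)
    resid = np.concatenate([isotherm.Sigma_specific - model_sp,
                            isotherm.Sigma_nonspecific - model_ns])
    n_sp = isotherm.c_specific.size
    vals = []
    for _ in range(n_boot):
        r = rng.choice(resid, size=resid.size, replace=True)
        sp = [SFR(c=c, Sigma=m + e, Gamma=np.nan, slope0=0.0, sigma_prev=0.0,
                  residual_rms=0.0)
              for c, m, e in zip(isotherm.c_specific, model_sp, r[:n_sp])]
        ns = [SFR(c=c, Sigma=m + e, Gamma=np.nan, slope0=0.0, sigma_prev=0.0,
                  residual_rms=0.0)
              for c, m, e in zip(isotherm.c_nonspecific, model_ns, r[n_sp:])]
        try:
            fit = langmuir_pair_fit(sp, ns)
            if fit.Kd_specific < fit.Kd_nonspecific:
                vals.append(k2_from_kd(fit.Kd_specific, fit.Kd_nonspecific))
        except (FitError, DataError):
            continue
    if len(vals) < max(10, n_boot // 10):
        raise FitError("bootstrap failed on too many resamples")
    return float(np.std(vals, ddof=1))


def nw_joint_fit(
    trace_specific: BindingTrace,
    trace_nonspecific: BindingTrace,
    discard: float = 10.0,
) -> NWJointFit:
    """Simultaneous nested-well least squares of a paired trace set.

    The nonspecific trace constrains (kon1, koff1, Σ∞); the specific trace
    additionally constrains (kon2, koff2).  Parameters are fitted as
    (log kon1, log K1, log kon2, log K2, Σ∞) to enforce positivity, starting
    from the stepwise/Langmuir estimates.  The result reports whether the
    kinetics sit in the fast-inner-exchange regime (τL within 5% of τL∞ at
    every step) and whether kon2 is identifiable at all (in the fast regime
    only K2 is; kon2 is then a lower bound).
    """
    sched = trace_specific.schedule
    if sched.step_times != trace_nonspecific.schedule.step_times or (
            sched.concentrations != trace_nonspecific.schedule.concentrations):
        raise DataError("paired traces must share the injection schedule")

    # initialization from the stepwise / Langmuir route
    steps_sp = fit_all_steps(trace_specific, discard=discard)
    steps_ns = fit_all_steps(trace_nonspecific, discard=discard)
    iso = langmuir_pair_fit(steps_sp, steps_ns,
                            temperature=sched.temperature,
                            ionic_strength=sched.ionic_strength)
    gline = gamma_line_fit(steps_ns)
    kon1_0 = gline.kon if not gline.no_binding_signal else 1e-5
    k1_0 = iso.Kd_nonspecific
    try:
        k2_0 = k2_from_kd(iso.Kd_specific, iso.Kd_nonspecific)
    except NonphysicalSelectivityError:
        k2_0 = 1.0
    kon2_0 = 10.0 * kon1_0 * k1_0  # start near fast exchange

    params = Parameters()
    params.add("log_kon1", value=np.log(kon1_0))
    params.add("log_K1", value=np.log(k1_0))
    params.add("log_kon2", value=np.log(kon2_0), min=np.log(kon2_0) - 25, max=np.log(1e3))
    params.add("log_K2", value=np.log(k2_0))
    params.add("Sigma_inf", value=iso.Sigma_inf, min=1e-12)

    st, cc = sched.step_times, sched.concentrations

    def model(p, trace, single_well):
        kon1 = np.exp(p["log_kon1"].value)
        koff1 = kon1 * np.exp(p["log_K1"].value)
        if single_well:
            rates = RateSet(kon1=kon1, koff1=koff1)
        else:
            kon2 = np.exp(p["log_kon2"].value)
            rates = RateSet(kon1=kon1, koff1=koff1, kon2=kon2,
                            koff2=kon2 * np.exp(p["log_K2"].value))
        theta = piecewise_occupancy(st, cc, rates, trace.times)
        return p["Sigma_inf"].value * theta.sum(axis=1)

    def resid(p):
        return np.concatenate([
            model(p, trace_specific, False) - trace_specific.sigma,
            model(p, trace_nonspecific, True) - trace_nonspecific.sigma,
        ])

    out = minimize(resid, params, **_TIGHT)
    if not out.success:
        raise FitError(f"joint nested-well fit did not converge: {out.message}")
    p = out.params
    kon1 = float(np.exp(p["log_kon1"].value))
    koff1 = float(kon1 * np.exp(p["log_K1"].value))
    kon2 = float(np.exp(p["log_kon2"].value))
    k2 = float(np.exp(p["log_K2"].value))
    rates = RateSet(kon1=kon1, koff1=koff1, kon2=kon2, koff2=kon2 * k2)

    se_log = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
              for k in ("log_kon1", "log_K1", "log_kon2", "log_K2")}
    kon2_lb = (not np.isfinite(se_log["log_kon2"])) or se_log["log_kon2"] > 1.0
    collapse = k2 > 50.0

    fast = True
    for c in cc:
        spec = relaxation_spectrum(float(c), rates)
        if abs(spec.tauL - spec.tauL_inf) > 0.05 * spec.tauL_inf:
            fast = False
            break
    return NWJointFit(
        rates=rates, Sigma_inf=float(p["Sigma_inf"].value), se_log=se_log,
        fast_exchange=fast, kon2_lower_bound=kon2_lb,
        single_well_collapse=collapse,
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
    )


def vant_hoff_fit(series: list[tuple]) -> ThermoFit:
    """Weighted linear regression of ln K2 on 1/T.

    Entries are (T, K2) or (T, K2, se_K2); with standard errors the weights
    are (K2/se)², the delta-method weight for ln K2.  Slope = ΔH/R and
    intercept = −ΔS/R, with ΔH in kcal/mol and ΔS in cal/(mol·K).
    """
    if len(series) < 3:
        raise DataError("vant_hoff_fit needs at least 3 temperatures")
    T = np.array([row[0] for row in series], dtype=float)
    K2 = np.array([row[1] for row in series], dtype=float)
    if np.any(K2 <= 0):
        raise DataError("K2 values must be positive for the van't Hoff fit")
    if np.any(T <= 0):
        raise DataError("temperatures must be positive (kelvin)")
    se = np.array([row[2] if len(row) > 2 else np.nan for row in series], dtype=float)
    w = np.where(np.isfinite(se) & (se > 0), (K2 / se) ** 2, np.nan)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(K2)
    X = np.column_stack([1.0 / T, np.ones_like(T)])
    y = np.log(K2)
    WX = X * w[:, None]
    cov_u = np.linalg.inv(X.T @ WX)
    beta = cov_u @ (WX.T @ y)
    resid = y - X @ beta
    dof = max(T.size - 2, 1)
    s2 = float((w * resid**2).sum() / dof)
    cov_beta = cov_u * s2
    dH = float(beta[0] * R_KCAL)                  # kcal/mol
    dS = float(-beta[1] * R_KCAL * 1000.0)        # cal/(mol·K)
    J = np.diag([R_KCAL, -R_KCAL * 1000.0])
    cov = J @ cov_beta @ J.T
    return ThermoFit(dH=dH, dS=dS,
                     se_dH=float(np.sqrt(cov[0, 0])), se_dS=float(np.sqrt(cov[1, 1])),
                     cov=cov)


def delta_g(K2: float, T: float, R: float = R_KCAL) -> float:
    """Specific-vs-nonspecific free-energy gap ΔG = R·T·ln K2, kcal/mol.

    Negative when K2 < 1, i.e. when the specifically docked state is
    favoured over nonspecific contact.
    """
    if K2 <= 0 or T <= 0:
        raise InvalidParameterError("K2 and T must be positive")
    return R * T * np.log(K2)


def fraction_specific(K2: float) -> float:
    """Fraction 1/(1+K2) of bound proteins in the specifically docked state."""
    if K2 < 0:
        raise InvalidParameterError(f"K2 must be nonnegative, got {K2}")
    return 1.0 / (1.0 + K2)


def delta_delta_g(Kd_specific: float, Kd_nonspecific: float, T: float,
                  R: float = R_KCAL) -> float:
    """Free-energy difference R·T·ln(Kd_ns/Kd_sp) between the two probe classes."""
    if Kd_specific <= 0 or Kd_nonspecific <= 0 or T <= 0:
        raise InvalidParameterError("Kd values and T must be positive")
    return R * T * np.log(Kd_nonspecific / Kd_specific)


def analyze_pair(
    trace_specific: BindingTrace,
    trace_nonspecific: BindingTrace,
    discard: float = 10.0,
    regressor: str = "c",
    bootstrap: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Full per-condition pipeline on one paired trace set.

    Returns a flat dict of the condition-level quantities (Kd per class,
    shared Σ∞, kon, koff per class, K2, ΔG, ΔΔG) with uncertainties —
    the machine-readable summary the CLI writes.
    """
    steps_sp = fit_all_steps(trace_specific, discard=discard)
    steps_ns = fit_all_steps(trace_nonspecific, discard=discard)
    sched = trace_specific.schedule
    iso = langmuir_pair_fit(steps_sp, steps_ns, temperature=sched.temperature,
                            ionic_strength=sched.ionic_strength)
    rate = kon_from_slopes(steps_sp, steps_ns, iso, regressor=regressor)
    k2, k2_se = extract_k2(iso, bootstrap=bootstrap, n_boot=n_boot, seed=seed)
    T = sched.temperature
    return {
        "temperature_K": T,
        "ionic_strength_mM": sched.ionic_strength,
        "Sigma_inf": iso.Sigma_inf,
        "se_Sigma_inf": iso.se_Sigma_inf,
        "Kd_specific_nM": iso.Kd_specific,
        "se_Kd_specific_nM": iso.se_Kd_specific,
        "Kd_nonspecific_nM": iso.Kd_nonspecific,
        "se_Kd_nonspecific_nM": iso.se_Kd_nonspecific,
        "kon_per_s_per_nM": rate.kon,
        "se_kon_per_s_per_nM": rate.se_kon,
        "koff_specific_per_s": rate.koff_specific,
        "koff_nonspecific_per_s": rate.koff_nonspecific,
        "K2": k2,
        "se_K2": k2_se,
        "dG_kcal_per_mol": delta_g(k2, T),
        "ddG_kcal_per_mol": delta_delta_g(iso.Kd_specific, iso.Kd_nonspecific, T),
        "isotherm_warning": iso.warning,
    }
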