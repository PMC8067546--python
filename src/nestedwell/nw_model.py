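"""Nested-well (sequential two-state) model of protein–DNA surface binding.

A protein binding a surface-tethered DNA probe is described by two
consecutive reactions along a conformational coordinate:

    unbound  <-- kon1·c / koff1 -->  nonspecific  <-- kon2 / koff2 -->  specific

The outer (nonspecific) well is characterised by the bimolecular rates
``kon1`` (s⁻¹·nM⁻¹) and ``koff1`` (s⁻¹), i.e. the dissociation constant
``K1 = koff1/kon1`` in nM.  The inner (specific) well is reached only from
the nonspecific state through the unimolecular rates ``kon2``/``koff2``
(s⁻¹); its equilibrium coefficient ``K2 = koff2/kon2`` is the dimensionless
ratio of nonspecifically to specifically bound protein, so *small* K2 means
*strong* selectivity.  With ``kon2 = 0`` the model collapses to the
single-well (purely nonspecific) Langmuir kinetics.

The occupancy vector θ = (θ1, θ2) (fractions of probes in the nonspecific
and specific state) obeys the linear system

    dθ1/dt = kon1·c·(1 − θ1 − θ2) − koff1·θ1 − kon2·θ1 + koff2·θ2
    dθ2/dt = kon2·θ1 − koff2·θ2

whose relaxation towards equilibrium is a double exponential with times
τS ≤ τL (eigenvalues of the 2×2 rate matrix).  The equilibrium of the whole
system is a Langmuir isotherm with the effective dissociation constant
``Kd = K1·K2/(1+K2)``.

Units are fixed throughout the package: concentrations in nM, times in s,
rates in s⁻¹ or s⁻¹·nM⁻¹.  No unit inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._errors import InvalidParameterError, NonphysicalSelectivityError, ScheduleError

__all__ = [
    "RateSet",
    "Occupancy",
    "RelaxationSolution",
    "effective_kd",
    "k2_from_kd",
    "equilibrium_occupancy",
    "relaxation_spectrum",
    "tauL_limit",
    "piecewise_occupancy",
    "ode_oracle",
]


@dataclass(frozen=True)
class RateSet:
    """The four kinetic constants of the nested-well scheme.

    Parameters
    ----------
    kon1 : float
        Bimolecular association rate to the nonspecific state (s⁻¹·nM⁻¹).
    koff1 : float
        Dissociation rate from the nonspecific state (s⁻¹).
    kon2 : float
        Nonspecific → specific transition rate (s⁻¹).  ``kon2 = 0`` denotes
        a single-well (nonspecific-only) probe.
    koff2 : float
        Specific → nonspecific transition rate (s⁻¹).
    """

    kon1: float
    koff1: float
    kon2: float = 0.0
    koff2: float = 0.0

    def __post_init__(self):
        if not (self.kon1 > 0 and np.isfinite(self.kon1)):
            raise InvalidParameterError(f"kon1 must be positive, got {self.kon1}")
        if not (self.koff1 > 0 and np.isfinite(self.koff1)):
            raise InvalidParameterError(f"koff1 must be positive, got {self.koff1}")
        if self.kon2 < 0 or self.koff2 < 0:
            raise InvalidParameterError("kon2 and koff2 must be nonnegative")

    @property
    def K1(self) -> float:
        """Nonspecific (outer-well) dissociation constant, nM."""
        return self.koff1 / self.kon1

    @property
    def K2(self) -> float:
        """Selectivity coefficient koff2/kon2 (dimensionless); requires kon2 > 0."""
        if self.kon2 == 0:
            raise InvalidParameterError("K2 is undefined for a single-well probe (kon2 = 0)")
        return self.koff2 / self.kon2

    @property
    def is_single_well(self) -> bool:
        return self.kon2 == 0

    @property
    def kd_eff(self) -> float:
        """Effective dissociation constant of the whole nested system, nM."""
        if self.is_single_well:
            return self.K1
        return effective_kd(self.K1, self.K2)


@dataclass(frozen=True)
class Occupancy:
    """Fractions of probe sites in the nonspecific (theta1) and specific (theta2) state."""

    theta1: float
    theta2: float

    @property
    def total(self) -> float:
        return self.theta1 + self.theta2


@dataclass(frozen=True)
class RelaxationSolution:
    """Double-exponential relaxation of the nested-well system at fixed c.

    σ(c,t)/Σ(c) = 1 − B·e^(−t/τL) − (1−B)·e^(−t/τS), starting from empty
    probes.  ``tau1`` is the single-well reference time 1/(kon1·c + koff1)
    and ``tauL_inf`` the fast-inner-exchange limit of τL.
    """

    tauS: float
    tauL: float
    B: float
    sigma_eq: float
    tau1: float
    tauL_inf: float


def effective_kd(K1: float, K2: float) -> float:
    """Effective dissociation constant Kd = K1·K2/(1+K2) of the nested system.

    Always smaller than K1: the inner well can only deepen the overall
    binding.  K2 → ∞ (vanishing inner well) recovers K1.
    """
    if not (K1 > 0):
        raise InvalidParameterError(f"K1 must be positive, got {K1}")
    if not (K2 > 0):
        raise InvalidParameterError(f"K2 must be positive, got {K2}")
    return K1 * K2 / (1.0 + K2)


def k2_from_kd(Kd: float, K1: float) -> float:
    """Selectivity coefficient K2 = Kd/(K1 − Kd); inverse of :func:`effective_kd`.

    Raises
    ------
    NonphysicalSelectivityError
        If Kd ≥ K1: a probe carrying the specific site cannot bind more
        weakly than the nonspecific reference.
    """
    if not (Kd > 0) or not (K1 > 0):
        raise InvalidParameterError("Kd and K1 must be positive")
    if Kd >= K1:
        raise NonphysicalSelectivityError(
            f"Kd = {Kd} nM must be smaller than the nonspecific K1 = {K1} nM"
        )
    return Kd / (K1 - Kd)


def equilibrium_occupancy(c: float, rates: RateSet) -> Occupancy:
    """Equilibrium occupancies at solution concentration ``c`` (nM).

    The total bound fraction follows a Langmuir isotherm with the effective
    Kd; detailed balance partitions it as theta1/theta2 = K2.
    """
    if c < 0:
        raise InvalidParameterError(f"concentration must be nonnegative, got {c}")
    if c == 0:
        return Occupancy(0.0, 0.0)
    if rates.is_single_well:
        return Occupancy(c / (c + rates.K1), 0.0)
    if rates.koff2 == 0:
        # absorbing inner well: every bound protein ends up specific
        return Occupancy(0.0, 1.0)
    K2 = rates.K2
    total = c / (c + effective_kd(rates.K1, K2))
    theta2 = total / (1.0 + K2)
    return Occupancy(total - theta2, theta2)


def _rate_matrix(c: float, rates: RateSet) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, b) such that dθ/dt = A·θ + b."""
    u = rates.kon1 * c
    A = np.array(
        [
            [-(u + rates.koff1 + rates.kon2), -u + rates.koff2],
            [rates.kon2, -rates.koff2],
        ]
    )
    b = np.array([u, 0.0])
    return A, b


def _eigen_system(c: float, rates: RateSet):
    """Eigenvalues/vectors of the rate matrix plus the stationary point.

    The discriminant equals (kon1·c + koff1 − kon2 − koff2)² + 4·kon2·koff1,
    which is strictly positive for kon2 > 0, so both eigenvalues are real
    and distinct; the single-well case is handled separately by callers.
    """
    A, b = _rate_matrix(c, rates)
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = max(tr * tr - 4.0 * det, 0.0)
    root = np.sqrt(disc)
    lam_slow = 0.5 * (tr + root)   # closer to zero
    lam_fast = 0.5 * (tr - root)
    theta_eq = np.linalg.solve(A, -b)
    vecs = []
    for lam in (lam_slow, lam_fast):
        # eigenvector from the numerically better-conditioned row
        r0 = (A[0, 0] - lam, A[0, 1])
        r1 = (A[1, 0], A[1, 1] - lam)
        if max(abs(r0[0]), abs(r0[1])) >= max(abs(r1[0]), abs(r1[1])):
            v = np.array([-r0[1], r0[0]])
        else:
            v = np.array([-r1[1], r1[0]])
        n = np.linalg.norm(v)
        vecs.append(v / n if n > 0 else np.array([1.0, 0.0]))
    V = np.column_stack(vecs)
    return lam_slow, lam_fast, V, theta_eq


def relaxation_spectrum(c: float, rates: RateSet) -> RelaxationSolution:
    """Relaxation times and long-mode amplitude at concentration ``c``.

    For a single-well probe (kon2 = 0) the kinetics is a single exponential
    with rate Γ = kon1·c + koff1; by convention tauS = tauL = 1/Γ and B = 1.
    """
    if c < 0:
        raise InvalidParameterError(f"concentration must be nonnegative, got {c}")
    tau1 = 1.0 / (rates.kon1 * c + rates.koff1)
    if rates.is_single_well:
        sigma_eq = equilibrium_occupancy(c, rates).total
        return RelaxationSolution(tauS=tau1, tauL=tau1, B=1.0, sigma_eq=sigma_eq,
                                  tau1=tau1, tauL_inf=tau1)
    lam_slow, lam_fast, V, theta_eq = _eigen_system(c, rates)
    tauL = -1.0 / lam_slow
    tauS = -1.0 / lam_fast
    sigma_eq = float(theta_eq.sum())
    if sigma_eq > 0:
        coeff = np.linalg.solve(V, -theta_eq)  # θ(0) = 0
        a_slow = coeff[0] * V[:, 0].sum()
        B = float(-a_slow / sigma_eq)
    else:
        B = 1.0
    tl_inf = tauL_limit(c, rates.kon1, rates.koff1, rates.K2) if rates.koff2 > 0 else np.inf
    return RelaxationSolution(tauS=tauS, tauL=tauL, B=B, sigma_eq=sigma_eq,
                              tau1=tau1, tauL_inf=tl_inf)


def tauL_limit(c: float, kon1: float, koff1: float, K2: float) -> float:
    """Limiting slow time τL∞ = 1/(kon1·c + koff1·K2/(1+K2)).

    Obtained by letting kon2, koff2 → ∞ at fixed K2: the inner well stays in
    instantaneous equilibrium with the nonspecific state, and the system
    responds like a single well with the effective Kd.  Strictly greater
    than τ1 = 1/(kon1·c + koff1) for any finite K2 > 0.
    """
    if K2 <= 0:
        raise InvalidParameterError(f"K2 must be positive, got {K2}")
    if kon1 <= 0 or koff1 <= 0:
        raise InvalidParameterError("kon1 and koff1 must be positive")
    if c < 0:
        raise InvalidParameterError(f"concentration must be nonnegative, got {c}")
    return 1.0 / (kon1 * c + koff1 * K2 / (1.0 + K2))


def _propagate(theta0: np.ndarray, c: float, rates: RateSet, t: np.ndarray) -> np.ndarray:
    """Analytic propagation of θ over times ``t`` (measured from the step start).

    Returns an array of shape (len(t), 2).  Used by the synthetic generator
    and the joint kinetic fit; validated against :func:`ode_oracle`.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty((t.size, 2))
    if rates.is_single_well:
        # θ2 can only decay (kon2 = 0); θ1 relaxes with rate Γ = kon1·c + koff1
        gamma = rates.kon1 * c + rates.koff1
        th2 = theta0[1] * np.exp(-rates.koff2 * t)
        # forcing from θ2 is negligible only when θ2 ≡ 0; the synthetic
        # generator always uses θ2 = 0 for single-well probes.
        th1_eq = rates.kon1 * c / gamma
        th1 = th1_eq + (theta0[0] - th1_eq) * np.exp(-gamma * t)
        out[:, 0] = th1
        out[:, 1] = th2
        return out
    lam_slow, lam_fast, V, theta_eq = _eigen_system(c, rates)
    coeff = np.linalg.solve(V, np.asarray(theta0, dtype=float) - theta_eq)
    modes = coeff * V  # columns scaled by amplitude
    out[:] = theta_eq
    out += np.exp(np.outer(t, [lam_slow, lam_fast])) @ modes.T
    return out


def piecewise_occupancy(
    step_times: Sequence[float],
    concentrations: Sequence[float],
    rates: RateSet,
    times: np.ndarray,
) -> np.ndarray:
    """Occupancy (θ1, θ2) along a stepwise titration, analytic solution.

    ``step_times``/``concentrations`` define a piecewise-constant analyte
    concentration (excess analyte: no depletion within a step); θ is
    continuous across injections and starts from empty probes at the first
    injection.  Returns shape (len(times), 2).
    """
    step_times = np.asarray(step_times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    _validate_schedule(step_times, conc)
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < step_times[0]):
        raise ScheduleError("evaluation times precede the first injection")
    out = np.empty((times.size, 2))
    theta = np.zeros(2)
    bounds = np.append(step_times, np.inf)
    for i, c in enumerate(conc):
        mask = (times >= bounds[i]) & (times < bounds[i + 1])
        if mask.any():
            out[mask] = _propagate(theta, c, rates, times[mask] - bounds[i])
        if np.isfinite(bounds[i + 1]):
            theta = _propagate(theta, c, rates, np.array([bounds[i + 1] - bounds[i]]))[0]
    return out


def _validate_schedule(step_times: np.ndarray, conc: np.ndarray) -> None:
    if step_times.size != conc.size or step_times.size == 0:
        raise ScheduleError("step_times and concentrations must have equal, nonzero length")
    if np.any(np.diff(step_times) <= 0):
        raise ScheduleError("step_times must be strictly increasing")
    if np.any(conc < 0):
        raise ScheduleError("concentrations must be nonnegative")


def ode_oracle(
    step_times: Sequence[float],
    concentrations: Sequence[float],
    rates: RateSet,
    times: np.ndarray,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Numerically integrated occupancy series — independent check of the
    analytic solution.

    Integrates the two-state rate equations with LSODA across injection
    steps with continuity of (θ1, θ2).  Returns shape (len(times), 2).
    """
    step_times = np.asarray(step_times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    _validate_schedule(step_times, conc)
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < step_times[0]:
        raise ScheduleError("evaluation times precede the first injection")
    out = np.empty((times.size, 2))
    theta = np.zeros(2)
    last = max(times.max(), step_times[-1]) if times.size else step_times[-1]
    bounds = np.append(step_times, last + 1.0)
    for i, c in enumerate(conc):
        t0, t1 = bounds[i], bounds[i + 1]
        A, b = _rate_matrix(c, rates)
        mask = (times >= t0) & (times < t1)
        t_eval = np.unique(np.append(times[mask], t1))
        sol = solve_ivp(
            lambda t, y: A @ y + b,
            (t0, t1),
            theta,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac=lambda t, y: A,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on step {i}: {sol.message}")
        if mask.any():
            out[mask] = sol.y[:, : mask.sum()].T
        theta = sol.y[:, -1]  # continuity at the next injection
    return out
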