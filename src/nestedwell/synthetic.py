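"""Synthetic sensorgram generation for the stepwise-titration experiment.

Emulates the label-free biosensor measurement the analysis pipeline is built
for: paired DNA probe spots — one carrying the specific consensus site
(nested-well kinetics) and one without it (single-well kinetics) — exposed to
stepwise increasing analyte concentration, sharing a common saturation
surface density Σ∞.  Traces are the exact piecewise nested-well solution
scaled by Σ∞ plus i.i.d. Gaussian measurement noise; all generators are pure
functions of (parameters, seed).

Defaults mirror the measured Gal4–DNA system: K1 = 200 nM, K2 = 0.16,
kon1 = 1.6e-5 s⁻¹·nM⁻¹, titration doubling from 0.08 nM up to a final 50 nM
step, 3000 s per step, 30 °C, 150 mM NaCl.  The inner-well exchange default
kon2 = 5e-2 s⁻¹ places the generator in the fast-exchange regime (τL ≈ τL∞,
B ≈ 1), the regime in which step kinetics are nearly single-exponential.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._errors import ConfigError, InvalidParameterError, ScheduleError
from .nw_model import RateSet, piecewise_occupancy

__all__ = [
    "StepSchedule",
    "BindingTrace",
    "make_default_schedule",
    "generate_trace",
    "generate_probe_pair",
    "generate_k2_temperature_series",
    "generate_condition_table",
    "DEFAULT_K1",
    "DEFAULT_K2",
    "DEFAULT_KON1",
    "DEFAULT_KON2",
    "DEFAULT_SIGMA_INF",
    "R_KCAL",
]

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.987e-3

# Study-condition defaults (nonspecific Kd ~ 160-240 nM -> midpoint 200;
# selectivity K2 = 0.16 at 150 mM NaCl; pooled kon = 1.6e-5 s⁻¹ nM⁻¹).
DEFAULT_K1 = 200.0       # nM
DEFAULT_K2 = 0.16        # dimensionless
DEFAULT_KON1 = 1.6e-5    # s⁻¹ nM⁻¹
DEFAULT_KON2 = 5e-2      # s⁻¹, fast inner exchange (docking on ~20 s timescale)
DEFAULT_SIGMA_INF = 1000.0  # instrument units


@dataclass(frozen=True)
class StepSchedule:
    """Piecewise-constant injection schedule with condition metadata.

    ``step_times`` are injection instants (s, strictly increasing, first at
    t = 0 by convention); ``concentrations`` the analyte concentration (nM)
    holding after each injection, nondecreasing in a stepwise titration.
    ``end_time`` closes the last step.
    """

    step_times: tuple[float, ...]
    concentrations: tuple[float, ...]
    temperature: float = 303.15     # K
    ionic_strength: float = 150.0   # mM NaCl
    end_time: float | None = None

    def __post_init__(self):
        st = np.asarray(self.step_times, dtype=float)
        cc = np.asarray(self.concentrations, dtype=float)
        if st.size != cc.size or st.size == 0:
            raise ScheduleError("step_times and concentrations must have equal, nonzero length")
        if np.any(np.diff(st) <= 0):
            raise ScheduleError("step_times must be strictly increasing")
        if np.any(np.diff(cc) < 0):
            raise ScheduleError("stepwise titration requires nondecreasing concentrations")
        object.__setattr__(self, "step_times", tuple(st))
        object.__setattr__(self, "concentrations", tuple(cc))
        if self.end_time is None:
            dt = st[-1] - st[-2] if st.size > 1 else 3000.0
            object.__setattr__(self, "end_time", float(st[-1] + dt))
        elif self.end_time <= st[-1]:
            raise ScheduleError("end_time must exceed the last injection time")

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    def step_bounds(self) -> np.ndarray:
        """Array of step edges, length n_steps + 1 (last edge = end_time)."""
        return np.append(self.step_times, self.end_time)


@dataclass(frozen=True)
class BindingTrace:
    """Sampled surface density σ(t) for one probe spot."""

    times: np.ndarray
    sigma: np.ndarray
    schedule: StepSchedule
    probe_class: str  # "specific" | "nonspecific"
    spot_id: str = "spot"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise InvalidParameterError("times and sigma must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise InvalidParameterError("sigma contains non-finite values")
        if self.probe_class not in ("specific", "nonspecific"):
            raise InvalidParameterError(f"unknown probe_class {self.probe_class!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sigma", s)


def make_default_schedule(step_duration: float = 3000.0) -> StepSchedule:
    """The standard titration ladder: 0.08 nM doubling up to 40.96, then 50 nM.

    Eleven steps of ``step_duration`` seconds each at 30 °C (303.15 K) and
    150 mM NaCl.
    """
    conc = [0.08 * 2**k for k in range(10)]  # 0.08 ... 40.96
    conc.append(50.0)
    times = [i * step_duration for i in range(len(conc))]
    return StepSchedule(tuple(times), tuple(conc))


def _rng_for(seed: int, spot_id: str) -> np.random.Generator:
    # one named stream per trace: fixture sets are order-independent
    return np.random.default_rng([int(seed), zlib.crc32(spot_id.encode())])


def generate_trace(
    rates: RateSet,
    schedule: StepSchedule,
    sigma_inf: float = DEFAULT_SIGMA_INF,
    noise_sd: float = 0.0,
    sample_dt: float = 10.0,
    seed: int = 0,
    spot_id: str | None = None,
    probe_class: str | None = None,
) -> BindingTrace:
    """Sample a sensorgram from the exact nested-well solution plus noise.

    σ(t_k) = Σ∞·(θ1+θ2)(t_k) + ε_k, ε_k ~ N(0, noise_sd²) i.i.d., with the
    occupancy propagated analytically across the injection schedule.  The
    (seed, spot_id) pair fully determines the output.
    """
    if sample_dt <= 0:
        raise InvalidParameterError("sample_dt must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be nonnegative")
    if probe_class is None:
        probe_class = "nonspecific" if rates.is_single_well else "specific"
    if spot_id is None:
        spot_id = probe_class
    t0 = schedule.step_times[0]
    times = np.arange(t0, schedule.end_time, sample_dt)
    theta = piecewise_occupancy(schedule.step_times, schedule.concentrations, rates, times)
    sigma = sigma_inf * theta.sum(axis=1)
    if noise_sd > 0:
        sigma = sigma + _rng_for(seed, spot_id).normal(0.0, noise_sd, size=sigma.size)
    return BindingTrace(times=times, sigma=sigma, schedule=schedule,
                        probe_class=probe_class, spot_id=spot_id,
                        meta={"seed": int(seed), "noise_sd": float(noise_sd)})


def generate_probe_pair(
    K1: float = DEFAULT_K1,
    K2: float = DEFAULT_K2,
    kon1: float = DEFAULT_KON1,
    kon2: float = DEFAULT_KON2,
    sigma_inf: float = DEFAULT_SIGMA_INF,
    schedule: StepSchedule | None = None,
    noise_sd: float = 0.0,
    sample_dt: float = 10.0,
    seed: int = 0,
    spot_prefix: str = "",
) -> tuple[BindingTrace, BindingTrace]:
    """Paired specific/nonspecific traces sharing Σ∞, kon1 and koff1.

    The specific probe follows the full nested-well kinetics with inner
    rates (kon2, koff2 = K2·kon2); the nonspecific probe is the single-well
    limit (kon2 = 0).  Returns (specific, nonspecific).
    """
    if schedule is None:
        schedule = make_default_schedule()
    koff1 = K1 * kon1
    rates_sp = RateSet(kon1=kon1, koff1=koff1, kon2=kon2, koff2=K2 * kon2)
    rates_ns = RateSet(kon1=kon1, koff1=koff1, kon2=0.0, koff2=0.0)
    sp = generate_trace(rates_sp, schedule, sigma_inf, noise_sd, sample_dt, seed,
                        spot_id=f"{spot_prefix}specific", probe_class="specific")
    ns = generate_trace(rates_ns, schedule, sigma_inf, noise_sd, sample_dt, seed,
                        spot_id=f"{spot_prefix}nonspecific", probe_class="nonspecific")
    return sp, ns


def generate_k2_temperature_series(
    dH: float = -12.8,
    dS: float = -38.7,
    temperatures: Sequence[float] | None = None,
    rel_noise: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """K2(T) series from the van't Hoff relation K2 = exp(ΔH/RT − ΔS/R).

    ``dH`` in kcal/mol, ``dS`` in cal/(mol·K).  Noise is multiplicative
    lognormal, exp(N(0, rel_noise)), appropriate for a positive equilibrium
    coefficient estimated on a log-like scale.  Default grid: 6 temperatures
    from 288.15 to 310.15 K.
    """
    if rel_noise < 0:
        raise InvalidParameterError("rel_noise must be nonnegative")
    if temperatures is None:
        temperatures = np.linspace(288.15, 310.15, 6)
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise InvalidParameterError("temperatures must be positive (kelvin)")
    dS_kcal = dS / 1000.0
    k2 = np.exp(dH / (R_KCAL * temps) - dS_kcal / R_KCAL)
    if rel_noise > 0:
        rng = _rng_for(seed, "k2_temperature_series")
        k2 = k2 * np.exp(rng.normal(0.0, rel_noise, size=k2.size))
    return list(zip(temps.tolist(), k2.tolist()))


def generate_condition_table(
    K1_by_condition: Mapping[float, float],
    K2_by_condition: Mapping[float, float],
    kon1: float = DEFAULT_KON1,
    kon2: float = DEFAULT_KON2,
    sigma_inf: float = DEFAULT_SIGMA_INF,
    schedule: StepSchedule | None = None,
    noise_sd: float = 0.0,
    sample_dt: float = 10.0,
    seed: int = 0,
) -> dict[float, tuple[BindingTrace, BindingTrace]]:
    """One probe pair per condition (e.g. ionic strength in mM NaCl).

    ``K1_by_condition`` and ``K2_by_condition`` must share their keys; each
    key labels a condition and is recorded as the schedule's ionic strength
    when numeric.  Mimics a measured condition series for which no
    mechanistic K(I_s) model is assumed.
    """
    if set(K1_by_condition) != set(K2_by_condition):
        raise ConfigError("K1_by_condition and K2_by_condition must share the same keys")
    if schedule is None:
        schedule = make_default_schedule()
    out: dict[float, tuple[BindingTrace, BindingTrace]] = {}
    for key in K1_by_condition:
        sched = replace(schedule, ionic_strength=float(key)) if _is_number(key) else schedule
        out[key] = generate_probe_pair(
            K1=K1_by_condition[key], K2=K2_by_condition[key],
            kon1=kon1, kon2=kon2, sigma_inf=sigma_inf, schedule=sched,
            noise_sd=noise_sd, sample_dt=sample_dt, seed=seed,
            spot_prefix=f"{key}:",
        )
    return out


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
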