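"""Temperature-sensitivity decomposition of nocturnal respiration.

Distinguishes the *inherent* Q10 (measured over a brief, <= 30 min,
artificial temperature change) from the *apparent* Q10 (computed from
measurements hours apart under natural nocturnal cooling). Because the basal
rate itself declines through the night, the apparent Q10 overestimates the
inherent one, and the observed decrease in respiration splits into a
temperature-driven part (alpha) and a temperature-independent part (beta);
the temperature-control statistic is ``TC = alpha / (alpha + beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DeclineParams, decline_fraction
from .synthetic import CoolingSchedule

__all__ = [
    "UndefinedTCError",
    "Q10Estimate",
    "TCDecomposition",
    "CumulativeOverestimation",
    "q10_from_pair",
    "decompose",
    "apparent_q10_curve",
    "tc_curve",
    "cumulative_overestimation",
]

#: Maximum elapsed time (h) for a measurement pair to count as inherent Q10.
INHERENT_WINDOW_H = 0.5


class UndefinedTCError(ValueError):
    """TC is undefined (net respiration increase or a warming night)."""


@dataclass(frozen=True)
class Q10Estimate:
    """A Q10 value with its measurement provenance.

    ``kind`` is ``"inherent"`` for short-term artificial temperature changes
    (elapsed <= 0.5 h) or ``"apparent"`` for natural cooling over hours.
    """

    value: float
    kind: str
    elapsed: float  # hours between the two measurements

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("Q10 must be positive")
        if self.kind not in ("inherent", "apparent"):
            raise ValueError("kind must be 'inherent' or 'apparent'")
        if self.kind == "inherent" and self.elapsed > INHERENT_WINDOW_H:
            raise ValueError(
                f"inherent Q10 requires elapsed <= {INHERENT_WINDOW_H} h "
                f"(got {self.elapsed} h)"
            )


def q10_from_pair(R1: float, T1: float, R2: float, T2: float) -> float:
    """Q10 from two (respiration, temperature) measurements.

    ``Q10 = (R2 / R1) ** (10 / (T2 - T1))``; undefined when T1 = T2.
    """
    if R1 <= 0 or R2 <= 0:
        raise ValueError("respiration rates must be positive")
    if T1 == T2:
        raise UndefinedTCError("temperature sensitivity undefined for T1 = T2")
    return float((R2 / R1) ** (10.0 / (T2 - T1)))


@dataclass(frozen=True)
class TCDecomposition:
    """alpha/beta partition of an observed nocturnal respiration decrease.

    ``alpha`` is the decrease attributable to the temperature change alone
    (via the inherent Q10), ``beta`` the further temperature-independent
    decrease, and ``tc = alpha / (alpha + beta)``.
    """

    alpha: float
    beta: float
    tc: float


def decompose(R_start: float, R_end_obs: float, T_start: float, T_end: float,
              q10_inh: float) -> TCDecomposition:
    """Partition an observed start→end respiration decrease into alpha/beta.

    The temperature-only endpoint is
    ``R_temp = R_start * q10_inh^((T_end - T_start)/10)``; then
    ``alpha = R_start - R_temp`` and ``beta = R_temp - R_end_obs``.
    Warming nights and net respiration increases leave TC undefined and
    raise :class:`UndefinedTCError` — the construct assumes nocturnal
    cooling.
    """
    if R_start <= 0:
        raise ValueError("R_start must be positive")
    if q10_inh <= 0:
        raise ValueError("q10_inh must be positive")
    if T_end > T_start:
        raise UndefinedTCError("TC undefined on a warming night")
    r_temp = R_start * q10_inh ** ((T_end - T_start) / 10.0)
    alpha = R_start - r_temp
    beta = r_temp - R_end_obs
    total = alpha + beta
    if total < 0:
        raise UndefinedTCError("net respiration increase: TC undefined")
    if total == 0:
        return TCDecomposition(alpha=0.0, beta=0.0, tc=0.0)
    return TCDecomposition(alpha=float(alpha), beta=float(beta), tc=float(alpha / total))


def apparent_q10_curve(q10_inh: float, cooling_rates, night_length: float = 8.0,
                       decline: DeclineParams = DeclineParams()) -> pd.DataFrame:
    """Apparent Q10 versus the rate of nocturnal cooling.

    For a night of ``night_length`` hours cooling linearly at rate ``c``
    (deg C/h) the endpoint pair gives
    ``Q10_app(c) = q10_inh * (1 - a L^b)^(-10 / (c L))``: it diverges as the
    cooling rate tends to zero and relaxes to the inherent Q10 for fast
    cooling. Zero rates in the grid are flagged undefined (NaN).
    """
    c = np.asarray(cooling_rates, dtype=float)
    if np.any(c < 0):
        raise ValueError("cooling rates must be >= 0")
    D = decline_fraction(night_length, decline)
    with np.errstate(divide="ignore"):
        q_app = np.where(
            c > 0, q10_inh * D ** (-10.0 / (c * night_length)), np.nan
        )
    if not decline.enabled or decline.a == 0:
        q_app = np.where(c > 0, q10_inh, np.nan)
    return pd.DataFrame({"cooling_rate": c, "q10_app": q_app})


def tc_curve(q10_inh: float, cooling_rates, night_length: float = 8.0,
             decline: DeclineParams = DeclineParams()) -> pd.DataFrame:
    """Temperature control of respiration versus the rate of cooling.

    Applies the alpha/beta decomposition to the analytic endpoint states of
    a linearly cooling night: with ``g = q10_inh^(-c L / 10)`` and decline
    factor ``D(L)``, ``TC = (1 - g) / (1 - g D)``. TC → 0 as cooling → 0 and
    TC → 1 for fast cooling; with the decline disabled TC = 1 everywhere.
    """
    c = np.asarray(cooling_rates, dtype=float)
    if np.any(c < 0):
        raise ValueError("cooling rates must be >= 0")
    D = decline_fraction(night_length, decline)
    g = np.power(q10_inh, -c * night_length / 10.0)
    denom = 1.0 - g * D  # > 0 whenever cooling occurs or the decline is active
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(denom > 0, (1.0 - g) / np.where(denom > 0, denom, 1.0), 1.0)
    tc = np.where(c == 0, 0.0, tc)
    return pd.DataFrame({"cooling_rate": c, "tc": tc})


@dataclass
class CumulativeOverestimation:
    """Night-long respiration integrals with and without the decline."""

    series: pd.DataFrame        # h, r_with_decline, r_without_decline, cum_diff
    integral_with: float        # flux-hours
    integral_without: float
    difference: float
    relative_reduction: float   # difference / integral_without


def cumulative_overestimation(R_initial: float, q10_inh: float,
                              schedule: CoolingSchedule,
                              night_length: float = 8.0,
                              decline: DeclineParams = DeclineParams(),
                              timestep_h: float = 0.25) -> CumulativeOverestimation:
    """Cumulated overestimation of nocturnal respiration by a constant-basal
    model.

    Integrates (trapezoidal, on the model timestep) the respiration course
    with and without the temperature-independent decline under the same
    temperature path, and returns both integrals and their difference — the
    respiration a constant-basal-rate model overestimates across the night.
    At constant temperature the relative reduction has the closed form
    ``(a / (b + 1)) * L^b``.
    """
    if R_initial <= 0:
        raise ValueError("R_initial must be positive")
    n_steps = round(night_length / timestep_h)
    if abs(n_steps * timestep_h - night_length) > 1e-9 or n_steps < 1:
        raise ValueError("timestep must divide the night length")
    h = np.linspace(0.0, night_length, n_steps + 1)
    T = schedule.temperature(h)
    base = R_initial * np.power(q10_inh, (T - schedule.T_start) / 10.0)
    with_decline = base * decline_fraction(h, decline)
    diff = base - with_decline
    cum_diff = np.concatenate(
        [[0.0], np.cumsum((diff[1:] + diff[:-1]) / 2.0 * np.diff(h))]
    )
    integral_without = float(np.trapezoid(base, h))
    integral_with = float(np.trapezoid(with_decline, h))
    series = pd.DataFrame(
        {"h": h, "r_with_decline": with_decline, "r_without_decline": base,
         "cum_diff": cum_diff}
    )
    difference = integral_without - integral_with
    return CumulativeOverestimation(
        series=series,
        integral_with=integral_with,
        integral_without=integral_without,
        difference=difference,
        relative_reduction=difference / integral_without,
    )
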