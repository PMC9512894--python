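"""Closed-form equations for plant dark respiration.

The module collects the small set of algebraic models everything else in the
package is built from:

* the exponential Q10 temperature response of respiration (the *standard
  model*), with either a fixed Q10 or a temperature-dependent Q10
  ``TDQ10(T) = 3.09 - 0.0435 T``;
* the universal temperature-independent nocturnal decline of the basal rate,
  ``R_To / R_To-initial = 1 - a h^b`` with published coefficients
  ``a = 0.08``, ``b = 0.54`` (h = hours since onset of darkness), so the
  basal rate falls by ~25% after 8 h of darkness;
* the merged night-time formulation anchored at sunset, which multiplies the
  Q10 response by the decline factor;
* the land-surface-model respiration chain: leaf respiration with logistic
  high/low temperature limitation, whole-plant maintenance respiration via
  nitrogen-ratio scaling, and growth respiration as a fixed fraction of
  (GPP - R_m).

All respiration values are CO2 efflux, positive by convention. Functions are
vectorised over numpy arrays in their temperature/time arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Q10Spec",
    "DeclineParams",
    "JulesRespParams",
    "standard_model",
    "tdq10",
    "decline_fraction",
    "new_formulation",
    "jules_leaf_resp",
    "maintenance_resp",
    "growth_resp",
]

#: Supported temperature range (deg C) for the temperature-dependent Q10.
TDQ10_RANGE = (-10.0, 45.0)

#: Published coefficients of the temperature-dependent Q10.
TDQ10_INTERCEPT = 3.09
TDQ10_SLOPE = 0.0435  # per deg C

#: Published coefficients of the universal nocturnal decline.
DECLINE_A = 0.08
DECLINE_B = 0.54

#: Fixed smoothing constant of the logistic temperature limits (leaf resp.).
_LIMIT_SMOOTHING = 0.3


@dataclass(frozen=True)
class Q10Spec:
    """Temperature-sensitivity specification.

    mode
        ``"fixed"`` uses ``q10_fixed`` everywhere; ``"temperature_dependent"``
        evaluates ``tdq10_intercept - tdq10_slope * T`` at the instantaneous
        temperature.
    """

    mode: str = "fixed"
    q10_fixed: float = 2.0
    tdq10_intercept: float = TDQ10_INTERCEPT
    tdq10_slope: float = TDQ10_SLOPE

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "temperature_dependent"):
            raise ValueError(f"unknown Q10 mode {self.mode!r}")
        if self.q10_fixed <= 0:
            raise ValueError("q10_fixed must be positive")

    def value(self, T):
        """Q10 at temperature ``T`` (deg C)."""
        if self.mode == "fixed":
            return np.broadcast_to(self.q10_fixed, np.shape(T)).copy() if np.ndim(T) else self.q10_fixed
        return self.tdq10_intercept - self.tdq10_slope * np.asarray(T, dtype=float)


@dataclass(frozen=True)
class DeclineParams:
    """Coefficients of the nocturnal basal-rate decline ``1 - a h^b``."""

    a: float = DECLINE_A
    b: float = DECLINE_B
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("decline scale a must be >= 0")
        if self.b <= 0:
            raise ValueError("decline exponent b must be > 0")

    @classmethod
    def disabled(cls) -> "DeclineParams":
        return cls(enabled=False)


@dataclass(frozen=True)
class JulesRespParams:
    """Parameters of the land-surface respiration chain.

    Nitrogen contents enter only through the ratio ``(N_r + N_s) / N_l``
    (root + stem over leaf), so their absolute unit is arbitrary.
    """

    T_ref: float = 25.0      # deg C, reference temperature of R_ref
    T_upp: float = 36.0      # deg C, upper logistic limit
    T_low: float = 0.0       # deg C, lower logistic limit
    N_r: float = 0.5
    N_s: float = 0.5
    N_l: float = 1.0
    beta_sw: float = 1.0     # soil-water factor in [0, 1]
    growth_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.T_low >= self.T_upp:
            raise ValueError("require T_low < T_upp")
        if self.N_l <= 0:
            raise ValueError("leaf nitrogen N_l must be positive")
        if not 0.0 <= self.beta_sw <= 1.0:
            raise ValueError("beta_sw must lie in [0, 1]")
        if not 0.0 <= self.growth_fraction <= 1.0:
            raise ValueError("growth_fraction must lie in [0, 1]")


def _check_positive_rate(r, name: str = "respiration") -> None:
    if np.any(np.asarray(r) <= 0):
        raise ValueError(f"{name} must be positive (efflux convention)")


def standard_model(r_ref, q10: Q10Spec, T, T_ref: float):
    """Q10 temperature response: ``R_T = R_ref * Q10^((T - T_ref)/10)``.

    ``r_ref`` is the respiration rate at ``T_ref``. With a temperature-
    dependent spec the Q10 is evaluated at the instantaneous ``T``.
    """
    _check_positive_rate(r_ref, "r_ref")
    T = np.asarray(T, dtype=float) if np.ndim(T) else float(T)
    q = q10.value(T)
    return r_ref * np.power(q, (np.asarray(T) - T_ref) / 10.0)


def tdq10(T):
    """Temperature-dependent Q10, ``3.09 - 0.0435 T`` (T in deg C)."""
    T = np.asarray(T, dtype=float) if np.ndim(T) else float(T)
    lo, hi = TDQ10_RANGE
    if np.any(np.asarray(T) < lo) or np.any(np.asarray(T) > hi):
        warnings.warn(
            f"temperature outside the supported TDQ10 range {TDQ10_RANGE}",
            RuntimeWarning,
            stacklevel=2,
        )
    return TDQ10_INTERCEPT - TDQ10_SLOPE * T


def decline_fraction(h, p: DeclineParams = DeclineParams()):
    """Basal-rate ratio ``R_To / R_To-initial`` after ``h`` hours of darkness.

    Returns ``max(0, 1 - a h^b)``; exactly 1 at h = 0, monotonically
    non-increasing, and identically 1 when the decline is disabled.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("hours since darkness onset must be >= 0")
    if not p.enabled:
        out = np.ones_like(h_arr)
        return out if np.ndim(h) else 1.0
    out = np.clip(1.0 - p.a * np.power(h_arr, p.b), 0.0, None)
    return out if np.ndim(h) else float(out)


def new_formulation(r_sunset, q10: Q10Spec, T_t, T_sunset: float, h,
                    p: DeclineParams = DeclineParams()):
    """Merged night-time formulation anchored at sunset.

    ``R_T,t = R_T,sunset * Q10^(0.1 (T_t - T_sunset)) * (1 - a h^b)`` with
    ``h`` the hours since sunset. With the decline disabled and a fixed Q10
    this is exactly the standard model re-anchored at sunset.
    """
    _check_positive_rate(r_sunset, "r_sunset")
    base = standard_model(r_sunset, q10, T_t, T_sunset)
    return base * decline_fraction(h, p)


def jules_leaf_resp(r_ref, q10: Q10Spec, T, p: JulesRespParams):
    """Leaf respiration with logistic high/low temperature limitation.

    The standard Q10 response divided by
    ``(1 + exp(0.3 (T - T_upp))) * (1 + exp(0.3 (T_low - T)))``;
    approaches the plain Q10 response well inside (T_low, T_upp) and is
    halved at either limit.
    """
    base = standard_model(r_ref, q10, T, p.T_ref)
    T = np.asarray(T, dtype=float) if np.ndim(T) else float(T)
    denom = (1.0 + np.exp(_LIMIT_SMOOTHING * (np.asarray(T) - p.T_upp))) * (
        1.0 + np.exp(_LIMIT_SMOOTHING * (p.T_low - np.asarray(T)))
    )
    return base / denom


def maintenance_resp(r_leaf_canopy, p: JulesRespParams):
    """Whole-plant maintenance respiration from canopy leaf respiration.

    ``R_m = R_leaf * (beta_sw + (N_r + N_s) / N_l)``. Linear in the leaf
    term, so a nocturnal decline of leaf respiration propagates unchanged to
    root and stem maintenance respiration.
    """
    return np.asarray(r_leaf_canopy) * (p.beta_sw + (p.N_r + p.N_s) / p.N_l) \
        if np.ndim(r_leaf_canopy) else r_leaf_canopy * (p.beta_sw + (p.N_r + p.N_s) / p.N_l)


def growth_resp(gpp, r_m, p: JulesRespParams = JulesRespParams()):
    """Growth respiration ``R_g = f_g * max(GPP - R_m, 0)``.

    Clamped at zero: at night GPP = 0 and a negative growth term would be
    unphysical.
    """
    diff = np.maximum(np.asarray(gpp, dtype=float) - np.asarray(r_m, dtype=float), 0.0)
    out = p.growth_fraction * diff
    return out if (np.ndim(gpp) or np.ndim(r_m)) else float(out)
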