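"""Four-formulation evaluation of night-time respiration predictions.

Compares the four model variants — standard (fixed Q10 = 2), standard with
temperature-dependent Q10, and the two corresponding *new* variants that add
the temperature-independent basal decline — against observed (or synthetic)
traces, using one-to-one OLS regression (first point excluded), standardized
residuals, RMSE and Taylor-diagram statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import DeclineParams, Q10Spec
from .pipeline import normalize_trace
from .trace import Trace

__all__ = [
    "Formulation",
    "FORMULATIONS",
    "OneToOneStats",
    "TaylorStats",
    "EvalReport",
    "simulate_trace",
    "one_to_one_stats",
    "standardized_residuals",
    "taylor_stats",
    "evaluate_trace",
]


@dataclass(frozen=True)
class Formulation:
    """One of the four respiration formulations under comparison.

    ``standard`` and ``new`` use a fixed Q10 = 2; the ``-modified`` variants
    use the temperature-dependent Q10. The ``new`` variants enable the
    nocturnal basal-rate decline.
    """

    name: str
    q10: Q10Spec
    decline: DeclineParams

    @classmethod
    def from_name(cls, name: str, decline: DeclineParams = DeclineParams()) -> "Formulation":
        registry = {
            "standard": (Q10Spec(mode="fixed"), DeclineParams.disabled()),
            "standard-modified": (Q10Spec(mode="temperature_dependent"), DeclineParams.disabled()),
            "new": (Q10Spec(mode="fixed"), decline),
            "new-modified": (Q10Spec(mode="temperature_dependent"), decline),
        }
        if name not in registry:
            raise ValueError(f"unknown formulation {name!r}; choose from {sorted(registry)}")
        q10, dec = registry[name]
        return cls(name=name, q10=q10, decline=dec)


#: The four simulation variants, in their conventional order.
FORMULATION_NAMES = ("standard", "new", "standard-modified", "new-modified")
FORMULATIONS = tuple(Formulation.from_name(n) for n in FORMULATION_NAMES)


def simulate_trace(obs: Trace, f: Formulation, exclusion_min: float = 0.0) -> pd.DataFrame:
    """Predict the normalized respiration course of an observed trace.

    The first retained sample (after the exclusion window) anchors the
    prediction: its temperature plays the role of the sunset temperature and
    elapsed time ``h`` is counted from it, so the prediction there is exactly
    1. The prediction is driven by the observed temperature at every sample:
    ``pred = Q10(T)^(0.1 (T - T_anchor)) * (1 - a h^b)``.

    Returns a frame with columns ``h`` (hours since darkness onset),
    ``h_rel`` (since the anchor), ``temperature_C``, ``observed`` (normalized
    ratio) and ``predicted``.
    """
    norm = obs if obs.normalized else normalize_trace(obs, exclusion_min)
    if norm.samples["temperature_C"].isna().any():
        raise ValueError("observed trace must carry temperature at every sample")
    h = norm.hours
    T = norm.temperature
    h_rel = h - h[0]
    T_anchor = T[0]
    q = f.q10.value(T)
    pred = np.power(q, 0.1 * (T - T_anchor))
    if f.decline.enabled:
        from .models import decline_fraction

        pred = pred * decline_fraction(h_rel, f.decline)
    return pd.DataFrame(
        {"h": h, "h_rel": h_rel, "temperature_C": T,
         "observed": norm.respiration, "predicted": pred}
    )


@dataclass
class OneToOneStats:
    slope: float
    intercept: float
    r2: float
    p: float
    rmse: float
    n: int


def one_to_one_stats(pred, obs, exclude_first: bool = True) -> OneToOneStats:
    """OLS regression of predicted on observed normalized respiration.

    The first point of the night is excluded by default, being 1 by
    construction. RMSE is the root-mean-square of ``pred - obs`` (departure
    from the one-to-one line), not the regression residual.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if exclude_first:
        pred, obs = pred[1:], obs[1:]
    if pred.size < 3:
        raise ValueError("need at least three paired points after exclusion")
    if np.var(obs) == 0:
        raise ValueError("observed series has zero variance")
    res = stats.linregress(obs, pred)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return OneToOneStats(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue**2), p=float(res.pvalue),
                         rmse=rmse, n=pred.size)


def standardized_residuals(pred, obs, df: int | None = None) -> np.ndarray:
    """Standardized residuals of a model run against observations.

    ``S_i = (pred_i/pred_0 - obs_i/obs_0) / sqrt(sum_i r_i^2 / df)`` where
    both series are renormalized to their first element and ``df`` defaults
    to N - 1 (one constraint: the shared unit anchor). A perfect prediction
    returns an all-zero series.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size or pred.size < 2:
        raise ValueError("need two aligned series of length >= 2")
    r = pred / pred[0] - obs / obs[0]
    if df is None:
        df = pred.size - 1
    scale = np.sqrt(np.sum(r**2) / df)
    if scale == 0:
        return np.zeros_like(r)
    return r / scale


@dataclass
class TaylorStats:
    """The Taylor-diagram triple for one model run."""

    correlation: float
    sd_ratio: float          # sigma_pred / sigma_obs
    crmse: float             # centered pattern RMS difference


def taylor_stats(pred, obs) -> TaylorStats:
    """Pearson correlation, SD ratio and centered RMS difference.

    Population (ddof = 0) standard deviations, so the Taylor identity
    ``crmse^2 = sd_p^2 + sd_o^2 - 2 sd_p sd_o r`` holds exactly.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least three points")
    sd_p, sd_o = pred.std(), obs.std()
    if sd_p == 0 or sd_o == 0:
        raise ValueError("zero variance in one of the series")
    r = float(np.corrcoef(pred, obs)[0, 1])
    crmse = float(np.sqrt(np.mean(((pred - pred.mean()) - (obs - obs.mean())) ** 2)))
    return TaylorStats(correlation=r, sd_ratio=float(sd_p / sd_o), crmse=crmse)


@dataclass
class EvalReport:
    """Per-formulation evaluation of one trace (or pooled traces)."""

    one_to_one: dict[str, OneToOneStats]
    taylor: dict[str, TaylorStats]
    residuals: dict[str, np.ndarray]

    def to_dict(self) -> dict:
        return {
            name: {
                **asdict(self.one_to_one[name]),
                "taylor": asdict(self.taylor[name]),
            }
            for name in self.one_to_one
        }


def evaluate_trace(obs: Trace, formulations=FORMULATIONS,
                   exclusion_min: float = 0.0) -> EvalReport:
    """Run every formulation on one observed trace and collect statistics."""
    o2o, taylor, residuals = {}, {}, {}
    for f in formulations:
        sim = simulate_trace(obs, f, exclusion_min)
        o2o[f.name] = one_to_one_stats(sim["predicted"], sim["observed"])
        taylor[f.name] = taylor_stats(sim["predicted"], sim["observed"])
        residuals[f.name] = standardized_residuals(
            sim["predicted"].to_numpy(), sim["observed"].to_numpy()
        )
    return EvalReport(one_to_one=o2o, taylor=taylor, residuals=residuals)
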