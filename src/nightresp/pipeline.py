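"""Data-analysis pipeline for nocturnal basal-respiration decline.

Implements the chain normalization → hourly binning → replicate/species
aggregation → SEM-weighted power-law fit, plus the slope statistics used to
test whether groups of species (lab vs field, tree vs herbaceous, temperate
vs tropical) share a common decline: log-linearized slopes, Welch two-sample
t-tests, and Bonferroni-corrected pairwise slope comparisons.

The universal model fitted here is ``R_To / R_To-initial = 1 - a h^b`` with
the intercept pinned at 1 by the functional form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trace import Trace

__all__ = [
    "EmptyTraceError",
    "FitError",
    "SpeciesAggregate",
    "PowerLawFit",
    "SlopeEstimate",
    "WelchResult",
    "PairwiseSlopeResult",
    "normalize_trace",
    "bin_hourly",
    "aggregate_species",
    "species_aggregates",
    "fit_power_law",
    "linearize_and_slope",
    "welch_test",
    "pairwise_slope_tests",
    "filter_top_initial",
]

#: Offset added inside the log when linearizing 1 - ratio (guards ratio = 1).
LINEARIZE_EPS = 1e-6


class EmptyTraceError(ValueError):
    """No sample qualifies as the normalization basis."""


class FitError(RuntimeError):
    """The nonlinear fit failed to converge; carries solver diagnostics."""


def normalize_trace(t: Trace, exclusion_min: float = 30.0) -> Trace:
    """Normalize a trace to its initial basal rate.

    The basis ``R_To-initial`` is the first sample at or after
    ``exclusion_min`` minutes of darkness (the exclusion window discards any
    light-enhanced dark respiration transient); earlier samples are dropped
    and the remaining series is divided by the basis, so the first retained
    ratio is exactly 1.
    """
    h = t.hours
    keep = h * 60.0 >= exclusion_min - 1e-9
    if not keep.any():
        raise EmptyTraceError(
            f"trace {t.species}/{t.replicate}: no sample at or after "
            f"{exclusion_min} min of darkness"
        )
    samples = t.samples.loc[keep].reset_index(drop=True)
    basis = float(samples["respiration"].iloc[0])
    samples = samples.assign(respiration=samples["respiration"] / basis)
    return t.with_samples(samples, normalized=True, r_initial=basis)


def bin_hourly(t: Trace) -> pd.DataFrame:
    """Per-replicate hourly means of the normalized ratio.

    Bin ``k`` covers ``h in [k, k+1)``. Returns a frame with the bin index
    ``k``, the empirical mean hour ``h`` of the samples in the bin (the
    abscissa later used for fitting), the mean ratio and the sample count;
    empty bins are omitted.
    """
    if not t.normalized:
        raise ValueError("bin_hourly expects a normalized (ratio) trace")
    if len(t) == 0:
        raise EmptyTraceError("empty ratio trace")
    df = t.samples
    k = np.floor(df["hours"].to_numpy(dtype=float)).astype(int)
    grouped = (
        df.assign(k=k)
        .groupby("k")
        .agg(h=("hours", "mean"), ratio=("respiration", "mean"), n=("respiration", "size"))
        .reset_index()
    )
    return grouped


@dataclass
class SpeciesAggregate:
    """Hourly-binned mean ratio ± SEM for one species.

    ``bins`` columns: ``k`` (hour bin), ``h`` (mean hour), ``ratio`` (mean
    across replicates of replicate-level hourly means), ``sem`` (standard
    error of that mean; 0 for a single replicate), ``n`` (replicate count).
    """

    species: str
    bins: pd.DataFrame
    condition: str = "lab"
    growth_form: str = "tree"
    biome: str = "temperate"


def aggregate_species(replicate_bins: list[pd.DataFrame], species: str = "",
                      condition: str = "lab", growth_form: str = "tree",
                      biome: str = "temperate") -> SpeciesAggregate:
    """Combine per-replicate hourly means into species-level bins.

    Within each hour bin the species mean is the unweighted mean of the
    replicate means, SEM = sd / sqrt(n) over replicates (0 when only one
    replicate contributes), and ``n`` is the replicate count.
    """
    if not replicate_bins:
        raise ValueError("need at least one replicate")
    stacked = pd.concat(replicate_bins, ignore_index=True)
    agg = (
        stacked.groupby("k")
        .agg(
            h=("h", "mean"),
            ratio=("ratio", "mean"),
            sd=("ratio", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n=("ratio", "size"),
        )
        .reset_index()
    )
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    agg = agg.drop(columns="sd")[["k", "h", "ratio", "sem", "n"]]
    return SpeciesAggregate(species=species, bins=agg, condition=condition,
                            growth_form=growth_form, biome=biome)


def species_aggregates(traces: list[Trace], exclusion_min: float = 0.0) -> list[SpeciesAggregate]:
    """Full normalize → bin → aggregate chain, grouped by species."""
    by_species: dict[str, list[Trace]] = {}
    for t in traces:
        by_species.setdefault(t.species, []).append(t)
    out = []
    for species, group in by_species.items():
        bins = [bin_hourly(normalize_trace(t, exclusion_min)) for t in group]
        first = group[0]
        out.append(
            aggregate_species(bins, species=species, condition=first.condition,
                              growth_form=first.growth_form, biome=first.biome)
        )
    return out


@dataclass
class PowerLawFit:
    """Weighted least-squares estimate of the decline ``1 - a h^b``."""

    a: float
    b: float
    cov: np.ndarray           # 2x2 parameter covariance
    r2: float
    n: int
    dof: int
    weighted: bool

    def predict(self, h):
        h = np.asarray(h, dtype=float)
        return 1.0 - self.a * np.power(h, self.b)

    def param_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Per-parameter confidence intervals from the covariance."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.dof)
        se_a, se_b = np.sqrt(np.diag(self.cov))
        return {
            "a": (self.a - tcrit * se_a, self.a + tcrit * se_a),
            "b": (self.b - tcrit * se_b, self.b + tcrit * se_b),
        }

    def confidence_band(self, h, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Delta-method confidence band of the fitted curve over ``h``."""
        h = np.asarray(h, dtype=float)
        hb = np.power(h, self.b)
        with np.errstate(divide="ignore", invalid="ignore"):
            logh = np.where(h > 0, np.log(h), 0.0)
        # gradient of f = 1 - a h^b w.r.t. (a, b)
        J = np.stack([-hb, -self.a * hb * logh], axis=-1)
        var = np.einsum("...i,ij,...j->...", J, self.cov, J)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.dof)
        center = self.predict(h)
        half = tcrit * np.sqrt(np.maximum(var, 0.0))
        return center - half, center + half


def _pool_bins(aggregates) -> pd.DataFrame:
    if isinstance(aggregates, SpeciesAggregate):
        aggregates = [aggregates]
    frames = [a.bins[["h", "ratio", "sem"]] for a in aggregates]
    return pd.concat(frames, ignore_index=True)


def fit_power_law(aggregates, weighted: bool = True) -> PowerLawFit:
    """Fit ``1 - a h^b`` to pooled species-level hourly bins.

    Minimizes ``sum_i w_i (y_i - (1 - a h_i^b))^2`` with ``w_i = 1/SEM_i``
    (or 1 when unweighted). Bins with SEM = 0 — single replicates — receive
    the largest finite weight present, so they never dominate with an
    infinite weight. The parameter covariance is scaled by the reduced
    chi-square, and ``r2`` is computed on the weighted residuals.
    """
    pooled = _pool_bins(aggregates)
    h = pooled["h"].to_numpy(dtype=float)
    y = pooled["ratio"].to_numpy(dtype=float)
    if len(np.unique(np.floor(h))) < 3:
        raise FitError("need at least three distinct hour bins")
    if weighted:
        sem = pooled["sem"].to_numpy(dtype=float)
        pos = sem[sem > 0]
        sem_eff = np.where(sem > 0, sem, pos.min() if pos.size else 1.0)
        w = 1.0 / sem_eff
    else:
        w = np.ones_like(y)

    def model(hh, a, b):
        return 1.0 - a * np.power(hh, b)

    try:
        # curve_fit weights squared residuals by 1/sigma^2; sigma = sqrt(SEM)
        # realises the prescribed w = 1/SEM weighting.
        popt, pcov = optimize.curve_fit(
            model, h, y, p0=(0.05, 0.5), sigma=1.0 / np.sqrt(w),
            absolute_sigma=False, bounds=([0.0, 1e-3], [1.0, 3.0]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"power-law fit did not converge: {exc}") from exc
    a, b = popt
    resid = y - model(h, a, b)
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    n = len(y)
    return PowerLawFit(a=float(a), b=float(b), cov=np.asarray(pcov), r2=r2,
                       n=n, dof=max(n - 2, 1), weighted=weighted)


@dataclass
class SlopeEstimate:
    """OLS slope of the log-linearized decline for one species."""

    slope: float
    se: float
    n: int


def linearize_and_slope(agg: SpeciesAggregate) -> SlopeEstimate:
    """Log-linearize the species decline and return its slope.

    Regresses ``log(1 - ratio + eps)`` on ``log(h)`` over bins with ``h > 0``
    (eps = 1e-6 guards ratio = 1). For an exact power-law decline the slope
    equals the exponent ``b``. Bins with ratio > 1 (no decline signal) are
    filtered with a warning.
    """
    bins = agg.bins
    h = bins["h"].to_numpy(dtype=float)
    ratio = bins["ratio"].to_numpy(dtype=float)
    keep = h > 0
    depth = 1.0 - ratio + LINEARIZE_EPS
    bad = keep & (depth <= 0)
    if bad.any():
        warnings.warn(
            f"{agg.species}: dropped {int(bad.sum())} bins with ratio >= 1",
            RuntimeWarning,
            stacklevel=2,
        )
    keep &= depth > 0
    if keep.sum() < 3:
        raise ValueError("need at least three usable bins for the slope")
    res = stats.linregress(np.log(h[keep]), np.log(depth[keep]))
    return SlopeEstimate(slope=float(res.slope), se=float(res.stderr), n=int(keep.sum()))


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(slopes_a, slopes_b) -> WelchResult:
    """Welch two-sample t-test with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two slopes")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("both groups have zero variance but different means")
    sa2, sb2 = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


@dataclass
class PairwiseSlopeResult:
    """Bonferroni-corrected pairwise slope comparison summary."""

    m: int                    # number of comparisons
    n_significant: int
    alpha: float
    table: pd.DataFrame       # one row per comparison


def pairwise_slope_tests(slopes, ses, ns, groups: dict[str, list] | None = None,
                         alpha: float = 0.05) -> PairwiseSlopeResult:
    """Pairwise two-sample t-tests between species slopes.

    Each pair is compared with ``t = (s_i - s_j) / sqrt(SE_i^2 + SE_j^2)``
    on ``df = n_i + n_j - 4`` (two slopes and two intercepts estimated).
    When ``groups`` maps grouping names (e.g. condition, growth form, biome)
    to per-species labels, only pairs sharing a label within each grouping
    are compared and the Bonferroni correction uses the total comparison
    count ``m`` across all groupings; without ``groups`` all pairs are
    compared once.
    """
    slopes = np.asarray(slopes, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = slopes.size
    if k < 2:
        raise ValueError("need at least two slope series")

    pairs: list[tuple[str, int, int]] = []
    if groups is None:
        pairs = [("all", i, j) for i in range(k) for j in range(i + 1, k)]
    else:
        for gname, labels in groups.items():
            labels = np.asarray(labels)
            if labels.size != k:
                raise ValueError(f"grouping {gname!r} has wrong length")
            for level in pd.unique(labels):
                idx = np.flatnonzero(labels == level)
                pairs.extend(
                    (f"{gname}:{level}", int(i), int(j))
                    for a_, i in enumerate(idx) for j in idx[a_ + 1:]
                )
    m = len(pairs)
    rows = []
    for label, i, j in pairs:
        se = math.sqrt(ses[i] ** 2 + ses[j] ** 2)
        df = int(ns[i] + ns[j] - 4)
        t = (slopes[i] - slopes[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
        rows.append((label, i, j, t, df, p, p < alpha / m))
    table = pd.DataFrame(rows, columns=["group", "i", "j", "t", "df", "p", "significant"])
    return PairwiseSlopeResult(m=m, n_significant=int(table["significant"].sum()),
                               alpha=alpha, table=table)


def filter_top_initial(traces: list[Trace], fraction: float = 0.10) -> list[Trace]:
    """Retain the nights whose initial signal is in the top ``fraction``.

    Used for noisy whole-tree chamber data: nights are ranked by their first
    respiration sample and the strongest ``max(1, floor(fraction * n))``
    nights are kept (62 nights at 10% → 6 retained).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = max(1, math.floor(fraction * len(traces)))
    ranked = sorted(traces, key=lambda t: t.respiration[0], reverse=True)
    return ranked[:n_keep]
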