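"""CSV trace tables, YAML run configuration and JSON reports.

One canonical trace schema serves both leaf and whole-tree data (a ``scale``
column distinguishes them). Hours since darkness onset are derived from the
timestamps: the first sample of each replicate marks the onset of darkness.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import DeclineParams, JulesRespParams, Q10Spec
from .pipeline import PowerLawFit
from .trace import Trace

__all__ = [
    "TraceValidationError",
    "RunConfig",
    "read_traces",
    "write_traces",
    "load_config",
    "fit_report",
    "write_fit_report",
]

TRACE_COLUMNS = [
    "timestamp", "species", "replicate", "condition", "growth_form",
    "biome", "scale", "temperature_C", "respiration_umol_m2_s",
]


class TraceValidationError(ValueError):
    """A trace table violates the schema; the message names the row."""


def write_traces(traces: list[Trace], path) -> None:
    """Write traces to the canonical CSV dialect (UTF-8, comma, header)."""
    frames = []
    for t in traces:
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(t.samples["timestamp"]).dt.strftime(
                    "%Y-%m-%dT%H:%M:%S"
                ),
                "species": t.species,
                "replicate": t.replicate,
                "condition": t.condition,
                "growth_form": t.growth_form,
                "biome": t.biome,
                "scale": t.scale,
                "temperature_C": t.samples["temperature_C"].astype(float),
                "respiration_umol_m2_s": t.samples["respiration"].astype(float),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def read_traces(path) -> list[Trace]:
    """Read the canonical trace CSV back into :class:`Trace` objects.

    Hours since darkness onset are recomputed from the timestamps relative
    to each replicate's first sample. Validation failures (missing column,
    nonpositive respiration, unordered timestamps) raise
    :class:`TraceValidationError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceValidationError(f"{path}: missing columns {missing}")
    bad = df.index[df["respiration_umol_m2_s"] <= 0]
    if len(bad):
        raise TraceValidationError(
            f"{path}: nonpositive respiration at row {int(bad[0]) + 2}"
        )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    traces = []
    for (species, replicate), g in df.groupby(["species", "replicate"], sort=True):
        ts = g["timestamp"].reset_index(drop=True)
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            row = int(g.index[0]) + 2
            raise TraceValidationError(
                f"{path}: unordered timestamps in {species}/{replicate} "
                f"(first row {row})"
            )
        hours = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
        samples = pd.DataFrame(
            {
                "timestamp": ts,
                "hours": hours,
                "temperature_C": g["temperature_C"].to_numpy(dtype=float),
                "respiration": g["respiration_umol_m2_s"].to_numpy(dtype=float),
            }
        )
        first = g.iloc[0]
        traces.append(
            Trace(samples=samples, species=str(species), replicate=str(replicate),
                  condition=str(first["condition"]), growth_form=str(first["growth_form"]),
                  biome=str(first["biome"]), scale=str(first["scale"]))
        )
    return traces


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML document."""

    q10: Q10Spec = dataclasses.field(default_factory=Q10Spec)
    decline: DeclineParams = dataclasses.field(default_factory=DeclineParams)
    resp: JulesRespParams = dataclasses.field(default_factory=JulesRespParams)
    generator: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


def _build(dc_cls, mapping: dict, where: str):
    known = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config section {where!r}")
    return dc_cls(**mapping)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys reject."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"q10", "decline", "resp", "generator", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
    return RunConfig(
        q10=_build(Q10Spec, raw.get("q10", {}), "q10"),
        decline=_build(DeclineParams, raw.get("decline", {}), "decline"),
        resp=_build(JulesRespParams, raw.get("resp", {}), "resp"),
        generator=dict(raw.get("generator", {})),
        seed=int(raw.get("seed", 0)),
    )


def fit_report(fit: PowerLawFit) -> dict:
    """JSON-serialisable report of a power-law fit."""
    ci = fit.param_ci()
    return {
        "a": fit.a,
        "b": fit.b,
        "cov": np.asarray(fit.cov).tolist(),
        "r2": fit.r2,
        "n": fit.n,
        "dof": fit.dof,
        "weighted": fit.weighted,
        "ci95": {"a": list(ci["a"]), "b": list(ci["b"])},
    }


def write_fit_report(fit: PowerLawFit, path) -> None:
    Path(path).write_text(json.dumps(fit_report(fit), indent=2) + "\n")
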