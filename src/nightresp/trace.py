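"""The :class:`Trace` container — one replicate's night of measurements.

A trace is the raw unit of every analysis in the package: an ordered series
of (timestamp, hours since darkness onset, temperature, respiration) samples
from a single leaf or whole-tree replicate, tagged with species and
measurement metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Trace", "SAMPLE_COLUMNS"]

SAMPLE_COLUMNS = ["timestamp", "hours", "temperature_C", "respiration"]

_CONDITIONS = ("lab", "field")
_GROWTH_FORMS = ("tree", "herbaceous")
_BIOMES = ("temperate", "tropical")
_SCALES = ("leaf", "tree")


@dataclass(eq=False)  # identity comparison; DataFrames have no scalar ==
class Trace:
    """One replicate-night of respiration measurements.

    ``samples`` holds columns ``timestamp`` (datetime), ``hours`` (h since
    onset of darkness / sunset), ``temperature_C`` and ``respiration``
    (µmol CO2 m⁻² s⁻¹ for leaves, µmol CO2 tree⁻¹ s⁻¹ for whole trees;
    efflux positive). After :func:`nightresp.pipeline.normalize_trace` the
    ``respiration`` column holds dimensionless ratios and ``normalized`` is
    True.
    """

    samples: pd.DataFrame
    species: str
    replicate: str
    condition: str = "lab"
    growth_form: str = "tree"
    biome: str = "temperate"
    scale: str = "leaf"
    normalized: bool = False
    r_initial: float | None = None  # normalization basis, set by normalize_trace

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"trace samples missing columns {missing}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")
        if self.growth_form not in _GROWTH_FORMS:
            raise ValueError(f"growth_form must be one of {_GROWTH_FORMS}")
        if self.biome not in _BIOMES:
            raise ValueError(f"biome must be one of {_BIOMES}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")
        ts = pd.to_datetime(self.samples["timestamp"])
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        h = np.asarray(self.samples["hours"], dtype=float)
        if np.any(h < 0):
            raise ValueError("hours since darkness onset must be >= 0")
        r = np.asarray(self.samples["respiration"], dtype=float)
        if np.any(r <= 0):
            raise ValueError("respiration must be positive (efflux convention)")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def hours(self) -> np.ndarray:
        return np.asarray(self.samples["hours"], dtype=float)

    @property
    def temperature(self) -> np.ndarray:
        return np.asarray(self.samples["temperature_C"], dtype=float)

    @property
    def respiration(self) -> np.ndarray:
        return np.asarray(self.samples["respiration"], dtype=float)

    def with_samples(self, samples: pd.DataFrame, **changes) -> "Trace":
        """Copy of this trace with new samples (metadata preserved)."""
        return replace(self, samples=samples.reset_index(drop=True), **changes)
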