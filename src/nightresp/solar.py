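"""Sunrise/sunset times from standard solar geometry.

Solar declination follows the simple cosine approximation
``delta = -23.44 deg * cos(2*pi*(doy + 10)/365)`` and the day half-length
comes from the hour-angle relation ``cos H = -tan(phi) tan(delta)``. Polar
night/day clamp to 24 h / 0 h of darkness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SunTimes", "sun_times"]


@dataclass(frozen=True)
class SunTimes:
    """Local solar sunrise/sunset (hours, 0-24) and night length (h)."""

    sunrise: float
    sunset: float
    night_length: float


def sun_times(latitude: float, day_of_year: int) -> SunTimes:
    """Sunrise, sunset and night length at ``latitude`` on ``day_of_year``.

    Times are local solar time; solar noon is 12:00 exactly. For polar day
    the night length clamps to 0 h (sunrise 0, sunset 24); for polar night
    it clamps to 24 h (sunrise = sunset = 12).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90] degrees")
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (day_of_year + 10) / 365.0)
    phi = np.deg2rad(latitude)
    cos_h = -np.tan(phi) * np.tan(decl)
    if cos_h <= -1.0:  # polar day
        return SunTimes(sunrise=0.0, sunset=24.0, night_length=0.0)
    if cos_h >= 1.0:  # polar night
        return SunTimes(sunrise=12.0, sunset=12.0, night_length=24.0)
    half_day = np.rad2deg(np.arccos(cos_h)) / 15.0  # hours
    return SunTimes(
        sunrise=12.0 - half_day,
        sunset=12.0 + half_day,
        night_length=24.0 - 2.0 * half_day,
    )
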