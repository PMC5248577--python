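"""Sunrise/sunset geometry and the sun-time transformation.

Camera-trap activity records are clock times; comparing activity across
seasons and species requires mapping them onto a circle anchored to the
solar day. This module computes sunrise and sunset from the standard
solar-position equations (NOAA formulation, zenith 90.833 deg, accurate
to about +/-2 minutes at mid latitudes) and provides the double-anchored
"sun time" transformation: sunrise maps to pi/2, sunset to 3*pi/2, with
linear interpolation inside the day and night segments. Solar midnight
is 0 (== 2*pi) and solar noon is pi.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

__all__ = ["SolarAnchors", "sun_events", "to_sun_time", "from_sun_time"]

_ZENITH_DEG = 90.833  # official sunrise/sunset: refraction + solar radius


@dataclass(frozen=True)
class SolarAnchors:
    """Sunrise/sunset for one date and location, in local clock hours."""

    date: _dt.date
    sunrise: float  # decimal hours, local time
    sunset: float
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not self.sunrise < self.sunset:
            raise ValueError(
                f"sunrise ({self.sunrise:.3f} h) must precede sunset "
                f"({self.sunset:.3f} h) on {self.date}"
            )

    @property
    def day_length(self) -> float:
        """Daylight duration in hours."""
        return self.sunset - self.sunrise

    @property
    def night_length(self) -> float:
        return 24.0 - self.day_length


def _fractional_year(date: _dt.date, hour: float = 12.0) -> float:
    doy = date.timetuple().tm_yday
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)

def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )

def _solar_declination(gamma: float) -> float:
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def sun_events(
    date: _dt.date,
    latitude: float,
    longitude: float,
    utc_offset: float = -7.0,
) -> SolarAnchors:
    """Sunrise and sunset (local clock hours) for a date and location.

    Parameters
    ----------
    date : datetime.date
    latitude, longitude : float
        Decimal degrees; longitude positive east.
    utc_offset : float
        Local offset from UTC in hours (default -7, local standard time
        of the Sonora study region).

    Raises
    ------
    ValueError
        If the sun never rises or never sets (polar day/night) — cannot
        occur at the mid-latitudes this package targets.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of range")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude} out of range")

    gamma = _fractional_year(date)
    eqtime = _equation_of_time_min(gamma)
    decl = _solar_declination(gamma)
    lat = np.deg2rad(latitude)

    cos_ha = np.cos(np.deg2rad(_ZENITH_DEG)) / (np.cos(lat) * np.cos(decl)) - np.tan(
        lat
    ) * np.tan(decl)
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            f"no sunrise/sunset on {date} at latitude {latitude} (polar day/night)"
        )
    ha_deg = np.rad2deg(np.arccos(cos_ha))

    # minutes UTC; longitude positive east
    sunrise_utc = 720.0 - 4.0 * (longitude + ha_deg) - eqtime
    sunset_utc = 720.0 - 4.0 * (longitude - ha_deg) - eqtime
    sunrise = (sunrise_utc / 60.0 + utc_offset) % 24.0
    sunset = (sunset_utc / 60.0 + utc_offset) % 24.0
    return SolarAnchors(date, sunrise, sunset, latitude, longitude)


def to_sun_time(clock_hours, anchors: SolarAnchors):
    """Map local clock time to sun-time radians in [0, 2*pi).

    Sunrise maps to pi/2 and sunset to 3*pi/2; times inside the day
    segment are interpolated linearly across [pi/2, 3*pi/2] and times in
    the night segment across [3*pi/2, 5*pi/2) (mod 2*pi), so the night
    midpoint lands at 0 regardless of season.
    """
    t = np.asarray(clock_hours, dtype=float) % 24.0
    day_len = anchors.day_length
    night_len = anchors.night_length
    in_day = (t >= anchors.sunrise) & (t <= anchors.sunset)
    theta_day = np.pi / 2 + np.pi * (t - anchors.sunrise) / day_len
    dt_night = (t - anchors.sunset) % 24.0
    theta_night = 3 * np.pi / 2 + np.pi * dt_night / night_len
    theta = np.where(in_day, theta_day, theta_night) % (2 * np.pi)
    if np.isscalar(clock_hours):
        return float(theta)
    return theta


def from_sun_time(theta, anchors: SolarAnchors):
    """Inverse of :func:`to_sun_time`: sun-time radians to clock hours."""
    th = np.asarray(theta, dtype=float) % (2 * np.pi)
    in_day = (th >= np.pi / 2) & (th <= 3 * np.pi / 2)
    t_day = anchors.sunrise + (th - np.pi / 2) / np.pi * anchors.day_length
    dth = (th - 3 * np.pi / 2) % (2 * np.pi)
    t_night = (anchors.sunset + dth / np.pi * anchors.night_length) % 24.0
    t = np.where(in_day, t_day, t_night)
    if np.isscalar(theta):
        return float(t)
    return t
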