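"""Sunrise/sunset via the NOAA solar-geometry equations.

The rest-phase analysis window runs from sunrise to 30 min before sunset, so
the only solar quantities needed are rise and set times at a tropical study
site.  This implements the NOAA solar-calculator equations (geometric mean
longitude/anomaly, equation of time, declination, hour angle at zenith
90.833° to include standard refraction), accurate to well under a minute at
tropical and temperate latitudes.
"""

from __future__ import annotations

import datetime as dt
import math

_ZENITH_OFFICIAL = 90.833  # degrees; accounts for refraction + solar radius


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at Julian
    century ``jc`` (from J2000.0)."""
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    eq_ctr = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + eq_ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0r = math.radians(l0)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2 * e * math.sin(mrad)
        + 4 * e * var_y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * var_y**2 * math.sin(4 * l0r)
        - 1.25 * e**2 * math.sin(2 * mrad)
    )
    return eq_time, decl


def sunrise_sunset_utc(date: dt.date, latitude: float, longitude: float) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset (UTC, naive datetimes) for a calendar date.

    Raises ``ValueError`` when the sun does not rise or set (polar day or
    night), which is outside the latitudes this package supports.
    """
    # Evaluate the slowly-varying solar parameters at local solar noon.
    jd = _julian_day(date) + 0.5 - longitude / 360.0
    jc = (jd - 2451545.0) / 36525.0
    eq_time, decl = _solar_params(jc)
    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(_ZENITH_OFFICIAL)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(
            f"sun does not rise and set at latitude {latitude} on {date} "
            "(polar day/night is out of scope)"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    noon_min = 720.0 - 4.0 * longitude - eq_time  # minutes past UTC midnight
    rise = noon_min - 4.0 * ha_deg
    sset = noon_min + 4.0 * ha_deg
    midnight = dt.datetime.combine(date, dt.time())
    return (
        midnight + dt.timedelta(minutes=rise),
        midnight + dt.timedelta(minutes=sset),
    )


def sunrise_sunset_local(
    date: dt.date, latitude: float, longitude: float, utc_offset_hours: float
) -> tuple[dt.datetime, dt.datetime]:
    """Rise/set as naive local-time datetimes at a fixed UTC offset."""
    rise, sset = sunrise_sunset_utc(date, latitude, longitude)
    off = dt.timedelta(hours=utc_offset_hours)
    return rise + off, sset + off
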