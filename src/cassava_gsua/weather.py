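"""Daily weather: stochastic generation, WTH/CSV exchange, thermal time.

The generator is a compact stand-in for observed station series: rain
occurrence follows a two-state Markov chain, rain amounts a gamma law,
temperature a (small) seasonal harmonic plus AR(1) noise, and solar
radiation is coupled to wet/dry state.  It is calibrated so that the
*growing-season* (planting day + fixed season length) means converge to
the site profile's targets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteProfile",
    "WeatherSeries",
    "generate_weather",
    "read_weather",
    "write_weather",
    "thermal_time",
]

SEASON_LENGTH = 300  # days; planting-to-harvest window used for calibration
DEFAULT_PLANTING_DOY = 115


@dataclass(frozen=True)
class SiteProfile:
    """Climate descriptors of a study site (growing-season means)."""

    name: str
    latitude: float
    longitude: float
    altitude: float
    season_mean_temp: float
    season_mean_srad: float
    season_rainfall: float
    diurnal_range: float = 10.0
    wet_day_freq: float = 0.42
    temp_amplitude: float = 1.0  # seasonal harmonic half-range, degC
    monthly_rain_mult: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.season_mean_srad <= 0:
            raise ValueError("srad must be positive")
        if not 0.0 <= self.wet_day_freq <= 1.0:
            raise ValueError("wet_day_freq must be in [0, 1]")
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be positive")


class WeatherSeries:
    """Contiguous daily weather records for one site."""

    def __init__(self, site: SiteProfile, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        required = {"date", "tmax", "tmin", "srad", "rain"}
        if not required.issubset(frame.columns):
            raise ValueError(f"weather frame needs columns {sorted(required)}")
        if len(frame) == 0:
            raise ValueError("empty weather series")
        dates = pd.to_datetime(frame["date"])
        gaps = dates.diff().dropna()
        if not (gaps == pd.Timedelta(days=1)).all():
            bad = int(np.argmax((gaps != pd.Timedelta(days=1)).to_numpy()) + 1)
            raise ValueError(f"non-contiguous dates at row {bad}")
        bad_rows = np.nonzero((frame["tmax"] < frame["tmin"]).to_numpy())[0]
        if bad_rows.size:
            raise ValueError(f"tmax < tmin at row {bad_rows[0]}")
        if (frame["rain"] < 0).any() or (frame["srad"] < 0).any():
            raise ValueError("negative rain or srad")
        self.site = site
        self.frame = frame.assign(date=dates)

    def __len__(self) -> int:
        return len(self.frame)

    def arrays(self) -> dict[str, np.ndarray]:
        f = self.frame
        return {
            "tmax": f["tmax"].to_numpy(float),
            "tmin": f["tmin"].to_numpy(float),
            "srad": f["srad"].to_numpy(float),
            "rain": f["rain"].to_numpy(float),
        }

    def index_of(self, year: int, doy: int) -> int:
        """Row index of a (year, day-of-year) pair; raises if absent."""
        target = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
        d0 = self.frame["date"].iloc[0].date()
        idx = (target - d0).days
        if idx < 0 or idx >= len(self.frame):
            raise KeyError(f"{target} not covered by series")
        return idx

    def season_stats(
        self, planting_doy: int = DEFAULT_PLANTING_DOY, season_length: int = SEASON_LENGTH
    ) -> pd.DataFrame:
        """Per-season mean temperature/srad and rainfall total."""
        rows = []
        years = sorted(self.frame["date"].dt.year.unique())
        for year in years:
            try:
                i0 = self.index_of(year, planting_doy)
            except KeyError:
                continue
            i1 = i0 + season_length
            if i1 > len(self.frame):
                continue
            chunk = self.frame.iloc[i0:i1]
            rows.append(
                {
                    "year": year,
                    "mean_temp": float((chunk["tmax"] + chunk["tmin"]).mean() / 2),
                    "mean_srad": float(chunk["srad"].mean()),
                    "rainfall": float(chunk["rain"].sum()),
                }
            )
        return pd.DataFrame(rows)


def thermal_time(tmax, tmin, tbase):
    """Daily thermal time: max(0, (tmax + tmin)/2 - tbase), degC-day."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    out = np.maximum(0.0, (tmax + tmin) / 2.0 - np.asarray(tbase, dtype=float))
    return out if out.ndim else float(out)


def generate_weather(
    profile: SiteProfile,
    n_years: int,
    seed: int | None = None,
    start_year: int = 2000,
    planting_doy: int = DEFAULT_PLANTING_DOY,
) -> WeatherSeries:
    """Generate ``n_years`` calendar years of daily weather for a site.

    Calibrated so the mean over growing seasons (``planting_doy`` +
    300 d) matches the profile's temperature, radiation, and rainfall
    targets in expectation.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(
        start=dt.date(start_year, 1, 1), end=dt.date(start_year + n_years - 1, 12, 31)
    )
    ndays = len(dates)
    doy = dates.dayofyear.to_numpy()

    # seasonal harmonic centred so its mean over the season window is zero
    phase = 2.0 * np.pi * (doy - 15) / 365.25
    harmonic = profile.temp_amplitude * np.cos(phase)
    window = np.arange(planting_doy, planting_doy + SEASON_LENGTH)
    w_phase = 2.0 * np.pi * (window - 15) / 365.25
    harmonic -= profile.temp_amplitude * float(np.mean(np.cos(w_phase)))

    # AR(1) temperature noise
    phi, sig = 0.7, 1.4
    eps = rng.normal(0.0, sig * np.sqrt(1 - phi**2), size=ndays)
    noise = np.empty(ndays)
    noise[0] = eps[0] / np.sqrt(1 - phi**2)
    for t in range(1, ndays):
        noise[t] = phi * noise[t - 1] + eps[t]
    tmean = profile.season_mean_temp + harmonic + noise

    dr = profile.diurnal_range * rng.uniform(0.85, 1.15, size=ndays)
    tmax = tmean + dr / 2.0
    tmin = tmean - dr / 2.0

    # two-state Markov rain occurrence with stationary frequency = target
    pi = profile.wet_day_freq
    p11 = min(0.95, pi + 0.4 * (1 - pi))
    p01 = np.clip(pi * (1 - p11) / max(1e-9, 1 - pi), 0.0, 1.0)
    wet = np.zeros(ndays, dtype=bool)
    u = rng.uniform(size=ndays)
    wet[0] = u[0] < pi
    for t in range(1, ndays):
        wet[t] = u[t] < (p11 if wet[t - 1] else p01)

    mean_amount = profile.season_rainfall / max(1e-9, pi * SEASON_LENGTH)
    shape = 0.9
    rain = np.where(wet, rng.gamma(shape, mean_amount / shape, size=ndays), 0.0)
    if profile.monthly_rain_mult is not None:
        mult = np.asarray(profile.monthly_rain_mult, dtype=float)
        rain = rain * mult[dates.month.to_numpy() - 1]

    # srad lower on wet days, rescaled to hit the target mean
    raw = (1.1 - 0.25 * wet.astype(float)) * (1.0 + 0.12 * rng.standard_normal(ndays))
    raw = np.maximum(raw, 0.05)
    srad = profile.season_mean_srad * raw / (1.1 - 0.25 * pi)

    frame = pd.DataFrame(
        {"date": dates, "tmax": tmax, "tmin": tmin, "srad": srad, "rain": rain}
    )
    return WeatherSeries(profile, frame)


# ---------------------------------------------------------------------------
# file exchange: DSSAT-like fixed-width WTH and a CSV dialect

_WTH_HEADER = "@DATE  SRAD  TMAX  TMIN  RAIN"


def write_weather(series: WeatherSeries, path) -> None:
    path = str(path)
    if path.endswith(".csv"):
        out = series.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        return
    site = series.site
    with open(path, "w") as fh:
        fh.write(f"*WEATHER DATA : {site.name}\n")
        fh.write("@ INSI      LAT     LONG  ELEV\n")
        fh.write(
            f"  {site.name[:4].upper():<4} {site.latitude:8.3f} {site.longitude:8.3f} "
            f"{site.altitude:5.0f}\n"
        )
        fh.write(_WTH_HEADER + "\n")
        for _, row in series.frame.iterrows():
            date = row["date"]
            stamp = f"{date.year:04d}{date.dayofyear:03d}"
            fh.write(
                f"{stamp} {row['srad']:5.1f} {row['tmax']:5.1f} {row['tmin']:5.1f} "
                f"{row['rain']:5.1f}\n"
            )


def read_weather(path, site: SiteProfile | None = None) -> WeatherSeries:
    path = str(path)
    if path.endswith(".csv"):
        frame = pd.read_csv(path)
        if site is None:
            site = _placeholder_site(path)
        return WeatherSeries(site, frame)

    with open(path) as fh:
        lines = fh.readlines()
    header_meta: dict[str, float] = {}
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("@DATE"):
            data_start = i + 1
            break
        if line.startswith("@ INSI") and i + 1 < len(lines):
            parts = lines[i + 1].split()
            if len(parts) >= 4:
                header_meta = {
                    "lat": float(parts[1]),
                    "lon": float(parts[2]),
                    "elev": float(parts[3]),
                }
    if data_start is None:
        raise ValueError("malformed WTH file: no @DATE column header")
    records = []
    for ln, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"malformed WTH record on line {ln}")
        stamp = parts[0]
        year, doy = int(stamp[:4]), int(stamp[4:])
        date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
        srad, tmax, tmin, rain = map(float, parts[1:5])
        records.append({"date": date, "tmax": tmax, "tmin": tmin, "srad": srad, "rain": rain})
    if not records:
        raise ValueError("WTH file holds no records")
    frame = pd.DataFrame(records)
    if site is None:
        site = _placeholder_site(
            path,
            latitude=header_meta.get("lat", 0.0),
            longitude=header_meta.get("lon", 0.0),
            altitude=header_meta.get("elev", 0.0),
        )
    return WeatherSeries(site, frame)


def _placeholder_site(path, latitude=0.0, longitude=0.0, altitude=0.0) -> SiteProfile:
    import os

    return SiteProfile(
        name=os.path.splitext(os.path.basename(path))[0],
        latitude=latitude,
        longitude=longitude,
        altitude=altitude,
        season_mean_temp=25.0,
        season_mean_srad=17.0,
        season_rainfall=1000.0,
    )
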