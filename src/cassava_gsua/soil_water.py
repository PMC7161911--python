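"""Tipping-bucket soil water balance and the soil-water drought factor.

All operations are vectorised over a batch dimension ``N`` (parameter
sets sharing one weather series) so that design-matrix evaluation stays
cheap; a batch of one gives scalar behaviour.

Water accounting per day: infiltration fills layers top-down to
saturation (excess is runoff), water above the drained upper limit
drains at ``drainage_rate`` per day, and root-weighted extraction meets
evaporative demand down to the lower limit.  The daily mass balance
closes exactly (float precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SoilProfile",
    "SoilWaterState",
    "load_soil_profile",
    "init_state",
    "step_water_balance",
    "drought_stress_factor",
    "priestley_taylor_et",
]


@dataclass(frozen=True)
class SoilProfile:
    """Layered profile: thickness (cm) and volumetric LL/DUL/SAT per layer."""

    thickness: np.ndarray  # cm
    ll: np.ndarray
    dul: np.ndarray
    sat: np.ndarray
    drainage_rate: float = 0.4  # fraction of above-DUL water per day
    runoff_curve: float = 0.0  # 0 => runoff only above saturation

    def __post_init__(self) -> None:
        th = np.asarray(self.thickness, dtype=float)
        ll = np.asarray(self.ll, dtype=float)
        dul = np.asarray(self.dul, dtype=float)
        sat = np.asarray(self.sat, dtype=float)
        if th.size == 0:
            raise ValueError("soil profile needs at least one layer")
        if np.any(th <= 0):
            raise ValueError("layer thickness must be positive")
        if not (np.all(0 < ll) and np.all(ll < dul) and np.all(dul < sat) and np.all(sat < 1)):
            raise ValueError("require 0 < LL < DUL < SAT < 1 in every layer")
        object.__setattr__(self, "thickness", th)
        object.__setattr__(self, "ll", ll)
        object.__setattr__(self, "dul", dul)
        object.__setattr__(self, "sat", sat)

    @property
    def n_layers(self) -> int:
        return int(self.thickness.size)

    @property
    def depth_cm(self) -> float:
        return float(self.thickness.sum())

    def layer_mm(self, theta: np.ndarray) -> np.ndarray:
        """Convert volumetric content (..., L) to stored mm per layer."""
        return theta * self.thickness * 10.0


def load_soil_profile(name_or_path: str) -> SoilProfile:
    """Load a packaged profile ('cool' / 'warm') or a CSV file."""
    if name_or_path in ("cool", "warm"):
        text = (
            resources.files("cassava_gsua")
            .joinpath(f"data/soil_{name_or_path}.csv")
            .read_text()
        )
        import io

        frame = pd.read_csv(io.StringIO(text))
    else:
        frame = pd.read_csv(name_or_path)
    return SoilProfile(
        thickness=frame["thickness_cm"].to_numpy(float),
        ll=frame["ll"].to_numpy(float),
        dul=frame["dul"].to_numpy(float),
        sat=frame["sat"].to_numpy(float),
    )


@dataclass
class SoilWaterState:
    """Batched state: volumetric content, shape (N, n_layers)."""

    theta: np.ndarray
    cum_drainage: np.ndarray  # mm, shape (N,)
    cum_runoff: np.ndarray  # mm, shape (N,)


def init_state(profile: SoilProfile, n: int = 1) -> SoilWaterState:
    """State at field capacity (water content = DUL in every layer)."""
    theta = np.tile(profile.dul, (n, 1)).astype(float)
    return SoilWaterState(theta, np.zeros(n), np.zeros(n))


def step_water_balance(
    state: SoilWaterState,
    profile: SoilProfile,
    rain: float,
    et_demand: np.ndarray | float,
    root_depth_cm: float | None = None,
) -> dict[str, np.ndarray]:
    """Advance one day; mutates ``state`` and returns the day's fluxes (mm).

    ``et_demand`` may be per-batch-row.  Extraction is weighted by each
    layer's share of the root zone and by its available water, and never
    draws a layer below LL.
    """
    if rain < 0:
        raise ValueError("rain must be non-negative")
    n, nl = state.theta.shape
    et = np.broadcast_to(np.asarray(et_demand, dtype=float), (n,)).copy()
    if np.any(et < 0):
        raise ValueError("et_demand must be non-negative")

    th_mm = profile.thickness * 10.0  # per-layer depth in mm of soil
    cap_sat = profile.sat * th_mm
    cap_dul = profile.dul * th_mm
    floor_ll = profile.ll * th_mm

    water = state.theta * th_mm  # (N, L) stored mm

    # --- infiltration: fill layers top-down to saturation
    todo = np.full(n, float(rain))
    for j in range(nl):
        room = cap_sat[j] - water[:, j]
        add = np.minimum(todo, np.maximum(room, 0.0))
        water[:, j] += add
        todo -= add
    runoff = todo  # what never entered the profile

    # --- drainage: above-DUL water leaves each layer at drainage_rate,
    #     cascading into the layer below
    drain_in = np.zeros(n)
    drained = np.zeros(n)
    for j in range(nl):
        water[:, j] += drain_in
        # cascade overflow above saturation immediately
        over = np.maximum(water[:, j] - cap_sat[j], 0.0)
        water[:, j] -= over
        free = np.maximum(water[:, j] - cap_dul[j], 0.0)
        out = profile.drainage_rate * free + over
        water[:, j] -= profile.drainage_rate * free
        drain_in = out
    drained = drain_in  # what leaves the bottom layer

    # --- extraction, root-zone weighted
    if root_depth_cm is None:
        root_depth_cm = profile.depth_cm
    weights = _root_weights(profile, root_depth_cm)
    extracted = np.zeros(n)
    avail = np.maximum(water - floor_ll, 0.0) * weights  # extractable mm per layer
    total_avail = avail.sum(axis=1)
    take_total = np.minimum(et, total_avail)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_avail[:, None] > 0, avail / total_avail[:, None], 0.0)
    take = frac * take_total[:, None]
    water -= take
    extracted = take.sum(axis=1)

    state.theta = water / th_mm
    state.cum_drainage += drained
    state.cum_runoff += runoff
    return {
        "runoff": runoff,
        "drainage": drained,
        "extraction": extracted,
        "infiltration": np.full(n, float(rain)) - runoff,
    }


def _root_weights(profile: SoilProfile, root_depth_cm: float) -> np.ndarray:
    """Fraction of each layer inside the root zone."""
    tops = np.concatenate([[0.0], np.cumsum(profile.thickness)])[:-1]
    bots = np.cumsum(profile.thickness)
    inside = np.clip(root_depth_cm - tops, 0.0, profile.thickness)
    w = inside / profile.thickness
    return np.where(bots <= 0, 0.0, w)


def drought_stress_factor(
    state: SoilWaterState,
    profile: SoilProfile,
    *,
    germination: bool = False,
    sensitivity: float = 1.0,
    germination_sensitivity: float = 0.6,
    root_depth_cm: float | None = None,
) -> np.ndarray:
    """Stress factor in [0, 1] from root-zone plant-available water.

    Linear ramp: available-water fraction divided by a sensitivity
    threshold, clamped to [0, 1].  Germination uses its own threshold;
    all other processes share one.
    """
    if root_depth_cm is None:
        root_depth_cm = profile.depth_cm
    w = _root_weights(profile, root_depth_cm) * profile.thickness
    w = w / w.sum()
    theta_bar = state.theta @ w
    ll_bar = float(profile.ll @ w)
    dul_bar = float(profile.dul @ w)
    paw = (theta_bar - ll_bar) / (dul_bar - ll_bar)
    s = germination_sensitivity if germination else sensitivity
    return np.clip(paw / s, 0.0, 1.0)


def priestley_taylor_et(srad: float, tmean: float, alpha: float = 1.26) -> float:
    """Reference evapotranspiration (mm/day) from srad (MJ/m2/d) and temp."""
    es = 0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))  # kPa
    slope = 4098.0 * es / (tmean + 237.3) ** 2  # kPa/degC
    gamma = 0.0665  # psychrometric constant, kPa/degC
    rn = 0.75 * srad  # crude net radiation
    lam = 2.45  # MJ/kg latent heat
    return float(max(0.0, alpha * slope / (slope + gamma) * rn / lam))
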