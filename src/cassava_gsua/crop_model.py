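"""Daily-time-step cassava growth simulator.

The crop is represented as cohorts of nodes (leaf + internode) created
each day across all apices.  Development is driven by thermal time with
separate base temperatures for leaf processes (the GSP ``TBLSZ``) and
for branching / leaf ageing (species constants).  Assimilate follows a
spill-over rule: aboveground organs and fibrous roots are satisfied
first (reduced proportionally when supply falls short) and only the
surplus goes to storage roots, which are the harvested yield.

Everything is vectorised over a batch of parameter sets sharing one
weather series; cohort state lives in ``(N, n_days)`` arrays where the
cohort index is the day of creation.  A batch of one reproduces the
scalar single-run contract.
"""

from __future__ import annotations


from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import soil_water as sw
from .weather import WeatherSeries, thermal_time

__all__ = [
    "GSPSet",
    "SpeciesConstants",
    "Management",
    "SeasonOutputs",
    "OUTPUT_NAMES",
    "simulate_season",
    "simulate_batch",
    "leaf_appearance_rate",
    "potential_leaf_size",
    "node_growth_rate",
    "node_mass_potential",
    "daily_assimilation",
    "compute_demand",
    "allocate_spillover",
]

OUTPUT_NAMES = (
    "aboveground_biomass",
    "yield_",
    "max_lai",
    "leaves_at_harvest",
    "day_first_branch",
    "day_second_branch",
)


@dataclass(frozen=True)
class GSPSet:
    """The 16 genotype-specific parameters (scalar or per-batch arrays)."""

    B01ND: float  # degC-day to first branching
    B12ND: float  # degC-day between later branching levels
    LAXS: float  # cm2, maximum individual leaf area
    SLAS: float  # cm2/g, specific leaf area
    LLIFA: float  # degC-day of active leaf life after full expansion
    LPEFR: float  # petiole fraction of leaf (lamina+petiole) weight
    LNSLP: float  # multiplier on the leaf appearance reference curve
    NODWT: float  # g, asymptotic individual node weight
    NODL: float  # cm, internode length (geometry only)
    PARUE: float  # g/MJ radiation use efficiency
    TBLSZ: float  # degC base temperature for leaf development
    BR1F: float  # branches per fork, levels 1..4
    BR2F: float
    BR3F: float
    BR4F: float
    KCAN: float  # PAR extinction coefficient

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SpeciesConstants:
    """Species-wide constants and the functional-form coefficients that the
    model narrative leaves open.  Kept in one place so recalibration is
    a local edit."""

    leaf_size_peak_age: float = 900.0  # degC-day at which leaf size peaks
    leaf_size_f0: float = 0.2  # potential size at age 0, as fraction of LAXS
    leaf_size_decline: float = 5e-4  # exponential decline per degC-day past peak
    fibrous_fraction: float = 0.10  # fibrous-root demand per unit aboveground demand
    par_fraction: float = 0.5  # PAR fraction of global radiation
    tbase_branching: float = 13.0
    tbase_leaf_aging: float = 13.0
    appearance_r0: float = 0.025  # nodes per degC-day per apex at age 0
    appearance_halflife: float = 900.0  # degC-day scale of appearance slowdown
    node_logistic_k: float = 0.01  # per degC-day steepness of node mass curve
    node_midpoint: float = 250.0  # degC-day logistic midpoint at leaf_no = 0
    node_midpoint_per_leaf: float = 2.0  # midpoint shift per leaf already formed
    leaf_expansion_tt: float = 150.0  # degC-day from appearance to full leaf size
    germination_tt: float = 10.0  # degC-day from planting to germination
    planting_reserve: float = 6.0  # g/plant of stake reserves fueling early growth
    max_branch_level: int = 4
    root_depth_init_cm: float = 10.0
    root_growth_cm_day: float = 1.5


@dataclass(frozen=True)
class Management:
    planting_doy: int = 115
    season_length: int = 300  # days planting -> harvest
    preplant_days: int = 30  # water balance spin-up at field capacity
    density: float = 1.0  # plants per m2
    water_limited: bool = True  # False forces the stress factor to 1


@dataclass(frozen=True)
class SeasonOutputs:
    """Six end-of-season output variables.

    Branch days are censored at ``season_length`` when branching never
    happened within the season.
    """

    aboveground_biomass: float  # kg/ha dry
    yield_: float  # kg/ha storage-root dry mass
    max_lai: float
    leaves_at_harvest: float  # cumulative leaves per plant
    day_first_branch: float  # days after planting
    day_second_branch: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in OUTPUT_NAMES)


# ---------------------------------------------------------------------------
# elementary process functions (all vectorised)


def leaf_appearance_rate(crop_thermal_age, lnslp, constants: SpeciesConstants = SpeciesConstants()):
    """Nodes per degC-day per apex: saturation-decay reference curve scaled
    by LNSLP."""
    age = np.asarray(crop_thermal_age, dtype=float)
    if np.any(age < 0):
        raise ValueError("negative thermal age")
    rate = np.asarray(lnslp, dtype=float) * constants.appearance_r0 / (
        1.0 + age / constants.appearance_halflife
    )
    return rate if rate.ndim else float(rate)


def potential_leaf_size(crop_thermal_age, laxs, constants: SpeciesConstants = SpeciesConstants()):
    """Potential individual leaf area (cm2): linear ramp from f0*LAXS at
    planting to LAXS at the peak age, then exponential decline."""
    age = np.asarray(crop_thermal_age, dtype=float)
    if np.any(age < 0):
        raise ValueError("negative thermal age")
    laxs = np.asarray(laxs, dtype=float)
    peak = constants.leaf_size_peak_age
    f0 = constants.leaf_size_f0
    ramp = laxs * (f0 + (1.0 - f0) * np.minimum(age, peak) / peak)
    decline = np.exp(-constants.leaf_size_decline * np.maximum(age - peak, 0.0))
    out = ramp * decline
    return out if out.ndim else float(out)


def node_mass_potential(node_thermal_age, leaf_no_at_creation, nodwt,
                        constants: SpeciesConstants = SpeciesConstants()):
    """Cumulative potential node mass (g): logistic in node age, normalised
    so mass is 0 at age 0 and approaches NODWT asymptotically."""
    age = np.asarray(node_thermal_age, dtype=float)
    mid = constants.node_midpoint + constants.node_midpoint_per_leaf * np.asarray(
        leaf_no_at_creation, dtype=float
    )
    k = constants.node_logistic_k
    l0 = 1.0 / (1.0 + np.exp(k * mid))
    lt = 1.0 / (1.0 + np.exp(-k * (age - mid)))
    out = np.asarray(nodwt, dtype=float) * (lt - l0) / (1.0 - l0)
    return out if out.ndim else float(out)


def node_growth_rate(node_thermal_age, leaf_no_at_creation, nodwt,
                     constants: SpeciesConstants = SpeciesConstants(),
                     eps: float = 1e-4):
    """Instantaneous node growth rate (g per degC-day), central difference
    of the potential-mass logistic."""
    age = np.asarray(node_thermal_age, dtype=float)
    hi = node_mass_potential(age + eps, leaf_no_at_creation, nodwt, constants)
    lo = node_mass_potential(np.maximum(age - eps, 0.0), leaf_no_at_creation, nodwt, constants)
    span = (age + eps) - np.maximum(age - eps, 0.0)
    out = (hi - lo) / span
    return out if np.ndim(out) else float(out)


def daily_assimilation(srad, lai, parue, kcan, constants: SpeciesConstants = SpeciesConstants()):
    """Gross daily assimilate (g/m2/day): Beer-law interception x RUE."""
    srad = np.asarray(srad, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(srad < 0) or np.any(lai < 0):
        raise ValueError("negative srad or lai")
    out = (
        constants.par_fraction
        * srad
        * (1.0 - np.exp(-np.asarray(kcan, dtype=float) * lai))
        * np.asarray(parue, dtype=float)
    )
    return out if out.ndim else float(out)


def allocate_spillover(supply, leaf_demand, stem_demand, fibrous_demand):
    """Spill-over allocation.

    Returns (leaf, stem, fibrous, storage) increments: demands are met in
    full with the surplus to storage roots, or scaled by supply/demand
    with zero storage growth when supply is short.
    """
    supply = np.asarray(supply, dtype=float)
    ld = np.asarray(leaf_demand, dtype=float)
    sd = np.asarray(stem_demand, dtype=float)
    fd = np.asarray(fibrous_demand, dtype=float)
    if np.any(supply < 0) or np.any(ld < 0) or np.any(sd < 0) or np.any(fd < 0):
        raise ValueError("negative supply or demand")
    total = ld + sd + fd
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, np.minimum(1.0, supply / np.where(total > 0, total, 1.0)), 1.0)
    storage = np.maximum(supply - total, 0.0)
    out = (ld * scale, sd * scale, fd * scale, storage)
    if supply.ndim == 0:
        return tuple(float(v) for v in out)
    return out


def compute_demand(d_area_pot, d_node_pot, slas, lpefr,
                   constants: SpeciesConstants = SpeciesConstants()):
    """Organ demands (g) from potential area (cm2) and node-mass (g)
    increments: lamina mass = area/SLAS, grossed up by the petiole
    fraction; fibrous roots add 10% of the aboveground total."""
    lamina = np.asarray(d_area_pot, dtype=float) / np.asarray(slas, dtype=float)
    leaf = lamina / (1.0 - np.asarray(lpefr, dtype=float))
    stem = np.asarray(d_node_pot, dtype=float)
    fibrous = constants.fibrous_fraction * (leaf + stem)
    return leaf, stem, fibrous


# ---------------------------------------------------------------------------
# season orchestration


def _as_batch(values, n: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(values, dtype=float), (n,)).copy()


def simulate_batch(
    gsps: dict[str, np.ndarray],
    weather: WeatherSeries,
    soil: sw.SoilProfile,
    mgmt: Management = Management(),
    constants: SpeciesConstants = SpeciesConstants(),
    start_index: int | None = None,
    year: int | None = None,
) -> dict[str, np.ndarray]:
    """Simulate one season for ``N`` parameter sets sharing one weather
    window; returns arrays of the six outputs keyed by ``OUTPUT_NAMES``.

    The window starts ``mgmt.preplant_days`` before planting.  Provide
    either ``start_index`` (row of the planting day in the series) or
    ``year`` (calendar year whose ``mgmt.planting_doy`` is used).
    """
    n = max(np.size(v) for v in gsps.values())
    g = {k: _as_batch(v, n) for k, v in gsps.items()}

    if start_index is None:
        if year is None:
            start_index = mgmt.preplant_days
        else:
            start_index = weather.index_of(year, mgmt.planting_doy)
    i0 = start_index - mgmt.preplant_days
    i1 = start_index + mgmt.season_length
    if i0 < 0 or i1 > len(weather):
        raise ValueError(
            f"weather series does not cover pre-plant + season window [{i0}, {i1})"
        )
    wx = weather.arrays()
    tmax = wx["tmax"][i0:i1]
    tmin = wx["tmin"][i0:i1]
    srad = wx["srad"][i0:i1]
    rain = wx["rain"][i0:i1]
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin inside simulation window")
    tmean = (tmax + tmin) / 2.0
    ndays = i1 - i0
    p0 = mgmt.preplant_days
    nseason = mgmt.season_length

    br_f = np.stack([np.rint(g[k]) for k in ("BR1F", "BR2F", "BR3F", "BR4F")])

    # row state
    crop_age = np.zeros(n)  # degC-day, leaf-development base (TBLSZ)
    branch_tt = np.zeros(n)
    germ_tt = np.zeros(n)
    germinated = np.zeros(n, dtype=bool)
    branch_level = np.zeros(n, dtype=int)
    apex = np.ones(n)
    cum_leaves = np.zeros(n)
    day_branch = np.full((2, n), float(nseason))  # censored at harvest
    lamina_mass = np.zeros(n)
    petiole_mass = np.zeros(n)
    stem_mass = np.zeros(n)
    fibrous_mass = np.zeros(n)
    storage_mass = np.zeros(n)
    reserve = np.full(n, constants.planting_reserve)
    lai = np.zeros(n)
    max_lai = np.zeros(n)
    cum_supply = np.zeros(n)  # assimilation + reserve draw, for conservation

    # cohort state, column = day-after-planting of creation
    coh_n = np.zeros((n, nseason))
    coh_target = np.zeros((n, nseason))
    coh_area = np.zeros((n, nseason))
    coh_age = np.zeros((n, nseason))  # leaf-development degC-day since creation
    coh_exp_age = np.zeros((n, nseason))  # leaf-aging degC-day past full expansion
    coh_leafno = np.zeros((n, nseason))
    coh_live = np.zeros((n, nseason), dtype=bool)

    soil_state = sw.init_state(soil, n)
    supply_limited_days = np.zeros(n)
    trace_rows = [] if n == 1 else None

    for t in range(ndays):
        day = t - p0  # days after planting; cohorts exist for day >= 0
        # --- water balance & stress
        if mgmt.water_limited:
            stress = sw.drought_stress_factor(
                soil_state, soil, root_depth_cm=_root_depth(day, soil, constants)
            )
            germ_stress = sw.drought_stress_factor(
                soil_state, soil, germination=True,
                root_depth_cm=_root_depth(day, soil, constants),
            )
            cover = 1.0 - np.exp(-g["KCAN"] * lai)
            et0 = sw.priestley_taylor_et(srad[t], tmean[t])
            et_demand = et0 * np.maximum(cover, 0.1)  # soil evap floor
            sw.step_water_balance(
                soil_state, soil, rain[t], et_demand,
                root_depth_cm=_root_depth(day, soil, constants),
            )
        else:
            stress = np.ones(n)
            germ_stress = np.ones(n)

        if day < 0:
            continue

        # --- thermal times
        tt_leaf = np.maximum(0.0, tmean[t] - g["TBLSZ"])
        tt_branch = max(0.0, tmean[t] - constants.tbase_branching)
        tt_aging = max(0.0, tmean[t] - constants.tbase_leaf_aging)

        # --- germination
        not_germ = ~germinated
        if np.any(not_germ):
            germ_tt[not_germ] += germ_stress[not_germ] * tt_leaf[not_germ]
            germinated = germinated | (germ_tt >= constants.germination_tt)
        active = germinated
        if not np.any(active):
            continue

        crop_age = np.where(active, crop_age + tt_leaf, crop_age)
        branch_tt = np.where(active, branch_tt + tt_branch * stress, branch_tt)

        # --- branching (at most one level per day per row is plenty)
        for _ in range(constants.max_branch_level):
            thresh = g["B01ND"] + branch_level * g["B12ND"]
            fork = active & (branch_level < constants.max_branch_level) & (branch_tt >= thresh)
            if not np.any(fork):
                break
            idx = np.nonzero(fork)[0]
            apex[idx] *= br_f[branch_level[idx], idx]
            for lvl in (0, 1):
                rec = idx[branch_level[idx] == lvl]
                # 1-based: branching on the j-th day after planting reads j
                day_branch[lvl, rec] = np.minimum(day_branch[lvl, rec], day + 1)
            branch_level[idx] += 1

        # --- new cohort for today
        rate = leaf_appearance_rate(crop_age, g["LNSLP"], constants)
        dn = np.where(active, rate * tt_leaf * stress * apex, 0.0)
        coh_n[:, day] = dn
        coh_target[:, day] = np.where(
            dn > 0, potential_leaf_size(crop_age, g["LAXS"], constants) * stress, 0.0
        )
        coh_leafno[:, day] = cum_leaves
        coh_live[:, day] = dn > 0
        cum_leaves = cum_leaves + dn

        # --- cohort potential increments over the active slice
        sl = slice(0, day + 1)
        age_old = coh_age[:, sl]
        age_new = age_old + (tt_leaf * stress)[:, None]
        prog_old = np.minimum(age_old / constants.leaf_expansion_tt, 1.0)
        prog_new = np.minimum(age_new / constants.leaf_expansion_tt, 1.0)
        live = coh_live[:, sl]
        d_area = np.where(live, coh_target[:, sl] * (prog_new - prog_old), 0.0)

        pot_old = node_mass_potential(age_old, coh_leafno[:, sl], 1.0, constants)
        pot_new = node_mass_potential(age_new, coh_leafno[:, sl], 1.0, constants)
        d_node = g["NODWT"][:, None] * (pot_new - pot_old)  # nodes grow even after leaf fall
        coh_age[:, sl] = age_new

        d_area_tot = np.einsum("ij,ij->i", d_area, coh_n[:, sl])
        d_node_tot = np.einsum("ij,ij->i", d_node, coh_n[:, sl])
        leaf_dem, stem_dem, fib_dem = compute_demand(
            d_area_tot, d_node_tot, g["SLAS"], g["LPEFR"], constants
        )
        total_dem = leaf_dem + stem_dem + fib_dem

        # --- supply: canopy assimilation (+ stake reserves while they last)
        assim = daily_assimilation(srad[t], lai, g["PARUE"], g["KCAN"], constants) * stress
        draw = np.minimum(reserve, np.maximum(total_dem - assim, 0.0))
        reserve -= draw
        supply = assim + draw
        supply_limited_days += (total_dem > supply + 1e-12).astype(float)

        leaf_inc, stem_inc, fib_inc, storage_inc = allocate_spillover(
            supply, leaf_dem, stem_dem, fib_dem
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(total_dem > 0, np.minimum(1.0, supply / np.where(total_dem > 0, total_dem, 1.0)), 1.0)
        coh_area[:, sl] += d_area * scale[:, None]

        lamina_mass += leaf_inc * (1.0 - g["LPEFR"])
        petiole_mass += leaf_inc * g["LPEFR"]
        stem_mass += stem_inc
        fibrous_mass += fib_inc
        storage_mass += storage_inc
        cum_supply += supply

        # --- senescence: leaf-aging clock runs after full expansion
        expanded = live & (prog_new >= 1.0)
        coh_exp_age[:, sl] = np.where(expanded, coh_exp_age[:, sl] + tt_aging, coh_exp_age[:, sl])
        senesce = expanded & (coh_exp_age[:, sl] > g["LLIFA"][:, None])
        coh_live[:, sl] = live & ~senesce

        lai = mgmt.density * np.einsum("ij,ij->i", coh_area[:, sl] * coh_live[:, sl], coh_n[:, sl]) / 1e4
        max_lai = np.maximum(max_lai, lai)

        if trace_rows is not None:
            trace_rows.append(
                {
                    "day": day,
                    "lai": float(lai[0]),
                    "stress": float(stress[0]),
                    "crop_age": float(crop_age[0]),
                    "branch_level": int(branch_level[0]),
                    "apex": float(apex[0]),
                    "cum_leaves": float(cum_leaves[0]),
                    "lamina_mass": float(lamina_mass[0]),
                    "petiole_mass": float(petiole_mass[0]),
                    "stem_mass": float(stem_mass[0]),
                    "fibrous_mass": float(fibrous_mass[0]),
                    "storage_mass": float(storage_mass[0]),
                    "assimilation": float(assim[0]),
                    "reserve_draw": float(draw[0]),
                    "supply": float(supply[0]),
                    "demand": float(total_dem[0]),
                }
            )

    for name, arr in (
        ("lamina", lamina_mass), ("petiole", petiole_mass), ("stem", stem_mass),
        ("fibrous", fibrous_mass), ("storage", storage_mass),
    ):
        if not np.all(np.isfinite(arr)):
            bad = int(np.nonzero(~np.isfinite(arr))[0][0])
            raise FloatingPointError(f"non-finite {name} mass in batch row {bad}")

    aboveground = (lamina_mass + petiole_mass + stem_mass) * mgmt.density * 10.0  # kg/ha
    out = {
        "aboveground_biomass": aboveground,
        "yield_": storage_mass * mgmt.density * 10.0,
        "max_lai": max_lai,
        "leaves_at_harvest": cum_leaves,
        "day_first_branch": day_branch[0],
        "day_second_branch": day_branch[1],
        "_cum_supply": cum_supply,
        "_total_mass": lamina_mass + petiole_mass + stem_mass + fibrous_mass + storage_mass,
        "_supply_limited_days": supply_limited_days,
    }
    if trace_rows is not None:
        out["_trace"] = pd.DataFrame(trace_rows)
    return out


def _root_depth(day: int, soil: sw.SoilProfile, constants: SpeciesConstants) -> float:
    if day < 0:
        return constants.root_depth_init_cm
    return min(
        soil.depth_cm, constants.root_depth_init_cm + constants.root_growth_cm_day * day
    )


def simulate_season(
    gsps: GSPSet,
    weather: WeatherSeries,
    soil: sw.SoilProfile,
    mgmt: Management = Management(),
    constants: SpeciesConstants = SpeciesConstants(),
    *,
    trace: bool = False,
    start_index: int | None = None,
    year: int | None = None,
):
    """Single-run convenience wrapper; returns ``SeasonOutputs`` (and the
    daily trace DataFrame when ``trace=True``)."""
    raw = simulate_batch(
        {k: np.asarray([v]) for k, v in gsps.as_dict().items()},
        weather, soil, mgmt, constants, start_index=start_index, year=year,
    )
    outputs = SeasonOutputs(*(float(raw[name][0]) for name in OUTPUT_NAMES))
    if trace:
        return outputs, raw.get("_trace")
    return outputs
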