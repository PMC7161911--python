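"""End-to-end GSUA experiment: screening + Sobol over four environments.

Treatments are the factorial of {cool, warm} sites x {rainfed,
unlimited} water regimes.  Each design row is simulated for every year
of a synthetic multi-year weather series and outputs are averaged
across years before the sensitivity statistics are computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crop_model as cm
from . import esu_screening as esu
from . import sobol_gsua as sob
from . import soil_water as sw
from .gsp import GSP_NAMES, default_gsp_values, load_gsp_distributions
from .weather import SiteProfile, WeatherSeries, generate_weather

log = logging.getLogger("cassava_gsua")

__all__ = [
    "ExperimentConfig",
    "ResultsBundle",
    "load_sites",
    "run_screening",
    "run_sobol",
    "run_full",
    "report",
]

TREATMENTS = (
    ("warm", "unlimited"),
    ("warm", "rainfed"),
    ("cool", "unlimited"),
    ("cool", "rainfed"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    years: int = 30
    esu_levels: int = 8
    esu_r: int = 24
    esu_pool: int = 500
    sobol_n: int = 512
    seed_weather: int = 11
    seed_esu: int = 22
    seed_sobol: int = 33
    planting_doy: int = 115
    season_length: int = 300
    threshold: float = 0.5
    scale_preset: str = "full"  # or "desk"

    @classmethod
    def desk(cls, **overrides) -> "ExperimentConfig":
        base = dict(years=5, esu_r=8, esu_pool=64, sobol_n=64, scale_preset="desk")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ResultsBundle:
    config: ExperimentConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = {"config": dataclasses.asdict(self.config), "hash": self.config.config_hash()}
        prov.update({k: v for k, v in self.meta.items() if _jsonable(v)})
        (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
        for name, frame in self.tables.items():
            frame.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_sites() -> dict[str, SiteProfile]:
    text = resources.files("cassava_gsua").joinpath("data/sites.yaml").read_text()
    raw = yaml.safe_load(text)
    return {key: SiteProfile(**rec) for key, rec in raw.items()}


def _environments(config: ExperimentConfig) -> dict[str, dict]:
    """Weather series + soil + management per treatment (weather shared
    between the two regimes of a site)."""
    sites = load_sites()
    envs: dict[str, dict] = {}
    for site_key in ("cool", "warm"):
        profile = sites[site_key]
        series = generate_weather(
            profile,
            n_years=config.years + 1,  # season spills into the next calendar year
            seed=config.seed_weather + (0 if site_key == "cool" else 1),
            planting_doy=config.planting_doy,
        )
        soil = sw.load_soil_profile(site_key)
        for regime in ("unlimited", "rainfed"):
            mgmt = cm.Management(
                planting_doy=config.planting_doy,
                season_length=config.season_length,
                water_limited=(regime == "rainfed"),
            )
            envs[f"{site_key}_{regime}"] = {
                "site": site_key,
                "regime": regime,
                "weather": series,
                "soil": soil,
                "mgmt": mgmt,
            }
    return envs


def _evaluate_design(
    params: pd.DataFrame,
    env: dict,
    config: ExperimentConfig,
) -> np.ndarray:
    """Simulate every design row for every year; returns outputs with
    shape (rows, years, 6), year-ordering fixed by the weather series."""
    weather: WeatherSeries = env["weather"]
    mgmt: cm.Management = env["mgmt"]
    gsp_arrays = {k: params[k].to_numpy(float) for k in params.columns}
    start_year = int(weather.frame["date"].iloc[0].year)
    out = np.empty((len(params), config.years, len(cm.OUTPUT_NAMES)))
    for yi in range(config.years):
        raw = cm.simulate_batch(
            gsp_arrays, weather, env["soil"], mgmt, year=start_year + yi
        )
        for oi, name in enumerate(cm.OUTPUT_NAMES):
            out[:, yi, oi] = raw[name]
    return out


def _full_param_frame(sampled: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Complete a sampled sub-frame with unsampled GSPs at their medians."""
    defaults = default_gsp_values()
    frame = pd.DataFrame(index=sampled.index)
    for name in GSP_NAMES:
        frame[name] = sampled[name] if name in sampled.columns else defaults[name]
    return frame


def run_screening(config: ExperimentConfig) -> ResultsBundle:
    """Elementary-effects screening over all 16 GSPs in 4 treatments."""
    dists = load_gsp_distributions()
    k = len(GSP_NAMES)
    design = esu.build_esu_design(
        k, levels=config.esu_levels, r=config.esu_r,
        pool_size=config.esu_pool, seed=config.seed_esu,
    )
    params = esu.map_to_parameters(design, {n: dists[n] for n in GSP_NAMES})
    log.info("screening design: %d rows (r=%d, k=%d)", design.n_rows, config.esu_r, k)

    envs = _environments(config)
    effects_tables: dict[str, dict] = {}
    for trt_key, env in envs.items():
        outputs = _evaluate_design(params, env, config)
        means = outputs.mean(axis=1)  # across years
        effects_tables[trt_key] = {
            name: esu.elementary_effects(design, means[:, oi])
            for oi, name in enumerate(cm.OUTPUT_NAMES)
        }
        log.info("screening: treatment %s done", trt_key)

    normalized = esu.normalize_effects(effects_tables)
    selected = esu.select_important(normalized, list(GSP_NAMES), config.threshold)
    frame = esu.effects_frame(effects_tables, normalized, list(GSP_NAMES))

    bundle = ResultsBundle(config)
    bundle.tables["esu_design"] = params.assign(
        trajectory=design.trajectory_id, changed=design.changed_parameter
    )
    bundle.tables["esu_effects"] = frame
    bundle.meta["selected"] = selected
    bundle.meta["design_rows"] = design.n_rows
    return bundle


def run_sobol(config: ExperimentConfig, selected: list[str]) -> ResultsBundle:
    """Sobol indices + uncertainty summaries over the selected GSPs."""
    if not selected:
        raise ValueError("empty parameter selection")
    dists = load_gsp_distributions()
    k = len(selected)
    design, sampled = sob.build_sobol_design(
        k, config.sobol_n, {n: dists[n] for n in selected}, seed=config.seed_sobol
    )
    params = _full_param_frame(sampled, config)
    log.info("sobol design: %d rows (n=%d, k=%d)", design.n_rows, config.sobol_n, k)

    envs = _environments(config)
    idx_rows, unc_rows, cdf_rows = [], [], []
    raw_means: dict[str, np.ndarray] = {}
    for trt_key, env in envs.items():
        outputs = _evaluate_design(params, env, config)  # (rows, years, 6)
        means = outputs.mean(axis=1)
        raw_means[trt_key] = means
        for oi, name in enumerate(cm.OUTPUT_NAMES):
            indices = sob.estimate_indices(design, means[:, oi], seed=config.seed_sobol)
            for pi, pname in enumerate(selected):
                idx_rows.append(
                    {
                        "parameter": pname,
                        "output": name,
                        "treatment": trt_key,
                        "s_first": indices.s_first[pi],
                        "s_total": indices.s_total[pi],
                        "s_first_lo": indices.s_first_ci[pi, 0],
                        "s_first_hi": indices.s_first_ci[pi, 1],
                        "s_total_lo": indices.s_total_ci[pi, 0],
                        "s_total_hi": indices.s_total_ci[pi, 1],
                    }
                )
            summary = sob.uncertainty_summary(outputs[:, :, oi])
            unc_rows.append(
                {
                    "output": name,
                    "treatment": trt_key,
                    "mean": summary.mean,
                    "sd": summary.sd,
                    "cv_percent": summary.cv_percent,
                }
            )
            stride = max(1, len(summary.cdf_values) // 200)
            for v, p, lo, hi in zip(
                summary.cdf_values[::stride], summary.cdf_probs[::stride],
                summary.ci_low[::stride], summary.ci_high[::stride],
            ):
                cdf_rows.append(
                    {"output": name, "treatment": trt_key, "value": v,
                     "prob": p, "ci_low": lo, "ci_high": hi}
                )
        log.info("sobol: treatment %s done", trt_key)

    bundle = ResultsBundle(config)
    bundle.tables["sobol_indices"] = pd.DataFrame(idx_rows)
    bundle.tables["uncertainty"] = pd.DataFrame(unc_rows)
    bundle.tables["cdf"] = pd.DataFrame(cdf_rows)
    bundle.meta["selected"] = selected
    bundle.meta["fixed_at_median"] = {
        n: default_gsp_values()[n] for n in GSP_NAMES if n not in selected
    }
    bundle.meta["design_rows"] = design.n_rows
    return bundle


def run_full(config: ExperimentConfig) -> ResultsBundle:
    """Screening, selection, Sobol, and the method-comparison table."""
    screening = run_screening(config)
    selected = screening.meta["selected"]
    if not selected:  # degenerate desk configs: fall back to all GSPs
        selected = list(GSP_NAMES)
    sobol = run_sobol(config, selected)

    bundle = ResultsBundle(config)
    bundle.tables.update(screening.tables)
    bundle.tables.update(sobol.tables)
    bundle.meta.update(sobol.meta)
    bundle.meta["screening_rows"] = screening.meta["design_rows"]

    # mu* vs total-order comparison per output x treatment
    eff = screening.tables["esu_effects"]
    idx = sobol.tables["sobol_indices"]
    rows = []
    for (output, trt), chunk in idx.groupby(["output", "treatment"]):
        merged = chunk.merge(
            eff[(eff["output"] == output) & (eff["treatment"] == trt)][
                ["parameter", "mu_star"]
            ],
            on="parameter",
        )
        if len(merged) >= 3 and merged["s_total"].std() > 0:
            slope, intercept, r2 = sob.compare_methods(
                merged["mu_star"].to_numpy(), merged["s_total"].to_numpy()
            )
            rows.append(
                {"output": output, "treatment": trt,
                 "slope": slope, "intercept": intercept, "r_squared": r2}
            )
    bundle.tables["method_comparison"] = pd.DataFrame(rows)
    return bundle


def report(bundle: ResultsBundle, outdir, plots: bool = False) -> None:
    """Write all bundle tables (and optional quick-look plots)."""
    bundle.write(outdir)
    if not plots:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        log.warning("matplotlib unavailable; skipping plots")
        return
    outdir = Path(outdir)
    if "cdf" in bundle.tables:
        cdf = bundle.tables["cdf"]
        outputs = cdf["output"].unique()
        fig, axes = plt.subplots(2, 3, figsize=(14, 8))
        for ax, output in zip(axes.ravel(), outputs):
            for trt, chunk in cdf[cdf["output"] == output].groupby("treatment"):
                ax.plot(chunk["value"], chunk["prob"], label=trt)
            ax.set_title(output)
            ax.set_ylabel("cumulative probability")
        axes.ravel()[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "cdf.png", dpi=120)
        plt.close(fig)
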