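"""Morris-type elementary-effects screening with uniformity-enhanced
trajectory selection.

Trajectories live on a ``p``-level grid in the unit hypercube with step
``delta = p / (2(p-1))``.  A pool of random trajectories is oversampled
and ``r`` of them are kept by greedy max-min spread (Campolongo-style
inter-trajectory distance), which is the uniformity enhancement.  The
design has exactly ``r * (k+1)`` rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import TruncatedDistribution

__all__ = [
    "ScreeningDesign",
    "ElementaryEffects",
    "build_esu_design",
    "map_to_parameters",
    "elementary_effects",
    "normalize_effects",
    "select_important",
]


@dataclass(frozen=True)
class ScreeningDesign:
    k: int
    levels: int
    r: int
    delta: float
    points: np.ndarray  # (r*(k+1), k) in [0, 1]
    trajectory_id: np.ndarray  # (r*(k+1),)
    changed_parameter: np.ndarray  # (r*(k+1),) int; -1 for trajectory starts

    @property
    def n_rows(self) -> int:
        return self.points.shape[0]


def _random_trajectories(
    n_traj: int, k: int, levels: int, delta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """``n_traj`` Morris trajectories at once.

    Returns points ``(n_traj, k+1, k)`` and the coordinate changed at
    each of the k steps, ``(n_traj, k)``.  Base coordinates are drawn
    from the half of the grid that keeps ``base + direction*delta``
    inside [0, 1].
    """
    grid = np.arange(levels) / (levels - 1)
    n_ok = int(np.sum(grid <= 1.0 - delta + 1e-12))  # == levels/2 for Morris delta
    direction = rng.integers(0, 2, size=(n_traj, k)) * 2 - 1
    idx = rng.integers(0, n_ok, size=(n_traj, k))
    base = np.where(direction > 0, grid[idx], grid[levels - n_ok + idx])
    order = np.argsort(rng.random((n_traj, k)), axis=1)  # random permutations
    rank = np.argsort(order, axis=1)  # rank[t, i] = step at which coord i flips
    steps = np.arange(k + 1)
    flipped = rank[:, None, :] < steps[None, :, None]  # (n_traj, k+1, k)
    pts = base[:, None, :] + direction[:, None, :] * delta * flipped
    return pts, order


def _trajectory_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Spread between two trajectories: sum over point pairs of squared
    euclidean distance (Campolongo-style, squared for speed)."""
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return float(d2.sum())


def build_esu_design(
    k: int,
    levels: int = 8,
    r: int = 24,
    pool_size: int = 500,
    seed: int | None = None,
) -> ScreeningDesign:
    """Build an ``r``-trajectory screening design over ``k`` parameters.

    ``pool_size`` random trajectories are generated and the ``r`` with
    the greatest mutual spread are kept greedily.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if levels % 2 != 0:
        raise ValueError("levels must be even for the Morris step delta = p/(2(p-1))")
    if r > pool_size:
        raise ValueError("pool_size must be >= r")
    if r % levels != 0:
        warnings.warn(
            "trajectory count r is recommended to be a multiple of the level count",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))

    pts, orders = _random_trajectories(pool_size, k, levels, delta, rng)

    if r == pool_size:
        chosen = list(range(pool_size))
    else:
        # spread = sum over point pairs of squared euclidean distance; its
        # closed form needs only per-trajectory point sums and norm sums
        ssum = np.einsum("tik,tik->t", pts, pts)  # sum_i |a_i|^2
        psum = pts.sum(axis=1)  # (P, k)
        m = k + 1
        dist = m * (ssum[:, None] + ssum[None, :]) - 2.0 * psum @ psum.T
        np.fill_diagonal(dist, 0.0)
        # greedy max-min: seed with the farthest pair, then grow
        i0, j0 = np.unravel_index(np.argmax(dist), dist.shape)
        chosen = [int(i0), int(j0)]
        in_pool = np.ones(pool_size, dtype=bool)
        in_pool[chosen] = False
        min_d = np.minimum(dist[:, i0], dist[:, j0])
        while len(chosen) < r:
            scores = np.where(in_pool, min_d, -np.inf)
            c = int(np.argmax(scores))
            chosen.append(c)
            in_pool[c] = False
            min_d = np.minimum(min_d, dist[:, c])

    rows, tid, changed = [], [], []
    for t, c in enumerate(chosen):
        rows.append(pts[c])
        tid.extend([t] * (k + 1))
        changed.append(-1)
        changed.extend(int(i) for i in orders[c])
    points = np.vstack(rows)
    return ScreeningDesign(
        k=k,
        levels=levels,
        r=r,
        delta=delta,
        points=points,
        trajectory_id=np.asarray(tid),
        changed_parameter=np.asarray(changed),
    )


def map_to_parameters(
    design: ScreeningDesign,
    dists: dict[str, TruncatedDistribution] | list[TruncatedDistribution],
) -> pd.DataFrame:
    """Inverse-CDF map of the unit-hypercube design onto parameter values.

    Integer-flagged distributions are rounded to the nearest integer.
    """
    if isinstance(dists, dict):
        names = list(dists)
        dist_list = [dists[n] for n in names]
    else:
        names = [f"x{i}" for i in range(len(dists))]
        dist_list = list(dists)
    if len(dist_list) != design.k:
        raise ValueError(f"need {design.k} distributions, got {len(dist_list)}")
    cols = {}
    for j, (name, dist) in enumerate(zip(names, dist_list)):
        v = np.asarray(dist.quantile(design.points[:, j]))
        if dist.spec.integer:
            v = np.rint(v)
        cols[name] = v
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class ElementaryEffects:
    mu: np.ndarray  # (k,) signed mean
    mu_star: np.ndarray  # (k,) mean absolute
    sigma: np.ndarray  # (k,) sd of effects (ddof=1)
    effects: np.ndarray  # (r, k) raw elementary effects


def elementary_effects(design: ScreeningDesign, y: np.ndarray) -> ElementaryEffects:
    """Per-parameter elementary effects from the model outputs ``y``
    evaluated at every design row."""
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_rows,):
        raise ValueError(f"y must have {design.n_rows} entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite model output")
    k, r = design.k, design.r
    ee = np.full((r, k), np.nan)
    for t in range(r):
        base = t * (k + 1)
        for step in range(1, k + 1):
            i = int(design.changed_parameter[base + step])
            dx = design.points[base + step, i] - design.points[base + step - 1, i]
            ee[t, i] = (y[base + step] - y[base + step - 1]) / dx
    mu = ee.mean(axis=0)
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1) if r > 1 else np.zeros(k)
    return ElementaryEffects(mu=mu, mu_star=mu_star, sigma=sigma, effects=ee)


def normalize_effects(tables: dict) -> dict:
    """Normalise mu* and sigma jointly across treatments.

    ``tables`` maps treatment -> {output -> ElementaryEffects}; the
    result maps treatment -> output -> dict with ``mu_star_norm`` and
    ``sigma_norm`` arrays.  Per output, each statistic is divided by its
    maximum over all parameters and all treatments.
    """
    if not tables:
        raise ValueError("no treatments")
    outputs = next(iter(tables.values())).keys()
    out: dict = {trt: {} for trt in tables}
    for output in outputs:
        max_mu = max(float(tables[trt][output].mu_star.max()) for trt in tables)
        max_sig = max(float(tables[trt][output].sigma.max()) for trt in tables)
        if max_mu == 0 and max_sig == 0:
            warnings.warn(f"all elementary effects are zero for output {output!r}")
        for trt in tables:
            eff = tables[trt][output]
            out[trt][output] = {
                "mu_star_norm": eff.mu_star / max_mu if max_mu > 0 else np.zeros_like(eff.mu_star),
                "sigma_norm": eff.sigma / max_sig if max_sig > 0 else np.zeros_like(eff.sigma),
            }
    return out


def select_important(
    normalized: dict,
    parameter_names: list[str],
    threshold: float = 0.5,
) -> list[str]:
    """Parameters whose normalised mu* OR sigma strictly exceeds the
    threshold for at least one output in at least one treatment."""
    selected = set()
    for trt, by_output in normalized.items():
        for output, stats in by_output.items():
            mask = (stats["mu_star_norm"] > threshold) | (stats["sigma_norm"] > threshold)
            for i in np.nonzero(mask)[0]:
                selected.add(parameter_names[int(i)])
    return [p for p in parameter_names if p in selected]


def effects_frame(
    tables: dict, normalized: dict, parameter_names: list[str]
) -> pd.DataFrame:
    """Long-format table of raw and normalised effects."""
    rows = []
    for trt, by_output in tables.items():
        for output, eff in by_output.items():
            norm = normalized[trt][output]
            for i, p in enumerate(parameter_names):
                rows.append(
                    {
                        "parameter": p,
                        "output": output,
                        "treatment": trt,
                        "mu": eff.mu[i],
                        "mu_star": eff.mu_star[i],
                        "sigma": eff.sigma[i],
                        "mu_star_norm": norm["mu_star_norm"][i],
                        "sigma_norm": norm["sigma_norm"][i],
                    }
                )
    return pd.DataFrame(rows)
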