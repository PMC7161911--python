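"""Variance-based global sensitivity analysis (Sobol indices) and the
uncertainty summaries built on top of it.

The design is the classic radial layout with both hybrid sets: base
matrices A and B plus, per parameter i, A with column i from B and B
with column i from A, for a total of ``2 n (k + 1)`` rows.  First-order
indices use the Saltelli (2010) estimator, total-order indices the
Jansen estimator; both average the two symmetric hybrid sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .distributions import TruncatedDistribution

__all__ = [
    "SobolDesign",
    "SobolIndices",
    "UncertaintySummary",
    "build_sobol_design",
    "estimate_indices",
    "uncertainty_summary",
    "compare_methods",
]


@dataclass(frozen=True)
class SobolDesign:
    k: int
    n: int
    unit_rows: np.ndarray  # (2n(k+1), k) points in [0, 1]
    scheme: str  # "sobol" or "random"

    @property
    def n_rows(self) -> int:
        return self.unit_rows.shape[0]

    def blocks(self, y: np.ndarray):
        """Split a length-2n(k+1) output vector into (fA, fB, fAB, fBA)."""
        n, k = self.n, self.k
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_rows,):
            raise ValueError(f"y must have {self.n_rows} entries")
        f_a = y[:n]
        f_b = y[n : 2 * n]
        f_ab = y[2 * n : 2 * n + n * k].reshape(k, n)
        f_ba = y[2 * n + n * k :].reshape(k, n)
        return f_a, f_b, f_ab, f_ba


def build_sobol_design(
    k: int,
    n: int,
    dists: dict[str, TruncatedDistribution] | list[TruncatedDistribution] | None = None,
    seed: int | None = None,
    scheme: str = "sobol",
) -> tuple[SobolDesign, pd.DataFrame | None]:
    """Radial Sobol design with ``2 n (k+1)`` rows.

    Returns the unit-hypercube design plus (when distributions are
    given) the inverse-CDF-mapped parameter table aligned row-for-row.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    if scheme == "sobol":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # n not a power of two
            sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
            ab = sampler.random(n)
        a, b = ab[:, :k], ab[:, k:]
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(n, k))
        b = rng.uniform(size=(n, k))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = [a, b]
    for i in range(k):
        ab_i = a.copy()
        ab_i[:, i] = b[:, i]
        rows.append(ab_i)
    for i in range(k):
        ba_i = b.copy()
        ba_i[:, i] = a[:, i]
        rows.append(ba_i)
    unit = np.vstack(rows)
    design = SobolDesign(k=k, n=n, unit_rows=unit, scheme=scheme)

    params = None
    if dists is not None:
        if isinstance(dists, dict):
            names = list(dists)
            dist_list = [dists[m] for m in names]
        else:
            names = [f"x{i}" for i in range(len(dists))]
            dist_list = list(dists)
        if len(dist_list) != k:
            raise ValueError(f"need {k} distributions, got {len(dist_list)}")
        cols = {}
        for j, (name, dist) in enumerate(zip(names, dist_list)):
            v = np.asarray(dist.quantile(np.clip(unit[:, j], 0.0, 1.0)))
            if dist.spec.integer:
                v = np.rint(v)
            cols[name] = v
        params = pd.DataFrame(cols)
    return design, params


@dataclass(frozen=True)
class SobolIndices:
    s_first: np.ndarray  # (k,)
    s_total: np.ndarray  # (k,)
    s_first_ci: np.ndarray  # (k, 2) bootstrap 95% interval
    s_total_ci: np.ndarray  # (k, 2)


def _indices_from_blocks(f_a, f_b, f_ab, f_ba):
    both = np.concatenate([f_a, f_b])
    var = np.var(both, ddof=1)
    # relative threshold: constant outputs give var ~ eps^2, not exactly 0
    if var <= 1e-20 * float(np.mean(both**2) + 1e-300):
        k = f_ab.shape[0]
        return np.zeros(k), np.zeros(k), 0.0
    # Saltelli 2010 first order, averaged over both hybrid sets
    s1 = 0.5 * (
        np.mean(f_b * (f_ab - f_a[None, :]), axis=1)
        + np.mean(f_a * (f_ba - f_b[None, :]), axis=1)
    ) / var
    # Jansen total order, averaged likewise
    st = 0.5 * (
        0.5 * np.mean((f_a[None, :] - f_ab) ** 2, axis=1)
        + 0.5 * np.mean((f_b[None, :] - f_ba) ** 2, axis=1)
    ) / var
    return s1, st, var


def estimate_indices(
    design: SobolDesign,
    y: np.ndarray,
    n_boot: int = 200,
    seed: int | None = None,
) -> SobolIndices:
    """First- and total-order Sobol indices with bootstrap 95% CIs."""
    f_a, f_b, f_ab, f_ba = design.blocks(y)
    if not (
        np.all(np.isfinite(f_a)) and np.all(np.isfinite(f_b))
        and np.all(np.isfinite(f_ab)) and np.all(np.isfinite(f_ba))
    ):
        raise ValueError("non-finite model output")
    s1, st, var = _indices_from_blocks(f_a, f_b, f_ab, f_ba)
    k = design.k
    if var == 0:
        warnings.warn("zero output variance; all Sobol indices set to 0")
        zeros_ci = np.zeros((k, 2))
        return SobolIndices(s1, st, zeros_ci, zeros_ci)

    rng = np.random.default_rng(seed)
    boot1 = np.empty((n_boot, k))
    boott = np.empty((n_boot, k))
    n = design.n
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b1, bt, _ = _indices_from_blocks(f_a[idx], f_b[idx], f_ab[:, idx], f_ba[:, idx])
        boot1[b] = b1
        boott[b] = bt
    ci1 = np.percentile(boot1, [2.5, 97.5], axis=0).T
    cit = np.percentile(boott, [2.5, 97.5], axis=0).T
    return SobolIndices(s1, st, ci1, cit)


@dataclass(frozen=True)
class UncertaintySummary:
    mean: float
    sd: float
    cv_percent: float
    cdf_values: np.ndarray  # sorted per-sample across-year means
    cdf_probs: np.ndarray
    ci_low: np.ndarray  # per-sample 2.5th pct over years, sorted like cdf
    ci_high: np.ndarray


def uncertainty_summary(outputs: np.ndarray) -> UncertaintySummary:
    """Summarise an (n_samples, n_years) output block.

    The CDF is over per-sample across-year means; sd/cv are over the
    same means; the 95% band comes from the 2.5/97.5 percentiles of
    single-year values within each sample.
    """
    arr = np.atleast_2d(np.asarray(outputs, dtype=float))
    if arr.size == 0:
        raise ValueError("empty outputs")
    means = arr.mean(axis=1)
    order = np.argsort(means)
    means_sorted = means[order]
    n = means.size
    probs = (np.arange(1, n + 1)) / n
    lo = np.percentile(arr, 2.5, axis=1)[order]
    hi = np.percentile(arr, 97.5, axis=1)[order]
    mean = float(means.mean())
    sd = float(means.std(ddof=1)) if n > 1 else 0.0
    cv = float(100.0 * sd / mean) if mean != 0 else float("nan")
    return UncertaintySummary(mean, sd, cv, means_sorted, probs, lo, hi)


def compare_methods(mu_star: np.ndarray, s_total: np.ndarray):
    """OLS regression of screening mu* (response) on Sobol total-order
    indices (regressor); returns (slope, intercept, r_squared)."""
    x = np.asarray(s_total, dtype=float)
    y = np.asarray(mu_star, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    from scipy.stats import linregress

    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
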