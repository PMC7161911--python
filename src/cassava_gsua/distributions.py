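"""Parametric distributions for genotype-specific parameters (GSPs).

Supports six families (uniform, triangular, normal, lognormal, gamma,
Weibull) with a mixed truncation convention: each side of the support may
be pinned either at a *value* or at a *probability* of the untruncated
distribution.  Truncated sampling is exact inverse-CDF on a rescaled
uniform, so no rejection is involved.

Also provides maximum-likelihood fitting with AIC ranking and a
Kolmogorov-Smirnov goodness-of-fit statistic, including the uniform
fallback used when fewer than 10 observations are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DistributionSpec",
    "TruncationRule",
    "TruncatedDistribution",
    "FitResult",
    "make_distribution",
    "fit_distribution",
    "ks_statistic",
    "FAMILIES",
]

FAMILIES = ("uniform", "triangular", "normal", "lognormal", "gamma", "weibull")

#: number of free parameters per family (used for AIC)
_N_PARAMS = {
    "uniform": 2,
    "triangular": 3,
    "normal": 2,
    "lognormal": 2,
    "gamma": 2,
    "weibull": 2,
}


@dataclass(frozen=True)
class TruncationRule:
    """Truncation of one or both tails, each by value or by probability.

    ``kind == "probability"`` resolves the bound through the untruncated
    quantile function; ``kind == "value"`` pins it directly.
    """

    left_kind: str = "probability"
    left: float = 0.0
    right_kind: str = "probability"
    right: float = 1.0

    def __post_init__(self) -> None:
        for kind in (self.left_kind, self.right_kind):
            if kind not in ("value", "probability"):
                raise ValueError(f"unknown truncation kind {kind!r}")
        if self.left_kind == "probability" and not 0.0 <= self.left < 1.0:
            raise ValueError("left probability bound must be in [0, 1)")
        if self.right_kind == "probability" and not 0.0 < self.right <= 1.0:
            raise ValueError("right probability bound must be in (0, 1]")


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of one GSP distribution."""

    family: str
    params: dict[str, float] = field(default_factory=dict)
    truncation: TruncationRule | None = None
    integer: bool = False  # round samples to integers (branch counts)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "uniform":
            if not p["min"] < p["max"]:
                raise ValueError("uniform requires min < max")
        elif self.family == "triangular":
            if not (p["min"] <= p["mode"] <= p["max"] and p["min"] < p["max"]):
                raise ValueError("triangular requires min <= mode <= max, min < max")
        elif self.family == "normal":
            if p["sigma"] <= 0:
                raise ValueError("normal requires sigma > 0")
        elif self.family == "lognormal":
            if p["sigma_log"] <= 0:
                raise ValueError("lognormal requires sigma_log > 0")
        elif self.family in ("gamma", "weibull"):
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError(f"{self.family} requires shape, scale > 0")


def _frozen(spec: DistributionSpec):
    """Untruncated scipy frozen distribution for a spec."""
    p = spec.params
    if spec.family == "uniform":
        return stats.uniform(loc=p["min"], scale=p["max"] - p["min"])
    if spec.family == "triangular":
        width = p["max"] - p["min"]
        return stats.triang(c=(p["mode"] - p["min"]) / width, loc=p["min"], scale=width)
    if spec.family == "normal":
        return stats.norm(loc=p["mu"], scale=p["sigma"])
    if spec.family == "lognormal":
        return stats.lognorm(s=p["sigma_log"], scale=math.exp(p["mu_log"]))
    if spec.family == "gamma":
        return stats.gamma(a=p["shape"], scale=p["scale"])
    if spec.family == "weibull":
        return stats.weibull_min(c=p["shape"], scale=p["scale"])
    raise ValueError(spec.family)


class TruncatedDistribution:
    """A (possibly) truncated distribution exposing cdf/pdf/quantile/sample.

    The support ``[lo, hi]`` is resolved from the truncation rule; the
    truncated cdf is the untruncated one rescaled to [0, 1] over the
    support.
    """

    def __init__(self, spec: DistributionSpec):
        self.spec = spec
        self._dist = _frozen(spec)
        rule = spec.truncation
        if rule is None:
            lo = float(self._dist.ppf(0.0))
            hi = float(self._dist.ppf(1.0))
        else:
            if rule.left_kind == "probability":
                lo = float(self._dist.ppf(rule.left))
            else:
                lo = float(rule.left)
            if rule.right_kind == "probability":
                hi = float(self._dist.ppf(rule.right))
            else:
                hi = float(rule.right)
        if not lo < hi:
            raise ValueError(f"empty truncated support [{lo}, {hi}]")
        self.lo = lo
        self.hi = hi
        self._flo = float(self._dist.cdf(lo)) if np.isfinite(lo) else 0.0
        self._fhi = float(self._dist.cdf(hi)) if np.isfinite(hi) else 1.0
        self._mass = self._fhi - self._flo
        if self._mass <= 0:
            raise ValueError("truncation leaves zero probability mass")

    @property
    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = (self._dist.cdf(np.clip(x, self.lo, self.hi)) - self._flo) / self._mass
        return np.clip(out, 0.0, 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lo) & (x <= self.hi)
        return np.where(inside, self._dist.pdf(x) / self._mass, 0.0)

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probability outside [0, 1]")
        u = self._flo + p * self._mass
        q = self._dist.ppf(u)
        # pin the endpoints exactly; ppf can drift at the boundaries
        q = np.where(p <= 0, self.lo, q)
        q = np.where(p >= 1, self.hi, q)
        return q if q.ndim else float(q)

    def sample(self, n: int, seed: int | np.random.Generator | None = None):
        """Draw ``n`` values by inverse-CDF on a rescaled uniform stream."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        u = rng.uniform(size=n)
        x = np.asarray(self.quantile(u))
        if self.spec.integer:
            x = np.rint(x)
        return x

    def median(self) -> float:
        return float(self.quantile(0.5))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TruncatedDistribution({self.spec.family}, params={self.spec.params}, "
            f"support=[{self.lo:g}, {self.hi:g}])"
        )


def make_distribution(spec: DistributionSpec) -> TruncatedDistribution:
    """Build a sampling-ready distribution from its spec."""
    return TruncatedDistribution(spec)


# ---------------------------------------------------------------------------
# goodness of fit


def ks_statistic(obs: Sequence[float], cdf: Callable) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    ``D = sup |F_n - F|`` evaluated at every jump of the empirical cdf;
    the p-value uses the asymptotic Kolmogorov distribution (no
    correction for estimated parameters).
    """
    x = np.sort(np.asarray(obs, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty observation vector")
    f = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1) / n)
    d = float(max(d_plus, d_minus, 0.0))
    pvalue = float(special.kolmogorov(math.sqrt(n) * d))
    return d, min(pvalue, 1.0)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass(frozen=True)
class FitResult:
    spec: DistributionSpec
    loglik: float
    aic: float
    ks_stat: float
    ks_pvalue: float
    n_obs: int
    fallback: bool = False


def _loglik(spec: DistributionSpec, x: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        ll = np.log(_frozen(spec).pdf(x))
    return float(np.sum(ll))


def _fit_uniform(x: np.ndarray) -> DistributionSpec:
    return DistributionSpec("uniform", {"min": float(x.min()), "max": float(x.max())})


def _fit_normal(x: np.ndarray) -> DistributionSpec:
    return DistributionSpec("normal", {"mu": float(x.mean()), "sigma": float(x.std())})


def _fit_lognormal(x: np.ndarray) -> DistributionSpec:
    if np.any(x <= 0):
        raise ValueError("lognormal requires positive data")
    lx = np.log(x)
    return DistributionSpec(
        "lognormal", {"mu_log": float(lx.mean()), "sigma_log": float(lx.std())}
    )


def _fit_gamma(x: np.ndarray) -> DistributionSpec:
    if np.any(x <= 0):
        raise ValueError("gamma requires positive data")
    a, _, scale = stats.gamma.fit(x, floc=0.0)
    return DistributionSpec("gamma", {"shape": float(a), "scale": float(scale)})


def _fit_weibull(x: np.ndarray) -> DistributionSpec:
    if np.any(x <= 0):
        raise ValueError("weibull requires positive data")
    c, _, scale = stats.weibull_min.fit(x, floc=0.0)
    return DistributionSpec("weibull", {"shape": float(c), "scale": float(scale)})


def _fit_triangular(x: np.ndarray) -> DistributionSpec:
    # bounds just outside the data (pdf is 0 at a and b), profile over mode
    span = float(x.max() - x.min())
    pad = max(span, 1e-12) * 1e-3
    a = float(x.min()) - pad
    b = float(x.max()) + pad

    def nll(c: float) -> float:
        spec = DistributionSpec("triangular", {"min": a, "max": b, "mode": c})
        return -_loglik(spec, x)

    res = optimize.minimize_scalar(nll, bounds=(a + pad / 2, b - pad / 2), method="bounded")
    return DistributionSpec("triangular", {"min": a, "max": b, "mode": float(res.x)})


_FITTERS = {
    "uniform": _fit_uniform,
    "triangular": _fit_triangular,
    "normal": _fit_normal,
    "lognormal": _fit_lognormal,
    "gamma": _fit_gamma,
    "weibull": _fit_weibull,
}


def fit_distribution(
    obs: Sequence[float],
    families: Iterable[str] = FAMILIES,
    *,
    fallback_bounds: tuple[float, float] | None = None,
    min_obs: int = 10,
) -> list[FitResult]:
    """Maximum-likelihood fit per family, ranked by AIC (ascending).

    With fewer than ``min_obs`` observations a uniform spanning the
    observed range (or ``fallback_bounds`` if given) is returned alone,
    flagged ``fallback=True`` — sparse data do not justify a shaped
    distribution.
    """
    x = np.asarray(obs, dtype=float)
    if x.size == 0:
        raise ValueError("no observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("observations must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all observations identical; no distribution is identifiable")
    families = list(families)
    if not families:
        raise ValueError("no families requested")

    if x.size < min_obs:
        lo, hi = fallback_bounds if fallback_bounds is not None else (x.min(), x.max())
        spec = DistributionSpec("uniform", {"min": float(lo), "max": float(hi)})
        ll = _loglik(spec, x)
        d, p = ks_statistic(x, _frozen(spec).cdf)
        return [
            FitResult(spec, ll, 2 * _N_PARAMS["uniform"] - 2 * ll, d, p, int(x.size), True)
        ]

    results: list[FitResult] = []
    for family in families:
        try:
            spec = _FITTERS[family](x)
        except (ValueError, RuntimeError):
            continue
        ll = _loglik(spec, x)
        if not np.isfinite(ll):
            continue
        aic = 2 * _N_PARAMS[family] - 2 * ll
        d, p = ks_statistic(x, _frozen(spec).cdf)
        results.append(FitResult(spec, ll, aic, d, p, int(x.size)))
    if not results:
        raise RuntimeError("no family could be fitted to the data")
    results.sort(key=lambda r: r.aic)
    return results


def fit_report_frame(results: Sequence[FitResult], name: str = ""):
    """Tabulate fit results (one row per family) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "name": name,
                "family": r.spec.family,
                "params": ";".join(f"{k}={v:.6g}" for k, v in r.spec.params.items()),
                "loglik": r.loglik,
                "aic": r.aic,
                "ks_stat": r.ks_stat,
                "ks_pvalue": r.ks_pvalue,
                "n": r.n_obs,
                "fallback": r.fallback,
            }
        )
    return pd.DataFrame(rows)
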