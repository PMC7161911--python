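"""Packaged GSP distribution catalogue and helpers."""

from __future__ import annotations

from importlib import resources

import yaml

from .distributions import (
    DistributionSpec,
    TruncatedDistribution,
    TruncationRule,
    make_distribution,
)

__all__ = ["GSP_NAMES", "load_gsp_specs", "load_gsp_distributions", "default_gsp_values"]

#: canonical parameter order used by every design matrix
GSP_NAMES = (
    "B01ND",
    "B12ND",
    "LAXS",
    "SLAS",
    "LLIFA",
    "LPEFR",
    "LNSLP",
    "NODWT",
    "NODL",
    "PARUE",
    "TBLSZ",
    "BR1F",
    "BR2F",
    "BR3F",
    "BR4F",
    "KCAN",
)


def _spec_from_record(rec: dict) -> DistributionSpec:
    trunc = None
    if "truncation" in rec:
        trunc = TruncationRule(**rec["truncation"])
    return DistributionSpec(
        family=rec["family"],
        params={k: float(v) for k, v in rec["params"].items()},
        truncation=trunc,
        integer=bool(rec.get("integer", False)),
    )


def load_gsp_specs(path=None) -> dict[str, DistributionSpec]:
    """Load the GSP distribution catalogue (packaged default or a file)."""
    if path is None:
        text = (
            resources.files("cassava_gsua").joinpath("data/gsp_distributions.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    specs = {name: _spec_from_record(rec) for name, rec in raw.items()}
    missing = [n for n in GSP_NAMES if n not in specs]
    if path is None and missing:
        raise RuntimeError(f"packaged catalogue is missing GSPs: {missing}")
    return specs


def load_gsp_distributions(path=None) -> dict[str, TruncatedDistribution]:
    return {name: make_distribution(spec) for name, spec in load_gsp_specs(path).items()}


def default_gsp_values(path=None) -> dict[str, float]:
    """Median of every GSP distribution (integer GSPs rounded)."""
    out = {}
    for name, dist in load_gsp_distributions(path).items():
        v = dist.median()
        out[name] = float(round(v)) if dist.spec.integer else v
    return out
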