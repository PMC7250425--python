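"""Diversification per unit time and per unit distance.

Net diversification *rate* is log(n)/t: n extant species accumulated over a
stem age of t Myr, i.e. species per lineage per Myr.  Net diversification
*density* is log(n)/sqrt(A): the same log-accumulation measured against the
linear extent of the clade's range (A in km^2), i.e. species per lineage per
km.  The square root puts the denominator on a one-dimensional distance
scale, since ranges spread in two dimensions.  Three cruder variants
(n/A, log(n)/A, log(n)/log(A)) are provided for comparison; simulations
show they do not track the spatial scale of diversification the way
log(n)/sqrt(A) does.

Logs are natural by default (matching the lineage-accumulation rationale of
the rate formula); base 10 is available and, when chosen, is applied to both
metrics so rate and density stay directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DENSITY_VARIANTS = ("log_sqrt", "raw_ratio", "log_ratio", "log_log")

_LOG = {"e": math.log, "10": math.log10}


def _logf(base: str):
    try:
        return _LOG[str(base)]
    except KeyError:
        raise ValueError(f"log base must be 'e' or '10', got {base!r}")


def net_diversification_rate(n: int, t_stem: float, base: str = "e") -> float:
    """log(n) / t_stem in species per lineage per Myr; 0 for monotypic clades."""
    if n < 1:
        raise ValueError("species count must be >= 1")
    if t_stem <= 0:
        raise ValueError(f"stem age must be positive, got {t_stem}")
    return _logf(base)(n) / t_stem


def diversification_density(
    n: int, area_km2: float, variant: str = "log_sqrt", base: str = "e"
) -> float:
    """Diversification density for a clade of ``n`` species occupying ``area_km2``.

    The preferred variant is ``log_sqrt`` = log(n)/sqrt(A) (spp per km);
    ``raw_ratio`` = n/A, ``log_ratio`` = log(n)/A, ``log_log`` = log(n)/log(A).
    """
    if n < 1:
        raise ValueError("species count must be >= 1")
    if area_km2 <= 0:
        raise ValueError(f"area must be positive, got {area_km2}")
    log = _logf(base)
    if variant == "log_sqrt":
        return log(n) / math.sqrt(area_km2)
    if variant == "raw_ratio":
        return n / area_km2
    if variant == "log_ratio":
        return log(n) / area_km2
    if variant == "log_log":
        la = log(area_km2)
        if la == 0:
            raise ValueError("log(A) = 0: area equal to 1 in log_log variant")
        return log(n) / la
    raise ValueError(f"unknown variant {variant!r}; choose from {DENSITY_VARIANTS}")


@dataclass
class DiversificationMetrics:
    """All metrics for one clade: rate plus the four density variants."""

    clade_id: str
    n: int
    stem_age: float
    area_km2: float
    rate: float
    density: float          # log(n)/sqrt(A), the preferred metric
    raw_ratio: float        # n/A
    log_ratio: float        # log(n)/A
    log_log: float          # log(n)/log(A)


def clade_metrics(
    clade_id: str, n: int, stem_age: float, area_km2: float, base: str = "e"
) -> DiversificationMetrics:
    return DiversificationMetrics(
        clade_id=clade_id,
        n=n,
        stem_age=stem_age,
        area_km2=area_km2,
        rate=net_diversification_rate(n, stem_age, base=base),
        density=diversification_density(n, area_km2, "log_sqrt", base=base),
        raw_ratio=diversification_density(n, area_km2, "raw_ratio", base=base),
        log_ratio=diversification_density(n, area_km2, "log_ratio", base=base),
        log_log=diversification_density(n, area_km2, "log_log", base=base),
    )
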