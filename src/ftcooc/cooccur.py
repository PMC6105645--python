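"""Focal-TF co-occupancy statistics against a background-TF null.

The co-occupancy rate is the percentage of regulatory regions footprinted by
the focal TF that also carry a partner footprint. The null is the mean and
sample SD of the focal TF's co-occupancy rates with a panel of ~10
background TFs; enrichment is reported as fold (rate / mean) and z
((rate - mean) / sd). A two-age contrast reports the percent decline in
focal-footprinted genes and the percent drop in co-occupied genes.

Rates are reported in percent throughout. Undefined quantities (zero focal
regions, zero-mean or zero-SD null) are flagged, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .reganno import RegionOccupancy

__all__ = [
    "CooccupancyStat",
    "BackgroundNull",
    "EnrichmentSummary",
    "AgeContrast",
    "cooccupancy_rate",
    "background_null",
    "enrichment_summary",
    "age_contrast",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CooccupancyStat:
    focal: str
    partner: str
    n_focal_regions: int
    n_co_regions: int
    rate: float | None  # percent; None when no focal region exists

    @property
    def defined(self) -> bool:
        return self.rate is not None


@dataclass(frozen=True)
class BackgroundNull:
    panel: tuple[str, ...]
    rates: tuple[float, ...]  # percent, aligned with panel
    mean: float
    sd: float


@dataclass(frozen=True)
class EnrichmentSummary:
    fold: float | None  # None when the null mean is 0
    z: float | None  # None when the null SD is 0


@dataclass(frozen=True)
class AgeContrast:
    young_n_focal_genes: int
    old_n_focal_genes: int
    young_co_rate: float
    old_co_rate: float
    young_co_genes: float  # unrounded genes x rate/100 unless integers given
    old_co_genes: float
    pct_decline_focal_genes: float | None
    pct_drop_co_genes: float | None

    @property
    def pct_decline_focal_genes_rounded(self) -> int | None:
        if self.pct_decline_focal_genes is None:
            return None
        return round(self.pct_decline_focal_genes)

    @property
    def pct_drop_co_genes_rounded(self) -> int | None:
        if self.pct_drop_co_genes is None:
            return None
        return round(self.pct_drop_co_genes)


def cooccupancy_rate(
    occupancy: RegionOccupancy, focal: str, partner: str
) -> CooccupancyStat:
    """Percent of focal-footprinted regions also footprinted by the partner."""
    focal_regions = [rid for rid, tfs in occupancy.items() if focal in tfs]
    co = [rid for rid in focal_regions if partner in occupancy[rid]]
    n_focal, n_co = len(focal_regions), len(co)
    rate = 100.0 * n_co / n_focal if n_focal else None
    if rate is None:
        logger.warning("no regions footprinted by %s; rate undefined", focal)
    return CooccupancyStat(
        focal=focal,
        partner=partner,
        n_focal_regions=n_focal,
        n_co_regions=n_co,
        rate=rate,
    )


def background_null(
    occupancy: RegionOccupancy, focal: str, panel: Sequence[str]
) -> BackgroundNull:
    """Mean and sample SD (n-1) of the focal TF's co-occupancy rates with
    each background panel TF. Panel TFs whose rate is undefined are
    excluded; the panel must retain >= 2 members."""
    if focal in panel:
        raise ValueError("focal TF must not be in the background panel")
    if len(panel) < 2:
        raise ValueError("background panel needs >= 2 TFs")
    kept: list[str] = []
    rates: list[float] = []
    for tf in panel:
        stat = cooccupancy_rate(occupancy, focal, tf)
        if stat.rate is None:
            logger.warning("panel TF %s has no focal regions; excluded", tf)
            continue
        kept.append(tf)
        rates.append(stat.rate)
    if len(kept) < 2:
        raise ValueError("background panel shrank below 2 usable TFs")
    mean = sum(rates) / len(rates)
    sd = math.sqrt(sum((r - mean) ** 2 for r in rates) / (len(rates) - 1))
    return BackgroundNull(panel=tuple(kept), rates=tuple(rates), mean=mean, sd=sd)


def enrichment_summary(
    stat: CooccupancyStat, null: BackgroundNull
) -> EnrichmentSummary:
    """Fold and z of the focal-partner rate against the background null.

    No internal rounding; fold is None when the null mean is 0 and z is None
    when the null SD is 0.
    """
    if stat.rate is None:
        return EnrichmentSummary(fold=None, z=None)
    fold = stat.rate / null.mean if null.mean > 0 else None
    z = (stat.rate - null.mean) / null.sd if null.sd > 0 else None
    if fold is None:
        logger.warning("null mean is 0; fold undefined")
    if z is None:
        logger.warning("null SD is 0; z undefined")
    return EnrichmentSummary(fold=fold, z=z)


def age_contrast(
    young: tuple[int, float],
    old: tuple[int, float],
    young_co_genes: int | None = None,
    old_co_genes: int | None = None,
) -> AgeContrast:
    """Contrast two ages computed with identical parameters.

    ``young``/``old`` are (n focal-footprinted genes, co-occupancy rate in
    percent). Co-occupied gene counts default to genes x rate/100
    (unrounded); pass integer counts to use direct gene-category tallies
    instead. Percent declines are 100*(young - old)/young; both unrounded
    values and nearest-integer roundings are exposed.
    """
    (young_n, young_rate) = young
    (old_n, old_rate) = old
    y_co = float(young_co_genes) if young_co_genes is not None \
        else young_n * young_rate / 100.0
    o_co = float(old_co_genes) if old_co_genes is not None \
        else old_n * old_rate / 100.0

    decline = 100.0 * (young_n - old_n) / young_n if young_n > 0 else None
    drop = 100.0 * (y_co - o_co) / y_co if y_co > 0 else None
    if decline is None or drop is None:
        logger.warning("zero young counts; contrast partially undefined")
    return AgeContrast(
        young_n_focal_genes=young_n,
        old_n_focal_genes=old_n,
        young_co_rate=young_rate,
        old_co_rate=old_rate,
        young_co_genes=y_co,
        old_co_genes=o_co,
        pct_decline_focal_genes=decline,
        pct_drop_co_genes=drop,
    )
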