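"""Promoter/enhancer regulatory regions, footprint-to-region assignment, and
the two-category gene classification.

Promoters are fixed windows around the TSS (default 2000 bp upstream /
300 bp downstream). Enhancers come from a cis-element interval list and are
attached to genes whose span contains them, with a nearest-TSS fallback
within 100 kb. Gene categories: ``focal_and_partner`` when both the focal
and the partner TF are footprinted somewhere in the gene's regulatory
regions (gene-level union, no distance condition), else ``focal_only`` when
the focal TF is, else ``other``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .footprint import FootprintCall
from .formats_io import GenomicInterval, TssRecord

__all__ = [
    "RegulatoryRegion",
    "RegionOccupancy",
    "make_promoters",
    "attach_enhancers",
    "assign_footprints",
    "gene_categories",
]

logger = logging.getLogger(__name__)

NEAREST_TSS_MAX_DIST = 100_000


@dataclass(frozen=True)
class RegulatoryRegion:
    region_id: str
    kind: str  # "promoter" | "enhancer"
    interval: GenomicInterval
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"invalid region kind {self.kind!r}")
        if not self.gene_ids:
            raise ValueError("region must map to at least one gene")


RegionOccupancy = dict[str, set[str]]  # region_id -> TF names footprinted inside


def make_promoters(
    tss_records: Sequence[TssRecord],
    up: int = 2000,
    down: int = 300,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryRegion]:
    """One promoter window per TSS.

    Plus strand: [tss - up, tss + down); minus strand: [tss - down + 1,
    tss + up + 1). Windows are clipped to the chromosome.
    """
    promoters: list[RegulatoryRegion] = []
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - up, rec.tss + down
        else:
            start, end = rec.tss - down + 1, rec.tss + up + 1
        clipped_start = max(start, 0)
        clipped_end = end
        if chrom_sizes is not None and rec.chrom in chrom_sizes:
            clipped_end = min(end, chrom_sizes[rec.chrom])
        if clipped_start != start or clipped_end != end:
            logger.info("promoter for %s clipped at chromosome edge", rec.gene_id)
        promoters.append(
            RegulatoryRegion(
                region_id=f"prom_{rec.gene_id}",
                kind="promoter",
                interval=GenomicInterval(
                    chrom=rec.chrom,
                    start=clipped_start,
                    end=clipped_end,
                    strand=rec.strand,
                    name=f"prom_{rec.gene_id}",
                ),
                gene_ids=(rec.gene_id,),
            )
        )
    return promoters


def attach_enhancers(
    cis_elements: Sequence[GenomicInterval],
    gene_spans: Mapping[str, GenomicInterval],
    tss_records: Sequence[TssRecord] | None = None,
) -> list[RegulatoryRegion]:
    """Turn cis-elements into enhancer regions assigned to containing genes.

    An element is attached to every gene whose span wholly contains it
    (intragenic assignment). Elements inside no gene fall back to the
    nearest TSS within 100 kb; beyond that they are dropped with a log
    message.
    """
    enhancers: list[RegulatoryRegion] = []
    n_dropped = 0
    for i, el in enumerate(cis_elements, 1):
        hosts = tuple(
            sorted(g for g, span in gene_spans.items() if span.contains(el))
        )
        if not hosts and tss_records:
            mid = (el.start + el.end) // 2
            best, best_dist = None, None
            for rec in tss_records:
                if rec.chrom != el.chrom:
                    continue
                dist = abs(rec.tss - mid)
                if best_dist is None or dist < best_dist:
                    best, best_dist = rec.gene_id, dist
            if best is not None and best_dist is not None and best_dist <= NEAREST_TSS_MAX_DIST:
                hosts = (best,)
        if not hosts:
            n_dropped += 1
            continue
        name = el.name if el.name != "." else f"enh_{i}"
        enhancers.append(
            RegulatoryRegion(
                region_id=name,
                kind="enhancer",
                interval=el,
                gene_ids=hosts,
            )
        )
    if n_dropped:
        logger.info("dropped %d cis-elements with no gene within 100 kb", n_dropped)
    return enhancers


def assign_footprints(
    calls_by_tf: Mapping[str, Iterable[FootprintCall]],
    regions: Sequence[RegulatoryRegion],
) -> RegionOccupancy:
    """Region occupancy: TFs with >= 1 bound call overlapping each region
    by >= 1 bp. Regions with no bound TF map to an empty set."""
    occ: RegionOccupancy = {r.region_id: set() for r in regions}
    by_chrom: dict[str, list[RegulatoryRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom_regions in by_chrom.values():
        chrom_regions.sort(key=lambda r: r.interval.start)

    unknown_chroms: set[str] = set()
    for tf, calls in calls_by_tf.items():
        for call in calls:
            if not call.bound:
                continue
            iv = call.site.interval
            if iv.chrom not in by_chrom:
                unknown_chroms.add(iv.chrom)
                continue
            for region in by_chrom[iv.chrom]:
                if region.interval.start >= iv.end:
                    break
                if region.interval.overlaps(iv):
                    occ[region.region_id].add(tf)
    if unknown_chroms:
        logger.warning(
            "ignored bound calls on chromosomes without regions: %s",
            ", ".join(sorted(unknown_chroms)),
        )
    return occ


def gene_categories(
    occupancy: RegionOccupancy,
    regions: Sequence[RegulatoryRegion],
    focal: str,
    partner: str,
) -> dict[str, str]:
    """Classify every gene seen in ``regions``.

    ``focal_and_partner``: both TFs footprinted somewhere in the gene's
    promoter/enhancer regions (not necessarily the same region);
    ``focal_only``: focal footprinted, partner not; ``other``: no focal
    footprint.
    """
    gene_tfs: dict[str, set[str]] = {}
    for region in regions:
        tfs = occupancy.get(region.region_id, set())
        for gene in region.gene_ids:
            gene_tfs.setdefault(gene, set()).update(tfs)
    out: dict[str, str] = {}
    for gene, tfs in gene_tfs.items():
        if focal in tfs and partner in tfs:
            out[gene] = "focal_and_partner"
        elif focal in tfs:
            out[gene] = "focal_only"
        else:
            out[gene] = "other"
    return out
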