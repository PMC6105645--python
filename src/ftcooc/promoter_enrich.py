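"""Single-site motif over-representation in promoters of a foreground gene
set versus a background set.

Per TF, a nucleotide-rate Z-score compares the foreground hit count with the
expectation under the background hit rate, and a one-sided Fisher exact test
compares the fractions of genes with at least one hit. PWMs below the
total-information-content filter (default 8 bits) are excluded up front; the
scan threshold is the relative matrix score (default 0.90) and the promoter
window is -1000/+300 around the TSS (narrower than the footprinting
window, by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

from scipy import stats

from .formats_io import Pwm, TssRecord
from .motifscan import information_content, scan
from .reganno import make_promoters

__all__ = ["EnrichParams", "EnrichmentResult", "enrich"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichParams:
    up: int = 1000
    down: int = 300
    rel_threshold: float = 0.90
    min_ic_bits: float = 8.0
    z_flag: float = 10.0


@dataclass(frozen=True)
class EnrichmentResult:
    tf_name: str
    fg_hits: int
    fg_nt: int
    bg_hits: int
    bg_nt: int
    bg_rate: float  # hits per scanned nucleotide in background
    z: float
    fg_gene_frac: float
    bg_gene_frac: float
    fisher_p: float
    passes_z: bool


def _promoter_hits(
    genes: Sequence[str],
    tss_by_gene: Mapping[str, TssRecord],
    genome: Mapping[str, str],
    pwm: Pwm,
    params: EnrichParams,
    chrom_sizes: Mapping[str, int],
) -> tuple[int, int, int]:
    """(total hits, scanned nucleotides, genes with >= 1 hit)."""
    hits = 0
    nt = 0
    genes_hit = 0
    promoters = make_promoters(
        [tss_by_gene[g] for g in genes],
        up=params.up,
        down=params.down,
        chrom_sizes=chrom_sizes,
    )
    for region in promoters:
        sites = scan([region.interval], genome, pwm, params.rel_threshold)
        nt += len(region.interval)
        hits += len(sites)
        if sites:
            genes_hit += 1
    return hits, nt, genes_hit


def enrich(
    fg_genes: Sequence[str],
    bg_genes: Sequence[str],
    tss_records: Sequence[TssRecord],
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    params: EnrichParams | None = None,
) -> list[EnrichmentResult]:
    """Per-TF over-representation of motif hits in foreground promoters.

    z = (fg_hits - fg_nt * bg_rate) / sqrt(fg_nt * bg_rate * (1 - bg_rate));
    the Fisher p is a one-sided exact test on the 2x2 gene-hit table.
    Results are sorted by descending z and flagged at z >= 10.
    """
    if params is None:
        params = EnrichParams()
    if not fg_genes:
        raise ValueError("empty foreground gene set")
    tss_by_gene = {r.gene_id: r for r in tss_records}
    missing = [g for g in list(fg_genes) + list(bg_genes) if g not in tss_by_gene]
    if missing:
        raise ValueError(f"genes without TSS records: {missing[:5]}")
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    results: list[EnrichmentResult] = []
    for pwm in pwms:
        total_ic, _ = information_content(pwm)
        if total_ic < params.min_ic_bits:
            logger.info(
                "excluding %s: %.2f bits < %.1f-bit specificity filter",
                pwm.tf_name, total_ic, params.min_ic_bits,
            )
            continue
        fg_hits, fg_nt, fg_genes_hit = _promoter_hits(
            fg_genes, tss_by_gene, genome, pwm, params, chrom_sizes
        )
        bg_hits, bg_nt, bg_genes_hit = _promoter_hits(
            bg_genes, tss_by_gene, genome, pwm, params, chrom_sizes
        )
        bg_rate = bg_hits / bg_nt if bg_nt else 0.0
        expected = fg_nt * bg_rate
        var = fg_nt * bg_rate * (1.0 - bg_rate)
        z = (fg_hits - expected) / math.sqrt(var) if var > 0 else 0.0

        table = [
            [fg_genes_hit, len(fg_genes) - fg_genes_hit],
            [bg_genes_hit, len(bg_genes) - bg_genes_hit],
        ]
        _, fisher_p = stats.fisher_exact(table, alternative="greater")

        results.append(
            EnrichmentResult(
                tf_name=pwm.tf_name,
                fg_hits=fg_hits,
                fg_nt=fg_nt,
                bg_hits=bg_hits,
                bg_nt=bg_nt,
                bg_rate=bg_rate,
                z=z,
                fg_gene_frac=fg_genes_hit / len(fg_genes),
                bg_gene_frac=bg_genes_hit / len(bg_genes) if bg_genes else 0.0,
                fisher_p=float(fisher_p),
                passes_z=z >= params.z_flag,
            )
        )
    results.sort(key=lambda r: -r.z)
    return results
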