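"""Synthetic ATAC-seq-like dataset generator.

Builds a complete desk-scale dataset on one synthetic chromosome: a gene/TSS
annotation, promoter and intragenic-enhancer regions, a TF panel (one focal
factor, one partner, ~10 background factors) with synthetic PWMs, planted
motif instances, per-age bound/unbound truth labels with a controllable
region-level co-occupancy structure, and simulated cut-count tracks in which
bound sites show central cut depletion with flanking enrichment inside
accessible regions.

Site presence (a motif instance planted in a region) is decoupled from
binding (a footprint realized in the cut track), so unbound motif instances
exist as hard negatives for the footprint model. Joint binding of the focal
and partner factors is planted at the region level: in a designated
"growth-relevant" subset of focal-bound regions, the partner binds with
probability ``rho_co`` instead of its marginal probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .formats_io import (
    CutTrack,
    GenomicInterval,
    Pwm,
    TssRecord,
    write_bed,
    write_cut_track,
    write_fasta,
    write_pwms_jaspar,
    write_tss_table,
)
from .motifscan import MotifSite
from .footprint import CutMatrix
from .reganno import RegulatoryRegion

__all__ = [
    "SyntheticConfig",
    "PlantedSite",
    "SyntheticTruth",
    "design_truth",
    "simulate_cut_track",
    "simulate_footprint_matrix",
    "emit_dataset",
    "generate",
]

_RETRY_LIMIT = 200


def _as_age_map(value: float | Mapping[str, float], ages: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {a: float(value[a]) for a in ages}
    return {a: float(value) for a in ages}


@dataclass
class SyntheticConfig:
    """Every knob of the generator; reproducible from (config, seed)."""

    n_genes: int = 250
    promoter_up: int = 2000
    promoter_down: int = 300
    n_enhancers: int = 50
    enhancer_length: int = 1000
    chrom: str = "chrS"
    chrom_length: int = 5_000_000
    ages: tuple[str, ...] = ("P0", "adult")

    focal_tf: str = "KLF6L"
    partner_tf: str = "STAT3L"
    background_tfs: tuple[str, ...] = tuple(f"BG{i:02d}" for i in range(1, 11))
    motif_width: int = 12
    site_prob: float = 0.5  # chance a TF gets a motif instance in a region
    # sites are planted this far inside region edges so that footprint
    # profile windows stay within homogeneously accessible DNA
    site_margin: int = 150

    focal_bind_prob: float | Mapping[str, float] = field(
        default_factory=lambda: {"P0": 0.4, "adult": 0.2}
    )
    partner_bind_prob: float | Mapping[str, float] = 0.05
    background_bind_prob: float = 0.05
    co_subset_frac: float = 0.75
    rho_co: float | Mapping[str, float] = 0.6

    background_cut_rate: float = 0.2
    peak_fold: float = 8.0
    footprint_depletion: float = 0.2
    flank_boost: float = 2.0
    flank_width: int = 10
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.ages = tuple(self.ages)
        self.background_tfs = tuple(self.background_tfs)
        names = (self.focal_tf, self.partner_tf, *self.background_tfs)
        if len(set(names)) != len(names):
            raise ValueError("TF panel names must be unique")
        for p in (self.site_prob, self.co_subset_frac, self.background_bind_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (self.focal_bind_prob, self.partner_bind_prob, self.rho_co):
            for v in _as_age_map(m, self.ages).values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must lie in [0, 1]")
        if not (self.footprint_depletion < 1 < self.flank_boost):
            raise ValueError("need footprint_depletion < 1 < flank_boost")
        min_region = min(self.promoter_up + self.promoter_down, self.enhancer_length)
        if self.motif_width >= min_region:
            raise ValueError("motif width must be smaller than region widths")
        if self.motif_width + 2 * self.site_margin >= min_region:
            raise ValueError("site_margin leaves no room to plant motifs")

    @property
    def tf_names(self) -> tuple[str, ...]:
        return (self.focal_tf, self.partner_tf, *self.background_tfs)

    def marginal(self, tf: str, age: str) -> float:
        if tf == self.focal_tf:
            return _as_age_map(self.focal_bind_prob, self.ages)[age]
        if tf == self.partner_tf:
            return _as_age_map(self.partner_bind_prob, self.ages)[age]
        return self.background_bind_prob

    def rho(self, age: str) -> float:
        return _as_age_map(self.rho_co, self.ages)[age]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ages", "background_tfs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class PlantedSite:
    """A planted motif instance with per-age bound labels."""

    tf_name: str
    region_id: str
    interval: GenomicInterval
    rel_score: float
    bound: dict[str, bool]  # age -> label

    def as_motif_site(self) -> MotifSite:
        return MotifSite(
            interval=self.interval,
            tf_name=self.tf_name,
            strand=self.interval.strand,
            score=self.rel_score,
            rel_score=self.rel_score,
        )


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    tss: list[TssRecord]
    gene_spans: dict[str, GenomicInterval]
    regions: list[RegulatoryRegion]
    pwms: dict[str, Pwm]
    sites: list[PlantedSite]
    growth_relevant: set[str]  # region_ids

    def sites_for(self, tf: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.tf_name == tf]

    def region_occupancy(self, age: str) -> dict[str, set[str]]:
        """Truth-level occupancy: bound TFs per region at an age."""
        occ: dict[str, set[str]] = {r.region_id: set() for r in self.regions}
        for s in self.sites:
            if s.bound[age]:
                occ[s.region_id].add(s.tf_name)
        return occ


def _make_pwm(name: str, width: int, rng: np.random.Generator) -> Pwm:
    consensus = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), 0.05)
    probs[np.arange(width), consensus] = 0.85
    return Pwm(tf_name=name, probs=probs)


def design_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Lay out genes, regions, PWMs, planted sites and per-age bound labels.

    Genes are placed on a jittered grid of equal slots so that promoters
    never overlap; enhancers are placed intragenically with redraws on
    overlap (error past the retry limit).
    """
    rng = np.random.default_rng([config.seed, 0])
    cfg = config
    prom_width = cfg.promoter_up + cfg.promoter_down
    slot = cfg.chrom_length // cfg.n_genes
    need = prom_width + (cfg.enhancer_length if cfg.n_enhancers else 0) + 40
    if slot < need:
        raise ValueError(
            f"chromosome too short: slot {slot} bp cannot hold a {prom_width} bp "
            f"promoter" + (
                f" plus a {cfg.enhancer_length} bp enhancer" if cfg.n_enhancers else ""
            )
        )

    tss: list[TssRecord] = []
    gene_spans: dict[str, GenomicInterval] = {}
    regions: list[RegulatoryRegion] = []
    for i in range(cfg.n_genes):
        gene = f"g{i:04d}"
        s0, s1 = i * slot, (i + 1) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            t = s0 + cfg.promoter_up
            prom = GenomicInterval(cfg.chrom, s0, s0 + prom_width, "+", f"prom_{gene}")
            span = GenomicInterval(cfg.chrom, t, s1 - 10, "+", gene)
        else:
            t = s1 - 1 - cfg.promoter_up
            prom = GenomicInterval(cfg.chrom, s1 - prom_width, s1, "-", f"prom_{gene}")
            span = GenomicInterval(cfg.chrom, s0 + 10, t + 1, "-", gene)
        tss.append(TssRecord(gene_id=gene, chrom=cfg.chrom, strand=strand, tss=t))
        gene_spans[gene] = span
        regions.append(
            RegulatoryRegion(f"prom_{gene}", "promoter", prom, (gene,))
        )

    # intragenic enhancers, non-overlapping with promoters and each other
    taken = [r.interval for r in regions]
    for k in range(cfg.n_enhancers):
        for attempt in range(_RETRY_LIMIT + 1):
            if attempt == _RETRY_LIMIT:
                raise RuntimeError("could not place enhancer without overlap")
            gi = int(rng.integers(0, cfg.n_genes))
            gene = f"g{gi:04d}"
            span = gene_spans[gene]
            if len(span) <= cfg.enhancer_length:
                continue
            off = int(rng.integers(0, len(span) - cfg.enhancer_length))
            cand = GenomicInterval(
                cfg.chrom,
                span.start + off,
                span.start + off + cfg.enhancer_length,
                ".",
                f"enh_{k:03d}",
            )
            if any(cand.overlaps(iv) for iv in taken):
                continue
            taken.append(cand)
            regions.append(
                RegulatoryRegion(cand.name, "enhancer", cand, (gene,))
            )
            break

    pwms = {tf: _make_pwm(tf, cfg.motif_width, rng) for tf in cfg.tf_names}

    # plant motif instances: one per TF per region with probability site_prob
    sites: list[PlantedSite] = []
    w = cfg.motif_width
    margin = cfg.site_margin
    for region in regions:
        iv = region.interval
        for tf in cfg.tf_names:
            if rng.random() >= cfg.site_prob:
                continue
            off = margin + int(rng.integers(0, len(iv) - w - 2 * margin))
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append(
                PlantedSite(
                    tf_name=tf,
                    region_id=region.region_id,
                    interval=GenomicInterval(
                        cfg.chrom, iv.start + off, iv.start + off + w, strand,
                        f"{tf}|{region.region_id}",
                    ),
                    rel_score=float(rng.uniform(0.85, 1.0)),
                    bound={},
                )
            )

    # growth-relevant flags over focal-sited regions
    focal_regions = {s.region_id for s in sites if s.tf_name == cfg.focal_tf}
    growth_relevant = {
        rid for rid in sorted(focal_regions) if rng.random() < cfg.co_subset_frac
    }

    # per-age bound labels: focal first, then partner (region-coupled), then
    # background TFs independently
    for age in cfg.ages:
        focal_bound_regions: set[str] = set()
        for s in sites:
            if s.tf_name != cfg.focal_tf:
                continue
            b = bool(rng.random() < cfg.marginal(cfg.focal_tf, age))
            s.bound[age] = b
            if b:
                focal_bound_regions.add(s.region_id)
        for s in sites:
            if s.tf_name == cfg.focal_tf:
                continue
            if s.tf_name == cfg.partner_tf:
                coupled = (
                    s.region_id in growth_relevant
                    and s.region_id in focal_bound_regions
                )
                p = cfg.rho(age) if coupled else cfg.marginal(cfg.partner_tf, age)
            else:
                p = cfg.marginal(s.tf_name, age)
            s.bound[age] = bool(rng.random() < p)

    return SyntheticTruth(
        config=cfg,
        tss=tss,
        gene_spans=gene_spans,
        regions=regions,
        pwms=pwms,
        sites=sites,
        growth_relevant=growth_relevant,
    )


def _mean_profile(truth: SyntheticTruth, age: str) -> np.ndarray:
    cfg = truth.config
    mu = np.full(cfg.chrom_length, cfg.background_cut_rate)
    for region in truth.regions:
        iv = region.interval
        mu[iv.start : iv.end] *= cfg.peak_fold
    fw = cfg.flank_width
    for s in truth.sites:
        if not s.bound[age]:
            continue
        iv = s.interval
        mu[iv.start : iv.end] *= cfg.footprint_depletion
        mu[max(iv.start - fw, 0) : iv.start] *= cfg.flank_boost
        mu[iv.end : iv.end + fw] *= cfg.flank_boost
    return mu


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_cut_track(
    truth: SyntheticTruth, config: SyntheticConfig, age: str
) -> CutTrack:
    """Negative-binomial per-base cut counts for one age.

    Mean = background rate, times peak_fold inside regulatory regions, times
    footprint_depletion over the cores of bound motif instances and
    flank_boost over their flanks; unbound instances leave the accessibility
    profile unmodified.
    """
    if age not in config.ages:
        raise ValueError(f"unknown age {age!r}")
    rng = np.random.default_rng([config.seed, 1000 + list(config.ages).index(age)])
    mu = _mean_profile(truth, age)
    return CutTrack({config.chrom: _nb_draw(mu, config.nb_dispersion, rng)})


def simulate_footprint_matrix(
    n_sites: int = 500,
    bound_frac: float = 0.3,
    motif_width: int = 12,
    L: int = 100,
    cut_rate: float = 1.6,
    footprint_depletion: float = 0.2,
    flank_boost: float = 2.0,
    flank_width: int = 10,
    nb_dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[CutMatrix, np.ndarray]:
    """Directly simulate a footprint-model input matrix with known labels.

    Rows are per-site NB counts over W + 2L positions at ``cut_rate`` per
    base (sites sit inside accessible peaks); bound rows get the depleted
    core and boosted flanks. Returns (matrix, labels) with labels[i] = 1 for
    bound. Site coordinates are laid out on a virtual chromosome and scores
    are drawn independently of the labels.
    """
    rng = np.random.default_rng(seed)
    C = motif_width + 2 * L
    labels = (rng.random(n_sites) < bound_frac).astype(int)
    mu = np.full((n_sites, C), cut_rate)
    core = slice(L, L + motif_width)
    bound_rows = labels == 1
    mu[bound_rows, core] *= footprint_depletion
    mu[bound_rows, L - flank_width : L] *= flank_boost
    mu[bound_rows, L + motif_width : L + motif_width + flank_width] *= flank_boost
    counts = _nb_draw(mu, nb_dispersion, rng)

    sites = []
    gap = C + 20
    for i in range(n_sites):
        start = 10_000 + i * gap
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            MotifSite(
                interval=GenomicInterval(
                    "chrV", start, start + motif_width, strand, f"site_{i}"
                ),
                tf_name="TFV",
                strand=strand,
                score=float(rng.uniform(0.85, 1.0)),
                rel_score=float(rng.uniform(0.85, 1.0)),
            )
        )
    matrix = CutMatrix(sites=sites, window_halfwidth=L, counts=counts)
    return matrix, labels


def generate(config: SyntheticConfig) -> tuple[SyntheticTruth, dict[str, CutTrack]]:
    """Truth plus one cut track per configured age."""
    truth = design_truth(config)
    tracks = {age: simulate_cut_track(truth, config, age) for age in config.ages}
    return truth, tracks


def _random_genome(truth: SyntheticTruth, rng: np.random.Generator) -> dict[str, str]:
    cfg = truth.config
    bases = np.array(list("ACGT"))
    seq = rng.integers(0, 4, size=cfg.chrom_length)
    chars = bases[seq]
    from .motifscan import reverse_complement

    for s in truth.sites:
        consensus = truth.pwms[s.tf_name].consensus
        if s.interval.strand == "-":
            consensus = reverse_complement(consensus)
        chars[s.interval.start : s.interval.end] = list(consensus)
    return {cfg.chrom: "".join(chars)}


def emit_dataset(
    truth: SyntheticTruth,
    tracks: Mapping[str, CutTrack],
    outdir: str | Path,
    with_fasta: bool = False,
) -> dict[str, Path]:
    """Write the dataset as plain-text files; byte-identical per (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    paths: dict[str, Path] = {}

    sizes_path = outdir / "chrom.sizes"
    sizes_path.write_text(f"{cfg.chrom}\t{cfg.chrom_length}\n")
    paths["chrom_sizes"] = sizes_path

    tss_path = outdir / "tss.tsv"
    write_tss_table(truth.tss, tss_path)
    paths["tss"] = tss_path

    enh_path = outdir / "enhancers.bed"
    write_bed(
        [r.interval for r in truth.regions if r.kind == "enhancer"], enh_path
    )
    paths["enhancers"] = enh_path

    pwm_path = outdir / "motifs.jaspar"
    write_pwms_jaspar([truth.pwms[tf] for tf in cfg.tf_names], pwm_path)
    paths["pwms"] = pwm_path

    for age in sorted(tracks):
        p = outdir / f"cuts_{age}.bedGraph"
        write_cut_track(tracks[age], p)
        paths[f"cuts_{age}"] = p

    truth_path = outdir / "truth_sites.tsv"
    with open(truth_path, "w") as fh:
        cols = ["tf", "region_id", "chrom", "start", "end", "strand", "rel_score"]
        cols += [f"bound_{age}" for age in cfg.ages]
        fh.write("\t".join(cols) + "\n")
        for s in truth.sites:
            row = [
                s.tf_name,
                s.region_id,
                s.interval.chrom,
                str(s.interval.start),
                str(s.interval.end),
                s.interval.strand,
                f"{s.rel_score:.6f}",
            ]
            row += ["1" if s.bound[age] else "0" for age in cfg.ages]
            fh.write("\t".join(row) + "\n")
    paths["truth_sites"] = truth_path

    gr_path = outdir / "growth_relevant.txt"
    gr_path.write_text("".join(f"{rid}\n" for rid in sorted(truth.growth_relevant)))
    paths["growth_relevant"] = gr_path

    if with_fasta:
        rng = np.random.default_rng([cfg.seed, 999])
        fasta_path = outdir / "genome.fa"
        write_fasta(_random_genome(truth, rng), fasta_path)
        paths["genome"] = fasta_path

    return paths
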