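"""Config-driven orchestration: simulate -> peaks -> candidate sites ->
footprint -> annotate -> co-occupancy -> report.

The report is a plain dict (JSON-serializable, sorted keys on write) and is
byte-identical across reruns of the same config and seed. Candidate motif
sites are taken from the synthetic truth in coordinates mode and restricted
to called peaks, which is where a real run would place its PWM scans.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import cooccur as cc
from . import reganno
from .footprint import FitOptions, build_cut_matrix, fit_centipede, posterior_calls
from .formats_io import CutTrack, write_narrowpeak
from .peakcall import PeakcallParams, call_peaks
from .synthetic_cortex import SyntheticConfig, SyntheticTruth, generate, emit_dataset

__all__ = ["PipelineConfig", "run_all", "analyze_age"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None
    synthetic: dict = field(default_factory=dict)
    peakcall: dict = field(default_factory=dict)
    footprint_L: int = 100
    posterior_threshold: float = 0.99
    restrict_sites_to_peaks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(**{**self.synthetic, "seed": self.seed})


def _peaks_mask(sites, peaks) -> np.ndarray:
    """Boolean mask of sites overlapping >= 1 called peak."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    for v in by_chrom.values():
        v.sort()
    mask = np.zeros(len(sites), dtype=bool)
    for i, s in enumerate(sites):
        iv = s.interval
        for ps, pe in by_chrom.get(iv.chrom, ()):
            if ps >= iv.end:
                break
            if iv.start < pe:
                mask[i] = True
                break
    return mask


def analyze_age(
    truth: SyntheticTruth,
    track: CutTrack,
    age: str,
    peak_params: PeakcallParams | None = None,
    L: int = 100,
    posterior_threshold: float = 0.99,
    restrict_sites_to_peaks: bool = True,
    fit_opts: FitOptions | None = None,
) -> dict[str, Any]:
    """Run peaks -> footprints -> annotation -> co-occupancy for one age."""
    cfg = truth.config
    peaks = call_peaks(track, peak_params)

    calls_by_tf: dict[str, list] = {}
    for tf in cfg.tf_names:
        planted = [s.as_motif_site() for s in truth.sites_for(tf)]
        if restrict_sites_to_peaks:
            mask = _peaks_mask(planted, peaks)
            planted = [s for s, m in zip(planted, mask) if m]
        if len(planted) < 2:
            logger.warning("TF %s has %d candidate sites; skipped", tf, len(planted))
            calls_by_tf[tf] = []
            continue
        matrix = build_cut_matrix(planted, track, L=L)
        fit = fit_centipede(matrix, opts=fit_opts)
        calls_by_tf[tf] = posterior_calls(matrix, fit, threshold=posterior_threshold)

    occupancy = reganno.assign_footprints(calls_by_tf, truth.regions)
    categories = reganno.gene_categories(
        occupancy, truth.regions, cfg.focal_tf, cfg.partner_tf
    )
    stat = cc.cooccupancy_rate(occupancy, cfg.focal_tf, cfg.partner_tf)
    null = cc.background_null(occupancy, cfg.focal_tf, list(cfg.background_tfs))
    summary = cc.enrichment_summary(stat, null)

    n_focal_genes = sum(
        1 for v in categories.values() if v in ("focal_only", "focal_and_partner")
    )
    n_co_genes = sum(1 for v in categories.values() if v == "focal_and_partner")
    return {
        "age": age,
        "n_peaks": len(peaks),
        "peaks": peaks,
        "calls_by_tf": calls_by_tf,
        "occupancy": occupancy,
        "categories": categories,
        "stat": stat,
        "null": null,
        "summary": summary,
        "n_focal_genes": n_focal_genes,
        "n_co_genes": n_co_genes,
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage per age and assemble the machine-readable report."""
    syn = config.synthetic_config()
    truth, tracks = generate(syn)
    peak_params = PeakcallParams(**config.peakcall)

    outdir = Path(config.outdir) if config.outdir else None
    provenance: dict[str, Any] = {
        "seed": config.seed,
        "synthetic": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(syn).items()
        },
        "peakcall": asdict(peak_params),
        "footprint_L": config.footprint_L,
        "posterior_threshold": config.posterior_threshold,
    }
    if outdir is not None:
        data_dir = outdir / "data"
        paths = emit_dataset(truth, tracks, data_dir)
        provenance["input_digests"] = {
            k: _digest(p) for k, p in sorted(paths.items())
        }

    per_age: dict[str, Any] = {}
    results: dict[str, dict[str, Any]] = {}
    for age in syn.ages:
        try:
            res = analyze_age(
                truth,
                tracks[age],
                age,
                peak_params=peak_params,
                L=config.footprint_L,
                posterior_threshold=config.posterior_threshold,
                restrict_sites_to_peaks=config.restrict_sites_to_peaks,
            )
        except Exception as exc:  # pragma: no cover - error surface
            raise RuntimeError(f"stage failure at age {age!r}: {exc}") from exc
        results[age] = res
        if outdir is not None:
            write_narrowpeak(res["peaks"], outdir / f"peaks_{age}.narrowPeak")
            _write_calls(res["calls_by_tf"], outdir / f"calls_{age}.tsv")
        stat, null, summary = res["stat"], res["null"], res["summary"]
        per_age[age] = {
            "n_peaks": res["n_peaks"],
            "n_focal_regions": stat.n_focal_regions,
            "n_co_regions": stat.n_co_regions,
            "cooccupancy_rate_pct": stat.rate,
            "background_mean_pct": null.mean,
            "background_sd_pct": null.sd,
            "background_rates_pct": dict(zip(null.panel, null.rates)),
            "fold": summary.fold,
            "z": summary.z,
            "n_focal_genes": res["n_focal_genes"],
            "n_co_genes": res["n_co_genes"],
        }

    report: dict[str, Any] = {"provenance": provenance, "per_age": per_age}
    if len(syn.ages) >= 2:
        young, old = syn.ages[0], syn.ages[1]
        contrast = cc.age_contrast(
            (results[young]["n_focal_genes"], results[young]["stat"].rate or 0.0),
            (results[old]["n_focal_genes"], results[old]["stat"].rate or 0.0),
            young_co_genes=results[young]["n_co_genes"],
            old_co_genes=results[old]["n_co_genes"],
        )
        report["age_contrast"] = {
            "young": young,
            "old": old,
            "pct_decline_focal_genes": contrast.pct_decline_focal_genes,
            "pct_decline_focal_genes_rounded": contrast.pct_decline_focal_genes_rounded,
            "pct_drop_co_genes": contrast.pct_drop_co_genes,
            "pct_drop_co_genes_rounded": contrast.pct_drop_co_genes_rounded,
        }
    if outdir is not None:
        write_report(report, outdir / "report.json")
    return report


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_calls(calls_by_tf: Mapping[str, list], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tchrom\tstart\tend\tstrand\trel_score\tposterior\tbound\n")
        for tf in sorted(calls_by_tf):
            for call in calls_by_tf[tf]:
                iv = call.site.interval
                fh.write(
                    f"{tf}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{call.site.strand}\t"
                    f"{call.site.rel_score:.6f}\t{call.posterior:.6g}\t"
                    f"{int(call.bound)}\n"
                )
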