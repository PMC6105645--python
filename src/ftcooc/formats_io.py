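"""Readers and writers for the text formats the pipeline touches, plus the
shared genomic-interval data model.

All coordinates are 0-based half-open internally (the BED convention);
1-based coordinates appear only in human-readable reports. Cut counts are
per-base transposase insertion events, pooled over strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "Pwm",
    "CutTrack",
    "Peak",
    "TssRecord",
    "FormatError",
    "read_pwms",
    "write_pwms_jaspar",
    "read_cut_track",
    "write_cut_track",
    "read_chrom_sizes",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tss_table",
    "write_tss_table",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix with background base frequencies.

    ``probs`` has shape (width, 4) in base order A, C, G, T; each row sums
    to 1 and every entry is strictly positive (pseudocounted).
    """

    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must have shape (width >= 1, 4)")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class Peak:
    """A called peak with narrowPeak statistics."""

    interval: GenomicInterval
    summit_offset: int
    fold_enrichment: float
    neg_log10_p: float
    neg_log10_q: float

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError("summit_offset outside peak interval")
        if min(self.fold_enrichment, self.neg_log10_p, self.neg_log10_q) < 0:
            raise ValueError("peak statistics must be non-negative")


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site (position of the first transcribed
    base, 0-based)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


class CutTrack:
    """Dense per-chromosome vectors of per-base cut counts."""

    def __init__(self, counts: Mapping[str, np.ndarray]):
        self._counts: dict[str, np.ndarray] = {}
        for chrom, vec in counts.items():
            arr = np.asarray(vec, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: counts must be a 1-D vector")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative cut counts")
            self._counts[chrom] = arr

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "CutTrack":
        return cls({c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()})

    @property
    def chroms(self) -> list[str]:
        return sorted(self._counts)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._counts[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._counts

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self._counts.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CutTrack):
            return NotImplemented
        return self._counts.keys() == other._counts.keys() and all(
            np.array_equal(self._counts[c], other._counts[c]) for c in self._counts
        )


# ---------------------------------------------------------------------------
# PWM text formats

_BASES = "ACGT"


def _pseudocount_normalize(counts: np.ndarray, pseudocount: float = 0.25) -> np.ndarray:
    # uniform Laplace smoothing: 0.25 added per base before normalization
    sm = counts + pseudocount
    return sm / sm.sum(axis=1, keepdims=True)


def read_pwms(path: str | Path, dialect: str = "jaspar") -> list[Pwm]:
    """Read PWMs from a JASPAR PFM file or a Cis-BP probability-matrix file.

    JASPAR records hold integer-ish counts, one row per base; counts are
    converted to probabilities with a pseudocount of 0.25 per base. Cis-BP
    records hold probabilities (positions as rows, bases as columns) and are
    renormalized with a floor of 1e-4.
    """
    if dialect == "jaspar":
        return _read_jaspar(Path(path))
    if dialect == "cisbp":
        return _read_cisbp(Path(path))
    raise ValueError(f"unknown PWM dialect {dialect!r}")


def _read_jaspar(path: Path) -> list[Pwm]:
    pwms: list[Pwm] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"{path}: record {name!r} has {len(rows)} base rows, expected 4"
            )
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path}: record {name!r} has unequal row lengths")
        counts = np.asarray(rows, dtype=float).T  # width x 4
        if np.any(counts < 0):
            raise FormatError(f"{path}: record {name!r} has negative counts")
        pwms.append(Pwm(tf_name=name, probs=_pseudocount_normalize(counts)))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                # JASPAR headers are ">ID name"; prefer the name when present
                name = fields[1] if len(fields) > 1 else fields[0]
                continue
            if name is None:
                raise FormatError(f"{path}: matrix rows before any '>' header")
            # rows look like "A [ 0 3 79 ... ]"; base letter and brackets optional
            body = line
            if body[0].upper() in _BASES and not _is_float(body.split()[0]):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(tok) for tok in body.split()])
            except ValueError as exc:
                raise FormatError(f"{path}: record {name!r}: {exc}") from exc
    flush()
    if not pwms:
        raise FormatError(f"{path}: no PWM records found")
    return pwms


def _read_cisbp(path: Path) -> list[Pwm]:
    """Cis-BP text: optional 'TF'/'Motif' metadata lines, then a table with a
    'Pos A C G T' header and one probability row per motif position."""
    name = Path(path).stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            key = fields[0].lower()
            if key in {"tf", "tf_name", "motif"} and len(fields) > 1:
                name = fields[1]
                continue
            if key == "pos":
                continue
            try:
                vals = [float(x) for x in fields[1:]] if not _is_float(fields[0]) \
                    else [float(x) for x in fields]
            except ValueError as exc:
                raise FormatError(f"{path}: bad Cis-BP row {line!r}") from exc
            # rows may carry a leading position index; keep the last 4 numbers
            if len(vals) < 4:
                raise FormatError(f"{path}: Cis-BP row with <4 probabilities")
            rows.append(vals[-4:])
    if not rows:
        raise FormatError(f"{path}: no matrix rows found")
    probs = np.asarray(rows, dtype=float)
    if np.any(probs < 0):
        raise FormatError(f"{path}: negative probabilities")
    probs = np.maximum(probs, 1e-4)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return [Pwm(tf_name=name, probs=probs)]


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_pwms_jaspar(pwms: Iterable[Pwm], path: str | Path,
                      scale: int = 100) -> None:
    """Write PWMs as JASPAR PFM text, scaling probabilities to pseudo-counts."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name} {pwm.tf_name}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for b, base in enumerate(_BASES):
                vals = " ".join(str(int(v)) for v in counts[:, b])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# bedGraph cut tracks and chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: need 'name length'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: bad length {fields[1]!r}") from exc
    return sizes


def read_cut_track(path: str | Path, chrom_sizes: Mapping[str, int]) -> CutTrack:
    """Read a bedGraph of integer cut counts into dense per-base vectors.

    Positions absent from the file are 0. Intervals must stay within the
    declared chromosome length.
    """
    track = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: need 4 bedGraph columns")
            chrom, start, end, value = fields[0], fields[1], fields[2], fields[3]
            try:
                s, e, v = int(start), int(end), int(float(value))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric field") from exc
            if chrom not in track:
                raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if v < 0:
                raise FormatError(f"{path}:{ln}: negative cut count")
            if not (0 <= s < e <= len(track[chrom])):
                raise FormatError(
                    f"{path}:{ln}: interval [{s},{e}) outside chromosome "
                    f"{chrom} of length {len(track[chrom])}"
                )
            track[chrom][s:e] = v
    return CutTrack(track)


def write_cut_track(track: CutTrack, path: str | Path) -> None:
    """Write a CutTrack as bedGraph, run-length encoding and omitting zeros."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track[chrom]
            if len(vec) == 0:
                continue
            # boundaries of runs of equal value
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            iv = p.interval
            name = iv.name if iv.name != "." else f"peak_{i}"
            score = min(1000, int(round(10 * p.neg_log10_q)))
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        name,
                        str(score),
                        iv.strand,
                        repr(float(p.fold_enrichment)),
                        repr(float(p.neg_log10_p)),
                        repr(float(p.neg_log10_q)),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def read_narrowpeak(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{ln}: narrowPeak needs 10 columns, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    name=fields[3],
                )
                peaks.append(
                    Peak(
                        interval=iv,
                        summit_offset=int(fields[9]),
                        fold_enrichment=float(fields[6]),
                        neg_log10_p=float(fields[7]),
                        neg_log10_q=float(fields[8]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return peaks


# ---------------------------------------------------------------------------
# TSS table and BED


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Tab-separated TSS table: gene_id, chrom, strand, tss (0-based)."""
    records: list[TssRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: need gene_id, chrom, strand, tss")
            try:
                records.append(
                    TssRecord(
                        gene_id=fields[0],
                        chrom=fields[1],
                        strand=fields[2],
                        tss=int(fields[3]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return records


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 verbatim (BED is already 0-based half-open)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else ".",
                        strand=fields[5] if len(fields) > 5 else ".",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              scores: Iterable[int] | None = None) -> None:
    with open(path, "w") as fh:
        score_list = list(scores) if scores is not None else None
        for i, iv in enumerate(intervals):
            score = score_list[i] if score_list is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA (plain, uncompressed)


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before any FASTA header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
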