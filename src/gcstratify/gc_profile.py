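"""CDS GC-content profiling and bimodal peak/cutoff detection.

Grass (Poaceae) coding sequences show a bimodal GC distribution, with a
low-GC mode near 47-49% and a high-GC mode near 67-68%. This module computes
per-transcript CDS GC content, bins it into integer-percent bins, smooths the
histogram with a moving-window average, and finds the two modes, which serve
as set points for building GC-stratified gene-prediction training sets.

The peak rule: a bin is a peak when every one of the ``(w_p - 1) / 2`` bins on
each side has a strictly lower smoothed count than the centre bin. "Lower
calculated GC values" is read as lower smoothed bin frequency — the only
reading under which the rule defines a mode of the distribution. Edge bins
without a full window on both sides are ineligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneModel, ModelError, SequenceRecord, write_fasta

__all__ = [
    "GCRecord",
    "GCHistogram",
    "GCCutoffs",
    "extract_cds_sequence",
    "gc_content",
    "build_histogram",
    "smooth_histogram",
    "detect_peaks",
    "determine_cutoffs",
    "write_profile_outputs",
    "read_gc_content",
    "read_cutoff_file",
    "flanking_gc",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

N_BINS = 101  # integer GC percent bins 0..100


class CutoffError(ValueError):
    """Raised when fewer than two peaks are found; pick manual cutoffs instead."""


@dataclass(frozen=True)
class GCRecord:
    """Nucleotide composition and GC percent of one CDS.

    ``gc_percent`` excludes N from the denominator and is NaN for all-N
    sequences (the record is flagged, not dropped).
    """

    transcript_id: str
    a: int
    c: int
    g: int
    t: int
    n: int
    length: int
    gc_percent: float

    @property
    def undefined(self) -> bool:
        return math.isnan(self.gc_percent)


@dataclass
class GCHistogram:
    """Integer-percent GC bins with raw and (optionally) smoothed counts."""

    raw: np.ndarray
    smoothed: np.ndarray | None = None
    smooth_window: int | None = None
    bins: np.ndarray = field(default_factory=lambda: np.arange(N_BINS))

    @property
    def values(self) -> np.ndarray:
        """Smoothed counts when available, else raw."""
        return self.raw if self.smoothed is None else self.smoothed


@dataclass(frozen=True)
class GCCutoffs:
    """Low/high GC set points (integer percent) used to partition training data."""

    low_peak: int
    high_peak: int
    peak_window: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.low_peak < self.high_peak <= 100):
            raise ModelError(
                f"cutoffs require 0 <= low < high <= 100, got "
                f"({self.low_peak}, {self.high_peak})"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds_sequence(model: GeneModel, genome: Sequence[SequenceRecord]) -> SequenceRecord:
    """Splice the CDS of ``model`` out of the genome, in transcript orientation.

    CDS intervals are concatenated 5'->3'; minus-strand models are
    reverse-complemented after concatenation in genome order.
    """
    by_id = {s.id: s for s in genome}
    if model.seqid not in by_id:
        raise ModelError(f"{model.transcript_id}: seqid {model.seqid!r} not in genome")
    chrom = by_id[model.seqid].sequence
    parts = []
    for iv in model.cds:
        if iv.end > len(chrom):
            raise ModelError(
                f"{model.transcript_id}: CDS {iv.start}-{iv.end} beyond end of "
                f"{model.seqid} (length {len(chrom)})"
            )
        parts.append(chrom[iv.start - 1 : iv.end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=model.transcript_id, sequence=seq)


def gc_content(seq: SequenceRecord) -> GCRecord:
    """Nucleotide composition and GC percent; N excluded from the denominator."""
    s = seq.sequence
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    n = len(s) - a - c - g - t  # N and any other ambiguity codes
    denom = a + c + g + t
    gc = 100.0 * (g + c) / denom if denom > 0 else float("nan")
    return GCRecord(seq.id, a, c, g, t, n, len(s), gc)


def build_histogram(records: Iterable[GCRecord]) -> GCHistogram:
    """Assign GC percents to integer bins by floor(); 100.0 goes to bin 100."""
    raw = np.zeros(N_BINS, dtype=float)
    for rec in records:
        if rec.undefined:
            continue
        b = min(int(math.floor(rec.gc_percent)), 100)
        raw[b] += 1
    return GCHistogram(raw=raw)


def smooth_histogram(h: GCHistogram, w_s: int = 7) -> GCHistogram:
    """Moving-window mean over a truncated centred window of ``w_s`` bins."""
    if w_s < 1 or w_s % 2 == 0:
        raise ValueError(f"smoothing window must be an odd integer >= 1, got {w_s}")
    half = (w_s - 1) // 2
    smoothed = np.empty(N_BINS)
    for b in range(N_BINS):
        lo, hi = max(0, b - half), min(N_BINS - 1, b + half)
        smoothed[b] = h.raw[lo : hi + 1].mean()
    return GCHistogram(raw=h.raw, smoothed=smoothed, smooth_window=w_s)


def detect_peaks(h: GCHistogram, w_p: int = 5) -> list[int]:
    """Bins whose ``(w_p - 1)/2`` neighbours on each side are all strictly lower.

    Edge bins without a full window on both sides are never peaks; ties
    (plateaus) are not peaks. Returns peak bins in ascending order.
    """
    if w_p < 3 or w_p % 2 == 0:
        raise ValueError(f"peak window must be an odd integer >= 3, got {w_p}")
    half = (w_p - 1) // 2
    vals = h.values
    peaks = []
    for b in range(half, N_BINS - half):
        centre = vals[b]
        side = np.concatenate([vals[b - half : b], vals[b + 1 : b + half + 1]])
        if np.all(side < centre):
            peaks.append(b)
    return peaks


def determine_cutoffs(h: GCHistogram, w_p: int = 5) -> GCCutoffs:
    """The two highest detected peaks, ordered as (low, high) set points.

    Ties on smoothed height are broken toward the bin farther from 50% GC, so
    the more extreme mode wins. Fewer than two peaks raises :class:`CutoffError`
    (the distribution is not usefully bimodal; pick cutoffs manually).
    """
    peaks = detect_peaks(h, w_p)
    if len(peaks) < 2:
        raise CutoffError(
            f"found {len(peaks)} peak(s); need 2 for automatic cutoffs — "
            "inspect the distribution and supply manual low/high GC cutoffs"
        )
    vals = h.values
    ranked = sorted(peaks, key=lambda b: (vals[b], abs(b - 50)), reverse=True)
    return GCCutoffs(low_peak=min(ranked[:2]), high_peak=max(ranked[:2]), peak_window=w_p)


def flanking_gc(
    model: GeneModel, genome: Sequence[SequenceRecord], flank_bp: int = 5000
) -> tuple[float | None, float | None]:
    """GC percent of ``flank_bp`` bases upstream/downstream of the model span.

    Flanks are truncated at sequence ends; an empty flank (model at a sequence
    boundary, or ``flank_bp`` = 0) is reported as None. "Upstream/downstream"
    are in genome coordinates, matching how flanking genomic GC is plotted
    against gene GC.
    """
    by_id = {s.id: s for s in genome}
    chrom = by_id[model.seqid].sequence

    def pct(a: int, b: int) -> float | None:  # 1-based inclusive, may be empty
        a, b = max(1, a), min(len(chrom), b)
        if b < a:
            return None
        rec = gc_content(SequenceRecord(id="flank", sequence=chrom[a - 1 : b]))
        return None if rec.undefined else rec.gc_percent

    if flank_bp <= 0:
        return None, None
    up = pct(model.location.start - flank_bp, model.location.start - 1)
    down = pct(model.location.end + 1, model.location.end + flank_bp)
    return up, down


# ---------------------------------------------------------------------------
# File outputs (BASE_NAME_* convention)


def write_profile_outputs(
    records: Sequence[GCRecord],
    h: GCHistogram,
    cutoffs: GCCutoffs | None,
    base_name: str | Path,
    cds_sequences: Sequence[SequenceRecord] | None = None,
) -> list[Path]:
    """Emit the profiling output files under a BASE_NAME prefix.

    BASE_NAME_cds.fasta (when sequences given), BASE_NAME_gc_content.txt,
    BASE_NAME_distribution.txt and BASE_NAME_cutoff.txt (when cutoffs given).
    """
    base = str(base_name)
    written: list[Path] = []

    if cds_sequences is not None:
        p = Path(base + "_cds.fasta")
        write_fasta(cds_sequences, p)
        written.append(p)

    p = Path(base + "_gc_content.txt")
    with open(p, "w") as fh:
        fh.write("transcript_id\tA\tC\tG\tT\tN\tlength\tgc_percent\n")
        for r in records:
            gc = "NA" if r.undefined else f"{r.gc_percent:.2f}"
            fh.write(f"{r.transcript_id}\t{r.a}\t{r.c}\t{r.g}\t{r.t}\t{r.n}\t{r.length}\t{gc}\n")
    written.append(p)

    p = Path(base + "_distribution.txt")
    sm = h.smoothed if h.smoothed is not None else h.raw
    with open(p, "w") as fh:
        fh.write("bin\traw\tsmoothed\n")
        for b in range(N_BINS):
            fh.write(f"{b}\t{int(h.raw[b])}\t{sm[b]:.4f}\n")
    written.append(p)

    if cutoffs is not None:
        p = Path(base + "_cutoff.txt")
        with open(p, "w") as fh:
            fh.write(f"low\t{cutoffs.low_peak}\nhigh\t{cutoffs.high_peak}\n")
        written.append(p)
    return written


def read_gc_content(path: str | Path) -> list[GCRecord]:
    """Re-read a BASE_NAME_gc_content.txt table back into GCRecords."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id\t"):
            raise ValueError(f"{path}: not a gc_content table")
        for line in fh:
            tid, a, c, g, t, n, length, gc = line.rstrip("\n").split("\t")
            records.append(
                GCRecord(
                    tid, int(a), int(c), int(g), int(t), int(n), int(length),
                    float("nan") if gc == "NA" else float(gc),
                )
            )
    return records


def read_cutoff_file(path: str | Path) -> GCCutoffs:
    vals: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition("\t")
            if key in ("low", "high"):
                vals[key] = int(val)
    if set(vals) != {"low", "high"}:
        raise ValueError(f"{path}: expected 'low' and 'high' lines")
    return GCCutoffs(low_peak=vals["low"], high_peak=vals["high"])
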