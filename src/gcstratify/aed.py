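"""Annotation edit distance (AED) between gene models and alignment evidence.

AED measures the concordance of a gene prediction with the transcript or
protein alignments that support it, at nucleotide resolution:

    SN = overlap / evidence_length      (sensitivity)
    SP = overlap / model_footprint      (specificity)
    AED = 1 - (SN + SP) / 2

so 0 means the prediction and the evidence cover exactly the same bases and 1
means no evidence overlaps the prediction at all. A model's score against a
collection of alignments is the minimum over single-alignment AEDs (its best
supporting evidence). Transcript evidence is compared against the exon
footprint, protein evidence against the CDS footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import EvidenceAlignment, GeneModel, GenomicInterval

__all__ = [
    "AEDResult",
    "overlap_bases",
    "aed_single",
    "aed_best",
    "aed_half_fraction",
    "cumulative_curve",
    "mean_transcript_length",
    "write_aed_table",
]


@dataclass(frozen=True)
class AEDResult:
    transcript_id: str
    best_evidence_id: str | None
    sn: float
    sp: float
    aed: float


def _merge(intervals: Iterable[GenomicInterval]) -> list[tuple[int, int]]:
    """Coalesce possibly-overlapping intervals into disjoint (start, end) pairs."""
    pairs = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def overlap_bases(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Number of genomic positions covered by both interval lists.

    Interval lists must be on one seqid each; lists on different seqids share
    no positions and return 0.
    """
    if not a or not b:
        return 0
    if a[0].seqid != b[0].seqid:
        return 0
    ma, mb = _merge(a), _merge(b)
    total = i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s <= e:
            total += e - s + 1
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return total


def _strands_compatible(model: GeneModel, ev: EvidenceAlignment) -> bool:
    # if either strand is unknown, compare; if both known and differ, no support
    return model.strand == "." or ev.strand == "." or model.strand == ev.strand


def _footprint(model: GeneModel, ev: EvidenceAlignment) -> list[GenomicInterval]:
    if ev.kind == "protein":
        return model.cds
    return model.footprint


def aed_single(model: GeneModel, ev: EvidenceAlignment) -> AEDResult:
    """AED of one model against one evidence alignment.

    A seqid or strand mismatch is not an error — it simply means no support
    (sn = sp = 0, aed = 1).
    """
    fp = _footprint(model, ev)
    if model.seqid != ev.seqid or not _strands_compatible(model, ev):
        return AEDResult(model.transcript_id, ev.evidence_id, 0.0, 0.0, 1.0)
    o = overlap_bases(fp, ev.blocks)
    sn = o / ev.aligned_length
    sp = o / sum(len(iv) for iv in fp)
    return AEDResult(model.transcript_id, ev.evidence_id, sn, sp, 1.0 - (sn + sp) / 2.0)


def aed_best(model: GeneModel, evidence: Sequence[EvidenceAlignment]) -> AEDResult:
    """Minimum AED over all evidence; no evidence at all scores 1."""
    best = AEDResult(model.transcript_id, None, 0.0, 0.0, 1.0)
    for ev in evidence:
        r = aed_single(model, ev)
        if r.aed < best.aed:
            best = r
    return best


def aed_half_fraction(results: Sequence[AEDResult | float]) -> tuple[int, float]:
    """Count and percentage of models with AED strictly below 0.5.

    The percentage is NaN (flagged, not an error) for an empty input.
    """
    aeds = [r.aed if isinstance(r, AEDResult) else float(r) for r in results]
    count = sum(1 for a in aeds if a < 0.5)
    pct = 100.0 * count / len(aeds) if aeds else float("nan")
    return count, pct


def cumulative_curve(results: Sequence[AEDResult | float]) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of models with AED <= t on a 0..1 grid (step 0.01)."""
    aeds = np.asarray([r.aed if isinstance(r, AEDResult) else float(r) for r in results])
    grid = np.round(np.arange(0, 101) / 100.0, 2)
    if len(aeds) == 0:
        return grid, np.full_like(grid, np.nan)
    frac = np.array([(aeds <= t).mean() for t in grid])
    return grid, frac


def mean_transcript_length(models: Sequence[GeneModel]) -> float:
    """Mean spliced (summed-exon, or summed-CDS) transcript length."""
    if not models:
        return float("nan")
    return float(np.mean([m.spliced_length for m in models]))


def write_aed_table(results: Iterable[AEDResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tbest_evidence_id\tsn\tsp\taed\n")
        for r in results:
            ev = r.best_evidence_id if r.best_evidence_id is not None else "NA"
            fh.write(f"{r.transcript_id}\t{ev}\t{r.sn:.4f}\t{r.sp:.4f}\t{r.aed:.4f}\n")
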