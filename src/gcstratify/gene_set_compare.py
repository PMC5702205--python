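"""Merging multi-source gene predictions and comparing annotation sets.

When several prediction sources (e.g. standard, high-GC and low-GC trained
gene finders, two programs each — six sources in all) each propose a model at
a locus, the merged annotation keeps the single best-supported model per locus
(lowest AED; ties broken by longer spliced length, then by a user-declared
source order). Novel models are those whose span overlaps nothing in any
reference set; improved models are standard-protocol models out-competed at
their locus by a non-standard source with strictly lower AED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import GeneModel, GenomicInterval, ModelError

__all__ = [
    "Locus",
    "Improvement",
    "ComparisonReport",
    "cluster_loci",
    "select_best_per_locus",
    "find_novel",
    "find_improved",
]


@dataclass
class Locus:
    """Mutually overlapping gene models (single linkage on span overlap)."""

    seqid: str
    strand: str  # "." when clustering is strand-agnostic
    span: GenomicInterval
    members: list[GeneModel]


@dataclass(frozen=True)
class Improvement:
    standard_id: str
    replacement_id: str
    aed_before: float
    aed_after: float


@dataclass
class ComparisonReport:
    novel: list[GeneModel] = field(default_factory=list)
    improved: list[Improvement] = field(default_factory=list)
    merged: list[GeneModel] = field(default_factory=list)


def _span_overlap(a: GeneModel, b_start: int, b_end: int, min_overlap: int) -> bool:
    s = max(a.location.start, b_start)
    e = min(a.location.end, b_end)
    return e - s + 1 >= min_overlap


def cluster_loci(
    models: Sequence[GeneModel],
    strand_aware: bool = True,
    min_overlap: int = 1,
) -> list[Locus]:
    """Single-linkage clustering of models by >= ``min_overlap`` bp span overlap.

    Loci are returned ordered by (seqid, start); within a locus, members keep
    a deterministic (start, transcript_id) order.
    """
    groups: dict[tuple, list[GeneModel]] = {}
    for m in models:
        key = (m.seqid, m.strand if strand_aware else ".")
        groups.setdefault(key, []).append(m)

    loci: list[Locus] = []
    for (seqid, strand), members in groups.items():
        members.sort(key=lambda m: (m.location.start, m.location.end, m.transcript_id))
        current: list[GeneModel] = []
        cur_end = -1
        for m in members:
            if current and m.location.start <= cur_end - min_overlap + 1:
                current.append(m)
                cur_end = max(cur_end, m.location.end)
            else:
                if current:
                    loci.append(_make_locus(seqid, strand, current))
                current = [m]
                cur_end = m.location.end
        if current:
            loci.append(_make_locus(seqid, strand, current))
    loci.sort(key=lambda loc: (loc.seqid, loc.span.start, loc.strand))
    return loci


def _make_locus(seqid: str, strand: str, members: list[GeneModel]) -> Locus:
    span = GenomicInterval(
        seqid,
        min(m.location.start for m in members),
        max(m.location.end for m in members),
        strand,
    )
    return Locus(seqid=seqid, strand=strand, span=span, members=list(members))


def select_best_per_locus(
    loci: Sequence[Locus], source_order: Sequence[str] = ()
) -> list[GeneModel]:
    """Keep exactly one model per locus: the member with minimal AED.

    Ties on AED go to the longer spliced length; remaining ties to the source
    earliest in ``source_order`` (unlisted sources rank last, then
    transcript id keeps the choice deterministic).
    """
    rank = {s: i for i, s in enumerate(source_order)}

    def key(m: GeneModel):
        if m.aed is None:
            raise ModelError(f"model {m.transcript_id!r} has no AED; score before merging")
        return (
            m.aed,
            -m.spliced_length,
            rank.get(m.source_label, len(rank)),
            m.transcript_id,
        )

    return [min(loc.members, key=key) for loc in loci]


def find_novel(
    query_set: Sequence[GeneModel],
    *reference_sets: Sequence[GeneModel],
    min_overlap: int = 1,
    strand_aware: bool = False,
) -> list[GeneModel]:
    """Query models whose span overlaps nothing in any reference set.

    Overlap is strand-agnostic by default, mirroring plain interval
    intersection of the two coordinate files.
    """
    refs: dict[str, list[tuple[int, int, str]]] = {}
    for ref_set in reference_sets:
        for r in ref_set:
            refs.setdefault(r.seqid, []).append(
                (r.location.start, r.location.end, r.strand)
            )
    novel = []
    for q in query_set:
        hit = False
        for (s, e, strand) in refs.get(q.seqid, ()):
            if strand_aware and q.strand != "." and strand != "." and q.strand != strand:
                continue
            if min(q.location.end, e) - max(q.location.start, s) + 1 >= min_overlap:
                hit = True
                break
        if not hit:
            novel.append(q)
    return novel


def find_improved(
    standard_set: Sequence[GeneModel],
    merged_set: Sequence[GeneModel],
    standard_sources: Sequence[str] = ("orig_snap", "orig_aug", "maker", "est2genome"),
    min_overlap: int = 1,
) -> list[Improvement]:
    """Standard models replaced in the merged set by a better non-standard model.

    A standard model is improved iff some merged model overlapping it (>=
    ``min_overlap`` bp span overlap, same strand when both known) comes from a
    source not in ``standard_sources`` and has strictly lower AED. When several
    qualify, the lowest-AED replacement is reported.
    """
    standard_ids = {m.transcript_id for m in standard_set}
    by_seqid: dict[str, list[GeneModel]] = {}
    for m in merged_set:
        by_seqid.setdefault(m.seqid, []).append(m)

    improved: list[Improvement] = []
    for s in standard_set:
        if s.aed is None:
            raise ModelError(f"standard model {s.transcript_id!r} has no AED")
        best: GeneModel | None = None
        for m in by_seqid.get(s.seqid, ()):
            if m.transcript_id in standard_ids or m.source_label in standard_sources:
                continue
            if s.strand != "." and m.strand != "." and s.strand != m.strand:
                continue
            if not _span_overlap(s, m.location.start, m.location.end, min_overlap):
                continue
            if m.aed is not None and m.aed < s.aed and (best is None or m.aed < best.aed):
                best = m
        if best is not None:
            improved.append(
                Improvement(s.transcript_id, best.transcript_id, s.aed, best.aed)
            )
    return improved
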