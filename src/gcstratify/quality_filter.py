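"""Evidence-based and transposable-element (TE) quality filters.

Two stages mirror the post-prediction clean-up of a structural annotation:

1. The "standard" high-quality list keeps every model with evidence support
   (AED < 1) or a significant Pfam domain (full-sequence E-value <= 1e-10).
2. The TE filter then removes models that look like transposable elements by
   any of four rules: a Gypsy-domain HMM hit (E <= 1e-5), a transposase
   homology hit (E <= 1e-10), a Pfam hit whose accession is on a TE-domain
   list, or overlap with a reference TE annotation (refmap membership).
   Reasons are accumulated, never short-circuited, so a verdict explains every
   rule a model tripped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import DomainHit, GeneModel, HomologyHit, RefmapEntry

__all__ = [
    "FilterVerdict",
    "maker_standard_list",
    "te_filter",
    "PFAM_CUTOFF",
    "GYPSY_CUTOFF",
    "TRANSPOSASE_CUTOFF",
]

PFAM_CUTOFF = 1e-10
GYPSY_CUTOFF = 1e-5
TRANSPOSASE_CUTOFF = 1e-10

REASONS = (
    "no_evidence_no_pfam",
    "gypsy_hit",
    "transposase_hit",
    "te_refmap_overlap",
    "te_pfam_domain",
)


@dataclass
class FilterVerdict:
    transcript_id: str
    kept: bool
    reasons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert self.kept == (not self.reasons), "kept iff no removal reasons"


def maker_standard_list(
    models: Sequence[GeneModel],
    pfam_hits: Iterable[DomainHit],
    pfam_cutoff: float = PFAM_CUTOFF,
) -> list[str]:
    """Transcript ids kept by the evidence-or-Pfam rule.

    A model passes when its AED < 1 (some transcript/protein evidence overlaps
    it) or when it has a Pfam hit with full-sequence E-value <= ``pfam_cutoff``.
    Models with no AED are treated as unsupported (AED = 1) with a warning.
    """
    pfam_ok: set[str] = {
        h.query_id for h in pfam_hits if h.full_seq_evalue <= pfam_cutoff
    }
    kept = []
    for m in models:
        aed = m.aed
        if aed is None:
            warnings.warn(
                f"model {m.transcript_id!r} has no AED; treating as unsupported",
                stacklevel=2,
            )
            aed = 1.0
        if aed < 1.0 or m.transcript_id in pfam_ok:
            kept.append(m.transcript_id)
    return kept


def te_filter(
    kept_models: Sequence[GeneModel],
    te_pfam_domains: Sequence[str],
    all_pfam_hits: Iterable[DomainHit],
    gypsy_hits: Iterable[DomainHit],
    transposase_hits: Iterable[HomologyHit],
    te_refmap: Iterable[RefmapEntry],
    pfam_cutoff: float = PFAM_CUTOFF,
    gypsy_cutoff: float = GYPSY_CUTOFF,
    transposase_cutoff: float = TRANSPOSASE_CUTOFF,
    refmap_class_codes: Sequence[str] | None = None,
) -> list[FilterVerdict]:
    """Flag TE-like models among an already evidence-filtered set.

    ``refmap_class_codes`` restricts the reference-TE-overlap rule to given
    gffcompare class codes; by default any refmap membership counts.
    """
    te_accessions = {_accession_base(a) for a in te_pfam_domains}
    if not te_accessions:
        warnings.warn("empty TE Pfam domain list; the TE-domain rule is inert", stacklevel=2)

    gypsy_ids = {h.query_id for h in gypsy_hits if h.full_seq_evalue <= gypsy_cutoff}
    tpase_ids = {h.query_id for h in transposase_hits if h.evalue <= transposase_cutoff}
    te_pfam_ids = {
        h.query_id
        for h in all_pfam_hits
        if h.full_seq_evalue <= pfam_cutoff
        and _accession_base(h.domain_accession) in te_accessions
    }
    refmap_ids: set[str] = set()
    for entry in te_refmap:
        if refmap_class_codes is not None and entry.class_code not in refmap_class_codes:
            continue
        refmap_ids.update(entry.query_ids)

    verdicts = []
    for m in kept_models:
        reasons: set[str] = set()
        for mid in (m.transcript_id, m.gene_id):
            if mid in gypsy_ids:
                reasons.add("gypsy_hit")
            if mid in tpase_ids:
                reasons.add("transposase_hit")
            if mid in te_pfam_ids:
                reasons.add("te_pfam_domain")
            if mid in refmap_ids:
                reasons.add("te_refmap_overlap")
        verdicts.append(
            FilterVerdict(m.transcript_id, kept=not reasons, reasons=reasons)
        )
    return verdicts


def _accession_base(acc: str) -> str:
    """Pfam accessions may carry a version suffix (PF00078.12); compare bare."""
    return acc.split(".", 1)[0]
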