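"""Readers, writers and domain types for the external formats the toolkit touches.

All genomic coordinates are 1-based inclusive (GFF3 convention) everywhere in
the public API; conversion to half-open arithmetic happens only inside interval
helpers. Writers emit UNIX newlines and no trailing whitespace, and the GFF3
writer is canonical: writing, re-reading and writing again is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ParseError",
    "ModelError",
    "SequenceRecord",
    "GenomicInterval",
    "GeneModel",
    "EvidenceAlignment",
    "DomainHit",
    "HomologyHit",
    "RefmapEntry",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_domain_table",
    "read_homology_table",
    "read_refmap",
]

STRANDS = ("+", "-", ".")  # "." = unknown, never coerced


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ModelError(ValueError):
    """A domain object violates its invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (IUPAC A/C/G/T/N, stored uppercase)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("sequence record with empty id")
        if not self.sequence:
            raise ModelError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive interval on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ModelError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )


def _check_parts(parts: Sequence[GenomicInterval], loc: GenomicInterval, what: str, owner: str) -> None:
    prev_end = 0
    for iv in parts:
        if iv.seqid != loc.seqid or iv.strand != loc.strand:
            raise ModelError(f"{owner}: {what} interval on different seqid/strand than span")
        if not loc.contains(iv):
            raise ModelError(f"{owner}: {what} interval {iv.start}-{iv.end} outside span")
        if iv.start <= prev_end:
            raise ModelError(f"{owner}: {what} intervals overlap or are unsorted")
        prev_end = iv.end


@dataclass
class GeneModel:
    """A transcript-level gene annotation with sorted CDS/exon intervals.

    ``aed`` is the annotation edit distance against the best supporting
    evidence (0 = perfect concordance, 1 = unsupported), or None when unscored.
    """

    gene_id: str
    transcript_id: str
    location: GenomicInterval
    cds: list[GenomicInterval]
    exons: list[GenomicInterval] = field(default_factory=list)
    source_label: str = "maker"
    aed: float | None = None

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.validate()

    def validate(self) -> None:
        if not self.gene_id or not self.transcript_id:
            raise ModelError("gene model with empty id")
        if not self.cds:
            raise ModelError(f"{self.transcript_id}: no CDS intervals")
        _check_parts(self.cds, self.location, "CDS", self.transcript_id)
        _check_parts(self.exons, self.location, "exon", self.transcript_id)
        for c in self.cds:
            if self.exons and not any(e.contains(c) for e in self.exons):
                raise ModelError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} not contained in any exon"
                )
        if self.aed is not None and not (0.0 <= self.aed <= 1.0):
            raise ModelError(f"{self.transcript_id}: AED {self.aed} outside [0,1]")

    @property
    def seqid(self) -> str:
        return self.location.seqid

    @property
    def strand(self) -> str:
        return self.location.strand

    @property
    def footprint(self) -> list[GenomicInterval]:
        """Exons when annotated, else CDS (the transcript-level footprint)."""
        return self.exons if self.exons else self.cds

    @property
    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.footprint)

    def with_aed(self, aed: float) -> "GeneModel":
        return replace(self, aed=aed)


@dataclass
class EvidenceAlignment:
    """A transcript or protein alignment footprint (match/match_part chain)."""

    evidence_id: str
    kind: str  # "transcript" | "protein"
    blocks: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.kind not in ("transcript", "protein"):
            raise ModelError(f"{self.evidence_id}: evidence kind {self.kind!r}")
        if not self.blocks:
            raise ModelError(f"{self.evidence_id}: no alignment blocks")
        self.blocks = sorted(self.blocks, key=lambda iv: iv.start)
        seqids = {b.seqid for b in self.blocks}
        if len(seqids) != 1:
            raise ModelError(f"{self.evidence_id}: blocks span multiple seqids {seqids}")

    @property
    def seqid(self) -> str:
        return self.blocks[0].seqid

    @property
    def strand(self) -> str:
        strands = {b.strand for b in self.blocks} - {"."}
        return strands.pop() if len(strands) == 1 else "."

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass(frozen=True)
class DomainHit:
    """One row of an HMMER3 ``--tblout`` table (hmmscan orientation)."""

    query_id: str
    domain_accession: str
    full_seq_evalue: float
    domain_evalue: float

    def __post_init__(self) -> None:
        if self.full_seq_evalue <= 0 or self.domain_evalue <= 0:
            raise ModelError(f"{self.query_id}: non-positive e-value")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column BLAST tabular (-outfmt 6) file."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    fields: tuple[str, ...] = ()  # the full 12 raw columns, kept opaque

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ModelError(f"{self.query_id}: non-positive e-value")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ModelError(f"{self.query_id}: identity {self.percent_identity} outside [0,100]")


@dataclass(frozen=True)
class RefmapEntry:
    """One row of a gffcompare ``.refmap`` table."""

    ref_gene_id: str
    ref_transcript_id: str
    class_code: str
    query_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_lines(numbered: Iterable[tuple[int, str]], origin: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{origin}: empty sequence for record at line {header_line}")
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise ParseError(f"{origin}: duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, sequence=seq.upper(), description=desc))

    for lineno, line in numbered:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            header_line = lineno
            chunks = []
            if not header:
                raise ParseError(f"{origin}: empty FASTA header at line {lineno}")
        else:
            if header is None:
                raise ParseError(
                    f"{origin}: line {lineno}: sequence data before any '>' header"
                )
            chunks.append(line.strip())
    flush()
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file; sequences are uppercased, order preserved."""
    with open(path) as fh:
        return _parse_fasta_lines(enumerate(fh, 1), str(path))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def _parse_attributes(col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


def _fmt_float(x: float) -> str:
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def read_gff3(
    path: str | Path, with_fasta: bool = False
) -> tuple[list[GeneModel], list[EvidenceAlignment], list[SequenceRecord]]:
    """Read gene models, evidence alignments and (optionally) embedded FASTA.

    mRNA features with their CDS/exon children become :class:`GeneModel`;
    match + match_part chains become :class:`EvidenceAlignment`. Sequences
    after a ``##FASTA`` directive are returned when ``with_fasta`` is set.
    """
    mrna_rows: dict[str, dict] = {}
    gene_of: dict[str, str] = {}
    cds_parts: dict[str, list[GenomicInterval]] = {}
    exon_parts: dict[str, list[GenomicInterval]] = {}
    match_rows: dict[str, dict] = {}
    match_parts: dict[str, list[GenomicInterval]] = {}
    orphan_parts: list[tuple[int, str]] = []
    fasta_lines: list[str] = []
    in_fasta = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if in_fasta:
                fasta_lines.append(line)
                continue
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_GFF_COLS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            seqid, source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if strand not in STRANDS and strand != "?":
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            strand = "." if strand == "?" else strand
            try:
                iv = GenomicInterval(seqid, start, end, strand)
            except ModelError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            attrs = _parse_attributes(attr_s)

            if ftype == "mRNA":
                tid = attrs.get("ID")
                if not tid:
                    raise ParseError(f"{path}: line {lineno}: mRNA without ID")
                if tid in mrna_rows:
                    raise ParseError(f"{path}: line {lineno}: duplicate transcript ID {tid!r}")
                aed = attrs.get("_AED")
                mrna_rows[tid] = {
                    "iv": iv,
                    "source": source,
                    "gene": attrs.get("Parent", tid),
                    "aed": float(aed) if aed is not None else None,
                }
            elif ftype in ("CDS", "exon"):
                parent = attrs.get("Parent")
                if not parent:
                    raise ParseError(f"{path}: line {lineno}: {ftype} without Parent")
                bucket = cds_parts if ftype == "CDS" else exon_parts
                bucket.setdefault(parent, []).append(iv)
                if parent not in mrna_rows:
                    orphan_parts.append((lineno, line))
            elif ftype.endswith("match_part"):
                parent = attrs.get("Parent")
                if not parent:
                    raise ParseError(f"{path}: line {lineno}: match_part without Parent")
                match_parts.setdefault(parent, []).append(iv)
                match_rows.setdefault(parent, {"source": source})
            elif ftype.endswith("match"):
                mid = attrs.get("ID")
                if mid:
                    match_rows[mid] = {"source": source}
            # gene rows and unknown types carry no extra information we keep

    # orphan CDS/exon lines are an error only if their parent never appeared
    for lineno, line in orphan_parts:
        parent = _parse_attributes(line.split("\t")[8]).get("Parent")
        if parent not in mrna_rows:
            raise ParseError(
                f"{path}: line {lineno}: Parent {parent!r} not defined: {line}"
            )

    models = []
    for tid, row in mrna_rows.items():
        try:
            models.append(
                GeneModel(
                    gene_id=row["gene"],
                    transcript_id=tid,
                    location=row["iv"],
                    cds=cds_parts.get(tid, []),
                    exons=exon_parts.get(tid, []),
                    source_label=row["source"],
                    aed=row["aed"],
                )
            )
        except ModelError as exc:
            raise ParseError(f"{path}: invalid model {tid!r}: {exc}") from None

    evidence = []
    for mid, parts in match_parts.items():
        source = match_rows.get(mid, {}).get("source", "")
        kind = "protein" if source.startswith("protein") else "transcript"
        evidence.append(EvidenceAlignment(evidence_id=mid, kind=kind, blocks=parts))
    evidence.sort(key=lambda e: (e.seqid, e.blocks[0].start, e.evidence_id))

    sequences: list[SequenceRecord] = []
    if with_fasta and fasta_lines:
        sequences = _parse_fasta_lines(enumerate(fasta_lines, 1), f"{path}##FASTA")
        # validate embedded coordinates
        lengths = {s.id: len(s) for s in sequences}
        for m in models:
            if m.seqid in lengths and m.location.end > lengths[m.seqid]:
                raise ParseError(
                    f"{path}: model {m.transcript_id!r} extends past end of "
                    f"embedded sequence {m.seqid!r}"
                )
    return models, evidence, sequences


def write_gff3(
    models: Iterable[GeneModel],
    path: str | Path,
    evidence: Iterable[EvidenceAlignment] = (),
) -> None:
    """Write the canonical GFF3 dialect (gene > mRNA > exon > CDS nesting).

    Attributes are restricted to ID/Parent (plus ``_AED`` on scored mRNAs so
    that a read/write cycle is lossless); features are sorted by
    (seqid, start, ID), making a write -> read -> write cycle byte-stable.
    """
    models = list(models)
    for m in models:
        m.validate()
    tids = [m.transcript_id for m in models]
    if len(set(tids)) != len(tids):
        dup = sorted({t for t in tids if tids.count(t) > 1})
        raise ModelError(f"duplicate transcript IDs: {dup}")

    # gene span = union of its transcripts
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    rows: list[tuple] = []  # (seqid, start, id, rendered lines)
    for gid, members in by_gene.items():
        seqids = {m.seqid for m in members}
        strands = {m.strand for m in members}
        if len(seqids) != 1 or len(strands) != 1:
            raise ModelError(f"gene {gid!r}: transcripts disagree on seqid/strand")
        seqid, strand = seqids.pop(), strands.pop()
        gstart = min(m.location.start for m in members)
        gend = max(m.location.end for m in members)
        lines = [
            f"{seqid}\tgcstratify\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
        ]
        for m in sorted(members, key=lambda m: (m.location.start, m.transcript_id)):
            attrs = f"ID={m.transcript_id};Parent={gid}"
            if m.aed is not None:
                attrs += f";_AED={_fmt_float(m.aed)}"
            lines.append(
                f"{seqid}\t{m.source_label}\tmRNA\t{m.location.start}\t"
                f"{m.location.end}\t.\t{strand}\t.\t{attrs}"
            )
            for ftype, parts in (("exon", m.exons), ("CDS", m.cds)):
                for i, iv in enumerate(parts, 1):
                    lines.append(
                        f"{seqid}\t{m.source_label}\t{ftype}\t{iv.start}\t{iv.end}"
                        f"\t.\t{strand}\t.\tID={m.transcript_id}:{ftype.lower()}{i};"
                        f"Parent={m.transcript_id}"
                    )
        rows.append((seqid, gstart, gid, lines))

    for ev in evidence:
        lines = [
            f"{ev.seqid}\t{ev.kind}2genome\tmatch\t{ev.blocks[0].start}\t"
            f"{ev.blocks[-1].end}\t.\t{ev.strand}\t.\tID={ev.evidence_id}"
        ]
        for i, b in enumerate(ev.blocks, 1):
            lines.append(
                f"{ev.seqid}\t{ev.kind}2genome\tmatch_part\t{b.start}\t{b.end}\t.\t"
                f"{b.strand}\t.\tID={ev.evidence_id}:hsp{i};Parent={ev.evidence_id}"
            )
        rows.append((ev.seqid, ev.blocks[0].start, ev.evidence_id, lines))

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, _, _, lines in rows:
            fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular dialects


def _parse_evalue(tok: str, path, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: bad e-value {tok!r}") from None


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read an HMMER3 ``--tblout`` file (hmmscan orientation).

    The query is the searched protein (column 3); the domain accession is the
    target accession (column 2), falling back to the target name when hmmscan
    prints "-".
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 18:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=18 whitespace-separated "
                    f"tblout columns, found {len(cols)}"
                )
            target_name, target_acc, query_name = cols[0], cols[1], cols[2]
            acc = target_name if target_acc == "-" else target_acc
            hits.append(
                DomainHit(
                    query_id=query_name,
                    domain_accession=acc,
                    full_seq_evalue=_parse_evalue(cols[4], path, lineno),
                    domain_evalue=_parse_evalue(cols[7], path, lineno),
                )
            )
    return hits


def read_homology_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column BLAST tabular (-outfmt 6) file."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"found {len(cols)}"
                )
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    evalue=_parse_evalue(cols[10], path, lineno),
                    fields=tuple(cols),
                )
            )
    return hits


def read_refmap(path: str | Path) -> list[RefmapEntry]:
    """Read a gffcompare ``.refmap`` table (4 tab-separated columns).

    The query list holds comma-separated ``gene|transcript`` items; every
    pipe-separated token is kept so callers can match on either id.
    """
    entries: list[RefmapEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] in ("ref_gene_id", "ref_gene"):
                continue  # header
            if len(cols) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated refmap "
                    f"columns, found {len(cols)}"
                )
            qids: list[str] = []
            for item in cols[3].split(","):
                item = item.strip()
                if item:
                    qids.extend(tok for tok in item.split("|") if tok)
            entries.append(
                RefmapEntry(
                    ref_gene_id=cols[0],
                    ref_transcript_id=cols[1],
                    class_code=cols[2],
                    query_ids=tuple(qids),
                )
            )
    return entries
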