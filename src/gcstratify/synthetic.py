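"""Synthetic genomes, annotations and evidence with known ground truth.

The simulators emulate the statistical structure the toolkit assumes about a
grass genome, so every pipeline stage can be exercised against a truth table
with no external data:

* CDS GC content follows a two-component mixture (defaults: modes at 47% and
  68% GC, the low/high gene classes of a bimodal Poaceae distribution);
* gene GC is tuned at synonymous third codon positions, the way high-GC grass
  genes concentrate their GC, so encoded peptides stay realistic;
* intergenic sequence GC is drawn independently of neighbouring gene GC
  (grasses have no isochores: flanking genomic GC carries no information
  about gene GC);
* evidence alignments are exon chains with controlled end-extension and
  dropout, giving analytically known AEDs;
* TE decoy tables (Gypsy-domain, transposase-homology, reference-TE refmap,
  TE Pfam domains) mark a known subset of genes as transposon-like;
* TRAP/mRNA count tables have a known translatome enrichment per gene.

Every simulator is a pure function of its config: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    DomainHit,
    EvidenceAlignment,
    GeneModel,
    GenomicInterval,
    HomologyHit,
    RefmapEntry,
    SequenceRecord,
)

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "SOURCE_LABELS",
    "simulate_genome",
    "simulate_evidence",
    "simulate_sources",
    "simulate_te_tables",
    "TETables",
    "simulate_counts",
    "CountTables",
    "write_domain_table",
    "write_homology_table",
    "write_refmap",
]

SOURCE_LABELS = ("orig_snap", "orig_aug", "high_snap", "high_aug", "low_snap", "low_aug")

# 4-fold degenerate codon boxes: the third base is free, so GC can be tuned
# there without changing the peptide or creating stops.
_BOX_HALF_GC = ("CT", "GT", "TC", "AC")  # Leu4, Val, Ser4, Thr: 1 GC in pos 1-2
_BOX_FULL_GC = ("CC", "GC", "CG", "GG")  # Pro, Ala, Arg4, Gly: 2 GC in pos 1-2

_TE_PFAM_DOMAINS = ("PF03732", "PF07727", "PF00078", "PF13456", "PF03004")
_CLEAN_PFAM_DOMAINS = ("PF00069", "PF00067", "PF00847", "PF03106", "PF00010")


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all simulators (see module docstring).

    GC values are percentages; lengths are bp. ``seq_length``, when set, fixes
    every simulated sequence to that length (error if the gene layout does not
    fit; padded with intergenic sequence if shorter).
    """

    seed: int = 0
    n_genes: int = 200
    n_seqids: int = 5
    # CDS GC mixture
    mixture_weight_low: float = 0.5
    mu_low: float = 47.0
    sigma_low: float = 3.0
    mu_high: float = 68.0
    sigma_high: float = 3.0
    # CDS length (multiple of 3 enforced)
    cds_length_mean: float = 900.0
    cds_length_sd: float = 300.0
    cds_length_min: int = 300
    # gene structure
    max_exons: int = 3
    intron_length_mean: float = 250.0
    intron_length_min: int = 60
    # intergenic spacers
    intergenic_length_mean: float = 1000.0
    intergenic_length_min: int = 200
    intergenic_gc: float = 43.0
    seq_length: int | None = None
    # evidence
    evidence_extension: int = 25
    evidence_dropout: float = 0.1
    # TE decoys
    te_fraction: float = 0.1
    decoy_rate: float = 0.1
    # multi-source predictions
    n_sources: int = 6
    source_aed_noise: float = 0.05
    # expression
    tissues: tuple[str, ...] = ("root", "leaf", "seed")
    mean_depth: float = 800.0
    nb_dispersion: float = 50.0
    enriched_fraction: float = 0.15
    depleted_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.mixture_weight_low <= 1.0):
            raise SimulationError("mixture weight must be in [0,1]")
        if self.mu_low >= self.mu_high:
            raise SimulationError("low-GC mode must lie below high-GC mode")
        if min(self.sigma_low, self.sigma_high) <= 0:
            raise SimulationError("mixture sigmas must be positive")
        if self.intergenic_length_min <= self.evidence_extension:
            raise SimulationError(
                "intergenic_length_min must exceed evidence_extension so evidence "
                "extensions never run off a sequence end"
            )
        if not (1 <= self.n_sources <= len(SOURCE_LABELS)):
            raise SimulationError(f"n_sources must be in 1..{len(SOURCE_LABELS)}")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    """n random bases with P(G or C) = gc/100."""
    is_gc = rng.random(n) < gc / 100.0
    which = rng.integers(0, 2, n)
    bases = np.where(is_gc, np.where(which == 0, "G", "C"), np.where(which == 0, "A", "T"))
    return "".join(bases)


def _make_cds(rng: np.random.Generator, n_codons: int, target_gc: float) -> str:
    """ATG + internal codons + TAA, with GC steered to ``target_gc`` percent.

    Internal codons come from 4-fold degenerate boxes only; positions 1-2 set
    a baseline GC and exactly the number of third positions needed to hit the
    target are made G/C. Feasible targets span roughly 34-98% GC.
    """
    g = target_gc / 100.0
    n = n_codons - 2  # internal codons (start + stop fixed)
    w = min(max(2.0 * (1.0 - g), 0.0), 1.0)  # share of half-GC boxes
    half = rng.random(n) < w
    box_idx = rng.integers(0, 4, n)
    pairs = np.where(
        half,
        np.array(_BOX_HALF_GC)[box_idx],
        np.array(_BOX_FULL_GC)[box_idx],
    )
    gc12 = int(np.sum(np.where(half, 1, 2))) + 1  # +1 for the G of ATG
    length = 3 * n_codons
    target_count = int(round(g * length))
    third_gc = min(max(target_count - gc12, 0), n)
    gc_positions = np.zeros(n, dtype=bool)
    if third_gc:
        gc_positions[rng.choice(n, size=third_gc, replace=False)] = True
    which = rng.integers(0, 2, n)
    thirds = np.where(
        gc_positions,
        np.where(which == 0, "G", "C"),
        np.where(which == 0, "A", "T"),
    )
    body = "".join(p + t for p, t in zip(pairs, thirds))
    return "ATG" + body + "TAA"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[list[SequenceRecord], list[GeneModel], pd.DataFrame]:
    """Generate (genome, transcript-derived annotation, truth table).

    Genes are laid out left to right on ``cfg.n_seqids`` sequences, separated
    by independent intergenic spacers, on both strands. The truth table has
    one row per gene: ids, coordinates, GC class/target/realized value,
    exon count and the TE flag.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    seqids = [f"chr{i + 1}" for i in range(cfg.n_seqids)]
    for sid in seqids:
        chrom_parts[sid] = []
        chrom_pos[sid] = 0

    models: list[GeneModel] = []
    rows = []
    for i in range(cfg.n_genes):
        sid = seqids[i % cfg.n_seqids]
        # independent intergenic spacer before the gene
        ig_len = cfg.intergenic_length_min + int(
            rng.exponential(max(cfg.intergenic_length_mean - cfg.intergenic_length_min, 1))
        )
        chrom_parts[sid].append(_random_bases(rng, ig_len, cfg.intergenic_gc))
        chrom_pos[sid] += ig_len

        low = rng.random() < cfg.mixture_weight_low
        mu, sigma = (cfg.mu_low, cfg.sigma_low) if low else (cfg.mu_high, cfg.sigma_high)
        target_gc = float(np.clip(rng.normal(mu, sigma), 34.0, 98.0))
        n_codons = max(
            cfg.cds_length_min // 3,
            int(round(rng.normal(cfg.cds_length_mean, cfg.cds_length_sd) / 3.0)),
        )
        cds_seq = _make_cds(rng, n_codons, target_gc)
        L = len(cds_seq)
        realized = 100.0 * (cds_seq.count("G") + cds_seq.count("C")) / L

        n_exons = int(rng.integers(1, cfg.max_exons + 1))
        # split the CDS into n_exons chunks of >= 30 bp
        if n_exons > 1 and L >= 30 * n_exons:
            cuts = np.sort(rng.choice(np.arange(30, L - 29), size=n_exons - 1, replace=False))
            # enforce >=30 bp chunks; fall back to even split on collision
            bounds = [0, *cuts.tolist(), L]
            if min(b - a for a, b in zip(bounds, bounds[1:])) < 30:
                bounds = [round(j * L / n_exons) for j in range(n_exons + 1)]
        else:
            n_exons = 1
            bounds = [0, L]
        chunk_lens = [b - a for a, b in zip(bounds, bounds[1:])]

        strand = "+" if rng.random() < 0.5 else "-"
        genome_seq = cds_seq if strand == "+" else _revcomp(cds_seq)
        glens = chunk_lens if strand == "+" else chunk_lens[::-1]

        start = chrom_pos[sid] + 1
        pos = start
        exons: list[GenomicInterval] = []
        parts: list[str] = []
        offset = 0
        for j, clen in enumerate(glens):
            exons.append(GenomicInterval(sid, pos, pos + clen - 1, strand))
            parts.append(genome_seq[offset : offset + clen])
            offset += clen
            pos += clen
            if j < len(glens) - 1:
                ilen = cfg.intron_length_min + int(
                    rng.exponential(max(cfg.intron_length_mean - cfg.intron_length_min, 1))
                )
                parts.append(_random_bases(rng, ilen, cfg.intergenic_gc))
                pos += ilen
        end = pos - 1
        chrom_parts[sid].append("".join(parts))
        chrom_pos[sid] = end

        gid = f"gene{i + 1:05d}"
        tid = f"{gid}.1"
        loc = GenomicInterval(sid, start, end, strand)
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=tid,
                location=loc,
                cds=list(exons),
                exons=list(exons),
                source_label="est2genome",
            )
        )
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "seqid": sid,
                "strand": strand,
                "start": start,
                "end": end,
                "gc_class": "low" if low else "high",
                "target_gc": target_gc,
                "realized_gc": realized,
                "cds_length": L,
                "n_exons": n_exons,
                "is_te": bool(rng.random() < cfg.te_fraction),
            }
        )

    # trailing spacer so downstream flanks exist, then optional fixed length
    genome: list[SequenceRecord] = []
    for sid in seqids:
        tail = cfg.intergenic_length_min + int(
            rng.exponential(max(cfg.intergenic_length_mean - cfg.intergenic_length_min, 1))
        )
        chrom_parts[sid].append(_random_bases(rng, tail, cfg.intergenic_gc))
        seq = "".join(chrom_parts[sid])
        if cfg.seq_length is not None:
            if len(seq) > cfg.seq_length:
                raise SimulationError(
                    f"{sid}: layout needs {len(seq)} bp but seq_length={cfg.seq_length}"
                )
            seq += _random_bases(rng, cfg.seq_length - len(seq), cfg.intergenic_gc)
        if seq:
            genome.append(SequenceRecord(id=sid, sequence=seq))

    truth = pd.DataFrame(rows)
    return genome, models, truth


def simulate_evidence(
    models: Sequence[GeneModel], cfg: SimulationConfig
) -> list[EvidenceAlignment]:
    """Transcript evidence: exon chains with terminal ends extended by ``e``.

    Each gene independently keeps its evidence with probability
    1 - ``evidence_dropout``. For a model of spliced length L the induced best
    AED is exactly 1 - (1 + L/(L + 2e))/2.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    e = cfg.evidence_extension
    out: list[EvidenceAlignment] = []
    for m in models:
        if rng.random() < cfg.evidence_dropout:
            continue
        blocks = [GenomicInterval(b.seqid, b.start, b.end, b.strand) for b in m.exons or m.cds]
        first = blocks[0]
        blocks[0] = GenomicInterval(first.seqid, max(1, first.start - e), first.end, first.strand)
        last = blocks[-1]
        blocks[-1] = GenomicInterval(last.seqid, last.start, last.end + e, last.strand)
        out.append(
            EvidenceAlignment(
                evidence_id=f"ev_{m.transcript_id}", kind="transcript", blocks=blocks
            )
        )
    return out


def simulate_sources(
    models: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
) -> dict[str, list[GeneModel]]:
    """Per-source gene predictions at every true locus, with known AEDs.

    Sources matching a gene's GC class (high_* for high-GC genes, low_* for
    low-GC) centre on better (lower) AEDs, standard sources sit between, and
    mismatched sources are worst — mimicking class-specific training. The
    assigned AED is the truth; coordinates are the true gene's.
    """
    rng = np.random.default_rng(cfg.seed + 202)
    gc_class = dict(zip(truth["transcript_id"], truth["gc_class"]))
    labels = SOURCE_LABELS[: cfg.n_sources]
    out: dict[str, list[GeneModel]] = {lab: [] for lab in labels}
    for m in models:
        cls = gc_class[m.transcript_id]
        for lab in labels:
            if lab.startswith("orig"):
                centre = 0.25
            elif lab.startswith(cls):
                centre = 0.12
            else:
                centre = 0.45
            aed = float(np.clip(rng.normal(centre, cfg.source_aed_noise), 0.0, 1.0))
            out[lab].append(
                replace(
                    m,
                    transcript_id=f"{lab}:{m.transcript_id}",
                    source_label=lab,
                    aed=aed,
                )
            )
    return out


@dataclass
class TETables:
    """Decoy TE-detection tables plus the truth they encode."""

    gypsy_hits: list[DomainHit]
    transposase_hits: list[HomologyHit]
    refmap: list[RefmapEntry]
    te_pfam_domains: list[str]
    pfam_hits: list[DomainHit]  # background Pfam table (TE and non-TE hits)
    te_ids: set[str]


def _evalue(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def simulate_te_tables(truth: pd.DataFrame, cfg: SimulationConfig) -> TETables:
    """Tables in which exactly the truth-flagged TE genes trip the TE filter.

    Every TE gene receives at least one qualifying record (E-value below the
    relevant threshold); clean genes receive only sub-threshold decoys (at
    rate ``decoy_rate``) that must never cause removal.
    """
    rng = np.random.default_rng(cfg.seed + 303)
    gypsy: list[DomainHit] = []
    tpase: list[HomologyHit] = []
    refmap: list[RefmapEntry] = []
    pfam: list[DomainHit] = []
    te_ids: set[str] = set()

    def blast_row(tid: str, subj: str, ev: float) -> HomologyHit:
        ident = float(rng.uniform(30, 95))
        fields = (
            tid, subj, f"{ident:.1f}", "200", "10", "2", "1", "200", "1", "200",
            f"{ev:.2e}", "150.0",
        )
        return HomologyHit(tid, subj, ident, ev, fields)

    for row in truth.itertuples():
        tid = row.transcript_id
        if row.is_te:
            te_ids.add(tid)
            rules = rng.random(4) < 0.5
            if not rules.any():
                rules[rng.integers(0, 4)] = True
            if rules[0]:
                gypsy.append(DomainHit(tid, f"GYVIT{rng.integers(1000):04d}",
                                       _evalue(rng, -30, -5.2), _evalue(rng, -30, -5.2)))
            if rules[1]:
                tpase.append(blast_row(tid, f"Tpase{rng.integers(1000):04d}",
                                       _evalue(rng, -40, -10.2)))
            if rules[2]:
                acc = _TE_PFAM_DOMAINS[int(rng.integers(len(_TE_PFAM_DOMAINS)))]
                pfam.append(DomainHit(tid, acc, _evalue(rng, -40, -10.2),
                                      _evalue(rng, -40, -10.2)))
            if rules[3]:
                refmap.append(
                    RefmapEntry(f"TE_{row.gene_id}", f"TE_{tid}", "=",
                                (row.gene_id, tid))
                )
        else:
            # harmless background: a real (non-TE) Pfam domain for most genes
            if rng.random() < 0.7:
                acc = _CLEAN_PFAM_DOMAINS[int(rng.integers(len(_CLEAN_PFAM_DOMAINS)))]
                pfam.append(DomainHit(tid, acc, _evalue(rng, -40, -11),
                                      _evalue(rng, -40, -11)))
            # sub-threshold decoys that must never fire
            if rng.random() < cfg.decoy_rate:
                gypsy.append(DomainHit(tid, f"GYVIT{rng.integers(1000):04d}",
                                       _evalue(rng, -4.8, -2.0), _evalue(rng, -4.8, -2.0)))
            if rng.random() < cfg.decoy_rate:
                tpase.append(blast_row(tid, f"Tpase{rng.integers(1000):04d}",
                                       _evalue(rng, -9.8, -6.0)))
    return TETables(
        gypsy_hits=gypsy,
        transposase_hits=tpase,
        refmap=refmap,
        te_pfam_domains=list(_TE_PFAM_DOMAINS),
        pfam_hits=pfam,  # TE-domain and clean Pfam hits together
        te_ids=te_ids,
    )


@dataclass
class CountTables:
    """TRAP/mRNA count tables and the expected-TPM truth behind them."""

    trap_counts: pd.DataFrame  # transcripts x tissues
    mrna_counts: pd.DataFrame
    lengths: pd.Series
    true_tei: pd.Series  # ratio of expected TPMs, constant across tissues


def simulate_counts(
    models: Sequence[GeneModel], cfg: SimulationConfig
) -> CountTables:
    """Negative-binomial TRAP/mRNA counts with known per-gene enrichment.

    A fraction of genes is translationally enriched (TEI 2-4) or depleted
    (TEI 0.25-0.5); the rest sit at TEI 1. The recorded truth is the ratio of
    expected TPMs, which the TPM/TEI pipeline estimates consistently.
    """
    rng = np.random.default_rng(cfg.seed + 404)
    ids = [m.transcript_id for m in models]
    lengths = pd.Series([float(m.spliced_length) for m in models], index=ids, name="length")
    n = len(ids)

    u = rng.random(n)
    ratio = np.ones(n)
    enriched = u < cfg.enriched_fraction
    depleted = u > 1.0 - cfg.depleted_fraction
    ratio[enriched] = rng.uniform(2.0, 4.0, enriched.sum())
    ratio[depleted] = rng.uniform(0.25, 0.5, depleted.sum())

    mrna_mean = rng.lognormal(mean=np.log(cfg.mean_depth), sigma=0.5, size=n)
    trap_mean = mrna_mean * ratio

    def nb(mean_matrix: np.ndarray) -> np.ndarray:
        size = cfg.nb_dispersion
        p = size / (size + mean_matrix)
        return rng.negative_binomial(size, p)

    tissue_effect = rng.lognormal(0.0, 0.2, size=(n, len(cfg.tissues)))
    mrna_mat = mrna_mean[:, None] * tissue_effect
    trap_mat = trap_mean[:, None] * tissue_effect
    mrna_counts = pd.DataFrame(nb(mrna_mat), index=ids, columns=list(cfg.tissues))
    trap_counts = pd.DataFrame(nb(trap_mat), index=ids, columns=list(cfg.tissues))

    # truth = ratio of expected TPMs (compositional scaling included)
    mrna_rate = mrna_mean / lengths.to_numpy()
    trap_rate = trap_mean / lengths.to_numpy()
    true_tei = pd.Series(
        (trap_rate / trap_rate.sum()) / (mrna_rate / mrna_rate.sum()),
        index=ids,
        name="true_tei",
    )
    return CountTables(trap_counts, mrna_counts, lengths, true_tei)


# ---------------------------------------------------------------------------
# Writers for the decoy tables (text dialects matching io_formats readers)


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write DomainHits in the HMMER3 --tblout dialect (18+ columns)."""
    with open(path, "w") as fh:
        fh.write("# synthetic tblout\n")
        for h in hits:
            cols = [
                h.domain_accession, h.domain_accession, h.query_id, "-",
                f"{h.full_seq_evalue:.2e}", "100.0", "0.1",
                f"{h.domain_evalue:.2e}", "95.0", "0.1",
                "1.0", "1", "1", "0", "1", "1", "1", "1", "synthetic domain",
            ]
            fh.write(" ".join(cols) + "\n")


def write_homology_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write HomologyHits as 12-column BLAST tabular."""
    with open(path, "w") as fh:
        for h in hits:
            fields = h.fields or (
                h.query_id, h.subject_id, f"{h.percent_identity:.1f}",
                "100", "0", "0", "1", "100", "1", "100", f"{h.evalue:.2e}", "100.0",
            )
            fh.write("\t".join(fields) + "\n")


def write_refmap(entries: Iterable[RefmapEntry], path: str | Path) -> None:
    """Write RefmapEntries in the gffcompare .refmap dialect."""
    with open(path, "w") as fh:
        fh.write("ref_gene_id\tref_id\tclass_code\tqry_id_list\n")
        for e in entries:
            fh.write(
                f"{e.ref_gene_id}\t{e.ref_transcript_id}\t{e.class_code}\t"
                + "|".join(e.query_ids)
                + "\n"
            )
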