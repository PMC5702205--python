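"""Codon usage bias: GC3s and the effective number of codons (Nc).

GC3s is the fraction of third codon positions that are G or C, counted only
over synonymously variable codons — amino acids encoded by a single codon
(Met, Trp) and stop codons carry no synonymous signal and are excluded.

Nc (Wright's effective number of codons) summarises how evenly an amino
acid's synonymous codons are used, on a 20 (one codon per amino acid) to 61
(uniform usage) scale. Per amino acid a with n_a >= 2 counted codons and k_a
synonyms, homozygosity is estimated as

    F_a = (n_a * sum(p_i^2) - 1) / (n_a - 1)

and Nc is assembled from the mean F within each degeneracy class of the
standard genetic code (9 two-fold, 1 three-fold [Ile], 5 four-fold, 3 six-fold
amino acids):

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

Conventional fallbacks: amino acids with n_a < 2 are left out of their class
mean; if Ile is absent, F3 is replaced by (F2 + F4)/2; zero F estimates are
dropped from their class mean (and noted on the record). Nc is capped at 61.

Under pure mutational pressure (no selection on codon usage) the expected Nc
at a given GC3s value s follows Wright's null curve

    Nc_null(s) = 2 + s + 29 / (s^2 + (1 - s)^2)

plotting observed (GC3s, Nc) pairs against this curve shows whether usage
bias exceeds what base composition alone explains.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import SequenceRecord

__all__ = [
    "CodonUsage",
    "count_codons",
    "gc3s",
    "effective_codon_number",
    "nc_null_curve",
    "write_codon_usage_table",
    "SYNONYM_FAMILIES",
    "DEGENERACY_CLASS_SIZES",
]

CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
STOP_CODONS = set(standard_dna_table.stop_codons)
AA_OF = dict(standard_dna_table.forward_table)  # codon -> amino acid, stops absent

# amino acid -> tuple of synonymous codons (standard code)
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for codon, aa in AA_OF.items():
    SYNONYM_FAMILIES.setdefault(aa, ())
SYNONYM_FAMILIES = {
    aa: tuple(sorted(c for c, a in AA_OF.items() if a == aa)) for aa in SYNONYM_FAMILIES
}

# degeneracy class -> number of amino acids in it (2:9, 3:1 [Ile], 4:5, 6:3)
DEGENERACY_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonUsage:
    """64-codon counts for one CDS, with bookkeeping for skipped codons."""

    transcript_id: str
    codon_counts: dict[str, int]
    n_codons: int
    skipped: int = 0  # codons containing non-ACGT bases
    internal_stops: int = 0
    notes: list[str] = field(default_factory=list)


def count_codons(cds: SequenceRecord) -> CodonUsage:
    """Frame-0 codon tally; the terminal stop codon is excluded from usage.

    Codons containing non-ACGT bases are skipped (counted in ``skipped``);
    internal stop codons are excluded from usage statistics and warned about.
    """
    seq = cds.sequence
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{cds.id}: CDS length {len(seq)} is not a multiple of 3"
        )
    counts = {c: 0 for c in CODONS}
    skipped = 0
    internal_stops = 0
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if any(b not in "ACGT" for b in codon):
            skipped += 1
            continue
        if codon in STOP_CODONS:
            internal_stops += 1
            continue
        counts[codon] += 1
    usage = CodonUsage(
        transcript_id=cds.id,
        codon_counts=counts,
        n_codons=sum(counts.values()),
        skipped=skipped,
        internal_stops=internal_stops,
    )
    if internal_stops:
        warnings.warn(
            f"{cds.id}: {internal_stops} internal stop codon(s) excluded from usage",
            stacklevel=2,
        )
    return usage


def gc3s(u: CodonUsage) -> float:
    """Fraction of G/C third positions among synonymously variable codons.

    Met (ATG), Trp (TGG) and stop codons are excluded. NaN when no eligible
    codons were counted.
    """
    eligible = 0
    gc = 0
    for aa, codons in SYNONYM_FAMILIES.items():
        if len(codons) < 2:
            continue  # Met, Trp
        for codon in codons:
            n = u.codon_counts[codon]
            eligible += n
            if codon[2] in "GC":
                gc += n
    if eligible == 0:
        u.notes.append("gc3s undefined: no synonymously variable codons")
        return float("nan")
    return gc / eligible


def _family_homozygosity(u: CodonUsage, codons: Sequence[str]) -> tuple[int, float | None]:
    n = sum(u.codon_counts[c] for c in codons)
    if n < 2:
        return n, None
    s = sum((u.codon_counts[c] / n) ** 2 for c in codons)
    return n, (n * s - 1.0) / (n - 1.0)


def effective_codon_number(u: CodonUsage) -> float:
    """Wright's Nc from the codon tally; NaN when no amino acid has n >= 2."""
    class_F: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASS_SIZES}
    any_counted = False
    for aa, codons in SYNONYM_FAMILIES.items():
        k = len(codons)
        if k < 2:
            continue
        n, F = _family_homozygosity(u, codons)
        if F is None:
            continue
        any_counted = True
        class_F[k].append(F)
    if not any_counted:
        u.notes.append("nc undefined: no amino acid observed >= 2 times")
        return float("nan")

    def class_mean(k: int) -> float | None:
        vals = class_F[k]
        if not vals:
            return None
        mean = float(np.mean(vals))
        if mean <= 0:
            positive = [v for v in vals if v > 0]
            u.notes.append(f"class {k}: zero homozygosity estimates dropped")
            if not positive:
                return None
            mean = float(np.mean(positive))
        return mean

    F2, F3, F4, F6 = (class_mean(k) for k in (2, 3, 4, 6))
    if F3 is None and F2 is not None and F4 is not None:
        u.notes.append("Ile absent: F3 estimated as (F2+F4)/2")
        F3 = (F2 + F4) / 2.0
    if any(f is None for f in (F2, F3, F4, F6)):
        u.notes.append("nc undefined: an entire degeneracy class is missing")
        return float("nan")
    nc = 2.0 + 9.0 / F2 + 1.0 / F3 + 5.0 / F4 + 3.0 / F6
    return min(nc, 61.0)


def nc_null_curve(s: float | np.ndarray) -> float | np.ndarray:
    """Expected Nc at GC3s = ``s`` under no selection on codon usage."""
    s = np.asarray(s, dtype=float)
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


def write_codon_usage_table(
    usages: Iterable[CodonUsage], path: str | Path
) -> None:
    """TSV of per-CDS codon-usage summaries: id, n_codons, gc3s, nc."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tn_codons\tgc3s\tnc\n")
        for u in usages:
            g = gc3s(u)
            nc = effective_codon_number(u)
            gs = "NA" if math.isnan(g) else f"{g:.4f}"
            ns = "NA" if math.isnan(nc) else f"{nc:.4f}"
            fh.write(f"{u.transcript_id}\t{u.n_codons}\t{gs}\t{ns}\n")
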