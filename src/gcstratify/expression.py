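"""TPM normalisation and the translatome enrichment index (TEI).

TEI is the ratio of TRAP-seq (translating-ribosome affinity purification) TPM
to total mRNA-seq TPM for a transcript in one tissue; values well above 1
suggest preferential translation. TPM is the standard length-normalised
relative abundance: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TEIRecord", "tpm", "tpm_table", "tei", "tei_table", "row_scale", "support_fraction"]


@dataclass(frozen=True)
class TEIRecord:
    transcript_id: str
    tissue: str
    trap_tpm: float
    mrna_tpm: float
    tei: float  # NaN when mrna_tpm == 0 (undefined, distinct from 0)


def tpm(counts: Sequence[float] | pd.Series, lengths: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Transcripts-per-million from raw counts and transcript lengths."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if c.shape != l.shape:
        raise ValueError(f"counts ({c.shape}) and lengths ({l.shape}) differ in shape")
    if np.any(l <= 0):
        raise ValueError("all transcript lengths must be positive")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rates = c / l
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero counts: TPM undefined")
    out = 1e6 * rates / total
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out

def tpm_table(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Column-wise TPM for a transcripts x samples count table."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing lengths for transcripts {missing}")
    return counts.apply(lambda col: tpm(col, lengths), axis=0)


def tei(trap_tpm: float, mrna_tpm: float, transcript_id: str = "", tissue: str = "") -> TEIRecord:
    """TEI = TRAP TPM / mRNA TPM; undefined (NaN) when the denominator is 0."""
    if trap_tpm < 0 or mrna_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    value = trap_tpm / mrna_tpm if mrna_tpm > 0 else float("nan")
    return TEIRecord(transcript_id, tissue, trap_tpm, mrna_tpm, value)


def tei_table(trap_tpm: pd.DataFrame, mrna_tpm: pd.DataFrame) -> pd.DataFrame:
    """Element-wise TEI for aligned transcripts x tissues TPM tables."""
    if not trap_tpm.index.equals(mrna_tpm.index) or not trap_tpm.columns.equals(mrna_tpm.columns):
        raise ValueError("TRAP and mRNA TPM tables must share index and columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = trap_tpm / mrna_tpm
    return out.where(mrna_tpm > 0, np.nan)


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to sum 1 (heatmap display); all-zero rows stay zero."""
    sums = matrix.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero row(s) left unscaled", stacklevel=2)
    safe = sums.replace(0, 1.0)
    return matrix.div(safe, axis=0)


def support_fraction(novel_ids: Sequence[str], expressed_ids: Sequence[str]) -> tuple[int, float]:
    """How many novel models have expression support, and the percentage.

    The percentage is rounded to the nearest integer; NaN for an empty novel
    set (flagged, not an error).
    """
    novel = set(novel_ids)
    if not novel:
        return 0, float("nan")
    count = len(novel & set(expressed_ids))
    return count, float(round(100.0 * count / len(novel)))
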