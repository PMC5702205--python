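"""Construction of GC-stratified and randomized gene-prediction training sets.

High-quality transcript-derived (est2genome) gene models — those with
AED <= 0.2 — are either partitioned by CDS GC content at the detected low/high
peaks (boundaries inclusive: a model sitting exactly on a peak belongs to that
stratum) or sampled at random as GC-agnostic controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gc_profile import GCCutoffs, GCRecord
from .io_formats import GeneModel, ModelError, SequenceRecord, write_fasta, write_gff3

__all__ = [
    "TrainingSet",
    "select_training_models",
    "partition_by_gc",
    "random_training_subsets",
    "write_training_set",
]

DEFAULT_AED_THRESHOLD = 0.2


@dataclass
class TrainingSet:
    """A labelled set of training gene models with its provenance."""

    label: str
    members: list[GeneModel]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.transcript_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ModelError(f"training set {self.label!r}: duplicate transcript ids")

    @property
    def transcript_ids(self) -> list[str]:
        return [m.transcript_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def select_training_models(
    models: Sequence[GeneModel], aed_threshold: float = DEFAULT_AED_THRESHOLD
) -> list[GeneModel]:
    """Keep high-quality models with AED <= threshold (boundary inclusive)."""
    for m in models:
        if m.aed is None:
            raise ModelError(
                f"model {m.transcript_id!r} carries no AED; score models before "
                "training-set selection"
            )
    return [m for m in models if m.aed <= aed_threshold]


def partition_by_gc(
    models: Sequence[GeneModel],
    gc: Mapping[str, GCRecord],
    cutoffs: GCCutoffs,
) -> tuple[TrainingSet, TrainingSet]:
    """Split models into low-GC (gc <= low peak) and high-GC (gc >= high peak).

    Models strictly between the peaks belong to neither set. Membership is a
    function of (gc, cutoffs) only — input order never matters.
    """
    low, high = [], []
    for m in models:
        rec = gc.get(m.transcript_id)
        if rec is None:
            raise ModelError(f"no GC record for model {m.transcript_id!r}")
        if rec.undefined:
            continue
        if rec.gc_percent <= cutoffs.low_peak:
            low.append(m)
        elif rec.gc_percent >= cutoffs.high_peak:
            high.append(m)
    if not low and not high:
        warnings.warn(
            "no models at or beyond either GC cutoff; both training sets are empty",
            stacklevel=2,
        )
    prov = {"low_peak": cutoffs.low_peak, "high_peak": cutoffs.high_peak}
    return (
        TrainingSet("low_gc", low, dict(prov)),
        TrainingSet("high_gc", high, dict(prov)),
    )


def random_training_subsets(
    models: Sequence[GeneModel], k: int, base_seed: int
) -> tuple[TrainingSet, TrainingSet, TrainingSet]:
    """Three independent size-``k`` subsets sampled without replacement.

    Subset i is drawn with ``numpy.random.default_rng(base_seed + i)`` for
    i in 0..2, so runs are reproducible given ``base_seed``; the three subsets
    are independent draws and may overlap each other.
    """
    if not (1 <= k <= len(models)):
        raise ValueError(f"k={k} outside 1..{len(models)}")
    out = []
    for i in range(3):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(models), size=k, replace=False)
        members = [models[j] for j in sorted(idx)]
        out.append(
            TrainingSet(f"standard_random_{i + 1}", members, {"seed": seed, "k": k})
        )
    return tuple(out)


def write_training_set(
    ts: TrainingSet,
    base: str | Path,
    genome: Sequence[SequenceRecord] | None = None,
) -> list[Path]:
    """Write BASE.gff3, BASE_ids.txt and (when a genome is given) BASE_cds.fasta."""
    from .gc_profile import extract_cds_sequence

    base = str(base)
    written = []
    p = Path(base + ".gff3")
    write_gff3(ts.members, p)
    written.append(p)

    p = Path(base + "_ids.txt")
    with open(p, "w") as fh:
        for tid in ts.transcript_ids:
            fh.write(tid + "\n")
    written.append(p)

    if genome is not None:
        p = Path(base + "_cds.fasta")
        write_fasta((extract_cds_sequence(m, genome) for m in ts.members), p)
        written.append(p)
    return written
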