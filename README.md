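# gcstratify

A toolkit for **GC-stratified structural genome annotation**, aimed at
genomes — the grasses (Poaceae) above all — whose protein-coding genes fall
into two GC classes. In rice-like genomes the distribution of CDS GC content
is bimodal, with a low-GC mode near 47–49% and a high-GC mode near 67–68%,
and gene GC is essentially uncorrelated with the GC of the surrounding
genomic sequence (no isochores). A gene predictor trained on a random sample
of such genes is trained on two populations at once; training separate
predictors on low-GC and high-GC gene sets, then letting the annotation
pipeline keep the best-supported model at each locus, yields both improved
and entirely novel gene models.

`gcstratify` implements the analysis machinery around that protocol so it can
be run, tested and benchmarked without any external data:

* **GC profiling and cutoff detection** — per-transcript CDS GC content,
  integer-percent histogram, moving-window smoothing (default window 7), and
  windowed peak detection (default window 5): a bin is a peak when the
  `(w−1)/2` bins on each side all have strictly lower smoothed counts. The two
  highest peaks become the low/high GC set points.
* **Training-set construction** — high-quality transcript-derived models
  (AED ≤ 0.2) partitioned at the cutoffs (boundaries inclusive), plus three
  seeded random subsets as GC-agnostic controls.
* **Annotation edit distance (AED)** — nucleotide-level concordance between a
  gene model and its best supporting transcript/protein alignment:
  `AED = 1 − (SN + SP)/2`, with `SN = overlap/|evidence|` and
  `SP = overlap/|model|`; 0 is perfect agreement, 1 is no support. Includes
  the AED<0.5 summary and cumulative AED curves.
* **Multi-source merging and comparison** — single-linkage loci, one winner
  per locus (lowest AED, ties to longer transcript, then source order), novel
  models by zero span overlap, improved models by strict AED decrease.
* **Quality and TE filtering** — keep models with evidence support or a Pfam
  domain at E ≤ 1e-10; then remove transposon-like models via Gypsy-domain
  hits (E ≤ 1e-5), transposase homology (E ≤ 1e-10), TE Pfam domains, or
  overlap with a reference TE annotation.
* **Codon usage** — GC3s and Wright's effective number of codons (Nc), with
  the no-selection null curve `Nc = 2 + s + 29/(s² + (1−s)²)`.
* **Expression support** — TPM, the translatome enrichment index
  (TEI = TRAP TPM / mRNA TPM), row scaling for heatmaps, and expression
  support fractions for novel models.
* **A synthetic-genome simulator** — genomes, annotations, evidence,
  TE decoy tables and count tables with known ground truth for every stage.

## Worked example

Simulate a small genome, profile its GC distribution, and score the models:

```bash
gc-stratify simulate --seed 5 --n-genes 150 --out-dir demo/
gc-stratify gc-profile --fasta demo/genome.fasta --gff demo/annotation.gff3 \
    --name demo/RUN --peak 5 --smooth 7
gc-stratify aed --models demo/annotation.gff3 --evidence demo/evidence.gff3 \
    --out demo/aed.tsv
```

which prints

```
wrote 5 sequences, 150 genes to demo
low peak 47  high peak 67
demo/RUN_cds.fasta
demo/RUN_gc_content.txt
demo/RUN_distribution.txt
demo/RUN_cutoff.txt
150 models scored; AED<0.5: 134 (89.3%)
```

The detected peaks (47 and 67) are the modes of the simulated bimodal CDS GC
mixture and become the partition set points in `demo/RUN_cutoff.txt`. The AED
line says 134 of 150 models have evidence support better than 0.5 — the rest
are the simulator's evidence-dropout genes, which score AED = 1 (no support).
From here, `gc-stratify partition` splits the training models at the cutoffs,
`gc-stratify compare` merges multi-source predictions and reports novel and
improved models, and `gc-stratify standard-filter` / `te-filter` produce the
final high-quality, TE-free gene list.

The same functionality is available as a library:

```python
from gcstratify import SimulationConfig, simulate_genome
from gcstratify.gc_profile import (extract_cds_sequence, gc_content,
                                   build_histogram, smooth_histogram,
                                   determine_cutoffs)

genome, models, truth = simulate_genome(SimulationConfig(seed=5, n_genes=150))
records = [gc_content(extract_cds_sequence(m, genome)) for m in models]
cutoffs = determine_cutoffs(smooth_histogram(build_histogram(records), 7), 5)
print(cutoffs.low_peak, cutoffs.high_peak)   # 47 67
```

## Layout

```
src/gcstratify/
  io_formats.py       FASTA / GFF3 / tblout / BLAST tabular / refmap
  gc_profile.py       GC content, histogram, smoothing, peaks, cutoffs
  training_sets.py    AED selection, GC partition, random subsets
  aed.py              annotation edit distance and summaries
  gene_set_compare.py loci, per-locus merge, novel and improved models
  quality_filter.py   evidence/Pfam standard list and TE removal
  codon_usage.py      GC3s, Nc, no-selection null curve
  expression.py       TPM, TEI, row scaling, support fractions
  synthetic.py        ground-truth simulators for all of the above
  cli.py              the gc-stratify command
```

`docs/methods.md` describes the models, parameter choices and limitations in
detail.
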