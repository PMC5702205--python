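# Methods

This note documents the models and procedures `gcstratify` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## The problem

In grass genomes the GC content of protein-coding sequence is bimodal: one
population of genes sits near 47–49% GC, another near 67–68%. Gene GC is not
predicted by flanking genomic GC (grasses lack isochores), so the two classes
cannot be separated by genomic context — only by the genes themselves. Gene
predictors trained on a random sample of genes are therefore trained on a
mixture of two sequence-composition regimes. The protocol this package
supports partitions the training data by CDS GC content at the modes of the
distribution, trains class-specific predictors, and merges all predictions by
keeping the best-supported model per locus.

## GC profiling and cutoff detection

Per transcript, CDS intervals are spliced 5′→3′ (minus-strand models
reverse-complemented) and GC% is computed with N excluded from the
denominator; all-N sequences yield an undefined (NaN) GC and are flagged
rather than dropped. Values are binned by `floor()` into integer-percent bins
0–100, with 100.0 folded into bin 100.

The raw histogram is smoothed by a moving average over a centred window of
`--smooth` bins (odd, default 7). The window is truncated at the domain
edges and the mean is taken over the bins actually present, so
`smoothed[0]` with window 3 is the mean of bins 0–1. A consequence worth
knowing: each interior count is conserved exactly by smoothing, but mass
within a half-window of the edges can be slightly amplified or attenuated.
GC histograms have essentially no mass at the extremes, so in practice total
mass is conserved.

A bin is a **peak** when every one of the `(w−1)/2` bins on each side
(`--peak` window, odd, default 5) has a *strictly* lower smoothed count.
Edge bins without a full window are ineligible, and ties produce no peak —
this prevents flat-topped modes from yielding adjacent double peaks, at the
price that an exact tie between the two top bins of a mode suppresses that
peak entirely. With integer counts this happens occasionally (a few percent
of simulated 2,000-gene genomes); the cutoff finder then reports fewer than
two peaks and asks for manual cutoffs instead of guessing. Among detected
peaks the two with the highest smoothed counts are kept, ties broken toward
the bin farther from 50% GC (the more extreme mode), and ordered as the
(low, high) set points.

Interpretive choices: the peak rule compares smoothed bin *frequencies* (the
only reading under which it finds modes of a distribution), and binning and
smoothing are treated as separate steps (fixed integer bins, then a windowed
moving average).

## Training sets

Only high-quality transcript-derived models train predictors: AED ≤ 0.2,
boundary inclusive. The AED filter is applied before GC partitioning
(disable with `--no-aed-filter`). Partitioning is boundary-inclusive on both
sides — a model whose GC equals a peak value belongs to that stratum, since
the peak bin holds the densest, most typical members of its class — and
models strictly between the cutoffs join neither set. Membership is a pure
function of (GC, cutoffs): input order can never change it.

The randomized controls are three independent subsets of size `k`, sampled
without replacement with `numpy.random.default_rng(base_seed + i)` for
i = 0, 1, 2. They may overlap one another; no disjointness is claimed. The
default `k` matches the stratified set sizes so the controls are
size-comparable.

## Annotation edit distance

For a model with footprint F (exons when annotated, else CDS; CDS when the
evidence is protein) and an evidence alignment with blocks B on the same
sequence:

    SN = |F ∩ B| / |B|,  SP = |F ∩ B| / |F|,  AED = 1 − (SN + SP)/2

computed at nucleotide resolution. AED is 0 iff F and B cover identical
position sets and 1 iff they share no position. A model's score against an
evidence collection is the minimum over single-alignment AEDs — its best
supporting evidence; pooled multi-evidence scoring and splice-aware variants
are out of scope. Strand handling: unknown strands are compared; two known,
opposite strands mean no support. A seqid mismatch is "no support"
(AED = 1), not an error. The AED<0.5 summary counts strictly-below-0.5
scores; transcript length summaries use spliced (summed-exon) length.

## Merging, novelty, improvement

Loci are single-linkage clusters of models with ≥ 1 bp span overlap, on one
seqid and (by default) one strand — gene loci on opposite strands are
biologically distinct. Per locus exactly one model survives: minimal AED,
ties to the longer spliced length, remaining ties to the earliest source in
the declared source order, then transcript id for full determinism.

Novelty is strand-agnostic zero-overlap of spans against every reference set
(mirroring plain coordinate intersection with its 1 bp default); both the
strand flag and the minimum overlap are configurable. A standard model is
*improved* when the merged annotation's model at an overlapping locus comes
from a non-standard source with strictly lower AED; equal AEDs never count.

## Quality and TE filters

The standard list keeps a model when AED < 1 (some evidence overlaps it) or
it has a Pfam hit with full-sequence E ≤ 1e-10. Evidence support is
operationalized as AED < 1 — a deliberate simplification that collapses
separate transcript/protein support flags into the score that already
encodes them. Models with no AED are treated as unsupported, with a warning.

The TE filter removes a model when any of four rules fire, and records every
rule that fired: Gypsy-domain hit at E ≤ 1e-5; transposase homology at
E ≤ 1e-10; a Pfam hit whose accession (version-stripped) is on the TE-domain
list at the Pfam cutoff; membership in a reference-TE refmap entry (any
class code by default; restrictable). E-value comparisons use the
full-sequence E-value column of the tblout dialect, not the per-domain
value. Both filters are idempotent and order-independent, and thresholds
applied at parse time versus filter time agree.

## Codon usage

GC3s is the G+C fraction of third positions among synonymously variable
codons — Met, Trp and stops excluded. Nc follows Wright's estimator: per
amino acid with n ≥ 2 counted codons, F̂ = (n·Σp̂² − 1)/(n − 1); class means
F̄ₖ over the degeneracy classes of the standard genetic code (9 two-fold,
Ile as the single three-fold, 5 four-fold, 3 six-fold);
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. Conventional fallbacks,
each noted on the record: amino acids with n < 2 leave their class mean; if
Ile is absent, F̄₃ := (F̄₂ + F̄₄)/2; if a class mean is ≤ 0, zero-F̂ members
are dropped and the class recomputed. Terminal stops are excluded from the
tally; internal stops are excluded and warned about; codons containing
non-ACGT bases are skipped and counted. The no-selection expectation is
Nc(s) = 2 + s + 29/(s² + (1−s)²); note this curve is *not* exactly
symmetric about s = 0.5 (the linear term), though its maximum on a 0.01 grid
is 60.5 at s = 0.5.

## Expression

TPM is the standard length-normalised relative abundance with effective
length = transcript length (no fragment-length correction — a simplification
of pseudoalignment models). TEI = TRAP TPM / mRNA TPM per transcript and
tissue; a zero denominator yields "undefined", reported distinctly from 0.
Heatmap rows are scaled to sum 1, all-zero rows left untouched with a
warning. "Expressed", for support fractions over novel models, means at
least one assigned count in at least one sample (threshold configurable).

## The synthetic benchmark

`synthetic.SimulationConfig` defaults define the study conditions:

| parameter | default | why |
|---|---|---|
| GC mixture | 50/50 at μ = 47/68, σ = 3 | the two CDS GC modes of a bimodal grass-like genome |
| CDS length | N(900, 300) bp, ≥ 300, ×3 | typical spliced CDS scale |
| exons per gene | 1–3 | exercises splicing without modelling intron biology |
| intergenic GC | 43% | genome background distinct from both gene modes |
| evidence extension e | 25 bp | yields the closed-form AED 1 − (1 + L/(L+2e))/2 |
| evidence dropout | 0.1 | a minority of genes with no support (AED = 1) |
| TE fraction | 0.1 | decoy tables with a known removable set |
| NB dispersion | 50 | mild overdispersion so TEI is recoverable |
| mean depth | 800 | counts deep enough for ratio estimation |

CDS sequences are built from 4-fold degenerate codon boxes: positions 1–2
set a baseline GC and exactly the number of third positions needed to hit
the per-gene GC target are made G/C — so GC is concentrated at synonymous
sites, as in real high-GC grass genes, peptides stay stop-free, and realized
GC lands within rounding of the target. Intergenic sequence is drawn
independently of gene GC, which is what makes the no-isochore check
(|r| < 0.1 between gene GC and 5 kb flank GC) a property of the generator
rather than an accident. Genomes span 5 sequences to exercise multi-seqid
paths. Every simulator is a pure function of its config; identical seeds
give byte-identical outputs.

What passing these tests shows: the algorithms are exact against independent
oracles and closed forms, and parameter recovery works when the data match
the assumed structure. What they do not show: robustness to real-data
features the generator omits — UTRs, alternative isoforms, overlapping
genes, repeat landscapes, sequencing error, GC-content gradients along
genes, and evidence that disagrees with gene structure in ways other than
uniform end-extension.

## Numerical and format choices

Coordinates are 1-based inclusive everywhere (GFF3 native); half-open
arithmetic exists only inside interval intersection. The GFF3 writer is
canonical — gene→mRNA→exon→CDS nesting, ID/Parent attributes (plus `_AED`
on scored mRNAs so read/write is lossless), features sorted by
(seqid, start, ID) — making write→read→write byte-stable, which the tests
assert. Unknown strand is stored explicitly, never coerced. Duplicate
transcript ids are an error, never a silent rename. All writers emit UNIX
newlines with no trailing whitespace. Undefined quantities (GC of an all-N
sequence, TEI with zero denominator, summaries of empty sets) are NaN/flags,
never silently 0.

Problem sizes in the test-suite and acceptance script (2,000-gene genomes,
20 seeds for cutoff recovery, 1,000-case oracle comparisons, 500-locus merge
checks) were chosen as the smallest scales at which the distributional
properties under test are stable.

## Known limitations

* AED here is the nucleotide-level definition; pipeline-specific variants
  (splice-aware, pooled-evidence, eAED) will differ on multi-isoform loci.
* The Nc fallbacks for rare amino acids are conventions; other
  implementations make different choices for tiny samples, so Nc values for
  very short CDS are comparable only within one implementation.
* The strict peak rule can drop a mode on an exact tie of its two top bins;
  the intended remedy is the documented manual-cutoff path, not a softer
  rule.
* The expression module deliberately stops at TPM/TEI arithmetic; estimating
  counts from reads is out of scope.
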