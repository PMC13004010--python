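# Methods

## Coordinate and strand conventions

All coordinates are 0-based half-open (BED convention); GTF input is
converted on load. Strand-aware positions are expressed in the same
convention: the PAS of a + strand transcript is its half-open end, of a −
strand transcript its start. The 3′ end of a long read is taken as the
polymerase position, which is the premise behind both readthrough
classification and the nascent interpretation of splicing status. Every
strand-aware computation must be invariant under mirroring (reflect
coordinates at the chromosome length and flip strands); this symmetry is
enforced by tests and used internally by the simulator, which generates −
strand reads in mirrored (+) space with a single direction of logic.

## Gene models

Two representative transcripts are kept per gene because they answer
different questions. Splicing metrics are computed against the *canonical*
transcript (taken from an `Ensembl_canonical`-style tag when present; when
absent the longest transcript is used and a warning logged, so that
annotations without the tag remain usable). Readthrough is judged against
the transcript with the *distal-most 3′ end*, because a read ending inside
an annotated long 3′ UTR isoform is not evidence of failed cleavage. The
readthrough boundary is 100 nt past that PAS in the direction of
transcription, and a 3′ end exactly at the boundary counts as readthrough
(the boundary definition is "at least 100 nt downstream"; inclusivity at
the exact boundary is asserted by a dedicated test, and sensitivity to the
choice can be probed by changing `Thresholds.boundary_offset`).

Tandem pairs — the substrate for readthrough chimeras — are consecutive
same-strand genes on a chromosome in transcription order. Opposite-strand
genes lying between the two do not break adjacency, since readthrough
proceeds along one strand. The pair distance runs from the upstream gene's
distal 3′ end to the downstream gene's 5′-most coordinate.

## Per-read classification

Reads are assigned to the same-strand gene with the greatest aligned
overlap, with the gene span extended to its readthrough boundary so reads
lying only in the post-PAS zone still find their parent; exact ties go to
the lexicographically smaller gene id, making the result independent of
input order. An intron counts as spanned only when the read covers it
entirely with at least one aligned base on each flanking exon; it counts
as spliced when a junction matches both boundaries within
`junction_tolerance` nt. The tolerance defaults to 0, which is correct for
the simulator's exact junctions; real aligners wobble at junction edges,
and a tolerance of ~3 nt is the intended setting there. Junctions matching
no annotated intron are ignored — the metrics are defined against
annotated introns, and novel junctions are neither spliced nor retained
evidence for them. Reads spanning no intron are `not_informative` and are
excluded from splicing denominators. Reads not touching the last exon
(one aligned base suffices, configurable) take no part in RTI.

## Metrics and testing

RTI, CoSE, and SPI are all pooled-count proportions; per-replicate values
are retained for dispersion checks, and the ≥ 10 last-exon reads filter is
applied per replicate before pooling. Gene-level CoSE (for all-or-none
calling) pools spliced/spanning counts over the gene's introns — a
count-weighted aggregation; a per-intron mean is available as an option.
Differential splicing uses a Pearson chi-square without continuity
correction on each replicate pair, and combines the per-pair p-values by
their **maximum**. The combination rule is genuinely open; the maximum is
the conservative reading (an intron is only called when every replicate
pair concurs) and is configurable (Fisher's method is provided). A
degenerate 2×2 table whose spliced or unspliced column is zero in both
conditions has identical proportions and is scored p = 1 rather than
dropped; a table with an empty replicate is undefined and excluded from
the combination. BH adjustment runs across the introns of one contrast
only. Two alpha defaults coexist deliberately: 0.05 for ΔCoSE calls and
0.01 for SPI-only calls, both exposed in `Thresholds` (the stricter SPI
alpha reflects the higher depth of short-read data; the source protocols
state both values in different places, so neither is hard-coded).

PAS-downstream coverage counts aligned block bases only (junction gaps
contribute nothing) at offsets −200 … +4000 relative to each PAS in
transcription direction, normalized to the coverage 200 nt upstream;
genes with zero anchor coverage are dropped with a log entry. The 4 kb
downstream window is a default, not a constraint. ΔΔCt quantification
normalizes each target's Ct to a spike-in, references the upstream gene's
last exon, and reports fold changes with the control sample at 1.0.

## Synthetic data

The generator emulates the *structure* of a stranded nascent RNA long-read
experiment, not any dataset's content. Its model, per read: a Bernoulli
choice between a terminal snapshot (polymerase in the last-exon region)
and an internal one; terminal reads read through with probability ρ_g, in
which case the 3′ end extends past the boundary by a geometric tail (mean
1/`tail_decay` ≈ 100 nt by default, capped), and otherwise end exactly at
the PAS; internal 3′ ends are uniform upstream of the last exon. This
makes ρ_g exactly the probability of readthrough among last-exon reads —
the quantity RTI estimates — so recovery tests are well-posed. Starts are
TSS-anchored with configured probability, else uniform within the gene;
the read-length cap truncates from the anchored 3′ end backwards, removing
5′ sequence, which reproduces the bias that makes TSS filtering meaningful.
Each spanned intron is excised with probability σ_i, emitting an exact
junction; there is no junction noise or base-level error model (alignment
is upstream of this package), matching tolerance 0. When the length cap is
active the geometric tail is clamped so truncation always leaves the
minimum span aligned inside the gene; without that clamp, a deeply
truncated readthrough read could lie wholly beyond the boundary and become
unassignable, and no real library preparation yields such reads.

What the generator does **not** emulate — junction wobble, mapping
ambiguity, expression-level variation between genes, PCR duplicates,
antisense contamination — bounds what passing tests show: they validate
the arithmetic, the boundary semantics, and the statistical calibration of
the pipeline, not its robustness to alignment artifacts on real data.

Simulated fusion tables contain rows for designated chimera pairs with
passing support, plus one decoy per filter rule (low span, low junction —
which necessarily also breaks the ≥ 6 total rule, since 3 + 2 < 6 is the
only way to fail the total with one type at its minimum — opposite
strands, non-adjacency, sub-500 nt separation, snoRNA partner,
unannotated gene), each with its expected verdict recorded. Ct tables are
noise-free encodings of configured fold changes, so ΔΔCt recovery is
exact. Identical configuration and seed give byte-identical output files.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `boundary_offset` | 100 nt | readthrough boundary past the PAS |
| `rti_high` | 0.2 | RTI cutoff for readthrough genes |
| `min_reads_per_replicate` | 10 | last-exon reads required per replicate |
| `cose_all_or_none_max` | 0.7 | gene-level CoSE cutoff for all-or-none calls |
| `delta_cose_min` / `alpha_cose` | 0.1 / 0.05 | ΔCoSE significance |
| `alpha_spi` | 0.01 | SPI significance |
| `spi_min_pooled` | 500 | pooled splice-site reads per intron |
| `tss_window` | 100 nt | TSS-start window |
| `pas_norm_upstream` | 200 nt | profile normalization anchor |
| `tail_decay` / `max_tail` | 0.01 / 4000 nt | geometric readthrough tail |
| `read_length_cap` | 2500 nt | 3′-anchored truncation |
| `reads_per_gene` | 100/replicate | sequencing depth per gene |

## Problem sizes

The evaluation experiments (shared by the acceptance tests and
`scripts/acceptance.py`) use 200 genes × 300 last-exon reads for RTI
recovery (a tenth of genes at ρ = 0, exercising the exact-zero path),
~530 introns at ~400 reads for CoSE and SPI recovery, 1000 null introns at
depth 200 × 3 replicate pairs for FDR calibration, 500 introns (10%
shifted by Δσ = 0.3, depth 500) for power, 1000 random vectors / 50 genes /
1000 fusion rows for the oracle-equivalence checks. These sizes give each
check clear statistical resolution while the whole battery runs in well
under a minute per experiment on one core. The analysis drivers use 60
genes × 300 reads/replicate, approximating study-scale per-gene coverage
(the 500-pooled-read SPI filter presupposes depths of that order; at tens
of reads per gene the conservative max-combination test is correctly
near-silent, which is a statement about depth, not about the test).

## Known limitations

* Overlapping same-strand genes are disambiguated only by the
  greatest-overlap rule; no split assignment is attempted.
* The chimera filter consumes fusion-caller output; it performs no
  read-level fusion detection and considers only intra-chromosomal,
  same-strand, adjacent-gene events.
* The per-pair maximum combination is conservative; with few replicates
  and shallow depth it under-calls real changes (by design — it never
  trades FDR control for power).
* SPI input is a generic splice-site count contract; extracting those
  counts from alignments is upstream of this package.
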