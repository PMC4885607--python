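# Methods

## The screening procedure

`eveorf` identifies protein-coding remnants of endogenous viral elements
(EVEs) by a region-based screen rather than gene prediction: candidate
intervals proposed by repeat detection or homology are scanned
exhaustively for codon runs, and sequence-motif evidence — not coding
statistics — decides retention. The underlying assumptions are:

* EVE ORFs are short, unspliced, single-exon codon runs; a stop-free
  stretch is the unit of interest, with no requirement for a start codon
  (an ATG-less ORF can still be exonized in a spliced transcript). The
  sub-ORF from the first methionine is derived and reported separately as
  the MetORF.
* A minimum length of 80 codons (inclusive: 80 passes) separates genuine
  viral coding remnants from the background of short random stop-free
  runs; in random sequence a ≥ 80-codon run occurs at a per-frame rate of
  roughly (61/64)^80 ≈ 2% per position-window, so the length gate alone is
  not sufficient — motif evidence is the real filter.
* Viral protein motifs (retroviral gag/pro/pol/env domains) survive
  recognizably even in degraded copies; one qualifying motif hit is
  sufficient for retention.

### Six-frame scanning

Within each candidate region, each of the three frame offsets on each
strand is translated (standard genetic code; a codon containing an
undetermined base N translates to X and never creates nor breaks a stop,
since an N must not terminate an ORF — the N count is reported as its own
annotation column). Every **maximal** stop-free run of ≥ `min_aa` codons
is emitted, not only the longest per region: a provirus contributes
separate gag, pro, pol and env ORFs in different frames, and collapsing to
one per region would discard them. A `--longest-only` flag provides the
stricter alternative. Runs are clipped to the candidate region (a run
starts at the first full codon in frame inside the region); flank padding
at region construction compensates for detectors that trim edges.
Reported genomic spans are always ascending, exclude the stop codon, and
are exact codon multiples, so `aa_len = span/3` holds for every record.

Frame labels on records are region-relative (`+1..+3`, `-1..-3` from the
region's 5' end on each strand); deduplication and export use the
genome-stable phase `(start - 1) mod 3` per strand, which is invariant
under region choice because spans are codon multiples.

### Motif evidence

Two routes attach `MotifHit`s to ORFs:

* **Domain tables** (`parse_domtblout`): the per-domain tabular dialect of
  profile-HMM search tools is parsed; a hit qualifies when its independent
  E-value is ≤ the cutoff (default 10, the search tools' default reporting
  bound — stricter values are a parameter, not a default, since the
  procedure's contract is "has at least one reported hit").
* **Built-in consensus matcher** (`scan_consensus`): each profile carries
  a consensus peptide that is slid ungapped along the ORF; the
  best-scoring offset is a hit when identity ≥ 90% of the peptide length.
  This is a deterministic identity scorer, deliberately *not* a
  profile-HMM implementation: it makes the pipeline self-contained and
  exactly testable (implanted motifs are found at their implant offsets),
  while production users supply real domain tables. The shipped profile
  file (`src/eveorf/data/default_profiles.tsv`) contains **invented**
  peptides named after representative retroviral domain families; it is a
  synthetic stand-in, not a curated motif library.

### Frame-aware deduplication

Only overlaps on the same chromosome, strand and genome-stable frame are
redundant. Overlaps across frames or strands are kept: retroviral genomes
genuinely overlap gag/pol in different frames, and opposite-strand
nested elements are distinct loci. Within a conflict set the longest ORF
survives; ties break by smaller start, then '+' before '-', then frame
label — a total order, so the output is deterministic and independent of
input order. The survivor's provenance records the union of contributing
rounds and methods, so a locus found both by a detector and by homology
lists both. A `--collapse any` mode collapses any overlap to one survivor
per locus for users who want strictly disjoint annotations.

### Annotation

Gene category (gag/pro/pol/env/other) comes from the best-scoring motif
hit's profile, using the profile file's category column with a keyword
fallback on the profile name (gag→gag; prot/PR/RVP→pro;
RVT/rve/RNase_H/integrase→pol; env/coat→env). *pol* ORFs are flagged as
LINE-derived when their source region's repeat class begins with "LINE"
or their best viral-database hit is one of the LINE reverse-transcriptase
accessions YP_073558.1 / NP_048132.1 — LINE RT scores well against
retroviral pol profiles and would otherwise inflate the pol tally.
Gene-model overlap is exon-level, strand-blind, with a 1 bp threshold
(the most permissive reading; strand-blind because EVE ORFs are reported
on their coding strand, which need not match the host gene). Best-hit
tables are consumed pre-computed (minimal E-value, ties by bitscore then
first occurrence); running the protein searches is out of scope.

## Coordinates and identifiers

Internally all intervals are 0-based half-open. Exported coordinates —
locus IDs and GTF — are 1-based inclusive, and the minus strand is the
ASCII hyphen. The ID `genomeID.chrom.start.end.strand` is unique per
genome by construction; parsing anchors the last three dot-fields so
chromosome names containing dots are recoverable when the genome ID is
known. The datasheet column order (ID, AA length, method, N letters,
MetORF ID and length, HMM profiles, viral/NR/known-EVE best hits,
RetroTector, Repbase, overlapping genes) is fixed and byte-stable.

## The synthetic-data generator

The simulator emulates the statistical structure the pipeline must
handle, not the evolution of real ERV families:

* background sequence is i.i.d. at a configurable GC fraction (default
  0.41, mammalian-like), which reproduces the realistic density of random
  ≥ 80-codon motif-free runs the filter must reject;
* proviral cassettes are LTR–gag–pro–pol–env–LTR, with literal LTR
  repeats (non-coding, not detected — realism only). Each gene ORF starts
  with Met, is stop-free by construction (reverse translation through
  random synonymous codons), embeds an exact copy of its category's
  consensus peptide (`--mutate-motif k` substitutes k residues to
  exercise the identity threshold), and is bracketed by in-frame stop
  codons so the maximal run the scanner finds coincides exactly with the
  recorded truth span. Default gene lengths are gag 140, pro 90, pol 150,
  env 130 codons — within the 80–159 codon window where a premature stop
  can always split a gene into two sub-threshold fragments;
* disruptions: `premature_stop` replaces an in-frame codon (position
  chosen so both fragments are < 80 codons), `frameshift` deletes one
  mid-ORF nucleotide, `truncation` cuts to 40–79 codons. Spacers with stop
  codons in all six frames bound the runs a frameshift leaves behind;
* the default scenario implants five intact gag–pro–pol–env proviruses
  (20 intact gene ORFs) on mixed strands plus 10 disrupted genes across a
  2 × 100 kb genome, at fixed non-overlapping slots.

What the simulator does **not** model: substitution/indel decay gradients,
family structure among ERV copies, nested insertions, real LTR promoter
content, or genome-scale repeat density. Passing the synthetic recovery
tests therefore demonstrates the pipeline's interval arithmetic, frame
handling and gating are exact — not that the shipped profile peptides
would detect real EVEs; for real genomes users must supply real profile
HMM results or curated consensus peptides.

## Numerical and degenerate-input choices

* Length gate is inclusive (≥ 80 aa).
* Regions shorter than `3·min_aa` nt return an empty result, not an error.
* Touching intervals merge at gap 0; `merge_gap` extends this for
  fragmented detector output. Homology hits are padded ±1000 nt by default
  before rescanning, enough to recover a full-length ORF around a local
  protein hit at desk scale.
* Empty inputs export valid header-only/empty files.
* Frameshift recovery is intentionally not asserted to be zero: a
  frameshifted implant legitimately leaves a shorter in-frame run that may
  still pass both gates; tests verify such calls against a brute-force
  positional oracle instead.

## Test and acceptance problem sizes

The oracle-equivalence checks run the scanner against a positional
brute-force enumerator on 1000 seeded random sequences of 300–6000 nt,
and the deduplicator against an exhaustive pairwise conflict-graph oracle
on 200 seeded sets of up to 500 ORFs; the synthetic end-to-end checks use
the default 2 × 100 kb scenario. These sizes exercise every code path
(all frames, both strands, region edges, N handling, tie-breaks) while
keeping the default test run fast; the generators accept larger sizes
unchanged.

## Known limitations

* The consensus matcher is ungapped identity, blind to indel-containing
  motif copies; real profile-HMM tables are the production route.
* RetroTector chains are ingested only as BED-converted intervals; the
  native output format is not parsed.
* Spliced or frameshift-reconstructed ORFs are out of scope; each ORF is
  a single stop-free run.
* LTRs and other non-coding EVE sequence are not detected or annotated.
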