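# eveorf

Discovery and annotation of endogenous viral element (EVE) open reading
frames in genome sequences.

Roughly a tenth of a mammalian genome descends from ancient germline viral
infections — endogenous retroviruses and other EVEs. Most copies are
decayed, but many still contain protein-coding open reading frames (some,
like the syncytins, were domesticated by their hosts), and these ORFs are
usually absent from standard gene annotation. `eveorf` implements a
four-step screen that turns candidate repeat regions into a non-redundant,
fully annotated set of EVE ORFs:

1. **Candidate regions** — parse the outputs of repeat detectors
   (RepeatMasker `.out`, RetroTector-style interval tables as BED) into
   genomic intervals, pad and merge them.
2. **ORF extraction and motif filtering** — scan every region in all six
   reading frames (three per strand) and keep each maximal stop-free codon
   run of ≥ 80 amino acids; an ORF is retained only if it carries at least
   one viral motif hit (a parsed profile-HMM domain table, or the built-in
   consensus-peptide matcher). An ORF need not begin with ATG; the sub-ORF
   from the first methionine ("MetORF") is recorded separately.
3. **Second-round recovery** — convert protein homology hits (BLAT PSL or
   12-column tabular search output) back into genomic regions and rescan,
   retrieving loci the detectors missed.
4. **Frame-aware deduplication** — remove overlapping ORFs, treating only
   same-strand, same-reading-frame overlaps as redundant (overlapping
   gag/pol ORFs in different frames are genuine) and keeping the longest
   per conflict.

Each surviving ORF is named by its locus,
`genomeID.chrom.start.end.strand` (1-based inclusive, e.g.
`Hsap38.chr1.100259758.100261128.-`), classified as *gag*, *pro*, *pol*,
*env* or *other* from its best motif hit, flagged when a *pol* ORF is
LINE-derived (LINE repeat class, or a best viral hit to the LINE
reverse-transcriptase accessions YP_073558.1 / NP_048132.1), annotated
with best protein-search hits and gene-model overlaps, and exported as an
annotation datasheet (TSV), nucleotide and amino-acid FASTA, and a GTF
usable directly by RNA-seq quantifiers.

A seeded simulator (`eveorf.synthetic_data`) generates test genomes with
implanted intact and degraded LTR–gag–pro–pol–env–LTR cassettes and
ground-truth records, so the whole pipeline is testable end to end with no
downloads.

## Worked example

Simulate a genome with 30 implanted gene ORFs (20 intact, 10 disrupted),
then run the pipeline:

```sh
eve-orf simulate --seed 11 --out-prefix demo/syn
eve-orf run --genome demo/syn.genome.fasta --regions-bed demo/syn.regions.bed \
            --genome-id SynG1 --flank 500 --out-prefix demo/eve
```

The log reports per-stage counts and the command prints a summary:

```
eve-orf INFO: round 1: 8 regions -> 39 ORFs -> 21 with motifs
eve-orf INFO: dedup: 21 -> 21 non-overlapping ORFs
{"counts": {"total": 21, "met": 21, "gag": 5, "pro": 5, "pol": 6, "env": 5,
            "other": 0, "pol_line": 0}, ...}
```

39 six-frame ORFs of ≥ 80 aa were found in the padded candidate regions;
21 carry a viral motif — the 20 intact implants plus one residual
stop-free run left by a frameshifted implant (the extra *pol*). All 20
intact implants are recovered at their exact coordinates and categories;
the premature-stop and truncation loci yield nothing. The first datasheet
rows:

```
ID                      AA_length  Method       N_letters  MetORF_ID               ...  HMM_profile
SynG1.chr1.1136.1555.+  140        retrotector  0          SynG1.chr1.1136.1555.+  ...  Gag_p30
SynG1.chr1.1574.1843.+  90         retrotector  0          SynG1.chr1.1574.1843.+  ...  RVP
```

`demo/eve.gtf` carries one exon and one CDS line per ORF with
`gene_id`/`transcript_id` equal to the locus ID, ready for expression
quantification.

The same stages are available as library functions
(`eveorf.scan_region_orfs`, `eveorf.filter_orfs`,
`eveorf.dedup_frame_aware`, `eveorf.write_outputs`, ...) and as standalone
subcommands (`regions`, `scan`, `run`, `simulate`) connected by plain
BED/FASTA/TSV files.

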