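"""Locus identifiers and export of the annotated EVE ORF set.

The locus identifier is the dot-joined string
``genomeID.chrom.start.end.strand`` with 1-based inclusive coordinates and
ASCII '+'/'-' strands; it is unique per genome by construction. Outputs are
a tab-delimited annotation datasheet, nucleotide and amino-acid FASTA files
headed by the locus ID, and a GTF with one exon and one CDS line per ORF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .annotator import OrfAnnotation
from .orf_scanner import OrfRecord

TSV_COLUMNS = (
    "ID",
    "AA_length",
    "Method",
    "N_letters",
    "MetORF_ID",
    "MetORF_AA_length",
    "HMM_profile",
    "Viral_BLAST",
    "NR_BLAST",
    "EVE_BLAST",
    "RetroTector",
    "Repbase",
    "Overlapping",
)

_ID_RE = re.compile(r"^(?P<rest>.+)\.(?P<start>\d+)\.(?P<end>\d+)\.(?P<strand>[+-])$")


class IdError(ValueError):
    pass


def make_geve_id(genome_id: str, chrom: str, start: int, end: int, strand: str) -> str:
    """Mint a locus ID: ``genomeID.chrom.start.end.strand`` (1-based inclusive)."""
    if strand not in "+-":
        raise IdError(f"strand must be '+' or '-', got {strand!r}")
    if not (0 < start < end):
        raise IdError(f"require 0 < start < end, got {start}..{end}")
    return f"{genome_id}.{chrom}.{start}.{end}.{strand}"


def parse_geve_id(
    locus_id: str, *, genome_id: str | None = None
) -> tuple[str, str, int, int, str]:
    """Invert :func:`make_geve_id`.

    The last three dot fields are anchored as start, end, strand, so
    chromosome names containing dots are recoverable when ``genome_id`` is
    supplied; otherwise the genome ID is taken as the first dot field.
    """
    m = _ID_RE.match(locus_id)
    if m is None:
        raise IdError(f"unparseable locus ID {locus_id!r}")
    start, end, strand = int(m["start"]), int(m["end"]), m["strand"]
    rest = m["rest"]
    if genome_id is not None:
        prefix = genome_id + "."
        if not rest.startswith(prefix) or len(rest) <= len(prefix):
            raise IdError(f"ID {locus_id!r} does not carry genome ID {genome_id!r}")
        gid, chrom = genome_id, rest[len(prefix):]
    else:
        if "." not in rest:
            raise IdError(f"ID {locus_id!r} has too few fields")
        gid, chrom = rest.split(".", 1)
    if start >= end:
        raise IdError(f"ID {locus_id!r}: start must be < end")
    return gid, chrom, start, end, strand


def orf_id(orf: OrfRecord, genome_id: str) -> str:
    return make_geve_id(genome_id, orf.chrom, orf.start, orf.end, orf.strand)


def met_orf_id(orf: OrfRecord, genome_id: str) -> str:
    """Locus ID of the sub-ORF from the first ATG; '' when there is none."""
    span = orf.met_span
    if span is None:
        return ""
    return make_geve_id(genome_id, orf.chrom, span[0], span[1], orf.strand)


@dataclass(frozen=True)
class AnnotationRow:
    """One datasheet line; field order mirrors :data:`TSV_COLUMNS`."""

    id: str
    aa_length: int
    method: str
    n_letters: int
    met_orf_id: str
    met_aa_length: str
    hmm_profile: str
    viral_blast: str
    nr_blast: str
    eve_blast: str
    retrotector: str
    repbase: str
    overlapping: str

    def as_fields(self) -> tuple[str, ...]:
        return (
            self.id, str(self.aa_length), self.method, str(self.n_letters),
            self.met_orf_id, self.met_aa_length, self.hmm_profile,
            self.viral_blast, self.nr_blast, self.eve_blast,
            self.retrotector, self.repbase, self.overlapping,
        )


def build_row(orf: OrfRecord, annotation: OrfAnnotation, genome_id: str) -> AnnotationRow:
    best = annotation.best_hits
    return AnnotationRow(
        id=orf_id(orf, genome_id),
        aa_length=orf.aa_len,
        method=";".join(orf.methods) if orf.methods else "",
        n_letters=orf.n_count,
        met_orf_id=met_orf_id(orf, genome_id),
        met_aa_length="" if orf.met_aa_len is None else str(orf.met_aa_len),
        hmm_profile=";".join(sorted({h.profile_name for h in orf.motif_hits})),
        viral_blast=best["viral"].description if "viral" in best else "",
        nr_blast=best["nr"].description if "nr" in best else "",
        eve_blast=best["known_eve"].description if "known_eve" in best else "",
        retrotector=annotation.retrotector,
        repbase=annotation.repbase,
        overlapping=";".join(annotation.overlapping_genes),
    )


def read_orf_fasta(
    path: str | Path, genome, genome_id: str, *, round: int = 1
) -> list[OrfRecord]:
    """Reconstruct ORF records from an amino-acid FASTA headed by locus IDs.

    The locus ID supplies coordinates and strand; the nucleotide sequence is
    re-fetched from the genome and must translate to the stored amino acids
    (mismatches raise). This is what lets every pipeline stage run
    standalone on plain files.
    """
    from Bio import SeqIO

    from .genome_io import revcomp, translate

    frame_plus = ("+1", "+2", "+3")
    frame_minus = ("-1", "-2", "-3")
    orfs: list[OrfRecord] = []
    for record in SeqIO.parse(str(path), "fasta"):
        gid, chrom, start, end, strand = parse_geve_id(record.id, genome_id=genome_id)
        nt = genome.fetch(chrom, start - 1, end)
        if strand == "-":
            nt = revcomp(nt)
        aa = str(record.seq)
        if translate(nt) != aa:
            raise IdError(
                f"{path}: sequence of {record.id} does not match the genome"
            )
        phase = (start - 1) % 3
        frame = frame_plus[phase] if strand == "+" else frame_minus[phase]
        orfs.append(
            OrfRecord(chrom=chrom, start=start, end=end, strand=strand,
                      frame=frame, nt_seq=nt, aa_seq=aa, round=round)
        )
    return orfs


def _sorted_orfs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    return sorted(orfs, key=lambda o: (o.chrom, o.start, o.end, o.strand))


def write_outputs(
    orfs: list[OrfRecord],
    annotations: dict[tuple, OrfAnnotation],
    genome_id: str,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write the datasheet TSV, nt/aa FASTA and GTF for an annotated set.

    Files are ``<prefix>.tsv``, ``<prefix>.nt.fasta``, ``<prefix>.aa.fasta``
    and ``<prefix>.gtf``, sorted by (chrom, start); empty input yields valid
    header-only/empty-bodied files. Returns the path of each output.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": prefix.with_suffix(".tsv"),
        "nt_fasta": Path(str(prefix) + ".nt.fasta"),
        "aa_fasta": Path(str(prefix) + ".aa.fasta"),
        "gtf": prefix.with_suffix(".gtf"),
    }
    ordered = _sorted_orfs(orfs)

    with open(paths["tsv"], "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for orf in ordered:
            ann = annotations.get(orf.key(), OrfAnnotation())
            fh.write("\t".join(build_row(orf, ann, genome_id).as_fields()) + "\n")

    with open(paths["nt_fasta"], "w") as nt, open(paths["aa_fasta"], "w") as aa:
        for orf in ordered:
            lid = orf_id(orf, genome_id)
            nt.write(f">{lid}\n{orf.nt_seq}\n")
            aa.write(f">{lid}\n{orf.aa_seq}\n")

    with open(paths["gtf"], "w") as fh:
        for orf in ordered:
            lid = orf_id(orf, genome_id)
            attrs = f'gene_id "{lid}"; transcript_id "{lid}";'
            for feature in ("exon", "CDS"):
                fh.write(
                    f"{orf.chrom}\tgEVE\t{feature}\t{orf.start}\t{orf.end}\t.\t"
                    f"{orf.strand}\t0\t{attrs}\n"
                )
    return paths
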