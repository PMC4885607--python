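"""Genome sequence I/O and nucleotide/amino-acid primitives.

Sequences are plain uppercase strings over the alphabet {A, C, G, T, N}.
Internal coordinates throughout the package are 0-based half-open;
exported coordinates (locus IDs, GTF) are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

VALID_NT = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1), nuclear mammalian genomes.
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class GenomeIOError(ValueError):
    """Raised for malformed genome input."""


def _validate_nt(seq: str) -> None:
    bad = set(seq) - VALID_NT
    if bad:
        raise GenomeIOError(
            f"invalid nucleotide character(s): {sorted(bad)!r} (expected A/C/G/T/N)"
        )


@dataclass
class GenomeSequence:
    """A named genome: ordered mapping of chromosome name -> nucleotide string.

    Parameters
    ----------
    genome_id:
        Short label used as the prefix of locus identifiers (e.g. ``Hsap38``).
    chromosomes:
        Ordered mapping chromosome name -> uppercase sequence over {A,C,G,T,N}.
    """

    genome_id: str
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise GenomeIOError("genome_id must be non-empty")
        for name, seq in self.chromosomes.items():
            if not name:
                raise GenomeIOError("chromosome names must be non-empty")
            if not seq:
                raise GenomeIOError(f"chromosome {name!r} has empty sequence")
            _validate_nt(seq)

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the 0-based half-open slice ``[start, end)`` of ``chrom``."""
        seq = self.chromosomes[chrom]
        if not (0 <= start < end <= len(seq)):
            raise GenomeIOError(
                f"span [{start},{end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]


def read_fasta(path: str | Path, genome_id: str, *, normalize_n: bool = False) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`.

    The chromosome name is the header token before the first whitespace.
    Sequences are uppercased. Characters outside {A,C,G,T,N} are rejected,
    or normalized to N when ``normalize_n`` is true.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chromosomes:
            raise GenomeIOError(f"duplicate FASTA header: {name!r}")
        seq = str(record.seq).upper()
        if normalize_n:
            seq = "".join(c if c in VALID_NT else "N" for c in seq)
        chromosomes[name] = seq
    if not chromosomes:
        raise GenomeIOError(f"no FASTA records in {path}")
    return GenomeSequence(genome_id=genome_id, chromosomes=chromosomes)


def write_fasta(genome: GenomeSequence, path: str | Path, *, width: int = 60) -> None:
    """Write a genome back to FASTA (fixed line width, byte-stable)."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    _validate_nt(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate with the standard genetic code.

    Stop codons render ``*``; any codon containing N renders ``X`` (an
    undetermined base never creates or breaks a stop); a trailing partial
    codon is ignored, so the output length is ``len(seq) // 3``.
    """
    _validate_nt(seq)
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aas.append("X" if "N" in codon else _CODON_TO_AA[codon])
    return "".join(aas)
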