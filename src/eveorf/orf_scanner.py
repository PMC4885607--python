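"""Six-frame ORF extraction within candidate regions.

For each candidate region every maximal stop-free codon run fully inside
the region, in all three frames on each strand, is reported when it encodes
at least ``min_aa`` amino acids (default 80). An ORF is not required to
begin with ATG; the first-methionine sub-ORF ("MetORF") is derived
separately. ORFs are clipped to the candidate region: codons straddling a
region edge are discarded, so a run starts at the first full codon in
frame — flank padding at region construction compensates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .candidate_regions import CandidateRegion
from .genome_io import GenomeSequence, revcomp, translate

FRAME_LABELS_PLUS = ("+1", "+2", "+3")
FRAME_LABELS_MINUS = ("-1", "-2", "-3")

DEFAULT_MIN_AA = 80


@dataclass
class OrfRecord:
    """One EVE ORF.

    ``start``/``end`` are the 1-based inclusive genomic span of the coding
    stretch (stop codon excluded), ascending regardless of strand. ``frame``
    is the region-relative label in {+1,+2,+3,-1,-2,-3}; the genome-stable
    frame used for deduplication is :attr:`genome_frame`. ``nt_seq`` is the
    coding-strand sequence (reverse-complemented for '-').
    """

    chrom: str
    start: int
    end: int
    strand: str
    frame: str
    nt_seq: str
    aa_seq: str
    round: int = 1
    methods: tuple[str, ...] = ()
    repeat_class: str = ""
    motif_hits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span <= 0 or span % 3 != 0:
            raise ValueError(f"ORF span {self.start}..{self.end} is not a codon multiple")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must be stop-free")
        if len(self.aa_seq) * 3 != span or len(self.nt_seq) != span:
            raise ValueError("sequence lengths inconsistent with span")

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    @property
    def n_count(self) -> int:
        return self.nt_seq.count("N")

    @property
    def met_offset(self) -> Optional[int]:
        idx = self.aa_seq.find("M")
        return idx if idx >= 0 else None

    @property
    def met_aa_len(self) -> Optional[int]:
        off = self.met_offset
        return None if off is None else self.aa_len - off

    @property
    def genome_frame(self) -> int:
        """Genome-stable frame in 0..2: codon-boundary phase on this strand.

        Two same-strand ORFs overlap in the same reading frame exactly when
        their genome_frame values agree (spans are codon multiples, so the
        5'-most genomic base mod 3 is phase-invariant along the ORF).
        """
        return (self.start - 1) % 3

    @property
    def met_span(self) -> Optional[tuple[int, int]]:
        """1-based inclusive genomic span of the sub-ORF from the first ATG."""
        off = self.met_offset
        if off is None:
            return None
        if self.strand == "+":
            return (self.start + 3 * off, self.end)
        return (self.start, self.end - 3 * off)

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand, self.frame)


def _runs_at_least(aa: str, min_aa: int):
    """Yield (codon_offset, aa_segment) for maximal stop-free runs >= min_aa."""
    pos = 0
    for segment in aa.split("*"):
        if len(segment) >= min_aa:
            yield pos, segment
        pos += len(segment) + 1


def scan_region_orfs(
    region: CandidateRegion,
    genome: GenomeSequence,
    min_aa: int = DEFAULT_MIN_AA,
    *,
    longest_only: bool = False,
) -> list[OrfRecord]:
    """Extract all qualifying ORFs from the six frames of a candidate region.

    Returns every maximal stop-free codon run of >= ``min_aa`` amino acids
    fully inside the region (or only the single longest across all frames
    when ``longest_only``). A region shorter than ``3 * min_aa`` nt yields an
    empty list. Output is sorted by (start, end, strand, frame).
    """
    chrom_len = len(genome.chromosomes[region.chrom])
    if not (0 <= region.start < region.end <= chrom_len):
        raise ValueError(f"region out of genome bounds: {region}")
    sub = genome.fetch(region.chrom, region.start, region.end)
    if len(sub) < 3 * min_aa:
        return []

    methods = tuple(sorted(region.meta.get("sources", region.source).split(";")))
    repeat_class = region.meta.get("repeat_class", "")
    orfs: list[OrfRecord] = []

    for off, label in enumerate(FRAME_LABELS_PLUS):
        aa = translate(sub[off:])
        for codon_off, segment in _runs_at_least(aa, min_aa):
            g0 = region.start + off + 3 * codon_off  # 0-based
            length = 3 * len(segment)
            orfs.append(
                OrfRecord(
                    chrom=region.chrom, start=g0 + 1, end=g0 + length,
                    strand="+", frame=label,
                    nt_seq=sub[off + 3 * codon_off : off + 3 * codon_off + length],
                    aa_seq=segment, round=region.round,
                    methods=methods, repeat_class=repeat_class,
                )
            )

    rc = revcomp(sub)
    for off, label in enumerate(FRAME_LABELS_MINUS):
        aa = translate(rc[off:])
        for codon_off, segment in _runs_at_least(aa, min_aa):
            i = off + 3 * codon_off  # offset on the reverse-complemented region
            length = 3 * len(segment)
            g_end = region.end - i  # 0-based exclusive end on plus strand
            g0 = g_end - length
            orfs.append(
                OrfRecord(
                    chrom=region.chrom, start=g0 + 1, end=g_end,
                    strand="-", frame=label,
                    nt_seq=rc[i : i + length],
                    aa_seq=segment, round=region.round,
                    methods=methods, repeat_class=repeat_class,
                )
            )

    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    if longest_only and orfs:
        orfs = [max(orfs, key=lambda o: (o.aa_len, -o.start, o.strand == "+", o.frame))]
    return orfs


def scan_regions(
    regions: list[CandidateRegion],
    genome: GenomeSequence,
    min_aa: int = DEFAULT_MIN_AA,
    *,
    longest_only: bool = False,
) -> list[OrfRecord]:
    """Scan a collection of regions; concatenated, region-ordered results."""
    out: list[OrfRecord] = []
    for region in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        out.extend(scan_region_orfs(region, genome, min_aa, longest_only=longest_only))
    return out


def derive_met_orf(orf: OrfRecord) -> OrfRecord:
    """Return the ORF unchanged; Met fields are derived properties.

    Kept as an explicit operation for pipeline symmetry: it validates that
    the Met sub-ORF span is a codon multiple inside the parent span.
    """
    span = orf.met_span
    if span is not None:
        s, e = span
        assert (e - s + 1) % 3 == 0 and orf.start <= s <= e <= orf.end
    return orf


def count_ns(orf: OrfRecord) -> int:
    """Number of undetermined nucleotides (N) in the ORF's coding sequence."""
    return orf.n_count
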