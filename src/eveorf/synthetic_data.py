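"""Seeded synthetic genomes with implanted proviral ORF cassettes.

The generator emulates, at desk scale, what the discovery pipeline faces in
a real genome: random intergenic background at mammalian-like GC content,
proviral cassettes laid out as LTR–gag–pro–pol–env–LTR whose gene ORFs are
stop-free, >= 80 codons, and carry a recognizable consensus motif peptide,
plus degraded copies (premature stops, frameshifts, truncations). Every
implant is recorded as a ground-truth interval so end-to-end recovery can
be checked exactly.

Each designed gene is bracketed by in-frame stop codons, so the maximal
stop-free run the scanner reports coincides exactly with the recorded
truth span. Inter-element spacers contain stop codons in all six frames,
which bounds runs created by frameshift disruptions inside the cassette.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .candidate_regions import CandidateRegion, parse_bed
from .genome_io import GenomeSequence, revcomp, _STANDARD
from .motif_filter import Profile, ProfileSet, default_profiles

DISRUPTIONS = ("none", "premature_stop", "frameshift", "truncation")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# stop codons in all three frames, on both strands (the sequence is its own
# reverse complement)
STOP_SPACER = "TTAATTAATTAA"

# default gene lengths in codons; all in [80, 159] so a premature stop can
# always split a gene into two sub-80-codon fragments
DEFAULT_GENE_CODONS = {"gag": 140, "pro": 90, "pol": 150, "env": 130, "other": 110}

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()


@dataclass(frozen=True)
class ImplantTruth:
    """Ground truth for one implanted gene ORF (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_category: str
    intact: bool
    disruption: str
    motif_profile: str

    def __post_init__(self) -> None:
        if self.disruption not in DISRUPTIONS:
            raise ValueError(f"unknown disruption {self.disruption!r}")
        if self.intact:
            span = self.end - self.start + 1
            assert span % 3 == 0 and span >= 240, "intact implants are >=80 codons"


@dataclass
class Scenario:
    """A synthetic genome plus its implant truths and detector-like regions."""

    genome: GenomeSequence
    truths: list[ImplantTruth]
    regions: list[CandidateRegion]


def generate_genome(
    n_chroms: int = 2,
    chrom_len: int = 100_000,
    gc: float = 0.41,
    seed: int = 0,
    genome_id: str = "SynG1",
) -> GenomeSequence:
    """Random background genome at the given GC fraction (seeded).

    The 0.41 default approximates mammalian genome-wide GC content.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10000")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=chrom_len, p=probs))
        for i in range(n_chroms)
    }
    return GenomeSequence(genome_id=genome_id, chromosomes=chroms)


def _profile_for(category: str, profiles: ProfileSet, rng: np.random.Generator) -> Profile:
    candidates = [p for p in profiles if p.category == category and p.consensus]
    if not candidates:
        raise ValueError(f"no consensus-bearing profile for category {category!r}")
    return candidates[int(rng.integers(len(candidates)))]


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        _SYNONYMS[aa][int(rng.integers(len(_SYNONYMS[aa])))] for aa in peptide
    )


def build_gene(
    category: str,
    rng: np.random.Generator,
    profiles: ProfileSet,
    n_codons: int | None = None,
    mutate_motif: int = 0,
) -> tuple[str, str]:
    """Design one stop-free gene ORF carrying its category's motif peptide.

    Returns (nucleotide sequence of length 3*n_codons, profile name). The
    peptide starts with Met, embeds an exact copy of the profile's consensus
    (or a copy with ``mutate_motif`` substituted residues), and is otherwise
    random. Reverse translation picks random synonymous codons, so the ORF
    is stop-free in its own frame by construction.
    """
    if n_codons is None:
        n_codons = DEFAULT_GENE_CODONS.get(category, 110)
    profile = _profile_for(category, profiles, rng)
    motif = list(profile.consensus)
    if mutate_motif:
        positions = rng.choice(len(motif), size=min(mutate_motif, len(motif)), replace=False)
        for pos in positions:
            choices = [a for a in AA_ALPHABET if a != motif[pos]]
            motif[pos] = choices[int(rng.integers(len(choices)))]
    motif = "".join(motif)
    if n_codons < len(motif) + 2:
        raise ValueError("gene too short for its motif")
    body_len = n_codons - 1  # leading Met
    offset = int(rng.integers(1, body_len - len(motif) + 1))
    random_aa = "".join(
        AA_ALPHABET[int(i)] for i in rng.integers(len(AA_ALPHABET), size=body_len)
    )
    peptide = "M" + random_aa[: offset - 1] + motif + random_aa[offset - 1 + len(motif):]
    assert len(peptide) == n_codons
    return _reverse_translate(peptide, rng), profile.name


def _disrupt(
    gene_nt: str, disruption: str, rng: np.random.Generator
) -> tuple[str, bool]:
    """Apply a disruption to a designed gene; returns (nt, intact)."""
    n_codons = len(gene_nt) // 3
    if disruption == "none":
        return gene_nt, True
    if disruption == "premature_stop":
        lo, hi = max(1, n_codons - 80), min(79, n_codons - 2)
        pos = int(rng.integers(lo, hi + 1))  # codon index; both fragments < 80
        return gene_nt[: 3 * pos] + "TAA" + gene_nt[3 * pos + 3 :], False
    if disruption == "frameshift":
        cut = 3 * (n_codons // 2) + 1
        return gene_nt[:cut] + gene_nt[cut + 1 :], False
    if disruption == "truncation":
        keep = int(rng.integers(40, 80))  # < 80 codons survive
        return gene_nt[: 3 * keep], False
    raise ValueError(f"unknown disruption {disruption!r}")


def build_cassette(
    genes: list[str],
    rng: np.random.Generator,
    profiles: ProfileSet,
    *,
    disruptions: dict[str, str] | None = None,
    ltr_len: int = 120,
    mutate_motif: int = 0,
) -> tuple[str, list[tuple[int, int, str, bool, str, str]]]:
    """Assemble an LTR–genes–LTR cassette on its coding strand.

    Returns the cassette sequence and per-gene layout tuples
    (start_offset, end_offset 0-based half-open, category, intact,
    disruption, profile name). Each gene is bracketed by in-frame TAA stop
    codons so its maximal stop-free run equals its recorded span.
    """
    disruptions = disruptions or {}
    ltr = "".join("ACGT"[int(i)] for i in rng.integers(4, size=ltr_len))
    parts = [ltr, STOP_SPACER]
    layout = []
    for gene in genes:
        nt, profile_name = build_gene(gene, rng, profiles, mutate_motif=mutate_motif)
        disruption = disruptions.get(gene, "none")
        nt, intact = _disrupt(nt, disruption, rng)
        parts.append("TAA")
        start = sum(len(p) for p in parts)
        parts.append(nt)
        layout.append((start, start + len(nt), gene, intact, disruption, profile_name))
        parts.append("TAA")
        parts.append(STOP_SPACER)
    parts.append(ltr)
    return "".join(parts), layout


def implant_eve(
    genome: GenomeSequence,
    genes: list[str],
    strand: str,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    profiles: ProfileSet | None = None,
    disruptions: dict[str, str] | None = None,
    chrom: str | None = None,
    position: int | None = None,
    mutate_motif: int = 0,
) -> tuple[GenomeSequence, list[ImplantTruth], CandidateRegion]:
    """Write one proviral cassette into the genome and record ground truth.

    The cassette replaces background sequence (chromosome length is
    preserved). Returns the modified genome, one truth record per gene with
    final genomic coordinates, and the cassette span as a detector-style
    candidate region.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = default_profiles()
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    cassette, layout = build_cassette(
        genes, rng, profiles, disruptions=disruptions, mutate_motif=mutate_motif
    )
    if chrom is None:
        chrom = list(genome.chromosomes)[int(rng.integers(len(genome.chromosomes)))]
    chrom_seq = genome.chromosomes[chrom]
    L = len(cassette)
    if L > len(chrom_seq):
        raise ValueError("cassette longer than chromosome")
    if position is None:
        position = int(rng.integers(0, len(chrom_seq) - L + 1))
    if position + L > len(chrom_seq):
        raise ValueError("cassette does not fit at requested position")

    inserted = cassette if strand == "+" else revcomp(cassette)
    new_seq = chrom_seq[:position] + inserted + chrom_seq[position + L :]
    chroms = dict(genome.chromosomes)
    chroms[chrom] = new_seq
    new_genome = GenomeSequence(genome_id=genome.genome_id, chromosomes=chroms)

    truths = []
    for a, b, gene, intact, disruption, profile_name in layout:
        if strand == "+":
            g0, g1 = position + a, position + b
        else:
            g0, g1 = position + L - b, position + L - a
        truths.append(
            ImplantTruth(
                chrom=chrom, start=g0 + 1, end=g1, strand=strand,
                gene_category=gene, intact=intact, disruption=disruption,
                motif_profile=profile_name,
            )
        )
    region = CandidateRegion(
        chrom=chrom, start=position, end=position + L,
        source="retrotector", round=1, metadata=(("sources", "retrotector"),),
    )
    return new_genome, truths, region


def default_scenario(seed: int = 0, *, profiles: ProfileSet | None = None) -> Scenario:
    """The standard test scenario: 20 intact gene implants (five intact
    gag–pro–pol–env proviruses on mixed strands) plus 10 disrupted gene
    implants (premature stops, frameshifts, truncations) in a 2 x 100 kb
    background genome."""
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    genome = generate_genome(n_chroms=2, chrom_len=100_000, gc=0.41,
                             seed=int(rng.integers(2**31)))
    provirus = ["gag", "pro", "pol", "env"]
    plans: list[tuple[str, dict[str, str]]] = [
        ("+", {}), ("-", {}), ("+", {}), ("-", {}), ("+", {}),
        ("-", {"gag": "premature_stop", "pro": "truncation",
               "pol": "frameshift", "env": "premature_stop"}),
        ("+", {"gag": "truncation", "pro": "premature_stop",
               "pol": "frameshift", "env": "truncation"}),
        ("-", {"gag": "frameshift", "pro": "premature_stop"}),
    ]
    # spread cassettes over fixed non-overlapping slots
    n_slots_per_chrom = 4
    slot_len = 100_000 // n_slots_per_chrom
    slots = [
        (f"chr{c + 1}", s * slot_len + 1000)
        for c in range(2) for s in range(n_slots_per_chrom)
    ]
    truths: list[ImplantTruth] = []
    regions: list[CandidateRegion] = []
    for (strand, disruptions), (chrom, position) in zip(plans, slots):
        genes = provirus if len(disruptions) != 2 else ["gag", "pro"]
        genome, t, region = implant_eve(
            genome, genes, strand, rng=rng, profiles=profiles,
            disruptions=disruptions, chrom=chrom, position=position,
        )
        truths.extend(t)
        regions.append(region)
    return Scenario(genome=genome, truths=truths, regions=regions)


def write_truth(truths: list[ImplantTruth], path: str | Path) -> None:
    """Write truths as BED6 plus category/intact/disruption/profile columns."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.gene_category}\t0\t{t.strand}\t"
                f"{t.gene_category}\t{int(t.intact)}\t{t.disruption}\t{t.motif_profile}\n"
            )


def read_truth(path: str | Path) -> list[ImplantTruth]:
    """Inverse of :func:`write_truth` (round-trips through the BED parser)."""
    truths = []
    for region in parse_bed(path):
        extra = region.meta.get("extra", "").split("\t")
        if len(extra) != 4:
            raise ValueError(f"{path}: not a truth BED (need 10 columns)")
        category, intact, disruption, profile = extra
        truths.append(
            ImplantTruth(
                chrom=region.chrom, start=region.start + 1, end=region.end,
                strand=region.meta.get("strand", "+"),
                gene_category=category, intact=intact == "1",
                disruption=disruption, motif_profile=profile,
            )
        )
    return truths
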