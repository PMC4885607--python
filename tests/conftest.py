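"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written position-wise (per-base /
per-position enumeration) so they share no code path with the package's
split-and-index implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from eveorf.genome_io import GenomeSequence, revcomp
from eveorf.motif_filter import default_profiles
from eveorf.orf_scanner import OrfRecord
from eveorf.synthetic_data import default_scenario

_STOPS = {"TAA", "TAG", "TGA"}


def _is_stop(codon: str) -> bool:
    # an undetermined base never makes a stop
    return codon in _STOPS


def oracle_scan(chrom: str, region_start: int, region_end: int,
                chrom_seq: str, min_aa: int = 80):
    """Brute-force six-frame ORF enumeration inside a region.

    For every strand and every in-region position, a position starts a
    maximal stop-free run iff its codon is not a stop and the preceding
    in-frame codon is outside the region or a stop; the run is extended
    codon by codon to the next stop or the region edge. Returns a set of
    (start 1-based, end 1-based, strand, aa_len) tuples.
    """
    out = set()
    sub = chrom_seq[region_start:region_end]
    for strand in "+-":
        seq = sub if strand == "+" else revcomp(sub)
        n = len(seq)
        for s in range(0, n - 2):
            if _is_stop(seq[s : s + 3]):
                continue
            if s - 3 >= 0 and not _is_stop(seq[s - 3 : s]):
                continue  # not the start of a maximal run
            e = s
            while e + 3 <= n and not _is_stop(seq[e : e + 3]):
                e += 3
            aa_len = (e - s) // 3
            if aa_len < min_aa:
                continue
            if strand == "+":
                g0 = region_start + s
                out.add((g0 + 1, g0 + 3 * aa_len, "+", aa_len))
            else:
                g_end = region_end - s
                out.add((g_end - 3 * aa_len + 1, g_end, "-", aa_len))
    return out


def oracle_dedup(orfs: list[OrfRecord]) -> set[tuple]:
    """Exhaustive conflict-graph deduplication.

    Builds every pairwise conflict (same chrom, strand and genome-stable
    frame with overlapping 1-based spans) and keeps records greedily in
    priority order (longest first; ties by smaller start, '+' before '-',
    frame label). Returns the surviving span keys.
    """
    order = sorted(
        range(len(orfs)),
        key=lambda i: (-orfs[i].aa_len, orfs[i].start,
                       0 if orfs[i].strand == "+" else 1, orfs[i].frame),
    )

    def conflicts(a: OrfRecord, b: OrfRecord) -> bool:
        return (
            a.chrom == b.chrom and a.strand == b.strand
            and a.genome_frame == b.genome_frame
            and a.start <= b.end and b.start <= a.end
        )

    kept: list[int] = []
    for i in order:
        if all(not conflicts(orfs[i], orfs[j]) for j in kept):
            kept.append(i)
    return {orfs[i].key() for i in kept}


def make_orf(chrom="chr1", start=1, aa_len=80, strand="+", frame=None,
             round=1, methods=("bed",)) -> OrfRecord:
    """Construct a synthetic poly-Ala ORF record for dedup/annotation tests."""
    if frame is None:
        frame = ("+1", "+2", "+3")[(start - 1) % 3] if strand == "+" else "-1"
    return OrfRecord(
        chrom=chrom, start=start, end=start + 3 * aa_len - 1,
        strand=strand, frame=frame,
        nt_seq="GCT" * aa_len, aa_seq="A" * aa_len,
        round=round, methods=tuple(methods),
    )


def random_orf_set(rng: np.random.Generator, n: int) -> list[OrfRecord]:
    """A random, possibly heavily overlapping set of ORFs on two chromosomes."""
    orfs = []
    for _ in range(n):
        aa_len = int(rng.integers(80, 400))
        start = int(rng.integers(1, 5000))
        strand = "+" if rng.integers(2) == 0 else "-"
        chrom = f"chr{int(rng.integers(1, 3))}"
        orfs.append(make_orf(chrom=chrom, start=start, aa_len=aa_len, strand=strand))
    return orfs


def random_genome(rng: np.random.Generator, length: int,
                  genome_id: str = "T1") -> GenomeSequence:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeSequence(genome_id=genome_id, chromosomes={"chr1": seq})


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic scenario (seeded, shared across tests)."""
    return default_scenario(7)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()
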