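"""Frame-aware removal of overlapping ORFs (final non-overlapping set).

Only overlaps on the same chromosome, same strand, and same genome-stable
reading frame are redundant: a gag ORF overlapping a pol ORF in another
frame, or ORFs facing each other on opposite strands, are genuine distinct
coding stretches and are all kept. Within each conflict set the longest
ORF survives; ties break by smaller start, then '+' before '-', then
lexicographic frame label, giving a total order and a deterministic,
input-order-invariant result.
"""

from __future__ import annotations

from dataclasses import replace

from intervaltree import IntervalTree

from .orf_scanner import OrfRecord


def _priority(orf: OrfRecord) -> tuple:
    # higher aa_len first; then smaller start, '+' before '-', frame label
    return (-orf.aa_len, orf.start, 0 if orf.strand == "+" else 1, orf.frame)


def dedup_frame_aware(
    orfs: list[OrfRecord],
    *,
    collapse: str = "frame",
) -> list[OrfRecord]:
    """Remove redundant overlapping ORFs.

    ``collapse='frame'`` (default) treats only same-(chrom, strand,
    genome-stable frame) overlaps as redundant; ``collapse='any'`` collapses
    any genomic overlap on a chromosome to one survivor per locus. Exact
    duplicate records always collapse to one, whose provenance records the
    union of contributing rounds and methods. Output is a subset of the
    input sorted by (chrom, start, end, strand).
    """
    if collapse not in ("frame", "any"):
        raise ValueError("collapse must be 'frame' or 'any'")

    def group_key(orf: OrfRecord):
        if collapse == "frame":
            return (orf.chrom, orf.strand, orf.genome_frame)
        return (orf.chrom,)

    groups: dict[tuple, list[OrfRecord]] = {}
    for orf in orfs:
        groups.setdefault(group_key(orf), []).append(orf)

    survivors: list[OrfRecord] = []
    for members in groups.values():
        members = sorted(members, key=_priority)
        tree = IntervalTree()
        kept: list[tuple[OrfRecord, set[int], set[str]]] = []
        for orf in members:
            overlapping = tree.overlap(orf.start - 1, orf.end)  # 0-based half-open
            if overlapping:
                # redundant: fold provenance into the (longer-or-equal) survivor
                for iv in overlapping:
                    idx = iv.data
                    kept[idx][1].add(orf.round)
                    kept[idx][2].update(orf.methods)
                continue
            tree.addi(orf.start - 1, orf.end, len(kept))
            kept.append((orf, {orf.round}, set(orf.methods)))
        for orf, rounds, methods in kept:
            survivors.append(
                replace(
                    orf,
                    round=min(rounds),
                    methods=tuple(sorted(methods)),
                    motif_hits=list(orf.motif_hits),
                )
            )
    survivors.sort(key=lambda o: (o.chrom, o.start, o.end, o.strand, o.frame))
    return survivors
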