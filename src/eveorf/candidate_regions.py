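"""Candidate-region ingestion: detector and homology outputs -> scan-ready intervals.

First-round candidates come from repeat detectors (RepeatMasker ``.out``
files, RetroTector-style interval tables carried as BED); second-round
candidates come from protein homology hits (BLAT PSL or 12-column tabular
search output) mapped back onto the genome. All intervals are held 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

SOURCES = ("repeatmasker", "retrotector", "bed", "homology")


class RegionParseError(ValueError):
    """Raised for malformed region input files."""


@dataclass(frozen=True)
class CandidateRegion:
    """A genomic interval with provenance.

    ``start``/``end`` are 0-based half-open. ``round`` is 1 for first-round
    detector output and 2 for homology-recovered regions. ``metadata``
    carries pass-through fields such as the RepeatMasker repeat class/family.
    """

    chrom: str
    start: int
    end: int
    source: str
    round: int = 1
    metadata: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise RegionParseError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.source not in SOURCES:
            raise RegionParseError(f"unknown source {self.source!r}")
        if self.round not in (1, 2):
            raise RegionParseError(f"round must be 1 or 2, got {self.round}")

    @property
    def meta(self) -> dict[str, str]:
        return dict(self.metadata)


def parse_repeatmasker_out(
    path: str | Path, *, require_header: bool = True
) -> list[CandidateRegion]:
    """Parse a RepeatMasker ``.out`` file into candidate regions.

    The standard layout has 3 header lines followed by whitespace-delimited
    annotation lines whose query begin/end are 1-based inclusive. The repeat
    class/family column is retained as metadata (feeds the LINE-derived pol
    flag and Repbase annotation downstream).
    """
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    if require_header:
        # 2 column-header lines + 1 blank separator line
        if len(lines) >= 3 and ("score" in lines[0].lower() or "SW" in lines[0]):
            body_start = 3
        else:
            raise RegionParseError(
                f"{path}: missing RepeatMasker header (pass require_header=False "
                "for headerless files)"
            )
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise RegionParseError(
                f"{path}:{lineno}: expected >=11 RepeatMasker columns, got {len(fields)}"
            )
        try:
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise RegionParseError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
        repeat_name = fields[9]
        repeat_class = fields[10]
        regions.append(
            CandidateRegion(
                chrom=chrom,
                start=begin - 1,
                end=end,
                source="repeatmasker",
                round=1,
                metadata=(("repeat_name", repeat_name), ("repeat_class", repeat_class)),
            )
        )
    return regions


def parse_bed(path: str | Path, *, source: str = "bed") -> list[CandidateRegion]:
    """Parse a BED3+ file (0-based half-open) into candidate regions.

    ``source`` may be set to ``retrotector`` for RetroTector chains that were
    converted to intervals. Track and comment lines are skipped. Extra columns
    beyond the first six are kept as ``extra`` metadata.
    """
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionParseError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RegionParseError(f"{path}:{lineno}: bad coordinates") from exc
            if end <= start:
                raise RegionParseError(
                    f"{path}:{lineno}: empty/inverted interval [{start},{end})"
                )
            meta: list[tuple[str, str]] = []
            line_source, line_round = source, 1 if source != "homology" else 2
            if len(fields) >= 4 and fields[3]:
                meta.append(("name", fields[3]))
                # restore provenance written by write_bed ("source:roundN")
                if ":" in fields[3]:
                    tag, _, rnd = fields[3].partition(":")
                    if tag in SOURCES and rnd in ("round1", "round2"):
                        line_source = tag
                        line_round = int(rnd[-1])
            if len(fields) >= 6 and fields[5] in "+-":
                meta.append(("strand", fields[5]))
            if len(fields) > 6:
                meta.append(("extra", "\t".join(fields[6:])))
            regions.append(
                CandidateRegion(
                    chrom=fields[0], start=start, end=end,
                    source=line_source, round=line_round,
                    metadata=tuple(meta),
                )
            )
    return regions


_PSL_HEADER_TOKENS = ("psLayout", "match", "-----")


def parse_psl(path: str | Path) -> list[CandidateRegion]:
    """Parse BLAT PSL alignments into second-round candidate regions.

    Target coordinates in PSL are 0-based half-open and already normalized to
    plus-strand space for the extent columns (tStart < tEnd), so a hit and its
    reverse-orientation twin yield the identical region.
    """
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or any(stripped.startswith(t) for t in _PSL_HEADER_TOKENS):
                continue
            fields = stripped.split()
            if len(fields) != 21:
                raise RegionParseError(
                    f"{path}:{lineno}: PSL requires 21 columns, got {len(fields)}"
                )
            try:
                t_name = fields[13]
                t_start = int(fields[15])
                t_end = int(fields[16])
            except ValueError as exc:
                raise RegionParseError(f"{path}:{lineno}: bad PSL coordinates") from exc
            lo, hi = min(t_start, t_end), max(t_start, t_end)
            regions.append(
                CandidateRegion(
                    chrom=t_name, start=lo, end=hi, source="homology", round=2,
                    metadata=(("query", fields[9]),),
                )
            )
    return regions


def parse_blast_tab(path: str | Path) -> list[CandidateRegion]:
    """Parse 12-column tabular protein-search output into candidate regions.

    Subject start may exceed subject end for minus-strand hits; the region is
    the min/max of the 1-based subject coordinates converted to 0-based
    half-open. The E-value column is ignored for region extraction.
    """
    regions: list[CandidateRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise RegionParseError(
                    f"{path}:{lineno}: expected 12 tabular columns, got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise RegionParseError(
                    f"{path}:{lineno}: non-numeric subject coordinates"
                ) from exc
            lo, hi = min(sstart, send), max(sstart, send)
            regions.append(
                CandidateRegion(
                    chrom=fields[1], start=lo - 1, end=hi, source="homology", round=2,
                    metadata=(("query", fields[0]),),
                )
            )
    return regions


def expand_and_merge(
    regions: list[CandidateRegion],
    flank: int,
    chrom_lengths: dict[str, int],
    *,
    merge_gap: int = 0,
) -> list[CandidateRegion]:
    """Extend each region by ``flank`` nt on both sides, clip to the
    chromosome, and union overlapping or touching regions per chromosome.

    Regions within ``merge_gap`` nt of each other are also merged (useful for
    fragmented detector output). Output is sorted by (chrom, start);
    provenance of a merged region is the union of its inputs' sources, with
    round = min of contributing rounds.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        if r.chrom not in chrom_lengths:
            raise RegionParseError(f"unknown chromosome {r.chrom!r}")
        by_chrom.setdefault(r.chrom, []).append(r)

    merged: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        length = chrom_lengths[chrom]
        tree = IntervalTree()
        for r in by_chrom[chrom]:
            start = max(0, r.start - flank)
            end = min(length, r.end + flank)
            # pad by merge_gap so "close" intervals coalesce, then strip it;
            # strict=False already merges touching intervals at gap 0
            tree.addi(start, end + merge_gap, (r.source, r.round))
        tree.merge_overlaps(data_reducer=lambda a, b: None, strict=False)
        spans = sorted((iv.begin, min(iv.end - merge_gap, length)) for iv in tree)
        for start, end in spans:
            contributing = [
                r for r in by_chrom[chrom]
                if max(0, r.start - flank) < end and min(length, r.end + flank) > start
            ]
            sources = sorted({r.source for r in contributing})
            rnd = min(r.round for r in contributing)
            meta: list[tuple[str, str]] = [("sources", ";".join(sources))]
            classes = sorted(
                {r.meta["repeat_class"] for r in contributing if "repeat_class" in r.meta}
            )
            if classes:
                meta.append(("repeat_class", ";".join(classes)))
            merged.append(
                CandidateRegion(
                    chrom=chrom, start=start, end=end,
                    source=sources[0], round=rnd, metadata=tuple(meta),
                )
            )
    return merged


def write_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open) with source/round in the name."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.source}:round{r.round}\n")
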