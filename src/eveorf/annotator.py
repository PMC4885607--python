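"""Annotation of final EVE ORFs.

Attaches best protein-search hits (viral / nr / known-EVE databases, each
consumed as pre-computed 12-column tabular output), assigns the retroviral
gene category (gag / pro / pol / env / other) from the best-scoring motif
profile, flags pol ORFs that are LINE reverse-transcriptase look-alikes,
and records overlaps with exons of annotated gene models.
"""

from __future__ import annotations

import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .motif_filter import GENE_CATEGORIES, ProfileSet
from .orf_scanner import OrfRecord

BEST_HIT_DBS = ("viral", "nr", "known_eve")

# RefSeq accessions of LINE reverse transcriptases that masquerade as
# retroviral pol in viral-database searches
LINE_POL_ACCESSIONS = frozenset({"YP_073558.1", "NP_048132.1"})

# keyword fallback when a profile has no category column
_CATEGORY_KEYWORDS = (
    ("gag", ("gag",)),
    ("pro", ("prot", "_pr", "pr_", "rvp")),
    ("pol", ("rvt", "rve", "rnase_h", "rnaseh", "integrase", "pol")),
    ("env", ("env", "coat")),
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class BestHit:
    """One protein-search hit for an (ORF, database) pair."""

    subject_id: str
    description: str
    evalue: float
    bitscore: float
    db: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise AnnotationError("evalue must be non-negative")
        if self.db not in BEST_HIT_DBS:
            raise AnnotationError(f"unknown database tag {self.db!r}")


@dataclass
class OrfAnnotation:
    """Per-ORF annotation bundle assembled by this module."""

    category: str = "other"
    line_pol: bool = False
    best_hits: dict[str, BestHit] = field(default_factory=dict)
    overlapping_genes: list[str] = field(default_factory=list)
    retrotector: str = ""
    repbase: str = ""


def select_best_hit(hits: list[BestHit]) -> BestHit | None:
    """Best hit for one (ORF, db) pair: minimal E-value, ties by maximal
    bitscore, then first occurrence. None when there are no hits."""
    best = None
    for hit in hits:
        if best is None or (hit.evalue, -hit.bitscore) < (best.evalue, -best.bitscore):
            best = hit
    return best


def parse_hit_table(path: str | Path, db: str) -> dict[str, list[BestHit]]:
    """Parse 12-column tabular search output into query -> hits.

    Query names are the exported locus identifiers. Column 2 is the subject
    accession (also used as the description for plain 12-column files; a
    13th column, when present, supplies the free-text description).
    """
    hits: dict[str, list[BestHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 tabular columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad numeric field") from exc
            description = fields[12] if len(fields) > 12 else fields[1]
            hits.setdefault(fields[0], []).append(
                BestHit(
                    subject_id=fields[1], description=description,
                    evalue=evalue, bitscore=bitscore, db=db,
                )
            )
    return hits


def assign_category(orf: OrfRecord, profiles: ProfileSet | None = None) -> str:
    """Gene category of the best-scoring motif hit's profile.

    Uses the profile file's category column when available, a keyword match
    on the profile name otherwise, and 'other' as the final fallback.
    ORFs without motif hits are 'other'.
    """
    if not orf.motif_hits:
        return "other"
    best = max(orf.motif_hits, key=lambda h: (h.score, -h.evalue))
    if profiles is not None:
        category = profiles.category_of(best.profile_name)
        if category:
            return category
    name = best.profile_name.lower()
    for category, keywords in _CATEGORY_KEYWORDS:
        if any(k in name for k in keywords):
            return category
    return "other"


def flag_line_pol(
    orf: OrfRecord,
    category: str,
    repeat_class: str | None = None,
    viral_best: BestHit | None = None,
) -> bool:
    """True iff a pol ORF looks LINE-derived: its region was annotated as a
    LINE repeat, or its best viral hit is a LINE reverse-transcriptase
    accession. Always False for non-pol ORFs."""
    if category != "pol":
        return False
    if repeat_class is None:
        repeat_class = orf.repeat_class
    if repeat_class and any(part.startswith("LINE") for part in repeat_class.split(";")):
        return True
    return viral_best is not None and viral_best.subject_id in LINE_POL_ACCESSIONS


def load_exon_index(gtf_path: str | Path) -> dict[str, IntervalTree]:
    """Index exons of a GTF/GFF3 gene-model file per chromosome.

    Interval data is the gene identifier (``gene_id`` attribute, or the
    parent gene's ``ID``/the feature's ``Parent`` for GFF3).
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        merge_strategy="create_unique", keep_order=True, verbose=False,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    index: dict[str, IntervalTree] = {}
    for exon in db.features_of_type("exon"):
        gene_ids = exon.attributes.get("gene_id") or exon.attributes.get("Parent") or []
        gene_id = gene_ids[0] if gene_ids else (exon.id or "unknown")
        index.setdefault(exon.seqid, IntervalTree()).addi(
            exon.start - 1, exon.end, gene_id
        )
    return index


def gene_overlap(orf: OrfRecord, exon_index: dict[str, IntervalTree]) -> list[str]:
    """Identifiers of genes with >=1 exon overlapping the ORF span by >=1 bp,
    strand-blind; sorted, deduplicated. Chromosomes absent from the
    annotation yield an empty list (with a warning to stderr)."""
    tree = exon_index.get(orf.chrom)
    if tree is None:
        print(f"warning: chromosome {orf.chrom!r} absent from gene annotation",
              file=sys.stderr)
        return []
    return sorted({iv.data for iv in tree.overlap(orf.start - 1, orf.end)})


def annotate_orfs(
    orfs: list[OrfRecord],
    profiles: ProfileSet | None = None,
    *,
    hit_tables: dict[str, dict[str, list[BestHit]]] | None = None,
    exon_index: dict[str, IntervalTree] | None = None,
    id_of=None,
) -> dict[tuple, OrfAnnotation]:
    """Assemble the full annotation bundle for each ORF.

    ``hit_tables`` maps db tag -> (query id -> hits); ``id_of`` maps an ORF
    to the query identifier used in those tables (defaults to the bare locus
    string ``chrom.start.end.strand``).
    """
    from .motif_filter import orf_query_name

    if id_of is None:
        id_of = orf_query_name
    annotations: dict[tuple, OrfAnnotation] = {}
    for orf in orfs:
        ann = OrfAnnotation()
        ann.category = assign_category(orf, profiles)
        qid = id_of(orf)
        if hit_tables:
            for db, table in hit_tables.items():
                hits = table.get(qid, [])
                best = select_best_hit(hits)
                if best is not None:
                    ann.best_hits[db] = best
        ann.line_pol = flag_line_pol(
            orf, ann.category, viral_best=ann.best_hits.get("viral")
        )
        if exon_index is not None:
            ann.overlapping_genes = gene_overlap(orf, exon_index)
        ann.repbase = orf.repeat_class
        if "retrotector" in orf.methods:
            ann.retrotector = "retrotector"
        annotations[orf.key()] = ann
    return annotations


def summarize_counts(
    orfs: list[OrfRecord],
    annotations: dict[tuple, OrfAnnotation],
) -> dict[str, int]:
    """Per-category tally mirroring the per-genome viral-profile table:
    total EVEs, EVEs with >=1 Met, gag/pro/pol/env/other counts and the
    LINE-derived pol subcount."""
    counts = Counter()
    counts["total"] = len(orfs)
    for orf in orfs:
        ann = annotations[orf.key()]
        if orf.met_offset is not None:
            counts["met"] += 1
        counts[ann.category] += 1
        if ann.line_pol:
            counts["pol_line"] += 1
    return {
        "total": counts["total"],
        "met": counts["met"],
        **{c: counts[c] for c in GENE_CATEGORIES},
        "pol_line": counts["pol_line"],
    }
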