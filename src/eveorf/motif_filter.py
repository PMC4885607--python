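"""Viral-motif gate: an ORF is retained iff it carries >=1 qualifying motif hit.

Two evidence routes are supported:

* parsing per-domain tables from a profile-HMM search (hmmscan
  ``domtblout`` dialect), the production route;
* a built-in consensus-peptide matcher that slides a profile's consensus
  peptide ungapped along the ORF's amino-acid sequence and reports a hit
  when the best window reaches the identity threshold (default 90%). This
  is a deterministic identity scorer, not a profile HMM; it makes the
  pipeline self-contained for testing and desk-scale use.

The retention rule itself is existence-of-hit, not the score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .orf_scanner import OrfRecord

PROFILE_SOURCES = ("pfam", "gypsy", "custom")
GENE_CATEGORIES = ("gag", "pro", "pol", "env", "other")

DEFAULT_EVALUE_CUTOFF = 10.0  # the search tool's default reporting bound
DEFAULT_MIN_IDENTITY = 0.9


class MotifParseError(ValueError):
    """Raised for malformed domain tables or profile files."""


@dataclass(frozen=True)
class MotifHit:
    """One profile match on an ORF amino-acid sequence.

    ``ali_from``/``ali_to`` are 1-based inclusive positions on the ORF's
    amino acids. For consensus-matcher hits the score is the identity count
    and the E-value is 0 by convention.
    """

    profile_name: str
    profile_source: str
    score: float
    evalue: float
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError("require 1 <= ali_from <= ali_to")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class Profile:
    name: str
    source: str
    category: str
    consensus: str


@dataclass
class ProfileSet:
    """A set of named motif profiles with an E-value cutoff for table hits."""

    profiles: list[Profile]
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF

    def __post_init__(self) -> None:
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise MotifParseError("profile names must be unique")
        self._by_name = {p.name: p for p in self.profiles}

    def __iter__(self):
        return iter(self.profiles)

    def get(self, name: str) -> Profile | None:
        return self._by_name.get(name)

    def category_of(self, profile_name: str) -> str | None:
        p = self._by_name.get(profile_name)
        return p.category if p and p.category else None


def load_profiles(path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> ProfileSet:
    """Load a tab-delimited profile definition file.

    Columns: name, source (pfam|gypsy|custom), gene category hint
    (gag|pro|pol|env|other or empty), consensus peptide (may be empty for
    profiles used only via domain tables). '#' lines are comments.
    """
    profiles: list[Profile] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MotifParseError(f"{path}:{lineno}: need >=2 tab-delimited columns")
            name = fields[0].strip()
            source = fields[1].strip().lower()
            if source not in PROFILE_SOURCES:
                raise MotifParseError(f"{path}:{lineno}: unknown source {source!r}")
            category = fields[2].strip().lower() if len(fields) > 2 else ""
            if category and category not in GENE_CATEGORIES:
                raise MotifParseError(f"{path}:{lineno}: unknown category {category!r}")
            consensus = fields[3].strip().upper() if len(fields) > 3 else ""
            profiles.append(Profile(name, source, category, consensus))
    return ProfileSet(profiles, evalue_cutoff)


def default_profiles(evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> ProfileSet:
    """The profile set shipped with the package (synthetic consensus peptides).

    These peptides are invented stand-ins for testing the pipeline without
    external profile databases; they are not authoritative viral motifs.
    """
    path = importlib.resources.files("eveorf").joinpath("data/default_profiles.tsv")
    with importlib.resources.as_file(path) as p:
        return load_profiles(p, evalue_cutoff)


# domtblout whitespace-aligned column indices (per-domain table dialect):
# 0 target name, 3 query name, 12 i-Evalue, 13 domain score, 17/18 ali from/to
def parse_domtblout(
    path: str | Path,
    orfs: list[OrfRecord],
    *,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    profile_source: str = "custom",
) -> tuple[dict[tuple, list[MotifHit]], list[str]]:
    """Parse a per-domain table and attach hits to ORFs by identifier.

    Query names must equal ORF identifiers (the dot-joined locus ID). Hits
    with independent E-value above ``evalue_cutoff`` are dropped. Returns
    (mapping ORF key -> hits, unmatched query names). Hits are also appended
    to each matched ORF's ``motif_hits``.
    """
    by_id: dict[str, OrfRecord] = {}
    for orf in orfs:
        by_id.setdefault(orf_query_name(orf), orf)

    hits: dict[tuple, list[MotifHit]] = {}
    unmatched: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 19:
                raise MotifParseError(
                    f"{path}:{lineno}: expected >=19 domtblout columns, got {len(fields)}"
                )
            try:
                target = fields[0]
                query = fields[3]
                i_evalue = float(fields[12])
                score = float(fields[13])
                ali_from = int(fields[17])
                ali_to = int(fields[18])
            except ValueError as exc:
                raise MotifParseError(f"{path}:{lineno}: bad field: {exc}") from exc
            if i_evalue > evalue_cutoff:
                continue
            orf = by_id.get(query)
            if orf is None and "." in query:
                # tolerate a genome-ID prefix on exported locus IDs
                orf = by_id.get(query.split(".", 1)[1])
            if orf is None:
                unmatched.append(query)
                continue
            hit = MotifHit(
                profile_name=target, profile_source=profile_source,
                score=score, evalue=i_evalue, ali_from=ali_from, ali_to=ali_to,
            )
            orf.motif_hits.append(hit)
            hits.setdefault(orf.key(), []).append(hit)
    return hits, unmatched


def orf_query_name(orf: OrfRecord) -> str:
    """Canonical query name for an ORF in external searches (locus string)."""
    return f"{orf.chrom}.{orf.start}.{orf.end}.{orf.strand}"


def scan_consensus(
    orf: OrfRecord,
    profiles: ProfileSet,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[MotifHit]:
    """Score an ORF against every profile's consensus peptide.

    For each profile the peptide is slid ungapped along ``aa_seq``; the
    best-scoring offset is reported as a hit when its identity fraction is
    >= ``min_identity``. Hits are appended to ``orf.motif_hits``.
    """
    found: list[MotifHit] = []
    aa = orf.aa_seq
    for profile in profiles:
        pep = profile.consensus
        L = len(pep)
        if not pep or L > len(aa):
            continue
        best_ident, best_off = -1, -1
        for off in range(len(aa) - L + 1):
            ident = sum(a == b for a, b in zip(aa[off : off + L], pep))
            if ident > best_ident:
                best_ident, best_off = ident, off
        if best_ident / L >= min_identity:
            found.append(
                MotifHit(
                    profile_name=profile.name, profile_source=profile.source,
                    score=float(best_ident), evalue=0.0,
                    ali_from=best_off + 1, ali_to=best_off + L,
                )
            )
    orf.motif_hits.extend(found)
    return found


def attach_consensus_hits(
    orfs: list[OrfRecord],
    profiles: ProfileSet,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> None:
    for orf in orfs:
        scan_consensus(orf, profiles, min_identity=min_identity)


def filter_orfs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Keep exactly the ORFs with at least one motif hit; order preserved."""
    return [orf for orf in orfs if orf.motif_hits]
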