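"""Restriction-fragment locus construction and marker typing.

Implements the reduced-representation side of the pipeline: in-silico
double digest (XhoI + MseI), size selection, greedy single-linkage
clustering of fixed-length tags at an identity threshold, locus filters
(repetitive when more than four distinct tags; optional depth floors)
and marker typing into SNP / enzyme-site SNP / indel / no-polymorphism /
unknown categories, plus the category summary table.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "XHOI_SITE",
    "MSEI_SITE",
    "SlafTag",
    "SlafLocus",
    "Fragment",
    "digest",
    "cluster_tags",
    "filter_loci",
    "type_marker",
    "slaf_summary",
    "hamming_identity",
]

XHOI_SITE = "CTCGAG"
MSEI_SITE = "TTAA"

MARKER_CATEGORIES = (
    "SNP", "EPSNP", "INDEL", "no_polymorphism", "unknown", "repeat", "low_depth",
)


@dataclass(frozen=True)
class SlafTag:
    """One distinct tag sequence observed in one sample."""

    tag_id: str
    sequence: str
    sample: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("tag depth must be >= 1")


@dataclass
class SlafLocus:
    """A cluster of tags at one genomic locus.

    ``tags`` groups the member tags by distinct sequence; ``depths``
    accumulates reads per (sequence, sample). ``category`` is assigned
    by :func:`filter_loci` / :func:`type_marker`.
    """

    locus_id: str
    scaffold: str = ""
    position: int = 0  # leftmost tag coordinate, 1-based; 0 = unplaced
    tags: dict[str, list[SlafTag]] = field(default_factory=dict)
    category: str = "unknown"

    @property
    def n_distinct(self) -> int:
        return len(self.tags)

    @property
    def total_depth(self) -> int:
        return sum(t.depth for members in self.tags.values() for t in members)

    @property
    def polymorphic(self) -> bool:
        return 2 <= self.n_distinct <= 4 and self.category in ("SNP", "EPSNP", "INDEL")


@dataclass(frozen=True)
class Fragment:
    """A digest fragment with 1-based inclusive coordinates on its source."""

    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _cut_positions(sequence: str, sites: Sequence[str]) -> list[int]:
    """0-based cut offsets: a cut before each occurrence of any site."""
    cuts: set[int] = set()
    for site in sites:
        start = 0
        while True:
            i = sequence.find(site, start)
            if i == -1:
                break
            cuts.add(i)
            start = i + 1
    return sorted(cuts)


def digest(
    sequence: str,
    enzymes: Sequence[str] = (XHOI_SITE, MSEI_SITE),
    size_window: Optional[tuple[int, int]] = None,
) -> list[Fragment]:
    """Double-digest a sequence and size-select the fragments.

    Cuts are placed before every occurrence of either recognition site;
    fragments run between consecutive cuts (and the sequence ends).
    With ``size_window=(lo, hi)`` only fragments with lo <= length <= hi
    are returned; ``None`` returns all fragments, whose concatenation
    reconstructs the input.
    """
    if not sequence:
        return []
    cuts = _cut_positions(sequence, enzymes)
    bounds = [0, *[c for c in cuts if c > 0], len(sequence)]
    frags = [
        Fragment(start=bounds[i] + 1, end=bounds[i + 1], sequence=sequence[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    if size_window is not None:
        lo, hi = size_window
        frags = [f for f in frags if lo <= f.length <= hi]
    return frags


def hamming_identity(a: str, b: str) -> float:
    """Ungapped identity between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 1.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def cluster_tags(
    tags: Iterable[SlafTag], identity_threshold: float = 0.9
) -> list[list[SlafTag]]:
    """Group tags into loci by greedy single-linkage identity clustering.

    A tag joins an existing group when its ungapped identity with any
    member exceeds the threshold; otherwise it founds a new group.
    Processing order is the lexicographic order of the tag sequences, so
    the partition is deterministic and, under single linkage, identical
    to the transitive closure of the pairwise above-threshold relation.
    """
    if not (0.5 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must lie in (0.5, 1.0]")
    tags = sorted(tags, key=lambda t: (t.sequence, t.sample, t.tag_id))
    lengths = {len(t.sequence) for t in tags}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths {sorted(lengths)}")

    groups: list[list[SlafTag]] = []
    for tag in tags:
        hits = [
            gi for gi, group in enumerate(groups)
            if any(hamming_identity(tag.sequence, m.sequence) > identity_threshold for m in group)
        ]
        if not hits:
            groups.append([tag])
        else:
            # single linkage: the new tag may bridge several groups
            keep = hits[0]
            for gi in reversed(hits[1:]):
                groups[keep].extend(groups.pop(gi))
            groups[keep].append(tag)
    return groups


def filter_loci(
    groups: Iterable[list[SlafTag]],
    max_tags: int = 4,
    min_depth: int = 10,
    low_depth_cutoff: Optional[int] = None,
    positions: Optional[dict[str, tuple[str, int]]] = None,
) -> list[SlafLocus]:
    """Assemble loci from tag groups and flag repetitive/low-depth ones.

    A locus with more than ``max_tags`` distinct sequences is
    categorised ``repeat`` (a diploid carries at most four tags at one
    locus); total depth below ``min_depth`` — or below
    ``low_depth_cutoff`` when that stricter optional floor is given —
    makes it ``low_depth``. Surviving loci keep category ``unknown``
    until :func:`type_marker` assigns one. ``positions`` optionally maps
    a member tag's sequence to its (scaffold, 1-based position).
    """
    loci: list[SlafLocus] = []
    for i, group in enumerate(groups):
        by_seq: dict[str, list[SlafTag]] = defaultdict(list)
        for t in group:
            by_seq[t.sequence].append(t)
        locus = SlafLocus(locus_id=f"L{i + 1:05d}", tags=dict(by_seq))
        if positions:
            placed = [positions[s] for s in by_seq if s in positions]
            if placed:
                locus.scaffold, locus.position = min(placed, key=lambda sp: (sp[0], sp[1]))
        cutoff = max(min_depth, low_depth_cutoff or 0)
        if locus.n_distinct > max_tags:
            locus.category = "repeat"
        elif locus.total_depth < cutoff:
            locus.category = "low_depth"
        loci.append(locus)
    return loci


def _differs_by_substitution_in_site(
    a: str, b: str, enzymes: Sequence[str] = (XHOI_SITE, MSEI_SITE)
) -> bool:
    """True if any mismatch between equal-length a, b falls inside an
    enzyme recognition-site occurrence of either sequence."""
    mismatches = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    for seq in (a, b):
        for site in enzymes:
            start = 0
            while True:
                j = seq.find(site, start)
                if j == -1:
                    break
                if any(j <= m < j + len(site) for m in mismatches):
                    return True
                start = j + 1
    return False


def type_marker(
    locus: SlafLocus,
    parent_alleles: Optional[dict[str, str]] = None,
    enzymes: Sequence[str] = (XHOI_SITE, MSEI_SITE),
) -> str:
    """Assign the marker category of a retained locus.

    One distinct tag is ``no_polymorphism``. With several tags:
    length-changing differences give ``INDEL``; pure substitutions give
    ``SNP``, upgraded to ``EPSNP`` when a substitution hits an enzyme
    recognition site (creating or destroying a cut site — the
    enzyme-locus variation category). If ``parent_alleles`` (mapping
    parent name to its tag sequence at this locus) is provided and no
    tag matches any parent, the locus is ``unknown``.
    The category is stored on the locus and returned.
    """
    if locus.category in ("repeat", "low_depth"):
        return locus.category
    seqs = sorted(locus.tags)
    if len(seqs) == 1:
        locus.category = "no_polymorphism"
        return locus.category
    if parent_alleles is not None:
        parental = set(parent_alleles.values())
        if not any(s in parental for s in seqs):
            locus.category = "unknown"
            return locus.category
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        locus.category = "INDEL"
        return locus.category
    epsnp = any(
        _differs_by_substitution_in_site(seqs[i], seqs[j], enzymes)
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    )
    locus.category = "EPSNP" if epsnp else "SNP"
    return locus.category


def slaf_summary(loci: Iterable[SlafLocus]) -> pd.DataFrame:
    """Count loci per category with percentages to two decimals.

    Returns a DataFrame indexed by category with columns ``number`` and
    ``percent`` plus a ``Total`` row; percentages are count/total*100.
    """
    counts = Counter(l.category for l in loci)
    total = sum(counts.values())
    rows = []
    for cat in MARKER_CATEGORIES:
        if counts.get(cat, 0) or cat in MARKER_CATEGORIES[:6]:
            n = counts.get(cat, 0)
            rows.append({"category": cat, "number": n,
                         "percent": round(100.0 * n / total, 2) if total else 0.0})
    rows.append({"category": "Total", "number": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows).set_index("category")
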