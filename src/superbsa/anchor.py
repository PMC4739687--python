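"""Anchoring scaffold markers onto chromosome assemblies.

Marker tag sequences are located on a chromosome-level assembly by
seed-and-extend search (16 bp exact seeds, ungapped extension to the
full marker length, identity threshold), on both strands. Markers
hitting more than ``max_hits`` distinct locations are discarded as
promiscuous; retained markers report their best hit. Anchored markers
are then grouped per chromosome into fine-map tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = ["ChromAnchor", "anchor_markers", "project_regions", "SEED_LENGTH"]

SEED_LENGTH = 16


@dataclass(frozen=True)
class ChromAnchor:
    """One marker placed on a chromosome (1-based inclusive interval)."""

    marker: str
    chromosome: str
    start: int
    end: int
    strand: str
    identity: float
    hit_count: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("anchor end must be >= start")


def _identity_at(chrom: str, offset: int, query: str) -> float:
    """Ungapped identity of query aligned at 0-based offset (0 if out of bounds)."""
    if offset < 0 or offset + len(query) > len(chrom):
        return 0.0
    window = chrom[offset : offset + len(query)]
    return sum(a == b for a, b in zip(window, query)) / len(query)


def _seed_hits(chrom: str, query: str, min_identity: float) -> dict[int, float]:
    """All offsets where the query aligns at >= min_identity, found via
    exact 16-mer seeds tiled across the query."""
    hits: dict[int, float] = {}
    n = len(query)
    seed_offsets = list(range(0, max(n - SEED_LENGTH, 0) + 1, SEED_LENGTH))
    if seed_offsets and seed_offsets[-1] != n - SEED_LENGTH:
        seed_offsets.append(n - SEED_LENGTH)
    for so in seed_offsets:
        seed = query[so : so + SEED_LENGTH]
        start = 0
        while True:
            i = chrom.find(seed, start)
            if i == -1:
                break
            offset = i - so
            if offset not in hits:
                ident = _identity_at(chrom, offset, query)
                if ident >= min_identity:
                    hits[offset] = ident
            start = i + 1
    return hits


def anchor_markers(
    marker_seqs: dict[str, str],
    assembly: dict[str, str],
    min_identity: float = 0.9,
    max_hits: int = 2,
) -> tuple[list[ChromAnchor], list[str]]:
    """Place marker sequences on an assembly; discard promiscuous ones.

    Each marker is searched on both strands of every chromosome. A hit
    is a distinct (chromosome, offset, strand) where the full marker
    aligns ungapped at >= ``min_identity``. Markers with more than
    ``max_hits`` hits are discarded; markers with no hit are reported as
    discarded too. Retained markers keep their best hit (highest
    identity; ties broken by smallest (chromosome, start), logged).

    Returns (anchors sorted by (chromosome, start), discarded marker ids).
    """
    if not (0.8 < min_identity <= 1.0):
        raise ValueError("min_identity must lie in (0.8, 1.0]")
    anchors: list[ChromAnchor] = []
    discarded: list[str] = []
    for marker, seq in sorted(marker_seqs.items()):
        if len(seq) < SEED_LENGTH:
            raise ValueError(f"marker {marker} shorter than the {SEED_LENGTH} bp seed")
        candidates: list[tuple[float, str, int, str]] = []  # (identity, chrom, offset, strand)
        rc = str(Seq(seq).reverse_complement())
        for chrom_id, chrom_seq in assembly.items():
            if len(chrom_seq) < len(seq):
                continue
            for strand, query in (("+", seq), ("-", rc)):
                for offset, ident in _seed_hits(chrom_seq, query, min_identity).items():
                    candidates.append((ident, chrom_id, offset, strand))
        if not candidates:
            logger.info("marker %s: no hit in the assembly", marker)
            discarded.append(marker)
            continue
        if len(candidates) > max_hits:
            discarded.append(marker)
            continue
        best_identity = max(c[0] for c in candidates)
        top = sorted(
            (c for c in candidates if c[0] == best_identity),
            key=lambda c: (c[1], c[2]),
        )
        if len(top) > 1:
            logger.info("marker %s: best-hit tie, keeping smallest coordinate", marker)
        ident, chrom_id, offset, strand = top[0]
        anchors.append(
            ChromAnchor(
                marker=marker, chromosome=chrom_id,
                start=offset + 1, end=offset + len(seq),
                strand=strand, identity=ident, hit_count=len(candidates),
            )
        )
    anchors.sort(key=lambda a: (a.chromosome, a.start))
    return anchors, discarded


def project_regions(
    anchors: Iterable[ChromAnchor],
    trait: Optional[str] = None,
    trait_markers: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Build a per-chromosome fine-map table from retained anchors.

    With ``trait`` and ``trait_markers`` (marker id -> trait) given,
    only that trait's markers are kept. Rows are grouped by chromosome
    and sorted by start, with columns chromosome, marker, start, end.
    """
    rows = []
    for a in anchors:
        if trait is not None and trait_markers is not None:
            if trait_markers.get(a.marker) != trait:
                continue
        rows.append(
            {"chromosome": a.chromosome, "marker": a.marker, "start": a.start, "end": a.end}
        )
    df = pd.DataFrame(rows, columns=["chromosome", "marker", "start", "end"])
    return df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
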