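"""Bulk allele-depth ratio statistics and candidate-region calling.

The mapping statistic: per marker, reads in each extreme-phenotype F2
bulk are attributed to the maternal (M, sweet parent) or paternal (P,
sour parent) allele, and two ratios are formed —

    Ratio_sweet = M_sweet / P_nsns
    Ratio_sour  = P_sour  / M_nsns

where "nsns" is the non-sweet non-sour bulk. A zero denominator maps
to a sentinel (1000). A marker is differential for a trait when its
ratio meets the threshold (default >= 3); runs of consecutive
differential markers on one scaffold become candidate trait regions
with kb-rounded bounds and overlapping-gene counts. A display cap
(default 20) applies to plotted intensities only, never to the
differential decision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from .sim import Gene
from .slaf import SlafLocus

logger = logging.getLogger(__name__)

__all__ = [
    "SENTINEL",
    "THRESHOLD",
    "DISPLAY_CAP",
    "BulkRatio",
    "TraitRegion",
    "compute_ratio",
    "assign_parental_origin",
    "bulk_ratios",
    "call_regions",
    "count_region_genes",
    "marker_density",
]

SENTINEL = 1000.0
THRESHOLD = 3.0
DISPLAY_CAP = 20.0


@dataclass
class BulkRatio:
    """Per-marker bulk depths with both trait ratios and flags."""

    marker: str
    scaffold: str
    position: int
    m_sweet: int
    p_nsns: int
    p_sour: int
    m_nsns: int
    ratio_sweet: float
    ratio_sour: float
    display_sweet: float
    display_sour: float
    differential_sweet: bool
    differential_sour: bool


@dataclass
class TraitRegion:
    """A candidate region called from a run of differential markers."""

    trait: str  # "sweet" | "sour"
    scaffold: str
    start: int
    end: int
    markers: list[str]

    @property
    def size(self) -> int:
        return self.end - self.start


def compute_ratio(
    numerator_depth: int,
    denominator_depth: int,
    sentinel: float = SENTINEL,
    threshold: float = THRESHOLD,
    cap: float = DISPLAY_CAP,
) -> tuple[float, float, bool]:
    """Form one bulk depth ratio with sentinel, display cap and flag.

    Returns (ratio, display, differential). The ratio is
    numerator/denominator, replaced by the sentinel when the denominator
    is zero (including the degenerate 0/0 case, which is logged);
    display = min(ratio, cap); the marker is differential when
    ratio >= threshold.
    """
    if numerator_depth < 0 or denominator_depth < 0:
        raise ValueError("depths must be >= 0")
    if denominator_depth == 0:
        if numerator_depth == 0:
            logger.warning("0/0 depth ratio: sentinel applied to an unreliable marker")
        ratio = sentinel
    else:
        ratio = numerator_depth / denominator_depth
    return ratio, min(ratio, cap), ratio >= threshold


def assign_parental_origin(
    locus: SlafLocus,
    parent_alleles: dict[str, str],
) -> dict[str, tuple[int, int]]:
    """Split each pool's tag depths into maternal (M) and paternal (P) reads.

    ``parent_alleles`` maps "sweet"/"sour" to that parent's tag sequence
    at this locus. Depths of tags matching the sweet (female) parent sum
    to M, the sour (male) parent to P, per sample; tags matching neither
    are counted to neither and logged, and the locus is flagged
    ``unknown`` when more than half its reads are unattributable.

    Returns {sample: (m_depth, p_depth)}.
    """
    sweet_seq = parent_alleles.get("sweet")
    sour_seq = parent_alleles.get("sour")
    if sweet_seq is None or sour_seq is None:
        raise ValueError("parent_alleles must provide 'sweet' and 'sour' sequences")
    out: dict[str, list[int]] = {}
    orphan = 0
    total = 0
    for seq, members in locus.tags.items():
        for t in members:
            m, p = out.setdefault(t.sample, [0, 0])
            total += t.depth
            if seq == sweet_seq:
                out[t.sample][0] += t.depth
            elif seq == sour_seq:
                out[t.sample][1] += t.depth
            else:
                orphan += t.depth
    if orphan:
        logger.info("locus %s: %d reads match neither parent", locus.locus_id, orphan)
        if total and orphan / total > 0.5:
            locus.category = "unknown"
    return {s: (m, p) for s, (m, p) in out.items()}


def bulk_ratios(
    depths: pd.DataFrame,
    sentinel: float = SENTINEL,
    threshold: float = THRESHOLD,
    cap: float = DISPLAY_CAP,
) -> list[BulkRatio]:
    """Compute both trait ratios for every marker in a depth table.

    ``depths`` needs columns marker, scaffold, position, M_sweet,
    P_nsns, P_sour, M_nsns (the simulator's table is a superset).
    Output is sorted by (scaffold, position).
    """
    out: list[BulkRatio] = []
    for row in depths.itertuples(index=False):
        rs, ds, fs = compute_ratio(int(row.M_sweet), int(row.P_nsns), sentinel, threshold, cap)
        rr, dr, fr = compute_ratio(int(row.P_sour), int(row.M_nsns), sentinel, threshold, cap)
        out.append(
            BulkRatio(
                marker=row.marker, scaffold=row.scaffold, position=int(row.position),
                m_sweet=int(row.M_sweet), p_nsns=int(row.P_nsns),
                p_sour=int(row.P_sour), m_nsns=int(row.M_nsns),
                ratio_sweet=rs, ratio_sour=rr,
                display_sweet=ds, display_sour=dr,
                differential_sweet=fs, differential_sour=fr,
            )
        )
    out.sort(key=lambda b: (b.scaffold, b.position))
    return out


def call_regions(
    markers: Iterable[BulkRatio],
    trait: str,
    min_run: int = 2,
    bin_size: int = 1000,
) -> list[TraitRegion]:
    """Call candidate regions from runs of consecutive differential markers.

    Markers are position-sorted per scaffold; a maximal run of at least
    ``min_run`` adjacent differential markers (no intervening
    non-differential marker) becomes one region. Bounds are rounded to
    ``bin_size``: start floored at the first marker, end ceiled at the
    last, so region size is a multiple of the bin. The default
    ``min_run=2`` matches the reported two-marker regions; 3 applies
    the stricter three-in-succession rule.
    """
    if trait not in ("sweet", "sour"):
        raise ValueError("trait must be 'sweet' or 'sour'")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    markers = list(markers)
    ordered = sorted(markers, key=lambda b: (b.scaffold, b.position))
    if [('%s:%d' % (m.scaffold, m.position)) for m in markers] != [
        ('%s:%d' % (m.scaffold, m.position)) for m in ordered
    ]:
        logger.warning("markers were not position-sorted; sorting internally")

    flag = (lambda b: b.differential_sweet) if trait == "sweet" else (lambda b: b.differential_sour)
    regions: list[TraitRegion] = []
    run: list[BulkRatio] = []

    def close_run() -> None:
        if len(run) >= min_run:
            start = (run[0].position // bin_size) * bin_size
            end = math.ceil(run[-1].position / bin_size) * bin_size
            regions.append(
                TraitRegion(
                    trait=trait, scaffold=run[0].scaffold,
                    start=start, end=end, markers=[b.marker for b in run],
                )
            )

    current_scaffold: Optional[str] = None
    for b in ordered:
        if b.scaffold != current_scaffold:
            close_run()
            run = []
            current_scaffold = b.scaffold
        if flag(b):
            run.append(b)
        else:
            close_run()
            run = []
    close_run()
    return regions


def count_region_genes(region: TraitRegion, genes: Iterable[Gene]) -> int:
    """Count gene models overlapping the region by at least 1 bp."""
    tree = IntervalTree()
    for g in genes:
        if g.scaffold == region.scaffold:
            tree[g.start : g.end + 1] = g.gene_id  # half-open interval tree
    return len(tree.overlap(region.start, region.end + 1))


def marker_density(region: TraitRegion) -> float:
    """Marker spacing of a region in Mb per marker."""
    if not region.markers:
        raise ValueError("region has no member markers")
    return (region.size / 1e6) / len(region.markers)
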