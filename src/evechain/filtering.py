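"""Hit filtering and region construction.

Reduces a raw viral-vs-host hit list to candidate EVE loci. The cascade
keeps hits that pass an e-value cut-off and whose host footprint is
corroborated by hits from at least ``min_support_accessions`` distinct
viral queries — independent viruses aligning over the same host locus is
the signature that distinguishes a genuine endogenous viral element from
a spurious local match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import AlignmentHit

__all__ = [
    "FilterConfig",
    "Region",
    "FilterResult",
    "filter_hits",
    "build_regions",
    "hit_intervals",
    "select_representative",
    "regions_to_frame",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the hit-retention cascade.

    ``min_viral_genome_len`` documents the query-database length filter
    (near-complete genomes only); it is applied when building the query
    set, so here it is configuration metadata recorded in the ledger.
    """

    max_evalue: float = 0.001
    min_viral_genome_len: int = 10_000
    min_support_accessions: int = 2
    region_merge_dist: int = 100_000

    def __post_init__(self) -> None:
        if self.max_evalue < 0 or self.min_viral_genome_len < 0 \
                or self.min_support_accessions < 0 or self.region_merge_dist < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class Region:
    """A merged host-genome footprint of overlapping/nearby hits."""

    chrom: str
    start: int
    end: int
    n_hits: int
    n_accessions: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_hits < 1 or self.n_accessions < 1:
            raise ValueError("counts must be >= 1")

    @property
    def length(self) -> int:
        """Span as a coordinate difference (end - start)."""
        return self.end - self.start


@dataclass
class FilterResult:
    retained: list[AlignmentHit]
    ledger: list[tuple[str, int]] = field(default_factory=list)

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ledger, columns=["stage", "n_removed"])


def _overlap_support(hits: Sequence[AlignmentHit], min_support: int) -> list[AlignmentHit]:
    """Keep hits whose host interval overlaps >= min_support distinct accessions
    (counting the hit's own accession)."""
    if min_support <= 1:
        return list(hits)
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.subject_id, []).append(h)
    kept: list[AlignmentHit] = []
    for contig_hits in by_contig.values():
        contig_hits.sort(key=lambda h: (h.s_lo, h.s_hi))
        for h in contig_hits:
            accs = {h.query_acc}
            for other in contig_hits:
                if other.s_lo > h.s_hi:
                    break
                if other.s_hi >= h.s_lo and other is not h:
                    accs.add(other.query_acc)
                if len(accs) >= min_support:
                    break
            if len(accs) >= min_support:
                kept.append(h)
    order = {id(h): i for i, h in enumerate(hits)}
    kept.sort(key=lambda h: order[id(h)])
    return kept


def filter_hits(hits: Sequence[AlignmentHit], config: FilterConfig | None = None) -> FilterResult:
    """Apply the retention cascade; returns survivors plus per-stage discard counts.

    Stage order: (1) e-value <= ``max_evalue``; (2) host-overlap support by
    >= ``min_support_accessions`` distinct viral accessions.
    """
    config = config or FilterConfig()
    current = list(hits)
    ledger: list[tuple[str, int]] = []

    passed = [h for h in current if h.evalue <= config.max_evalue]
    ledger.append(("evalue", len(current) - len(passed)))
    current = passed

    passed = _overlap_support(current, config.min_support_accessions)
    ledger.append(("multi_virus_support", len(current) - len(passed)))
    current = passed

    return FilterResult(retained=current, ledger=ledger)


def build_regions(intervals: Iterable[tuple[str, int, int, str]],
                  merge_dist: int = 100_000) -> list[Region]:
    """Single-linkage merge of host intervals into regions.

    ``intervals`` are (chrom, lo, hi, accession) with lo <= hi, 1-based
    inclusive. Two intervals on one contig join a region iff the gap
    between them is <= merge_dist. Regions are sorted by (chrom, start).
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, lo, hi, acc in intervals:
        if lo > hi:
            raise ValueError(f"inverted interval on {chrom}: {lo} > {hi}")
        by_contig.setdefault(chrom, []).append((lo, hi, acc))
    regions: list[Region] = []
    for chrom in sorted(by_contig):
        ivals = sorted(by_contig[chrom])
        start, end = ivals[0][0], ivals[0][1]
        members = [ivals[0]]
        for lo, hi, acc in ivals[1:]:
            if lo - end <= merge_dist:
                end = max(end, hi)
                members.append((lo, hi, acc))
            else:
                regions.append(Region(chrom, start, end, len(members),
                                      len({m[2] for m in members})))
                start, end, members = lo, hi, [(lo, hi, acc)]
        regions.append(Region(chrom, start, end, len(members),
                              len({m[2] for m in members})))
    return regions


def hit_intervals(hits: Iterable[AlignmentHit]) -> list[tuple[str, int, int, str]]:
    """Host-footprint intervals of hits, in build_regions input form."""
    return [(h.subject_id, h.s_lo, h.s_hi, h.query_acc) for h in hits]


def select_representative(hits: Sequence[AlignmentHit], region: Region) -> str:
    """Accession covering the most non-redundant host bases within a region.

    Ties break lexicographically. Coverage is the union length (inclusive)
    of the accession's hit footprints clipped to the region.
    """
    coverage: dict[str, int] = {}
    for acc in {h.query_acc for h in hits
                if h.subject_id == region.chrom and h.s_lo <= region.end and h.s_hi >= region.start}:
        ivals = sorted((max(h.s_lo, region.start), min(h.s_hi, region.end))
                       for h in hits
                       if h.query_acc == acc and h.subject_id == region.chrom
                       and h.s_lo <= region.end and h.s_hi >= region.start)
        total, cur_lo, cur_hi = 0, None, None
        for lo, hi in ivals:
            if cur_hi is None or lo > cur_hi + 1:
                if cur_hi is not None:
                    total += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        if cur_hi is not None:
            total += cur_hi - cur_lo + 1
        coverage[acc] = total
    if not coverage:
        raise ValueError("region contains no hits")
    top = max(coverage.values())
    return min(acc for acc, cov in coverage.items() if cov == top)


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Region list as a table (chromosome, start, end, n_hits, n_accessions)."""
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_hits, r.n_accessions) for r in regions],
        columns=["chromosome", "start", "end", "n_hits", "n_accessions"],
    )
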