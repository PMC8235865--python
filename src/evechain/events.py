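"""Grouping of EVE fragments into integration events.

The core signal is gap consistency: after a long viral sequence integrates
and is subsequently fragmented by internal deletions, the distance between
two surviving fragments measured on the viral genome stays close to the
distance measured on the host genome. Fragments chained by such matched
gaps, and fragments whose viral intervals overlap substantially with high
identity (duplicated copies of the same insertion), are assigned to one
integration event. Events whose viral footprints abut within a few tens of
bases can further be merged when small-RNA orientation evidence supports a
single original insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .filtering import Region, build_regions
from .io import AlignmentHit, EveRecord

__all__ = [
    "GapPair",
    "LinkEvidence",
    "IntegrationEvent",
    "ChainConfig",
    "compute_gap",
    "chain_collinear",
    "identity_cluster",
    "flag_duplicates",
    "merge_adjacent_events",
    "pairwise_identity",
    "infer_events",
    "infer_events_from_hits",
    "records_from_hits",
]


@dataclass(frozen=True)
class GapPair:
    """Distances between two adjacent fragments on each coordinate system.

    ``viral_gap`` may be negative when the viral intervals overlap.
    """

    viral_gap: int
    host_gap: int


@dataclass(frozen=True)
class LinkEvidence:
    kind: str  # collinear | overlap_identity | duplicate | cross_region_adjacency
    score: float  # identity % or gap discrepancy in bases, per kind
    pair: tuple[str, str]


@dataclass
class IntegrationEvent:
    """A set of fragments inferred to descend from one insertion."""

    event_id: int
    members: list[EveRecord]
    regions: list[Region] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.identifier for m in self.members]

    @property
    def viral_span(self) -> tuple[int, int]:
        return (min(m.v_start for m in self.members), max(m.v_end for m in self.members))

    @property
    def chroms(self) -> set[str]:
        return {m.chrom for m in self.members}

    @property
    def viruses(self) -> set[str]:
        return {m.virus for m in self.members}


@dataclass(frozen=True)
class ChainConfig:
    """Thresholds of the chaining/clustering rules.

    Gap tolerance: two adjacent fragments link when
    ``|g_v - g_h| <= max(gap_tol_abs, gap_tol_rel * max(g_v, g_h))`` and
    both gaps are below ``max_chain_gap``. Identity clustering merges units
    sharing > ``min_overlap`` bp of viral interval at > ``min_identity`` %
    identity; without sequence identity the same-region viral overlap alone
    is accepted as a proxy (nearby fragments of one event are far more
    similar to each other than to anything else).
    """

    gap_tol_abs: int = 300
    gap_tol_rel: float = 0.5
    max_chain_gap: int = 5_000
    min_overlap: int = 50
    min_identity: float = 94.0
    dup_identity: float = 99.0
    dup_coverage: float = 1.0
    adjacency_tol: int = 50
    allow_unevidenced_merge: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.gap_tol_rel <= 1:
            raise ValueError("gap_tol_rel must be in [0,1]")
        for v in (self.min_identity, self.dup_identity):
            if not 0 <= v <= 100:
                raise ValueError("identity thresholds must be in [0,100]")

    def gap_tolerance(self, g_v: int, g_h: int) -> float:
        return max(self.gap_tol_abs, self.gap_tol_rel * max(g_v, g_h))


def compute_gap(a: EveRecord, b: EveRecord) -> GapPair:
    """Gap pair between two fragments on the same contig.

    Each gap is the distance between the nearest interval ends: the later
    interval's smaller coordinate minus the earlier interval's larger
    coordinate, so that non-overlapping intervals yield the printed
    non-negative distances on both minus- and plus-strand blocks. A
    negative viral gap encodes viral-interval overlap.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"{a.identifier} and {b.identifier} lie on different contigs")
    g_v = max(a.v_start, b.v_start) - min(a.v_end, b.v_end)
    g_h = max(a.h_lo, b.h_lo) - min(a.h_hi, b.h_hi)
    return GapPair(viral_gap=g_v, host_gap=g_h)


def _collinear_link(a: EveRecord, b: EveRecord, config: ChainConfig) -> LinkEvidence | None:
    """Evidence for linking host-adjacent fragments a -> b (a before b on host).

    Requires a shared orientation under which viral order matches host
    order, both gaps within range, and gap discrepancy within tolerance.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    if a.strand == "+":
        ordered = b.v_start > a.v_end
    else:  # increasing host coordinate walks the virus backwards
        ordered = a.v_start > b.v_end
    if not ordered:
        return None
    gap = compute_gap(a, b)
    g_v, g_h = gap.viral_gap, gap.host_gap
    if not (0 < g_v <= config.max_chain_gap and 0 <= g_h <= config.max_chain_gap):
        return None
    if abs(g_v - g_h) > config.gap_tolerance(g_v, g_h):
        return None
    return LinkEvidence(kind="collinear", score=abs(g_v - g_h),
                        pair=(a.identifier, b.identifier))


def chain_collinear(records: Sequence[EveRecord], config: ChainConfig | None = None,
                    ) -> tuple[list[list[str]], list[LinkEvidence]]:
    """Maximal runs of gap-consistent fragments within one region.

    ``records`` must lie in a single region; they are sorted by host
    coordinate internally. Returns chains as identifier lists (singletons
    included) plus the link evidence.
    """
    config = config or ChainConfig()
    ordered = sorted(records, key=lambda r: (r.h_lo, r.h_hi, r.identifier))
    chains: list[list[str]] = []
    evidence: list[LinkEvidence] = []
    current: list[str] = []
    for i, rec in enumerate(ordered):
        if not current:
            current = [rec.identifier]
            continue
        link = _collinear_link(ordered[i - 1], rec, config)
        if link is not None:
            evidence.append(link)
            current.append(rec.identifier)
        else:
            chains.append(current)
            current = [rec.identifier]
    if current:
        chains.append(current)
    return chains, evidence


class _DisjointSet:
    """Union-find with index-ordered union for deterministic roots."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # smaller index wins: result independent of merge order
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


def _viral_overlap(a: EveRecord, b: EveRecord) -> int:
    return min(a.v_end, b.v_end) - max(a.v_start, b.v_start)


IdentityTable = Mapping[frozenset, tuple[float, int]]


def _pair_identity(a: EveRecord, b: EveRecord,
                   identity_source: IdentityTable | Mapping[str, str] | None,
                   ) -> tuple[float, int] | None:
    """(identity %, overlap bp) for a record pair, or None in coordinate-only mode.

    A sequence mapping (identifier -> sequence) triggers built-in local
    alignment; otherwise the source is a sparse pairwise table keyed by
    frozenset identifier pairs, where an absent pair means no alignment.
    """
    if identity_source is None:
        return None
    if a.identifier in identity_source and isinstance(identity_source[a.identifier], str):
        return pairwise_identity(identity_source[a.identifier],
                                 identity_source[b.identifier])
    return identity_source.get(frozenset((a.identifier, b.identifier)), (0.0, 0))


def identity_cluster(records: Sequence[EveRecord],
                     chains: Sequence[Sequence[str]] | None = None,
                     identity_source: Mapping | None = None,
                     config: ChainConfig | None = None,
                     region_merge_dist: int = 100_000,
                     ) -> list[IntegrationEvent]:
    """Union chains and singletons into integration events.

    Two units merge when some member pair shares viral-interval overlap
    > ``min_overlap`` bp and identity > ``min_identity`` % (or, without an
    identity source, same-region overlap alone). Merges never cross
    regions here; use :func:`merge_adjacent_events` for that. Events are
    numbered by (chromosome, leftmost host coordinate).
    """
    config = config or ChainConfig()
    if not records:
        return []
    ordered = sorted(records, key=lambda r: (r.chrom, r.h_lo, r.h_hi, r.identifier))
    index = {r.identifier: i for i, r in enumerate(ordered)}
    if identity_source is not None:
        for key in identity_source:
            ids = key if isinstance(key, frozenset) else (key,)
            unknown = [i for i in ids if i not in index]
            if unknown:
                raise KeyError(f"identity source references unknown identifier(s): {unknown}")

    regions = build_regions([(r.chrom, r.h_lo, r.h_hi, r.virus) for r in ordered],
                            merge_dist=region_merge_dist)
    region_of: dict[str, int] = {}
    for r in ordered:
        for k, reg in enumerate(regions):
            if r.chrom == reg.chrom and reg.start <= r.h_lo and r.h_hi <= reg.end:
                region_of[r.identifier] = k
                break

    dsu = _DisjointSet(len(ordered))
    if chains is None:
        by_region: dict[int, list[EveRecord]] = {}
        for r in ordered:
            by_region.setdefault(region_of[r.identifier], []).append(r)
        chains = []
        for k in sorted(by_region):
            region_chains, _ = chain_collinear(by_region[k], config)
            chains.extend(region_chains)
    for chain in chains:
        for prev, cur in zip(chain, chain[1:]):
            dsu.union(index[prev], index[cur])

    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if region_of[a.identifier] != region_of[b.identifier]:
                continue
            overlap = _viral_overlap(a, b)
            if overlap <= config.min_overlap:
                continue
            pid = _pair_identity(a, b, identity_source)
            if pid is None or pid[0] > config.min_identity:
                dsu.union(index[a.identifier], index[b.identifier])

    components: dict[int, list[EveRecord]] = {}
    for i, r in enumerate(ordered):
        components.setdefault(dsu.find(i), []).append(r)
    events = []
    for members in sorted(components.values(),
                          key=lambda ms: (ms[0].chrom, min(m.h_lo for m in ms))):
        touched = sorted({region_of[m.identifier] for m in members})
        events.append(IntegrationEvent(event_id=len(events) + 1, members=members,
                                       regions=[regions[k] for k in touched]))
    return events


def flag_duplicates(records: Sequence[EveRecord],
                    identity_source: Mapping,
                    config: ChainConfig | None = None) -> list[tuple[str, str]]:
    """Symmetric pairs that look like genomic duplications of one insertion.

    Flags pairs at >= ``dup_identity`` % identity whose alignment covers
    >= ``dup_coverage`` of both fragments. Requires sequence identity
    (a pairwise table or sequences); coordinates alone cannot distinguish
    duplication from independent insertion of a similar virus.
    """
    config = config or ChainConfig()
    if identity_source is None:
        raise ValueError("identity required: provide a pairwise table or sequences")
    out: list[tuple[str, str]] = []
    ordered = sorted(records, key=lambda r: r.identifier)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            pid = _pair_identity(a, b, identity_source)
            if pid is None:
                continue
            identity, overlap = pid
            len_a = max(a.length, 1)
            len_b = max(b.length, 1)
            coverage = min(overlap / len_a, overlap / len_b)
            if identity >= config.dup_identity and coverage >= config.dup_coverage:
                out.append((a.identifier, b.identifier))
    return out


def merge_adjacent_events(events: Sequence[IntegrationEvent],
                          orientation_evidence: Mapping[frozenset, str] | None = None,
                          config: ChainConfig | None = None) -> list[IntegrationEvent]:
    """Merge events whose viral footprints abut within ``adjacency_tol``.

    Eligible pairs share a virus and one event's viral span ends within
    ``adjacency_tol`` bases before the other's start (no viral overlap).
    A merge additionally requires ``orientation_evidence`` — keyed by the
    frozenset of the two event ids, value ``"consistent"`` /
    ``"inconsistent"`` / ``"indeterminate"`` — to mark the pair consistent,
    unless ``allow_unevidenced_merge`` is set and no verdict is recorded.
    Output events are renumbered by (chromosome, leftmost host coordinate).
    """
    config = config or ChainConfig()
    orientation_evidence = orientation_evidence or {}
    dsu = _DisjointSet(len(events))
    for i, ea in enumerate(events):
        for j, eb in enumerate(events):
            if i >= j or not (ea.viruses & eb.viruses):
                continue
            sa, ea_end = ea.viral_span
            sb, eb_end = eb.viral_span
            adjacent = (0 <= sb - ea_end <= config.adjacency_tol
                        or 0 <= sa - eb_end <= config.adjacency_tol)
            if not adjacent:
                continue
            verdict = orientation_evidence.get(frozenset((ea.event_id, eb.event_id)))
            if verdict == "consistent" or (verdict is None and config.allow_unevidenced_merge):
                dsu.union(i, j)
    groups: dict[int, list[IntegrationEvent]] = {}
    for i in range(len(events)):
        groups.setdefault(dsu.find(i), []).append(events[i])
    merged = []
    for evs in sorted(groups.values(),
                      key=lambda g: min((m.chrom, m.h_lo) for e in g for m in e.members)):
        members = sorted((m for e in evs for m in e.members),
                         key=lambda m: (m.chrom, m.h_lo))
        regions = [reg for e in evs for reg in e.regions]
        merged.append(IntegrationEvent(event_id=len(merged) + 1, members=members,
                                       regions=regions))
    return merged


def pairwise_identity(seq_a: str, seq_b: str,
                      match: float = 2, mismatch: float = -3,
                      gap_open: float = -5, gap_extend: float = -2,
                      ) -> tuple[float, int]:
    """Best local alignment identity between two sequences.

    Returns (identity %, overlap length in alignment columns) under
    megablast-style scoring. Identity = matches / alignment columns * 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        columns += a1 - a0
        matches += sum(1 for x, y in zip(seq_a[a0:a1].upper(), seq_b[b0:b1].upper()) if x == y)
    # count gap columns between aligned blocks
    blocks_a, blocks_b = aln.aligned
    for k in range(1, len(blocks_a)):
        columns += (blocks_a[k][0] - blocks_a[k - 1][1]) + (blocks_b[k][0] - blocks_b[k - 1][1])
    if columns == 0:
        return 0.0, 0
    return matches / columns * 100.0, columns


def records_from_hits(hits: Iterable[AlignmentHit], prefix: str = "H") -> list[EveRecord]:
    """Adapt alignment hits into EVE fragment records for event inference.

    Hits are numbered in (contig, host position) order; host strand keeps
    the coordinate-order encoding.
    """
    ordered = sorted(hits, key=lambda h: (h.subject_id, h.s_lo, h.s_hi, h.query_acc))
    return [
        EveRecord(identifier=f"{prefix}{i}", virus=h.query_acc,
                  v_start=h.q_start, v_end=h.q_end, chrom=h.subject_id,
                  h_start=h.s_start, h_end=h.s_end,
                  length=abs(h.s_end - h.s_start))
        for i, h in enumerate(ordered, start=1)
    ]


def infer_events_from_hits(hits: Sequence[AlignmentHit],
                           filter_config=None,
                           chain_config: ChainConfig | None = None,
                           ) -> list[IntegrationEvent]:
    """End-to-end grouping from a raw hit table.

    Filters hits, merges footprints into regions, keeps each region's
    representative accession (the one covering the most non-redundant host
    bases), and runs chaining + clustering on the surviving fragments.
    """
    from .filtering import (FilterConfig, build_regions, filter_hits,
                            hit_intervals, select_representative)

    filter_config = filter_config or FilterConfig()
    result = filter_hits(hits, filter_config)
    if not result.retained:
        return []
    regions = build_regions(hit_intervals(result.retained),
                            merge_dist=filter_config.region_merge_dist)
    kept: list[AlignmentHit] = []
    for region in regions:
        rep = select_representative(result.retained, region)
        kept.extend(h for h in result.retained
                    if h.subject_id == region.chrom and h.query_acc == rep
                    and region.start <= h.s_lo and h.s_hi <= region.end)
    records = records_from_hits(kept)
    return infer_events(records, config=chain_config,
                        region_merge_dist=filter_config.region_merge_dist)


def infer_events(records: Sequence[EveRecord],
                 identity_source: Mapping | None = None,
                 config: ChainConfig | None = None,
                 region_merge_dist: int = 100_000,
                 orientation_evidence: Mapping[frozenset, str] | None = None,
                 merge_adjacent: bool = False) -> list[IntegrationEvent]:
    """Full grouping: regions -> collinear chains -> identity clustering,
    optionally followed by evidence-gated adjacency merging."""
    events = identity_cluster(records, chains=None, identity_source=identity_source,
                              config=config, region_merge_dist=region_merge_dist)
    if merge_adjacent:
        events = merge_adjacent_events(events, orientation_evidence, config)
    return events
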