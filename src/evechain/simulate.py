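"""Synthetic integration/fragmentation data with known ground truth.

Emulates the life history that produces fragmented endogenous viral
elements: a contiguous slice of a GC-rich viral genome (~11 kbp, GC ~0.49)
integrates into an AT-rich host genome (GC ~0.38); internal deletions
fragment the insertion, leaving near-equal gap pairs on the viral and host
coordinate systems (host gap = viral gap + Gaussian jitter); sub-slices may
be duplicated to nearby loci with extra divergence; and the whole insertion
decays by neutral substitution to ~70% identity against the extant virus.
A cohort layer adds per-sample read depth with presence/dropout structure,
per-region variant counts, and strand-biased piRNA-sized small-RNA reads.

Every edit is recorded in a :class:`SyntheticTruth` genealogy so the
pipeline's output can be scored against what was actually simulated.
Substitution-only decay keeps coordinate truth exact; indel decay within
fragments is deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import AlignmentHit, DepthTable, SmallRnaAlignment, VariantRecord

__all__ = [
    "SimulationConfig",
    "TruthFragment",
    "SyntheticTruth",
    "CohortData",
    "simulate_genomes",
    "simulate_integration",
    "simulate_hit_table",
    "simulate_cohort",
    "aegypti_like_config",
    "albopictus_like_config",
]

_BASES = np.array(list("ACGT"))
HOST_CONTIG = "hostchr1"
ORGANELLE_CONTIG = "organelle"
VIRUS_ACC = "SIMV_1"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    # genomes
    host_len: int = 1_500_000
    host_gc: float = 0.38
    virus_len: int = 11_000
    virus_gc: float = 0.49
    # integration / fragmentation
    n_events: int = 4
    fragments_per_event: int = 4
    integrated_len: int = 8_000
    min_fragment_len: int = 100
    deletion_len_range: tuple[int, int] = (200, 1_500)
    gap_jitter_sd: float = 50.0
    duplication_prob: float = 0.2
    duplication_dist_range: tuple[int, int] = (5_000, 40_000)
    duplication_extra_divergence: float = 0.01
    decay_divergence: float = 0.30
    min_event_separation: int = 150_000
    random_orientation: bool = True
    # cohort
    n_samples: int = 30
    dropout_prob: float = 0.02
    event_dropout_prob: float = 0.0
    depth_mean: float = 20.0
    depth_dispersion: float = 10.0
    flank_depth_factor: float = 7.0
    flank_len: int = 500
    variant_rate_per_kbp: float = 1.0
    indel_fraction: float = 0.1
    organelle_len: int = 15_000
    smallrna_antisense_bias: float = 0.85
    smallrna_reads_per_event: int = 400

    def __post_init__(self) -> None:
        for p in (self.host_gc, self.virus_gc, self.duplication_prob,
                  self.dropout_prob, self.event_dropout_prob,
                  self.smallrna_antisense_bias, self.indel_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not 0 <= self.decay_divergence <= 0.75:
            raise ValueError("decay_divergence must be in [0, 0.75]")
        if self.host_len < 1_000 or self.virus_len < 1_000:
            raise ValueError("genome lengths must be >= 1000")


@dataclass(frozen=True)
class TruthFragment:
    fragment_id: str
    event_id: int
    v_start: int
    v_end: int
    h_start: int  # orientation-encoding order, as the printed tables use
    h_end: int
    duplicate_of: str | None
    divergence: float

    @property
    def strand(self) -> str:
        return "-" if self.h_start > self.h_end else "+"

    @property
    def h_lo(self) -> int:
        return min(self.h_start, self.h_end)

    @property
    def h_hi(self) -> int:
        return max(self.h_start, self.h_end)

    @property
    def length(self) -> int:
        return self.h_hi - self.h_lo


@dataclass
class SyntheticTruth:
    """Genealogy of every simulated edit, the oracle for recovery tests."""

    fragments: list[TruthFragment]
    n_events: int
    host_len: int
    virus_acc: str = VIRUS_ACC
    host_contig: str = HOST_CONTIG
    event_strand: dict[int, str] = field(default_factory=dict)
    variant_rates: dict[str, float] = field(default_factory=dict)

    def partition(self) -> dict[str, int]:
        return {f.fragment_id: f.event_id for f in self.fragments}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_events": self.n_events,
            "host_len": self.host_len,
            "virus_acc": self.virus_acc,
            "host_contig": self.host_contig,
            "event_strand": self.event_strand,
            "variant_rates": self.variant_rates,
            "fragments": [asdict(f) for f in self.fragments],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def simulate_genomes(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> tuple[str, str]:
    """I.i.d. host and virus sequences at their configured GC contents."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    host = _random_seq(rng, config.host_len, config.host_gc)
    virus = _random_seq(rng, config.virus_len, config.virus_gc)
    return "".join(host), "".join(virus)


def _decay(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with a different one with probability d."""
    if d <= 0:
        return seq.copy()
    codes = np.zeros(len(seq), dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[seq == b] = i
    hit = rng.random(len(seq)) < d
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return _BASES[codes]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return np.array([_COMP[b] for b in seq[::-1]])


def _fragment_layout(slice_len: int, config: SimulationConfig,
                     rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Fragment and deletion lengths partitioning an integrated slice."""
    n_frag = config.fragments_per_event
    if n_frag < 1:
        raise ValueError("fragments_per_event must be >= 1")
    for _ in range(100):
        dels = [int(rng.integers(*config.deletion_len_range, endpoint=True))
                for _ in range(n_frag - 1)]
        remaining = slice_len - sum(dels)
        if remaining >= n_frag * config.min_fragment_len:
            break
    else:
        raise ValueError("cannot fit fragments: integrated_len too small for the deletion model")
    extra = remaining - n_frag * config.min_fragment_len
    cuts = np.sort(rng.integers(0, extra + 1, size=n_frag - 1)) if n_frag > 1 else np.array([], dtype=int)
    shares = np.diff(np.concatenate([[0], cuts, [extra]]))
    frags = [config.min_fragment_len + int(s) for s in shares]
    return frags, dels


def simulate_integration(host: str, virus: str, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[str, SyntheticTruth]:
    """Insert, fragment, duplicate and decay viral slices in the host.

    Each of the ``n_events`` insertions receives a contiguous viral slice,
    internal deletions that replace viral sequence with host-like spacers
    of near-equal length (gap jitter ~ N(0, gap_jitter_sd)), optionally a
    duplicated sub-slice placed within the same locus neighbourhood with
    extra divergence, and substitution decay at ``decay_divergence``.
    Insertion sites are drawn pairwise at least ``min_event_separation``
    apart (re-drawn up to a retry limit).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    host_arr = np.array(list(host))
    virus_arr = np.array(list(virus))
    K = config.n_events
    if K < 1:
        raise ValueError("n_events must be >= 1")
    if config.integrated_len > len(virus):
        raise ValueError("integrated slice longer than the virus")

    # spacing transform: subtract the mandatory separations, draw sorted
    # uniforms in the slack, then add the separations back
    sep = config.min_event_separation
    margin = sep
    slack = (len(host_arr) - 2 * margin) - (K - 1) * sep
    if slack < 0:
        raise ValueError("could not place non-overlapping insertion sites; host too short")
    sites = np.sort(rng.integers(0, slack + 1, size=K)) + margin + np.arange(K) * sep

    fragments: list[TruthFragment] = []
    event_strand: dict[int, str] = {}
    pieces: list[np.ndarray] = []
    cursor = 0  # position in original host consumed so far
    out_len = 0  # length of modified host emitted so far

    for k, site in enumerate(sites, start=1):
        pieces.append(host_arr[cursor:site])
        out_len += site - cursor
        cursor = site

        v0 = int(rng.integers(0, len(virus_arr) - config.integrated_len + 1))
        frag_lens, del_lens = _fragment_layout(config.integrated_len, config, rng)

        # build the inserted block and per-fragment offsets within it
        block_parts: list[np.ndarray] = []
        local: list[tuple[int, int, int, int]] = []  # (v_start, v_end, off_lo, off_hi) 0-based
        v_cursor = v0
        off = 0
        for i, fl in enumerate(frag_lens):
            frag_seq = _decay(virus_arr[v_cursor:v_cursor + fl], config.decay_divergence, rng)
            block_parts.append(frag_seq)
            local.append((v_cursor, v_cursor + fl - 1, off, off + fl - 1))
            off += fl
            v_cursor += fl
            if i < len(del_lens):
                g_v = del_lens[i]
                g_h = max(0, g_v + int(round(rng.normal(0, config.gap_jitter_sd))))
                block_parts.append(_random_seq(rng, g_h, config.host_gc))
                off += g_h
                v_cursor += g_v

        dup_of: int | None = None
        if rng.random() < config.duplication_prob:
            j = int(rng.integers(0, len(frag_lens)))
            spacer = int(rng.integers(*config.duplication_dist_range, endpoint=True))
            block_parts.append(_random_seq(rng, spacer, config.host_gc))
            off += spacer
            src_seq = block_parts[2 * j]  # fragments sit at even part indices
            dup_seq = _decay(src_seq, config.duplication_extra_divergence, rng)
            block_parts.append(dup_seq)
            local.append((local[j][0], local[j][1], off, off + len(dup_seq) - 1))
            dup_of = j
            off += len(dup_seq)

        block = np.concatenate(block_parts)
        strand = "-" if (config.random_orientation and rng.random() < 0.5) else "+"
        if strand == "-":
            block = _revcomp(block)
        event_strand[k] = strand
        base = out_len  # 0-based start of the block in the modified host
        for i, (vs, ve, lo, hi) in enumerate(local):
            if strand == "+":
                h_start, h_end = base + lo + 1, base + hi + 1
            else:
                # block reversed: local offset o maps to base + (len(block)-1-o)
                h_start = base + (len(block) - 1 - lo) + 1
                h_end = base + (len(block) - 1 - hi) + 1
            is_dup = dup_of is not None and i == len(local) - 1
            fragments.append(TruthFragment(
                fragment_id=f"E{k}F{i + 1}" if not is_dup else f"E{k}D1",
                event_id=k, v_start=int(vs) + 1, v_end=int(ve) + 1,
                h_start=int(h_start), h_end=int(h_end),
                duplicate_of=f"E{k}F{dup_of + 1}" if is_dup else None,
                divergence=config.decay_divergence + (config.duplication_extra_divergence if is_dup else 0.0),
            ))
        pieces.append(block)
        out_len += len(block)

    pieces.append(host_arr[cursor:])
    out_len += len(host_arr) - cursor
    modified = "".join(np.concatenate(pieces))
    truth = SyntheticTruth(fragments=fragments, n_events=K, host_len=int(out_len),
                           event_strand=event_strand)
    return modified, truth


def simulate_hit_table(truth: SyntheticTruth, config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       min_frag: int = 50,
                       identity_noise_sd: float = 1.0,
                       support_accessions: Sequence[str] = (VIRUS_ACC, "SIMV_2", "SIMV_3"),
                       n_decoys: int = 20,
                       decoy_evalue: float = 1e-5) -> list[AlignmentHit]:
    """Emit an alignment-hit table from the truth genealogy.

    Stands in for the homology search: each surviving fragment of at least
    ``min_frag`` bases yields one hit per supporting viral accession
    (related viruses align over the same locus), with exact coordinates
    and identity 100(1 - divergence) plus Gaussian noise. Decoy hits from
    unrelated single viruses land outside the true loci, giving the
    multi-virus support filter something to remove.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    hits: list[AlignmentHit] = []
    for f in truth.fragments:
        span = f.h_hi - f.h_lo + 1
        if span < min_frag:
            continue
        for acc in support_accessions:
            ident = float(np.clip(100 * (1 - f.divergence) + rng.normal(0, identity_noise_sd), 0, 100))
            hits.append(AlignmentHit(
                query_acc=acc, subject_id=truth.host_contig,
                identity_pct=ident, aln_len=span,
                mismatches=int(round(span * f.divergence)), gap_opens=0,
                q_start=f.v_start, q_end=f.v_end,
                s_start=f.h_start, s_end=f.h_end,
                evalue=1e-30, bitscore=2.0 * span,
            ))
    # decoys avoid the true loci and each other, so each stays single-accession
    occupied = sorted((f.h_lo, f.h_hi) for f in truth.fragments)
    for i in range(n_decoys):
        for _ in range(100):
            length = int(rng.integers(100, 500))
            pos = int(rng.integers(1, truth.host_len - length))
            if all(pos + length < lo - 1_000 or pos > hi + 1_000 for lo, hi in occupied):
                occupied.append((pos, pos + length - 1))
                break
        else:
            continue
        hits.append(AlignmentHit(
            query_acc=f"DECOY_{i + 1}", subject_id=truth.host_contig,
            identity_pct=float(rng.uniform(65, 75)), aln_len=length,
            mismatches=int(length * 0.3), gap_opens=0,
            q_start=1, q_end=length,
            s_start=pos, s_end=pos + length - 1,
            evalue=decoy_evalue, bitscore=1.5 * length,
        ))
    return hits


@dataclass
class CohortData:
    depths: dict[str, DepthTable]
    variants: list[VariantRecord]
    small_rna: list[SmallRnaAlignment]
    true_presence: dict[str, dict[str, bool]]  # fragment_id -> sample -> present


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_cohort(truth: SyntheticTruth, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    dropout: Mapping[str, float] | float | None = None,
                    ) -> CohortData:
    """Per-sample depth, variant and small-RNA data over the true loci.

    A fragment present in a sample receives one negative-binomial depth
    draw applied across its footprint (read depth varies between loci and
    libraries far more than base-to-base); flanks get
    ``flank_depth_factor`` times that depth, emulating the transposon-rich
    borders. Dropped fragments get depth 0. Variants arrive as a Poisson
    count at ``variant_rate_per_kbp`` per fragment and sample; small-RNA
    reads cover each event's span with the configured antisense bias.
    ``dropout`` may be a scalar or a per-fragment mapping and defaults to
    ``config.dropout_prob``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    if dropout is None:
        dropout = config.dropout_prob

    def drop_p(fragment_id: str) -> float:
        if isinstance(dropout, Mapping):
            return dropout.get(fragment_id, config.dropout_prob)
        return float(dropout)

    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    depths: dict[str, DepthTable] = {}
    variants: list[VariantRecord] = []
    presence: dict[str, dict[str, bool]] = {f.fragment_id: {} for f in truth.fragments}

    org_pos = np.arange(1, config.organelle_len + 1)
    for s in samples:
        table = DepthTable(sample_id=s)
        org_depth = max(_nb_draw(rng, config.depth_mean, config.depth_dispersion), 1)
        table.add_contig(ORGANELLE_CONTIG, org_pos, np.full(config.organelle_len, org_depth))

        pos_chunks: list[np.ndarray] = []
        dep_chunks: list[np.ndarray] = []
        # whole-event loss (one deletion removes every fragment it carries)
        event_lost = {k: rng.random() < config.event_dropout_prob
                      for k in range(1, truth.n_events + 1)}
        for f in truth.fragments:
            present = (not event_lost[f.event_id]) and rng.random() >= drop_p(f.fragment_id)
            presence[f.fragment_id][s] = present
            if not present:
                continue
            d = _nb_draw(rng, config.depth_mean, config.depth_dispersion)
            fd = int(d * config.flank_depth_factor)
            left = np.arange(max(1, f.h_lo - config.flank_len), f.h_lo)
            body = np.arange(f.h_lo, f.h_hi + 1)
            right = np.arange(f.h_hi + 1, min(truth.host_len, f.h_hi + config.flank_len) + 1)
            pos_chunks += [left, body, right]
            dep_chunks += [np.full(left.size, fd), np.full(body.size, d), np.full(right.size, fd)]
            n_var = rng.poisson(config.variant_rate_per_kbp * f.length / 1000.0)
            span = f.h_hi - f.h_lo + 1
            for off in sorted(rng.choice(span, size=min(n_var, span), replace=False)):
                p = f.h_lo + int(off)
                if rng.random() < config.indel_fraction:
                    variants.append(VariantRecord(truth.host_contig, p, "A", "AT", "InDel", s))
                else:
                    variants.append(VariantRecord(truth.host_contig, p, "A", "C", "SNP", s))
        if pos_chunks:
            pos_all = np.concatenate(pos_chunks)
            dep_all = np.concatenate(dep_chunks)
            uniq, inv = np.unique(pos_all, return_inverse=True)
            dep = np.zeros(uniq.size, dtype=np.int64)
            np.maximum.at(dep, inv, dep_all)  # overlapping flanks keep the deeper draw
            table.add_contig(truth.host_contig, uniq, dep)
        else:
            # sample lost every fragment: the contig is present but uncovered
            table.add_contig(truth.host_contig,
                             np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        depths[s] = table

    small_rna: list[SmallRnaAlignment] = []
    for k in range(1, truth.n_events + 1):
        members = [f for f in truth.fragments if f.event_id == k]
        lo = min(f.h_lo for f in members)
        hi = max(f.h_hi for f in members)
        eve_strand = truth.event_strand.get(k, "+")
        anti = "-" if eve_strand == "+" else "+"
        for _ in range(config.smallrna_reads_per_event):
            strand = anti if rng.random() < config.smallrna_antisense_bias else eve_strand
            small_rna.append(SmallRnaAlignment(
                chrom=truth.host_contig, pos=int(rng.integers(lo, hi + 1)),
                strand=strand, read_length=int(rng.integers(25, 30))))
    return CohortData(depths=depths, variants=variants, small_rna=small_rna,
                      true_presence=presence)


def aegypti_like_config(**overrides) -> SimulationConfig:
    """Conserved-cohort preset: the core element set is carried by nearly
    every sample, with rare fragment- and event-level dropouts."""
    return replace(SimulationConfig(), dropout_prob=0.02, event_dropout_prob=0.01,
                   **overrides)


def albopictus_like_config(**overrides) -> SimulationConfig:
    """Patchy-cohort preset: heavy fragment- and event-level dropout
    producing strong between-sample heterogeneity."""
    return replace(SimulationConfig(), dropout_prob=0.40, event_dropout_prob=0.15,
                   **overrides)
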