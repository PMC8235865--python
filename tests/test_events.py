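import numpy as np
import pytest
from Bio import Align

from evechain.events import (ChainConfig, chain_collinear, compute_gap,
                             flag_duplicates, identity_cluster, infer_events,
                             merge_adjacent_events, pairwise_identity)
from evechain.io import EveRecord

EXPECTED_FIVE = [
    ["AE1.1"],
    [f"AE{i}.2" for i in range(2, 16)],
    ["AE16.2", "AE17.2"],
    [f"AE{i}.3" for i in range(18, 26)],
    [f"AE{i}.4" for i in range(26, 30)],
]


def _rec(ident, vs, ve, chrom="c", hs=None, he=None, virus="V"):
    hs = hs if hs is not None else vs + 1000
    he = he if he is not None else ve + 1000
    return EveRecord(ident, virus, vs, ve, chrom, hs, he, abs(he - hs))


class TestComputeGap:
    # every printed gap pair of the curated table, plus/minus strand blocks alike
    PRINTED = [
        ("AE2.2", "AE3.2", 359, 260),
        ("AE3.2", "AE4.2", 193, 172),
        ("AE4.2", "AE5.2", 1387, 1338),
        ("AE5.2", "AE6.2", 407, 395),
        ("AE6.2", "AE7.2", 601, 589),
        ("AE8.2", "AE9.2", 359, 260),
        ("AE14.2", "AE15.2", 3957, 5898),
        ("AE18.3", "AE19.3", 295, 481),
        ("AE19.3", "AE20.3", 592, 349),
        ("AE20.3", "AE21.3", 574, 545),
        ("AE22.3", "AE23.3", 295, 481),
        ("AE23.3", "AE24.3", 592, 349),
        ("AE24.3", "AE25.3", 574, 545),
    ]

    @pytest.mark.parametrize("a,b,g_v,g_h", PRINTED)
    def test_printed_gap_pairs(self, aaegl5_by_id, a, b, g_v, g_h):
        gap = compute_gap(aaegl5_by_id[a], aaegl5_by_id[b])
        assert (gap.viral_gap, gap.host_gap) == (g_v, g_h)

    def test_different_contigs_error(self, aaegl5_by_id):
        with pytest.raises(ValueError, match="different contigs"):
            compute_gap(aaegl5_by_id["AE1.1"], aaegl5_by_id["AE2.2"])

    def test_overlapping_viral_intervals_give_negative_gap(self, aaegl5_by_id):
        gap = compute_gap(aaegl5_by_id["AE26.4"], aaegl5_by_id["AE27.4"])
        assert gap.viral_gap < 0


class TestChaining:
    def test_plus_strand_chain_of_six(self, aaegl5_records):
        block = [r for r in aaegl5_records
                 if r.identifier in {f"AE{i}.2" for i in range(2, 8)}]
        chains, evidence = chain_collinear(block)
        assert chains == [[f"AE{i}.2" for i in range(2, 8)]]
        assert all(e.kind == "collinear" for e in evidence)

    def test_minus_strand_chain_of_four(self, aaegl5_records):
        """The three reverse-block gap pairs each pass the default rule."""
        block = [r for r in aaegl5_records
                 if r.identifier in {"AE18.3", "AE19.3", "AE20.3", "AE21.3"}]
        cfg = ChainConfig()
        ordered = sorted(block, key=lambda r: r.h_lo)
        for a, b in zip(ordered, ordered[1:]):
            gap = compute_gap(a, b)
            assert abs(gap.viral_gap - gap.host_gap) <= cfg.gap_tolerance(
                gap.viral_gap, gap.host_gap)
        chains, _ = chain_collinear(block)
        assert chains == [["AE18.3", "AE19.3", "AE20.3", "AE21.3"]]

    def test_discordant_gaps_not_linked(self):
        a = _rec("a", 100, 200, hs=1000, he=1100)
        b = _rec("b", 300, 400, hs=5100, he=5200)  # g_v 100, g_h 4000
        chains, evidence = chain_collinear([a, b])
        assert chains == [["a"], ["b"]] and evidence == []

    def test_gap_tolerance_honoured_on_every_link(self, aaegl5_records):
        cfg = ChainConfig()
        by_id = {r.identifier: r for r in aaegl5_records}
        for region_ids in EXPECTED_FIVE:
            _, evidence = chain_collinear([by_id[i] for i in region_ids], cfg)
            for link in evidence:
                gap = compute_gap(by_id[link.pair[0]], by_id[link.pair[1]])
                assert abs(gap.viral_gap - gap.host_gap) <= cfg.gap_tolerance(
                    gap.viral_gap, gap.host_gap)


class TestIdentityCluster:
    def test_aaegl5_five_event_partition(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        assert [e.member_ids for e in events] == EXPECTED_FIVE

    def test_overlap_below_threshold_not_merged(self):
        a = _rec("a", 100, 200, hs=1000, he=1100)
        b = _rec("b", 160, 300, hs=9000, he=9140)  # viral overlap 40 < 50
        events = identity_cluster([a, b])
        assert [e.member_ids for e in events] == [["a"], ["b"]]

    def test_partition_property(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        seen = [m for e in events for m in e.member_ids]
        assert sorted(seen) == sorted(r.identifier for r in aaegl5_records)

    def test_order_invariance(self, aaegl5_records):
        rng = np.random.default_rng(3)
        shuffled = [aaegl5_records[i] for i in rng.permutation(len(aaegl5_records))]
        assert [e.member_ids for e in infer_events(shuffled)] == EXPECTED_FIVE

    def test_identity_table_gates_merges(self):
        a = _rec("a", 100, 400, hs=1000, he=1300)
        b = _rec("b", 100, 400, hs=5000, he=5300)
        low = {frozenset(("a", "b")): (80.0, 300)}
        high = {frozenset(("a", "b")): (98.0, 300)}
        assert len(identity_cluster([a, b], identity_source=low)) == 2
        assert len(identity_cluster([a, b], identity_source=high)) == 1

    def test_unknown_identifier_in_table_errors(self):
        a = _rec("a", 100, 400)
        with pytest.raises(KeyError, match="unknown identifier"):
            identity_cluster([a], identity_source={frozenset(("a", "ghost")): (99.0, 100)})

    def test_brute_force_oracle_equivalence(self):
        """On small random inputs the partition equals the transitive closure
        of the pairwise link predicates, computed naively."""
        cfg = ChainConfig()
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            records = []
            for i in range(n):
                vs = int(rng.integers(1, 5000))
                ve = vs + int(rng.integers(50, 1200))
                hs = int(rng.integers(1, 50_000))
                he = hs + (ve - vs) + int(rng.integers(-20, 20))
                records.append(_rec(f"r{i}", vs, ve, chrom="c", hs=hs, he=max(he, hs + 1)))
            events = identity_cluster(records, config=cfg, region_merge_dist=10_000)

            # independent path: explicit edge list + union by repeated sweeps
            from evechain.filtering import build_regions
            regions = build_regions([(r.chrom, r.h_lo, r.h_hi, "x") for r in records],
                                    merge_dist=10_000)
            def region_idx(r):
                return next(k for k, reg in enumerate(regions)
                            if reg.start <= r.h_lo and r.h_hi <= reg.end)
            edges = set()
            for k in range(len(regions)):
                members = sorted((r for r in records if region_idx(r) == k),
                                 key=lambda r: (r.h_lo, r.h_hi, r.identifier))
                _, evidence = chain_collinear(members, cfg)
                edges |= {e.pair for e in evidence}
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        ov = min(a.v_end, b.v_end) - max(a.v_start, b.v_start)
                        if ov > cfg.min_overlap:
                            edges.add((a.identifier, b.identifier))
            groups = {r.identifier: {r.identifier} for r in records}
            changed = True
            while changed:
                changed = False
                for x, y in edges:
                    if groups[x] is not groups[y]:
                        merged = groups[x] | groups[y]
                        for m in merged:
                            groups[m] = merged
                        changed = True
            oracle = {frozenset(g) for g in groups.values()}
            assert {frozenset(e.member_ids) for e in events} == oracle


class TestDuplicatesAndMerging:
    def test_identical_sequences_flagged(self):
        a = _rec("a", 1, 300, hs=1000, he=1300)
        b = _rec("b", 1, 300, hs=9000, he=9300)
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 300))
        pairs = flag_duplicates([a, b], {"a": seq, "b": seq})
        assert pairs == [("a", "b")]

    def test_one_percent_divergence_full_length_flagged(self):
        rng = np.random.default_rng(1)
        seq = list(rng.choice(list("ACGT"), 300))
        mutated = seq.copy()
        for pos in (50, 150, 250):  # exactly 1% interior substitutions
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        a = _rec("a", 1, 300, hs=1000, he=1300)
        b = _rec("b", 1, 300, hs=9000, he=9300)
        assert flag_duplicates([a, b], {"a": "".join(seq), "b": "".join(mutated)}) \
            == [("a", "b")]

    def test_95_percent_identity_not_flagged(self):
        rng = np.random.default_rng(2)
        seq = list(rng.choice(list("ACGT"), 300))
        mutated = seq.copy()
        for pos in range(10, 300, 20):  # 5% interior substitutions
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        a = _rec("a", 1, 300, hs=1000, he=1300)
        b = _rec("b", 1, 300, hs=9000, he=9300)
        assert flag_duplicates([a, b], {"a": "".join(seq), "b": "".join(mutated)}) == []

    def test_coordinate_only_mode_errors(self):
        a = _rec("a", 1, 300)
        with pytest.raises(ValueError, match="identity required"):
            flag_duplicates([a], None)

    def test_adjacent_events_merge_with_consistent_orientation(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        merged = merge_adjacent_events(events, {frozenset((2, 3)): "consistent"})
        assert len(merged) == 4
        chr2 = next(e for e in merged if "AE2.2" in e.member_ids)
        assert "AE16.2" in chr2.member_ids and "AE17.2" in chr2.member_ids

    def test_distant_viral_spans_unmerged(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        merged = merge_adjacent_events(events, {frozenset((4, 5)): "consistent"})
        # events 4 and 5 overlap on the virus; no adjacency, no merge
        assert len(merged) == 5

    def test_inconsistent_orientation_blocks_merge(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        merged = merge_adjacent_events(events, {frozenset((2, 3)): "inconsistent"})
        assert len(merged) == 5

    def test_no_evidence_no_merge_by_default(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        assert len(merge_adjacent_events(events)) == 5

    def test_merging_only_coarsens_partition(self, aaegl5_records):
        events = infer_events(aaegl5_records)
        merged = merge_adjacent_events(events, {frozenset((2, 3)): "consistent"})
        fine = {frozenset(e.member_ids) for e in events}
        coarse = {frozenset(e.member_ids) for e in merged}
        for block in fine:
            assert any(block <= c for c in coarse)


def _sw_score_oracle(a, b, match=2, mismatch=-3, open_=-5, extend=-2):
    """Exhaustive affine-gap local alignment DP, independent of the aligner."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + extend)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + extend)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 25
        identity, overlap = pairwise_identity(seq, seq)
        assert identity == 100.0 and overlap == 100

    def test_six_substitutions_in_100(self):
        seq = list("ACGT" * 25)
        other = seq.copy()
        for pos in (10, 25, 40, 55, 70, 85):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        identity, overlap = pairwise_identity("".join(seq), "".join(other))
        assert identity == pytest.approx(94.0)
        assert overlap == 100

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_identity("", "ACGT")

    @pytest.mark.parametrize("d", [0.05, 0.1, 0.2])
    def test_identity_tracks_known_divergence(self, d):
        rng = np.random.default_rng(int(d * 100))
        seq = rng.choice(list("ACGT"), 200)
        other = seq.copy()
        hit = rng.random(200) < d
        codes = {"A": 0, "C": 1, "G": 2, "T": 3}
        bases = "ACGT"
        for i in np.nonzero(hit)[0]:
            other[i] = bases[(codes[other[i]] + int(rng.integers(1, 4))) % 4]
        identity, _ = pairwise_identity("".join(seq), "".join(other))
        realized = 100 * (1 - hit.mean())
        assert identity == pytest.approx(realized, abs=2.0)

    def test_local_score_matches_exhaustive_dp(self):
        rng = np.random.default_rng(5)
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 60))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 60))))
            assert aligner.score(a, b) == pytest.approx(_sw_score_oracle(a, b))
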