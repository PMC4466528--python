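"""Overlap detection, greedy layout and consensus, checked against a
brute-force all-offset oracle and template reconstruction."""

import numpy as np
import pytest

from ghrecover.assembly import (
    consensus_column,
    find_overlaps,
    greedy_assemble,
)
from ghrecover.types import Read, revcomp

import oracles
from conftest import random_dna, tiling_reads


def _mutate(seq: str, positions: list[int]) -> str:
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = rot[s[p]]
    return "".join(s)


class TestFindOverlaps:
    def test_exact_50nt_suffix_prefix_overlap(self, cfg, rng):
        t = random_dna(rng, 150)
        a, b = Read(id="a", seq=t[:100]), Read(id="b", seq=t[50:150])
        (ov,) = find_overlaps([a, b], cfg)
        assert (ov.length, ov.identity) == (50, 1.0)
        assert ov.offset == 50 and ov.orientation == "+"

    def test_39nt_overlap_rejected_40_accepted(self, cfg, rng):
        t = random_dna(rng, 400)
        a = Read(id="a", seq=t[:200])
        b39 = Read(id="b", seq=t[161:361])
        b40 = Read(id="b", seq=t[160:360])
        assert find_overlaps([a, b39], cfg) == []
        assert len(find_overlaps([a, b40], cfg)) == 1

    def test_identity_boundary_90_accepted_88_rejected(self, cfg, rng):
        t = random_dna(rng, 160)
        a = Read(id="a", seq=t[:110])
        # 50-nt overlap with 5 mismatches = 0.90; 6 mismatches = 0.88
        tail5 = _mutate(t[60:110], [3, 13, 23, 33, 43])
        tail6 = _mutate(t[60:110], [3, 11, 19, 27, 35, 43])
        b5 = Read(id="b", seq=tail5 + random_dna(rng, 60))
        b6 = Read(id="b", seq=tail6 + random_dna(rng, 60))
        ovs5 = find_overlaps([a, b5], cfg)
        assert len(ovs5) == 1 and ovs5[0].identity == pytest.approx(0.90)
        assert find_overlaps([a, b6], cfg) == []

    def test_reverse_complement_overlap_found(self, cfg, rng):
        t = random_dna(rng, 150)
        a = Read(id="a", seq=t[:100])
        b = Read(id="b", seq=revcomp(t[55:150]))
        (ov,) = find_overlaps([a, b], cfg)
        assert ov.orientation == "-" and ov.length == 45

    @pytest.mark.parametrize("n_reads,seed", [(8, 0), (12, 1), (15, 2)])
    def test_matches_brute_force_all_offset_oracle(self, cfg, n_reads, seed):
        """On small error-free tilings, every reported overlap matches the
        naive all-offset scan (and vice versa)."""
        rng = np.random.default_rng(seed)
        t = random_dna(rng, 100 + 56 * (n_reads - 1))
        reads = tiling_reads(t, 100, 56)[:n_reads]
        got = {(ov.read_a, ov.read_b, ov.orientation):
               (ov.offset, ov.length, round(ov.identity, 6))
               for ov in find_overlaps(reads, cfg, method="exhaustive")}
        byid = {r.id: r.seq for r in reads}
        expected = {}
        ids = sorted(byid)
        for i, aid in enumerate(ids):
            for bid in ids[i + 1:]:
                for orient in "+-":
                    bseq = byid[bid] if orient == "+" else revcomp(byid[bid])
                    best = oracles.overlap_oracle(
                        byid[aid], bseq, cfg.min_overlap_len,
                        cfg.min_overlap_identity)
                    if best:
                        expected[(aid, bid, orient)] = (
                            best[0], best[1], round(best[2], 6))
        assert got == expected

    def test_seeded_agrees_with_exhaustive_on_error_free_tiling(self, cfg, rng):
        t = random_dna(rng, 3000)
        reads = tiling_reads(t, 120, 60, orientations="+-")
        a = set((o.read_a, o.read_b, o.orientation, o.offset, o.length)
                for o in find_overlaps(reads, cfg, method="exhaustive"))
        b = set((o.read_a, o.read_b, o.orientation, o.offset, o.length)
                for o in find_overlaps(reads, cfg, method="seeded"))
        assert a == b

    def test_fewer_than_two_reads(self, cfg):
        assert find_overlaps([], cfg) == []
        assert find_overlaps([Read(id="a", seq="ACGT" * 30)], cfg) == []


class TestConsensusColumn:
    def test_simple_majority(self):
        assert consensus_column({"A": 3, "G": 1}) == "A"

    def test_quality_breaks_count_tie(self):
        assert consensus_column({"A": (2, 40.0), "G": (2, 60.0)}) == "G"

    def test_lexicographic_tie_break(self):
        assert consensus_column({"A": 1, "C": 1}) == "A"
        assert consensus_column({"T": 2, "G": 2}) == "G"

    def test_n_only_wins_alone(self):
        assert consensus_column({"N": 5, "A": 1}) == "A"
        assert consensus_column({"N": 3}) == "N"


class TestGreedyAssemble:
    def test_26_tiling_reads_reconstruct_template_exactly(self, cfg, rng):
        template = random_dna(rng, 1500)
        reads = tiling_reads(template, 100, 56)
        assert len(reads) == 26
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        assert len(contigs) == 1
        assert contigs[0].seq == template

    def test_single_read_becomes_singleton_contig(self, cfg, rng):
        r = Read(id="solo", seq=random_dna(rng, 120))
        (c,) = greedy_assemble([r], [], cfg)
        assert c.seq == r.seq
        assert [p.read_id for p in c.placements] == ["solo"]

    def test_two_unrelated_templates_give_two_contigs(self, cfg, rng):
        t1, t2 = random_dna(rng, 600), random_dna(rng, 600)
        reads = (tiling_reads(t1, 100, 50, prefix="a") +
                 tiling_reads(t2, 100, 50, prefix="b"))
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        assert len(contigs) == 2
        assert {c.seq for c in contigs} == {t1, t2}

    def test_mixed_orientation_reads_reconstruct_template(self, cfg, rng):
        template = random_dna(rng, 900)
        reads = tiling_reads(template, 120, 60, orientations="+-")
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        assert len(contigs) == 1
        assert contigs[0].seq in (template, revcomp(template))

    def test_read_conservation(self, cfg, rng):
        t1, t2 = random_dna(rng, 500), random_dna(rng, 700)
        reads = (tiling_reads(t1, 90, 45, prefix="a") +
                 tiling_reads(t2, 90, 45, prefix="b") +
                 [Read(id="lone", seq=random_dna(rng, 80))])
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        placed = sorted(p.read_id for c in contigs for p in c.placements)
        assert placed == sorted(r.id for r in reads)

    def test_determinism_byte_identical(self, cfg, rng):
        template = random_dna(rng, 1200)
        reads = tiling_reads(template, 110, 55, orientations="+-")
        runs = []
        for _ in range(2):
            contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
            runs.append([(c.id, c.seq, tuple(c.placements)) for c in contigs])
        assert runs[0] == runs[1]

    def test_consensus_fixes_isolated_read_errors(self, cfg, rng):
        """At >= 8x coverage with one erroneous read, the consensus still
        equals the template."""
        template = random_dna(rng, 800)
        reads = tiling_reads(template, 100, 12)
        bad = reads[30]
        reads[30] = Read(id=bad.id, seq=_mutate(bad.seq, [50]),
                         sample=bad.sample)
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        assert len(contigs) == 1 and contigs[0].seq == template

    def test_per_sample_counts_sum_to_placements(self, cfg, rng):
        template = random_dna(rng, 700)
        reads = tiling_reads(template, 100, 50, sample="Z7")
        reads += [Read(id=r.id + "x", seq=r.seq, sample="Z8") for r in reads]
        contigs = greedy_assemble(reads, find_overlaps(reads, cfg), cfg)
        for c in contigs:
            assert sum(c.per_sample_reads.values()) == len(c.placements)
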