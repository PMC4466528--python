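"""Recruitment: translated-search scoring, statistics and the seeding
accelerator, checked against independent pure-python dynamic programming."""

import numpy as np
import pytest

from ghrecover.align import best_local, protein_aligner
from ghrecover.recruit import align_translated, recruit_reads
from ghrecover.simulate import SampleSpec, SimConfig, reverse_translate, simulate
from ghrecover.stats import protein_stats
from ghrecover.types import PipelineConfig, Read, ReferenceProtein, revcomp

import oracles
from conftest import random_dna


class TestScoring:
    def test_exact_triplet_scores_blosum_diagonal(self):
        # M=5, K=5, L=4 on the BLOSUM62 diagonal
        hit = best_local("MKL", "MKL", protein_aligner())
        assert hit.score == 14

    def test_poly_lysine_read_vs_lysine_free_protein_has_no_hit(self, rng):
        read = Read(id="r", seq="AAA" * 40)  # poly-K (+ frames), poly-F (-)
        # D, G and P score negatively against both K and F in BLOSUM62
        prot = ReferenceProtein(id="p", family="GH5",
                                seq="".join(rng.choice(list("DGP"), 60)))
        assert oracles.sw_score("K" * 40, prot.seq) == 0.0
        assert oracles.sw_score("F" * 40, prot.seq) == 0.0
        hits = align_translated(read, prot)
        assert not hits

    @pytest.mark.parametrize("trial", range(12))
    def test_aligner_matches_pure_python_dp(self, trial):
        """The C aligner's local score equals an independent affine-gap DP
        (validates the gap-open/extend convention)."""
        rng = np.random.default_rng(500 + trial)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        q = "".join(rng.choice(aas, rng.integers(8, 40)))
        t = "".join(rng.choice(aas, rng.integers(20, 80)))
        expected = oracles.sw_score(q, t)
        hit = best_local(q, t, protein_aligner())
        got = hit.score if hit else 0.0
        assert got == expected

    def test_longer_identical_segment_has_smaller_evalue(self):
        stats = protein_stats(m=10_000, n=10_000)
        al = protein_aligner()
        s100 = best_local("M" * 100, "M" * 100, al).score
        s20 = best_local("M" * 20, "M" * 20, al).score
        assert stats.evalue(s100) < stats.evalue(s20)

    def test_hsp_never_crosses_a_stop(self):
        # frame translation with an internal stop: local alignment must
        # stay on one side of it
        read = Read(id="r", seq="ATGAAACTGTAAATGAAACTG")  # MKL*MKL frame +1
        prot = ReferenceProtein(id="p", family="GH5", seq="MKLWMKLDDDDDDD"
                                + "D" * 20)
        hits = align_translated(read, prot)
        h = [x for x in hits if x.frame == 1]
        assert h and h[0].score == 14  # MKL only, not MKL*MKL


class TestRecruitment:
    def _mini_sim(self, n_reads=120, seed=3, err=0.0):
        from ghrecover.simulate import synthetic_panel

        panel = synthetic_panel(seed, families=("GH5", "GH9"), per_family=1,
                                length_range=(150, 180))
        sc = SimConfig(n_genomes=2, genome_len=3000, genes_per_genome=1,
                       samples=[SampleSpec("Z7", n_reads, (0.5, 0.5))],
                       read_len_mean=250, read_len_sd=50,
                       subst_rate=err, homopolymer_indel_rate=err,
                       rng_seed=seed)
        genomes, reads, truth, panel = simulate(sc, panel)
        return reads, panel

    def test_matches_exhaustive_dp_oracle(self, cfg):
        """Recruited set equals the independent six-frame pure-python SW
        oracle at the inclusive 1e-2 cutoff (small scale)."""
        reads, panel = self._mini_sim(n_reads=60, err=0.003)
        recruited, _ = recruit_reads(reads, panel, cfg)
        expected = oracles.recruit_oracle(reads, panel, cfg.recruit_evalue_max)
        assert {r.id for r in recruited} == expected

    def test_gene_read_recruited_with_true_family(self, cfg, rng):
        prot = ReferenceProtein(id="p1", family="GH5",
                                seq="M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 149)))
        gene = reverse_translate(prot.seq, rng)
        read = Read(id="generead", seq=gene[30:105])  # exact 25-aa match
        noise = Read(id="noise", seq=random_dna(rng, 400))
        recruited, hits = recruit_reads([read, noise], [prot], cfg)
        assert [r.id for r in recruited] == ["generead"]
        assert hits[0].family == "GH5"

    def test_cutoff_is_inclusive_at_exactly_1e_minus_2(self, cfg, rng):
        """A hit whose e-value lands exactly on the cutoff is recruited."""
        prot = ReferenceProtein(id="p1", family="GH5",
                                seq="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200)))
        # borrow a real alignment score, then set the cutoff to exactly
        # that hit's e-value and check it is still recruited
        read = Read(id="r", seq=reverse_translate(prot.seq[50:60], rng)[:30])
        hits = align_translated(read, prot)
        best = max(hits, key=lambda h: h.score)
        from ghrecover.recruit import total_translated_residues
        stats = protein_stats(len(prot.seq), total_translated_residues([read]))
        ev = stats.evalue(best.score)
        cfg_eq = PipelineConfig(recruit_evalue_max=ev, rng_seed=0)
        recruited, _ = recruit_reads([read], [prot], cfg_eq)
        assert [r.id for r in recruited] == ["r"]
        # and a cutoff just below excludes it
        cfg_lt = PipelineConfig(recruit_evalue_max=ev * 0.999, rng_seed=0)
        recruited, _ = recruit_reads([read], [prot], cfg_lt)
        assert recruited == []

    def test_monotone_in_cutoff(self, cfg):
        reads, panel = self._mini_sim(n_reads=40, err=0.01)
        loose = PipelineConfig(recruit_evalue_max=1e-1)
        tight = PipelineConfig(recruit_evalue_max=1e-4)
        r_loose, _ = recruit_reads(reads, panel, loose)
        r_mid, _ = recruit_reads(reads, panel, cfg)
        r_tight, _ = recruit_reads(reads, panel, tight)
        assert {r.id for r in r_tight} <= {r.id for r in r_mid} \
               <= {r.id for r in r_loose}

    def test_strand_symmetry(self, cfg):
        reads, panel = self._mini_sim(n_reads=50, err=0.005)
        flipped = [Read(id=r.id, seq=revcomp(r.seq), sample=r.sample)
                   for r in reads]
        a, _ = recruit_reads(reads, panel, cfg)
        b, _ = recruit_reads(flipped, panel, cfg)
        assert {r.id for r in a} == {r.id for r in b}

    def test_seeded_equals_exhaustive(self, cfg):
        reads, panel = self._mini_sim(n_reads=80, err=0.01)
        s, _ = recruit_reads(reads, panel, cfg, method="seeded")
        e, _ = recruit_reads(reads, panel, cfg, method="exhaustive")
        assert {r.id for r in s} == {r.id for r in e}

    def test_empty_reads_and_empty_panel(self, cfg, small_panel):
        assert recruit_reads([], small_panel, cfg) == ([], [])
        with pytest.raises(ValueError):
            recruit_reads([Read(id="r", seq="ACGT")], [], cfg)

    def test_best_hit_per_protein_kept(self, cfg, rng):
        prot = ReferenceProtein(id="p1", family="GH5",
                                seq="M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 199)))
        gene = reverse_translate(prot.seq, rng)
        read = Read(id="r", seq=gene[:300])
        recruited, hits = recruit_reads([read], [prot], cfg)
        assert len(hits) == 1  # one best HSP for the single (read, protein)
        assert hits[0].read_span[1] <= len(read.seq)
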