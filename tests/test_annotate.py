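"""ORF calling, family assignment and the 16S read screen."""

import numpy as np
import pytest

from ghrecover.annotate import (
    assign_family,
    call_orfs,
    screen_rrna,
    select_gh_contigs,
)
from ghrecover.simulate import reverse_translate
from ghrecover.translate import translate
from ghrecover.types import Contig, Read, ReferenceProtein, revcomp

from conftest import random_dna


def _codons(rng, n):
    """n sense (non-stop) codons."""
    out = []
    while len(out) < n:
        c = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3)])
        if translate(c) not in "*M" or True:
            if translate(c) != "*":
                out.append(c)
    return "".join(out)


class TestCallOrfs:
    def test_120_codon_gene_gives_366nt_orf(self, rng):
        gene = "ATG" + _codons(rng, 120) + "TAA"
        contig = Contig(id="c", seq=random_dna(rng, 90) + gene + random_dna(rng, 90))
        # flanks kept short and stop-rich enough not to host their own ORFs
        orfs = [o for o in call_orfs(contig, min_orf_nt=300) if not o.partial]
        assert any(o.span[1] - o.span[0] == 366 and o.strand == "+"
                   for o in orfs)

    def test_reverse_strand_gives_same_protein(self, rng):
        gene = "ATG" + _codons(rng, 150) + "TGA"
        fwd = Contig(id="f", seq=random_dna(rng, 200) + gene + random_dna(rng, 200))
        rev = Contig(id="r", seq=revcomp(fwd.seq))
        prot_f = {o.protein for o in call_orfs(fwd) if not o.partial}
        prot_r = {o.protein for o in call_orfs(rev) if not o.partial}
        assert prot_f == prot_r
        strands = {o.strand for o in call_orfs(rev) if not o.partial}
        assert "-" in strands or "+" in strands

    def test_only_longest_orf_per_stop_reported(self, rng):
        # two in-frame starts sharing one stop: the earlier start wins
        inner = _codons(rng, 50)
        gene = "ATG" + _codons(rng, 30) + "ATG" + inner + "TAA"
        # embed after a stop so the segment does not touch the edge
        seq = "TAA" + gene + random_dna(rng, 30)
        contig = Contig(id="c", seq=seq)
        orfs = [o for o in call_orfs(contig, min_orf_nt=150)
                if o.strand == "+" and o.span[1] == 3 + len(gene)]
        assert len(orfs) == 1
        assert orfs[0].span[0] == 3  # the first ATG

    def test_partial_orf_at_contig_edge_flagged(self, rng):
        gene_tail = _codons(rng, 120) + "TAA"  # no start codon, runs to a stop
        contig = Contig(id="c", seq=gene_tail)
        orfs = call_orfs(contig, min_orf_nt=300)
        assert any(o.partial for o in orfs)

    def test_every_reported_protein_is_stop_free(self, rng):
        contig = Contig(id="c", seq=random_dna(rng, 3000))
        for o in call_orfs(contig, min_orf_nt=90):
            assert "*" not in o.protein
            assert (o.span[1] - o.span[0]) % 3 == 0


class TestAssignFamily:
    def test_exact_panel_protein_gets_its_family(self, cfg, rng, small_panel):
        prot = small_panel[0]
        gene = reverse_translate(prot.seq, rng)
        contig = Contig(id="c", seq=gene)
        orf = next(o for o in call_orfs(contig) if o.protein == prot.seq)
        ann = assign_family(orf, small_panel, cfg)
        assert ann.family == prot.family
        assert ann.identity == pytest.approx(1.0)

    def test_random_orf_unassigned(self, cfg, rng, small_panel):
        from ghrecover.types import ORF

        orf = ORF(contig_id="c", span=(0, 300), strand="+", frame=1,
                  protein="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100)))
        ann = assign_family(orf, small_panel, cfg)
        assert ann.family == "unassigned"

    def test_tie_broken_by_lexicographic_protein_id(self, cfg):
        from ghrecover.types import ORF

        seq = "M" + "ACDEFGHIKLMNPQRSTVWY" * 5
        twin_b = ReferenceProtein(id="b_twin", family="GH3", seq=seq)
        twin_a = ReferenceProtein(id="a_twin", family="GH3", seq=seq)
        orf = ORF(contig_id="c", span=(0, 3 * len(seq)), strand="+", frame=1,
                  protein=seq)
        ann = assign_family(orf, [twin_b, twin_a], cfg)
        assert ann.best_protein_id == "a_twin"
        # panel order must not matter
        ann2 = assign_family(orf, [twin_a, twin_b], cfg)
        assert ann2.best_protein_id == "a_twin"


class TestSelectGhContigs:
    def test_keeps_only_contigs_with_assigned_orf(self, cfg, rng, small_panel):
        gene = reverse_translate(small_panel[0].seq, rng)
        gh = Contig(id="gh", seq=random_dna(rng, 100) + gene + random_dna(rng, 100))
        junk = Contig(id="junk", seq=random_dna(rng, 1200))
        anns = []
        for c in (gh, junk):
            for orf in call_orfs(c):
                anns.append(assign_family(orf, small_panel, cfg))
        kept = select_gh_contigs([gh, junk], anns)
        assert [c.id for c in kept] == ["gh"]


class TestScreenRrna:
    def _ref(self, rng, n=1200):
        return Read(id="ref16s", seq=random_dna(rng, n))

    def _mutated_fragment(self, rng, ref, start, length, identity):
        frag = list(ref.seq[start:start + length])
        n_mut = round(length * (1 - identity))
        pos = rng.choice(length, size=n_mut, replace=False)
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for p in pos:
            frag[p] = rot[frag[p]]
        return "".join(frag)

    def test_passing_read_retained(self, cfg, rng):
        ref = self._ref(rng)
        frag = self._mutated_fragment(rng, ref, 100, 70, 0.857)  # 70nt, 85.7%
        read = Read(id="hit", seq=frag + random_dna(rng, 200))
        assert [r.id for r in screen_rrna([read], [ref], cfg)] == ["hit"]

    def test_64nt_perfect_match_rejected_65_accepted(self, cfg, rng):
        ref = self._ref(rng)
        r64 = Read(id="r64", seq=ref.seq[200:264])
        r65 = Read(id="r65", seq=ref.seq[200:265])
        kept = screen_rrna([r64, r65], [ref], cfg)
        assert [r.id for r in kept] == ["r65"]

    def test_100nt_79pct_rejected_80pct_accepted(self, cfg, rng):
        """Identity boundary: mutations are spread evenly so that no
        >= 65-column sub-alignment beats the overall identity."""
        ref = self._ref(rng)
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}

        def evenly_mutated(n_mut):
            frag = list(ref.seq[300:400])
            for i in range(n_mut):
                p = round(i * 100 / n_mut)
                frag[p] = rot[frag[p]]
            return "".join(frag)

        r_below = Read(id="r_below", seq=evenly_mutated(22))  # 78%, <80 everywhere
        r80 = Read(id="r80", seq=evenly_mutated(20))  # exactly 80%
        kept = {r.id for r in screen_rrna([r_below, r80], [ref], cfg)}
        assert "r80" in kept and "r_below" not in kept

    def test_reverse_complement_reads_detected(self, cfg, rng):
        ref = self._ref(rng)
        read = Read(id="rc", seq=revcomp(ref.seq[500:600]))
        assert screen_rrna([read], [ref], cfg)

    def test_random_reads_rejected(self, cfg, rng):
        ref = self._ref(rng)
        reads = [Read(id=f"n{i}", seq=random_dna(rng, 300)) for i in range(10)]
        assert screen_rrna(reads, [ref], cfg) == []
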