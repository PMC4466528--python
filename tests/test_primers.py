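"""Primer design constraints and in-silico PCR verdicts."""

import pytest

from ghrecover.primers import (
    PrimerConstraints,
    design_primers,
    insilico_pcr,
    validate_contigs,
    wallace_tm,
)
from ghrecover.types import Contig, PipelineConfig, PrimerPair, revcomp

from conftest import random_dna


class TestWallaceTm:
    def test_balanced_16mer_is_48C(self):
        # 8 A/T + 8 G/C: 2*8 + 4*8 = 48 C, below the 55 C floor
        assert wallace_tm("AAAATTTTGGGGCCCC") == 48.0

    def test_gc_rich_20mer(self):
        assert wallace_tm("G" * 10 + "C" * 10) == 80.0

    def test_admissible_range_example(self):
        # 20-mer with 10 A/T + 10 G/C: 2*10 + 4*10 = 60 C
        assert wallace_tm("ATATATATAT" + "GCGCGCGCGC") == 60.0


class TestDesignPrimers:
    def test_valid_contig_yields_pairs_meeting_all_constraints(self, rng):
        contig = Contig(id="c1", seq=random_dna(rng, 1200))
        res = design_primers(contig, [contig])
        assert res.pairs
        cons = PrimerConstraints()
        for p in res.pairs:
            for primer in (p.fwd, p.rev):
                assert cons.min_len <= len(primer) <= cons.max_len
                gc = (primer.count("G") + primer.count("C")) / len(primer)
                assert cons.gc_min <= gc <= cons.gc_max
                assert cons.tm_min <= wallace_tm(primer) <= cons.tm_max
            assert abs(p.tm_fwd - p.tm_rev) <= cons.tm_diff_max
            assert cons.product_min <= p.product_len <= cons.product_max

    def test_nonspecific_three_prime_end_rejected(self, rng):
        seq = random_dna(rng, 1200)
        # duplicate an internal 200-nt block onto a second contig: every
        # primer whose 3' 15-mer falls in the copied block is non-specific
        other = Contig(id="c2", seq=random_dna(rng, 300) + seq[400:600]
                       + random_dna(rng, 300))
        contig = Contig(id="c1", seq=seq)
        res = design_primers(contig, [contig, other])
        for p in res.pairs:
            fwd_site = p.fwd[-15:]
            assert fwd_site not in other.seq
            assert fwd_site not in revcomp(other.seq)

    def test_hopeless_contig_returns_reason_codes(self):
        contig = Contig(id="c1", seq="AT" * 300)  # Tm always below range
        res = design_primers(contig, [contig])
        assert res.pairs == []
        assert res.reasons  # e.g. tm_fail / gc_fail dominate

    def test_short_contig_is_error(self, rng):
        with pytest.raises(ValueError, match="400"):
            design_primers(Contig(id="c", seq=random_dna(rng, 300)), [])


class TestInsilicoPcr:
    def _setting(self, rng, n=2000):
        template = random_dna(rng, n)
        contig = Contig(id="c1", seq=template[400:1600])
        res = design_primers(contig, [contig])
        assert res.pairs
        return template, contig, res.pairs[0]

    def test_template_containing_contig_validates(self, rng):
        template, contig, pair = self._setting(rng)
        amplicons, verdict = insilico_pcr(pair, [("t", template)],
                                          contig_seq=contig.seq)
        assert verdict == "validated"
        assert len(amplicons) == 1
        assert len(amplicons[0][1]) == pair.product_len

    def test_template_without_sites_not_validated(self, rng):
        _, contig, pair = self._setting(rng)
        other = random_dna(rng, 2000)
        amplicons, verdict = insilico_pcr(pair, [("t", other)],
                                          contig_seq=contig.seq)
        assert amplicons == [] and verdict == "not_validated"

    def test_amplicon_identity_boundary_95(self, rng):
        """An amplicon matching its predicted interval at 94% fails the
        >= 95% rule; at 96% it passes."""
        template, contig, pair = self._setting(rng)
        predicted = contig.seq[pair.fwd_pos:pair.rev_pos + len(pair.rev)]
        inner = predicted[len(pair.fwd):-len(pair.rev)]
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}

        def mutated_template(identity):
            n_mut = round(len(predicted) * (1 - identity))
            body = list(inner)
            pos = rng.choice(len(body), size=n_mut, replace=False)
            for p in pos:
                body[p] = rot[body[p]]
            return pair.fwd + "".join(body) + revcomp(pair.rev)

        _, v94 = insilico_pcr(pair, [("t", mutated_template(0.94))],
                              contig_seq=contig.seq)
        _, v96 = insilico_pcr(pair, [("t", mutated_template(0.96))],
                              contig_seq=contig.seq)
        assert v94 == "not_validated" and v96 == "validated"

    def test_divergent_orientation_yields_no_amplicon(self, rng):
        template = random_dna(rng, 800)
        fwd = "ATGCATGCATGCATGCAT"
        rev = "GGCCGGCCGGCCGGCCGG"
        # place the rev site BEFORE the fwd site: divergent, no product
        t = template[:100] + revcomp(rev) + template[120:400] + fwd \
            + template[420:]
        pair = PrimerPair(contig_id="c", fwd=fwd, rev=rev, fwd_pos=0,
                          rev_pos=500, product_len=520, tm_fwd=58, tm_rev=60)
        amplicons, verdict = insilico_pcr(pair, [("t", t)])
        assert amplicons == []

    def test_two_distinct_amplicons_not_validated(self, rng):
        template, contig, pair = self._setting(rng)
        predicted = contig.seq[pair.fwd_pos:pair.rev_pos + len(pair.rev)]
        variant = pair.fwd + random_dna(rng, len(predicted) - len(pair.fwd)
                                        - len(pair.rev)) + revcomp(pair.rev)
        amplicons, verdict = insilico_pcr(
            pair, [("t1", template), ("t2", variant)], contig_seq=contig.seq)
        assert len({a for _, a in amplicons}) == 2
        assert verdict == "not_validated"


class TestValidateContigs:
    def test_error_free_contigs_all_validate(self, rng):
        cfg = PipelineConfig(rng_seed=5)
        genomes = {f"g{i}": random_dna(rng, 3000) for i in range(3)}
        contigs = [Contig(id=f"c{i}", seq=genomes[f"g{i}"][500:2500])
                   for i in range(3)]
        rows = validate_contigs(contigs, list(genomes.items()), cfg,
                                n_contigs=3)
        assert rows and all(r["verdict"] == "validated" for r in rows)
        assert all(r["amplicon_identity"] >= 0.95 for r in rows)

    def test_selection_is_seeded(self, rng):
        cfg = PipelineConfig(rng_seed=5)
        genomes = {f"g{i}": random_dna(rng, 2000) for i in range(6)}
        contigs = [Contig(id=f"c{i}", seq=genomes[f"g{i}"][200:1600])
                   for i in range(6)]
        r1 = validate_contigs(contigs, list(genomes.items()), cfg, n_contigs=3)
        r2 = validate_contigs(contigs, list(genomes.items()), cfg, n_contigs=3)
        assert [r["contig_id"] for r in r1] == [r["contig_id"] for r in r2]
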