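"""Contig-specific primer design and in-silico PCR validation.

Primer pairs satisfy: length 18-25 nt, GC 40-60%, Wallace-rule melting
temperature 55-65 C with |dTm| <= 5, a product of 100-1500 nt, and a
specificity rule — the 15-nt 3' end of each primer must occur exactly
once (its own site) across the whole contig set, either strand.  The
Wallace rule Tm = 2(A+T) + 4(G+C) keeps the check closed-form and
deterministic, which is all an in-silico validation needs.

In-silico PCR reports every template interval flanked by perfectly
matched primer sites in convergent orientation within the product cap;
a contig is "validated" when exactly one distinct amplicon arises and
it matches the predicted contig interval at >= 95% identity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import nw_identity
from .types import Contig, PipelineConfig, PrimerPair, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 55.0
    tm_max: float = 65.0
    tm_diff_max: float = 5.0
    product_min: int = 100
    product_max: int = 1500
    specificity_k: int = 15  # 3'-end word checked for uniqueness
    end_margin: int = 50  # keep primers off the single-read contig margins


@dataclass
class DesignResult:
    pairs: list[PrimerPair] = field(default_factory=list)
    reasons: Counter = field(default_factory=Counter)


def wallace_tm(seq: str) -> float:
    """Wallace rule 2(A+T) + 4(G+C), valid for <= 25-mers."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / max(len(seq), 1)


def _kmer_census(contigs: list[Contig], k: int) -> Counter:
    census: Counter = Counter()
    for c in contigs:
        for strand_seq in (c.seq, revcomp(c.seq)):
            for i in range(len(strand_seq) - k + 1):
                census[strand_seq[i:i + k]] += 1
    return census


def _candidate_sites(seq: str, census: Counter, cons: PrimerConstraints,
                     reasons: Counter) -> list[tuple[int, int, float]]:
    """(start, length, tm) of admissible primer sites on *seq* (+ strand)."""
    k = cons.specificity_k
    sites = []
    for i in range(cons.end_margin, len(seq) - cons.end_margin):
        for ln in range(cons.min_len, cons.max_len + 1):
            if i + ln > len(seq) - cons.end_margin:
                break
            p = seq[i:i + ln]
            if "N" in p:
                reasons["ambiguous_base"] += 1
                continue
            if not cons.gc_min <= gc_fraction(p) <= cons.gc_max:
                reasons["gc_fail"] += 1
                continue
            tm = wallace_tm(p)
            if not cons.tm_min <= tm <= cons.tm_max:
                reasons["tm_fail"] += 1
                continue
            if census[p[-k:]] != 1:
                reasons["specificity_fail"] += 1
                continue
            sites.append((i, ln, tm))
    return sites


def design_primers(contig: Contig, all_contigs: list[Contig],
                   constraints: PrimerConstraints | None = None,
                   max_pairs: int = 5,
                   _census: Counter | None = None) -> DesignResult:
    """Design contig-specific primer pairs for one contig.

    Specificity is checked against *all_contigs* (which should include
    *contig* itself).  Returns admissible pairs (deterministic order:
    smallest Tm difference, then leftmost, shortest product) and, when
    empty, the censored reason counts.
    """
    cons = constraints or PrimerConstraints()
    if len(contig.seq) < 400:
        raise ValueError(f"contig {contig.id} shorter than 400 nt")
    census = _census if _census is not None else _kmer_census(all_contigs,
                                                              cons.specificity_k)
    result = DesignResult()
    fwd_sites = _candidate_sites(contig.seq, census, cons, result.reasons)
    rc = revcomp(contig.seq)
    rev_sites_rc = _candidate_sites(rc, census, cons, result.reasons)
    L = len(contig.seq)
    # express reverse sites in + strand coordinates
    rev_sites = [(L - (i + ln), ln, tm) for i, ln, tm in rev_sites_rc]
    rev_sites.sort()

    from bisect import bisect_left

    rev_starts = [rj for rj, _, _ in rev_sites]
    candidates = []
    cap = max(200, max_pairs * 40)  # bounded search keeps big contigs cheap
    for fi, fl, ftm in fwd_sites:
        j0 = bisect_left(rev_starts, fi + cons.product_min - cons.max_len)
        for rj, rl, rtm in rev_sites[j0:]:
            product = rj + rl - fi
            if product < cons.product_min:
                continue
            if product > cons.product_max:
                break
            if abs(ftm - rtm) > cons.tm_diff_max:
                result.reasons["tm_pair_fail"] += 1
                continue
            candidates.append((abs(ftm - rtm), fi, product, fl, rj, rl, ftm, rtm))
        if len(candidates) >= cap:
            break
    if not candidates and not result.reasons:
        result.reasons["no_candidate_sites"] += 1
    candidates.sort()
    for dtm, fi, product, fl, rj, rl, ftm, rtm in candidates[:max_pairs]:
        fwd = contig.seq[fi:fi + fl]
        rev = revcomp(contig.seq[rj:rj + rl])
        result.pairs.append(PrimerPair(
            contig_id=contig.id, fwd=fwd, rev=rev, fwd_pos=fi, rev_pos=rj,
            product_len=product, tm_fwd=ftm, tm_rev=rtm))
    return result


def _sites_with_mismatch(pattern: str, seq: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        out = []
        start = 0
        while True:
            i = seq.find(pattern, start)
            if i < 0:
                return out
            out.append(i)
            start = i + 1
    k = len(pattern)
    pa = np.frombuffer(pattern.encode(), dtype=np.uint8)
    sa = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = []
    for i in range(len(seq) - k + 1):
        if np.count_nonzero(sa[i:i + k] != pa) <= max_mismatch:
            out.append(i)
    return out


def insilico_pcr(pair: PrimerPair, templates: list[tuple[str, str]],
                 contig_seq: str | None = None, max_mismatch: int = 0,
                 validation_min_identity: float = 0.95,
                 product_cap: int = 1500
                 ) -> tuple[list[tuple[str, str]], str]:
    """Predict amplicons of *pair* from *templates* ``(id, seq)``.

    An amplicon is the interval between a forward-primer site and a
    reverse-primer site in convergent orientation within *product_cap*
    nt.  Verdict is ``validated`` iff exactly one distinct amplicon
    sequence arises and (when *contig_seq* is given) it matches the
    predicted contig interval at >= *validation_min_identity*.
    """
    amplicons: list[tuple[str, str]] = []
    for tid, tseq in templates:
        for strand, s_seq in (("+", tseq), ("-", revcomp(tseq))):
            f_sites = _sites_with_mismatch(pair.fwd, s_seq, max_mismatch)
            r_sites = _sites_with_mismatch(revcomp(pair.rev), s_seq, max_mismatch)
            for f in f_sites:
                for r in r_sites:
                    end = r + len(pair.rev)
                    if end <= f:
                        continue  # divergent or nested the wrong way
                    if end - f > product_cap:
                        continue
                    amplicons.append((tid, s_seq[f:end]))
    distinct = sorted(set(seq for _, seq in amplicons))
    if len(distinct) != 1:
        return amplicons, "not_validated"
    if contig_seq is not None:
        predicted = contig_seq[pair.fwd_pos:pair.rev_pos + len(pair.rev)]
        ident, _ = nw_identity(distinct[0], predicted)
        if ident < validation_min_identity:
            return amplicons, "not_validated"
    return amplicons, "validated"


def validate_contigs(contigs: list[Contig], templates: list[tuple[str, str]],
                     cfg: PipelineConfig, n_contigs: int = 50,
                     constraints: PrimerConstraints | None = None
                     ) -> list[dict]:
    """Design one primer pair per (seeded-randomly chosen) contig and run
    in-silico PCR against *templates*; mirrors a wet-lab PCR validation.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    eligible = [c for c in contigs if len(c.seq) >= 400]
    chosen_idx = rng.choice(len(eligible), size=min(n_contigs, len(eligible)),
                            replace=False) if eligible else []
    census = _kmer_census(contigs, (constraints or PrimerConstraints()).specificity_k)
    rows = []
    for i in sorted(int(j) for j in chosen_idx):
        c = eligible[i]
        res = design_primers(c, contigs, constraints, max_pairs=1, _census=census)
        if not res.pairs:
            rows.append({"contig_id": c.id, "verdict": "no_primers",
                         "fwd": "", "rev": "", "product_len": 0,
                         "amplicon_identity": 0.0,
                         "reasons": ";".join(f"{k}:{v}" for k, v in
                                             sorted(res.reasons.items()))})
            continue
        pair = res.pairs[0]
        amplicons, verdict = insilico_pcr(
            pair, templates, contig_seq=c.seq,
            validation_min_identity=cfg.validation_min_identity)
        ident = 0.0
        if amplicons:
            predicted = c.seq[pair.fwd_pos:pair.rev_pos + len(pair.rev)]
            ident, _ = nw_identity(sorted(set(a for _, a in amplicons))[0],
                                   predicted)
        rows.append({"contig_id": c.id, "verdict": verdict,
                     "fwd": pair.fwd, "rev": pair.rev,
                     "product_len": pair.product_len,
                     "amplicon_identity": round(ident, 4), "reasons": ""})
    return rows
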