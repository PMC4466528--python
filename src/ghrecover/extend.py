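"""Iterative contig end-extension against the full read pool.

After the recruited reads are assembled, each contig end is extended by
walking into the flanking sequence: pool sequences (all reads, plus
optional whole-metagenome contigs) that overlap an end at the assembly
thresholds (>= 40 nt, >= 90% identity -- reused here, as no separate
cutoffs are defined for this step) and protrude beyond it are collected;
if their protruding parts agree pairwise (identity >= the same
threshold over the shared region) the end grows by their consensus,
otherwise the end is a fork and is flagged ``ambiguous`` with no
extension.  The loop runs to a fixpoint or ``max_extension_iters``.

Candidate discovery is exact-word (28-mer) seeding between the contig
end region and the pool, a fast stand-in for a megablast-style search;
high-identity overlaps are then verified with edlib.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import infix_align, nw_identity, suffix_prefix_align
from .assembly import _rc_codes
from .kmers import KmerIndex, encode, kmer_values
from .types import Contig, Placement, PipelineConfig, Read, revcomp

logger = logging.getLogger(__name__)

EXT_SEED_K = 28
POOL_PREFIX_NT = 140  # indexed prefix of each oriented pool sequence
END_WINDOW_NT = 1000  # contig tail searched for overlap starts


@dataclass(frozen=True)
class EndReport:
    contig_id: str
    end: str  # "5'" or "3'"
    iterations: int
    nt_added: int
    status: str  # fixpoint | ambiguous | max_iters


class ExtensionPool:
    """Seeding index over the pool sequences, built once and reused."""

    def __init__(self, reads: list[Read], contigs: list[Contig] | None = None):
        self.seqs: list[tuple[str, str, str]] = []  # (id, seq, sample)
        for r in reads:
            self.seqs.append((r.id, r.seq, r.sample))
        for c in contigs or []:
            self.seqs.append((c.id, c.seq, ""))
        self.quals: dict[str, list[int] | None] = {r.id: r.qual for r in reads}
        self.samples: dict[str, str] = {sid: smp for sid, _s, smp in self.seqs}
        self.lengths: dict[str, int] = {sid: len(s) for sid, s, _ in self.seqs}
        self.seq_by_id: dict[str, str] = {sid: s for sid, s, _ in self.seqs}
        self.index = KmerIndex(EXT_SEED_K)
        for i, (_, seq, _) in enumerate(self.seqs):
            codes = encode(seq)
            # both orientations: oriented prefix k-mers are what a
            # right-protruding candidate shares with the contig tail
            self.index.add(2 * i, codes, 0, POOL_PREFIX_NT)
            self.index.add(2 * i + 1, _rc_codes(codes), 0, POOL_PREFIX_NT)
        self.index.build()

    def oriented(self, idx: int) -> tuple[str, str, str, str]:
        """(id, oriented_seq, orientation, sample) for an index owner id."""
        sid, seq, sample = self.seqs[idx // 2]
        if idx % 2 == 0:
            return sid, seq, "+", sample
        return sid, revcomp(seq), "-", sample

    def qual_for(self, sid: str, orient: str) -> list[int] | None:
        q = self.quals.get(sid)
        if q is None:
            return None
        return q if orient == "+" else list(reversed(q))


def _find_tail_candidates(seq: str, pool: ExtensionPool, cfg: PipelineConfig,
                          exclude: set[str]
                          ) -> list[tuple[str, str, str, int, float, int]]:
    """Pool sequences overlapping the 3' end of *seq* and protruding.

    Returns ``(id, oriented_seq, orientation, start_on_contig, identity,
    aligned_end_on_pool_seq)`` tuples.
    """
    L = len(seq)
    w0 = max(0, L - END_WINDOW_NT)
    codes = encode(seq[w0:])
    vals, valid = kmer_values(codes, EXT_SEED_K)
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return []
    qidx, owner, pos = pool.index.query(vals[idx])
    if len(qidx) == 0:
        return []
    qpos = idx[qidx] + w0
    diag = qpos - pos  # candidate start of the oriented pool seq on the contig
    key = owner * np.int64(1 << 22) + (diag + (1 << 20))
    uk, counts = np.unique(key, return_counts=True)
    # best-supported diagonal per owner
    own = uk >> np.int64(22)
    order = np.lexsort((-counts, own))
    uk, own = uk[order], own[order]
    first = np.ones(len(uk), dtype=bool)
    first[1:] = own[1:] != own[:-1]
    out = []
    for k in uk[first]:
        oidx = int(k >> np.int64(22))
        s = int(k & ((1 << 22) - 1)) - (1 << 20)
        sid, oseq, orient, sample = pool.oriented(oidx)
        if sid in exclude:
            continue
        if s < 0 or s >= L:
            continue
        if s + len(oseq) <= L:
            continue  # does not protrude past the 3' end
        ident, cols, pend = suffix_prefix_align(seq[s:], oseq, gap_cap=3)
        if cols < cfg.min_overlap_len or ident < cfg.min_overlap_identity:
            continue
        out.append((sid, oseq, orient, s, ident, pend))
    out.sort(key=lambda t: (t[3], t[0]))
    return out


def _protrusions_agree(prots: list[str], cfg: PipelineConfig) -> bool:
    """Pairwise fork test over the shared protruding region.

    Sequencing noise must not masquerade as a fork: up to 2 error
    columns are always tolerated, and a pair is only compared when the
    shared region reaches ``min_overlap_len`` — the same evidence
    standard an overlap itself must meet.  A genuine fork diverges over
    most of the shared region and fails regardless of the allowance.
    """
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            n = min(len(prots[i]), len(prots[j]))
            if n < cfg.min_overlap_len:
                continue
            ident, cols = nw_identity(prots[i][:n], prots[j][:n])
            allowed = max(2, int((1.0 - cfg.min_overlap_identity) * cols))
            if cols - round(ident * cols) > allowed:
                return False
    return True


def _consensus_of_protrusions(cands, pool: ExtensionPool) -> str:
    """Consensus of the protruding parts: longest candidate as draft,
    then cigar-aware polish rounds (shared with the assembler)."""
    from .assembly import _polish_round

    entries = []
    for sid, prot, orient in cands:
        qual = pool.qual_for(sid, orient)
        pq = qual[len(qual) - len(prot):] if qual is not None else None
        entries.append((Read(id=sid, seq=prot, qual=pq), 0, "+"))
    draft = max((p for _, p, _ in cands), key=len)
    seq = draft
    for _ in range(2):
        new_seq, _starts = _polish_round(seq, entries)
        if new_seq == seq:
            break
        seq = new_seq
    return seq


def _rc_contig(contig: Contig, lengths: dict[str, int]) -> Contig:
    L = len(contig.seq)
    placements = [
        Placement(p.read_id, "-" if p.orientation == "+" else "+",
                  L - (p.start + lengths.get(p.read_id, 0)), p.identity)
        for p in contig.placements
    ]
    return Contig(id=contig.id, seq=revcomp(contig.seq), placements=placements,
                  per_sample_reads=dict(contig.per_sample_reads),
                  depth=contig.depth)


def _extend_3prime(contig: Contig, pool: ExtensionPool, cfg: PipelineConfig
                   ) -> tuple[Contig, EndReport]:
    seq = contig.seq
    placements = list(contig.placements)
    per_sample = dict(contig.per_sample_reads)
    used = {p.read_id for p in placements} | {contig.id}
    added = 0
    status = "max_iters"
    it = 0
    for it in range(1, cfg.max_extension_iters + 1):
        cands = _find_tail_candidates(seq, pool, cfg, used)
        protruding = [(sid, oseq[pend:], orient, s, ident)
                      for sid, oseq, orient, s, ident, pend in cands
                      if pend < len(oseq)]
        if not protruding:
            status = "fixpoint"
            break
        if not _protrusions_agree([p for _, p, _, _, _ in protruding], cfg):
            status = "ambiguous"
            break
        ext = _consensus_of_protrusions(
            [(sid, prot, orient) for sid, prot, orient, _, _ in protruding],
            pool)
        if not ext:
            status = "fixpoint"
            break
        seq = seq + ext
        added += len(ext)
        for sid, _prot, orient, s, ident in protruding:
            placements.append(Placement(sid, orient, s, round(ident, 4)))
            used.add(sid)
            sample = pool.samples.get(sid, "")
            per_sample[sample] = per_sample.get(sample, 0) + 1
    out = Contig(id=contig.id, seq=seq, placements=placements,
                 per_sample_reads=per_sample, depth=contig.depth)
    report = EndReport(contig.id, "3'", it, added, status)
    return out, report


def extend_contig(contig: Contig, pool: ExtensionPool, cfg: PipelineConfig
                  ) -> tuple[Contig, list[EndReport]]:
    """Extend both ends of *contig* to fixpoint, fork or iteration cap.

    Contig length never decreases; newly incorporated pool reads are
    appended to the placements.  Forked ends are flagged ``ambiguous``
    and left unextended.
    """
    c3, rep3 = _extend_3prime(contig, pool, cfg)
    flipped = _rc_contig(c3, pool.lengths)
    c5r, rep5 = _extend_3prime(flipped, pool, cfg)
    final = _rc_contig(c5r, pool.lengths)
    if rep3.nt_added or rep5.nt_added:
        final = _final_polish(final, pool, min_len=len(contig.seq))
    rep5 = EndReport(contig.id, "5'", rep5.iterations, rep5.nt_added,
                     rep5.status)
    return final, [rep5, rep3]


def _final_polish(contig: Contig, pool: ExtensionPool, min_len: int) -> Contig:
    """Cigar-aware consensus polish of an extended contig from its placed
    reads (extension appends were anchored on possibly imperfect tails).
    Never shortens the contig below its pre-extension length."""
    from .assembly import _polish_round

    entries = []
    for p in contig.placements:
        seq = pool.seq_by_id.get(p.read_id)
        if seq is None:
            continue
        qual = pool.quals.get(p.read_id)
        entries.append((Read(id=p.read_id, seq=seq, qual=qual),
                        p.start, p.orientation))
    if not entries:
        return contig
    seq = contig.seq
    starts = [e[1] for e in entries]
    for _ in range(2):
        new_seq, starts = _polish_round(seq, entries)
        entries = [(r, s, o) for (r, _p, o), s in zip(entries, starts)]
        if new_seq == seq:
            break
        seq = new_seq
    if len(seq) < min_len:
        return contig
    old = {p.read_id: p for p in contig.placements}
    placements = [Placement(r.id, o, s, old[r.id].identity)
                  for (r, _p2, o), s in zip(entries, starts)]
    return Contig(id=contig.id, seq=seq, placements=placements,
                  per_sample_reads=dict(contig.per_sample_reads),
                  depth=contig.depth)


def extend_contigs(contigs: list[Contig], reads: list[Read],
                   cfg: PipelineConfig,
                   global_contigs: list[Contig] | None = None
                   ) -> tuple[list[Contig], list[EndReport]]:
    pool = ExtensionPool(reads, global_contigs)
    out: list[Contig] = []
    reports: list[EndReport] = []
    for c in contigs:
        ext, reps = extend_contig(c, pool, cfg)
        out.append(ext)
        reports.extend(reps)
    return out, reports


def merge_with_global_contigs(targeted: list[Contig],
                              global_contigs: list[Contig],
                              cfg: PipelineConfig) -> list[Contig]:
    """Absorb whole-metagenome assembly contigs that contain or dovetail
    a targeted contig; the targeted contig keeps its id and placements.

    A containment replaces the targeted sequence by the (oriented)
    global one; a dovetail splices the global protrusion onto the
    matching end.  When several global contigs match, the
    highest-identity merge wins and the rest are logged.
    """
    out: list[Contig] = []
    for t in targeted:
        best = None  # (identity, merged_seq, global_id)
        n_matches = 0
        for g in global_contigs:
            for orient in "+-":
                gseq = g.seq if orient == "+" else revcomp(g.seq)
                cand = _merge_candidate(t.seq, gseq, cfg)
                if cand is None:
                    continue
                ident, merged = cand
                n_matches += 1
                if best is None or ident > best[0]:
                    best = (ident, merged, g.id)
        if best is None:
            out.append(t)
            continue
        if n_matches > 1:
            logger.info("contig %s matched %d global contigs; keeping the "
                        "highest-identity merge (%s)", t.id, n_matches, best[2])
        out.append(Contig(id=t.id, seq=best[1], placements=list(t.placements),
                          per_sample_reads=dict(t.per_sample_reads),
                          depth=t.depth))
    return out


def _merge_candidate(tseq: str, gseq: str, cfg: PipelineConfig
                     ) -> tuple[float, str] | None:
    # containment of the targeted contig in the global contig
    ident, cols, ts, te = infix_align(tseq, gseq)
    if cols >= len(tseq) and ident >= cfg.min_overlap_identity:
        return ident, gseq
    # dovetail: targeted 3' end onto global 5' end
    best = None
    for flip in (False, True):
        a = tseq if not flip else tseq[::-1]
        b = gseq if not flip else gseq[::-1]
        for s in _dovetail_offsets(a, b, cfg):
            idn, ncols, pend = suffix_prefix_align(a[s:], b, gap_cap=3)
            if ncols >= cfg.min_overlap_len and idn >= cfg.min_overlap_identity \
                    and pend < len(b):
                merged = a[:s] + b  # a prefix + aligned region + b protrusion
                if flip:
                    merged = merged[::-1]
                if best is None or idn > best[0]:
                    best = (idn, merged)
    return best


def _dovetail_offsets(a: str, b: str, cfg: PipelineConfig) -> list[int]:
    """Candidate offsets of b's start on a, from 28-mer seeds near a's 3' end."""
    ca = encode(a[-END_WINDOW_NT:])
    base = max(0, len(a) - END_WINDOW_NT)
    avals, avalid = kmer_values(ca, EXT_SEED_K)
    bvals, bvalid = kmer_values(encode(b[:POOL_PREFIX_NT]), EXT_SEED_K)
    aidx = np.nonzero(avalid)[0]
    bidx = np.nonzero(bvalid)[0]
    if len(aidx) == 0 or len(bidx) == 0:
        return []
    av = avals[aidx]
    order = np.argsort(av, kind="stable")
    av_s, ai_s = av[order], aidx[order]
    offs: dict[int, int] = {}
    lo = np.searchsorted(av_s, bvals[bidx], side="left")
    hi = np.searchsorted(av_s, bvals[bidx], side="right")
    for bi, l, h in zip(bidx, lo, hi):
        for x in range(l, h):
            s = base + int(ai_s[x]) - int(bi)
            if 0 <= s < len(a):
                offs[s] = offs.get(s, 0) + 1
    return [s for s, _ in sorted(offs.items(), key=lambda kv: (-kv[1], kv[0]))[:3]]


def filter_by_length(contigs: list[Contig], cfg: PipelineConfig) -> list[Contig]:
    """Keep contigs of length >= cfg.min_contig_len (inclusive)."""
    return [c for c in contigs if len(c.seq) >= cfg.min_contig_len]
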