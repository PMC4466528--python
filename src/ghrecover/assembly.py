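"""Greedy overlap-layout-consensus assembly of recruited reads.

Overlap detection admits dovetail and containment overlaps of
>= ``min_overlap_len`` columns at >= ``min_overlap_identity`` (both
inclusive), in both orientations.  Candidate offsets come either from an
exhaustive all-offset ungapped scan (small inputs, and the reference
behaviour) or from exact 16-mer prefix seeding (large inputs); every
candidate is then re-aligned with edlib so that 454-style homopolymer
indels are absorbed within the identity allowance (indel columns count
as mismatches).

Layout is greedy: longest overlap first, then higher identity, then
lexicographically smallest read pair.  An overlap whose two reads
already sit in the same layout is skipped.  The consensus is a weighted
per-column majority (count, then summed quality, then fixed base order
A<C<G<T); ``N`` votes only win a column they occupy alone.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .align import infix_align, suffix_prefix_align
from .kmers import KmerIndex, encode, kmer_values
from .types import Contig, Overlap, Placement, PipelineConfig, Read, revcomp

logger = logging.getLogger(__name__)

EXHAUSTIVE_MAX_READS = 60  # auto method switches to seeding above this
SEED_K = 16
SEED_WINDOW = 48  # end windows queried against the full-position index
MAX_DIAGS_PER_PAIR = 2
GAP_CAP = 3  # longest indel run an overlap alignment may contain

_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes[::-1]]


# ---------------------------------------------------------------------------
# overlap verification


def _verify(a: str, b: str, s: int, cfg: PipelineConfig
            ) -> tuple[int, int, float] | None:
    """Re-align a candidate overlap (oriented *b* at offset *s* on *a*).

    Returns ``(refined_offset, columns, identity)`` or None.
    """
    la, lb = len(a), len(b)
    slack = 8
    if s >= 0 and s + lb >= la:
        # b protrudes right (or flush): suffix of a vs prefix of b
        if s >= la:
            return None
        ident, cols, _ = suffix_prefix_align(a[s:], b, gap_cap=GAP_CAP)
        return (s, cols, ident)
    if s >= 0:
        # b contained in a
        ws = max(0, s - slack)
        we = min(la, s + lb + slack)
        ident, cols, ts, _te = infix_align(b, a[ws:we], gap_cap=GAP_CAP)
        return (ws + ts, cols, ident)
    # s < 0: b starts left of a
    if s + lb <= la:
        # b protrudes left: prefix of a vs suffix of b -- align reversed
        if s + lb <= 0:
            return None
        ident, cols, _ = suffix_prefix_align(a[:s + lb][::-1], b[::-1],
                                             gap_cap=GAP_CAP)
        return (s, cols, ident)
    # a contained in b
    ws = max(0, -s - slack)
    we = min(lb, -s + la + slack)
    ident, cols, ts, _te = infix_align(a, b[ws:we], gap_cap=GAP_CAP)
    return (-(ws + ts), cols, ident)


def _flip(ov: Overlap, la: int, lb: int) -> Overlap:
    """Express the same overlap with the roles of the reads exchanged."""
    if ov.orientation == "+":
        off = -ov.offset
    else:
        off = ov.offset + lb - la
    return Overlap(read_a=ov.read_b, read_b=ov.read_a,
                   orientation=ov.orientation, offset=off,
                   length=ov.length, identity=ov.identity)


def _match_profile(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Ungapped match counts for every offset of b relative to a.

    Index ``s + len(b) - 1`` holds the match count at offset ``s``.
    """
    la, lb = len(ca), len(cb)
    out = np.zeros(la + lb - 1)
    for base in range(4):
        ia = (ca == base).astype(np.float64)
        ib = (cb == base).astype(np.float64)
        out += np.correlate(ia, ib, mode="full")
    return out


def _candidate_offsets_exhaustive(ca: np.ndarray, cb: np.ndarray,
                                  cfg: PipelineConfig) -> list[int]:
    la, lb = len(ca), len(cb)
    prof = _match_profile(ca, cb)
    offsets = np.arange(-(lb - 1), la)
    ov_len = np.minimum(la, offsets + lb) - np.maximum(0, offsets)
    ok_len = ov_len >= cfg.min_overlap_len
    if not ok_len.any():
        return []
    ident = np.where(ov_len > 0, prof / np.maximum(ov_len, 1), 0.0)
    strong = ok_len & (ident >= cfg.min_overlap_identity - 0.02)
    cand = set(offsets[strong].tolist())
    # a few highest-match offsets catch indel-shifted overlaps
    masked = np.where(ok_len, prof, -1.0)
    top = np.argsort(masked)[::-1][:4]
    cand.update(int(offsets[i]) for i in top if masked[i] > 0)
    return sorted(cand)


def find_overlaps(reads: list[Read], cfg: PipelineConfig,
                  method: str = "auto") -> list[Overlap]:
    """All pairwise overlaps meeting the thresholds.

    One best overlap (most columns, then highest identity) is reported
    per read pair and orientation; ``read_a`` is the lexicographically
    smaller id.
    """
    if len(reads) < 2:
        return []
    if method == "auto":
        method = "exhaustive" if len(reads) <= EXHAUSTIVE_MAX_READS else "seeded"
    codes = {r.id: encode(r.seq) for r in reads}
    seqs = {r.id: r.seq for r in reads}

    raw: dict[tuple[str, str, str], tuple[int, int, float]] = {}

    def consider(a_id: str, b_id: str, orient: str, s: int) -> None:
        a, la = seqs[a_id], len(seqs[a_id])
        b = seqs[b_id] if orient == "+" else revcomp(seqs[b_id])
        lb = len(b)
        res = _verify(a, b, s, cfg)
        if res is None:
            return
        off, cols, ident = res
        if cols < cfg.min_overlap_len or ident < cfg.min_overlap_identity:
            return
        ov = Overlap(a_id, b_id, orient, off, cols, ident)
        if a_id > b_id:
            ov = _flip(ov, la, lb)
        key = (ov.read_a, ov.read_b, ov.orientation)
        # best candidate per pair by alignment score (matches minus error
        # columns): a shifted near-alignment can reach 90% identity by
        # spending gap columns, but never outscores the true offset
        matches = int(round(ov.identity * ov.length))
        score = 2 * matches - ov.length
        cur = raw.get(key)
        if cur is None or (score, ov.identity, ov.length) > \
                (cur[3], cur[2], cur[0]):
            raw[key] = (ov.length, ov.offset, ov.identity, score)

    if method == "exhaustive":
        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                a, b = reads[i], reads[j]
                ca = codes[a.id]
                for orient in "+-":
                    cb = codes[b.id] if orient == "+" else _rc_codes(codes[b.id])
                    for s in _candidate_offsets_exhaustive(ca, cb, cfg):
                        consider(a.id, b.id, orient, s)
    elif method == "seeded":
        _seeded_candidates(reads, codes, cfg, consider)
    else:
        raise ValueError(f"unknown overlap method {method!r}")

    out = [Overlap(a, b, o, off, cols, ident)
           for (a, b, o), (cols, off, ident, _score) in raw.items()]
    out.sort(key=lambda v: (-v.length, -v.identity, v.read_a, v.read_b))
    return out


def _seeded_candidates(reads, codes, cfg, consider) -> None:
    """16-mer prefix seeding: query each read's first SEED_WINDOW nt (both
    orientations) against an index of every read position."""
    ids = [r.id for r in reads]
    index = KmerIndex(SEED_K)
    for i, r in enumerate(reads):
        index.add(i, codes[r.id])
    index.build()

    qv_l, qmeta_l, qpos_l = [], [], []
    for i, r in enumerate(reads):
        for oi, orient in enumerate("+-"):
            c = codes[r.id] if orient == "+" else _rc_codes(codes[r.id])
            # both end windows: the prefix catches dovetails where the
            # oriented query starts inside the target, the suffix catches
            # head-to-head reverse-complement overlaps (negative offsets)
            windows = [(0, min(SEED_WINDOW, len(c)))]
            if len(c) > SEED_WINDOW:
                windows.append((len(c) - SEED_WINDOW, len(c)))
            for w0, w1 in windows:
                vals, valid = kmer_values(c[w0:w1], SEED_K)
                idx = np.nonzero(valid)[0]
                if len(idx) == 0:
                    continue
                qv_l.append(vals[idx])
                qmeta_l.append(np.full(len(idx), i * 2 + oi, dtype=np.int64))
                qpos_l.append((idx + w0).astype(np.int64))
    if not qv_l:
        return
    qvals = np.concatenate(qv_l)
    qmeta = np.concatenate(qmeta_l)
    qpos = np.concatenate(qpos_l)

    qidx, towner, tpos = index.query(qvals)
    if len(qidx) == 0:
        return
    qm = qmeta[qidx]
    qreadi = qm >> 1
    qorient = qm & 1
    keep = towner != qreadi
    qreadi, qorient, towner = qreadi[keep], qorient[keep], towner[keep]
    diag = tpos[keep] - qpos[qidx][keep]  # offset of oriented q within t

    # count seeds per (target, query, orient, diag)
    key = (((towner << np.int64(22)) | qreadi) << np.int64(14)) \
        | ((qorient << np.int64(13)) | (diag + 4096))
    uk, counts = np.unique(key, return_counts=True)
    # per (target, query, orient) keep the best-supported diagonals
    pair = uk >> np.int64(13)
    order = np.lexsort((-counts, pair))
    uk, counts, pair = uk[order], counts[order], pair[order]
    newpair = np.ones(len(uk), dtype=bool)
    newpair[1:] = pair[1:] != pair[:-1]
    rank = np.arange(len(uk)) - np.maximum.accumulate(
        np.where(newpair, np.arange(len(uk)), 0))
    sel = rank < MAX_DIAGS_PER_PAIR
    for k in uk[sel]:
        t = int(k >> np.int64(36))
        q = int((k >> np.int64(14)) & ((1 << 22) - 1))
        orient = "+" if (int(k) >> 13) & 1 == 0 else "-"
        d = (int(k) & ((1 << 13) - 1)) - 4096
        consider(ids[t], ids[q], orient, d)


# ---------------------------------------------------------------------------
# consensus


def consensus_column(votes) -> str:
    """Consensus base for one column.

    *votes* maps base -> count or base -> (count, summed_quality).
    Majority count wins; ties break by higher summed quality, then by
    the fixed order A<C<G<T.  ``N`` wins only when nothing else voted.
    """
    norm: dict[str, tuple[int, float]] = {}
    for base, v in votes.items():
        if isinstance(v, tuple):
            norm[base] = (int(v[0]), float(v[1]))
        else:
            norm[base] = (int(v), 0.0)
    acgt = {b: v for b, v in norm.items() if b in "ACGT" and v[0] > 0}
    if not acgt:
        return "N" if norm.get("N", (0, 0))[0] > 0 else ""
    order = {b: i for i, b in enumerate("ACGT")}
    return max(acgt, key=lambda b: (acgt[b][0], acgt[b][1], -order[b]))


def _draft_consensus(entries: list[tuple[Read, int, str]]) -> str:
    """First-pass consensus by straight column voting at layout offsets."""
    span = max(pos + len(r.seq) for r, pos, _ in entries)
    counts = np.zeros((4, span), dtype=np.int32)
    qsum = np.zeros((4, span), dtype=np.float64)
    ncnt = np.zeros(span, dtype=np.int32)
    for r, pos, o in entries:
        c = encode(r.seq)
        q = np.asarray(r.qual, dtype=np.float64) if r.qual is not None else None
        if o == "-":
            c = _rc_codes(c)
            if q is not None:
                q = q[::-1]
        cols = np.arange(pos, pos + len(c))
        valid = c < 4
        np.add.at(counts, (c[valid], cols[valid]), 1)
        if q is not None:
            np.add.at(qsum, (c[valid], cols[valid]), q[valid])
        np.add.at(ncnt, cols[~valid], 1)
    base_bonus = (3 - np.arange(4))[:, None] * 1e-7
    keys = counts.astype(np.float64) * 1e9 + qsum + base_bonus
    winner = np.argmax(keys, axis=0)
    covered = counts.sum(axis=0) > 0
    out = np.empty(span, dtype="<U1")
    out[:] = np.array(list("ACGT"))[winner]
    out[~covered & (ncnt > 0)] = "N"
    out[~covered & (ncnt == 0)] = "N"  # uncovered gaps should not occur
    return "".join(out)


def _polish_round(draft: str, entries: list[tuple[Read, int, str]]
                  ) -> tuple[str, list[int]]:
    """One cigar-aware polish round.

    Each read is re-aligned (edlib, free target ends) to its window of
    the draft and votes through the alignment path, so a homopolymer
    indel inside one read no longer shifts all its downstream votes.
    Deletion votes can remove a draft column; insertion votes supported
    by a strict majority of the covering reads add one.
    Returns the polished consensus and the refined read start positions.
    """
    import edlib

    from .align import _CIGAR_OP

    L = len(draft)
    votes: list[dict] = [dict() for _ in range(L)]
    dels = np.zeros(L, dtype=np.int64)
    cov = np.zeros(L, dtype=np.int64)
    ins: list[dict] = [dict() for _ in range(L + 1)]
    starts: list[int] = []
    slack = 30
    for r, pos, o in entries:
        seq = r.seq if o == "+" else revcomp(r.seq)
        qual = r.qual if r.qual is not None else None
        if qual is not None and o == "-":
            qual = list(reversed(qual))
        w0 = max(0, pos - slack)
        w1 = min(L, pos + len(seq) + slack)
        res = edlib.align(seq, draft[w0:w1], mode="HW", task="path")
        if not res["locations"]:
            starts.append(pos)
            continue
        t = w0 + res["locations"][0][0]
        starts.append(t)
        qp = 0
        for num, op in _CIGAR_OP.findall(res["cigar"]):
            n = int(num)
            if op in "=XM":
                for i in range(n):
                    col = t + i
                    if col >= L:
                        break
                    base = seq[qp + i]
                    q = float(qual[qp + i]) if qual is not None else 0.0
                    cnt, qs = votes[col].get(base, (0, 0.0))
                    votes[col][base] = (cnt + 1, qs + q)
                    cov[col] += 1
                t += n
                qp += n
            elif op == "D":  # draft has extra columns
                for i in range(n):
                    if t + i < L:
                        dels[t + i] += 1
                        cov[t + i] += 1
                t += n
            elif op == "I":  # read has extra bases
                if t <= L:
                    base = seq[qp]
                    ins[t][base] = ins[t].get(base, 0) + 1
                qp += n
    out: list[str] = []
    for col in range(L):
        ivotes = ins[col]
        if ivotes:
            n_ins = sum(ivotes.values())
            support = max(cov[col] if col < L else 0,
                          cov[col - 1] if col > 0 else 0)
            if n_ins * 2 > support:
                out.append(max(sorted(ivotes), key=lambda b: ivotes[b]))
        if not votes[col]:
            if dels[col] == 0:
                out.append(draft[col])  # uncovered: keep draft
            continue
        base = consensus_column(votes[col])
        n_base = sum(v[0] for v in votes[col].values())
        if dels[col] > n_base:
            continue  # majority deletes this column
        out.append(base)
    # trailing insertions
    ivotes = ins[L]
    if ivotes and sum(ivotes.values()) * 2 > (cov[L - 1] if L else 0):
        out.append(max(sorted(ivotes), key=lambda b: ivotes[b]))
    return "".join(out), starts


def _layout_consensus(entries: list[tuple[Read, int, str]], rounds: int = 2
                      ) -> tuple[str, list[tuple[Read, int, str]]]:
    """Consensus of placed reads: (consensus, entries with refined pos)."""
    shift = -min(pos for _, pos, _ in entries)
    entries = [(r, pos + shift, o) for r, pos, o in entries]
    seq = _draft_consensus(entries)
    for _ in range(rounds):
        new_seq, starts = _polish_round(seq, entries)
        entries = [(r, s, o) for (r, _p, o), s in zip(entries, starts)]
        if new_seq == seq:
            break
        seq = new_seq
    return seq, entries


# ---------------------------------------------------------------------------
# greedy layout


def greedy_assemble(reads: list[Read], overlaps: list[Overlap],
                    cfg: PipelineConfig) -> list[Contig]:
    """Merge reads along overlaps in greedy priority order.

    Every input read is placed in exactly one contig (singletons
    allowed).  Overlaps whose reads already share a layout are skipped.
    Deterministic: identical input and config give byte-identical
    contigs.
    """
    byid = {r.id: i for i, r in enumerate(reads)}
    lens = [len(r.seq) for r in reads]
    state: list[tuple[int, int, str]] = [(i, 0, "+") for i in range(len(reads))]
    members: dict[int, list[int]] = {i: [i] for i in range(len(reads))}

    ordered = sorted(overlaps,
                     key=lambda v: (-v.length, -v.identity, v.read_a, v.read_b))
    skipped = 0
    for ov in ordered:
        ia, ib = byid[ov.read_a], byid[ov.read_b]
        la_lid, pa, oa = state[ia]
        lb_lid, pb, ob = state[ib]
        if la_lid == lb_lid:
            skipped += 1
            continue
        la, lb = lens[ia], lens[ib]
        # target placement of read_b in read_a's layout
        if oa == "+":
            tgt_pos = pa + ov.offset
            tgt_or = ov.orientation
        else:
            tgt_pos = pa + la - ov.offset - lb
            tgt_or = "-" if ov.orientation == "+" else "+"
        # transform layout of b onto layout of a
        if ob == tgt_or:
            delta = tgt_pos - pb
            moves = [(ri, state[ri][1] + delta, state[ri][2])
                     for ri in members[lb_lid]]
        else:
            delta = tgt_pos + pb + lb
            moves = [(ri, delta - (state[ri][1] + lens[ri]),
                      "-" if state[ri][2] == "+" else "+")
                     for ri in members[lb_lid]]
        for ri, pos, orient in moves:
            state[ri] = (la_lid, pos, orient)
        members[la_lid].extend(members.pop(lb_lid))
    if skipped:
        logger.info("greedy layout: %d redundant/conflicting overlaps skipped",
                    skipped)

    contigs: list[Contig] = []
    for lid, idxs in members.items():
        entries = [(reads[ri], state[ri][1], state[ri][2]) for ri in idxs]
        seq, entries = _layout_consensus(entries)
        placements = []
        per_sample: dict[str, int] = defaultdict(int)
        for r, pos, o in sorted(entries, key=lambda e: (e[1], e[0].id)):
            oriented = r.seq if o == "+" else revcomp(r.seq)
            w0 = max(0, pos - 30)
            w1 = min(len(seq), pos + len(r.seq) + 30)
            ident, cols, ts, _te = infix_align(oriented, seq[w0:w1])
            placements.append(Placement(r.id, o, w0 + ts, round(ident, 4)))
            per_sample[r.sample] += 1
        contigs.append(Contig(id="", seq=seq, placements=placements,
                              per_sample_reads=dict(per_sample)))
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    for i, c in enumerate(contigs, start=1):
        c.id = f"contig_{i:05d}"
    return contigs


def assemble(reads: list[Read], cfg: PipelineConfig,
             method: str = "auto") -> list[Contig]:
    """find_overlaps + greedy_assemble in one call."""
    overlaps = find_overlaps(reads, cfg, method=method)
    return greedy_assemble(reads, overlaps, cfg)
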