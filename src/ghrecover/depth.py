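"""Read-to-contig mapping and per-sample depth weighting.

Depth is defined as mean per-base coverage: the summed aligned bases of
the reads assigned to a contig, divided by contig length.  Each read is
assigned to at most one contig (its best alignment at >= 90% identity
over >= 90% of the read; ties go to the lexicographically smallest
contig id), which keeps per-sample read counts additive.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .align import infix_align
from .assembly import _rc_codes
from .kmers import KmerIndex, encode, kmer_values
from .types import Contig, DepthRecord, Read, revcomp

logger = logging.getLogger(__name__)

MAP_SEED_K = 14
MAP_SEED_STRIDE = 8
MAX_CANDIDATES = 4
POOLED = "ALL"


def map_reads(contigs: list[Contig], reads: list[Read],
              min_identity: float = 0.90, min_read_fraction: float = 0.90
              ) -> dict[str, tuple[str, int] | None]:
    """Assign each read to its best-matching contig.

    Returns ``read_id -> (contig_id, aligned_bases)`` or ``None`` for
    unmapped reads.  A read maps when its alignment reaches
    *min_identity* over at least *min_read_fraction* of the read (reads
    hanging off a contig end are clipped to the in-contig part first).
    """
    if not contigs:
        raise ValueError("contig set must be non-empty")
    index = KmerIndex(MAP_SEED_K)
    ccodes = [encode(c.seq) for c in contigs]
    for i, codes in enumerate(ccodes):
        index.add(i, codes)
    index.build()
    cids = [c.id for c in contigs]
    clens = [len(c.seq) for c in contigs]

    out: dict[str, tuple[str, int] | None] = {}
    for read in reads:
        rc = encode(read.seq)
        L = len(read.seq)
        best = None  # (identity, -lex rank handled via id compare, contig, bases)
        for orient in "+-":
            codes = rc if orient == "+" else _rc_codes(rc)
            vals, valid = kmer_values(codes, MAP_SEED_K)
            idx = np.nonzero(valid)[0][::MAP_SEED_STRIDE]
            if len(idx) == 0:
                continue
            qidx, owner, pos = index.query(vals[idx])
            if len(qidx) == 0:
                continue
            diag = pos - idx[qidx]
            key = owner * np.int64(1 << 22) + (diag + (1 << 20))
            uk, counts = np.unique(key, return_counts=True)
            top = uk[np.argsort(-counts, kind="stable")[:MAX_CANDIDATES]]
            oriented = read.seq if orient == "+" else revcomp(read.seq)
            for k in top:
                ci = int(k >> np.int64(22))
                s = int(k & ((1 << 22) - 1)) - (1 << 20)
                cand = _align_candidate(oriented, contigs[ci].seq, s,
                                        min_identity, min_read_fraction)
                if cand is None:
                    continue
                ident, bases = cand
                # tie on identity -> lexicographically smaller contig id
                if best is None or ident > best[0] or \
                        (ident == best[0] and cids[ci] < cids[best[1]]):
                    best = (ident, ci, bases)
        out[read.id] = (cids[best[1]], best[2]) if best else None
    n_mapped = sum(1 for v in out.values() if v)
    logger.info("mapped %d/%d reads", n_mapped, len(reads))
    return out


def _align_candidate(read_seq: str, contig_seq: str, s: int,
                     min_identity: float, min_read_fraction: float
                     ) -> tuple[float, int] | None:
    """Identity and aligned bases of a read at candidate start *s*."""
    L = len(read_seq)
    clen = len(contig_seq)
    slack = 12
    ws = max(0, s - slack)
    we = min(clen, s + L + slack)
    if we - ws <= 0:
        return None
    query = read_seq
    # clip the read to the in-contig part when it hangs over an edge
    if s < 0:
        query = read_seq[-s:]
    if s + L > clen:
        over = s + L - clen
        query = query[:len(query) - over] if over < len(query) else ""
    if len(query) < min_read_fraction * L:
        return None
    ident, cols, _ts, _te = infix_align(query, contig_seq[ws:we])
    if cols == 0 or ident < min_identity:
        return None
    return ident, len(query)


def compute_depth(assignments: dict[str, tuple[str, int] | None],
                  contigs: list[Contig], reads: list[Read],
                  by_sample: bool = True) -> list[DepthRecord]:
    """Depth records from read assignments.

    Per contig: a pooled record (sample=``ALL``) plus, when *by_sample*,
    one record per sample with that sample's read count and coverage
    share.  depth = summed aligned bases / contig length.
    """
    sample_of = {r.id: r.sample for r in reads}
    counts: dict[tuple[str, str], int] = defaultdict(int)
    bases: dict[tuple[str, str], int] = defaultdict(int)
    samples: set[str] = set()
    for rid, asg in assignments.items():
        if asg is None:
            continue
        cid, ab = asg
        smp = sample_of.get(rid, "")
        samples.add(smp)
        for key in ((cid, POOLED), (cid, smp)):
            counts[key] += 1
            bases[key] += ab
    out: list[DepthRecord] = []
    for c in contigs:
        clen = max(len(c.seq), 1)
        out.append(DepthRecord(c.id, POOLED, counts[(c.id, POOLED)],
                               bases[(c.id, POOLED)] / clen))
        c.depth = bases[(c.id, POOLED)] / clen
        if by_sample:
            for smp in sorted(samples):
                out.append(DepthRecord(c.id, smp, counts[(c.id, smp)],
                                       bases[(c.id, smp)] / clen))
    return out


def depth_to_rows(records: list[DepthRecord],
                  contigs: list[Contig]) -> list[dict]:
    clen = {c.id: len(c.seq) for c in contigs}
    return [{
        "contig_id": r.contig_id, "length": clen.get(r.contig_id, 0),
        "sample": r.sample, "mapped_reads": r.mapped_reads,
        "depth": round(r.depth, 4),
    } for r in records]
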