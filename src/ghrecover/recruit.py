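"""Homology-guided read recruitment by six-frame translated local alignment.

Each read is translated in all six frames under genetic code 11 and
searched against the reference protein panel with Smith-Waterman local
alignment (BLOSUM62, gap open 11 / extend 1).  A read is recruited when
any frame yields an HSP with e-value <= the configured cutoff
(inclusive), the e-value being Karlin-Altschul calibrated over the
whole search space (total panel residues x total translated residues).

Stop codons score as hard forbidden columns by default, so an HSP never
crosses a stop: reading-frame-intact fragments of real genes are exactly
what the downstream assembler wants.

The default search is accelerated by exact 3-mer two-hit diagonal
seeding; ``method="exhaustive"`` aligns every frame against every panel
protein and must produce the identical recruited set.
"""

from __future__ import annotations

import logging

import numpy as np

from .align import best_local, protein_aligner
from .stats import AlignmentStats, protein_stats
from .translate import FRAMES, frame_aa_to_read_nt, translate_six_frames
from .types import PipelineConfig, Read, ReferenceProtein, TranslatedHit

logger = logging.getLogger(__name__)

WORD_SIZE = 4
TWO_HIT_WINDOW = 40  # max aa separation of two same-diagonal word hits
MIN_SEEDABLE_FRAME = 8  # frames shorter than this skip seeding entirely

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = np.full(256, 25, dtype=np.uint8)
for _i, _a in enumerate(_AA_ORDER):
    _AA_CODE[ord(_a)] = _i
# X, * and anything unexpected encode as >= 20 and never seed


def _encode_aa(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _word_values(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - WORD_SIZE + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(WORD_SIZE):
        c = codes[j:j + n]
        vals = vals * 20 + c.astype(np.int64)
        valid &= c < 20
    return vals, valid


def total_translated_residues(reads: list[Read]) -> int:
    return sum(sum((len(r.seq) - off) // 3 for off in (0, 1, 2)) * 2 for r in reads)


def align_translated(read: Read, protein: ReferenceProtein,
                     stats: AlignmentStats | None = None,
                     genetic_code: int = 11) -> list[TranslatedHit]:
    """All positive-scoring frame-vs-protein HSPs for one read/protein pair.

    One best HSP per frame is reported.  When *stats* is not given, the
    search space is this read against this protein alone.
    """
    frames = translate_six_frames(read.seq, genetic_code)
    if stats is None:
        stats = protein_stats(len(protein.seq), total_translated_residues([read]))
    aligner = protein_aligner()
    hits: list[TranslatedHit] = []
    for f in FRAMES:
        aa = frames[f]
        hit = best_local(aa, protein.seq, aligner)
        if hit is None:
            continue
        read_span = frame_aa_to_read_nt(f, hit.query_span, len(read.seq))
        hits.append(TranslatedHit(
            read_id=read.id, frame=f, protein_id=protein.id,
            family=protein.family, score=int(round(hit.score)),
            bitscore=stats.bitscore(hit.score), evalue=stats.evalue(hit.score),
            read_span=read_span, protein_span=hit.target_span,
        ))
    return hits


def _seed_candidates(frame_seqs: list[str], frame_meta: list[tuple[int, int]],
                     panel: list[ReferenceProtein]) -> set[tuple[int, int, int]]:
    """Two-hit diagonal seeding.

    Returns candidate ``(read_idx, frame, protein_idx)`` triples: pairs
    with two exact 3-mer word matches on the same diagonal within
    TWO_HIT_WINDOW aa, plus every protein for frames too short to seed.
    """
    # panel word index
    pvals_l, powner_l, ppos_l = [], [], []
    for pi, prot in enumerate(panel):
        vals, valid = _word_values(_encode_aa(prot.seq))
        idx = np.nonzero(valid)[0]
        pvals_l.append(vals[idx])
        powner_l.append(np.full(len(idx), pi, dtype=np.int64))
        ppos_l.append(idx.astype(np.int64))
    pvals = np.concatenate(pvals_l) if pvals_l else np.empty(0, dtype=np.int64)
    powner = np.concatenate(powner_l) if powner_l else np.empty(0, dtype=np.int64)
    ppos = np.concatenate(ppos_l) if ppos_l else np.empty(0, dtype=np.int64)
    order = np.argsort(pvals, kind="stable")
    pvals, powner, ppos = pvals[order], powner[order], ppos[order]

    candidates: set[tuple[int, int, int]] = set()

    # process query frames in blocks to bound peak memory
    block_words = 2_000_000
    qvals_l, qmeta_l, qpos_l = [], [], []
    pending = 0

    def flush() -> None:
        nonlocal qvals_l, qmeta_l, qpos_l, pending
        if not qvals_l:
            return
        qvals = np.concatenate(qvals_l)
        qframe = np.concatenate(qmeta_l)
        qpos = np.concatenate(qpos_l)
        qvals_l, qmeta_l, qpos_l = [], [], []
        pending = 0
        lo = np.searchsorted(pvals, qvals, side="left")
        hi = np.searchsorted(pvals, qvals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return
        base = np.repeat(lo, counts)
        csum = np.cumsum(counts) - counts
        flat = base + (np.arange(total) - np.repeat(csum, counts))
        h_frame = np.repeat(qframe, counts)
        h_qpos = np.repeat(qpos, counts)
        h_prot = powner[flat]
        h_diag = ppos[flat] - h_qpos
        # two word hits on one (frame, protein, diagonal) within the window
        key = (h_frame << np.int64(34)) | (h_prot << np.int64(14)) \
            | (h_diag + 8192)
        order = np.lexsort((h_qpos, key))
        key_s, qpos_s = key[order], h_qpos[order]
        same = key_s[1:] == key_s[:-1]
        close = (qpos_s[1:] - qpos_s[:-1]) <= TWO_HIT_WINDOW
        fired = np.nonzero(same & close)[0]
        for i in np.unique(key_s[fired]):
            fi = int(i >> 34)
            pi = int((i >> 14) & ((1 << 20) - 1))
            meta = frame_meta[fi]
            candidates.add((meta[0], meta[1], pi))

    for fi, (aa, meta) in enumerate(zip(frame_seqs, frame_meta)):
        if len(aa) < MIN_SEEDABLE_FRAME:
            for pi in range(len(panel)):
                candidates.add((meta[0], meta[1], pi))
            continue
        vals, valid = _word_values(_encode_aa(aa))
        idx = np.nonzero(valid)[0]
        if len(idx) == 0:
            continue
        qvals_l.append(vals[idx])
        qmeta_l.append(np.full(len(idx), fi, dtype=np.int64))
        qpos_l.append(idx.astype(np.int64))
        pending += len(idx)
        if pending >= block_words:
            flush()
    flush()
    return candidates


def recruit_reads(reads: list[Read], panel: list[ReferenceProtein],
                  cfg: PipelineConfig, method: str = "seeded"
                  ) -> tuple[list[Read], list[TranslatedHit]]:
    """Recruit the reads homologous to the panel.

    A read is recruited iff at least one HSP reaches
    ``evalue <= cfg.recruit_evalue_max`` (inclusive).  For every
    recruited read the best passing HSP per panel protein is reported.
    Deterministic for fixed inputs; ``method`` ("seeded" or
    "exhaustive") must not change the result.
    """
    if not panel:
        raise ValueError("reference panel must be non-empty")
    if not reads:
        return [], []
    if method not in ("seeded", "exhaustive"):
        raise ValueError(f"unknown recruitment method {method!r}")

    m = sum(len(p.seq) for p in panel)
    n = total_translated_residues(reads)
    stats = protein_stats(m, n)
    min_raw = stats.min_score_for_evalue(cfg.recruit_evalue_max)
    aligner = protein_aligner()

    # frame translations, flat-indexed
    frame_seqs: list[str] = []
    frame_meta: list[tuple[int, int]] = []  # (read_idx, frame)
    frame_lookup: dict[tuple[int, int], str] = {}
    for ri, read in enumerate(reads):
        frames = translate_six_frames(read.seq, cfg.genetic_code)
        for f in FRAMES:
            frame_seqs.append(frames[f])
            frame_meta.append((ri, f))
            frame_lookup[(ri, f)] = frames[f]

    if method == "seeded":
        candidates = _seed_candidates(frame_seqs, frame_meta, panel)
    else:
        candidates = {(ri, f, pi)
                      for ri in range(len(reads))
                      for f in FRAMES
                      for pi in range(len(panel))}

    # score candidates; keep best passing frame per (read, protein)
    frame_rank = {f: i for i, f in enumerate(FRAMES)}
    best: dict[tuple[int, int], tuple[float, int, int]] = {}  # (ri,pi) -> (score, rank, f)
    for ri, f, pi in sorted(candidates, key=lambda c: (c[0], c[2], frame_rank[c[1]])):
        aa = frame_lookup[(ri, f)]
        if not aa:
            continue
        score = aligner.score(aa, panel[pi].seq)
        # the raw-score prefilter gets a float fudge so the e-value test
        # alone decides boundary cases (the cutoff is inclusive)
        if score < min_raw - 1e-6 or stats.evalue(score) > cfg.recruit_evalue_max:
            continue
        cur = best.get((ri, pi))
        if cur is None or (score, -frame_rank[f]) > (cur[0], -cur[1]):
            best[(ri, pi)] = (score, frame_rank[f], f)

    hits: list[TranslatedHit] = []
    recruited_idx: set[int] = set()
    for (ri, pi), (score, _rank, f) in sorted(best.items()):
        read, prot = reads[ri], panel[pi]
        aa = frame_lookup[(ri, f)]
        hit = best_local(aa, prot.seq, aligner)
        assert hit is not None
        read_span = frame_aa_to_read_nt(f, hit.query_span, len(read.seq))
        hits.append(TranslatedHit(
            read_id=read.id, frame=f, protein_id=prot.id, family=prot.family,
            score=int(round(hit.score)), bitscore=stats.bitscore(hit.score),
            evalue=stats.evalue(hit.score), read_span=read_span,
            protein_span=hit.target_span,
        ))
        recruited_idx.add(ri)

    recruited = [reads[ri] for ri in sorted(recruited_idx)]
    logger.info("recruited %d/%d reads (%d HSPs kept)",
                len(recruited), len(reads), len(hits))
    return recruited, hits


def hits_to_rows(hits: list[TranslatedHit]) -> list[dict]:
    return [{
        "read_id": h.read_id, "frame": h.frame, "protein_id": h.protein_id,
        "family": h.family, "score": h.score, "bitscore": round(h.bitscore, 2),
        "evalue": f"{h.evalue:.3g}",
        "read_start": h.read_span[0], "read_end": h.read_span[1],
        "protein_start": h.protein_span[0], "protein_end": h.protein_span[1],
    } for h in hits]
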