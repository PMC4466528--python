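"""Pairwise alignment backends.

Protein local alignment (the translated-search and annotation scoring
step) runs on Bio.Align.PairwiseAligner with BLOSUM62 and BLAST-style
affine gaps: a gap of length k costs ``open + k * extend`` with
open = 11, extend = 1, i.e. PairwiseAligner scores of -12 / -1.

Nucleotide overlap verification runs on edlib (unit-cost edit distance);
identity is matches over alignment columns with indel columns counting
as mismatches, which is exactly ``1 - dist / columns``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1
STOP_PENALTY = -1000.0  # forbids local alignments crossing a stop codon

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@lru_cache(maxsize=4)
def blosum62_matrix(forbid_stops: bool = True):
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    if forbid_stops:
        stop = mat.alphabet.index("*")
        arr[stop, :] = STOP_PENALTY
        arr[:, stop] = STOP_PENALTY
        arr[stop, stop] = STOP_PENALTY
        mat = substitution_matrices.Array(alphabet=mat.alphabet, data=arr)
    return mat


@lru_cache(maxsize=4)
def protein_aligner(forbid_stops: bool = True) -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = blosum62_matrix(forbid_stops)
    al.mode = "local"
    al.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    al.extend_gap_score = -GAP_EXTEND
    return al


@lru_cache(maxsize=4)
def nucleotide_aligner(match: float = 1.0, mismatch: float = -2.0,
                       gap_open: float = 4.0, gap_extend: float = 2.0
                       ) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


@dataclass(frozen=True)
class LocalHit:
    score: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    target_span: tuple[int, int]
    identity: float  # matches / alignment columns
    columns: int


def best_local(query: str, target: str, aligner: PairwiseAligner
               ) -> LocalHit | None:
    """Best local alignment with spans and identity, or None if score <= 0."""
    if not query or not target:
        return None
    score = aligner.score(query, target)
    if score <= 0:
        return None
    aln = aligner.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    matches = 0
    cols = 0
    prev_qe = prev_te = None
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        if prev_qe is not None:
            cols += (q0 - prev_qe) + (t0 - prev_te)  # gap columns
        for a, b in zip(query[q0:q1], target[t0:t1]):
            cols += 1
            if a == b:
                matches += 1
        prev_qe, prev_te = q1, t1
    identity = matches / cols if cols else 0.0
    return LocalHit(float(score), (qs, qe), (ts, te), identity, cols)


def cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended cigar."""
    matches = 0
    cols = 0
    for num, op in _CIGAR_OP.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def max_gap_run(cigar: str) -> int:
    """Longest single insertion/deletion run in an edlib cigar."""
    longest = 0
    for num, op in _CIGAR_OP.findall(cigar):
        if op in "ID":
            longest = max(longest, int(num))
    return longest


def nw_identity(a: str, b: str) -> tuple[float, int]:
    """Global (NW) identity between two strings: (identity, columns)."""
    if not a or not b:
        return 0.0, 0
    r = edlib.align(a, b, mode="NW", task="path")
    matches, cols = cigar_stats(r["cigar"])
    return (matches / cols if cols else 0.0), cols


def suffix_prefix_align(suffix: str, target: str,
                        gap_cap: int | None = None) -> tuple[float, int, int]:
    """Align *suffix* (whole) onto a prefix of *target* (edlib SHW).

    Returns ``(identity, columns, target_end)`` where ``target_end`` is
    the 0-based end (exclusive) of the aligned prefix on *target*.
    With *gap_cap*, an alignment containing a single indel run longer
    than the cap reports identity 0 (platform indels are short; a long
    gap means a mis-anchored candidate, not a real overlap).
    """
    if not suffix or not target:
        return 0.0, 0, 0
    r = edlib.align(suffix, target, mode="SHW", task="path")
    matches, cols = cigar_stats(r["cigar"])
    tend = r["locations"][0][1] + 1 if r["locations"] else 0
    if gap_cap is not None and max_gap_run(r["cigar"]) > gap_cap:
        return 0.0, cols, tend
    return (matches / cols if cols else 0.0), cols, tend


def infix_align(query: str, target: str,
                gap_cap: int | None = None) -> tuple[float, int, int, int]:
    """Align *query* (whole) into *target* (edlib HW, free target ends).

    Returns ``(identity, columns, target_start, target_end)``; see
    :func:`suffix_prefix_align` for *gap_cap*.
    """
    if not query or not target:
        return 0.0, 0, 0, 0
    r = edlib.align(query, target, mode="HW", task="path")
    matches, cols = cigar_stats(r["cigar"])
    if not r["locations"]:
        return 0.0, 0, 0, 0
    ts, te = r["locations"][0]
    if gap_cap is not None and max_gap_run(r["cigar"]) > gap_cap:
        return 0.0, cols, ts, te + 1
    return (matches / cols if cols else 0.0), cols, ts, te + 1
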