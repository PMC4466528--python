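"""Independent reference implementations used only by the test suite.

Everything here is deliberately naive (pure-python dynamic programming,
all-offset scanning, hand-built codon table) and shares no code with
the package's alignment or seeding paths.
"""

from __future__ import annotations

import math

# hand-entered genetic code, table 11 (bacterial): codon -> aa, stops as '*'
_T11 = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _T11[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse
    complement), dropping the trailing partial codon."""
    s = seq if frame > 0 else rc(seq)
    s = s[abs(frame) - 1:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        out.append(_T11.get(s[i:i + 3], "X"))
    return "".join(out)


def load_blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a plain dict (data via biopython, scoring logic here)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


_B62 = load_blosum62()
STOP_SCORE = -1000.0


def sw_score(q: str, t: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Plain O(nm) affine-gap Smith-Waterman best score.

    A gap of length k costs gap_open + k * gap_extend (BLAST
    convention).  Stop columns are forbidden.
    """
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return 0.0
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in t (consumes q)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q (consumes t)
    best = 0.0
    first_gap = -(gap_open + gap_extend)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend, H[i - 1][j] + first_gap)
            F[i][j] = max(F[i][j - 1] - gap_extend, H[i][j - 1] + first_gap)
            sub = _B62.get((qi, t[j - 1]), -4.0)
            if qi == "*" or t[j - 1] == "*":
                sub = STOP_SCORE
            h = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def bitscore(raw: float, lam: float = 0.267, k: float = 0.041) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def evalue(raw: float, m: int, n: int, lam: float = 0.267,
           k: float = 0.041) -> float:
    return m * n * 2.0 ** (-bitscore(raw, lam, k))


def recruit_oracle(reads, panel, evalue_max: float) -> set[str]:
    """Exhaustive six-frame SW recruitment over the full search space."""
    m = sum(len(p.seq) for p in panel)
    n = sum(sum((len(r.seq) - off) // 3 for off in (0, 1, 2)) * 2
            for r in reads)
    recruited = set()
    for read in reads:
        frames = [translate_frame(read.seq, f) for f in (1, 2, 3, -1, -2, -3)]
        for prot in panel:
            for aa in frames:
                if not aa:
                    continue
                s = sw_score(aa, prot.seq)
                if s > 0 and evalue(s, m, n) <= evalue_max:
                    recruited.add(read.id)
                    break
            if read.id in recruited:
                break
    return recruited


def overlap_oracle(a: str, b: str, min_len: int, min_identity: float):
    """Best ungapped overlap of b (as given) on a over all offsets.

    Returns (offset, length, identity) or None — the all-offset scan
    the assembler's overlap finder is checked against.
    """
    la, lb = len(a), len(b)
    best = None
    for s in range(-(lb - 1), la):
        lo, hi = max(0, s), min(la, s + lb)
        ov = hi - lo
        if ov < min_len:
            continue
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - s])
        ident = matches / ov
        if ident < min_identity:
            continue
        if best is None or (ov, ident) > (best[1], best[2]):
            best = (s, ov, ident)
    return best
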