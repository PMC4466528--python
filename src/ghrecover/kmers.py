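"""Vectorised 2-bit k-mer encoding and exact-match index (numpy-backed).

Used as the seeding layer of the overlap finder, the contig extender and
the depth mapper.  k-mers containing ``N`` are dropped.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..3 with 4 for N."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer values and a validity mask (no N inside).

    Returns ``(values, valid)`` of length ``len(codes) - k + 1`` (empty
    arrays when the sequence is shorter than k).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    vals = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        vals = (vals << np.uint64(2)) | (c & 3).astype(np.uint64)
        valid &= c != 4
    return vals, valid


class KmerIndex:
    """Sorted-array exact k-mer index over a set of sequences."""

    def __init__(self, k: int):
        self.k = k
        self._vals: list[np.ndarray] = []
        self._owner: list[np.ndarray] = []
        self._pos: list[np.ndarray] = []
        self.vals = np.empty(0, dtype=np.uint64)
        self.owner = np.empty(0, dtype=np.int64)
        self.pos = np.empty(0, dtype=np.int64)

    def add(self, owner_id: int, codes: np.ndarray,
            start: int = 0, end: int | None = None) -> None:
        """Index k-mers of ``codes[start:end]`` (positions kept absolute)."""
        sub = codes[start:end]
        vals, valid = kmer_values(sub, self.k)
        if len(vals) == 0:
            return
        idx = np.nonzero(valid)[0]
        self._vals.append(vals[idx])
        self._owner.append(np.full(len(idx), owner_id, dtype=np.int64))
        self._pos.append(idx + start)

    def build(self) -> None:
        if self._vals:
            vals = np.concatenate(self._vals)
            owner = np.concatenate(self._owner)
            pos = np.concatenate(self._pos)
            order = np.argsort(vals, kind="stable")
            self.vals, self.owner, self.pos = vals[order], owner[order], pos[order]
        self._vals, self._owner, self._pos = [], [], []

    def query(self, qvals: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Match query k-mer values against the index.

        Returns ``(query_idx, owner, pos)`` triples, one row per hit.
        """
        if len(self.vals) == 0 or len(qvals) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        lo = np.searchsorted(self.vals, qvals, side="left")
        hi = np.searchsorted(self.vals, qvals, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(len(qvals)), counts)
        if len(qidx) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        # flatten ranges [lo_i, hi_i) without a per-query python loop
        total = int(counts.sum())
        base = np.repeat(lo, counts)
        csum = np.cumsum(counts) - counts
        offsets = base + (np.arange(total) - np.repeat(csum, counts))
        return qidx, self.owner[offsets], self.pos[offsets]
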