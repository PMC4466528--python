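"""Six-frame translation under the bacterial genetic code (table 11).

Frames +1/+2/+3 read the forward strand with offsets 0/1/2; frames
-1/-2/-3 apply the same offsets to the reverse complement (the BLAST
convention).  Trailing partial codons are dropped; stop codons are
rendered ``*``; codons containing ``N`` translate to ``X``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .types import revcomp

FRAMES = (1, 2, 3, -1, -2, -3)


def _build_codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(table.forward_table)
    for stop in table.stop_codons:
        m[stop] = "*"
    return m


_CODON11 = _build_codon_map(11)

# aa -> list of codons, for codon-randomised reverse translation
SYNONYMOUS_CODONS_11: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON11.items()):
    SYNONYMOUS_CODONS_11.setdefault(_aa, []).append(_codon)

START_CODONS_11 = ("ATG", "GTG", "TTG")
STOP_CODONS_11 = tuple(sorted(c for c, a in _CODON11.items() if a == "*"))


def translate(seq: str, genetic_code: int = 11) -> str:
    """Translate a forward-strand nucleotide string, dropping the trailing
    partial codon."""
    if genetic_code != 11:
        raise ValueError("only genetic code table 11 is supported")
    n = len(seq) - len(seq) % 3
    out = []
    for i in range(0, n, 3):
        codon = seq[i:i + 3]
        out.append(_CODON11.get(codon, "X"))
    return "".join(out)


def translate_six_frames(seq: str, genetic_code: int = 11) -> dict[int, str]:
    """Return the six frame translations keyed by frame (+1..+3, -1..-3)."""
    rc = revcomp(seq)
    frames: dict[int, str] = {}
    for f in (1, 2, 3):
        frames[f] = translate(seq[f - 1:], genetic_code)
        frames[-f] = translate(rc[f - 1:], genetic_code)
    return frames


def frame_aa_to_read_nt(frame: int, aa_span: tuple[int, int], read_len: int
                        ) -> tuple[int, int]:
    """Map an aa interval on a frame translation to forward-strand nt coords."""
    a0, a1 = aa_span
    off = abs(frame) - 1
    s, e = off + 3 * a0, off + 3 * a1
    if frame > 0:
        return s, e
    return read_len - e, read_len - s
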