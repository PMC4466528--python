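"""Core domain types shared across the pipeline.

Coordinate convention: every interval stored on these types is 0-based,
half-open ``[start, end)`` on the forward strand of the sequence it refers
to.  GFF3 emission converts to 1-based inclusive at the boundary
(:func:`ghrecover.io.write_gff3`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_NT = frozenset("ACGTN")
VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class Read:
    """A single-end metagenomic read with an optional sample tag.

    ``qual`` holds Phred scores (Sanger scale, 0-60) when the read came
    from FASTQ; FASTA input leaves it ``None``.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    sample: str = ""

    def validate(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_NT
        if bad:
            raise ValueError(
                f"read {self.id!r}: non-IUPAC nucleotide(s) {sorted(bad)!r}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceProtein:
    """A reference panel protein carrying a family label such as ``GH5``."""

    id: str
    family: str
    seq: str

    def validate(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.family:
            raise ValueError(f"protein {self.id!r}: family label must be non-empty")
        if len(self.seq) < 30:
            raise ValueError(
                f"protein {self.id!r}: length {len(self.seq)} < 30 aa minimum"
            )
        bad = set(self.seq) - VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """Placement of one read inside a contig layout.

    ``start`` is the 0-based offset of the (oriented) read on the contig
    consensus; ``orientation`` is ``'+'`` if the read's forward strand
    matches the consensus, ``'-'`` if its reverse complement does.
    """

    read_id: str
    orientation: str  # '+' or '-'
    start: int
    identity: float


@dataclass
class Contig:
    id: str
    seq: str
    placements: list[Placement] = field(default_factory=list)
    per_sample_reads: dict[str, int] = field(default_factory=dict)
    depth: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Overlap:
    """A pairwise overlap between two reads.

    ``orientation`` ``'+'`` means ``read_b`` as given, ``'-'`` means its
    reverse complement.  ``offset`` is the start of the oriented
    ``read_b`` in ``read_a`` forward-strand coordinates and may be
    negative (``read_b`` begins left of ``read_a``).  ``length`` counts
    alignment columns in the overlapping region; ``identity`` is matches
    over columns, indel columns counting as mismatches.
    """

    read_a: str
    read_b: str
    orientation: str
    offset: int
    length: int
    identity: float


@dataclass(frozen=True)
class TranslatedHit:
    """One local alignment (HSP) of a translated read frame to a panel protein."""

    read_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    protein_id: str
    family: str
    score: int
    bitscore: float
    evalue: float
    read_span: tuple[int, int]  # 0-based half-open, read forward strand, nt
    protein_span: tuple[int, int]  # 0-based half-open, aa


@dataclass(frozen=True)
class ORF:
    """An open reading frame on a contig.

    ``span`` is on the contig forward strand and includes the stop codon
    when one is present; ``protein`` excludes the stop.  ``partial`` marks
    ORFs truncated by a contig edge (missing start codon and/or stop).
    """

    contig_id: str
    span: tuple[int, int]
    strand: str  # '+' or '-'
    frame: int  # 1, 2 or 3 on the reading strand
    protein: str
    partial: bool = False


@dataclass(frozen=True)
class GeneAnnotation:
    orf: ORF
    family: str  # e.g. "GH5", or "unassigned"
    best_protein_id: str = ""
    bitscore: float = 0.0
    evalue: float = float("inf")
    identity: float = 0.0


@dataclass(frozen=True)
class DepthRecord:
    contig_id: str
    sample: str  # sample name, or "ALL" for the pooled record
    mapped_reads: int
    depth: float  # mean per-base coverage


@dataclass(frozen=True)
class PrimerPair:
    contig_id: str
    fwd: str
    rev: str  # reverse-complement orientation (anneals to the + strand)
    fwd_pos: int  # 0-based start of the forward primer site on the contig
    rev_pos: int  # 0-based start of the reverse primer site (+ strand coords)
    product_len: int
    tm_fwd: float
    tm_rev: float


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, in one place.

    Defaults are the published operating point of the original screen:
    translated-search recruitment at e-value <= 1e-2 under the bacterial
    genetic code (table 11), overlap assembly at >= 40 bp / >= 90%
    identity, a >= 1 kb contig floor, the 16S screen at e <= 1e-5 /
    >= 65 nt / >= 80% identity, and primer validation at >= 95% amplicon
    identity.  All cutoffs are inclusive.
    """

    recruit_evalue_max: float = 1e-2
    genetic_code: int = 11
    min_overlap_len: int = 40
    min_overlap_identity: float = 0.90
    min_contig_len: int = 1000
    rrna_evalue_max: float = 1e-5
    rrna_min_len: int = 65
    rrna_min_identity: float = 0.80
    validation_min_identity: float = 0.95
    max_extension_iters: int = 20
    min_orf_nt: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_overlap_identity", "rrna_min_identity", "validation_min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_overlap_len", "min_contig_len", "rrna_min_len",
                     "max_extension_iters", "min_orf_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recruit_evalue_max <= 0:
            raise ValueError("recruit_evalue_max must be > 0")
        if self.rrna_evalue_max <= 0:
            raise ValueError("rrna_evalue_max must be > 0")
        if self.genetic_code != 11:
            raise ValueError("only genetic code table 11 is supported")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N nucleotide string."""
    return seq.translate(_COMP)[::-1]
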