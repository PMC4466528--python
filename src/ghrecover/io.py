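"""On-disk formats: FASTA, FASTQ (Phred+33), GFF3 and TSV reports.

Parsing goes through Bio.SeqIO; this module adds the strict validation
the pipeline relies on (unique ids, IUPAC alphabets, single FASTQ
dialect) and the 0-based/1-based conversion at the GFF3 boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .types import (
    VALID_AA,
    VALID_NT,
    Contig,
    GeneAnnotation,
    Read,
    ReferenceProtein,
)

_FAMILY_ATTR = re.compile(r"family=(\S+)")
_FAMILY_PREFIX = re.compile(r"^(GH\d+)")


def _find_offending_line(path: Path, record_id: str, valid: frozenset) -> int:
    """Locate the first line of a record containing a character outside *valid*."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].split() else False
                continue
            if in_record:
                if set(line.strip().upper()) - valid - {"*"}:
                    return lineno
    return -1


def read_fasta(path, *, as_proteins: bool = False, sample: str = ""):
    """Read a FASTA file into :class:`Read` or :class:`ReferenceProtein` records.

    Protein headers may carry a ``family=GH5`` attribute; failing that, a
    leading ``GH<digits>`` token of the id is used as the family label.
    Lowercase input is uppercased and a trailing ``*`` is stripped from
    protein sequences.  Duplicate ids, empty files and non-IUPAC
    characters are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if as_proteins:
            seq = seq.rstrip("*")
            if set(seq) - VALID_AA:
                lineno = _find_offending_line(path, rec.id, VALID_AA)
                raise ValueError(
                    f"{path}:{lineno}: record {rec.id!r} has non-IUPAC "
                    f"amino-acid character(s)"
                )
            m = _FAMILY_ATTR.search(rec.description) or _FAMILY_PREFIX.match(rec.id)
            if not m:
                raise ValueError(
                    f"{path}: record {rec.id!r} carries no family label "
                    f"(expected 'family=...' attribute or 'GH<n>' id prefix)"
                )
            prot = ReferenceProtein(id=rec.id, family=m.group(1), seq=seq)
            prot.validate()
            out.append(prot)
        else:
            if set(seq) - VALID_NT:
                lineno = _find_offending_line(path, rec.id, VALID_NT)
                raise ValueError(
                    f"{path}:{lineno}: record {rec.id!r} has non-IUPAC "
                    f"nucleotide character(s)"
                )
            read = Read(id=rec.id, seq=seq, sample=sample)
            read.validate()
            out.append(read)
    return out


def read_fastq(path, *, sample: str = "") -> list[Read]:
    """Read Sanger/Phred+33 FASTQ.  Qualities above 60 are rejected as a
    sign of a non-Sanger dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Read] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        quals = rec.letter_annotations["phred_quality"]
        if any(q > 60 or q < 0 for q in quals):
            raise ValueError(
                f"{path}: record {rec.id!r} has Phred scores outside 0-60; "
                f"only the Sanger/Phred+33 dialect is supported"
            )
        read = Read(id=rec.id, seq=str(rec.seq).upper(), qual=list(quals), sample=sample)
        read.validate()
        out.append(read)
    if not out:
        raise ValueError(f"{path}: empty FASTQ file")
    return out


def write_fasta(records: Iterable[Union[Read, ReferenceProtein, Contig]], path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else [30] * len(r.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


def write_gff3(annotations: Sequence[GeneAnnotation], path,
               contig_lengths: dict[str, int] | None = None) -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates).

    Internal spans are 0-based half-open, so ``[s, e)`` becomes
    ``start=s+1, end=e``.  When *contig_lengths* is given, out-of-range
    coordinates are a hard error.
    """
    lines = ["##gff-version 3"]
    for ann in annotations:
        orf = ann.orf
        s, e = orf.span
        if s < 0 or e <= s:
            raise ValueError(f"annotation on {orf.contig_id}: bad span {orf.span}")
        if contig_lengths is not None:
            clen = contig_lengths.get(orf.contig_id)
            if clen is None or e > clen:
                raise ValueError(
                    f"annotation span {orf.span} outside contig "
                    f"{orf.contig_id!r} (len {clen})"
                )
        score = f"{ann.bitscore:.1f}" if ann.family != "unassigned" else "."
        attrs = (
            f"ID=orf_{orf.contig_id}_{s}_{e}_{orf.strand};family={ann.family}"
            f";partial={'true' if orf.partial else 'false'}"
        )
        if ann.best_protein_id:
            attrs += f";best_hit={ann.best_protein_id};evalue={ann.evalue:.3g}"
        lines.append("\t".join([
            orf.contig_id, "ghrecover", "CDS", str(s + 1), str(e),
            score, orf.strand, "0", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as TSV with a header row (pandas-backed)."""
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
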