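"""ORF calling, GH-family assignment and the 16S metagenomic screen.

ORFs are called per stop-to-stop frame segment on both strands: within
each segment the longest reading frame starting at ATG/GTG/TTG (or at
the contig edge, flagged partial) and ending at a stop (or the edge,
flagged partial) is reported if it reaches ``min_orf_nt``.  Family
assignment is best-hit protein local alignment against the reference
panel under the same e-value cutoff as recruitment; contigs with at
least one assigned ORF are the GH-containing set.

The 16S screen retrieves reads with a nucleotide local alignment to any
reference at e-value <= 1e-5, aligned length >= 65 nt and identity
>= 80% (all inclusive), the published retrieval rule.
"""

from __future__ import annotations

import logging

from .align import best_local, nucleotide_aligner, protein_aligner
from .stats import nucleotide_stats, protein_stats
from .translate import START_CODONS_11, translate
from .types import (
    ORF,
    Contig,
    GeneAnnotation,
    PipelineConfig,
    Read,
    ReferenceProtein,
    revcomp,
)

logger = logging.getLogger(__name__)


def _orfs_on_strand(seq: str, min_orf_nt: int) -> list[tuple[int, int, int, bool]]:
    """ORFs on the forward strand of *seq*.

    Returns ``(start, end, frame, partial)`` in strand-local coordinates,
    end exclusive and including the stop codon when present.
    """
    out = []
    L = len(seq)
    for off in (0, 1, 2):
        ncod = (L - off) // 3
        if ncod == 0:
            continue
        seg_start = 0  # codon index where the current stop-free segment begins
        at_edge = True  # segment touches the 5' edge (no upstream stop)
        start_codon = None  # first ATG/GTG/TTG codon index in the segment
        for ci in range(ncod + 1):
            codon = seq[off + 3 * ci: off + 3 * ci + 3] if ci < ncod else ""
            is_stop = translate(codon) == "*" if len(codon) == 3 else False
            if ci == ncod or is_stop:
                # close the segment [seg_start, ci), stop at ci if is_stop
                cand_start = None
                partial5 = False
                if at_edge:
                    cand_start = seg_start
                    partial5 = start_codon != seg_start
                elif start_codon is not None:
                    cand_start = start_codon
                if cand_start is not None:
                    end_cod = ci + 1 if is_stop else ci
                    partial3 = not is_stop
                    s = off + 3 * cand_start
                    e = off + 3 * end_cod
                    if e - s >= min_orf_nt:
                        out.append((s, e, off + 1, partial5 or partial3))
                seg_start = ci + 1
                at_edge = False
                start_codon = None
            else:
                if start_codon is None and codon in START_CODONS_11:
                    start_codon = ci
    return out


def call_orfs(contig: Contig, min_orf_nt: int = 300,
              genetic_code: int = 11) -> list[ORF]:
    """Call ORFs >= *min_orf_nt* on both strands of a contig.

    One ORF per stop-delimited segment (the longest possible in that
    segment).  Edge-truncated ORFs are flagged partial.  Every reported
    protein translates without internal stops.
    """
    if genetic_code != 11:
        raise ValueError("only genetic code table 11 is supported")
    L = len(contig.seq)
    orfs: list[ORF] = []
    for strand in "+-":
        s_seq = contig.seq if strand == "+" else revcomp(contig.seq)
        for s, e, frame, partial in _orfs_on_strand(s_seq, min_orf_nt):
            prot = translate(s_seq[s:e]).rstrip("*")
            if "*" in prot:  # cannot arise from stop-free segments; guard anyway
                continue
            span = (s, e) if strand == "+" else (L - e, L - s)
            orfs.append(ORF(contig_id=contig.id, span=span, strand=strand,
                            frame=frame, protein=prot, partial=partial))
    orfs.sort(key=lambda o: (o.span, o.strand))
    return orfs


def assign_family(orf: ORF, panel: list[ReferenceProtein],
                  cfg: PipelineConfig) -> GeneAnnotation:
    """Best-hit family assignment of an ORF against the panel.

    Best bitscore wins; ties break by lower e-value, then higher
    identity, then lexicographic protein id — making the result
    invariant to panel order.  No hit at ``evalue <=
    cfg.recruit_evalue_max`` leaves the ORF "unassigned".
    """
    if not panel:
        raise ValueError("reference panel must be non-empty")
    m = sum(len(p.seq) for p in panel)
    stats = protein_stats(m, max(len(orf.protein), 1))
    aligner = protein_aligner()
    best = None  # (bitscore, -evalue is same order, identity, -id) tuple logic
    for prot in sorted(panel, key=lambda p: p.id):
        hit = best_local(orf.protein, prot.seq, aligner)
        if hit is None:
            continue
        ev = stats.evalue(hit.score)
        if ev > cfg.recruit_evalue_max:
            continue
        bs = stats.bitscore(hit.score)
        cand = (bs, -ev, hit.identity)
        if best is None or cand > best[0]:
            best = (cand, prot, hit, ev, bs)
    if best is None:
        return GeneAnnotation(orf=orf, family="unassigned")
    _, prot, hit, ev, bs = best
    return GeneAnnotation(orf=orf, family=prot.family, best_protein_id=prot.id,
                          bitscore=bs, evalue=ev, identity=hit.identity)


def annotate_contigs(contigs: list[Contig], panel: list[ReferenceProtein],
                     cfg: PipelineConfig) -> list[GeneAnnotation]:
    out = []
    for c in contigs:
        for orf in call_orfs(c, cfg.min_orf_nt, cfg.genetic_code):
            out.append(assign_family(orf, panel, cfg))
    return out


def select_gh_contigs(contigs: list[Contig],
                      annotations: list[GeneAnnotation]) -> list[Contig]:
    """Contigs carrying at least one family-assigned ORF."""
    assigned = {a.orf.contig_id for a in annotations if a.family != "unassigned"}
    return [c for c in contigs if c.id in assigned]


def screen_rrna(reads: list[Read], ref16s: list[Read],
                cfg: PipelineConfig) -> list[Read]:
    """Retrieve reads matching a 16S reference set.

    A read passes iff some local nucleotide alignment to a reference has
    e-value <= ``rrna_evalue_max`` AND >= ``rrna_min_len`` aligned
    columns AND identity >= ``rrna_min_identity`` (all inclusive).
    """
    if not ref16s:
        raise ValueError("16S reference set must be non-empty")
    m = sum(len(r.seq) for r in ref16s)
    n = sum(len(r.seq) for r in reads)
    stats = nucleotide_stats(m, max(n, 1))
    aligner = nucleotide_aligner()
    kept = []
    for read in reads:
        for ref in ref16s:
            found = False
            for qseq in (read.seq, revcomp(read.seq)):
                hit = best_local(qseq, ref.seq, aligner)
                if hit is None:
                    continue
                if (stats.evalue(hit.score) <= cfg.rrna_evalue_max
                        and hit.columns >= cfg.rrna_min_len
                        and hit.identity >= cfg.rrna_min_identity):
                    kept.append(read)
                    found = True
                    break
            if found:
                break
    return kept


def annotations_to_rows(annotations: list[GeneAnnotation]) -> list[dict]:
    return [{
        "contig_id": a.orf.contig_id,
        "start": a.orf.span[0], "end": a.orf.span[1],
        "strand": a.orf.strand, "frame": a.orf.frame,
        "partial": a.orf.partial, "family": a.family,
        "best_protein_id": a.best_protein_id,
        "bitscore": round(a.bitscore, 2),
        "evalue": f"{a.evalue:.3g}" if a.evalue != float("inf") else "",
        "identity": round(a.identity, 4),
    } for a in annotations]
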