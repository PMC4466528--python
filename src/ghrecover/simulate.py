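"""Ground-truthed synthetic communities with 454-style single-end reads.

The generator emulates the data this pipeline was built for: a
two-digester community sequenced on a pyrosequencing platform.  Genomes
are random background sequence (GC 50%) carrying glycoside-hydrolase
genes obtained by codon-randomised reverse translation (code 11,
uniform synonymous choice) of a reference protein panel, embedded on
either strand.  Reads have broad 454-like lengths (Normal, mean 400 sd
100, truncated at 50 nt), uniform starts weighted by per-sample genome
abundances, iid substitution errors, and the platform's hallmark
+/-1 nt indels inside homopolymer runs >= 3.  Everything is recorded in
a truth ledger so downstream modules can be scored without re-deriving
anything.  Flowgram-level simulation and quality-coupled errors are out
of scope; qualities are constant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .translate import SYNONYMOUS_CODONS_11
from .types import Read, ReferenceProtein, revcomp

DEFAULT_FAMILIES = ("GH1", "GH3", "GH5", "GH9", "GH10", "GH11")
_HOMOPOLYMER = re.compile(r"(A{3,}|C{3,}|G{3,}|T{3,})")


@dataclass(frozen=True)
class SampleSpec:
    name: str
    n_reads: int
    abundances: tuple[float, ...]  # one weight per genome, sums to 1


@dataclass
class SimConfig:
    n_genomes: int = 10
    genome_len: int = 40_000
    genes_per_genome: int = 2
    samples: list[SampleSpec] | None = None  # default: Z7/Z8, lognormal
    n_reads_per_sample: int = 20_000  # used only for the default samples
    read_len_mean: float = 400.0
    read_len_sd: float = 100.0
    read_len_min: int = 50
    subst_rate: float = 0.003
    homopolymer_indel_rate: float = 0.01
    base_quality: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subst_rate", "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_len_min < 1:
            raise ValueError("read_len_min must be >= 1")
        if self.n_reads_per_sample < 1:
            raise ValueError("n_reads_per_sample must be >= 1")
        if self.n_genomes < 1 or self.genes_per_genome < 0:
            raise ValueError("n_genomes >= 1 and genes_per_genome >= 0 required")
        if self.samples is not None:
            for s in self.samples:
                if s.n_reads < 1:
                    raise ValueError(f"sample {s.name}: n_reads must be >= 1")
                if len(s.abundances) != self.n_genomes:
                    raise ValueError(
                        f"sample {s.name}: abundance vector length "
                        f"{len(s.abundances)} != n_genomes {self.n_genomes}")
                if abs(sum(s.abundances) - 1.0) > 1e-6:
                    raise ValueError(f"sample {s.name}: abundances must sum to 1")


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    genome_id: str
    family: str
    protein_id: str
    interval: tuple[int, int]  # 0-based half-open, genome forward strand
    strand: str


@dataclass(frozen=True)
class ReadOrigin:
    genome_id: str
    interval: tuple[int, int]
    strand: str
    n_subst: int
    n_indel: int


@dataclass
class SimTruth:
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    genes: list[GenePlacement] = field(default_factory=list)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)
    gene_seqs: dict[str, str] = field(default_factory=dict)


def synthetic_panel(seed: int = 0, families=DEFAULT_FAMILIES,
                    per_family: int = 4,
                    length_range: tuple[int, int] = (450, 520)
                    ) -> list[ReferenceProtein]:
    """A synthetic reference protein panel (random sequences, labelled by
    family).  Stands in for a curated GH panel in tests and simulations;
    real panels are read from FASTA with ``family=`` header attributes.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    panel = []
    for fam in families:
        for i in range(per_family):
            ln = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "M" + "".join(rng.choice(aas, size=ln - 1))
            panel.append(ReferenceProtein(id=f"{fam}_syn{i + 1}", family=fam,
                                          seq=seq))
    return panel


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Codon-randomised reverse translation under code 11 (uniform
    synonymous choice), with a uniformly chosen stop codon appended."""
    codons = []
    for aa in protein:
        options = SYNONYMOUS_CODONS_11[aa]
        codons.append(options[int(rng.integers(len(options)))])
    stops = SYNONYMOUS_CODONS_11["*"]
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


def _lognormal_abundances(rng: np.random.Generator, n: int) -> tuple[float, ...]:
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    w = w / w.sum()
    return tuple(float(x) for x in w)


def simulate_community(cfg: SimConfig,
                       panel: list[ReferenceProtein] | None = None
                       ) -> tuple[dict[str, str], SimTruth, list[ReferenceProtein]]:
    """Generate genomes with embedded panel genes and the truth ledger.

    Returns ``(genomes, truth, panel)``; deterministic under
    ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if panel is None:
        panel = synthetic_panel(seed=int(rng.integers(2 ** 31)))
    bases = np.array(list("ACGT"))
    genomes: dict[str, str] = {}
    truth = SimTruth()

    samples = cfg.samples
    if samples is None:
        samples = [
            SampleSpec("Z7", cfg.n_reads_per_sample,
                       _lognormal_abundances(rng, cfg.n_genomes)),
            SampleSpec("Z8", cfg.n_reads_per_sample,
                       _lognormal_abundances(rng, cfg.n_genomes)),
        ]
    for s in samples:
        truth.abundances[s.name] = {}

    # distinct panel proteins across the community while the panel lasts:
    # two codon-randomised copies of one protein are ~75-80% identical at
    # the nt level and would model near-paralogs rather than distinct genes
    total_genes = cfg.n_genomes * cfg.genes_per_genome
    protein_order: list[int] = []
    while len(protein_order) < total_genes:
        protein_order.extend(int(i) for i in rng.permutation(len(panel)))

    margin = 200
    gene_no = 0
    for gi in range(cfg.n_genomes):
        gid = f"genome_{gi + 1:03d}"
        background = "".join(rng.choice(bases, size=cfg.genome_len))
        seq = list(background)
        placed: list[tuple[int, int]] = []
        for gj in range(cfg.genes_per_genome):
            prot = panel[protein_order[gene_no]]
            gene_no += 1
            gene_nt = reverse_translate(prot.seq, rng)
            if len(gene_nt) + 2 * margin > cfg.genome_len:
                raise ValueError(
                    f"gene of {len(gene_nt)} nt does not fit in a "
                    f"{cfg.genome_len} nt genome")
            for _attempt in range(1000):
                start = int(rng.integers(margin,
                                         cfg.genome_len - len(gene_nt) - margin))
                iv = (start, start + len(gene_nt))
                if all(iv[1] + margin <= a or iv[0] >= b + margin
                       for a, b in placed):
                    break
            else:
                raise ValueError("could not place gene without overlap")
            placed.append(iv)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = gene_nt if strand == "+" else revcomp(gene_nt)
            seq[iv[0]:iv[1]] = list(insert)
            gene_id = f"{gid}_gene{gj + 1}"
            truth.genes.append(GenePlacement(gene_id, gid, prot.family,
                                             prot.id, iv, strand))
            truth.gene_seqs[gene_id] = insert
        genomes[gid] = "".join(seq)

    for s in samples:
        for gi, w in enumerate(s.abundances):
            truth.abundances[s.name][f"genome_{gi + 1:03d}"] = float(w)
    return genomes, truth, panel


def _apply_454_errors(seq: str, rng: np.random.Generator, subst_rate: float,
                      homopolymer_indel_rate: float) -> tuple[str, int, int]:
    """(mutated sequence, n_substitutions, n_indels)."""
    n_sub = 0
    if subst_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < subst_rate)[0]
        bases = b"ACGT"
        for i in hits:
            cur = arr[i]
            alts = [b for b in bases if b != cur]
            arr[i] = alts[int(rng.integers(3))]
        n_sub = len(hits)
        seq = arr.tobytes().decode()
    n_indel = 0
    if homopolymer_indel_rate > 0:
        pieces = []
        last = 0
        for m in _HOMOPOLYMER.finditer(seq):
            pieces.append(seq[last:m.start()])
            run = m.group(0)
            if rng.random() < homopolymer_indel_rate:
                n_indel += 1
                if rng.random() < 0.5:
                    run = run + run[0]  # over-call
                else:
                    run = run[:-1]  # under-call
            pieces.append(run)
            last = m.end()
        pieces.append(seq[last:])
        seq = "".join(pieces)
    return seq, n_sub, n_indel


def simulate_reads(genomes: dict[str, str], truth: SimTruth, cfg: SimConfig
                   ) -> tuple[list[Read], SimTruth]:
    """Draw 454-style reads per sample; origins are added to the ledger."""
    rng = np.random.default_rng(cfg.rng_seed + 1)
    samples = cfg.samples
    if samples is None:
        if not truth.abundances:
            raise ValueError("truth carries no sample abundances")
        samples = [SampleSpec(name, cfg.n_reads_per_sample,
                              tuple(truth.abundances[name][g]
                                    for g in sorted(genomes)))
                   for name in sorted(truth.abundances)]
    gids = sorted(genomes)
    reads: list[Read] = []
    for s in samples:
        weights = np.asarray(s.abundances, dtype=float)
        choices = rng.choice(len(gids), size=s.n_reads, p=weights / weights.sum())
        lengths = rng.normal(cfg.read_len_mean, cfg.read_len_sd, size=s.n_reads)
        for i in range(s.n_reads):
            gid = gids[int(choices[i])]
            gseq = genomes[gid]
            ln = int(round(lengths[i]))
            ln = max(cfg.read_len_min, min(ln, len(gseq)))
            start = int(rng.integers(0, len(gseq) - ln + 1))
            frag = gseq[start:start + ln]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            frag, n_sub, n_indel = _apply_454_errors(
                frag, rng, cfg.subst_rate, cfg.homopolymer_indel_rate)
            rid = f"{s.name}_r{i + 1:06d}"
            reads.append(Read(id=rid, seq=frag,
                              qual=[cfg.base_quality] * len(frag),
                              sample=s.name))
            truth.read_origins[rid] = ReadOrigin(
                gid, (start, start + ln), strand, n_sub, n_indel)
    return reads, truth


def simulate(cfg: SimConfig, panel: list[ReferenceProtein] | None = None
             ) -> tuple[dict[str, str], list[Read], SimTruth,
                        list[ReferenceProtein]]:
    """Community + reads in one call."""
    genomes, truth, panel = simulate_community(cfg, panel)
    reads, truth = simulate_reads(genomes, truth, cfg)
    return genomes, reads, truth, panel
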