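"""Stage orchestration: simulate -> recruit -> assemble -> extend ->
annotate -> depth -> validate, with a manifest for reproducibility.

Stages communicate through plain-text artifacts in one output
directory, so any stage can be rerun or inspected in isolation.  The
manifest records every parameter value, the seed and the SHA-256 of
every artifact; two runs with identical config produce identical
manifests.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import annotate as annotate_mod
from . import assembly, depth, extend, io, primers, recruit
from .simulate import SimConfig
from .simulate import simulate as _simulate
from .types import Contig, Placement, PipelineConfig, Read

logger = logging.getLogger(__name__)

STAGES = ("simulate", "recruit", "assemble", "extend", "annotate",
          "depth", "validate")


# ---------------------------------------------------------------------------
# config parsing

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"samples"}
_CFG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> tuple[PipelineConfig, SimConfig]:
    """Parse a flat key=value config file.

    ``[defaults]`` holds pipeline thresholds, ``[simulate]`` the
    simulator settings.  Unknown keys are hard errors.
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(path)
    cfg_kwargs = {}
    for key, val in parser.items("defaults") if parser.has_section("defaults") else []:
        if key not in _CFG_KEYS:
            raise ValueError(f"unknown config key in [defaults]: {key!r}")
        field = next(f for f in dataclasses.fields(PipelineConfig) if f.name == key)
        cfg_kwargs[key] = _coerce(field, val)
    sim_kwargs = {}
    if parser.has_section("simulate"):
        for key, val in parser.items("simulate"):
            if key not in _SIM_KEYS:
                raise ValueError(f"unknown config key in [simulate]: {key!r}")
            field = next(f for f in dataclasses.fields(SimConfig)
                         if f.name == key)
            sim_kwargs[key] = _coerce(field, val)
    return PipelineConfig(**cfg_kwargs), SimConfig(**sim_kwargs)


def _coerce(field, val: str):
    t = str(field.type)
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val


# ---------------------------------------------------------------------------
# artifact helpers

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def contigs_to_files(contigs: list[Contig], fasta: Path, layout: Path) -> None:
    io.write_fasta(contigs, fasta)
    rows = []
    for c in contigs:
        for p in c.placements:
            rows.append({"contig_id": c.id, "read_id": p.read_id,
                         "orientation": p.orientation, "start": p.start,
                         "identity": p.identity})
    io.write_tsv(rows, layout,
                 columns=["contig_id", "read_id", "orientation", "start",
                          "identity"])


def contigs_from_files(fasta: Path, layout: Path,
                       sample_of: dict[str, str] | None = None) -> list[Contig]:
    recs = io.read_fasta(fasta)
    placements: dict[str, list[Placement]] = {}
    if layout.exists():
        df = io.read_tsv(layout)
        for row in df.itertuples(index=False):
            placements.setdefault(row.contig_id, []).append(
                Placement(str(row.read_id), row.orientation, int(row.start),
                          float(row.identity)))
    out = []
    for r in recs:
        pls = placements.get(r.id, [])
        per_sample: dict[str, int] = {}
        for p in pls:
            smp = (sample_of or {}).get(p.read_id, "")
            per_sample[smp] = per_sample.get(smp, 0) + 1
        out.append(Contig(id=r.id, seq=r.seq, placements=pls,
                          per_sample_reads=per_sample))
    return out


def _load_reads(outdir: Path, reads_path: Path | None) -> list[Read]:
    if reads_path is None:
        reads_path = outdir / "reads.fastq"
    if not Path(reads_path).exists():
        raise FileNotFoundError(f"reads input missing: {reads_path}")
    p = Path(reads_path)
    if p.suffix in (".fastq", ".fq"):
        reads = io.read_fastq(p)
    else:
        reads = io.read_fasta(p)
    # sample tag convention: "<sample>_r<number>" read ids
    for r in reads:
        if not r.sample and "_r" in r.id:
            r.sample = r.id.rsplit("_r", 1)[0]
    return reads


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: PipelineConfig, outdir,
                 sim_cfg: SimConfig | None = None,
                 stages: tuple[str, ...] = STAGES,
                 reads_path=None, panel_path=None, templates_path=None
                 ) -> dict:
    """Run the selected stages in fixed order; returns the manifest dict.

    Missing inputs for a selected stage are a hard error before any
    work.  All randomness flows from ``cfg.rng_seed`` (the simulator
    uses ``sim_cfg.rng_seed``, set from the same top-level seed by the
    CLI).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    stages = tuple(st for st in STAGES if st in stages)

    # fail fast on missing inputs
    if "simulate" not in stages:
        need_reads = {"recruit", "extend", "depth"} & set(stages)
        if need_reads and reads_path is None \
                and not (outdir / "reads.fastq").exists():
            raise FileNotFoundError("no reads input for selected stages")
        if {"recruit", "annotate"} & set(stages) and panel_path is None \
                and not (outdir / "panel.fasta").exists():
            raise FileNotFoundError("no reference panel for selected stages")

    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "sim_config": dataclasses.asdict(sim_cfg) if sim_cfg else None,
        "stages": list(stages),
        "artifacts": {},
    }
    if manifest["sim_config"] and manifest["sim_config"].get("samples"):
        manifest["sim_config"]["samples"] = [
            dataclasses.asdict(s) for s in sim_cfg.samples]

    def record(*paths: Path) -> None:
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)

    panel = None
    if "simulate" in stages:
        if sim_cfg is None:
            raise ValueError("simulate stage selected without a SimConfig")
        genomes, reads, truth, panel = _simulate(sim_cfg)
        io.write_fasta([Read(id=g, seq=s) for g, s in sorted(genomes.items())],
                       outdir / "genomes.fasta")
        io.write_fastq(reads, outdir / "reads.fastq")
        with open(outdir / "panel.fasta", "w") as fh:
            for p in panel:
                fh.write(f">{p.id} family={p.family}\n{p.seq}\n")
        io.write_tsv([{
            "gene_id": g.gene_id, "genome_id": g.genome_id,
            "family": g.family, "protein_id": g.protein_id,
            "start": g.interval[0], "end": g.interval[1], "strand": g.strand,
        } for g in truth.genes], outdir / "truth_genes.tsv")
        io.write_tsv([{"sample": s, "genome_id": g, "abundance": round(w, 6)}
                      for s, d in sorted(truth.abundances.items())
                      for g, w in sorted(d.items())],
                     outdir / "truth_abundances.tsv")
        record(outdir / "genomes.fasta", outdir / "reads.fastq",
               outdir / "panel.fasta", outdir / "truth_genes.tsv",
               outdir / "truth_abundances.tsv")

    reads = None
    sample_of: dict[str, str] = {}

    def get_reads() -> list[Read]:
        nonlocal reads
        if reads is None:
            reads = _load_reads(outdir, reads_path)
            sample_of.update({r.id: r.sample for r in reads})
        else:
            sample_of.update({r.id: r.sample for r in reads})
        return reads

    def get_panel():
        nonlocal panel
        if panel is None:
            p = Path(panel_path) if panel_path else outdir / "panel.fasta"
            panel = io.read_fasta(p, as_proteins=True)
        return panel

    if "recruit" in stages:
        recruited, hits = recruit.recruit_reads(get_reads(), get_panel(), cfg)
        io.write_fasta(recruited, outdir / "recruited.fasta")
        io.write_tsv(recruit.hits_to_rows(hits), outdir / "hits.tsv")
        record(outdir / "recruited.fasta", outdir / "hits.tsv")

    if "assemble" in stages:
        rec_path = outdir / "recruited.fasta"
        if not rec_path.exists():
            raise FileNotFoundError("assemble stage needs recruited.fasta")
        all_reads = {r.id: r for r in get_reads()}
        rec_reads = [all_reads[r.id] for r in io.read_fasta(rec_path)]
        contigs = assembly.assemble(rec_reads, cfg)
        contigs_to_files(contigs, outdir / "contigs_initial.fasta",
                         outdir / "layout_initial.tsv")
        record(outdir / "contigs_initial.fasta", outdir / "layout_initial.tsv")

    if "extend" in stages:
        cpath = outdir / "contigs_initial.fasta"
        if not cpath.exists():
            raise FileNotFoundError("extend stage needs contigs_initial.fasta")
        get_reads()
        contigs = contigs_from_files(cpath, outdir / "layout_initial.tsv",
                                     sample_of)
        globals_ = None
        extended, reports = extend.extend_contigs(contigs, get_reads(), cfg,
                                                  globals_)
        kept = extend.filter_by_length(extended, cfg)
        contigs_to_files(extended, outdir / "contigs_extended.fasta",
                         outdir / "layout_extended.tsv")
        contigs_to_files(kept, outdir / "contigs_filtered.fasta",
                         outdir / "layout_filtered.tsv")
        io.write_tsv([{
            "contig_id": r.contig_id, "end": r.end,
            "iterations": r.iterations, "nt_added": r.nt_added,
            "status": r.status,
        } for r in reports], outdir / "extension_report.tsv")
        record(outdir / "contigs_extended.fasta",
               outdir / "contigs_filtered.fasta",
               outdir / "extension_report.tsv")

    if "annotate" in stages:
        cpath = outdir / "contigs_filtered.fasta"
        if not cpath.exists():
            raise FileNotFoundError("annotate stage needs contigs_filtered.fasta")
        contigs = contigs_from_files(cpath, outdir / "layout_filtered.tsv",
                                     sample_of)
        anns = annotate_mod.annotate_contigs(contigs, get_panel(), cfg)
        gh = annotate_mod.select_gh_contigs(contigs, anns)
        io.write_gff3(anns, outdir / "annotations.gff3",
                      {c.id: len(c.seq) for c in contigs})
        io.write_tsv(annotate_mod.annotations_to_rows(anns),
                     outdir / "annotations.tsv")
        contigs_to_files(gh, outdir / "gh_contigs.fasta",
                         outdir / "layout_gh.tsv")
        record(outdir / "annotations.gff3", outdir / "annotations.tsv",
               outdir / "gh_contigs.fasta")

    if "depth" in stages:
        cpath = outdir / "gh_contigs.fasta"
        if not cpath.exists():
            raise FileNotFoundError("depth stage needs gh_contigs.fasta")
        get_reads()
        contigs = contigs_from_files(cpath, outdir / "layout_gh.tsv", sample_of)
        if contigs:
            asg = depth.map_reads(contigs, get_reads())
            records = depth.compute_depth(asg, contigs, get_reads())
        else:
            records = []
        io.write_tsv(depth.depth_to_rows(records, contigs),
                     outdir / "depth.tsv",
                     columns=["contig_id", "length", "sample",
                              "mapped_reads", "depth"])
        record(outdir / "depth.tsv")

    if "validate" in stages:
        cpath = outdir / "gh_contigs.fasta"
        if not cpath.exists():
            raise FileNotFoundError("validate stage needs gh_contigs.fasta")
        contigs = contigs_from_files(cpath, outdir / "layout_gh.tsv", sample_of)
        tpath = Path(templates_path) if templates_path else outdir / "genomes.fasta"
        if not tpath.exists():
            raise FileNotFoundError(f"validate stage needs templates: {tpath}")
        templates = [(r.id, r.seq) for r in io.read_fasta(tpath)]
        rows = primers.validate_contigs(contigs, templates, cfg)
        io.write_tsv(rows, outdir / "validation.tsv",
                     columns=["contig_id", "verdict", "fwd", "rev",
                              "product_len", "amplicon_identity", "reasons"])
        record(outdir / "validation.tsv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
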