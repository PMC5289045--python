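"""End-to-end orchestration: simulate -> structure -> call -> effects ->
design -> status -> diverge, with TSV outputs, a checksummed manifest and a
human-readable report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import divergence, effects, markers, pooled, structure, synthetic
from .plastome_io import (
    Plastome,
    PlastomeError,
    RunConfig,
    read_enzyme_catalog,
    write_gff3,
    write_plastome,
    write_variants_vcf,
)

logger = logging.getLogger("plastmarker")


@dataclass
class PipelineConfig:
    run: RunConfig = field(default_factory=RunConfig)
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)
    max_markers: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        run_kw = {
            k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__
        }
        synth_kw = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in (data.get("synthetic") or {}).items()
            if k in synthetic.SynthConfig.__dataclass_fields__
        }
        seed = data.get("seed", 0)
        run_kw.setdefault("seed", seed)
        synth_kw.setdefault("seed", seed)
        return cls(
            run=RunConfig(**run_kw),
            synth=synthetic.SynthConfig(**synth_kw),
            max_markers=data.get("max_markers", 8),
        )


@dataclass
class RunManifest:
    seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory artifacts of a pipeline run (outputs also land on disk)."""

    manifest: RunManifest
    genomes: dict[str, Plastome]
    truth: "synthetic.SynthTruth"
    panels: dict[str, list[Plastome]]
    records: list
    markers: list
    pools: dict[str, "pooled.PoolCounts"]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run the full synthetic-to-markers workflow; idempotent per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.synth.seed, config={
        "run": asdict(cfg.run), "synth": asdict(cfg.synth)})
    t0 = time.time()

    def stage(name):
        manifest.timings[name] = round(time.time() - t0, 3)

    # --- simulate -----------------------------------------------------
    ancestor = synthetic.generate_ancestor(cfg.synth)
    genomes, truth = synthetic.derive_species(ancestor, cfg.synth)
    panels: dict[str, list[Plastome]] = {}
    for label, n_geno, n_var in zip(
        truth.species, cfg.synth.genotypes, cfg.synth.intraspecific_counts
    ):
        rng = cfg.synth.rng(f"panel_{label}")
        panel, pvs = synthetic.derive_genotype_panel(
            genomes[label], n_geno, n_var, rng,
            avoid=truth.interspecific_positions(label),
        )
        panels[label] = panel
        truth.panel_variants[label] = pvs
    for label, g in genomes.items():
        write_plastome(g, outdir / f"genome_{label}.fasta")
        write_gff3(g.features, g.id, outdir / f"genome_{label}.gff3")
    synthetic.write_truth_tables(truth, outdir)
    stage("simulate")

    # --- structure ----------------------------------------------------
    with open(outdir / "structure.tsv", "w") as fh:
        fh.write("species\tlength\tlsc\tssc\tir\tgc\n")
        for label, g in genomes.items():
            s = structure.structure_summary(g, min_ir=min(10_000, g.length // 8))
            fh.write(
                f"{label}\t{s['length']}\t{s['lsc']}\t{s['ssc']}\t{s['ir']}\t{s['gc']}\n"
            )
    stage("structure")

    # --- call ---------------------------------------------------------
    ref = genomes["A"]
    pools = {}
    for label in ("A", "B"):
        rng = cfg.synth.rng(f"reads_{label}")
        reads, _ = synthetic.simulate_pooled_reads(panels[label], cfg.synth, rng)
        synthetic.write_fastq(reads, outdir / f"pool_{label}.fastq")
        alns, _ = pooled.map_reads_exactish(reads, ref)
        pools[label] = pooled.pileup(alns, ref, species=label)
    records = pooled.classify_sites(pools["A"], pools["B"], cfg.run, ref)
    if ref.partition is not None:
        records = pooled.mirror_ir_sites(records, ref.partition, ref.length)
    aln_ab = divergence.genome_alignment(ref, genomes["B"])
    posmap = divergence.build_position_map(aln_ab)
    for r in records:
        r.position_b = posmap.map(r.position)[0]
    stage("call")

    # --- effects ------------------------------------------------------
    effects.annotate_records(records, ref)
    write_variants_vcf(records, ref, outdir / "variants.vcf")
    with open(outdir / "variants.tsv", "w") as fh:
        fh.write("pos_A\tallele_A\tpos_B\tallele_B\tclass\teffect\tdepth_A\tdepth_B\n")
        for r in records:
            fh.write(
                f"{r.position}\t{r.allele_a}\t{r.position_b}\t{r.allele_b}\t"
                f"{r.site_class}\t{r.effect}\t{r.depth_a}\t{r.depth_b}\n"
            )
    stage("effects")

    # --- design + status ---------------------------------------------
    catalog = read_enzyme_catalog()
    fixed = [r for r in records if r.site_class == "fixed_interspecific"]
    designed: list = []
    design_genomes = {"A": genomes["A"], "B": genomes["B"]}
    for i, snp in enumerate(fixed[: cfg.max_markers]):
        marker, reason = markers.design_caps(
            snp, design_genomes, catalog, cfg.run, marker_id=f"C{i + 1}"
        )
        if marker is None:
            logger.info("SNP %d: CAPS design failed (%s)", snp.position, reason)
            marker, reason = markers.design_arms(
                snp, design_genomes, cfg.run, marker_id=f"A{i + 1}"
            )
        if marker is None:
            continue
        markers.predict_marker_status(
            marker, {"A": panels["A"], "B": panels["B"]}, cfg.run
        )
        designed.append(marker)
    with open(outdir / "markers.tsv", "w") as fh:
        fh.write(
            "id\ttype\tsnp_pos\tfwd\trev\tlength_A\tlength_B\tta\tenzyme\t"
            "status_A\tstatus_B\tspecies_specific\n"
        )
        for m in designed:
            if isinstance(m, markers.CAPSMarker):
                fh.write(
                    f"{m.id}\tCAPS\t{m.snp_position}\t{m.fwd.sequence}\t{m.rev.sequence}\t"
                    f"{m.product_length.get('A')}\t{m.product_length.get('B')}\t"
                    f"{m.ta:.0f}\t{m.enzyme.name}\t{m.status.get('A')}\t{m.status.get('B')}\t"
                    f"{m.species_specific}\n"
                )
            else:
                fh.write(
                    f"{m.id}\tARMS\t{m.snp_position}\t{m.outer_fwd.sequence}\t"
                    f"{m.outer_rev.sequence}\t"
                    f"{m.allele_length.get('A')}/{m.common_length.get('A')}\t"
                    f"{m.allele_length.get('B')}/{m.common_length.get('B')}\t"
                    f"{m.ta:.0f}\t-\t{m.status.get('A')}\t{m.status.get('B')}\t"
                    f"{m.species_specific}\n"
                )
    stage("design")

    # --- diverge ------------------------------------------------------
    ranking = divergence.rank_coding_divergence(genomes["A"], genomes["B"])
    with open(outdir / "identity.tsv", "w") as fh:
        fh.write("region\tlength_A\tlength_B\tidentity\n")
        for rec in ranking:
            fh.write(
                f"{rec.region}\t{rec.length_a}\t{rec.length_b}\t{rec.identity:.2f}\n"
            )
    profile = divergence.sliding_identity(aln_ab, cfg.run.window, cfg.run.step)
    with open(outdir / "identity_profile.tsv", "w") as fh:
        fh.write("column\tidentity\n")
        for col, ident in profile:
            fh.write(f"{col}\t{ident:.2f}\n")
    stage("diverge")

    for f in sorted(outdir.iterdir()):
        if f.name not in ("manifest.json", "report.md") and f.is_file():
            manifest.outputs[f.name] = _sha256(f)
    manifest.write(outdir / "manifest.json")
    report(outdir)
    return PipelineResult(
        manifest=manifest, genomes=genomes, truth=truth, panels=panels,
        records=records, markers=designed, pools=pools,
    )


def report(outdir: str | Path) -> str:
    """Summarize pipeline outputs into a markdown report."""
    outdir = Path(outdir)
    lines = ["# plastmarker run summary", ""]

    def table(path: Path, title: str, limit: int = 20):
        if not path.exists():
            return
        rows = path.read_text().strip().splitlines()
        lines.append(f"## {title} ({len(rows) - 1} rows)")
        lines.append("")
        for row in rows[: limit + 1]:
            lines.append("    " + row)
        lines.append("")

    table(outdir / "structure.tsv", "Genome structure")
    table(outdir / "identity.tsv", "Lowest-identity coding regions")
    variants = outdir / "variants.tsv"
    if variants.exists():
        rows = variants.read_text().strip().splitlines()[1:]
        tallies: dict[str, int] = {}
        for row in rows:
            cls = row.split("\t")[4]
            tallies[cls] = tallies.get(cls, 0) + 1
        lines.append("## Variant classes")
        lines.append("")
        if tallies:
            for cls, n in sorted(tallies.items()):
                lines.append(f"- {cls}: {n}")
        else:
            lines.append("- no variant sites detected")
        lines.append("")
    table(outdir / "markers.tsv", "Markers")
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text
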