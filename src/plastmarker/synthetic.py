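"""Synthetic plastome trio, genotype panels, and pooled reads with known truth.

Generates three related circular genomes on the tree ((A,B),C) with a
quadripartite LSC/IRa/SSC/IRb layout, IR-mirrored mutations, per-species
genotype panels with contrasting diversity, and pooled short reads — so the
whole downstream pipeline can be exercised against a planted truth table.

All randomness flows from one seed through named child generators, so the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .plastome_io import (
    GeneFeature,
    Plastome,
    PlastomeError,
    RegionPartition,
    fasta_string,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SynthConfig:
    """Parameters for the synthetic trio; defaults emulate the study scale."""

    length: int = 151_000
    lsc_frac: float = 0.555
    ssc_frac: float = 0.122
    ir_frac: float = 0.1615
    branch_divergence: float = 0.002  # substitutions/site on each terminal branch
    internal_branch: float = 0.0005  # root -> (A,B) ancestor
    ts_tv_ratio: float = 1.0
    indel_rate: float = 0.0002
    indel_mean_len: float = 3.0
    genotypes: tuple[int, int, int] = (24, 24, 12)
    intraspecific_counts: tuple[int, int, int] = (218, 31, 31)
    read_length: int = 150
    coverage: float = 300.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.lsc_frac + self.ssc_frac + 2 * self.ir_frac
        if abs(total - 1.0) > 1e-9:
            raise PlastomeError(f"region fractions sum to {total}, not 1")
        for r in (self.branch_divergence, self.indel_rate, self.error_rate):
            if not 0 <= r < 1:
                raise PlastomeError(f"rate {r} outside [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator; fixed mapping from stream name to seed."""
        ss = np.random.SeedSequence([self.seed, abs(hash_stream(stream))])
        return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable (non-salted) string hash so stream seeds survive interpreter runs
    h = 2166136261
    for ch in name.encode():
        h = (h ^ ch) * 16777619 % (1 << 32)
    return h


@dataclass
class PlantedVariant:
    """One planted mutation, in ancestor-core and per-species coordinates."""

    anc_pos: int  # 1-based position in ancestor core (LSC+IRa+SSC)
    alleles: dict[str, str]  # species label -> base
    positions: dict[str, int]  # species label -> 1-based genome position
    mirror_positions: dict[str, Optional[int]]  # IR mirror coordinate or None
    in_ir: bool


@dataclass
class PanelVariant:
    """One intraspecific variant planted across a genotype panel."""

    species: str
    position: int  # 1-based on the species genome
    mirror_position: Optional[int]
    ref_allele: str
    alt_allele: str
    carriers: frozenset[int]


@dataclass
class SynthTruth:
    """Planted truth for the trio: tree, fixed differences, indel positions."""

    topology: str = "((A,B),C)"
    species: tuple[str, ...] = ("A", "B", "C")
    variants: list[PlantedVariant] = field(default_factory=list)
    panel_variants: dict[str, list[PanelVariant]] = field(default_factory=dict)
    indel_positions: dict[str, list[int]] = field(default_factory=dict)
    coordinate_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def interspecific_positions(self, sp: str) -> set[int]:
        """Planted interspecific site positions (and IR mirrors) for sp."""
        out: set[int] = set()
        for v in self.variants:
            if sp in v.positions:
                out.add(v.positions[sp])
                if v.mirror_positions.get(sp):
                    out.add(v.mirror_positions[sp])
        return out

    def indels_in_coords(self, sp: str) -> list[int]:
        """All planted indel sites (any species) lifted to sp's coordinates."""
        cmap = self.coordinate_maps[sp]
        out: set[int] = set()
        for sites in self.indel_positions.values():
            for p in sites:
                q = p - 1
                while q < len(cmap) and cmap[q] < 0:
                    q += 1
                if q < len(cmap):
                    out.add(int(cmap[q]) + 1)
        return sorted(out)

    def fixed_between(self, a: str, b: str) -> list[PlantedVariant]:
        """Planted sites where species a and b carry different bases."""
        out = []
        for v in self.variants:
            if a in v.positions and b in v.positions and v.alleles[a] != v.alleles[b]:
                out.append(v)
        return out


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def region_lengths(cfg: SynthConfig) -> tuple[int, int, int]:
    """(lsc, ir, ssc) lengths implied by the configured fractions."""
    ir = round(cfg.ir_frac * cfg.length)
    ssc = round(cfg.ssc_frac * cfg.length)
    lsc = cfg.length - ssc - 2 * ir
    if min(lsc, ssc, ir) <= 0:
        raise PlastomeError("region fractions infeasible at this length")
    return lsc, ir, ssc


def generate_ancestor(cfg: SynthConfig) -> Plastome:
    """Random circular genome with quadripartite layout and gene annotation.

    IRb is constructed as the exact reverse complement of IRa; IR-resident
    genes are mirrored, and one tRNA (``trnF-GAA``) is additionally placed in
    the LSC so it has three copies genome-wide.
    """
    lsc, ir, ssc = region_lengths(cfg)
    rng = cfg.rng("ancestor")
    core_len = lsc + ir + ssc
    core_arr = rng.choice(_BASES, size=core_len)
    # pin the four bases flanking the IR boundaries so the planted repeat is
    # maximal exactly at its construction edges (no chance extension)
    core_arr[[0, lsc - 1]] = ord("A")  # LSC first/last: A vs comp(A)=T differ
    core_arr[[lsc + ir, core_len - 1]] = ord("A")  # SSC first/last
    core = core_arr.tobytes().decode()
    ira_seq = core[lsc : lsc + ir]
    sequence = core + revcomp(ira_seq)
    partition = RegionPartition(
        lsc=(1, lsc),
        ira=(lsc + 1, lsc + ir),
        ssc=(lsc + ir + 1, core_len),
        irb=(core_len + 1, cfg.length),
    )
    features = _place_genes(cfg, rng, lsc, ir, ssc)
    p = Plastome("ancestor", sequence, features=features, partition=partition)
    p.partition.validate(p)
    return p


def _mirror_interval(iv: tuple[int, int], ira: tuple[int, int], irb: tuple[int, int]) -> tuple[int, int]:
    s, e = iv
    ms = irb[1] - (e - ira[0])
    me = irb[1] - (s - ira[0])
    return (ms, me)


def _place_genes(cfg: SynthConfig, rng, lsc: int, ir: int, ssc: int) -> list[GeneFeature]:
    core_len = lsc + ir + ssc
    ira = (lsc + 1, lsc + ir)
    irb = (core_len + 1, cfg.length)
    features: list[GeneFeature] = []
    counter = [0]

    def cds_name():
        counter[0] += 1
        return f"gene{counter[0]:03d}"

    def place_region(start: int, end: int, spec: Sequence[tuple[str, str]]):
        """Walk a region placing (kind, tag) genes with random gaps;
        genes that no longer fit are skipped."""
        placed = []
        pos = start
        for kind, tag in spec:
            pos += int(rng.integers(80, 300))  # intergenic gap
            if kind == "CDS":
                length = int(rng.integers(100, 500)) * 3
            elif kind == "tRNA":
                length = 75
            elif kind == "rRNA":
                length = min(1500, max(300, (end - start) // 5))
            else:
                length = int(rng.integers(60, 200))
            if pos + length - 1 > end:
                continue
            name = tag if tag else (
                cds_name() if kind == "CDS" else f"trn{counter[0]}-X{int(rng.integers(10, 99))}"
            )
            if kind in ("tRNA", "rRNA", "pseudo_or_ORF") and not tag:
                counter[0] += 1
            strand = "+" if rng.random() < 0.5 else "-"
            placed.append(GeneFeature(name, kind, strand, [(pos, pos + length - 1)]))
            pos += length
        return placed

    # LSC: CDS-rich, a few tRNAs, one two-exon CDS, one trnF-GAA copy
    n_lsc_cds = max(3, lsc // 4500)
    lsc_spec: list[tuple[str, str]] = []
    for i in range(n_lsc_cds):
        lsc_spec.append(("CDS", ""))
        if i % 4 == 1:
            lsc_spec.append(("tRNA", ""))
    lsc_feats = place_region(1, lsc - 1200, lsc_spec)
    # two-exon CDS for intron tests, placed at the tail of the LSC
    last_end = lsc_feats[-1].intervals[-1][1] if lsc_feats else 1
    ex1 = (last_end + 150, last_end + 349)  # 200 bases
    ex2 = (last_end + 500, last_end + 899)  # 400 bases -> total 600, %3 == 0
    if ex2[1] < lsc - 200:
        lsc_feats.append(GeneFeature("geneI", "CDS", "+", [ex1, ex2]))
        tail = ex2[1]
    else:
        tail = last_end
    if tail + 300 < lsc:
        lsc_feats.append(GeneFeature("trnF-GAA", "tRNA", "+", [(tail + 200, tail + 274)]))
    features.extend(lsc_feats)

    # SSC
    n_ssc_cds = max(1, ssc // 5000)
    features.extend(
        place_region(lsc + ir + 1, core_len - 100, [("CDS", "")] * n_ssc_cds + [("tRNA", "")])
    )

    # IRa, mirrored into IRb; trnF-GAA placed early so it survives at small
    # genome scales (its LSC copy makes three copies genome-wide)
    ira_spec: list[tuple[str, str]] = [("rRNA", "rrnL"), ("tRNA", "trnF-GAA"),
                                       ("rRNA", "rrnS"), ("CDS", ""),
                                       ("pseudo_or_ORF", "psiOrf1")]
    ira_feats = place_region(ira[0] + 50, ira[1] - 100, ira_spec)
    features.extend(ira_feats)
    flip = {"+": "-", "-": "+"}
    for f in ira_feats:
        mirrored = [_mirror_interval(iv, ira, irb) for iv in reversed(f.intervals)]
        features.append(
            GeneFeature(f.name, f.kind, flip[f.strand], mirrored, f.codon_start)
        )
    return features


# ---------------------------------------------------------------------------
# species derivation
# ---------------------------------------------------------------------------

def _draw_substitutions(rng, core_len: int, rate: float, n_override: Optional[int] = None):
    n = int(rng.binomial(core_len, rate)) if n_override is None else n_override
    pos = rng.choice(core_len, size=min(n, core_len), replace=False)
    return np.sort(pos)


def _substitute(rng, base: str, ts_tv_ratio: float) -> str:
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    if rng.random() < p_ts:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][int(rng.integers(2))]


def derive_species(
    ancestor: Plastome, cfg: SynthConfig
) -> tuple[dict[str, Plastome], SynthTruth]:
    """Mutate the ancestor along ((A,B),C); returns genomes plus truth.

    Substitutions are drawn per branch at the configured per-site rate; IR
    sites mutate in both copies (IRb replays IRa).  Indels are confined to
    single-copy regions.  Species genomes carry lifted annotations and a
    partition.
    """
    part = ancestor.partition
    if part is None:
        raise PlastomeError("ancestor lacks a partition")
    lsc_len = part.lsc[1]
    ir_len = part.ira[1] - part.ira[0] + 1
    core_len = part.ssc[1]  # LSC + IRa + SSC
    core = ancestor.sequence[:core_len]
    rng = cfg.rng("species")

    branches = {
        "AB": cfg.internal_branch,
        "A": cfg.branch_divergence,
        "B": cfg.branch_divergence,
        "C": cfg.branch_divergence,
    }
    subs: dict[str, dict[int, str]] = {}
    indels: dict[str, list[tuple[int, int, str]]] = {}  # (pos0, dlen, inserted)
    drawn_total = 0
    collisions = 0
    for label, rate in branches.items():
        positions = _draw_substitutions(rng, core_len, rate)
        d: dict[int, str] = {}
        for p in positions:
            d[int(p)] = _substitute(rng, core[int(p)], cfg.ts_tv_ratio)
        subs[label] = d
        drawn_total += len(d)
        # indels only outside the IR
        n_ind = int(rng.binomial(core_len, cfg.indel_rate))
        ev = []
        for _ in range(n_ind):
            while True:
                p = int(rng.integers(core_len))
                if not (lsc_len <= p < lsc_len + ir_len):  # 0-based IRa range
                    break
            length = int(rng.geometric(1.0 / cfg.indel_mean_len))
            if rng.random() < 0.5:
                ev.append((p, length, ""))  # deletion of `length` bases
            else:
                ins = rng.choice(_BASES, size=length).tobytes().decode()
                ev.append((p, 0, ins))
        indels[label] = ev

    paths = {"A": ("AB", "A"), "B": ("AB", "B"), "C": ("C",)}
    # collision accounting: same site hit on more than one branch of a path
    for sp, path in paths.items():
        seen: set[int] = set()
        for br in path:
            for p in subs[br]:
                if p in seen:
                    collisions += 1
                seen.add(p)
    if drawn_total and collisions / drawn_total > 0.05:
        raise PlastomeError(
            f"divergence too high: {collisions}/{drawn_total} planted sites collide"
        )

    genomes: dict[str, Plastome] = {}
    truth = SynthTruth()
    sp_allele: dict[str, dict[int, str]] = {}
    for sp, path in paths.items():
        merged: dict[int, str] = {}
        for br in path:
            merged.update(subs[br])  # later branch overrides
        sp_allele[sp] = merged
        merged_indels: list[tuple[int, int, str]] = []
        for br in path:
            merged_indels.extend(indels[br])
        genomes[sp], coord_map, indel_sites = _materialize(
            sp, ancestor, core, merged, merged_indels, lsc_len, ir_len, core_len
        )
        truth.coordinate_maps[sp] = coord_map
        truth.indel_positions[sp] = indel_sites

    all_sites = sorted(set().union(*(set(d) for d in sp_allele.values())))
    for p in all_sites:
        alleles = {}
        positions = {}
        mirrors = {}
        in_ir = lsc_len <= p < lsc_len + ir_len
        for sp in paths:
            cmap = truth.coordinate_maps[sp]
            if cmap[p] < 0:
                continue  # deleted in this species
            alleles[sp] = sp_allele[sp].get(p, core[p])
            positions[sp] = int(cmap[p]) + 1
            if in_ir:
                L = genomes[sp].length
                ira_sp = genomes[sp].partition.ira
                irb_sp = genomes[sp].partition.irb
                mirrors[sp] = irb_sp[1] - (positions[sp] - ira_sp[0])
            else:
                mirrors[sp] = None
        if len(alleles) >= 2 and len(set(alleles.values())) > 1:
            truth.variants.append(
                PlantedVariant(p + 1, alleles, positions, mirrors, in_ir)
            )
    return genomes, truth


def _materialize(
    label: str,
    ancestor: Plastome,
    core: str,
    subs: dict[int, str],
    indels: list[tuple[int, int, str]],
    lsc_len: int,
    ir_len: int,
    core_len: int,
):
    """Apply events (ancestor-core coordinates) and build the full genome."""
    arr = list(core)
    for p, b in subs.items():
        arr[p] = b
    deleted = np.zeros(core_len, dtype=bool)
    insertions: dict[int, str] = {}
    indel_sites: list[int] = []
    for p, dlen, ins in sorted(indels):
        if dlen:
            if deleted[p : p + dlen].any():
                continue  # overlapping indels rejected
            deleted[p : p + dlen] = True
        else:
            if p in insertions:
                continue
            insertions[p] = ins
        indel_sites.append(p + 1)

    out: list[str] = []
    coord_map = np.full(core_len, -1, dtype=np.int64)
    written = 0
    for p in range(core_len):
        if p in insertions:
            out.append(insertions[p])
            written += len(insertions[p])
        if not deleted[p]:
            coord_map[p] = written  # 0-based position in species core
            out.append(arr[p])
            written += 1
    new_core = "".join(out)
    ira_start = int(coord_map[lsc_len])  # IR has no indels -> always mapped
    ira_sp = new_core[ira_start : ira_start + ir_len]
    sequence = new_core + revcomp(ira_sp)
    n = len(sequence)
    partition = RegionPartition(
        lsc=(1, ira_start),
        ira=(ira_start + 1, ira_start + ir_len),
        ssc=(ira_start + ir_len + 1, len(new_core)),
        irb=(len(new_core) + 1, n),
    )
    features = _lift_features(ancestor, coord_map, partition)
    p = Plastome(label, sequence, features=features, partition=partition)
    p.partition.validate(p)
    return p, coord_map, indel_sites


def _lift_features(ancestor: Plastome, coord_map: np.ndarray, partition: RegionPartition):
    """Map ancestor features into the derived genome's coordinates."""
    core_len = len(coord_map)
    anc_part = ancestor.partition
    out = []
    for f in ancestor.features:
        s0, e0 = f.span()
        if s0 - 1 >= core_len:  # IRb feature: regenerate from mirror later
            continue
        ivs = []
        ok = True
        for s, e in f.intervals:
            s2 = _lift_pos(s - 1, coord_map, forward=True)
            e2 = _lift_pos(e - 1, coord_map, forward=False)
            if s2 is None or e2 is None or e2 < s2:
                ok = False
                break
            ivs.append((s2 + 1, e2 + 1))
        if not ok:
            continue
        partial = f.partial
        if f.kind == "CDS":
            length = sum(e - s + 1 for s, e in ivs)
            if length % 3 != 0:
                partial = True  # indel truncated this CDS
        out.append(GeneFeature(f.name, f.kind, f.strand, ivs, f.codon_start, partial))
    # mirror IRa-resident features into IRb
    flip = {"+": "-", "-": "+"}
    n = partition.irb[1]
    for f in list(out):
        if f.intervals[0][0] >= partition.ira[0] and f.intervals[-1][1] <= partition.ira[1]:
            mirrored = [
                _mirror_interval(iv, partition.ira, partition.irb)
                for iv in reversed(f.intervals)
            ]
            out.append(GeneFeature(f.name, f.kind, flip[f.strand], mirrored, f.codon_start, f.partial))
    out.sort(key=lambda f: f.intervals[0][0])
    return out


def _lift_pos(p0: int, coord_map: np.ndarray, forward: bool) -> Optional[int]:
    n = len(coord_map)
    q = p0
    while 0 <= q < n and coord_map[q] < 0:
        q += 1 if forward else -1
    if not 0 <= q < n:
        return None
    return int(coord_map[q])


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------

def derive_genotype_panel(
    species: Plastome,
    n_genotypes: int,
    n_variants: int,
    rng: np.random.Generator,
    avoid: Optional[set[int]] = None,
) -> tuple[list[Plastome], list[PanelVariant]]:
    """Plant segregating SNPs across a panel of genotype genomes.

    Each variant lands in a random nonempty proper subset of genotypes; with
    a single genotype no variants segregate.  IR-resident variants are
    mirrored (complemented) in the other IR copy.  ``avoid`` excludes
    positions (e.g. planted interspecific sites) so truth classes stay
    disjoint.
    """
    if n_genotypes < 1:
        raise PlastomeError("zero genotypes requested")
    if n_variants >= species.length / 100:
        raise PlastomeError("too many intraspecific variants for genome length")
    if n_genotypes == 1:
        return [Plastome(f"{species.id}_g0", species.sequence)], []

    part = species.partition
    core_len = part.ssc[1] if part else species.length
    allowed = np.arange(core_len)
    if avoid:
        blocked = np.array(sorted(p - 1 for p in avoid if 1 <= p <= core_len))
        allowed = np.setdiff1d(allowed, blocked, assume_unique=True)
    positions = np.sort(rng.choice(allowed, size=n_variants, replace=False))
    variants: list[PanelVariant] = []
    for p0 in positions:
        pos = int(p0) + 1
        ref = species.base(pos)
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        k = int(rng.integers(1, n_genotypes))  # 1 .. n-1 carriers
        carriers = frozenset(int(x) for x in rng.choice(n_genotypes, size=k, replace=False))
        mirror = None
        if part is not None and in_ir_a(pos, part):
            mirror = part.irb[1] - (pos - part.ira[0])
        variants.append(PanelVariant(species.id, pos, mirror, ref, alt, carriers))

    genomes = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for g in range(n_genotypes):
        arr = list(species.sequence)
        for v in variants:
            if g in v.carriers:
                arr[v.position - 1] = v.alt_allele
                if v.mirror_position is not None:
                    arr[v.mirror_position - 1] = comp[v.alt_allele]
        genomes.append(Plastome(f"{species.id}_g{g}", "".join(arr)))
    return genomes, variants


def in_ir_a(pos: int, part: RegionPartition) -> bool:
    return part.ira[0] <= pos <= part.ira[1]


# ---------------------------------------------------------------------------
# pooled reads
# ---------------------------------------------------------------------------

def simulate_pooled_reads(
    panel: Sequence[Plastome],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], dict]:
    """Uniform circular single-end reads pooled across a genotype panel.

    Returns ``(reads, summary)`` where reads are (name, sequence) pairs; the
    name encodes genotype, 0-based start and strand for truth lookups.
    Per-base errors are i.i.d. substitutions at ``cfg.error_rate``.
    """
    if not panel:
        raise PlastomeError("empty panel")
    L = panel[0].length
    rl = cfg.read_length
    if rl > L:
        raise PlastomeError("read length exceeds genome length")
    n_reads = int(round(cfg.coverage * L / rl))
    gi = rng.integers(len(panel), size=n_reads)
    starts = rng.integers(L, size=n_reads)
    strands = rng.integers(2, size=n_reads)
    n_errs = rng.binomial(rl, cfg.error_rate, size=n_reads)
    doubled = [p.sequence + p.sequence[:rl] for p in panel]
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        g = int(gi[i])
        s = int(starts[i])
        seq = doubled[g][s : s + rl]
        if strands[i]:
            seq = revcomp(seq)
        ne = int(n_errs[i])
        if ne:
            seq_l = list(seq)
            for p in rng.choice(rl, size=ne, replace=False):
                cur = seq_l[p]
                seq_l[p] = "ACGT".replace(cur, "")[int(rng.integers(3))]
            seq = "".join(seq_l)
        strand = "-" if strands[i] else "+"
        reads.append((f"r{i}|g{g}|p{s}|s{strand}", seq))
    summary = {
        "n_reads": n_reads,
        "read_length": rl,
        "expected_coverage": n_reads * rl / L,
    }
    return reads, summary


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header.strip().lstrip("@"), seq))
    return reads


def write_truth_tables(truth: SynthTruth, outdir: str | Path) -> None:
    """TSV truth tables: fixed interspecific sites and panel variants."""
    outdir = Path(outdir)
    with open(outdir / "truth_interspecific.tsv", "w") as fh:
        fh.write("anc_pos\tin_ir\t" + "\t".join(
            f"pos_{s}\tallele_{s}" for s in truth.species) + "\n")
        for v in truth.variants:
            row = [str(v.anc_pos), str(int(v.in_ir))]
            for s in truth.species:
                row.append(str(v.positions.get(s, "")))
                row.append(v.alleles.get(s, ""))
            fh.write("\t".join(row) + "\n")
    with open(outdir / "truth_panels.tsv", "w") as fh:
        fh.write("species\tposition\tmirror\tref\talt\tcarriers\n")
        for sp, pvs in truth.panel_variants.items():
            for v in pvs:
                fh.write(
                    f"{sp}\t{v.position}\t{v.mirror_position or ''}\t"
                    f"{v.ref_allele}\t{v.alt_allele}\t"
                    f"{','.join(map(str, sorted(v.carriers)))}\n"
                )
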