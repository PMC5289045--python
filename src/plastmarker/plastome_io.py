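"""Core data model and readers/writers for plastome pipeline file formats.

Coordinates are 1-based inclusive throughout (GenBank convention).  Circular
intervals may wrap the origin, represented as ``end < start``.

Formats handled here: FASTA (60-column), a documented GFF3 subset, minimal
GenBank flat records (via Biopython), a VCF v4.2 subset, a single-end SAM
subset (via pysam) and a tab-separated restriction-enzyme catalog.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

logger = logging.getLogger("plastmarker")

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC recognition pattern into a plain regex."""
    out = []
    for ch in pattern:
        bases = IUPAC_EXPAND[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


class PlastomeError(ValueError):
    """Malformed input or violated invariant in plastome data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """An annotated gene on a circular genome.

    ``intervals`` is an ordered list of 1-based inclusive (start, end) pairs;
    multi-interval features are exon structures, and an interval with
    end < start wraps the origin.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA | pseudo_or_ORF
    strand: str  # "+" or "-"
    intervals: list[tuple[int, int]]
    codon_start: int = 1
    partial: bool = False

    KINDS = ("CDS", "tRNA", "rRNA", "pseudo_or_ORF")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise PlastomeError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise PlastomeError(f"bad strand {self.strand!r}")
        if not self.intervals:
            raise PlastomeError(f"feature {self.name}: empty interval list")
        if self.codon_start not in (1, 2, 3):
            raise PlastomeError(f"feature {self.name}: codon_start {self.codon_start}")

    def length(self, genome_length: int) -> int:
        return sum(interval_length(iv, genome_length) for iv in self.intervals)

    def span(self) -> tuple[int, int]:
        """Outer span (first start, last end) in genome order."""
        return self.intervals[0][0], self.intervals[-1][1]

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(in_interval(pos, iv, genome_length) for iv in self.intervals)


def interval_length(iv: tuple[int, int], genome_length: int) -> int:
    start, end = iv
    if end >= start:
        return end - start + 1
    return genome_length - start + 1 + end


def in_interval(pos: int, iv: tuple[int, int], genome_length: int) -> bool:
    start, end = iv
    if end >= start:
        return start <= pos <= end
    return pos >= start or pos <= end


@dataclass
class RegionPartition:
    """Quadripartite partition LSC / IRa / SSC / IRb of a circular genome.

    The four intervals tile the circle; IRa and IRb are reverse complements
    of each other.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]

    def lengths(self, genome_length: int) -> dict[str, int]:
        return {
            "lsc": interval_length(self.lsc, genome_length),
            "ira": interval_length(self.ira, genome_length),
            "ssc": interval_length(self.ssc, genome_length),
            "irb": interval_length(self.irb, genome_length),
        }

    def validate(self, plastome: "Plastome") -> None:
        n = plastome.length
        ln = self.lengths(n)
        if ln["ira"] != ln["irb"]:
            raise PlastomeError("IR copies differ in length")
        if ln["lsc"] + ln["ssc"] + 2 * ln["ira"] != n:
            raise PlastomeError("partition lengths do not sum to genome length")
        # tiling: walking LSC -> IRa -> SSC -> IRb must return to LSC start
        order = [self.lsc, self.ira, self.ssc, self.irb]
        for a, b in zip(order, order[1:] + order[:1]):
            nxt = a[1] % n + 1
            if nxt != b[0]:
                raise PlastomeError(
                    f"partition does not tile the circle: {a} then {b}"
                )
        if revcomp(plastome.fetch(*self.ira)) != plastome.fetch(*self.irb):
            raise PlastomeError("IRa is not the reverse complement of IRb")

    def region_of(self, pos: int, genome_length: int) -> str:
        for name in ("lsc", "ira", "ssc", "irb"):
            if in_interval(pos, getattr(self, name), genome_length):
                return name
        raise PlastomeError(f"position {pos} outside partition")


@dataclass
class Plastome:
    """A circular chloroplast genome with optional annotation and partition."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    partition: Optional[RegionPartition] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise PlastomeError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise PlastomeError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        n = self.length
        for f in self.features:
            for start, end in f.intervals:
                if not (1 <= start <= n and 1 <= end <= n):
                    raise PlastomeError(
                        f"{self.id}: feature {f.name} interval ({start},{end}) "
                        f"outside [1,{n}]"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Circular 1-based inclusive substring; wraps when end < start."""
        if end >= start:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def base(self, pos: int) -> str:
        return self.sequence[pos - 1]

    def rotated(self, offset: int) -> "Plastome":
        """Genome rotated so old position ``offset+1`` becomes position 1.

        Features and partition are dropped (coordinates would shift)."""
        s = self.sequence[offset:] + self.sequence[:offset]
        return Plastome(self.id, s)


@dataclass
class EnzymeSpec:
    """A type II restriction enzyme: IUPAC recognition site and cut offset.

    ``cut_offset`` is the number of bases 5' of the cut within the site on
    the top strand (0 = cut before the first site base).
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool = field(default=False)

    def __post_init__(self) -> None:
        self.recognition = self.recognition.upper()
        bad = set(self.recognition) - IUPAC_DNA
        if bad:
            raise PlastomeError(
                f"enzyme {self.name}: non-IUPAC letters {sorted(bad)}"
            )
        if len(self.recognition) < 4:
            raise PlastomeError(f"enzyme {self.name}: recognition shorter than 4")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise PlastomeError(f"enzyme {self.name}: cut offset outside site")
        self.palindromic = revcomp(self.recognition) == self.recognition

    @property
    def regex(self) -> re.Pattern:
        return re.compile(iupac_regex(self.recognition))

    def expansions(self) -> set[str]:
        """All concrete sequences matching the recognition pattern."""
        seqs = [""]
        for ch in self.recognition:
            seqs = [s + b for s in seqs for b in IUPAC_EXPAND[ch]]
        return set(seqs)


# The enzymes used by the study's marker tables, NEB-style sites.
DEFAULT_ENZYME_CATALOG = """\
AluI\tAGCT\t2
BanI\tGGYRCC\t1
BstEII\tGGTNACC\t1
DpnII\tGATC\t0
HaeIII\tGGCC\t2
HinfI\tGANTC\t1
KpnI\tGGTACC\t5
MluI\tACGCGT\t1
MspI\tCCGG\t1
NcoI\tCCATGG\t1
RsaI\tGTAC\t2
ScrFI\tCCNGG\t2
TaqI\tTCGA\t1
XbaI\tTCTAGA\t1
"""


def read_enzyme_catalog(path: Optional[str | Path] = None) -> list[EnzymeSpec]:
    """Read a tab-separated enzyme catalog (name, IUPAC site, cut offset).

    With no path, returns the embedded default catalog.
    """
    if path is None:
        text = DEFAULT_ENZYME_CATALOG
    else:
        text = Path(path).read_text()
    out: list[EnzymeSpec] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PlastomeError(
                f"enzyme catalog line {lineno}: expected 3+ tab-separated columns"
            )
        out.append(EnzymeSpec(parts[0], parts[1], int(parts[2])))
    if not out:
        logger.warning("enzyme catalog %s is empty", path)
    return out


@dataclass
class RunConfig:
    """Thresholds and constraints for the whole pipeline, YAML-serializable."""

    # site classification
    min_depth: int = 20
    fixed_freq: float = 0.98
    poly_freq: float = 0.03
    poly_min_count: int = 5
    # primer constraints
    primer_len_min: int = 18
    primer_len_max: int = 30
    tm_min: float = 50.0
    tm_max: float = 68.0
    product_min: int = 200
    product_max: int = 800
    snp_primer_clearance: int = 50
    band_resolution: int = 20
    # identity profile
    window: int = 100
    step: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fixed_freq <= 1:
            raise PlastomeError("fixed_freq must be in (0, 1]")
        if not 0 <= self.poly_freq < 1:
            raise PlastomeError("poly_freq must be in [0, 1)")
        if self.min_depth < 1:
            raise PlastomeError("min_depth must be >= 1")
        if self.primer_len_min < 15 or self.primer_len_max < self.primer_len_min:
            raise PlastomeError("bad primer length range")
        if self.product_min >= self.product_max:
            raise PlastomeError("bad product size range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_plastome(
    path: str | Path,
    format: str = "fasta",
    annotation_path: Optional[str | Path] = None,
) -> Plastome:
    """Read a genome record (FASTA or GenBank flat) plus optional GFF3."""
    from Bio import SeqIO

    path = Path(path)
    fmt = {"fasta": "fasta", "genbank_flat": "genbank", "genbank": "genbank"}.get(format)
    if fmt is None:
        raise PlastomeError(f"unknown format {format!r}")
    try:
        record = next(SeqIO.parse(str(path), fmt))
    except StopIteration:
        raise PlastomeError(f"{path}: no records found")
    except ValueError as exc:
        raise PlastomeError(f"{path}: parse error: {exc}") from exc

    features: list[GeneFeature] = []
    if fmt == "genbank":
        features = _features_from_genbank(record)
    p = Plastome(record.id, str(record.seq), features=features)
    if annotation_path is not None:
        p.features = read_gff3(annotation_path, seqid=p.id, genome_length=p.length)
        # re-validate coordinates against the sequence
        p = Plastome(p.id, p.sequence, features=p.features)
    return p


def _features_from_genbank(record) -> list[GeneFeature]:
    kind_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    out = []
    for feat in record.features:
        kind = kind_map.get(feat.type)
        if kind is None:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", ["?"])[0]
        )
        strand = "-" if feat.location.strand == -1 else "+"
        intervals = [
            (int(part.start) + 1, int(part.end)) for part in feat.location.parts
        ]
        codon_start = int(feat.qualifiers.get("codon_start", [1])[0])
        out.append(
            GeneFeature(
                name=name, kind=kind, strand=strand, intervals=intervals,
                codon_start=codon_start,
            )
        )
    return out


def write_plastome(p: Plastome, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA with a 60-column wrap (byte-stable round trip)."""
    if format != "fasta":
        raise PlastomeError(f"unsupported output format {format!r}")
    with open(path, "w") as fh:
        fh.write(fasta_string(p.id, p.sequence))


def fasta_string(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFF3 subset
# ---------------------------------------------------------------------------
#
# Dialect: 9 tab-separated columns, one line per interval; multi-interval
# features share an ID attribute and are merged in file order.  Types map
# CDS->CDS, tRNA->tRNA, rRNA->rRNA, anything else -> pseudo_or_ORF.

_GFF_KIND = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_gff3(
    path: str | Path, seqid: Optional[str] = None, genome_length: Optional[int] = None
) -> list[GeneFeature]:
    order: list[str] = []
    rows: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise PlastomeError(f"{path}:{lineno}: expected 9 columns")
        chrom, _src, ftype, start, end, _score, strand, phase, attrs = cols
        if seqid is not None and chrom != seqid:
            raise PlastomeError(
                f"{path}:{lineno}: seqid {chrom!r} does not match record {seqid!r}"
            )
        if ftype == "gene" or ftype == "region":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        fid = attr.get("ID") or attr.get("Name") or f"_anon{lineno}"
        name = attr.get("Name", fid)
        start_i, end_i = int(start), int(end)
        if genome_length is not None and not (
            1 <= start_i <= genome_length and 1 <= end_i <= genome_length
        ):
            raise PlastomeError(
                f"{path}:{lineno}: interval ({start_i},{end_i}) outside "
                f"[1,{genome_length}]"
            )
        codon_start = 1
        if phase in ("1", "2"):
            codon_start = int(phase) + 1
        if fid not in rows:
            rows[fid] = {
                "name": name,
                "kind": _GFF_KIND.get(ftype, "pseudo_or_ORF"),
                "strand": strand if strand in "+-" else "+",
                "intervals": [],
                "codon_start": codon_start,
                "partial": attr.get("partial", "false") == "true",
            }
            order.append(fid)
        rows[fid]["intervals"].append((start_i, end_i))
    return [GeneFeature(**rows[fid]) for fid in order]


def write_gff3(features: Sequence[GeneFeature], seqid: str, path: str | Path) -> None:
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudo_or_ORF": "pseudogene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fid = f"feat{i}"
            for start, end in f.intervals:
                attrs = f"ID={fid};Name={f.name}"
                if f.partial:
                    attrs += ";partial=true"
                phase = str(f.codon_start - 1) if f.kind == "CDS" else "."
                fh.write(
                    f"{seqid}\tplastmarker\t{type_map[f.kind]}\t{start}\t{end}"
                    f"\t.\t{f.strand}\t{phase}\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# VCF v4.2 subset
# ---------------------------------------------------------------------------

def write_variants_vcf(records: Iterable, reference: Plastome, path: str | Path) -> None:
    """Write variant records as minimal VCF v4.2.

    INFO carries the site class, effect label and per-pool depths.  Records
    must carry ``position``, ``ref_allele`` and ``alt_allele`` attributes
    consistent with the reference sequence.
    """
    records = sorted(records, key=lambda r: r.position)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference.id},length={reference.length}>",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Site class">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect label">',
        '##INFO=<ID=DPA,Number=1,Type=Integer,Description="Pool A depth">',
        '##INFO=<ID=DPB,Number=1,Type=Integer,Description="Pool B depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in records:
        ref_base = reference.base(r.position)
        if r.ref_allele != ref_base:
            raise PlastomeError(
                f"POS {r.position}: record REF {r.ref_allele} != genome {ref_base}"
            )
        info = [f"CLASS={r.site_class}"]
        effect = getattr(r, "effect", None)
        if effect:
            info.append(f"EFFECT={effect}")
        info.append(f"DPA={getattr(r, 'depth_a', 0)}")
        info.append(f"DPB={getattr(r, 'depth_b', 0)}")
        lines.append(
            f"{reference.id}\t{r.position}\t.\t{r.ref_allele}\t{r.alt_allele}"
            f"\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SAM subset (single-end, unspliced; soft clips honored)
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignment:
    """A placed read on the circular reference (0-based start)."""

    name: str
    pos0: int  # leftmost reference position, 0-based; may exceed L-1 only mod L
    strand: str  # "+"/"-" : strand the read sequence was written from
    seq: str  # read sequence as aligned to the forward reference
    mismatches: int = 0
    multimapped: bool = False


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def write_sam(alignments: Iterable[ReadAlignment], reference: Plastome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference.id}\tLN:{reference.length}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            # SAM SEQ is always forward-reference oriented, which is how
            # ReadAlignment.seq is stored.  Reads wrapping the origin keep
            # their left coordinate; the cigar states full-length M
            # (documented dialect deviation).
            seq = a.seq
            fh.write(
                f"{a.name}\t{flag}\t{reference.id}\t{a.pos0 + 1}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{a.mismatches}\n"
            )


def read_sam(path: str | Path, reference: Plastome) -> list[ReadAlignment]:
    """Read the single-end SAM dialect; rejects spliced/paired records."""
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_paired:
                raise PlastomeError(f"read {rec.query_name}: paired reads not supported")
            cigar = rec.cigarstring or ""
            if "N" in cigar:
                raise PlastomeError(f"read {rec.query_name}: spliced alignment rejected")
            seq = rec.query_sequence or ""
            # honor soft clips: trim clipped bases off the stored sequence
            ops = _CIGAR_RE.findall(cigar)
            if ops and ops[0][1] == "S":
                seq = seq[int(ops[0][0]):]
            if ops and ops[-1][1] == "S":
                seq = seq[: -int(ops[-1][0])]
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                ReadAlignment(
                    name=rec.query_name, pos0=rec.reference_start,
                    strand=strand, seq=seq, mismatches=int(nm),
                )
            )
    return out
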