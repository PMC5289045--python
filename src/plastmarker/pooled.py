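"""Pooled-read variant discovery against a reference plastome.

Per-species pools of short reads are mapped (built-in exact-ish mapper, or
any external aligner via the SAM subset), piled up into per-site allele
tallies, and sites are classified as fixed between species, polymorphic
within a pool, monomorphic, low-coverage or ambiguous.  IR-resident calls
are canonicalized onto the IRa copy.  Also includes the redundancy-filtered
interspecific selector for tagged contig alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .plastome_io import (
    Plastome,
    PlastomeError,
    ReadAlignment,
    RegionPartition,
    RunConfig,
    revcomp,
)

logger = logging.getLogger("plastmarker")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class PoolCounts:
    """Per-position allele tallies for one species pool.

    Columns of ``counts``: A, C, G, T, deletion.  Insertion anchors are kept
    separately and do not contribute to depth.
    """

    species: str
    counts: np.ndarray  # (L, 5) int32
    ins_anchors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ins_anchors is None:
            self.ins_anchors = np.zeros(len(self.counts), dtype=np.int32)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def summary(self) -> dict:
        d = self.depth
        covered = d[d > 0]
        if covered.size == 0:
            return {"mean": 0.0, "min": 0, "max": 0}
        return {
            "mean": float(covered.mean()),
            "min": int(covered.min()),
            "max": int(covered.max()),
        }


SITE_CLASSES = (
    "fixed_interspecific",
    "intraspecific_polymorphic",
    "monomorphic_shared",
    "low_coverage",
    "ambiguous",
)


@dataclass
class VariantRecord:
    """One classified site on the reference genome."""

    position: int  # 1-based reference coordinate
    ref_allele: str
    alt_allele: str
    site_class: str
    allele_a: str
    allele_b: str
    depth_a: int
    depth_b: int
    mirror_position: Optional[int] = None
    position_b: Optional[int] = None  # lifted coordinate on the pool-B genome
    poly_in: Optional[str] = None  # which pool is polymorphic, if any
    effect: Optional[str] = None


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

class ReadMapper:
    """Unique-best placement of short reads on a circular reference.

    Seeds with exact ``k``-mers, extends by Hamming distance on both strands;
    ties go to the lexicographically smallest (position, strand) and are
    flagged as multimapped.
    """

    def __init__(self, reference: Plastome, k: int = 31):
        if reference.length < k:
            raise PlastomeError("reference shorter than seed length")
        self.reference = reference
        self.k = k
        self.n = reference.length
        doubled = reference.sequence + reference.sequence
        self._arr2 = encode(doubled)
        index: dict[str, list[int]] = {}
        for i in range(self.n):
            index.setdefault(doubled[i : i + k], []).append(i)
        self._index = index

    def map_read(self, name: str, seq: str, max_mismatches: int) -> Optional[ReadAlignment]:
        k, n = self.k, self.n
        rl = len(seq)
        if rl < k:
            return None
        cands: dict[tuple[int, str], int] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = encode(s)
            offsets = list(range(0, rl - k + 1, k))
            for off in offsets:
                hits = self._index.get(s[off : off + k])
                if not hits:
                    continue
                for h in hits:
                    pos = (h - off) % n
                    key = (pos, strand)
                    if key not in cands:
                        mm = int(
                            np.count_nonzero(self._arr2[pos : pos + rl] != arr)
                        )
                        cands[key] = mm
                break  # first seeding offset with hits is enough per strand
        if not cands:
            # fall back: try remaining offsets (read may have an error in
            # the first seed window)
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                arr = encode(s)
                for off in range(self.k, rl - k + 1, k):
                    for h in self._index.get(s[off : off + k], ()):
                        pos = (h - off) % n
                        key = (pos, strand)
                        if key not in cands:
                            mm = int(
                                np.count_nonzero(self._arr2[pos : pos + rl] != arr)
                            )
                            cands[key] = mm
        if not cands:
            return None
        best_mm = min(cands.values())
        if best_mm > max_mismatches:
            return None
        ties = sorted(key for key, mm in cands.items() if mm == best_mm)
        pos, strand = ties[0]
        return ReadAlignment(
            name=name, pos0=pos, strand=strand,
            seq=revcomp(seq) if strand == "-" else seq,
            mismatches=best_mm, multimapped=len(ties) > 1,
        )


def map_reads_exactish(
    reads: Iterable[tuple[str, str]],
    reference: Plastome,
    max_mismatches: int = 5,
    mapper: Optional[ReadMapper] = None,
) -> tuple[list[ReadAlignment], int]:
    """Map (name, sequence) reads; returns (alignments, n_unmapped)."""
    if mapper is None:
        mapper = ReadMapper(reference)
    out: list[ReadAlignment] = []
    unmapped = 0
    for name, seq in reads:
        aln = mapper.map_read(name, seq, max_mismatches)
        if aln is None:
            unmapped += 1
        else:
            out.append(aln)
    if unmapped:
        logger.info("%d reads unmapped and dropped", unmapped)
    return out, unmapped


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup(
    alignments: Sequence[ReadAlignment],
    reference: Plastome,
    species: str = "pool",
    chunk: int = 20_000,
) -> PoolCounts:
    """Per-position A/C/G/T tallies from placed reads (circular wrap)."""
    n = reference.length
    counts = np.zeros((n, 5), dtype=np.int32)
    flat = counts.reshape(-1)
    for lo in range(0, len(alignments), chunk):
        batch = alignments[lo : lo + chunk]
        pos_parts = []
        code_parts = []
        for a in batch:
            rl = len(a.seq)
            if not 0 <= a.pos0 < n:
                raise PlastomeError(f"alignment {a.name} outside reference bounds")
            p = np.arange(a.pos0, a.pos0 + rl)
            p[p >= n] -= n
            pos_parts.append(p)
            code_parts.append(encode(a.seq))
        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        codes = np.concatenate(code_parts)
        keep = codes < 4  # N and friends don't tally
        np.add.at(flat, pos[keep] * 5 + codes[keep], 1)
    return PoolCounts(species=species, counts=counts)


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def classify_array(
    counts_a: PoolCounts, counts_b: PoolCounts, cfg: RunConfig
) -> np.ndarray:
    """Vectorized per-site class codes (index into SITE_CLASSES)."""
    ca = counts_a.counts[:, :4].astype(np.int64)
    cb = counts_b.counts[:, :4].astype(np.int64)
    if len(ca) != len(cb):
        raise PlastomeError("pools tallied against different reference lengths")
    da, db = ca.sum(axis=1), cb.sum(axis=1)

    def stats(c, d):
        major = c.argmax(axis=1)
        major_n = c.max(axis=1)
        tmp = c.copy()
        tmp[np.arange(len(c)), major] = -1
        second_n = tmp.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fmaj = np.where(d > 0, major_n / np.maximum(d, 1), 0.0)
            fsec = np.where(d > 0, second_n / np.maximum(d, 1), 0.0)
        return major, fmaj, second_n, fsec

    maj_a, fmaj_a, sec_a, fsec_a = stats(ca, da)
    maj_b, fmaj_b, sec_b, fsec_b = stats(cb, db)

    cls = np.full(len(ca), SITE_CLASSES.index("ambiguous"), dtype=np.int8)
    fixed_a = fmaj_a >= cfg.fixed_freq
    fixed_b = fmaj_b >= cfg.fixed_freq
    poly_a = (fsec_a >= cfg.poly_freq) & (sec_a >= cfg.poly_min_count)
    poly_b = (fsec_b >= cfg.poly_freq) & (sec_b >= cfg.poly_min_count)

    mono = fixed_a & fixed_b & (maj_a == maj_b)
    cls[mono] = SITE_CLASSES.index("monomorphic_shared")
    poly = (poly_a | poly_b) & ~(fixed_a & fixed_b)
    cls[poly] = SITE_CLASSES.index("intraspecific_polymorphic")
    fixed = fixed_a & fixed_b & (maj_a != maj_b)
    cls[fixed] = SITE_CLASSES.index("fixed_interspecific")
    low = (da < cfg.min_depth) | (db < cfg.min_depth)
    cls[low] = SITE_CLASSES.index("low_coverage")
    return cls


def classify_sites(
    counts_a: PoolCounts,
    counts_b: PoolCounts,
    cfg: RunConfig,
    reference: Plastome,
) -> list[VariantRecord]:
    """Classify every site; return records for variant sites only.

    Records are emitted for fixed_interspecific and intraspecific_polymorphic
    sites (monomorphic and low-coverage sites are summarized, not listed).
    """
    cls = classify_array(counts_a, counts_b, cfg)
    bases = "ACGT"
    out: list[VariantRecord] = []
    interesting = np.flatnonzero(
        (cls == SITE_CLASSES.index("fixed_interspecific"))
        | (cls == SITE_CLASSES.index("intraspecific_polymorphic"))
    )
    ca, cb = counts_a.counts, counts_b.counts
    for i in interesting:
        site_class = SITE_CLASSES[cls[i]]
        a_major = bases[int(ca[i, :4].argmax())]
        b_major = bases[int(cb[i, :4].argmax())]
        ref_base = reference.base(int(i) + 1)
        alt = b_major if a_major == ref_base else a_major
        if alt == ref_base:  # polymorphic site where both majors match ref
            da = ca[i, :4].copy()
            da[bases.index(ref_base)] = -1
            db = cb[i, :4].copy()
            db[bases.index(ref_base)] = -1
            alt = bases[int((da + db).argmax())]
        poly_in = None
        if site_class == "intraspecific_polymorphic":
            fa = _second_freq(ca[i, :4])
            fb = _second_freq(cb[i, :4])
            pa = fa[1] >= cfg.poly_freq and fa[0] >= cfg.poly_min_count
            pb = fb[1] >= cfg.poly_freq and fb[0] >= cfg.poly_min_count
            poly_in = {(True, True): "both", (True, False): counts_a.species,
                       (False, True): counts_b.species}[(pa, pb)]
        out.append(
            VariantRecord(
                position=int(i) + 1,
                ref_allele=ref_base,
                alt_allele=alt,
                site_class=site_class,
                allele_a=a_major,
                allele_b=b_major,
                depth_a=int(ca[i, :4].sum()),
                depth_b=int(cb[i, :4].sum()),
                poly_in=poly_in,
            )
        )
    return out


def _second_freq(c: np.ndarray) -> tuple[int, float]:
    d = int(c.sum())
    if d == 0:
        return 0, 0.0
    tmp = c.copy()
    tmp[c.argmax()] = -1
    s = int(tmp.max())
    return s, s / d


def class_tally(cls: np.ndarray) -> dict[str, int]:
    return {name: int((cls == i).sum()) for i, name in enumerate(SITE_CLASSES)}


# ---------------------------------------------------------------------------
# IR mirroring
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def mirror_ir_sites(
    records: Sequence[VariantRecord], partition: RegionPartition, genome_length: int
) -> list[VariantRecord]:
    """Canonicalize IR-resident calls onto the IRa copy.

    Concordant mirrored pairs collapse into a single record at the IRa
    coordinate (mirror coordinate recorded); discordant pairs are
    reclassified ambiguous.  Non-IR records pass through unchanged.
    """
    ira, irb = partition.ira, partition.irb

    def in_iv(pos, iv):
        s, e = iv
        return s <= pos <= e if e >= s else (pos >= s or pos <= e)

    def mirror(pos: int) -> int:
        if in_iv(pos, ira):
            return irb[1] - (pos - ira[0])
        return ira[0] + (irb[1] - pos)

    out: list[VariantRecord] = []
    by_canon: dict[int, list[VariantRecord]] = {}
    for r in records:
        if in_iv(r.position, ira):
            by_canon.setdefault(r.position, []).append(r)
        elif in_iv(r.position, irb):
            by_canon.setdefault(mirror(r.position), []).append(r)
        else:
            out.append(r)
    for canon, group in sorted(by_canon.items()):
        canonical = [r for r in group if in_iv(r.position, ira)]
        mirrored = [r for r in group if not in_iv(r.position, ira)]
        if canonical and mirrored:
            a, b = canonical[0], mirrored[0]
            concordant = (
                a.site_class == b.site_class
                and a.allele_a == _COMP[b.allele_a]
                and a.allele_b == _COMP[b.allele_b]
            )
            keep = a
            keep.mirror_position = b.position
            if not concordant:
                keep.site_class = "ambiguous"
            out.append(keep)
        else:
            keep = group[0]
            if not in_iv(keep.position, ira):
                # lone IRb call: re-express on the IRa copy
                keep = VariantRecord(
                    position=canon,
                    ref_allele=_COMP[keep.ref_allele],
                    alt_allele=_COMP[keep.alt_allele],
                    site_class=keep.site_class,
                    allele_a=_COMP[keep.allele_a],
                    allele_b=_COMP[keep.allele_b],
                    depth_a=keep.depth_a,
                    depth_b=keep.depth_b,
                    poly_in=keep.poly_in,
                    mirror_position=keep.position,
                )
            else:
                keep.mirror_position = mirror(keep.position)
            out.append(keep)
    out.sort(key=lambda r: r.position)
    return out


# ---------------------------------------------------------------------------
# EST-contig interspecific selector
# ---------------------------------------------------------------------------

def select_est_interspecific(
    contig_alignments: Sequence[Sequence[tuple[str, str]]],
    min_redundancy: int = 2,
) -> list[tuple[int, int, dict[str, str]]]:
    """Columns whose alleles partition perfectly by species, redundantly.

    ``contig_alignments`` is a list of multiple alignments, each a list of
    (species tag, aligned sequence).  A column is a candidate iff every
    species is internally monomorphic, species alleles are pairwise
    distinct, and each species contributes at least ``min_redundancy``
    observations.  Gap-containing columns are skipped.

    Returns (contig index, 1-based column, {species: allele}) triples.
    """
    out: list[tuple[int, int, dict[str, str]]] = []
    for ci, contig in enumerate(contig_alignments):
        species = {tag for tag, _ in contig}
        if len(species) < 2:
            logger.info("contig %d skipped: single species only", ci)
            continue
        lengths = {len(seq) for _, seq in contig}
        if len(lengths) != 1:
            raise PlastomeError(f"contig {ci}: ragged alignment")
        width = lengths.pop()
        for col in range(width):
            alleles: dict[str, set[str]] = {}
            counts: dict[str, int] = {}
            gap = False
            for tag, seq in contig:
                ch = seq[col].upper()
                if ch == "-":
                    gap = True
                    break
                alleles.setdefault(tag, set()).add(ch)
                counts[tag] = counts.get(tag, 0) + 1
            if gap:
                continue
            if any(len(a) != 1 for a in alleles.values()):
                continue
            flat = {tag: next(iter(a)) for tag, a in alleles.items()}
            if len(set(flat.values())) != len(flat):
                continue  # species share an allele: not a perfect partition
            if any(counts[tag] < min_redundancy for tag in flat):
                continue
            out.append((ci, col + 1, flat))
    return out
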