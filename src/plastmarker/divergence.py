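"""Pairwise divergence: global alignment, identity ranking, sliding profile,
and the cross-genome position map (lift-over).

Short sequences (<= 10 kb) get a full affine-gap dynamic program (Biopython
PairwiseAligner); longer collinear sequences are aligned piecewise between
unique shared k-mer anchors, which is exact in practice at the sub-percent
divergence this pipeline targets.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .plastome_io import Plastome, PlastomeError, revcomp

DEFAULT_SCORES = {"match": 1.0, "mismatch": -1.0, "open": -5.0, "extend": -1.0}


@dataclass
class AlignmentResult:
    """A global pairwise alignment as two gapped strings."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise PlastomeError("gapped strings differ in length")

    @property
    def columns(self) -> int:
        return len(self.a)

    def matches(self) -> np.ndarray:
        aa = np.frombuffer(self.a.encode(), dtype=np.uint8)
        bb = np.frombuffer(self.b.encode(), dtype=np.uint8)
        return (aa == bb) & (aa != ord("-"))


@dataclass
class IdentityRecord:
    """Per-region identity for one species pair."""

    region: str
    length_a: int
    length_b: int
    identity: float
    pair: tuple[str, str]


@dataclass
class PositionMap:
    """Monotone coordinate mapping between two aligned sequences.

    Built from matched (letter-vs-letter) alignment columns; inside gaps the
    nearest left anchor is returned with an ``exact=False`` flag.
    """

    a_pos: np.ndarray  # 1-based matched positions in a, strictly increasing
    b_pos: np.ndarray

    def map(self, pos: int) -> tuple[Optional[int], bool]:
        i = bisect.bisect_right(self.a_pos, pos) - 1
        if i < 0:
            return None, False
        if self.a_pos[i] == pos:
            return int(self.b_pos[i]), True
        return int(self.b_pos[i]), False

    def inverse(self) -> "PositionMap":
        return PositionMap(self.b_pos, self.a_pos)


def _aligner(scores: Optional[dict] = None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORES)
    if scores:
        s.update(scores)
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = s["match"]
    al.mismatch_score = s["mismatch"]
    al.open_gap_score = s["open"]
    al.extend_gap_score = s["extend"]
    return al


def _align_small(a: str, b: str, scores: Optional[dict]) -> AlignmentResult:
    if not a and not b:
        return AlignmentResult("", "", 0.0)
    if not a or not b:
        gap = max(len(a), len(b))
        s = DEFAULT_SCORES if scores is None else {**DEFAULT_SCORES, **scores}
        score = s["open"] + (gap - 1) * s["extend"]
        return AlignmentResult(a or "-" * gap, b or "-" * gap, score)
    aln = _aligner(scores).align(a, b)[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), float(aln.score))


def _anchors(a: str, b: str, k: int = 31, spacing: int = 400) -> list[tuple[int, int]]:
    """Collinear chain of unique shared k-mers, thinned to ~spacing bases."""

    def unique_kmers(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in seen:
                dup.add(km)
            else:
                seen[km] = i
        for km in dup:
            del seen[km]
        return seen

    ka, kb = unique_kmers(a), unique_kmers(b)
    shared = [(ia, kb[km]) for km, ia in ka.items() if km in kb]
    shared.sort()
    chain: list[tuple[int, int]] = []
    last_a = last_b = -(10 ** 9)
    for ia, ib in shared:
        if ia >= last_a + spacing and ib > last_b:
            chain.append((ia, ib))
            last_a, last_b = ia, ib
    return chain


def global_align(
    a: str, b: str, scores: Optional[dict] = None, small_limit: int = 10_000, k: int = 31
) -> AlignmentResult:
    """Affine-gap global alignment; anchored piecewise beyond ``small_limit``."""
    if not a or not b:
        raise PlastomeError("cannot align empty sequence")
    a, b = a.upper(), b.upper()
    if max(len(a), len(b)) <= small_limit:
        return _align_small(a, b, scores)
    chain = _anchors(a, b, k=k)
    if not chain:
        raise PlastomeError("no alignment anchors; sequences too divergent")
    match_score = {**DEFAULT_SCORES, **(scores or {})}["match"]
    parts_a: list[str] = []
    parts_b: list[str] = []
    score = 0.0
    pa = pb = 0
    for ia, ib in chain + [(len(a), len(b))]:
        seg = _align_small(a[pa:ia], b[pb:ib], scores) if (ia > pa or ib > pb) else None
        if seg is not None and seg.columns:
            parts_a.append(seg.a)
            parts_b.append(seg.b)
            score += seg.score
        if ia < len(a):
            parts_a.append(a[ia : ia + k])
            parts_b.append(b[ib : ib + k])
            score += k * match_score
            pa, pb = ia + k, ib + k
    return AlignmentResult("".join(parts_a), "".join(parts_b), score)


def percent_identity(alignment: AlignmentResult, decimals: int = 2) -> float:
    """100 * matched columns / all columns (gap columns count)."""
    if alignment.columns == 0:
        raise PlastomeError("empty alignment")
    return round(100.0 * alignment.matches().sum() / alignment.columns, decimals)


def sliding_identity(
    alignment: AlignmentResult, window: int = 100, step: int = 25
) -> list[tuple[int, float]]:
    """Windowed identity profile over alignment columns (1-based starts)."""
    if window > alignment.columns:
        raise PlastomeError("window exceeds alignment length")
    m = alignment.matches().astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(m)])
    out = []
    for start in range(0, alignment.columns - window + 1, step):
        matched = cum[start + window] - cum[start]
        out.append((start + 1, round(100.0 * matched / window, 2)))
    return out


def build_position_map(alignment: AlignmentResult) -> PositionMap:
    aa = np.frombuffer(alignment.a.encode(), dtype=np.uint8)
    bb = np.frombuffer(alignment.b.encode(), dtype=np.uint8)
    gap = ord("-")
    is_a = aa != gap
    is_b = bb != gap
    pos_a = np.cumsum(is_a)
    pos_b = np.cumsum(is_b)
    matched = is_a & is_b
    return PositionMap(pos_a[matched].astype(np.int64), pos_b[matched].astype(np.int64))


# ---------------------------------------------------------------------------
# coding-region divergence ranking
# ---------------------------------------------------------------------------

def _coding_regions(p: Plastome) -> dict[str, str]:
    """Strand-oriented exon sequences keyed by region name.

    Multi-interval features contribute one region per exon (``name exonN``);
    duplicate names (IR copies) keep the first copy in genome order.
    """
    out: dict[str, str] = {}
    for f in sorted(p.features, key=lambda f: f.intervals[0][0]):
        if f.kind not in ("CDS", "tRNA", "rRNA"):
            continue
        if len(f.intervals) == 1:
            segs = {f.name: p.fetch(*f.intervals[0])}
        else:
            segs = {
                f"{f.name} exon{i + 1}": p.fetch(*iv)
                for i, iv in enumerate(f.intervals)
            }
        for name, seq in segs.items():
            if f.strand == "-":
                seq = revcomp(seq)
            out.setdefault(name, seq)
    return out


def rank_coding_divergence(
    genome_a: Plastome, genome_b: Plastome, k: int = 15,
    scores: Optional[dict] = None,
) -> list[IdentityRecord]:
    """The k shared coding regions with the lowest percent identity, ascending."""
    ra, rb = _coding_regions(genome_a), _coding_regions(genome_b)
    records: list[IdentityRecord] = []
    for name in ra:
        if name not in rb:
            continue
        aln = global_align(ra[name], rb[name], scores=scores)
        records.append(
            IdentityRecord(
                region=name,
                length_a=len(ra[name]),
                length_b=len(rb[name]),
                identity=percent_identity(aln),
                pair=(genome_a.id, genome_b.id),
            )
        )
    records.sort(key=lambda r: (r.identity, r.region))
    return records[:k]


# ---------------------------------------------------------------------------
# genome-scale comparison
# ---------------------------------------------------------------------------

def genome_alignment(a: Plastome, b: Plastome, scores: Optional[dict] = None) -> AlignmentResult:
    """Anchored whole-sequence alignment of two collinear genomes."""
    return global_align(a.sequence, b.sequence, scores=scores)


def pairwise_genome_identity(a: Plastome, b: Plastome) -> float:
    """Whole-genome identity, region-by-region when both are partitioned.

    Aligning LSC, SSC and a single IR copy avoids double-counting the IR.
    """
    if a.partition is None or b.partition is None:
        return percent_identity(genome_alignment(a, b))
    matched = 0
    columns = 0
    for region in ("lsc", "ira", "ssc"):
        sa = a.fetch(*getattr(a.partition, region))
        sb = b.fetch(*getattr(b.partition, region))
        aln = global_align(sa, sb)
        matched += int(aln.matches().sum())
        columns += aln.columns
    return round(100.0 * matched / columns, 2)
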