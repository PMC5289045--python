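"""Structural characterization of circular plastomes.

Inverted-repeat detection (exact match, k-mer seeded), quadripartite
partitioning, GC content, gene copy counting and gene-order inversion-block
detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .plastome_io import (
    GeneFeature,
    Plastome,
    PlastomeError,
    RegionPartition,
    revcomp,
)


@dataclass
class InversionBlock:
    """A reversal block on a gene-order comparison.

    ``interval`` holds gene-order indices on the query (0-based inclusive);
    flanks name the genes bracketing each endpoint; nesting depth counts how
    many other detected blocks strictly contain this one (0 = outermost).
    """

    interval: tuple[int, int]
    start_flank: tuple[Optional[str], Optional[str]]
    end_flank: tuple[Optional[str], Optional[str]]
    depth: int = 0


# ---------------------------------------------------------------------------
# inverted repeat
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def find_inverted_repeat(
    p: Plastome, min_len: int = 10_000, k: int = 31
) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    """Longest pair of disjoint intervals that are exact reverse complements.

    Searched on the circular sequence (via doubling, so repeats spanning the
    origin are found) with ``k``-mer seeding and maximal extension along the
    anti-diagonal.  Returns 1-based inclusive intervals ordered by start, or
    ``None`` if the longest repeat is shorter than ``min_len``.  Intervals
    that wrap the origin are expressed with end < start.
    """
    if min_len < 1000:
        raise PlastomeError("min_len must be >= 1000")
    n = p.length
    if n <= k:
        return None
    seq2 = p.sequence * 2
    n2 = 2 * n

    index: dict[str, list[int]] = {}
    for i in range(0, n2 - k + 1):
        index.setdefault(seq2[i : i + k], []).append(i)
    rc2 = revcomp(seq2)

    # A pair (x, y) of complementary positions on one inverted repeat obeys
    # x + y == D for a constant anti-diagonal D; a seed fixes D, extension
    # along D is maximal in both directions.
    best: Optional[tuple[int, int, int]] = None  # (m, x_start0, y_start0) mod n
    seen_runs: dict[int, list[tuple[int, int]]] = {}
    seen_pair: set[tuple[int, int, int]] = set()
    step = max(1, k // 2)
    for j in range(0, n2 - k + 1, step):
        for i in index.get(rc2[j : j + k], ()):
            d = i + (n2 - 1 - j)
            runs = seen_runs.setdefault(d, [])
            if any(lo <= i <= hi for lo, hi in runs):
                continue  # this run on the diagonal is already extended
            lo, hi = i, i + k - 1
            while lo > 0 and d - lo + 1 < n2 and seq2[lo - 1] == _COMP.get(seq2[d - lo + 1], "?"):
                lo -= 1
            while hi + 1 < n2 and d - hi - 1 >= 0 and seq2[hi + 1] == _COMP.get(seq2[d - hi - 1], "?"):
                hi += 1
            runs.append((lo, hi))
            y1 = d - hi
            if y1 <= hi:  # overlapping arms (palindrome): trim to disjoint halves
                half = (d - 2 * lo + 1) // 2
                if half <= 0:
                    continue
                hi = lo + half - 1
                y1 = d - hi
            m = hi - lo + 1
            if m > n // 2:
                m = n // 2  # disjointness bound on a circle
                hi = lo + m - 1
                y1 = d - hi
            x0, y0 = lo % n, y1 % n
            a0, b0 = min(x0, y0), max(x0, y0)
            key = (a0, b0, m)
            if key in seen_pair:
                continue
            seen_pair.add(key)
            if not _circular_disjoint(a0, b0, m, n):
                continue
            if best is None or m > best[0]:
                best = (m, a0, b0)
    if best is None or best[0] < min_len:
        return None
    m, a0, b0 = best
    return (_to_interval(a0, m, n), _to_interval(b0, m, n))


def _to_interval(start0: int, m: int, n: int) -> tuple[int, int]:
    return (start0 + 1, (start0 + m - 1) % n + 1)


def _circular_disjoint(a0: int, b0: int, m: int, n: int) -> bool:
    """Do arcs [a0, a0+m) and [b0, b0+m) (mod n) avoid each other?"""
    if 2 * m > n:
        return False
    gap1 = (b0 - (a0 + m)) % n
    gap2 = (a0 - (b0 + m)) % n
    return gap1 + gap2 + 2 * m == n


def partition_quadripartite(
    p: Plastome, ir: tuple[tuple[int, int], tuple[int, int]]
) -> RegionPartition:
    """Label the two single-copy gaps between IR copies as LSC (longer) and
    SSC (shorter); an exact tie makes the gap after the first IR the LSC."""
    (a1, a2), (b1, b2) = ir
    n = p.length
    la = _gap_len((a1, a2), n)
    gap1 = _gap_between(a2, b1, n)  # after first copy
    gap2 = _gap_between(b2, a1, n)  # after second copy (may wrap origin)
    if gap1 is None or gap2 is None:
        raise PlastomeError("IR copies adjacent or overlapping; no single-copy gaps")
    len1, len2 = _gap_len(gap1, n), _gap_len(gap2, n)
    if len1 + len2 + 2 * la != n:
        raise PlastomeError("IR copies overlap: gaps and copies do not tile circle")
    if len1 >= len2:
        # documented tie-break: the gap following the first copy is the LSC
        lsc, ssc = gap1, gap2
        ira, irb = (b1, b2), (a1, a2)  # IRa follows the LSC
    else:
        lsc, ssc = gap2, gap1
        ira, irb = (a1, a2), (b1, b2)
    part = RegionPartition(lsc=lsc, ira=ira, ssc=ssc, irb=irb)
    part.validate(p)
    return part


def _gap_len(gap: tuple[int, int], n: int) -> int:
    s, e = gap
    if e >= s:
        return e - s + 1
    return n - s + 1 + e


def _gap_between(end: int, start: int, n: int) -> Optional[tuple[int, int]]:
    """The circular gap after position ``end`` and before ``start``."""
    length = (start - end - 1) % n
    if length == 0:
        return None
    s = end % n + 1
    e = (start - 2) % n + 1
    return (s, e)


# ---------------------------------------------------------------------------
# scalar characterization
# ---------------------------------------------------------------------------

def gc_content(p: Plastome | str) -> float:
    """GC percentage to one decimal (half-up); ambiguity codes excluded."""
    seq = p.sequence if isinstance(p, Plastome) else p.upper()
    if not seq:
        raise PlastomeError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise PlastomeError("no unambiguous bases")
    import decimal

    frac = decimal.Decimal(100 * gc) / decimal.Decimal(gc + at)
    return float(frac.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def count_gene_copies(p: Plastome, gene_name: str) -> int:
    """Number of annotated features whose name matches exactly (hyphen
    variants normalized to '-')."""
    norm = _norm_name(gene_name)
    return sum(1 for f in p.features if _norm_name(f.name) == norm)


def _norm_name(name: str) -> str:
    for dash in ("‐", "‑", "‒", "–", "—"):
        name = name.replace(dash, "-")
    return name


# ---------------------------------------------------------------------------
# inversion blocks on gene order
# ---------------------------------------------------------------------------

def detect_inversions(
    query_order: Sequence[tuple[str, int]],
    ref_order: Sequence[tuple[str, int]],
) -> list[InversionBlock]:
    """Greedy longest-first reversal decomposition of a signed gene order.

    Inputs are sequences of (gene name, sign) with sign +1/-1.  Returns the
    reversal blocks that, applied to the query in the order reported,
    recover the reference order (i.e. the planted reversals, outermost
    first).  Each block carries the gene names flanking its endpoints in
    the order it was applied to, plus a nesting depth.
    """
    ref_names = [g for g, _ in ref_order]
    if sorted(ref_names) != sorted(g for g, _ in query_order):
        raise PlastomeError("gene sets differ between orders")
    if len(set(ref_names)) != len(ref_names):
        raise PlastomeError("duplicate gene names; supply single-copy genes only")

    index = {g: i + 1 for i, (g, _) in enumerate(ref_order)}
    ref_sign = {g: s for g, s in ref_order}
    work = [(index[g] * (s * ref_sign[g]), g) for g, s in query_order]
    target = list(range(1, len(work) + 1))

    out: list[InversionBlock] = []
    guard = 0
    while [v for v, _ in work] != target:
        guard += 1
        if guard > len(work) + 2:
            raise PlastomeError("gene orders not reachable by simple reversals")
        found = False
        n = len(work)
        # longest-first: try big intervals before small ones
        for length in range(n, 1, -1):
            for i in range(0, n - length + 1):
                j = i + length - 1
                seg = [(-v, g) for v, g in reversed(work[i : j + 1])]
                cand = work[:i] + seg + work[j + 1 :]
                if _breakpoints([v for v, _ in cand]) < _breakpoints([v for v, _ in work]):
                    names = [g for _, g in work]
                    out.append(
                        InversionBlock(
                            (i, j),
                            (names[i - 1] if i > 0 else None, names[i]),
                            (names[j], names[j + 1] if j + 1 < n else None),
                        )
                    )
                    work = cand
                    found = True
                    break
            if found:
                break
        if not found:
            raise PlastomeError("no breakpoint-reducing reversal found")
    for b in out:
        b.depth = sum(
            1
            for o in out
            if o is not b
            and o.interval[0] <= b.interval[0]
            and b.interval[1] <= o.interval[1]
            and o.interval != b.interval
        )
    return out


def _breakpoints(perm: Sequence[int]) -> int:
    ext = [0] + list(perm) + [len(perm) + 1]
    return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)


def structure_summary(p: Plastome, min_ir: int = 10_000) -> dict:
    """Length, partition lengths, GC% and per-gene copy counts."""
    ir = find_inverted_repeat(p, min_len=min_ir)
    part = None
    if ir is not None:
        part = partition_quadripartite(p, ir)
    lengths = part.lengths(p.length) if part else {}
    copies: dict[str, int] = {}
    for f in p.features:
        copies[f.name] = copies.get(f.name, 0) + 1
    return {
        "id": p.id,
        "length": p.length,
        "gc": gc_content(p),
        "lsc": lengths.get("lsc"),
        "ssc": lengths.get("ssc"),
        "ir": lengths.get("ira"),
        "gene_copies": copies,
        "partition": part,
    }
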