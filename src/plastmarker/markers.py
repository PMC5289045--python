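"""Gel-scorable assay design from classified SNPs.

CAPS: a primer pair flanking the SNP plus a restriction enzyme whose site is
created or destroyed by the allele, scored by predicted digestion fragments.
Tetra-primer ARMS: two outer primers plus two allele-specific inner primers
whose 3' base sits on the SNP (with one deliberate destabilizing mismatch at
the second base from the 3' end), scored by allele-specific product lengths.

Also: in-silico PCR on circular templates, in-silico digestion, and band
pattern prediction/status assignment across genotype panels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .plastome_io import (
    EnzymeSpec,
    Plastome,
    PlastomeError,
    RunConfig,
    iupac_regex,
    revcomp,
)

logger = logging.getLogger("plastmarker")

_TRANSVERSION_PARTNER = {"A": "C", "C": "A", "G": "T", "T": "G"}


def primer_tm(seq: str) -> float:
    """Wallace rule below 14 bases, GC-fraction formula otherwise."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if len(seq) <= 13:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


@dataclass
class PrimerOligo:
    """A primer written 5'->3' with its genome anchor."""

    sequence: str
    anchor: int  # 1-based genome position of the 5' base
    strand: str  # "+" extends right, "-" extends left
    tm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.tm is None:
            self.tm = primer_tm(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BandPattern:
    """Fragment lengths as resolved on a gel, descending."""

    fragments: list[int]

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fragments):
            raise PlastomeError("fragment lengths must be >= 1")
        self.fragments = sorted(self.fragments, reverse=True)

    def matches(self, other: "BandPattern", resolution: int = 20) -> bool:
        if len(self.fragments) != len(other.fragments):
            return False
        return all(
            abs(a - b) <= resolution
            for a, b in zip(self.fragments, other.fragments)
        )


@dataclass
class CAPSMarker:
    id: str
    snp_position: int
    fwd: PrimerOligo
    rev: PrimerOligo
    ta: float
    enzyme: EnzymeSpec
    product_length: dict[str, int] = field(default_factory=dict)
    fragments: dict[str, list[int]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    species_specific: Optional[bool] = None
    candidate_enzymes: list[str] = field(default_factory=list)


@dataclass
class ARMSMarker:
    id: str
    snp_position: int
    outer_fwd: PrimerOligo
    outer_rev: PrimerOligo
    inner_fwd: PrimerOligo
    inner_rev: PrimerOligo
    ta: float
    common_length: dict[str, int] = field(default_factory=dict)
    allele_length: dict[str, int] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    species_specific: Optional[bool] = None


@dataclass
class PCRProduct:
    start: int  # 1-based position of the forward primer's 5' base
    length: int
    sequence: str


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _binding_sites(
    template2: str, n: int, primer: str, max_mismatch: int, three_prime_exact: bool
) -> tuple[list[int], list[int]]:
    """(right-extending 5' starts, left-extending 5' positions), 0-based mod n.

    A right-extending site is where the primer equals the top strand; a
    left-extending site is where its reverse complement does.
    """
    m = len(primer)
    arr = np.frombuffer(template2.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)[: n]
    p_arr = np.frombuffer(primer.encode(), dtype=np.uint8)
    rc_arr = np.frombuffer(revcomp(primer).encode(), dtype=np.uint8)
    mm_f = (win != p_arr).sum(axis=1)
    mm_r = (win != rc_arr).sum(axis=1)
    fwd_hits = np.flatnonzero(mm_f <= max_mismatch)
    rev_hits = np.flatnonzero(mm_r <= max_mismatch)
    if three_prime_exact:
        fwd_hits = fwd_hits[arr[fwd_hits + m - 1] == p_arr[-1]]
        rev_hits = rev_hits[arr[rev_hits] == rc_arr[0]]
    # left-extending 5' position is the rightmost base of the rc match
    return [int(i) for i in fwd_hits], [int(i) + m - 1 for i in rev_hits]


def in_silico_pcr(
    template: Plastome,
    fwd: PrimerOligo | str,
    rev: PrimerOligo | str,
    max_mismatch: int = 0,
    require_3prime_match: bool = True,
    max_product: int = 5000,
) -> list[PCRProduct]:
    """Predict amplicons on a circular template.

    Pairs convergent binding sites of the two primers (either may act as the
    left primer); product length runs from the left primer's 5' base to the
    right primer's 5' base inclusive.
    """
    f_seq = fwd.sequence if isinstance(fwd, PrimerOligo) else fwd.upper()
    r_seq = rev.sequence if isinstance(rev, PrimerOligo) else rev.upper()
    if min(len(f_seq), len(r_seq)) < 15:
        raise PlastomeError("primers must be at least 15 bases")
    n = template.length
    template2 = template.sequence + template.sequence[: min(n, max_product + 60)]
    f_right, f_left = _binding_sites(template2, n, f_seq, max_mismatch, require_3prime_match)
    r_right, r_left = _binding_sites(template2, n, r_seq, max_mismatch, require_3prime_match)

    products: dict[tuple[int, int], PCRProduct] = {}
    for rights, lefts in ((f_right, r_left), (r_right, f_left)):
        for p in rights:
            for q in lefts:
                length = (q - p) % n + 1
                if length > max_product:
                    continue
                # the left-extending site must lie beyond the right primer's
                # own footprint (convergent, non-degenerate pairing)
                if length < max(len(f_seq), len(r_seq)):
                    continue
                start1 = p + 1
                end1 = q % n + 1
                key = (start1, length)
                if key not in products:
                    seq = template.fetch(start1, end1)
                    products[key] = PCRProduct(start1, length, seq)
    return sorted(products.values(), key=lambda pr: (pr.start, pr.length))


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(product: str, enzyme: EnzymeSpec) -> BandPattern:
    """Cut a linear product at every recognition site (both strands).

    Degenerate IUPAC sites honored; palindromic sites counted once; no site
    yields a single full-length fragment.
    """
    product = product.upper()
    m = len(enzyme.recognition)
    cuts: set[int] = set()
    pat = re.compile("(?=" + iupac_regex(enzyme.recognition) + ")")
    for match in pat.finditer(product):
        cuts.add(match.start() + enzyme.cut_offset)
    if not enzyme.palindromic:
        rc_pat = re.compile("(?=" + iupac_regex(revcomp(enzyme.recognition)) + ")")
        for match in rc_pat.finditer(product):
            cuts.add(match.start() + m - enzyme.cut_offset)
    cuts = {c for c in cuts if 0 < c < len(product)}
    edges = [0] + sorted(cuts) + [len(product)]
    return BandPattern([b - a for a, b in zip(edges, edges[1:])])


def find_discriminating_enzymes(
    window_a: str,
    window_b: str,
    catalog: Sequence[EnzymeSpec],
) -> list[EnzymeSpec]:
    """Enzymes whose digestion patterns differ between two allelic windows.

    Windows with ambiguity codes are evaluated conservatively: no enzyme is
    returned (logged).
    """
    if set(window_a) - set("ACGT") or set(window_b) - set("ACGT"):
        logger.info("ambiguous flank; enzymes excluded conservatively")
        return []
    out = []
    for enz in catalog:
        if sorted(digest(window_a, enz).fragments) != sorted(digest(window_b, enz).fragments):
            out.append(enz)
    return out


def snp_windows(
    genome_a: Plastome,
    genome_b: Plastome,
    pos_a: int,
    pos_b: Optional[int] = None,
    window: int = 25,
) -> tuple[str, str]:
    """Allelic windows of +/- ``window`` bases around a SNP in each genome."""
    if pos_b is None:
        pos_b = pos_a
    n_a, n_b = genome_a.length, genome_b.length
    wa = genome_a.fetch((pos_a - window - 1) % n_a + 1, (pos_a + window - 1) % n_a + 1)
    wb = genome_b.fetch((pos_b - window - 1) % n_b + 1, (pos_b + window - 1) % n_b + 1)
    return wa, wb


# ---------------------------------------------------------------------------
# CAPS design
# ---------------------------------------------------------------------------

def _pick_primer(
    template: Plastome,
    three_prime: int,
    strand: str,
    cfg: RunConfig,
) -> Optional[PrimerOligo]:
    """Choose a primer with the given 3'-end genome position and Tm in range."""
    n = template.length
    for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
        if strand == "+":
            start = (three_prime - length) % n + 1  # 5' base
            seq = template.fetch(start, (three_prime - 1) % n + 1)
        else:
            end = (three_prime + length - 2) % n + 1
            seq = revcomp(template.fetch((three_prime - 1) % n + 1, end))
            start = end  # 5' base of a left-extending primer
        tm = primer_tm(seq)
        if cfg.tm_min <= tm <= cfg.tm_max:
            return PrimerOligo(seq, start, strand, tm)
    return None


def design_caps(
    snp,
    genomes: dict[str, Plastome],
    catalog: Sequence[EnzymeSpec],
    cfg: RunConfig,
    marker_id: str = "C?",
    positions: Optional[dict[str, int]] = None,
) -> tuple[Optional[CAPSMarker], str]:
    """Design a CAPS marker for a SNP; returns (marker or None, reason).

    ``genomes`` maps species label -> genome; the first entry is the design
    template.  ``positions`` gives the SNP coordinate per species (defaults
    to the record's reference position everywhere).
    """
    labels = list(genomes)
    ref_label = labels[0]
    template = genomes[ref_label]
    pos = snp.position
    if positions is None:
        positions = {lab: (pos if lab == ref_label else getattr(snp, "position_b", None) or pos)
                     for lab in labels}
    wa, wb = snp_windows(
        genomes[labels[0]], genomes[labels[1]], positions[labels[0]], positions[labels[1]]
    )
    enzymes = find_discriminating_enzymes(wa, wb, catalog)
    if not enzymes:
        return None, "no_enzyme"

    clearance = cfg.snp_primer_clearance
    half_max = cfg.product_max // 2
    for d_f in range(clearance + 10, half_max, 40):
        fwd = _pick_primer(template, pos - d_f, "+", cfg)
        if fwd is None:
            continue
        for d_r in range(clearance + 10, half_max, 40):
            rev = _pick_primer(template, pos + d_r, "-", cfg)
            if rev is None:
                continue
            length = (rev.anchor - fwd.anchor) % template.length + 1
            if not cfg.product_min <= length <= cfg.product_max:
                continue
            marker = _finalize_caps(
                snp, genomes, positions, enzymes, fwd, rev, cfg, marker_id
            )
            if marker is not None:
                return marker, "ok"
    return None, "no_feasible_primers"


def _finalize_caps(snp, genomes, positions, enzymes, fwd, rev, cfg, marker_id):
    products: dict[str, PCRProduct] = {}
    for lab, g in genomes.items():
        hits = in_silico_pcr(g, fwd, rev, max_mismatch=0, max_product=cfg.product_max + 200)
        if len(hits) != 1:
            return None
        products[lab] = hits[0]
    for enz in enzymes:
        frags = {lab: digest(p.sequence, enz) for lab, p in products.items()}
        labs = list(frags)
        if sorted(frags[labs[0]].fragments) != sorted(frags[labs[1]].fragments):
            marker = CAPSMarker(
                id=marker_id,
                snp_position=snp.position,
                fwd=fwd,
                rev=rev,
                ta=min(fwd.tm, rev.tm) - 5.0,
                enzyme=enz,
                product_length={lab: p.length for lab, p in products.items()},
                fragments={lab: f.fragments for lab, f in frags.items()},
                status={lab: "Fixed" for lab in products},
                candidate_enzymes=[e.name for e in enzymes],
            )
            return marker
    return None


# ---------------------------------------------------------------------------
# tetra-primer ARMS design
# ---------------------------------------------------------------------------

def _with_deliberate_mismatch(seq: str) -> str:
    """Swap the second base from the 3' terminus for its transversion."""
    s = list(seq)
    s[-2] = _TRANSVERSION_PARTNER[s[-2]]
    return "".join(s)


def design_arms(
    snp,
    genomes: dict[str, Plastome],
    cfg: RunConfig,
    marker_id: str = "A?",
    positions: Optional[dict[str, int]] = None,
    min_band_separation: int = 30,
) -> tuple[Optional[ARMSMarker], str]:
    """Design a tetra-primer ARMS marker; returns (marker or None, reason).

    Inner primers terminate on the SNP (one per allele, opposite strands)
    with a deliberate transversion mismatch at the penultimate 3' base;
    outer primers are offset asymmetrically so allele products differ by at
    least ``min_band_separation`` bases.
    """
    labels = list(genomes)
    ref_label = labels[0]
    template = genomes[ref_label]
    n = template.length
    pos = snp.position
    if positions is None:
        positions = {lab: (pos if lab == ref_label else getattr(snp, "position_b", None) or pos)
                     for lab in labels}
    allele_ref = snp.allele_a if hasattr(snp, "allele_a") else template.base(pos)
    allele_alt = snp.allele_b if hasattr(snp, "allele_b") else snp.alt_allele
    if template.base(pos) != allele_ref:
        allele_ref, allele_alt = allele_alt, allele_ref

    inner_len = max(cfg.primer_len_min + 4, 24)
    # inner forward: 3' base on the SNP, template allele
    if_start = (pos - inner_len) % n + 1
    if_seq = template.fetch(if_start, pos)
    inner_fwd = PrimerOligo(_with_deliberate_mismatch(if_seq), if_start, "+")
    # inner reverse: 3' base on the SNP from the other strand, other allele
    ir_end = (pos + inner_len - 2) % n + 1
    ir_template = allele_alt + template.fetch(pos % n + 1, ir_end)
    inner_rev = PrimerOligo(_with_deliberate_mismatch(revcomp(ir_template)), ir_end, "-")

    # asymmetric outer offsets: allele products differ by the offset gap
    for d_f in range(120, cfg.product_max // 2, 30):
        d_r = d_f + max(min_band_separation + 10, 40)
        outer_fwd = _pick_primer(template, pos - d_f, "+", cfg)
        outer_rev = _pick_primer(template, pos + d_r, "-", cfg)
        if outer_fwd is None or outer_rev is None:
            continue
        common = (outer_rev.anchor - outer_fwd.anchor) % n + 1
        len_ref = (pos - outer_fwd.anchor) % n + 1  # outer_fwd + inner_rev... see below
        len_alt = (outer_rev.anchor - pos) % n + 1
        if abs(len_ref - len_alt) < min_band_separation:
            continue
        if common > cfg.product_max + 200:
            continue
        marker = ARMSMarker(
            id=marker_id,
            snp_position=pos,
            outer_fwd=outer_fwd,
            outer_rev=outer_rev,
            inner_fwd=inner_fwd,
            inner_rev=inner_rev,
            ta=min(outer_fwd.tm, outer_rev.tm) - 5.0,
        )
        ok = True
        for lab, g in genomes.items():
            bands = arms_bands(marker, g, max_product=cfg.product_max + 200)
            if len(bands.fragments) != 2:  # common + exactly one allele band
                ok = False
                break
            marker.common_length[lab] = max(bands.fragments)
            marker.allele_length[lab] = min(bands.fragments)
            marker.status[lab] = "Fixed"
        if ok and len(set(marker.allele_length.values())) == len(genomes):
            return marker, "ok"
    return None, "no_feasible_primers"


def arms_bands(marker: ARMSMarker, genome: Plastome, max_product: int = 1200) -> BandPattern:
    """Predicted gel bands for an ARMS assay on one genome.

    The outer pair always amplifies; each inner primer amplifies only when
    its 3'-terminal base matches the template (one internal mismatch allowed
    for the deliberate destabilizer).
    """
    bands: list[int] = []
    common = in_silico_pcr(
        genome, marker.outer_fwd, marker.outer_rev, max_mismatch=1, max_product=max_product
    )
    bands.extend(p.length for p in common)
    for inner, outer in (
        (marker.inner_fwd, marker.outer_rev),
        (marker.inner_rev, marker.outer_fwd),
    ):
        hits = in_silico_pcr(
            genome, inner, outer, max_mismatch=1,
            require_3prime_match=True, max_product=max_product,
        )
        # drop re-detections of the common band (inner primers pair with
        # their facing outer primer only)
        bands.extend(p.length for p in hits)
    return BandPattern(bands)


# ---------------------------------------------------------------------------
# marker status across genotype panels
# ---------------------------------------------------------------------------

def predict_marker_status(
    marker: CAPSMarker | ARMSMarker,
    panels: dict[str, Sequence[Plastome]],
    cfg: RunConfig,
) -> CAPSMarker | ARMSMarker:
    """Fill per-species Fixed/Polymorphic status from genotype panels.

    A species is Fixed iff all its genotypes produce the same band pattern
    under the configured gel resolution; the marker is species-specific iff
    every species is Fixed and the patterns differ pairwise across species.
    """
    rep: dict[str, Optional[BandPattern]] = {}
    for lab, panel in panels.items():
        patterns: list[BandPattern] = []
        failures = 0
        for g in panel:
            bp = _band_pattern(marker, g, cfg)
            if bp is None or not bp.fragments:
                failures += 1
                continue
            patterns.append(bp)
        if failures:
            logger.warning(
                "%s: %d genotype(s) in %s failed to amplify; status from remainder",
                marker.id, failures, lab,
            )
        if not patterns:
            marker.status[lab] = "Polymorphic"
            rep[lab] = None
            continue
        fixed = all(
            patterns[0].matches(bp, cfg.band_resolution) for bp in patterns[1:]
        )
        marker.status[lab] = "Fixed" if fixed else "Polymorphic"
        rep[lab] = patterns[0]
    labs = [lab for lab in panels if rep[lab] is not None]
    distinct = all(
        not rep[a].matches(rep[b], cfg.band_resolution)
        for i, a in enumerate(labs)
        for b in labs[i + 1 :]
    )
    marker.species_specific = (
        all(marker.status[lab] == "Fixed" for lab in panels) and distinct and len(labs) > 1
    )
    return marker


def _band_pattern(
    marker: CAPSMarker | ARMSMarker, genome: Plastome, cfg: RunConfig
) -> Optional[BandPattern]:
    if isinstance(marker, ARMSMarker):
        return arms_bands(marker, genome, max_product=cfg.product_max + 200)
    hits = in_silico_pcr(
        genome, marker.fwd, marker.rev, max_mismatch=0,
        max_product=cfg.product_max + 200,
    )
    if len(hits) != 1:
        return None
    return digest(hits[0].sequence, marker.enzyme)
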