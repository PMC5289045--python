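"""Substitution class and functional-context labels for called variants.

Labels mirror a marker table layout: location (coding gene / intergenic
between flanks / intron), transition vs transversion, and synonymous vs
non-synonymous for CDS hits (bacterial/plastid code, translation table 11).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .plastome_io import GeneFeature, Plastome, PlastomeError, in_interval, revcomp

_TABLE11 = unambiguous_dna_by_id[11]
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class EffectLabel:
    """Functional context of a substitution."""

    kind: str  # coding | intergenic | intron
    gene: Optional[str] = None
    left_gene: Optional[str] = None
    right_gene: Optional[str] = None
    substitution: Optional[str] = None  # transition | transversion
    coding_effect: str = "not_applicable"  # synonymous | non-synonymous | not_applicable
    pseudo: bool = False

    def __str__(self) -> str:
        if self.kind == "coding":
            loc = self.gene or "?"
        elif self.kind == "intron":
            loc = f"intron:{self.gene}"
        else:
            loc = f"between:{self.left_gene},{self.right_gene}"
        return f"{loc}|{self.substitution or '-'}|{self.coding_effect}"


def classify_substitution(a: str, b: str) -> str:
    """Transition iff both purines or both pyrimidines."""
    a, b = a.upper(), b.upper()
    if a == b or a not in "ACGT" or b not in "ACGT":
        raise PlastomeError(f"need two distinct unambiguous bases, got {a}/{b}")
    if (a in _PURINES) == (b in _PURINES):
        return "transition"
    return "transversion"


_KIND_PRIORITY = {"CDS": 0, "tRNA": 1, "rRNA": 1, "pseudo_or_ORF": 2}


def locate(pos: int, features: Sequence[GeneFeature], genome_length: int) -> EffectLabel:
    """Locate a position: inside a gene, in an intron, or intergenic.

    Overlapping annotations resolve by CDS > tRNA/rRNA > pseudo.  Intergenic
    flanks are the nearest annotated features on either side in genome
    order, strand ignored.
    """
    if not 1 <= pos <= genome_length:
        raise PlastomeError(f"position {pos} outside [1,{genome_length}]")
    inside: list[GeneFeature] = []
    intronic: list[GeneFeature] = []
    for f in features:
        if f.contains(pos, genome_length):
            inside.append(f)
        elif len(f.intervals) > 1 and in_interval(pos, f.span(), genome_length):
            intronic.append(f)
    if inside:
        f = min(inside, key=lambda f: _KIND_PRIORITY[f.kind])
        return EffectLabel(kind="coding", gene=f.name, pseudo=f.kind == "pseudo_or_ORF")
    if intronic:
        return EffectLabel(kind="intron", gene=intronic[0].name)
    left, right = _flanks(pos, features, genome_length)
    return EffectLabel(kind="intergenic", left_gene=left, right_gene=right)


def _flanks(pos: int, features: Sequence[GeneFeature], genome_length: int):
    best_left = None  # (circular distance, name)
    best_right = None
    for f in features:
        s, e = f.span()
        dl = (pos - e) % genome_length  # distance from feature end back to pos
        dr = (s - pos) % genome_length
        if best_left is None or dl < best_left[0]:
            best_left = (dl, f.name)
        if best_right is None or dr < best_right[0]:
            best_right = (dr, f.name)
    return (
        best_left[1] if best_left else None,
        best_right[1] if best_right else None,
    )


def coding_effect(
    pos: int,
    ref_allele: str,
    alt_allele: str,
    feature: GeneFeature,
    genome: Plastome,
) -> str:
    """Synonymous/non-synonymous call for a SNP inside a CDS.

    Honors strand, codon_start and origin-wrapping multi-interval exon
    structures; translates the affected codon with both alleles.
    """
    if feature.kind != "CDS" and feature.kind != "pseudo_or_ORF":
        raise PlastomeError(f"feature {feature.name} is not a CDS")
    if genome.base(pos) != ref_allele.upper():
        raise PlastomeError(
            f"allele {ref_allele} disagrees with genome base "
            f"{genome.base(pos)} at {pos}"
        )
    # genomic-order concatenation of exons and the offset of `pos` within it
    concat = []
    offset = None
    total = 0
    for s, e in feature.intervals:
        seg = genome.fetch(s, e)
        if in_interval(pos, (s, e), genome.length):
            rel = (pos - s) % genome.length
            offset = total + rel
        concat.append(seg)
        total += len(seg)
    if offset is None:
        raise PlastomeError(f"position {pos} not inside feature {feature.name}")
    s = "".join(concat)
    if feature.strand == "-":
        cds_ref = revcomp(s)
        idx = len(s) - 1 - offset
        ref_c, alt_c = revcomp(ref_allele), revcomp(alt_allele)
    else:
        cds_ref = s
        idx = offset
        ref_c, alt_c = ref_allele.upper(), alt_allele.upper()
    trim = feature.codon_start - 1
    cds_ref = cds_ref[trim:]
    idx -= trim
    if idx < 0:
        return "synonymous"  # upstream of the first complete codon
    ci = idx // 3
    codon = list(cds_ref[ci * 3 : ci * 3 + 3])
    if len(codon) < 3:
        return "synonymous"  # trailing partial codon
    which = idx % 3
    assert codon[which] == ref_c
    alt_codon = list(codon)
    alt_codon[which] = alt_c
    return (
        "synonymous"
        if _translate("".join(codon)) == _translate("".join(alt_codon))
        else "non-synonymous"
    )


def _translate(codon: str) -> str:
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def effect_label(
    pos: int,
    ref_allele: str,
    alt_allele: str,
    plastome: Plastome,
) -> EffectLabel:
    """Full label for one SNP on an annotated genome."""
    label = locate(pos, plastome.features, plastome.length)
    label.substitution = classify_substitution(ref_allele, alt_allele)
    if label.kind == "coding":
        feats = [
            f
            for f in plastome.features
            if f.name == label.gene and f.contains(pos, plastome.length)
        ]
        f = feats[0]
        if f.kind in ("CDS", "pseudo_or_ORF"):
            try:
                label.coding_effect = coding_effect(pos, ref_allele, alt_allele, f, plastome)
            except (PlastomeError, KeyError):
                label.coding_effect = "not_applicable"
    return label


def annotate_records(records, plastome: Plastome) -> None:
    """Fill ``effect`` on variant records in place."""
    for r in records:
        lab = effect_label(r.position, r.ref_allele, r.alt_allele, plastome)
        r.effect = str(lab)
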