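"""Genic location and codon-level consequence annotation.

The annotator resolves the classic strand trap of candidate-gene reporting:
alleles are stored on the forward strand, so a forward-strand G>C falling in
a reverse-strand gene must be complemented (appearing as C>G in the reading
direction of the gene) before the codon is rebuilt and translated.

Only single-nucleotide variants receive codon-level calls; indels are
classified by genic location only.  Translation uses the standard nuclear
genetic code; stop codons render as ``*`` (so a stop gain labels like
``Q120*``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .model import (
    SNV,
    COMPLEMENT,
    GeneModel,
    Genome,
    ReferenceMismatchError,
    VariantRecord,
)

INTERGENIC = "intergenic"
INTRONIC = "intronic"
EXONIC = "exonic"
_SEVERITY = {INTERGENIC: 0, INTRONIC: 1, EXONIC: 2}

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_TO_AA[codon.upper()]


@dataclass
class ConsequenceCall:
    """Outcome of annotating one variant against one (or more) gene models."""

    location_class: str
    is_cds: bool = False
    gene_id: Optional[str] = None
    codon_index: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    synonymous: Optional[bool] = None
    label: Optional[str] = None


def classify_location(
    variant: VariantRecord, genes: Sequence[GeneModel]
) -> str:
    """Classify a position as exonic / intronic / intergenic.

    Exon boundaries are closed on both ends.  When several genes overlap the
    position, the most severe class wins (exonic > intronic > intergenic).
    """
    best = INTERGENIC
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        if gene.contains_cds(variant.chrom, variant.pos):
            return EXONIC
        if gene.span.contains(variant.chrom, variant.pos):
            if _SEVERITY[INTRONIC] > _SEVERITY[best]:
                best = INTRONIC
    return best


def cds_position(gene: GeneModel, pos: int) -> int:
    """1-based coordinate of a genomic position within the spliced CDS,
    measured from the transcript's 5' end (strand-aware)."""
    if not gene.contains_cds(gene.chrom, pos):
        raise ValueError(f"position {gene.chrom}:{pos} is not in the CDS of {gene.gene_id}")
    if gene.strand == "+":
        offset = 0
        for iv in gene.cds_intervals:
            if iv.start <= pos <= iv.end:
                return offset + (pos - iv.start + 1)
            offset += len(iv)
    else:
        offset = 0
        for iv in reversed(gene.cds_intervals):
            if iv.start <= pos <= iv.end:
                return offset + (iv.end - pos + 1)
            offset += len(iv)
    raise AssertionError("unreachable")


def annotate_cds_consequence(
    variant: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> ConsequenceCall:
    """Codon-level consequence of an SNV inside a CDS interval of ``gene``.

    The reference base is checked against the genome; a mismatch is an error
    naming the position.  For reverse-strand genes both alleles are
    complemented and the CDS coordinate is measured from the transcript's
    5' end before the codon is rebuilt.
    """
    if variant.variant_class != SNV:
        raise ValueError("codon-level annotation is defined for SNVs only")
    genome_base = genome[variant.chrom][variant.pos - 1]
    if genome_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: variant REF {variant.ref!r} "
            f"disagrees with genome base {genome_base!r}"
        )
    cpos = cds_position(gene, variant.pos)  # raises if outside the CDS
    if gene.strand == "-":
        ref_allele = variant.ref.translate(COMPLEMENT)
        alt_allele = variant.alt.translate(COMPLEMENT)
    else:
        ref_allele, alt_allele = variant.ref, variant.alt
    codon_index = math.ceil(cpos / 3)
    offset = (cpos - 1) % 3  # 0-based position within the codon
    cds = gene.coding_sequence(genome)
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    if ref_codon[offset] != ref_allele:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: gene-oriented REF {ref_allele!r} "
            f"inconsistent with CDS codon {ref_codon!r}"
        )
    alt_codon = ref_codon[:offset] + alt_allele + ref_codon[offset + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    synonymous = ref_aa == alt_aa
    return ConsequenceCall(
        location_class=EXONIC,
        is_cds=True,
        gene_id=gene.gene_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=synonymous,
        label=None if synonymous else f"{ref_aa}{codon_index}{alt_aa}",
    )


def annotate_variant(
    variant: VariantRecord,
    genes: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
) -> ConsequenceCall:
    """Full annotation of one variant against a transcript set.

    When the variant is a CDS SNV and a genome is supplied, the most severe
    codon-level consequence across overlapping transcripts is reported
    (nonsynonymous > synonymous > non-CDS); otherwise only the location class
    is filled in.  Indels never receive codon annotation.
    """
    location = classify_location(variant, genes)
    call = ConsequenceCall(location_class=location, is_cds=False)
    if location != EXONIC or variant.variant_class != SNV or genome is None:
        return call
    best: Optional[ConsequenceCall] = None
    for gene in genes:
        if not gene.contains_cds(variant.chrom, variant.pos):
            continue
        candidate = annotate_cds_consequence(variant, gene, genome)
        if best is None or (not candidate.synonymous and best.synonymous):
            best = candidate
    return best if best is not None else call


def apply_annotations(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
) -> None:
    """Annotate records in place, writing the funnel-visible keys.

    Keys written: ``location`` (exonic/intronic/intergenic), ``is_cds``
    ("1"/"0"), ``synonymous`` ("1"/"0", CDS SNVs only) and ``aa_label``
    (nonsynonymous SNVs only).  Records that already carry a ``location``
    annotation (e.g. fixtures with printed calls) are left untouched.
    """
    for variant in variants:
        if "location" in variant.annotations:
            continue
        call = annotate_variant(variant, genes, genome)
        variant.annotations["location"] = call.location_class
        variant.annotations["is_cds"] = "1" if call.is_cds else "0"
        if call.is_cds:
            variant.annotations["synonymous"] = "1" if call.synonymous else "0"
            if call.label:
                variant.annotations["aa_label"] = call.label
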