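"""Location classification and codon-level consequence calls, including the
reverse-strand handling that motivates the module."""

import numpy as np
import pytest
from Bio.Seq import Seq

from exomescreen import consequence
from exomescreen.model import (
    GeneModel,
    GenomicInterval,
    ReferenceMismatchError,
    VariantRecord,
)


def snv(chrom, pos, ref, alt):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         mapping_quality=60, read_depth=50)


# --- hand-built miniature genes -------------------------------------------

# reverse-strand gene: transcript ATG ACA TAA laid down as revcomp
REV_GENOME = {"t": "TTATGTCAT"}
REV_GENE = GeneModel(
    gene_id="rev", gene_name="rev", chrom="t", strand="-",
    cds_intervals=[GenomicInterval("t", 1, 9)],
)

FWD_GENOME = {"t": "ATGGCTTAA"}
FWD_GENE = GeneModel(
    gene_id="fwd", gene_name="fwd", chrom="t", strand="+",
    cds_intervals=[GenomicInterval("t", 1, 9)],
)


class TestClassifyLocation:
    def test_exon_boundaries_are_closed(self, tiny_world):
        _, genes = tiny_world
        gene = genes[0]
        iv = gene.cds_intervals[0]
        for pos in (iv.start, iv.end):
            assert consequence.classify_location(
                snv(gene.chrom, pos, "A", "C"), genes
            ) == "exonic"

    def test_position_between_genes_is_intergenic(self, tiny_world):
        """Positions clear of every gene span classify as intergenic, as for
        the published intergenic indel at 9:24346521."""
        genome, genes = tiny_world
        spans = [g.span for g in genes if g.chrom == "9"]
        pos = max(s.end for s in spans) + 100
        assert consequence.classify_location(snv("9", pos, "A", "C"), genes) == (
            "intergenic"
        )

    def test_exhaustive_scan_oracle(self, tiny_world):
        """Per-base brute force over the toy genome: positions are classified
        by direct membership scans and must agree with classify_location."""
        genome, genes = tiny_world
        for chrom, seq in genome.items():
            length = len(seq)
            exonic = np.zeros(length + 1, dtype=bool)
            genic = np.zeros(length + 1, dtype=bool)
            for gene in genes:
                if gene.chrom != chrom:
                    continue
                genic[gene.span.start : gene.span.end + 1] = True
                for iv in gene.cds_intervals:
                    exonic[iv.start : iv.end + 1] = True
            boundary_positions = set()
            for gene in genes:
                if gene.chrom != chrom:
                    continue
                for iv in gene.cds_intervals:
                    for edge in (iv.start, iv.end):
                        boundary_positions.update(
                            p for p in range(edge - 2, edge + 3)
                            if 1 <= p <= length
                        )
            positions = sorted(set(range(1, length + 1, 97)) | boundary_positions)
            for pos in positions:
                expected = (
                    "exonic" if exonic[pos]
                    else "intronic" if genic[pos]
                    else "intergenic"
                )
                got = consequence.classify_location(snv(chrom, pos, "A", "C"), genes)
                assert got == expected, f"{chrom}:{pos}"


class TestCdsConsequence:
    def test_reverse_strand_thr_to_arg(self):
        """Forward-strand G>C in a reverse-strand gene reads C>G in gene
        orientation: codon 2 ACA -> AGA, Thr -> Arg."""
        call = consequence.annotate_cds_consequence(
            snv("t", 5, "G", "C"), REV_GENE, REV_GENOME
        )
        assert (call.ref_codon, call.alt_codon) == ("ACA", "AGA")
        assert (call.ref_aa, call.alt_aa) == ("T", "R")
        assert call.codon_index == 2
        assert call.synonymous is False
        assert call.label == "T2R"

    def test_synonymous_third_position(self):
        """GCT -> GCC at codon position 3 is Ala -> Ala: no label."""
        call = consequence.annotate_cds_consequence(
            snv("t", 6, "T", "C"), FWD_GENE, FWD_GENOME
        )
        assert (call.ref_codon, call.alt_codon) == ("GCT", "GCC")
        assert call.synonymous is True
        assert call.label is None

    def test_stop_gain_labelled_with_asterisk(self):
        # codon 2 TAT (Tyr), third base T>A gives TAA: stop gain, rendered "*"
        genome = {"t": "ATGTATTAA"}
        gene = GeneModel(gene_id="g", gene_name="g", chrom="t", strand="+",
                         cds_intervals=[GenomicInterval("t", 1, 9)])
        call = consequence.annotate_cds_consequence(snv("t", 6, "T", "A"), gene, genome)
        assert call.alt_aa == "*"
        assert call.label == "Y2*"

    def test_reference_mismatch_error_names_position(self):
        with pytest.raises(ReferenceMismatchError, match="t:5"):
            consequence.annotate_cds_consequence(
                snv("t", 5, "A", "C"), REV_GENE, REV_GENOME
            )

    def test_variant_outside_cds_is_error(self, tiny_world):
        genome, genes = tiny_world
        gene = genes[0]
        pos = gene.cds_intervals[0].end + 1  # first intron base
        ref = genome[gene.chrom][pos - 1]
        alt = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="not in the CDS"):
            consequence.annotate_cds_consequence(
                snv(gene.chrom, pos, ref, alt), gene, genome
            )

    def test_indels_never_get_codon_annotation(self, tiny_world):
        genome, genes = tiny_world
        gene = genes[0]
        pos = gene.cds_intervals[0].start
        ref2 = genome[gene.chrom][pos - 1 : pos + 1]
        deletion = VariantRecord(chrom=gene.chrom, pos=pos, ref=ref2, alt=ref2[0],
                                 mapping_quality=60, read_depth=50)
        call = consequence.annotate_variant(deletion, genes, genome)
        assert call.location_class == "exonic"
        assert call.is_cds is False
        assert call.codon_index is None

    def test_most_severe_consequence_across_overlapping_genes(self):
        """Same SNV synonymous in one frame, missense in an overlapping one:
        the nonsynonymous call wins."""
        genome = {"t": "ATGGCTTAAATGTTT"}
        gene_a = GeneModel(gene_id="a", gene_name="a", chrom="t", strand="+",
                           cds_intervals=[GenomicInterval("t", 1, 9)])
        gene_b = GeneModel(gene_id="b", gene_name="b", chrom="t", strand="+",
                           cds_intervals=[GenomicInterval("t", 5, 13)])
        call = consequence.annotate_variant(snv("t", 6, "T", "C"),
                                            [gene_a, gene_b], genome)
        assert call.synonymous is False
        assert call.gene_id == "b"


def _mutant_protein(gene, genome, pos, alt):
    """Independent oracle: splice the mutant CDS out of a mutated genome copy
    and translate it whole with Biopython."""
    chrom_seq = genome[gene.chrom]
    mutant = {**genome, gene.chrom: chrom_seq[: pos - 1] + alt + chrom_seq[pos:]}
    return str(Seq(gene.coding_sequence(mutant)).translate())


class TestFullCdsOracle:
    def test_every_cds_snv_matches_whole_protein_diff(self, tiny_world):
        """For every CDS position and alternate allele in the toy genome the
        codon-level call equals the diff of the translated mutant protein
        against wildtype: same residue index, same substitution, and exactly
        one residue differs iff the call is nonsynonymous."""
        genome, genes = tiny_world
        for gene in genes:
            wildtype = str(Seq(gene.coding_sequence(genome)).translate())
            for iv in gene.cds_intervals:
                for pos in range(iv.start, iv.end + 1):
                    ref = genome[gene.chrom][pos - 1]
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        call = consequence.annotate_cds_consequence(
                            snv(gene.chrom, pos, ref, alt), gene, genome
                        )
                        mutant = _mutant_protein(gene, genome, pos, alt)
                        diffs = [
                            i for i, (w, m) in enumerate(zip(wildtype, mutant), start=1)
                            if w != m
                        ]
                        if call.synonymous:
                            assert diffs == []
                        else:
                            assert diffs == [call.codon_index]
                            assert wildtype[call.codon_index - 1] == call.ref_aa
                            assert mutant[call.codon_index - 1] == call.alt_aa


class TestStrandInvolution:
    def test_reverse_gene_equals_mirrored_forward_construct(self, tiny_world):
        """Annotating on a reverse-strand gene equals annotating the reverse
        complemented, coordinate-mirrored construct on the forward strand."""
        genome, genes = tiny_world
        rng = np.random.default_rng(0)
        rev_genes = [g for g in genes if g.strand == "-"]
        assert rev_genes
        for gene in rev_genes:
            length = len(genome[gene.chrom])
            mirrored_seq = str(Seq(genome[gene.chrom]).reverse_complement())
            mirrored_gene = GeneModel(
                gene_id=gene.gene_id, gene_name=gene.gene_name, chrom=gene.chrom,
                strand="+",
                cds_intervals=[
                    GenomicInterval(gene.chrom, length - iv.end + 1,
                                    length - iv.start + 1)
                    for iv in reversed(gene.cds_intervals)
                ],
            )
            mirrored_genome = {gene.chrom: mirrored_seq}
            cds_positions = [
                p for iv in gene.cds_intervals for p in range(iv.start, iv.end + 1)
            ]
            for pos in rng.choice(cds_positions, size=25, replace=False):
                pos = int(pos)
                ref = genome[gene.chrom][pos - 1]
                alt = rng.permuted([b for b in "ACGT" if b != ref])[0]
                original = consequence.annotate_cds_consequence(
                    snv(gene.chrom, pos, ref, alt), gene, genome
                )
                mpos = length - pos + 1
                mref = str(Seq(ref).reverse_complement())
                malt = str(Seq(alt).reverse_complement())
                mirrored = consequence.annotate_cds_consequence(
                    snv(gene.chrom, mpos, mref, malt), mirrored_gene, mirrored_genome
                )
                assert (original.codon_index, original.ref_codon, original.alt_codon,
                        original.ref_aa, original.alt_aa, original.synonymous) == (
                    mirrored.codon_index, mirrored.ref_codon, mirrored.alt_codon,
                    mirrored.ref_aa, mirrored.alt_aa, mirrored.synonymous
                )
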