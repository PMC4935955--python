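"""Published candidate-variant records, usable as desk-scale inputs.

Two small record sets from the original stonedeaf (S1pr2) screen are bundled
as constructors: the seven SNV-funnel survivors of the critical region on
chromosome 9 (with their published genic location, coding consequence,
zygosity and ancestral-ES-line flags), and the four structural-variant
survivors (1 bp deletions, none in coding sequence, two carried by the
ancestral ES line, none confirmed by capillary sequencing).

The SNV records carry their published alleles.  The published indel table
lists positions but no REF/ALT allele strings, so the indel records here use
SYNTHETIC placeholder alleles; positions, sizes, genic locations and ES-line
flags are as published.  Mapping quality and read depth were likewise not
published per record (all records had passed MQ >= 45, DP >= 10), so nominal
passing values are attached.
"""

from __future__ import annotations

from .model import (
    HET,
    HOM_ALT,
    ROLE_ES_LINE,
    CallSet,
    GenomicInterval,
    VariantRecord,
)

#: The seven candidate positions bound the critical region from the inside;
#: its exact published bounds were never printed.
CANDIDATE_BOUNDING_INTERVAL = GenomicInterval("9", 15_116_608, 23_211_238)

AFFECTED_SAMPLE_IDS = ("SD8.2c", "SD23.1g")

# gene, pos, ref, alt, location, zygosity, consequence, in_es
_TABLE5 = [
    ("Taf1d", 15_116_608, "T", "C", "intronic", HOM_ALT, None, True),
    ("Fat3", 15_834_189, "G", "T", "intronic", HET, None, False),
    ("Zfp426", 20_280_762, "CGTGTGTGTGTGTGTGTGTGTGTGTGTGT",
     "CGTGTGTGTGTGTGTGTGTGTGTGTGT", "intronic", HET, None, False),
    ("Col5a3", 20_602_750,
     "AACACACACACACACACACACACACACACACACACACACACAC",
     "AACACACACACACACACACACACACACACACACACACACAC", "intronic", HET, None, True),
    ("Rdh8", 20_627_812, "C", "T", "exonic", HOM_ALT, "synonymous", False),
    ("S1pr2", 20_772_109, "G", "C", "exonic", HOM_ALT, "T289R", False),
    ("Bmper", 23_211_238, "A", "C", "exonic", HET, "T570P", True),
]

#: (chrom, pos) of the causal S1pr2 variant; forward-strand G>C, reading C>G
#: in gene orientation (S1pr2 is on the reverse strand), Thr289 -> Arg.
CAUSAL_SNV_KEY = ("9", 20_772_109, "G", "C")

# gene, pos, ref, alt (alleles SYNTHETIC), location, in_es, call_quality
_TABLE3 = [
    ("Col5a3", 20_607_549, "CA", "C", "intronic", False, 850.0),
    ("Slc44a2", 21_149_853, "GT", "G", "intronic", True, 900.0),
    ("Rgl3", 21_786_028, "AG", "A", "intronic", True, 800.0),
    (None, 24_346_521, "TG", "T", "intergenic", False, 870.0),
]


def _make_record(gene, pos, ref, alt, location, zygosity, consequence, in_es):
    annotations = {
        "location": location,
        "is_cds": "1" if consequence is not None else "0",
        "in_es_line": "1" if in_es else "0",
    }
    if gene is not None:
        annotations["gene"] = gene
    if consequence is not None:
        annotations["synonymous"] = "1" if consequence == "synonymous" else "0"
        if consequence != "synonymous":
            annotations["aa_label"] = consequence
    return VariantRecord(
        chrom="9",
        pos=pos,
        ref=ref,
        alt=alt,
        mapping_quality=60.0,
        read_depth=50,
        call_quality=500.0,
        genotypes={sid: zygosity for sid in AFFECTED_SAMPLE_IDS},
        annotations=annotations,
    )


def candidate_snv_records() -> list[VariantRecord]:
    """The seven published critical-region candidates, with published
    location/consequence/ES-line annotations attached."""
    return [_make_record(*row) for row in _TABLE5]


def candidate_snv_es_line() -> CallSet:
    """Ancestral ES-cell-line call set implied by the published flags
    (the Taf1d, Col5a3 and Bmper records)."""
    es = CallSet(sample_id="ES_line", role=ROLE_ES_LINE)
    for record in candidate_snv_records():
        if record.annotations["in_es_line"] == "1":
            es.add(
                VariantRecord(
                    chrom=record.chrom, pos=record.pos,
                    ref=record.ref, alt=record.alt,
                    mapping_quality=60.0, read_depth=100, call_quality=500.0,
                )
            )
    return es


def indel_records() -> list[VariantRecord]:
    """The four published structural-variant survivors (1 bp deletions).

    Allele strings are synthetic placeholders (not published); positions,
    genic locations, ES-line flags and the unconfirmed capillary-sequencing
    status are as published.
    """
    records = []
    for gene, pos, ref, alt, location, in_es, qual in _TABLE3:
        annotations = {
            "location": location,
            "is_cds": "0",
            "in_es_line": "1" if in_es else "0",
            "capillary_confirmed": "0",
        }
        if gene is not None:
            annotations["gene"] = gene
        records.append(
            VariantRecord(
                chrom="9", pos=pos, ref=ref, alt=alt,
                mapping_quality=60.0, read_depth=50, call_quality=qual,
                genotypes={sid: HOM_ALT for sid in AFFECTED_SAMPLE_IDS},
                annotations=annotations,
            )
        )
    return records


def indel_es_line() -> CallSet:
    """ES-line call set implied by the published indel flags."""
    es = CallSet(sample_id="ES_line", role=ROLE_ES_LINE)
    for record in indel_records():
        if record.annotations["in_es_line"] == "1":
            es.add(
                VariantRecord(
                    chrom=record.chrom, pos=record.pos,
                    ref=record.ref, alt=record.alt,
                    mapping_quality=60.0, read_depth=100, call_quality=500.0,
                )
            )
    return es
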