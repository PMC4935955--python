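#!/usr/bin/env python
"""Prioritise exome candidates inside the mapped interval.

Reads the affected-animal call sets, the three reference panels, the gene
models and the genome written by 01, and the critical interval mapped by 02.
Runs the eight-stage SNV funnel (quality -> shared by both homozygotes ->
known-variant subtraction -> chromosome -> interval -> exonic ->
nonsynonymous -> ancestral-ES subtraction) and the three-stage indel branch,
then annotates the surviving candidate's codon-level consequence.

Writes the funnel tables, surviving candidates (VCF) and per-variant audit
trail to results/funnel/.
"""

from pathlib import Path

import pandas as pd

from exomescreen import consequence, funnel
from exomescreen import io_formats as io
from exomescreen.model import GenomicInterval, VariantRecord

ROOT = Path(__file__).resolve().parents[1]
SCREEN = ROOT / "results" / "screen"
OUT = ROOT / "results" / "funnel"


def main() -> None:
    affected = [
        io.read_variant_callset(SCREEN / f"affected{i}.vcf", f"SD{i}", "affected")
        for i in (1, 2)
    ]
    panels = [
        io.read_variant_callset(SCREEN / "known_db.vcf", "known_db", "known_db"),
        io.read_variant_callset(
            SCREEN / "strain_panel.vcf", "wildtype_strains", "strain_panel"
        ),
    ]
    es_line = io.read_variant_callset(SCREEN / "es_line.vcf", "ES_line", "es_line")
    genes = io.read_gene_models(SCREEN / "genes.gff3")
    genome = io.read_fasta(ROOT / "scratch" / "screen" / "genome.fa")

    bed = (ROOT / "results" / "linkage" / "critical_interval.bed").read_text().split()
    interval = GenomicInterval(bed[0], int(bed[1]) + 1, int(bed[2]))

    report = funnel.run_snv_funnel(affected, panels, es_line, interval, genes, genome)
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.stage_counts, columns=["stage", "remaining"]).to_csv(
        OUT / "snv_funnel.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "first_failed": v}
         for k, v in sorted(report.audit.items())]
    ).to_csv(OUT / "audit.tsv", sep="\t", index=False)

    survivors = io.CallSet(sample_id="candidates", role="known_db")
    for record in report.survivors:
        survivors.records[record.key] = record
    io.write_variant_callset(survivors, OUT / "candidates.vcf")

    print("SNV funnel:")
    for name, count in report.stage_counts:
        print(f"  {name}: {count}")
    for record in report.survivors:
        gene = next(g for g in genes if g.contains_cds(record.chrom, record.pos))
        call = consequence.annotate_cds_consequence(
            VariantRecord(chrom=record.chrom, pos=record.pos,
                          ref=record.ref, alt=record.alt),
            gene, genome,
        )
        print(
            f"sole candidate: {record.chrom}:{record.pos} {record.ref}>{record.alt} "
            f"in {gene.gene_name} (strand {gene.strand}); gene-oriented "
            f"{call.ref_codon}->{call.alt_codon}, consequence {call.label}"
        )

    indel_report = funnel.run_indel_funnel(
        affected, interval, es_line=es_line, genes=genes, genome=genome
    )
    pd.DataFrame(indel_report.stage_counts, columns=["stage", "remaining"]).to_csv(
        OUT / "indel_funnel.tsv", sep="\t", index=False
    )
    print(
        f"indel branch: {indel_report.stage_counts[-1][1]} survivors in region; "
        f"{indel_report.extras['coding_region_count']} in coding sequence, "
        f"{indel_report.extras['es_line_count']} in the ancestral ES line"
    )
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
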