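#!/usr/bin/env python
"""Simulate one complete forward-genetics deafness screen.

Generates the stated default world — a 161-offspring backcross, exome-like
call sets for two affected animals plus ES-line / wildtype-strain / known-
variant panels, and the toy genome with its gene models — and writes every
artefact to disk in its external format (VCF, GFF3, FASTA, TSV) so the later
stages run from files, exactly as the real pipeline would.

Small text outputs go to results/screen/; the multi-megabyte genome FASTA
goes to scratch/screen/.
"""

import argparse
from pathlib import Path

from exomescreen import io_formats as io
from exomescreen import synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results" / "screen"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "screen"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = synthetic.ScreenConfig(seed=args.seed)
    data = synthetic.simulate_screen(config)

    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    io.write_marker_table(data.marker_table, RESULTS / "markers.tsv")
    io.write_phenotype_table(data.phenotypes, RESULTS / "phenotypes.tsv")
    for i, affected in enumerate(data.callsets.affected, start=1):
        io.write_variant_callset(affected, RESULTS / f"affected{i}.vcf")
    io.write_variant_callset(data.callsets.es_line, RESULTS / "es_line.vcf")
    io.write_variant_callset(data.callsets.strain_panel, RESULTS / "strain_panel.vcf")
    io.write_variant_callset(data.callsets.known_db, RESULTS / "known_db.vcf")
    io.write_gene_models(data.genes, RESULTS / "genes.gff3")
    io.write_fasta(data.genome, SCRATCH / "genome.fa")

    n_affected = sum(p.stdf_genotype == "stdf/stdf" for p in data.phenotypes)
    print(f"seed {args.seed}: {n_affected} affected / {config.n_offspring} offspring")
    print(f"markers: {len(data.marker_table.markers)} "
          f"({config.marker_spacing_cM} cM spacing, {config.cM_per_Mb} cM/Mb)")
    print(f"affected exomes: {len(data.callsets.affected[0])} and "
          f"{len(data.callsets.affected[1])} calls "
          f"(planted causal variant at {config.causal_locus[0]}:"
          f"{config.causal_locus[1]})")
    print(f"wrote tables and call sets to {RESULTS}")
    print(f"wrote genome FASTA to {SCRATCH}")


if __name__ == "__main__":
    main()
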