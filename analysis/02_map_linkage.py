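#!/usr/bin/env python
"""Map the deafness locus by backcross linkage analysis.

Reads the marker genotypes and phenotypes written by 01_simulate_screen.py,
assigns affected status from click-ABR thresholds (>= 60 dB SPL or no
response, animals >= 4 weeks old), counts recombinants per marker, computes
two-point backcross LOD scores, and delimits the critical interval by the
nearest flanking markers showing recombinants.

Writes the per-marker LOD table, the interval as BED, and a LOD plot to
results/linkage/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from exomescreen import io_formats as io
from exomescreen import linkage, segregation

ROOT = Path(__file__).resolve().parents[1]
SCREEN = ROOT / "results" / "screen"
OUT = ROOT / "results" / "linkage"


def main() -> None:
    table = io.read_marker_table(SCREEN / "markers.tsv")
    phenotypes = {p.animal_id: p for p in io.read_phenotype_table(
        SCREEN / "phenotypes.tsv")}
    affected = [
        segregation.call_affected(phenotypes[animal]) for animal in table.animals
    ]
    assert all(status is not None for status in affected)

    result = linkage.map_critical_interval(table, affected)
    OUT.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [{"marker_id": m.marker_id, "chrom": m.chrom, "pos_bp": m.pos,
          "n": m.informative_count, "r": m.recombinant_count,
          "theta_hat": round(m.theta_hat, 4), "lod": round(m.lod, 3)}
         for m in result.per_marker]
    )
    frame.to_csv(OUT / "lod_table.tsv", sep="\t", index=False)

    interval = result.critical_interval
    io.write_interval_bed(interval, OUT / "critical_interval.bed")

    fig, axes = plt.subplots(
        1, frame["chrom"].nunique(), figsize=(9, 3.2), sharey=True
    )
    for ax, (chrom, sub) in zip(axes, frame.groupby("chrom", sort=True)):
        ax.plot(sub["pos_bp"] / 1e6, sub["lod"], "o-")
        ax.set_title(f"chromosome {chrom}")
        ax.set_xlabel("position (Mbp)")
        if chrom == interval.chrom:
            ax.axvspan(interval.start / 1e6, interval.end / 1e6, alpha=0.2)
    axes[0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(OUT / "lod_scan.png", dpi=120)

    peak = result.marker(result.peak_marker_id)
    print(f"phenotyped {len(affected)} offspring: {sum(affected)} affected")
    print(f"peak marker {peak.marker_id} at {peak.chrom}:{peak.pos} "
          f"(r={peak.recombinant_count}/{peak.informative_count}, "
          f"LOD={peak.lod:.2f})")
    print(f"critical interval {interval} "
          f"({len(interval) / 1e6:.1f} Mbp) -> {OUT}")


if __name__ == "__main__":
    main()
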