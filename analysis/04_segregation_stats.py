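#!/usr/bin/env python
"""Colony segregation statistics and the second-locus comparison.

Simulates a genotyped colony (n = 204 animals at 8 and 14 weeks) carrying a
phenotypically inert second targeted mutation, then computes: concordance of
affected status with the recessive full-penetrance model and per-genotype
penetrance; the chi-square test of the backcross 1:1 segregation (including
the published 79:82 counts); endocochlear-potential group summaries across
ages; and stratified Mann-Whitney tests of the second locus within each
(genotype, age) stratum.

Writes JSON/TSV outputs to results/segregation/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from exomescreen import io_formats as io
from exomescreen import segregation, synthetic
from exomescreen.model import GT_HET, GT_HOM, GT_WT

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "segregation"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    # published backcross counts as the reference Mendelian check
    chi2, p = segregation.mendelian_ratio_test(79, 82)
    print(f"backcross 79 affected : 82 unaffected vs 1:1 -> "
          f"chi2={chi2:.4f}, p={p:.3f} (consistent with Mendelian 1:1)")

    colony = synthetic.simulate_colony_phenotypes(
        204, {GT_WT: 0.25, GT_HET: 0.5, GT_HOM: 0.25},
        ages=[8.0, 14.0], seed=args.seed, second_locus="Mms22l",
    )
    io.write_phenotype_table(colony, OUT / "colony.tsv")
    report = segregation.segregation_concordance(colony)
    payload = {
        "n": report.n,
        "concordance": report.concordance,
        "penetrance": report.penetrance,
        "counts": {f"{g}|{'affected' if s else 'unaffected'}": c
                   for (g, s), c in sorted(report.counts.items())},
        "mendelian_chi2": report.mendelian_chi2,
        "mendelian_p": report.mendelian_p,
    }
    (OUT / "segregation.json").write_text(json.dumps(payload, indent=2))
    print(f"colony n={report.n}: concordance={report.concordance:.3f}; "
          f"penetrance stdf/stdf={report.penetrance[GT_HOM]:.2f}, "
          f"het={report.penetrance[GT_HET]:.2f}, wt={report.penetrance[GT_WT]:.2f}")

    # EP trajectories across ages, mirroring the electrophysiology design
    ep_colony = synthetic.simulate_colony_phenotypes(
        300, {GT_HET: 0.5, GT_HOM: 0.5}, ages=[2.0, 4.0, 8.0], seed=args.seed + 1
    )
    summary = segregation.group_summary(ep_colony, value="ep_mv")
    summary.to_csv(OUT / "ep_summary.tsv", sep="\t", index=False)
    print("EP summaries (mean +/- SD, mV):")
    for _, row in summary.iterrows():
        print(f"  {row['stdf_genotype']:>10s} at {row['age_weeks']:>4.0f} wk: "
              f"{row['mean']:6.1f} +/- {row['sd']:4.1f} (n={int(row['n'])})")

    strata = segregation.stratified_rank_sum(colony, "Mms22l", ("targeted", "wt"))
    frame = pd.DataFrame(
        [{"stdf_genotype": s.stratum[0], "age_weeks": s.stratum[1],
          "n_targeted": s.n_with, "n_wt": s.n_without,
          "U": s.u_statistic, "p": round(s.p_value, 4)} for s in strata]
    )
    frame.to_csv(OUT / "mms22l_rank_sum.tsv", sep="\t", index=False)
    worst = frame["p"].min()
    print(f"second locus (Mms22l) within {len(frame)} strata: "
          f"all p >= {worst:.3f}" if worst > 0.05 else
          f"second locus: smallest stratum p = {worst:.4f}")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
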