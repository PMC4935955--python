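"""Genotype-phenotype segregation statistics for the deafness colony.

Affected status is called from click-evoked ABR thresholds: an animal is
affected when its threshold reaches the cutoff (default 60 dB SPL, chosen to
sit far above the control distribution and below severe-loss mutants) or
shows no response at the 95 dB ceiling.  Animals younger than the minimum age
(default 4 weeks) are *indeterminate*, because recessive mutants are still
phenotypically normal at 2 weeks — calling them unaffected would create
false discordance.

Co-segregation with the candidate genotype is summarised as concordance with
the recessive full-penetrance model and per-genotype penetrance; Mendelian
segregation ratios are tested with a 1-df chi-square goodness of fit; and a
second locus is dissected with stratified two-sided Mann-Whitney tests
(exact enumeration for small tie-free groups, tie-corrected normal
approximation otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import GT_HET, GT_HOM, GT_UNKNOWN, GT_WT, NO_RESPONSE, PhenotypeRecord


@dataclass
class AffectedRule:
    """Decision rule mapping ABR phenotype to affected status."""

    cutoff_db: float = 60.0
    min_age_weeks: float = 4.0


@dataclass
class SegregationReport:
    concordance: float
    penetrance: dict[str, float]
    counts: dict[tuple[str, bool], int]
    mendelian_chi2: float
    mendelian_p: float
    model: str = "monogenic autosomal recessive, full penetrance"

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def call_affected(
    record: PhenotypeRecord, rule: Optional[AffectedRule] = None
) -> Optional[bool]:
    """Affected / unaffected / indeterminate (None) for one animal.

    Indeterminate below ``min_age_weeks``; otherwise affected iff the click
    threshold reaches ``cutoff_db`` (inclusive) or is NO_RESPONSE.  When the
    click threshold is absent, the best (minimum) tone threshold stands in;
    with neither, the record is uninterpretable.
    """
    rule = rule or AffectedRule()
    if record.age_weeks < rule.min_age_weeks:
        return None
    threshold = record.click_threshold
    if threshold is None:
        if not record.tone_thresholds:
            raise ValueError(
                f"animal {record.animal_id}: no click threshold and no tone data"
            )
        threshold = min(record.tone_thresholds.values())
    return threshold >= rule.cutoff_db


def segregation_concordance(
    records: Sequence[PhenotypeRecord],
    rule: Optional[AffectedRule] = None,
    expected_affected_fraction: float = 0.5,
) -> SegregationReport:
    """Concordance with the recessive model over determinate, genotyped animals.

    Predicted affected <=> homozygous mutant.  Penetrance is the affected
    fraction per genotype.  The report also carries a chi-square test of the
    affected:unaffected split against ``expected_affected_fraction``.
    """
    counts: dict[tuple[str, bool], int] = {}
    concordant = 0
    total = 0
    for record in records:
        if record.stdf_genotype == GT_UNKNOWN:
            continue
        status = call_affected(record, rule)
        if status is None:
            continue
        counts[(record.stdf_genotype, status)] = (
            counts.get((record.stdf_genotype, status), 0) + 1
        )
        predicted = record.stdf_genotype == GT_HOM
        concordant += int(status == predicted)
        total += 1
    if total == 0:
        raise ValueError("no determinate records with known genotype")
    penetrance = {}
    for genotype in (GT_WT, GT_HET, GT_HOM):
        n_g = counts.get((genotype, True), 0) + counts.get((genotype, False), 0)
        if n_g:
            penetrance[genotype] = counts.get((genotype, True), 0) / n_g
    n_affected = sum(c for (_, status), c in counts.items() if status)
    chi2, p = mendelian_ratio_test(
        n_affected, total - n_affected,
        expected_ratio=(expected_affected_fraction, 1 - expected_affected_fraction),
    )
    return SegregationReport(
        concordance=concordant / total,
        penetrance=penetrance,
        counts=counts,
        mendelian_chi2=chi2,
        mendelian_p=p,
    )


def mendelian_ratio_test(
    n_affected: int,
    n_unaffected: int,
    expected_ratio: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """1-df chi-square goodness of fit of observed counts to an expected ratio."""
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("counts must be non-negative")
    total = n_affected + n_unaffected
    if total == 0:
        raise ValueError("need at least one animal")
    weight = expected_ratio[0] + expected_ratio[1]
    expected = [total * expected_ratio[0] / weight, total * expected_ratio[1] / weight]
    chi2, p = stats.chisquare([n_affected, n_unaffected], f_exp=expected)
    return float(chi2), float(p)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null enumeration when both groups have <= 8 observations and no
    value is tied across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction.  Two
    identical groups (zero rank variance) return p = 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    has_ties = len(set(pooled)) != len(pooled)
    if len(set(pooled)) == 1:
        return len(x) * len(y) / 2.0, 1.0
    if len(x) <= 8 and len(y) <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    if math.isnan(p):  # degenerate rank variance
        p = 1.0
    return float(res.statistic), min(p, 1.0)


@dataclass
class StratumResult:
    stratum: tuple
    n_with: int
    n_without: int
    u_statistic: float
    p_value: float


def _rank_value(record: PhenotypeRecord) -> Optional[float]:
    """Click threshold for ranking; NO_RESPONSE ranks above the 95 dB ceiling."""
    value = record.click_threshold
    if value is None:
        return None
    if value == NO_RESPONSE:
        return 100.0  # censored just above the stimulus ceiling; ties among NR
    return value


def stratified_rank_sum(
    records: Sequence[PhenotypeRecord],
    group_locus: str,
    group_alleles: tuple[str, str],
) -> list[StratumResult]:
    """Mann-Whitney comparison of a second locus within (genotype, age) strata.

    ``group_alleles`` names the two states of ``record.extra_genotypes[group_locus]``
    to compare.  Strata where either group is empty are skipped with a warning.
    """
    strata: dict[tuple, dict[str, list[float]]] = {}
    for record in records:
        state = record.extra_genotypes.get(group_locus)
        if state not in group_alleles:
            continue
        value = _rank_value(record)
        if value is None:
            continue
        key = (record.stdf_genotype, record.age_weeks)
        strata.setdefault(key, {a: [] for a in group_alleles})[state].append(value)
    results: list[StratumResult] = []
    for key in sorted(strata):
        groups = strata[key]
        a, b = (groups[al] for al in group_alleles)
        if not a or not b:
            warnings.warn(f"stratum {key}: one group empty, skipped", stacklevel=2)
            continue
        u, p = rank_sum_test(a, b)
        results.append(
            StratumResult(stratum=key, n_with=len(a), n_without=len(b),
                          u_statistic=u, p_value=p)
        )
    return results


def group_summary(
    records: Sequence[PhenotypeRecord],
    value: str = "ep_mv",
) -> "pd.DataFrame":
    """Per-(genotype, age) summary table: n, mean, SD (n-1), min, max.

    NO_RESPONSE observations are excluded from the numeric summary and
    counted separately (``n_no_response``); the SD of a single observation is
    reported as missing.
    """
    import pandas as pd

    rows = []
    groups: dict[tuple, list[float]] = {}
    censored: dict[tuple, int] = {}
    for record in records:
        v = getattr(record, value) if value != "click_threshold" else record.click_threshold
        key = (record.stdf_genotype, record.age_weeks)
        if v is None:
            continue
        if v == NO_RESPONSE:
            censored[key] = censored.get(key, 0) + 1
            groups.setdefault(key, [])
            continue
        groups.setdefault(key, []).append(float(v))
    for key in sorted(groups):
        # sorted reduction keeps the summary invariant to record order
        vals = np.sort(np.asarray(groups[key], dtype=float))
        rows.append(
            {
                "stdf_genotype": key[0],
                "age_weeks": key[1],
                "n": len(vals),
                "n_no_response": censored.get(key, 0),
                "mean": float(np.mean(vals)) if len(vals) else math.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
                "min": float(np.min(vals)) if len(vals) else math.nan,
                "max": float(np.max(vals)) if len(vals) else math.nan,
            }
        )
    return pd.DataFrame(rows)
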