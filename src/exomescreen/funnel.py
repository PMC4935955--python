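"""Ordered, auditable variant-prioritisation funnels.

The SNV funnel applies eight stages in a fixed canonical order: per-sample
quality (MQ >= 45 and DP >= 10, boundary inclusive), presence in both
affected homozygotes, subtraction of known variants (dbSNP-like panel and
wildtype-strain panel), chromosome restriction, containment in the mapped
critical interval, exonic location, nonsynonymous consequence, and
subtraction of variants carried by the ancestral ES cell line (which pre-date
the new mutation).  Panel subtraction is allele-aware: a different alternate
allele at a known position is *not* excluded.  Zygosity is never a filter —
heterozygous calls are retained throughout.

The indel branch applies above-average call quality (strictly greater than
the mean over the funnel's initial input set, frozen into the context so
every stage remains a pure predicate), shared-affected and interval stages,
then reports coding-region overlap and ES-line membership as evidence rather
than exclusions.

Every stage is a pure predicate of (variant, context), so the final
candidate *set* is order-invariant; the per-stage survivor counts are
order-dependent and reported in the canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Mapping, Optional, Sequence

from . import consequence
from .model import (
    DELETION,
    HOM_REF,
    INSERTION,
    CallSet,
    GeneModel,
    Genome,
    GenomicInterval,
    VariantKey,
    VariantRecord,
)

STAGE_KINDS = frozenset(
    {
        "quality",
        "shared_affected",
        "known_subtraction",
        "chromosome",
        "interval",
        "exonic",
        "nonsynonymous",
        "ancestral_subtraction",
        "coding_region",
        "above_mean_quality",
    }
)


@dataclass(frozen=True)
class FilterStage:
    """One funnel stage: a named, parameterised pure predicate."""

    name: str
    kind: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in STAGE_KINDS:
            raise ValueError(f"unknown stage kind {self.kind!r}")

    @property
    def param_dict(self) -> dict[str, object]:
        return dict(self.params)


@dataclass
class FunnelContext:
    """Fixed context against which stage predicates are evaluated."""

    affected: Sequence[CallSet] = ()
    panels: Sequence[CallSet] = ()
    es_line: Optional[CallSet] = None
    genes: Sequence[GeneModel] = ()
    genome: Optional[Mapping[str, str]] = None
    #: mean call quality over the funnel's initial input set (indel branch)
    input_mean_quality: Optional[float] = None

    def records_for_key(self, key: VariantKey) -> list[VariantRecord]:
        return [cs.records[key] for cs in self.affected if key in cs]


@dataclass
class FunnelReport:
    """Machine twin of a printed filtering table: per-stage survivor counts,
    the final candidate set, and a per-variant audit trail naming the first
    failing stage (or "passed")."""

    stage_counts: list[tuple[str, int]]
    survivors: list[VariantRecord]
    audit: dict[VariantKey, str]
    extras: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stage_counts]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise AssertionError("funnel counts must be non-increasing")
        if counts and counts[-1] != len(self.survivors):
            raise AssertionError("final stage count does not match survivor set")


@dataclass
class FunnelConfig:
    mq_min: float = 45.0
    dp_min: int = 10
    chrom: str = "9"
    interval: Optional[GenomicInterval] = None


def make_standard_snv_stages(
    config: FunnelConfig,
    panels: Sequence[CallSet],
    es_line: Optional[CallSet],
) -> list[FilterStage]:
    """The eight canonical SNV stages, in printed-table order."""
    if config.interval is None:
        raise ValueError("funnel configuration requires a critical interval")
    if not panels:
        raise ValueError("known-variant subtraction requires >= 1 panel call set")
    if es_line is None:
        raise ValueError("ancestral subtraction requires the ES-line call set")
    return [
        FilterStage(
            "Mapping quality and read depth",
            "quality",
            (("mq_min", config.mq_min), ("dp_min", config.dp_min)),
        ),
        FilterStage("Present in both homozygotes", "shared_affected"),
        FilterStage("Not in known-variant panels", "known_subtraction"),
        FilterStage(f"On chromosome {config.chrom}", "chromosome", (("chrom", config.chrom),)),
        FilterStage(
            "Within mapped region", "interval", (("interval", config.interval),)
        ),
        FilterStage("Exonic", "exonic"),
        FilterStage("Nonsynonymous", "nonsynonymous"),
        FilterStage("Not present in ES cells", "ancestral_subtraction"),
    ]


def _annotation(variant: VariantRecord, context: FunnelContext) -> dict[str, str]:
    """Location/consequence annotations, computed on demand when absent."""
    if "location" not in variant.annotations:
        consequence.apply_annotations([variant], context.genes, context.genome)
    return variant.annotations


def _passes(stage: FilterStage, variant: VariantRecord, context: FunnelContext) -> bool:
    params = stage.param_dict
    kind = stage.kind
    key = variant.key
    if kind == "quality":
        records = context.records_for_key(key) or [variant]
        return all(
            r.mapping_quality >= params["mq_min"] and r.read_depth >= params["dp_min"]
            for r in records
        )
    if kind == "shared_affected":
        if not context.affected:
            raise ValueError("shared_affected stage requires affected call sets")
        return all(
            key in cs and cs.records[key].genotypes.get(cs.sample_id) != HOM_REF
            for cs in context.affected
        )
    if kind == "known_subtraction":
        return not any(key in panel for panel in context.panels)
    if kind == "chromosome":
        return variant.chrom == params["chrom"]
    if kind == "interval":
        interval: GenomicInterval = params["interval"]
        return interval.contains(variant.chrom, variant.pos)
    if kind == "exonic":
        return _annotation(variant, context).get("location") == consequence.EXONIC
    if kind == "nonsynonymous":
        ann = _annotation(variant, context)
        return ann.get("is_cds") == "1" and ann.get("synonymous") == "0"
    if kind == "ancestral_subtraction":
        if context.es_line is None:
            raise ValueError("ancestral_subtraction stage requires the ES-line call set")
        return key not in context.es_line
    if kind == "above_mean_quality":
        if context.input_mean_quality is None:
            raise ValueError("above_mean_quality stage requires input_mean_quality")
        return _call_quality(variant, context) > context.input_mean_quality
    if kind == "coding_region":
        return _annotation(variant, context).get("location") == consequence.EXONIC
    raise ValueError(f"unknown stage kind {kind!r}")


def _call_quality(variant: VariantRecord, context: FunnelContext) -> float:
    records = context.records_for_key(variant.key) or [variant]
    return fmean(r.call_quality for r in records)


def apply_stage(
    stage: FilterStage,
    variants: Sequence[VariantRecord],
    context: FunnelContext,
) -> list[VariantRecord]:
    """Apply one stage, returning survivors in input order."""
    return [v for v in variants if _passes(stage, v, context)]


def run_stages(
    stages: Sequence[FilterStage],
    variants: Sequence[VariantRecord],
    context: FunnelContext,
) -> FunnelReport:
    """Run an ordered stage list with full per-variant auditing."""
    audit: dict[VariantKey, str] = {}
    current = list(variants)
    stage_counts: list[tuple[str, int]] = [("Input", len(current))]
    for stage in stages:
        survivors = []
        for variant in current:
            if _passes(stage, variant, context):
                survivors.append(variant)
            else:
                audit[variant.key] = stage.name
        current = survivors
        stage_counts.append((stage.name, len(current)))
    for variant in current:
        audit[variant.key] = "passed"
    return FunnelReport(stage_counts=stage_counts, survivors=current, audit=audit)


def _merged_universe(affected: Sequence[CallSet]) -> list[VariantRecord]:
    """Union of affected call sets, one representative record per key."""
    merged: dict[VariantKey, VariantRecord] = {}
    for cs in affected:
        for record in cs:
            merged.setdefault(record.key, record)
    return sorted(merged.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


def run_snv_funnel(
    affected: Sequence[CallSet],
    panels: Sequence[CallSet],
    es_line: CallSet,
    interval: GenomicInterval,
    genes: Sequence[GeneModel] = (),
    genome: Optional[Mapping[str, str]] = None,
    config: Optional[FunnelConfig] = None,
) -> FunnelReport:
    """Run the eight-stage SNV funnel over the union of affected call sets."""
    if len(affected) < 2:
        raise ValueError("the SNV funnel requires both affected call sets")
    config = config or FunnelConfig(chrom=interval.chrom, interval=interval)
    if config.interval is None:
        config.interval = interval
    stages = make_standard_snv_stages(config, panels, es_line)
    context = FunnelContext(
        affected=affected, panels=panels, es_line=es_line, genes=genes, genome=genome
    )
    return run_stages(stages, _merged_universe(affected), context)


def indel_evidence(
    variants: Sequence[VariantRecord],
    es_line: Optional[CallSet] = None,
    genes: Sequence[GeneModel] = (),
    genome: Optional[Mapping[str, str]] = None,
) -> dict[str, object]:
    """Coding-region overlap and ES-line membership counts for indels.

    These are reported as evidence about surviving indels, not used as
    exclusion stages.  Location comes from existing annotations when present
    (printed records), otherwise from the gene models.
    """
    context = FunnelContext(es_line=es_line, genes=genes, genome=genome)
    coding = [
        v for v in variants
        if _annotation(v, context).get("location") == consequence.EXONIC
    ]
    in_es = [v for v in variants if es_line is not None and v.key in es_line]
    return {
        "coding_region_count": len(coding),
        "es_line_count": len(in_es),
        "coding_region_keys": [v.key for v in coding],
        "es_line_keys": [v.key for v in in_es],
    }


def run_indel_funnel(
    affected: Sequence[CallSet],
    interval: GenomicInterval,
    es_line: Optional[CallSet] = None,
    genes: Sequence[GeneModel] = (),
    genome: Optional[Mapping[str, str]] = None,
) -> FunnelReport:
    """Indel branch: above-mean quality, shared in both affected, interval.

    Coding-region overlap and ES-line membership of the survivors are added
    to ``report.extras`` as evidence annotations.
    """
    universe = [
        r for r in _merged_universe(affected)
        if r.variant_class in (DELETION, INSERTION)
    ]
    context = FunnelContext(
        affected=affected, es_line=es_line, genes=genes, genome=genome
    )
    if universe:
        context.input_mean_quality = fmean(
            _call_quality(v, context) for v in universe
        )
    stages = [
        FilterStage("Above mean call quality", "above_mean_quality"),
        FilterStage("Present in both homozygotes", "shared_affected"),
        FilterStage("Within mapped region", "interval", (("interval", interval),)),
    ]
    report = run_stages(stages, universe, context)
    report.extras.update(
        indel_evidence(report.survivors, es_line=es_line, genes=genes, genome=genome)
    )
    return report
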