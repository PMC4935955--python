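"""Shared domain types for the forward-genetics screen pipeline.

Coordinate convention throughout the package: 1-based, closed intervals on
both ends, matching the ``chrom:pos`` style of genetics papers and the GFF3
standard.  Conversions (e.g. to BED's 0-based half-open) happen only at
format boundaries.

Alleles are always stored on the forward (reference) strand.  Gene-oriented
alleles — the representation in which a reverse-strand G>C "appears as"
C>G — are computed on demand by the consequence annotator, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

# ---------------------------------------------------------------------------
# Sentinels and controlled vocabularies
# ---------------------------------------------------------------------------

#: Censoring sentinel for an animal with no auditory brainstem response at the
#: maximum stimulus level (95 dB SPL).  Using +inf makes "threshold >= cutoff"
#: behave correctly for affected-calling while remaining easy to exclude from
#: numeric summaries.
NO_RESPONSE: float = math.inf

#: Upper end of the free-field stimulus range (dB SPL, presented in 5 dB steps).
STIMULUS_CEILING_DB: float = 95.0

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPE_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

SNV = "SNV"
DELETION = "deletion"
INSERTION = "insertion"

ROLE_AFFECTED = "affected"
ROLE_ES_LINE = "es_line"
ROLE_STRAIN_PANEL = "strain_panel"
ROLE_KNOWN_DB = "known_db"
ROLES = frozenset({ROLE_AFFECTED, ROLE_ES_LINE, ROLE_STRAIN_PANEL, ROLE_KNOWN_DB})

GT_WT = "+/+"
GT_HET = "+/stdf"
GT_HOM = "stdf/stdf"
GT_UNKNOWN = "unknown"
STDF_GENOTYPES = (GT_WT, GT_HET, GT_HOM, GT_UNKNOWN)

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file does not conform to the expected (minimal) dialect."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference genome base."""


# ---------------------------------------------------------------------------
# Genomic primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, closed interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse a ``chrom:start-end`` region string (1-based, closed)."""
        try:
            chrom, rest = text.split(":", 1)
            start_s, end_s = rest.replace(",", "").split("-", 1)
            return cls(chrom, int(start_s), int(end_s))
        except (ValueError, AttributeError) as exc:
            raise FormatError(f"cannot parse region {text!r}") from exc


VariantKey = tuple[str, int, str, str]


def variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return SNV
    if len(ref) > len(alt):
        return DELETION
    if len(ref) < len(alt):
        return INSERTION
    raise ValueError(f"unsupported allele pair {ref!r}>{alt!r} (MNV)")


@dataclass
class VariantRecord:
    """One called sequence variant (forward-strand alleles, 1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mapping_quality: float = 60.0
    read_depth: int = 0
    call_quality: float = 0.0
    genotypes: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"allele {allele!r} not a non-empty A/C/G/T string")
        if self.read_depth < 0:
            raise ValueError("read depth must be >= 0")
        for sample, gt in self.genotypes.items():
            if gt not in GENOTYPE_CODES:
                raise ValueError(f"unknown genotype code {gt!r} for sample {sample}")
        variant_class(self.ref, self.alt)  # validates the allele pair

    @property
    def variant_class(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CallSet:
    """A sample's (or panel's) variant calls, keyed by (chrom, pos, ref, alt)."""

    sample_id: str
    role: str
    records: dict[VariantKey, VariantRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown call-set role {self.role!r}")

    def add(self, record: VariantRecord) -> None:
        if record.key in self.records:
            raise ValueError(f"duplicate variant key {record.key}")
        if self.role == ROLE_AFFECTED and self.sample_id not in record.genotypes:
            raise ValueError(
                f"affected call set {self.sample_id}: record {record.key} "
                "lacks a genotype entry for the sample"
            )
        self.records[record.key] = record

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records.values())


# ---------------------------------------------------------------------------
# Gene models and genomes
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Strand-aware transcript model holding ordered CDS intervals.

    ``cds_intervals`` are in ascending genomic order regardless of strand;
    transcript (5'→3') order for reverse-strand genes is the reverse of this
    list.  ``first_frame`` is the phase of the transcript's first CDS base
    (0 for complete models).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    cds_intervals: list[GenomicInterval]
    first_frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id} has no CDS intervals")
        ivals = sorted(self.cds_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivals, ivals[1:]):
            if a.end >= b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivals

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.cds_intervals[0].start, self.cds_intervals[-1].end
        )

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals)

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in gene (reading) orientation."""
        seq = "".join(
            genome[self.chrom][iv.start - 1 : iv.end] for iv in self.cds_intervals
        )
        return reverse_complement(seq) if self.strand == "-" else seq

    def contains_cds(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.cds_intervals)


Genome = dict[str, str]


def validate_genome(genome: Mapping[str, str], genes: Iterable[GeneModel] = ()) -> None:
    for name, seq in genome.items():
        if not set(seq) <= _DNA_N:
            raise ValueError(f"chromosome {name}: alphabet outside A/C/G/T/N")
    for gene in genes:
        if gene.chrom not in genome:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        if gene.span.end > len(genome[gene.chrom]):
            raise ValueError(
                f"gene {gene.gene_id} extends past the end of {gene.chrom}"
            )


# ---------------------------------------------------------------------------
# Backcross panel and phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chrom: str
    pos: int


@dataclass
class MarkerGenotypeTable:
    """Backcross genotype matrix: animals x markers, calls in {M, H, missing}.

    ``M`` = homozygous for the mutant strain, ``H`` = heterozygous (one
    mapping-strain allele); ``None`` = missing call.
    """

    markers: list[Marker]
    animals: list[str]
    calls: dict[tuple[str, str], Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        marker_ids = {m.marker_id for m in self.markers}
        if len(marker_ids) != len(self.markers):
            raise ValueError("duplicate marker ids")
        if len(set(self.animals)) != len(self.animals):
            raise ValueError("duplicate animal ids")
        for (animal, marker_id), call in self.calls.items():
            if marker_id not in marker_ids:
                raise ValueError(f"call for unknown marker {marker_id}")
            if animal not in set(self.animals):
                raise ValueError(f"call for unknown animal {animal}")
            if call not in {"M", "H", None}:
                raise ValueError(
                    f"unknown genotype code {call!r} at ({animal}, {marker_id})"
                )

    def column(self, marker_id: str) -> list[Optional[str]]:
        """Calls for one marker, in ``animals`` order (None = missing)."""
        return [self.calls.get((animal, marker_id)) for animal in self.animals]

    def set_call(self, animal: str, marker_id: str, call: Optional[str]) -> None:
        self.calls[(animal, marker_id)] = call


@dataclass
class PhenotypeRecord:
    """One animal's hearing phenotype at one age.

    Thresholds are dB SPL within the stimulus range [0, 95] or the
    NO_RESPONSE sentinel; ``ep_mv`` is the endocochlear potential in mV.
    """

    animal_id: str
    age_weeks: float
    click_threshold: Optional[float] = None
    tone_thresholds: dict[float, float] = field(default_factory=dict)
    ep_mv: Optional[float] = None
    stdf_genotype: str = GT_UNKNOWN
    extra_genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stdf_genotype not in STDF_GENOTYPES:
            raise ValueError(f"unknown stdf genotype {self.stdf_genotype!r}")
        for value in [self.click_threshold, *self.tone_thresholds.values()]:
            if value is None or value == NO_RESPONSE:
                continue
            if not 0.0 <= value <= STIMULUS_CEILING_DB:
                raise ValueError(
                    f"threshold {value} outside stimulus range "
                    f"[0, {STIMULUS_CEILING_DB}] dB SPL"
                )
        if self.ep_mv is not None and not math.isfinite(self.ep_mv):
            raise ValueError("EP must be finite when present")
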