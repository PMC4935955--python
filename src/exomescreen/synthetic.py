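"""Synthetic forward-genetics screen generator.

Everything downstream of raw sequencing is emulated here so the whole
inference chain is testable offline:

* a [(mut x mapping-strain)F1 x mut] backcross genotyped at a marker grid,
  with gametes drawn under the Haldane model (crossover count Poisson with
  mean equal to the map length in Morgans, no interference) and a fully
  penetrant recessive phenotype read off the causal-locus genotype;
* a toy diploid-free genome with multi-exon genes on both strands, including
  a reverse-strand "causal" gene engineered so that the planted causal SNV is
  a forward-strand G>C that reads C>G in gene orientation and converts an
  ACA (Thr) codon to AGA (Arg) — the classic strand trap;
* exome-like call sets for two affected animals, an ancestral ES-cell line,
  a wildtype-strain panel and a known-variant (dbSNP-like) panel, with the
  planted causal variant plus six classes of decoy, each constructed to fail
  exactly one funnel stage;
* colony phenotypes (click/tone ABR thresholds, endocochlear potential) whose
  group means and SDs are the printed values of the source colony where
  available.  Click thresholds are censored at the 95 dB SPL stimulus
  ceiling: draws above it become NO_RESPONSE.

All generators are byte-deterministic given the seed.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import consequence
from .model import (
    GT_HET,
    GT_HOM,
    GT_WT,
    HET,
    HOM_ALT,
    NO_RESPONSE,
    ROLE_AFFECTED,
    ROLE_ES_LINE,
    ROLE_KNOWN_DB,
    ROLE_STRAIN_PANEL,
    STIMULUS_CEILING_DB,
    CallSet,
    GeneModel,
    Genome,
    GenomicInterval,
    Marker,
    MarkerGenotypeTable,
    PhenotypeRecord,
    VariantRecord,
    reverse_complement,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
_TONE_FREQS_KHZ = (6.0, 12.0, 18.0, 24.0, 30.0)
_TONE_OFFSETS_DB = (0.0, -5.0, 0.0, 5.0, 10.0)


# ---------------------------------------------------------------------------
# Phenotype parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPheno:
    """Generating distribution for one (genotype group, age) cell."""

    click_mean: float
    click_sd: float
    ep_mean: float
    ep_sd: float
    p_no_response: float = 0.0

    def __post_init__(self) -> None:
        if self.click_sd < 0 or self.ep_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.p_no_response <= 1.0:
            raise ValueError("p_no_response must be in [0, 1]")


@dataclass(frozen=True)
class PhenoParams:
    """Per (group, age_weeks) generating parameters.

    EP means/SDs at 2, 4 and 8 weeks are the printed colony values
    (controls 100.0+-11.8, 125.5+-6.5, 120.5+-9.8 mV; mutants 98.0+-12.5,
    47.9+-22.2, 53.7+-17.9 mV).  Click-threshold parameters are a package
    choice (no group means were printed): controls stay ~30 dB SPL at all
    ages; mutants are control-like at 2 weeks, widely variable at 4 weeks and
    severe with a NO_RESPONSE probability from 8 weeks.
    """

    groups: tuple[tuple[tuple[str, float], GroupPheno], ...] = (
        (("control", 2.0), GroupPheno(30.0, 8.0, 100.0, 11.8)),
        (("control", 4.0), GroupPheno(30.0, 8.0, 125.5, 6.5)),
        (("control", 8.0), GroupPheno(30.0, 8.0, 120.5, 9.8)),
        (("control", 14.0), GroupPheno(30.0, 8.0, 120.5, 9.8)),
        (("mutant", 2.0), GroupPheno(32.0, 8.0, 98.0, 12.5)),
        (("mutant", 4.0), GroupPheno(70.0, 15.0, 47.9, 22.2)),
        (("mutant", 8.0), GroupPheno(90.0, 6.0, 53.7, 17.9, p_no_response=0.35)),
        (("mutant", 14.0), GroupPheno(93.0, 4.0, 53.7, 17.9, p_no_response=0.6)),
    )

    def group(self, group: str, age_weeks: float) -> GroupPheno:
        for (g, a), params in self.groups:
            if g == group and a == age_weeks:
                return params
        raise KeyError(f"no phenotype parameters for group {group!r} at {age_weeks} weeks")


# ---------------------------------------------------------------------------
# Screen configuration
# ---------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """The stated world of the synthetic screen.

    Defaults: 161 backcross offspring (79+82 in the source screen), mouse-like
    0.5 cM/Mb, a 25 Mbp causal chromosome "9" with the causal locus at 12 Mbp,
    markers every 2.5 cM, and decoy counts sized for desk-scale funnels.
    """

    seed: int = 0
    n_offspring: int = 161
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"9": 25_000_000, "2": 15_000_000}
    )
    marker_spacing_cM: float = 2.5
    cM_per_Mb: float = 0.5
    causal_locus: tuple[str, int] = ("9", 12_000_000)
    marker_positions: Optional[dict[str, list[int]]] = None
    missing_call_rate: float = 0.01
    phenotype_age_weeks: float = 8.0
    affected_ids: tuple[str, str] = ("SD1", "SD2")
    # decoy class counts: background splits over private / outside-interval /
    # synonymous / low-quality classes
    n_background_snvs: int = 32
    n_strain_snvs: int = 24
    n_es_snvs: int = 6
    n_indels: int = 8
    # quality-score distributions (passing calls)
    mq_mean: float = 57.0
    mq_sd: float = 3.0
    dp_mean: float = 130.0
    phenotype_params: PhenoParams = field(default_factory=PhenoParams)

    def __post_init__(self) -> None:
        for name in ("n_offspring", "n_background_snvs", "n_strain_snvs",
                     "n_es_snvs", "n_indels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        chrom, pos = self.causal_locus
        if chrom not in self.chrom_lengths or not 1 <= pos <= self.chrom_lengths[chrom]:
            raise ValueError("causal locus outside the declared chromosomes")

    def bp_per_cM(self) -> float:
        return 1e6 / self.cM_per_Mb

    def markers_for(self, chrom: str) -> list[int]:
        if self.marker_positions is not None:
            return list(self.marker_positions.get(chrom, []))
        spacing_bp = int(round(self.marker_spacing_cM * self.bp_per_cM()))
        length = self.chrom_lengths[chrom]
        return list(range(spacing_bp, length + 1, spacing_bp))


# ---------------------------------------------------------------------------
# Backcross simulation (Haldane model)
# ---------------------------------------------------------------------------


def _gamete_allele_lookup(
    rng: np.random.Generator, length_bp: int, morgans: float
) -> tuple[int, list[float]]:
    """One F1 gamete: (starting parental strand, sorted crossover positions)."""
    n_xo = rng.poisson(morgans)
    crossovers = sorted(rng.uniform(0.0, length_bp, size=n_xo).tolist())
    start = int(rng.integers(2))
    return start, crossovers


def _allele_at(start: int, crossovers: list[float], pos: int) -> int:
    """0 = mutant-strain allele, 1 = mapping-strain allele (arbitrary but fixed
    per gamete via ``start``)."""
    return (start + bisect_right(crossovers, pos)) % 2


def simulate_backcross(
    config: ScreenConfig,
) -> tuple[MarkerGenotypeTable, list[PhenotypeRecord]]:
    """Simulate the backcross panel: marker genotypes plus ABR phenotypes.

    Each offspring receives one F1 gamete per chromosome under the Haldane
    model combined with a mutant-strain gamete, so genotypes are M (gamete
    carried the mutant-strain allele) or H.  Affection is fully penetrant:
    affected iff homozygous mutant at the causal locus.  Phenotypes are drawn
    from the colony distributions at ``phenotype_age_weeks``.
    """
    rng = np.random.default_rng([config.seed, 1])
    causal_chrom, causal_pos = config.causal_locus
    markers: list[Marker] = []
    for chrom in sorted(config.chrom_lengths, key=lambda c: (len(c), c)):
        for i, pos in enumerate(config.markers_for(chrom), start=1):
            markers.append(Marker(f"D{chrom}S{i}", chrom, pos))
    if not markers:
        raise ValueError("marker map is empty")
    if not any(m.chrom == causal_chrom for m in markers):
        raise ValueError("marker map does not cover the causal chromosome")

    animals = [f"BC{i:04d}" for i in range(1, config.n_offspring + 1)]
    table = MarkerGenotypeTable(markers=markers, animals=animals, calls={})
    phenotypes: list[PhenotypeRecord] = []
    morgans = {
        chrom: length / config.bp_per_cM() / 100.0
        for chrom, length in config.chrom_lengths.items()
    }
    for animal in animals:
        gametes = {
            chrom: _gamete_allele_lookup(rng, config.chrom_lengths[chrom], morgans[chrom])
            for chrom in config.chrom_lengths
        }
        for marker in markers:
            start, xo = gametes[marker.chrom]
            call = "M" if _allele_at(start, xo, marker.pos) == 0 else "H"
            if config.missing_call_rate and rng.random() < config.missing_call_rate:
                table.set_call(animal, marker.marker_id, None)
            else:
                table.set_call(animal, marker.marker_id, call)
        start, xo = gametes[causal_chrom]
        affected = _allele_at(start, xo, causal_pos) == 0
        genotype = GT_HOM if affected else GT_HET
        phenotypes.append(
            _draw_phenotype(
                rng,
                animal_id=animal,
                age_weeks=config.phenotype_age_weeks,
                stdf_genotype=genotype,
                params=config.phenotype_params,
            )
        )
    return table, phenotypes


# ---------------------------------------------------------------------------
# Toy genomes and gene models
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(lut[rng.integers(0, 4, size=n, dtype=np.uint8)].tobytes())


def _random_coding(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = ["ATG"]
    codons += [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    ]
    codons.append(("TAA", "TAG", "TGA")[int(rng.integers(3))])
    return codons


def _split_exons(rng: np.random.Generator, total: int, n_exons: int) -> list[int]:
    """Split ``total`` coding bases into n_exons chunks, each >= 9 bp."""
    if n_exons == 1:
        return [total]
    cuts = sorted(rng.choice(range(9, total - 8), size=n_exons - 1, replace=False).tolist())
    sizes = []
    prev = 0
    for cut in cuts + [total]:
        sizes.append(cut - prev)
        prev = cut
    if min(sizes) < 9:  # resample degenerate splits
        return _split_exons(rng, total, n_exons)
    return sizes


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    gene_name: str,
    chrom: str,
    start: int,
    strand: str,
    transcript: list[str],
    n_exons: int = 2,
    intron_len: int = 200,
) -> tuple[GeneModel, list[tuple[GenomicInterval, str]]]:
    """Lay a transcript down on the genome as n_exons CDS pieces.

    Returns the model plus (interval, genomic-strand sequence) paste
    instructions; the ascending genomic concatenation of the pieces equals
    the transcript for + genes and its reverse complement for - genes.
    """
    coding = "".join(transcript)
    genomic_cds = coding if strand == "+" else reverse_complement(coding)
    sizes = _split_exons(rng, len(coding), n_exons)
    intervals: list[GenomicInterval] = []
    pastes: list[tuple[GenomicInterval, str]] = []
    cursor = start
    offset = 0
    for size in sizes:
        iv = GenomicInterval(chrom, cursor, cursor + size - 1)
        intervals.append(iv)
        pastes.append((iv, genomic_cds[offset : offset + size]))
        offset += size
        cursor += size + intron_len
    model = GeneModel(
        gene_id=gene_id, gene_name=gene_name, chrom=chrom,
        strand=strand, cds_intervals=intervals,
    )
    return model, pastes


# geometry of the engineered reverse-strand causal gene
_CAUSAL_N_CODONS = 100
_CAUSAL_E1 = 150
_CAUSAL_E2 = 150
_CAUSAL_INTRON = 200
_CAUSAL_CODON_INDEX = 60  # Thr codon rewritten to ACA, mutated to AGA
_CAUSAL_CDS_POS = 3 * (_CAUSAL_CODON_INDEX - 1) + 2  # middle of the codon


def _build_causal_gene(
    rng: np.random.Generator, chrom: str, causal_pos: int
) -> tuple[GeneModel, list[tuple[GenomicInterval, str]]]:
    """Two-exon reverse-strand gene in which ``causal_pos`` is the middle base
    of an ACA (Thr) codon — so the planted forward-strand G>C reads C>G in
    gene orientation and produces Thr -> Arg."""
    codons = _random_coding(rng, _CAUSAL_N_CODONS)
    codons[_CAUSAL_CODON_INDEX - 1] = "ACA"
    transcript = "".join(codons)
    # reverse strand, causal position inside the genomically-left exon:
    #   cds_pos = e2 + (exon1.end - pos + 1)  ==  _CAUSAL_CDS_POS
    exon1_end = causal_pos + _CAUSAL_CDS_POS - _CAUSAL_E2 - 1
    start = exon1_end - _CAUSAL_E1 + 1
    if start < 1:
        raise ValueError("causal locus too close to the chromosome start")
    iv1 = GenomicInterval(chrom, start, exon1_end)
    b_start = exon1_end + 1 + _CAUSAL_INTRON
    iv2 = GenomicInterval(chrom, b_start, b_start + _CAUSAL_E2 - 1)
    genomic_cds = reverse_complement(transcript)
    pastes = [(iv1, genomic_cds[: _CAUSAL_E1]), (iv2, genomic_cds[_CAUSAL_E1:])]
    model = GeneModel(
        gene_id=f"g{chrom}.causal", gene_name=f"toy{chrom}gC",
        chrom=chrom, strand="-", cds_intervals=[iv1, iv2],
    )
    return model, pastes


def make_toy_genome(
    seed: int,
    chrom_lengths: Optional[dict[str, int]] = None,
    gene_positions: Optional[dict[str, list[int]]] = None,
    causal_locus: Optional[tuple[str, int]] = None,
) -> tuple[Genome, list[GeneModel]]:
    """Deterministic toy genome: >= 2 chromosomes, multi-exon genes on both
    strands, all CDS lengths divisible by 3, every start codon ATG.

    When ``causal_locus`` is given, a reverse-strand gene is engineered around
    it (see :func:`_build_causal_gene`).
    """
    rng = np.random.default_rng([seed, 7])
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 9_000, "chr2": 7_000}
    if gene_positions is None:
        gene_positions = {
            chrom: [length // 4, length // 2]
            for chrom, length in chrom_lengths.items()
        }
    sequences: dict[str, bytearray] = {
        chrom: _random_bases(rng, length) for chrom, length in chrom_lengths.items()
    }
    genes: list[GeneModel] = []
    occupied: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_lengths}

    def paste(model: GeneModel, pastes) -> None:
        for iv, chunk in pastes:
            if iv.end > chrom_lengths[model.chrom]:
                raise ValueError(f"gene {model.gene_id} exceeds chromosome length")
            if any(iv.overlaps(o) for o in occupied[model.chrom]):
                raise ValueError(f"gene {model.gene_id} overlaps another gene")
            sequences[model.chrom][iv.start - 1 : iv.end] = chunk.encode()
        occupied[model.chrom].append(model.span)
        genes.append(model)

    if causal_locus is not None:
        paste(*_build_causal_gene(rng, causal_locus[0], causal_locus[1]))

    strand_cycle = ["+", "-"]
    counter = 0
    for chrom in sorted(chrom_lengths, key=lambda c: (len(c), c)):
        for i, start in enumerate(gene_positions.get(chrom, []), start=1):
            strand = strand_cycle[counter % 2]
            counter += 1
            n_codons = int(rng.integers(60, 160))
            model, pastes = _build_gene(
                rng,
                gene_id=f"g{chrom}.{i}",
                gene_name=f"toy{chrom}g{i}",
                chrom=chrom,
                start=start,
                strand=strand,
                transcript=_random_coding(rng, n_codons),
                n_exons=int(rng.integers(2, 4)),
            )
            if any(model.span.overlaps(o) for o in occupied[chrom]):
                continue  # slot collides with the engineered causal gene
            paste(model, pastes)
    genome: Genome = {c: bytes(b).decode("ascii") for c, b in sequences.items()}
    return genome, genes


def make_screen_world(
    config: ScreenConfig, genome_seed: int = 0
) -> tuple[Genome, list[GeneModel]]:
    """Genome + gene models sized for the default screen configuration.

    Gene slots cluster around the causal locus (so synonymous and ES-decoy
    plants fall inside the mapped interval) with further genes elsewhere on
    the causal chromosome and on the second chromosome.
    """
    chrom, pos = config.causal_locus
    other = [c for c in config.chrom_lengths if c != chrom]
    cluster = [pos - 1_500_000, pos - 800_000, pos + 700_000, pos + 1_400_000,
               pos + 1_900_000]
    distant = [3_000_000, 6_000_000, 18_000_000, 22_000_000]
    gene_positions = {chrom: cluster + [p for p in distant
                                        if p <= config.chrom_lengths[chrom] - 5000]}
    for c in other:
        gene_positions[c] = [
            p for p in (3_000_000, 6_000_000, 9_000_000, 12_000_000)
            if p <= config.chrom_lengths[c] - 5000
        ]
    return make_toy_genome(
        genome_seed,
        chrom_lengths=dict(config.chrom_lengths),
        gene_positions=gene_positions,
        causal_locus=config.causal_locus,
    )


# ---------------------------------------------------------------------------
# Exome-like call sets with planted causal variant and decoys
# ---------------------------------------------------------------------------


@dataclass
class ScreenCallsets:
    """The five call sets of a screen (role -> call set view via as_dict)."""

    affected: tuple[CallSet, CallSet]
    es_line: CallSet
    strain_panel: CallSet
    known_db: CallSet
    causal_key: tuple = ()

    def as_dict(self) -> dict[str, object]:
        return {
            ROLE_AFFECTED: list(self.affected),
            ROLE_ES_LINE: self.es_line,
            ROLE_STRAIN_PANEL: self.strain_panel,
            ROLE_KNOWN_DB: self.known_db,
        }


def _passing_quality(rng: np.random.Generator, config: ScreenConfig) -> tuple[float, int]:
    mq = max(46.0, round(float(rng.normal(config.mq_mean, config.mq_sd)), 2))
    dp = max(12, int(rng.poisson(config.dp_mean)))
    return mq, dp


def _failing_quality(rng: np.random.Generator) -> tuple[float, int]:
    # below both thresholds by >= 5 units, avoiding boundary flakiness
    return round(float(rng.uniform(20.0, 40.0)), 2), int(rng.integers(1, 6))


def _cds_genomic_position(gene: GeneModel, cds_pos: int) -> int:
    """Genomic coordinate of a 1-based position in the spliced CDS."""
    remaining = cds_pos
    intervals = (
        list(reversed(gene.cds_intervals)) if gene.strand == "-" else gene.cds_intervals
    )
    for iv in intervals:
        if remaining <= len(iv):
            return iv.end - remaining + 1 if gene.strand == "-" else iv.start + remaining - 1
        remaining -= len(iv)
    raise ValueError(f"CDS position {cds_pos} beyond gene {gene.gene_id}")


def _to_forward(base: str, strand: str) -> str:
    """Map a gene-oriented base to the forward strand."""
    return base if strand == "+" else reverse_complement(base)


def _pick_cds_snv(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    genome: Genome,
    want_synonymous: bool,
    used: set,
) -> tuple[str, int, str, str]:
    """Random CDS SNV (forward-strand chrom/pos/ref/alt) with the requested
    synonymy, drawn from internal codons of the supplied genes."""
    for _ in range(500):
        gene = genes[int(rng.integers(len(genes)))]
        cds = gene.coding_sequence(genome)
        n_codons = len(cds) // 3
        codon_index = int(rng.integers(2, n_codons))  # skip start and stop codons
        offset = int(rng.integers(3))
        codon = cds[(codon_index - 1) * 3 : codon_index * 3]
        ref_aa = consequence.translate_codon(codon)
        alts = []
        for base in _BASES:
            if base == codon[offset]:
                continue
            alt_codon = codon[:offset] + base + codon[offset + 1 :]
            alt_aa = consequence.translate_codon(alt_codon)
            if (alt_aa == ref_aa) == want_synonymous and alt_aa != "*":
                alts.append(base)
        if not alts:
            continue
        cds_pos = (codon_index - 1) * 3 + offset + 1
        pos = _cds_genomic_position(gene, cds_pos)
        ref = genome[gene.chrom][pos - 1]
        alt = _to_forward(alts[int(rng.integers(len(alts)))], gene.strand)
        key = (gene.chrom, pos, ref, alt)
        if key in used or ref == alt:
            continue
        return gene.chrom, pos, ref, alt
    raise RuntimeError("could not place a CDS decoy SNV")


def _random_snv(
    rng: np.random.Generator,
    genome: Genome,
    chrom: str,
    lo: int,
    hi: int,
    used: set,
) -> tuple[str, int, str, str]:
    for _ in range(500):
        pos = int(rng.integers(lo, hi + 1))
        ref = genome[chrom][pos - 1]
        if ref == "N":
            continue
        alt = _BASES[int(rng.integers(4))]
        if alt == ref:
            continue
        key = (chrom, pos, ref, alt)
        if key in used:
            continue
        return chrom, pos, ref, alt
    raise RuntimeError("could not place a decoy SNV")


def simulate_exome_callsets(
    config: ScreenConfig, genome: Genome, genes: Sequence[GeneModel]
) -> ScreenCallsets:
    """Exome-like call sets with one planted causal nonsynonymous SNV.

    Both affected call sets share the causal variant (homozygous, passing
    quality) inside the causal interval.  Decoy classes, each failing exactly
    one funnel stage: (a) private to one affected animal, (b) shared but
    present in the strain/known panels, (c) outside the linked region,
    (d) exonic synonymous near the causal locus, (e) nonsynonymous but
    carried by the ancestral ES line, (f) low-quality (below both thresholds
    by >= 5 units).  Indels emulate the structural-variant branch: shared
    high-quality in-interval deletions (some ES-line), plus off-interval and
    low-quality deletions.
    """
    rng = np.random.default_rng([config.seed, 2])
    causal_chrom, causal_pos = config.causal_locus
    causal_gene = next(
        (g for g in genes if g.contains_cds(causal_chrom, causal_pos)), None
    )
    if causal_gene is None:
        raise ValueError(
            f"causal locus {causal_chrom}:{causal_pos} is not inside any CDS; "
            "cannot plant a nonsynonymous causal variant"
        )

    id1, id2 = config.affected_ids
    aff1 = CallSet(sample_id=id1, role=ROLE_AFFECTED)
    aff2 = CallSet(sample_id=id2, role=ROLE_AFFECTED)
    es = CallSet(sample_id="ES_line", role=ROLE_ES_LINE)
    strains = CallSet(sample_id="wildtype_strains", role=ROLE_STRAIN_PANEL)
    known = CallSet(sample_id="known_db", role=ROLE_KNOWN_DB)
    used: set = set()

    def add_affected(chrom, pos, ref, alt, *, samples=(1, 1), passing=True,
                     genotype=HOM_ALT, qual=None):
        used.add((chrom, pos, ref, alt))
        for flag, cs in zip(samples, (aff1, aff2)):
            if not flag:
                continue
            mq, dp = _passing_quality(rng, config) if passing else _failing_quality(rng)
            cs.add(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    mapping_quality=mq, read_depth=dp,
                    call_quality=round(float(rng.uniform(400, 999)), 1) if qual is None else qual,
                    genotypes={cs.sample_id: genotype},
                )
            )

    def add_panel(cs: CallSet, chrom, pos, ref, alt) -> None:
        used.add((chrom, pos, ref, alt))
        if (chrom, pos, ref, alt) not in cs:
            cs.add(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    mapping_quality=60.0, read_depth=100,
                    call_quality=500.0, genotypes={},
                )
            )

    # --- the planted causal variant -------------------------------------
    ref = genome[causal_chrom][causal_pos - 1]
    causal_alt = None
    for base in "CGAT":
        if base == ref:
            continue
        probe = VariantRecord(chrom=causal_chrom, pos=causal_pos, ref=ref, alt=base)
        call = consequence.annotate_cds_consequence(probe, causal_gene, genome)
        if not call.synonymous:
            causal_alt = base
            break
    if causal_alt is None:
        raise ValueError("no nonsynonymous alternate allele exists at the causal locus")
    add_affected(causal_chrom, causal_pos, ref, causal_alt)
    causal_key = (causal_chrom, causal_pos, ref, causal_alt)

    cluster_genes = [
        g for g in genes
        if g.chrom == causal_chrom and abs(g.span.start - causal_pos) < 2_500_000
    ] or [causal_gene]

    # --- decoy SNVs ------------------------------------------------------
    n_bg = config.n_background_snvs
    quarters = [n_bg // 4 + (1 if i < n_bg % 4 else 0) for i in range(4)]
    n_private, n_outside, n_syn, n_lowq = quarters
    length9 = config.chrom_lengths[causal_chrom]
    other_chroms = [c for c in config.chrom_lengths if c != causal_chrom]

    for i in range(n_private):  # (a) present in only one affected animal
        chrom, pos, r, a = _random_snv(rng, genome, causal_chrom, 1, length9, used)
        add_affected(chrom, pos, r, a, samples=(1, 0) if i % 2 == 0 else (0, 1),
                     genotype=HET if i % 3 == 0 else HOM_ALT)

    for i in range(n_outside):  # (c) outside the linked region
        if other_chroms and i % 2 == 0:
            chrom = other_chroms[i // 2 % len(other_chroms)]
            hi = config.chrom_lengths[chrom]
            chrom, pos, r, a = _random_snv(rng, genome, chrom, 1, hi, used)
        else:
            chrom, pos, r, a = _random_snv(
                rng, genome, causal_chrom, 1, min(2_000_000, length9), used
            )
        add_affected(chrom, pos, r, a)

    for _ in range(n_syn):  # (d) exonic synonymous near the causal locus
        chrom, pos, r, a = _pick_cds_snv(rng, cluster_genes, genome, True, used)
        add_affected(chrom, pos, r, a, genotype=HOM_ALT)

    for i in range(n_lowq):  # (f) below quality thresholds
        chrom, pos, r, a = _random_snv(rng, genome, causal_chrom, 1, length9, used)
        add_affected(chrom, pos, r, a, passing=False)

    for i in range(config.n_strain_snvs):  # (b) shared with the panels
        chrom = causal_chrom if i % 2 == 0 else (other_chroms + [causal_chrom])[0]
        hi = config.chrom_lengths[chrom]
        chrom, pos, r, a = _random_snv(rng, genome, chrom, 1, hi, used)
        add_affected(chrom, pos, r, a, genotype=HET if i % 4 == 0 else HOM_ALT)
        add_panel(strains if i % 2 == 0 else known, chrom, pos, r, a)

    for _ in range(config.n_es_snvs):  # (e) nonsynonymous but ancestral
        chrom, pos, r, a = _pick_cds_snv(rng, cluster_genes, genome, False, used)
        add_affected(chrom, pos, r, a)
        add_panel(es, chrom, pos, r, a)

    # --- indels (structural-variant branch) ------------------------------
    n_in = max(0, config.n_indels - config.n_indels // 4 - config.n_indels // 4)
    n_out = config.n_indels // 4
    n_low = config.n_indels - n_in - n_out

    def add_indel(chrom, lo, hi, *, qual, in_es=False):
        for _ in range(500):
            pos = int(rng.integers(lo, hi))
            ref2 = genome[chrom][pos - 1 : pos + 1]
            if "N" in ref2 or (chrom, pos, ref2, ref2[0]) in used:
                continue
            if any(g.contains_cds(chrom, pos) or g.contains_cds(chrom, pos + 1)
                   for g in genes):
                continue  # the emulated branch has non-coding survivors only
            add_affected(chrom, pos, ref2, ref2[0], qual=qual)
            if in_es:
                add_panel(es, chrom, pos, ref2, ref2[0])
            return
        raise RuntimeError("could not place an indel")

    window = (max(1, causal_pos - 2_000_000), min(length9, causal_pos + 2_000_000))
    for i in range(n_in):
        add_indel(causal_chrom, *window, qual=round(float(rng.uniform(700, 950)), 1),
                  in_es=(i < min(2, n_in)))
    for i in range(n_out):
        chrom = other_chroms[0] if other_chroms else causal_chrom
        add_indel(chrom, 1, config.chrom_lengths[chrom] - 1,
                  qual=round(float(rng.uniform(700, 950)), 1))
    for _ in range(n_low):
        add_indel(causal_chrom, *window, qual=round(float(rng.uniform(30, 120)), 1))

    # a few panel-only records for realism
    for cs in (es, strains, known):
        for _ in range(5):
            chrom, pos, r, a = _random_snv(rng, genome, causal_chrom, 1, length9, used)
            add_panel(cs, chrom, pos, r, a)

    return ScreenCallsets(
        affected=(aff1, aff2), es_line=es, strain_panel=strains,
        known_db=known, causal_key=causal_key,
    )


# ---------------------------------------------------------------------------
# Colony phenotypes
# ---------------------------------------------------------------------------


def _draw_phenotype(
    rng: np.random.Generator,
    animal_id: str,
    age_weeks: float,
    stdf_genotype: str,
    params: PhenoParams,
    second_locus: Optional[str] = None,
) -> PhenotypeRecord:
    group = "mutant" if stdf_genotype == GT_HOM else "control"
    gp = params.group(group, age_weeks)

    def censor(value: float) -> float:
        if value > STIMULUS_CEILING_DB:
            return NO_RESPONSE
        return max(0.0, value)

    if gp.p_no_response and rng.random() < gp.p_no_response:
        click: float = NO_RESPONSE
    else:
        click = censor(float(rng.normal(gp.click_mean, gp.click_sd)))
    tones = {}
    for freq, offset in zip(_TONE_FREQS_KHZ, _TONE_OFFSETS_DB):
        if click == NO_RESPONSE:
            tones[freq] = NO_RESPONSE
        else:
            tones[freq] = censor(click + offset + float(rng.normal(0.0, 3.0)))
    extra = {}
    if second_locus is not None:
        extra[second_locus] = "targeted" if rng.random() < 0.5 else "wt"
    return PhenotypeRecord(
        animal_id=animal_id,
        age_weeks=age_weeks,
        click_threshold=click,
        tone_thresholds=tones,
        ep_mv=float(rng.normal(gp.ep_mean, gp.ep_sd)),
        stdf_genotype=stdf_genotype,
        extra_genotypes=extra,
    )


def simulate_colony_phenotypes(
    n_animals: int,
    genotype_proportions: dict[str, float],
    ages: Sequence[float],
    params: Optional[PhenoParams] = None,
    seed: int = 0,
    second_locus: Optional[str] = None,
) -> list[PhenotypeRecord]:
    """Colony phenotypes under the full-penetrance recessive model.

    Wildtype and heterozygous animals draw from the control distributions at
    every age; homozygotes from the age-dependent mutant distributions
    (control-like at 2 weeks, widely variable at 4, severe with NO_RESPONSE
    probability from 8).  When ``second_locus`` is named, each animal also
    receives an independent 50:50 genotype at that locus (a phenotypically
    inert second mutation, for stratified testing).
    """
    params = params or PhenoParams()
    for genotype in genotype_proportions:
        if genotype not in (GT_WT, GT_HET, GT_HOM):
            raise ValueError(f"unknown genotype label {genotype!r}")
    total = sum(genotype_proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"genotype proportions sum to {total}, expected 1")
    rng = np.random.default_rng([seed, 3])
    labels = list(genotype_proportions)
    probs = np.array([genotype_proportions[g] for g in labels], dtype=float)
    records = []
    for i in range(1, n_animals + 1):
        genotype = labels[int(rng.choice(len(labels), p=probs))]
        age = float(ages[int(rng.integers(len(ages)))])
        records.append(
            _draw_phenotype(
                rng, f"COL{i:05d}", age, genotype, params, second_locus=second_locus
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-screen convenience
# ---------------------------------------------------------------------------


@dataclass
class ScreenData:
    config: ScreenConfig
    genome: Genome
    genes: list[GeneModel]
    marker_table: MarkerGenotypeTable
    phenotypes: list[PhenotypeRecord]
    callsets: ScreenCallsets


def simulate_screen(
    config: Optional[ScreenConfig] = None,
    genome: Optional[Genome] = None,
    genes: Optional[Sequence[GeneModel]] = None,
) -> ScreenData:
    """One full synthetic screen: backcross panel + exome call sets.

    The genome/gene models may be passed in (they are seed-independent world
    furniture and expensive to rebuild per replicate); otherwise they are
    generated from the configuration.
    """
    config = config or ScreenConfig()
    if genome is None or genes is None:
        genome, genes = make_screen_world(config)
    table, phenotypes = simulate_backcross(config)
    callsets = simulate_exome_callsets(config, genome, list(genes))
    return ScreenData(
        config=config, genome=genome, genes=list(genes),
        marker_table=table, phenotypes=phenotypes, callsets=callsets,
    )
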