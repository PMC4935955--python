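"""Readers and writers for the pipeline's external formats.

Formats handled:

* a deliberately **minimal VCF dialect** (CHROM POS ID REF ALT QUAL FILTER
  INFO FORMAT sample) in which MQ is carried in INFO and DP preferentially in
  the per-sample FORMAT block, multi-allelic lines are split into one record
  per alternate allele, and all other INFO keys round-trip as opaque string
  annotations;
* GFF3 gene models (via :mod:`gffutils`);
* FASTA reference sequences (read via :mod:`pyfaidx`);
* TSV tables for backcross marker genotypes (long format) and colony
  phenotypes.

All coordinates are 1-based and closed; readers and writers never shift
positions.  The phasing/symbolic-allele/breakend parts of the full VCF
specification are intentionally out of scope.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional, Union

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .model import (
    NO_RESPONSE,
    ROLE_AFFECTED,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
    CallSet,
    FormatError,
    GeneModel,
    Genome,
    GenomicInterval,
    Marker,
    MarkerGenotypeTable,
    PhenotypeRecord,
    VariantRecord,
)

PathLike = Union[str, Path]

_VCF_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
_GT_RENDER = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------


def _parse_info(info: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    if info in (".", ""):
        return fields
    for item in info.split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        fields[key] = value
    return fields


def _genotype_for_alt(gt_token: str, alt_index: int, lineno: int) -> str:
    """Collapse a GT token onto the {hom_ref, het, hom_alt, missing} scale
    for one alternate allele of a (possibly multi-allelic) line."""
    alleles = gt_token.replace("|", "/").split("/")
    if any(a == "." for a in alleles):
        return MISSING
    try:
        calls = [int(a) for a in alleles]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: malformed GT field {gt_token!r}") from exc
    hits = sum(1 for a in calls if a == alt_index)
    if hits == 0:
        return HOM_REF
    if hits == len(calls):
        return HOM_ALT
    return HET


def read_variant_callset(path: PathLike, sample_id: str, role: str) -> CallSet:
    """Read a minimal-dialect VCF into a :class:`CallSet`.

    Multi-allelic lines are split into one record per alternate allele.  DP is
    taken from the sample FORMAT block when present, otherwise from INFO; MQ
    from INFO.  Unrecognised INFO keys are preserved as string annotations.
    """
    callset = CallSet(sample_id=sample_id, role=role)
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}: missing ##fileformat header line")
        header_cols: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header_cols = line.split("\t")
                if header_cols[: len(_VCF_COLUMNS)] != _VCF_COLUMNS:
                    raise FormatError(f"{path}: malformed #CHROM header line")
                continue
            if header_cols is None:
                raise FormatError(f"{path}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"line {lineno}: expected >= 8 columns")
            chrom, pos_s, _id, ref, alt_s, qual_s, _filt, info_s = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric POS {pos_s!r}") from exc
            qual = 0.0 if qual_s in (".", "") else float(qual_s)
            info = _parse_info(info_s)

            fmt_fields: dict[str, str] = {}
            if len(fields) >= 10:
                keys = fields[8].split(":")
                values = fields[9].split(":")
                fmt_fields = dict(zip(keys, values))

            try:
                mq = float(info.get("MQ", "nan"))
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: non-numeric MQ {info.get('MQ')!r}"
                ) from exc
            if math.isnan(mq):
                raise FormatError(f"line {lineno}: MQ missing from INFO")
            dp_s = fmt_fields.get("DP", info.get("DP"))
            if dp_s is None:
                raise FormatError(f"line {lineno}: DP missing from FORMAT and INFO")
            try:
                dp = int(dp_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric DP {dp_s!r}") from exc

            annotations = {
                k: v for k, v in info.items() if k not in {"MQ", "DP"}
            }
            alts = alt_s.split(",")
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: dict[str, str] = {}
                if "GT" in fmt_fields:
                    genotypes[sample_id] = _genotype_for_alt(
                        fmt_fields["GT"], alt_index, lineno
                    )
                elif role == ROLE_AFFECTED:
                    genotypes[sample_id] = MISSING
                try:
                    record = VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        mapping_quality=mq,
                        read_depth=dp,
                        call_quality=qual,
                        genotypes=genotypes,
                        annotations=dict(annotations),
                    )
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from exc
                callset.add(record)
        if header_cols is None:
            raise FormatError(f"{path}: no #CHROM header line found")
    return callset


def _chrom_sort_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def _sanitize_info_value(value: object) -> str:
    return str(value).replace(";", "_").replace("=", "_").replace(" ", "_")


def write_variant_callset(callset: CallSet, path: PathLike) -> None:
    """Write a :class:`CallSet` as minimal-dialect VCF, sorted by position.

    Lossless for every field :func:`read_variant_callset` consumes; the
    callset's own sample genotype is written as a single sample column.
    """
    records = sorted(
        callset.records.values(),
        key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.ref, r.alt),
    )
    info_keys = sorted({k for r in records for k in r.annotations})
    lines = ["##fileformat=VCFv4.2"]
    lines.append(f"##source=exomescreen;role={callset.role}")
    lines.append(
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">'
    )
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for key in info_keys:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="annotation">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in sorted({r.chrom for r in records}, key=_chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("\t".join(_VCF_COLUMNS + ["FORMAT", callset.sample_id]))
    for rec in records:
        info_items = [f"MQ={rec.mapping_quality:.10g}", f"DP={rec.read_depth}"]
        for key in sorted(rec.annotations):
            info_items.append(f"{key}={_sanitize_info_value(rec.annotations[key])}")
        gt = _GT_RENDER[rec.genotypes.get(callset.sample_id, MISSING)]
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    ".",
                    rec.ref,
                    rec.alt,
                    f"{rec.call_quality:.10g}",
                    "PASS",
                    ";".join(info_items),
                    "GT:DP",
                    f"{gt}:{rec.read_depth}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene/mRNA/CDS features from a GFF3 file into GeneModels.

    One model is produced per mRNA (transcript).  A CDS total length not
    divisible by 3 triggers a warning but the model is retained; a CDS
    feature without a parent is a format error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise FormatError(f"CDS feature at {cds.seqid}:{cds.start} has no parent")
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        gene_name = mrna.attributes.get("Name", [gene_id])[0]
        for parent in db.parents(mrna, featuretype="gene"):
            gene_name = parent.attributes.get("Name", [gene_name])[0]
        intervals = [GenomicInterval(f.seqid, f.start, f.end) for f in cds_feats]
        first_feat = cds_feats[-1] if mrna.strand == "-" else cds_feats[0]
        frame = int(first_feat.frame) if first_feat.frame not in (".", None) else 0
        model = GeneModel(
            gene_id=gene_id,
            gene_name=gene_name,
            chrom=mrna.seqid,
            strand=mrna.strand,
            cds_intervals=intervals,
            first_frame=frame,
        )
        if model.cds_length % 3 != 0:
            warnings.warn(
                f"gene {gene_id}: CDS length {model.cds_length} not divisible by 3",
                stacklevel=2,
            )
        models.append(model)
    return models


def write_gene_models(genes: list[GeneModel], path: PathLike) -> None:
    """Write GeneModels as a small, valid GFF3 (gene -> mRNA -> CDS)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        span = gene.span
        attrs = f"ID={gene.gene_id};Name={gene.gene_name}"
        lines.append(
            "\t".join(
                [gene.chrom, "exomescreen", "gene", str(span.start), str(span.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        mrna_id = f"{gene.gene_id}.1"
        lines.append(
            "\t".join(
                [gene.chrom, "exomescreen", "mRNA", str(span.start), str(span.end),
                 ".", gene.strand, ".", f"ID={mrna_id};Parent={gene.gene_id}"]
            )
        )
        # phase per CDS piece, accumulated in transcript order
        tx_order = (
            list(reversed(gene.cds_intervals))
            if gene.strand == "-"
            else list(gene.cds_intervals)
        )
        phases: dict[GenomicInterval, int] = {}
        consumed = 0
        for iv in tx_order:
            phases[iv] = (3 - ((consumed - gene.first_frame) % 3)) % 3
            consumed += len(iv)
        for i, iv in enumerate(gene.cds_intervals, start=1):
            lines.append(
                "\t".join(
                    [gene.chrom, "exomescreen", "CDS", str(iv.start), str(iv.end),
                     ".", gene.strand, str(phases[iv]),
                     f"ID={mrna_id}.cds{i};Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> Genome:
    fasta = Fasta(str(path), rebuild=False, build_index=True)
    genome: Genome = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    fasta.close()
    return genome


def write_fasta(genome: Genome, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["animal_id", "marker_id", "chrom", "pos_bp", "call"]


def read_marker_table(path: PathLike) -> MarkerGenotypeTable:
    """Read a long-format backcross genotype TSV (one row per animal x marker).

    Genotype codes are M (homozygous mutant strain), H (heterozygous) or NA
    (missing); anything else is an error naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"marker table missing columns: {missing_cols}")
    markers: list[Marker] = []
    seen_markers: dict[str, Marker] = {}
    animals: list[str] = []
    calls: dict[tuple[str, str], Optional[str]] = {}
    for row in df.itertuples(index=False):
        animal = str(row.animal_id)
        marker_id = str(row.marker_id)
        if marker_id not in seen_markers:
            marker = Marker(marker_id, str(row.chrom), int(row.pos_bp))
            seen_markers[marker_id] = marker
            markers.append(marker)
        if animal not in animals:
            animals.append(animal)
        call_raw = row.call
        if pd.isna(call_raw) or call_raw == "NA":
            call: Optional[str] = None
        elif call_raw in ("M", "H"):
            call = call_raw
        else:
            raise FormatError(
                f"unknown genotype code {call_raw!r} at "
                f"(animal {animal}, marker {marker_id})"
            )
        calls[(animal, marker_id)] = call
    return MarkerGenotypeTable(markers=markers, animals=animals, calls=calls)


def write_marker_table(table: MarkerGenotypeTable, path: PathLike) -> None:
    rows = []
    for animal in table.animals:
        for marker in table.markers:
            call = table.calls.get((animal, marker.marker_id))
            rows.append(
                {
                    "animal_id": animal,
                    "marker_id": marker.marker_id,
                    "chrom": marker.chrom,
                    "pos_bp": marker.pos,
                    "call": "NA" if call is None else call,
                }
            )
    pd.DataFrame(rows, columns=_MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def _threshold_to_text(value: Optional[float]) -> str:
    if value is None:
        return ""
    if value == NO_RESPONSE:
        return "NR"
    return f"{value:g}"


def _threshold_from_text(text: str, where: str) -> Optional[float]:
    if text == "" or pd.isna(text):
        return None
    if text == "NR":
        return NO_RESPONSE
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"non-numeric threshold {text!r} at {where}") from exc


def read_phenotype_table(path: PathLike) -> list[PhenotypeRecord]:
    """Read a colony phenotype TSV into PhenotypeRecords.

    Threshold cells contain dB SPL values or "NR" (no response at the 95 dB
    ceiling); tone columns are named ``tone_<freq>kHz``; second-locus
    genotype columns are prefixed ``geno_``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"animal_id", "age_weeks", "click_db", "stdf_genotype"}
    if not required <= set(df.columns):
        raise FormatError(f"phenotype table missing columns: {sorted(required - set(df.columns))}")
    tone_cols = [c for c in df.columns if c.startswith("tone_") and c.endswith("kHz")]
    geno_cols = [c for c in df.columns if c.startswith("geno_")]
    records: list[PhenotypeRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        animal = str(d["animal_id"])
        tones = {}
        for col in tone_cols:
            val = _threshold_from_text(d[col], f"(animal {animal}, {col})")
            if val is not None:
                tones[float(col[len("tone_") : -len("kHz")])] = val
        ep_text = d.get("ep_mv", "")
        extra = {c[len("geno_") :]: d[c] for c in geno_cols if d[c] != ""}
        records.append(
            PhenotypeRecord(
                animal_id=animal,
                age_weeks=float(d["age_weeks"]),
                click_threshold=_threshold_from_text(
                    d["click_db"], f"(animal {animal}, click_db)"
                ),
                tone_thresholds=tones,
                ep_mv=float(ep_text) if ep_text != "" else None,
                stdf_genotype=d["stdf_genotype"] or "unknown",
                extra_genotypes=extra,
            )
        )
    return records


def write_phenotype_table(records: list[PhenotypeRecord], path: PathLike) -> None:
    tone_freqs = sorted({f for r in records for f in r.tone_thresholds})
    loci = sorted({k for r in records for k in r.extra_genotypes})
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id,
            "age_weeks": f"{r.age_weeks:g}",
            "click_db": _threshold_to_text(r.click_threshold),
        }
        for f in tone_freqs:
            row[f"tone_{f:g}kHz"] = _threshold_to_text(r.tone_thresholds.get(f))
        row["ep_mv"] = "" if r.ep_mv is None else f"{r.ep_mv:.4f}"
        row["stdf_genotype"] = r.stdf_genotype
        for locus in loci:
            row[f"geno_{locus}"] = r.extra_genotypes.get(locus, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_interval_bed(interval: GenomicInterval, path: PathLike, name: str = "critical_interval") -> None:
    """Write a single interval as BED (converted to 0-based half-open here only)."""
    Path(path).write_text(
        f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t{name}\n"
    )
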