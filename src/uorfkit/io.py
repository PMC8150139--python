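"""VCF-in / TSV-or-VCF-out pipeline and run configuration.

The TSV schema has one row per (variant x transcript x consequence x uORF);
the VCF output preserves every input record and adds an ``UTRA`` INFO key
whose value is a comma-separated list of pipe-delimited entries in the TSV
column order, so the two formats are mutually convertible.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from cyvcf2 import VCF, Writer
from pyfaidx import Fasta

from .engine import (
    Annotator,
    ConsequenceAnnotation,
    VariantRecord,
    normalize_variant,
    prioritize_high_impact,
    within_size_limit,
)
from .evidence import load_evidence
from .transcripts import load_transcripts

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "transcript_id", "gene_id", "consequence",
    "existing_uORFs", "existing_InFrame_oORFs", "existing_OutOfFrame_oORFs",
    "KozakContext", "KozakStrength", "CapDistanceToStart", "StartDistanceToCDS",
    "StartDistanceToStop", "Type", "AltType", "Evidence", "AltStop",
    "AltStopDistanceToCDS", "FrameWithCDS", "NewStopDistanceToCDS",
]

INFO_KEY = "UTRA"
_DNA = set("ACGTN")


@dataclass
class RunConfig:
    """End-to-end run configuration (CLI flags mirror these field names)."""

    vcf_path: str
    gtf_path: str
    fasta_path: str
    output_path: str
    evidence_path: Optional[str] = None
    gene_list_path: Optional[str] = None
    output_format: str = "tsv"
    max_indel_len: int = 5
    cds_scan_horizon: int = 999
    high_impact_only: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.output_format not in ("tsv", "vcf"):
            raise ValueError(f"output_format must be tsv or vcf, not {self.output_format!r}")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


@dataclass
class RunResult:
    exit_status: int
    stats: Counter = field(default_factory=Counter)
    n_rows: int = 0


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return "True" if x else "False"
    return str(x)


def row_fields(row: ConsequenceAnnotation) -> list[str]:
    """A row's values in TSV column order, as strings."""
    return [
        _fmt(row.chrom), _fmt(row.pos), _fmt(row.ref), _fmt(row.alt),
        _fmt(row.transcript_id), _fmt(row.gene_id), _fmt(row.consequence),
        _fmt(row.ref_census.n_uorf), _fmt(row.ref_census.n_inframe_oorf),
        _fmt(row.ref_census.n_outofframe_oorf),
        _fmt(row.kozak_context), _fmt(row.kozak_strength),
        _fmt(row.cap_distance_to_start), _fmt(row.start_distance_to_cds),
        _fmt(row.start_distance_to_stop), _fmt(row.uorf_subtype),
        _fmt(row.alt_subtype), _fmt(row.evidence), _fmt(row.alt_stop_exists),
        _fmt(row.alt_stop_distance_to_cds), _fmt(row.frame_with_cds),
        _fmt(row.new_stop_distance_to_cds),
    ]


def write_tsv(rows, path) -> None:
    """Write annotation rows as a TSV with the fixed column schema."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row_fields(row)) + "\n")


def _sanitize(s: str) -> str:
    for ch in "|,;= \t":
        s = s.replace(ch, "_")
    return s


def write_vcf(rows, input_vcf_path, path) -> None:
    """Copy the input VCF, adding an UTRA INFO entry per annotation row.

    Rows are matched to records by (chrom, pos, ref, alt); a multi-allelic
    record collects the entries of all of its alternate alleles.
    """
    entries = defaultdict(list)
    for row in rows:
        entries[(row.chrom, int(row.pos), row.ref, row.alt)].append(
            "|".join(_sanitize(f) for f in row_fields(row))
        )
    vcf = VCF(str(input_vcf_path))
    vcf.add_info_to_header(
        {
            "ID": INFO_KEY,
            "Number": ".",
            "Type": "String",
            "Description": "5'UTR uORF consequence annotation: "
            + "|".join(TSV_COLUMNS),
        }
    )
    writer = Writer(str(path), vcf)
    for rec in vcf:
        parts = []
        for alt in rec.ALT:
            parts += entries.get((rec.CHROM, rec.POS, rec.REF, alt), [])
        if parts:
            rec.INFO[INFO_KEY] = ",".join(parts)
        writer.write_record(rec)
    writer.close()
    vcf.close()


def read_utra_entries(vcf_path) -> list[list[str]]:
    """Parse UTRA entries back out of an annotated VCF (TSV column order)."""
    out = []
    vcf = VCF(str(vcf_path))
    for rec in vcf:
        val = rec.INFO.get(INFO_KEY)
        if val is None:
            continue
        for entry in val.split(","):
            out.append(entry.split("|"))
    vcf.close()
    return out


def load_gene_list(path) -> set[str]:
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def run(config: RunConfig) -> RunResult:
    """Annotate every record of a VCF against a transcript set.

    Multi-allelic records are decomposed into per-alt pseudo-records before
    normalization. Records with no 5'UTR consequence get no TSV row / no
    UTRA key. Summary counts are logged; exit status 0 on success.
    """
    logging.getLogger("uorfkit").setLevel(config.log_level.upper())
    stats: Counter = Counter()
    try:
        transcripts = load_transcripts(config.gtf_path, config.fasta_path)
    except (OSError, ValueError) as exc:
        log.error("could not load transcripts: %s", exc)
        return RunResult(1, stats)
    if not transcripts:
        log.error("no usable transcripts loaded from %s", config.gtf_path)
        return RunResult(1, stats)
    genome = Fasta(str(config.fasta_path))
    chroms = set(genome.keys())
    evidence_store = None
    if config.evidence_path:
        try:
            evidence_store = load_evidence(config.evidence_path)
        except (OSError, ValueError) as exc:
            log.error("could not load evidence: %s", exc)
            return RunResult(1, stats)
    gene_list = set()
    if config.gene_list_path:
        try:
            gene_list = load_gene_list(config.gene_list_path)
        except OSError as exc:
            log.error("could not load gene list: %s", exc)
            return RunResult(1, stats)
    annotator = Annotator(
        transcripts,
        genome,
        evidence_store,
        cds_context_length=config.cds_scan_horizon,
        max_variant_len=config.max_indel_len,
    )
    all_rows: list[ConsequenceAnnotation] = []
    try:
        vcf = VCF(str(config.vcf_path))
    except OSError as exc:
        log.error("could not read VCF: %s", exc)
        return RunResult(1, stats)
    for rec in vcf:
        for alt in rec.ALT:
            stats["alleles_read"] += 1
            if not alt or not set(alt.upper()) <= _DNA or not set(rec.REF.upper()) <= _DNA:
                stats["skipped_symbolic"] += 1
                log.info("symbolic/non-DNA allele at %s:%d skipped", rec.CHROM, rec.POS)
                continue
            if rec.CHROM not in chroms:
                stats["skipped_ref_mismatch"] += 1
                log.warning("chromosome %s absent from FASTA; record skipped", rec.CHROM)
                continue
            fetched = str(genome[rec.CHROM][rec.POS - 1 : rec.POS - 1 + len(rec.REF)]).upper()
            if fetched != rec.REF.upper():
                stats["skipped_ref_mismatch"] += 1
                log.warning(
                    "REF %s does not match the genome at %s:%d (found %s); skipped",
                    rec.REF, rec.CHROM, rec.POS, fetched,
                )
                continue
            try:
                v = normalize_variant(
                    VariantRecord(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt)
                )
            except ValueError as exc:
                stats["skipped_symbolic"] += 1
                log.info("unusable allele at %s:%d skipped: %s", rec.CHROM, rec.POS, exc)
                continue
            if not within_size_limit(v, config.max_indel_len):
                stats["skipped_too_long"] += 1
                log.info(
                    "variant %s:%d %s>%s longer than %d bp; skipped",
                    rec.CHROM, rec.POS, rec.REF, alt, config.max_indel_len,
                )
                continue
            rows = annotator.annotate(v, display=(rec.POS, rec.REF, alt))
            if rows:
                stats["annotated"] += 1
                all_rows.extend(rows)
            else:
                stats["no_utr_consequence"] += 1
    vcf.close()
    if config.high_impact_only:
        all_rows = prioritize_high_impact(all_rows, gene_list or None)
    if config.output_format == "tsv":
        write_tsv(all_rows, config.output_path)
    else:
        write_vcf(all_rows, config.vcf_path, config.output_path)
    log.info(
        "read %d alt alleles: %d annotated, %d without 5'UTR consequence, "
        "%d symbolic/unusable, %d reference-mismatched, %d over the size cap; "
        "%d annotation rows written to %s",
        stats["alleles_read"], stats["annotated"], stats["no_utr_consequence"],
        stats["skipped_symbolic"], stats["skipped_ref_mismatch"],
        stats["skipped_too_long"], len(all_rows), config.output_path,
    )
    return RunResult(0, stats, n_rows=len(all_rows))
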