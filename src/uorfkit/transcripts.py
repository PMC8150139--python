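"""Transcript models built from a GTF annotation and a genome FASTA.

A :class:`TranscriptModel` carries a transcript's exon structure, strand and
the genomic position of the first base of its annotated start codon.
:func:`extract_spliced_utr` reconstructs the spliced 5'UTR in transcript
orientation (offset 0 is the cap-proximal base) together with a per-base map
back to genomic coordinates, plus the first ``cds_context_length`` nt of
spliced CDS used as the downstream scanning horizon for overlapping ORFs.

Coordinate convention: GTF and VCF are 1-based inclusive on disk; everything
in memory is 0-based half-open. Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

DEFAULT_CDS_CONTEXT_LENGTH = 999

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open genomic interval on a stranded feature."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript's exon structure and CDS start.

    ``exons`` are ordered 5'->3' in transcript orientation (descending genomic
    coordinate for minus-strand transcripts). ``cds_start_genomic`` is the
    genomic 0-based position of the first base of the annotated start codon.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    cds_start_genomic: int
    cds_intervals: list[GenomeInterval]


@dataclass
class SplicedUTR:
    """Spliced 5'UTR sequence of one transcript plus its genomic coordinate map.

    ``sequence[i]`` sits at genomic 0-based position ``genomic_positions[i]``;
    offsets run cap (0) to the base adjacent to the CDS. ``cds_context`` is the
    first K nt of spliced CDS in transcript orientation and always begins with
    the annotated start codon's bases.
    """

    transcript_id: str
    sequence: str
    cds_context: str
    genomic_positions: list[int]
    _pos_to_offset: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.genomic_positions):
            raise ValueError("sequence / coordinate map length mismatch")
        self._pos_to_offset = {p: i for i, p in enumerate(self.genomic_positions)}

    @property
    def utr_length(self) -> int:
        return len(self.sequence)

    def offset_of(self, genomic_pos: int) -> Optional[int]:
        """UTR offset of a genomic 0-based position, or None if outside."""
        return self._pos_to_offset.get(genomic_pos)

    def genomic_blocks(self) -> list[tuple[int, int]]:
        """Contiguous genomic runs (0-based half-open) covered by the UTR."""
        blocks: list[tuple[int, int]] = []
        run_start = prev = None
        for p in sorted(self.genomic_positions):
            if prev is not None and p == prev + 1:
                prev = p
                continue
            if run_start is not None:
                blocks.append((run_start, prev + 1))
            run_start = prev = p
        if run_start is not None:
            blocks.append((run_start, prev + 1))
        return blocks


def genomic_to_utr_offset(utr: SplicedUTR, genomic_pos: int) -> Optional[int]:
    """Map a genomic 0-based position to its UTR offset (None if intronic/outside)."""
    return utr.offset_of(genomic_pos)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) uppercased; accepts pyfaidx.Fasta or a dict."""
    return str(genome[chrom][start:end]).upper()


def extract_spliced_utr(
    tx: TranscriptModel,
    genome,
    cds_context_length: int = DEFAULT_CDS_CONTEXT_LENGTH,
) -> SplicedUTR:
    """Reconstruct the spliced 5'UTR and downstream CDS context of a transcript.

    Minus-strand exon sequences are reverse-complemented so offset 0 is always
    the cap-proximal base; soft-masked bases are uppercased.
    """
    seq_parts: list[str] = []
    positions: list[int] = []
    for exon in tx.exons:
        try:
            s = _fetch(genome, exon.chrom, exon.start, exon.end)
        except KeyError as exc:
            raise KeyError(
                f"transcript {tx.transcript_id}: chromosome {exon.chrom!r} "
                "not found in the genome"
            ) from exc
        if len(s) != len(exon):
            raise ValueError(
                f"transcript {tx.transcript_id}: genome lookup for "
                f"{exon.chrom}:{exon.start}-{exon.end} returned {len(s)} bases"
            )
        if tx.strand == "+":
            seq_parts.append(s)
            positions.extend(range(exon.start, exon.end))
        else:
            seq_parts.append(reverse_complement(s))
            positions.extend(range(exon.end - 1, exon.start - 1, -1))
    full = "".join(seq_parts)
    try:
        cds_idx = positions.index(tx.cds_start_genomic)
    except ValueError as exc:
        raise ValueError(
            f"transcript {tx.transcript_id}: CDS start "
            f"{tx.cds_start_genomic} is not inside any exon"
        ) from exc
    return SplicedUTR(
        transcript_id=tx.transcript_id,
        sequence=full[:cds_idx],
        cds_context=full[cds_idx : cds_idx + cds_context_length],
        genomic_positions=positions[:cds_idx],
    )


def _utr_length(tx: TranscriptModel) -> int:
    """Number of transcript bases 5' of the CDS start, without extracting sequence."""
    n = 0
    for exon in tx.exons:
        if exon.start <= tx.cds_start_genomic < exon.end:
            if tx.strand == "+":
                return n + (tx.cds_start_genomic - exon.start)
            return n + (exon.end - 1 - tx.cds_start_genomic)
        n += len(exon)
    return -1  # CDS start not inside any exon


def load_transcripts(gtf_path, fasta_path) -> list[TranscriptModel]:
    """Parse a GTF + FASTA into transcript models with a non-empty 5'UTR.

    Only transcripts with CDS features are considered (protein coding). The
    CDS start is taken from a start_codon feature when present, else from the
    5'-most CDS base in transcript orientation. Transcripts with no 5'UTR, a
    CDS start outside their exons, or a chromosome missing from the FASTA are
    skipped with a warning.
    """
    for p in (gtf_path, fasta_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    genome = Fasta(str(fasta_path))
    chroms = set(genome.keys())
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for kind in ("exon", "CDS", "start_codon"):
        for feat in db.features_of_type(kind):
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                log.warning("%s feature without transcript_id skipped (%s:%s)",
                            kind, feat.seqid, feat.start)
                continue
            rec = grouped.setdefault(
                tid, {"exon": [], "CDS": [], "start_codon": [], "feat": feat}
            )
            rec[kind].append(feat)

    models: list[TranscriptModel] = []
    for tid, rec in grouped.items():
        if not rec["CDS"]:
            continue  # non-coding: out of scope
        if not rec["exon"]:
            log.warning("transcript %s has CDS but no exons; skipped", tid)
            continue
        anchor = rec["feat"]
        chrom, strand = anchor.seqid, anchor.strand
        if strand not in ("+", "-"):
            log.warning("transcript %s has no strand; skipped", tid)
            continue
        if chrom not in chroms:
            log.warning("transcript %s: chromosome %s absent from FASTA; skipped",
                        tid, chrom)
            continue
        gene_id = anchor.attributes.get("gene_id", [""])[0]
        gene_symbol = anchor.attributes.get("gene_name", [""])[0]
        reverse = strand == "-"
        exons = sorted(
            (GenomeInterval(chrom, f.start - 1, f.end, strand) for f in rec["exon"]),
            key=lambda iv: iv.start,
            reverse=reverse,
        )
        cds = sorted(
            (GenomeInterval(chrom, f.start - 1, f.end, strand) for f in rec["CDS"]),
            key=lambda iv: iv.start,
            reverse=reverse,
        )
        if rec["start_codon"]:
            sc = rec["start_codon"]
            cds_start = (min(f.start for f in sc) - 1 if strand == "+"
                         else max(f.end for f in sc) - 1)
        else:
            cds_start = cds[0].start if strand == "+" else cds[0].end - 1
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            gene_symbol=gene_symbol,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start_genomic=cds_start,
            cds_intervals=cds,
        )
        n_utr = _utr_length(tx)
        if n_utr < 0:
            log.warning("transcript %s: CDS start not inside an exon; skipped", tid)
            continue
        if n_utr == 0:
            log.warning("transcript %s has a zero-length 5'UTR; skipped", tid)
            continue
        models.append(tx)
    return models
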