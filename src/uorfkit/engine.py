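"""Consequence detection for small variants in 5'UTRs.

Each variant is normalized (shared prefix then suffix trimmed), projected
into the spliced 5'UTR of every transcript whose UTR contains it, and run
through five detectors:

* uAUG_gained   — the alternate UTR carries a new AUG overlapping the edit;
* uAUG_lost     — a reference AUG no longer reads ATG;
* uSTOP_lost    — the stop codon of an existing uORF is destroyed;
* uSTOP_gained  — an existing (u)ORF meets a new, earlier in-frame stop;
* uFrameshift   — a non-multiple-of-three indel inside a (u)ORF body.

A variant with several consequences (or touching several uORFs) yields one
annotation row per (transcript x consequence x uORF). Distances are measured
on the allele where the feature exists: the alternate UTR for gained features
and frameshifted starts, the reference UTR for lost features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .scanner import (
    INFRAME_OORF,
    MODERATE,
    OUTOFFRAME_OORF,
    STOP_CODONS,
    STRONG,
    UORF,
    UorfCensus,
    census,
    find_uaugs,
    kozak_assess,
    scan_orf,
)
from .transcripts import SplicedUTR, TranscriptModel, extract_spliced_utr, reverse_complement

log = logging.getLogger(__name__)

UAUG_GAINED = "uAUG_gained"
UAUG_LOST = "uAUG_lost"
USTOP_LOST = "uSTOP_lost"
USTOP_GAINED = "uSTOP_gained"
UFRAMESHIFT = "uFrameshift"

#: Fixed report order for rows of one transcript.
CONSEQUENCE_ORDER = {
    UAUG_GAINED: 0,
    UAUG_LOST: 1,
    USTOP_LOST: 2,
    USTOP_GAINED: 3,
    UFRAMESHIFT: 4,
}

IN_FRAME = "inFrame"
OUT_OF_FRAME = "outOfFrame"

DEFAULT_MAX_VARIANT_LEN = 5

_DNA = set("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized VCF allele pair (pos is 1-based; alleles may be empty)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref or '-'}-{self.alt or '-'}"

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNV"
        if len(self.ref) > len(self.alt):
            return "deletion"
        return "insertion"


def normalize_variant(raw: VariantRecord) -> VariantRecord:
    """Trim the shared prefix, then the shared suffix, advancing pos.

    Raises ValueError for non-DNA alleles or ref == alt.
    """
    ref, alt = raw.ref.upper(), raw.alt.upper()
    if not set(ref) <= _DNA or not set(alt) <= _DNA:
        raise ValueError(f"non-DNA allele in {raw.chrom}:{raw.pos} {raw.ref}>{raw.alt}")
    if ref == alt:
        raise ValueError(f"ref == alt at {raw.chrom}:{raw.pos}")
    pos = raw.pos
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return VariantRecord(chrom=raw.chrom, pos=pos, ref=ref, alt=alt)


def within_size_limit(v: VariantRecord, max_len: int = DEFAULT_MAX_VARIANT_LEN) -> bool:
    """True when the (normalized) variant is within the small-variant scope."""
    return max(len(v.ref), len(v.alt)) <= max_len


@dataclass(frozen=True)
class Edit:
    """A variant expressed in UTR offset space.

    The reference UTR bases ``[offset, offset + ref_len)`` are replaced by
    ``alt_seq``; ``apply`` produces the alternate UTR string. The mapping
    helpers relate offsets of the two alleles outside the edited window, and
    the ``touches_*`` predicates test whether a fixed-width window overlaps
    the edited region (a window spanning a pure-deletion junction counts as
    touching).
    """

    offset: int
    ref_len: int
    alt_seq: str

    @property
    def alt_len(self) -> int:
        return len(self.alt_seq)

    @property
    def net_change(self) -> int:
        return self.alt_len - self.ref_len

    def apply(self, ref_seq: str) -> str:
        return ref_seq[: self.offset] + self.alt_seq + ref_seq[self.offset + self.ref_len :]

    def inverse(self, ref_seq: str) -> "Edit":
        """The edit that undoes this one on the alternate sequence."""
        removed = ref_seq[self.offset : self.offset + self.ref_len]
        return Edit(offset=self.offset, ref_len=self.alt_len, alt_seq=removed)

    def ref_to_alt(self, r: int) -> Optional[int]:
        if self.ref_len == self.alt_len:
            return r  # substitutions keep positional identity everywhere
        if r < self.offset:
            return r
        if r >= self.offset + self.ref_len:
            return r + self.net_change
        return None

    def alt_to_ref(self, a: int) -> Optional[int]:
        if self.ref_len == self.alt_len:
            return a
        if a < self.offset:
            return a
        if a >= self.offset + self.alt_len:
            return a - self.net_change
        return None

    def touches_ref_window(self, start: int, width: int) -> bool:
        if self.ref_len == 0:  # pure insertion: window must span the junction
            return start < self.offset < start + width
        return start < self.offset + self.ref_len and start + width > self.offset

    def touches_alt_window(self, start: int, width: int) -> bool:
        if self.alt_len == 0:  # pure deletion: window must span the junction
            return start < self.offset < start + width
        return start < self.offset + self.alt_len and start + width > self.offset


@dataclass
class ConsequenceAnnotation:
    """One (variant, transcript, consequence, uORF) annotation row.

    Optional fields are None (reported as NA) unless the consequence class
    populates them. ``anchor_offset`` is the UTR offset of the affected start
    site (alternate allele for uAUG_gained, reference otherwise) and is the
    within-consequence sort key; it is not part of the output schema.
    """

    chrom: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""
    transcript_id: str = ""
    gene_id: str = ""
    gene_symbol: str = ""
    consequence: str = ""
    ref_census: UorfCensus = field(default_factory=UorfCensus)
    kozak_context: str = ""
    kozak_strength: str = ""
    cap_distance_to_start: Optional[int] = None
    start_distance_to_cds: Optional[int] = None
    start_distance_to_stop: Optional[int] = None
    uorf_subtype: Optional[str] = None
    alt_subtype: Optional[str] = None
    evidence: Optional[bool] = None
    alt_stop_exists: Optional[bool] = None
    alt_stop_distance_to_cds: Optional[int] = None
    frame_with_cds: Optional[str] = None
    new_stop_distance_to_cds: Optional[int] = None
    anchor_offset: int = 0

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref or '-'}-{self.alt or '-'}"


EvidenceFn = Callable[[int], bool]


def _no_evidence(_: int) -> bool:
    return False


def _start_to_stop_distance(rec) -> Optional[int]:
    """Start->stop distance convention: nt from the A of AUG to the first stop
    base for uORFs; scan-horizon stop for out-of-frame oORFs (None if none);
    NA for in-frame oORFs, whose stop is the CDS stop."""
    if rec.subtype == UORF:
        return rec.stop_offset - rec.start_offset
    if rec.subtype == OUTOFFRAME_OORF and rec.stop_offset is not None:
        return rec.stop_offset - rec.start_offset
    return None


def _first_utr_stop(seq: str, start: int) -> Optional[int]:
    """Offset of the first in-frame stop codon wholly inside ``seq``."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def _start_intact(ref_seq: str, alt_seq: str, edit: Edit, r: int) -> Optional[int]:
    """Alt offset of a reference AUG that still reads ATG, else None."""
    a0 = edit.ref_to_alt(r)
    if a0 is None and edit.ref_len == 0:
        a0 = r  # insertions delete nothing; start base always maps
    if a0 is None or alt_seq[a0 : a0 + 3] != "ATG":
        return None
    return a0


def detect_uaug_gained(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: UorfCensus,
) -> list[ConsequenceAnnotation]:
    """New AUGs in the alternate UTR that overlap the edit.

    An alt AUG whose three bases all map to a contiguous reference ATG is a
    pre-existing start merely shifted by the indel, not a gain.
    """
    alt = edit.apply(ref_utr)
    rows = []
    for a in find_uaugs(alt):
        if not edit.touches_alt_window(a, 3):
            continue
        refs = [edit.alt_to_ref(a + k) for k in range(3)]
        if (
            None not in refs
            and refs[1] == refs[0] + 1
            and refs[2] == refs[0] + 2
            and ref_utr[refs[0] : refs[0] + 3] == "ATG"
        ):
            continue
        rec = scan_orf(a, alt, cds_context)
        rows.append(
            ConsequenceAnnotation(
                consequence=UAUG_GAINED,
                ref_census=ref_census,
                kozak_context=rec.kozak.context,
                kozak_strength=rec.kozak.strength,
                cap_distance_to_start=a,
                start_distance_to_cds=len(alt) - a,
                start_distance_to_stop=_start_to_stop_distance(rec),
                uorf_subtype=rec.subtype,
                evidence=None,  # a new uORF cannot have pre-existing support
                anchor_offset=a,
            )
        )
    return rows


def detect_uaug_lost(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: UorfCensus,
    evidence_fn: EvidenceFn = _no_evidence,
) -> list[ConsequenceAnnotation]:
    """Reference AUGs overlapping the edit that no longer read ATG."""
    alt = edit.apply(ref_utr)
    rows = []
    for r in find_uaugs(ref_utr):
        if not edit.touches_ref_window(r, 3):
            continue
        if _start_intact(ref_utr, alt, edit, r) is not None:
            continue
        rec = scan_orf(r, ref_utr, cds_context)
        rows.append(
            ConsequenceAnnotation(
                consequence=UAUG_LOST,
                ref_census=ref_census,
                kozak_context=rec.kozak.context,
                kozak_strength=rec.kozak.strength,
                start_distance_to_cds=len(ref_utr) - r,
                start_distance_to_stop=_start_to_stop_distance(rec),
                uorf_subtype=rec.subtype,
                evidence=evidence_fn(r),
                anchor_offset=r,
            )
        )
    return rows


def detect_ustop_lost(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: UorfCensus,
    evidence_fn: EvidenceFn = _no_evidence,
) -> list[ConsequenceAnnotation]:
    """uORFs (stop wholly in the UTR) whose stop codon the edit destroys.

    The alternative-stop search is confined to the alternate 5'UTR, strictly
    downstream of the old stop position; when no alternative exists the frame
    of the now-overlapping ORF relative to the CDS is reported instead.
    """
    alt = edit.apply(ref_utr)
    n_alt = len(alt)
    rows = []
    for r in find_uaugs(ref_utr):
        rec = scan_orf(r, ref_utr, cds_context)
        if rec.subtype != UORF:
            continue
        p = rec.stop_offset
        if not edit.touches_ref_window(p, 3):
            continue
        a0 = _start_intact(ref_utr, alt, edit, r)
        if a0 is None:
            continue
        p_alt = edit.ref_to_alt(p)
        survived = (
            p_alt is not None
            and (p_alt - a0) % 3 == 0
            and p_alt + 3 <= n_alt
            and alt[p_alt : p_alt + 3] in STOP_CODONS
        )
        if survived:
            continue
        threshold = p_alt if p_alt is not None else edit.offset + edit.alt_len - 1
        alt_stop = None
        for i in range(a0, n_alt - 2, 3):
            if i > threshold and alt[i : i + 3] in STOP_CODONS:
                alt_stop = i
                break
        row = ConsequenceAnnotation(
            consequence=USTOP_LOST,
            ref_census=ref_census,
            kozak_context=rec.kozak.context,
            kozak_strength=rec.kozak.strength,
            evidence=evidence_fn(r),
            alt_stop_exists=alt_stop is not None,
            anchor_offset=r,
        )
        if alt_stop is not None:
            row.alt_stop_distance_to_cds = n_alt - alt_stop
        else:
            row.frame_with_cds = IN_FRAME if (n_alt - a0) % 3 == 0 else OUT_OF_FRAME
        rows.append(row)
    return rows


def detect_ustop_gained(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: UorfCensus,
    evidence_fn: EvidenceFn = _no_evidence,
) -> list[ConsequenceAnnotation]:
    """(u)ORFs shortened by a new in-frame stop codon overlapping the edit.

    For uORFs the new stop must fall strictly before the (mapped) reference
    stop; for oORFs, which have no stop in the UTR, any new in-UTR stop
    qualifies.
    """
    alt = edit.apply(ref_utr)
    rows = []
    for r in find_uaugs(ref_utr):
        rec = scan_orf(r, ref_utr, cds_context)
        a0 = _start_intact(ref_utr, alt, edit, r)
        if a0 is None:
            continue
        s = _first_utr_stop(alt, a0)
        if s is None or not edit.touches_alt_window(s, 3):
            continue
        if rec.subtype == UORF:
            p_alt = edit.ref_to_alt(rec.stop_offset)
            if p_alt is None or s >= p_alt:
                continue  # old stop destroyed (uSTOP_lost territory) or not earlier
        rows.append(
            ConsequenceAnnotation(
                consequence=USTOP_GAINED,
                ref_census=ref_census,
                kozak_context=rec.kozak.context,
                kozak_strength=rec.kozak.strength,
                start_distance_to_cds=len(ref_utr) - r,
                uorf_subtype=rec.subtype,
                evidence=evidence_fn(r),
                new_stop_distance_to_cds=len(alt) - s,
                anchor_offset=r,
            )
        )
    return rows


def detect_uframeshift(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: UorfCensus,
    evidence_fn: EvidenceFn = _no_evidence,
) -> list[ConsequenceAnnotation]:
    """(u)ORFs whose body contains a non-multiple-of-three indel.

    The body runs from the AUG through the stop codon's last base (through
    the UTR end for oORFs). The subtype is reported for both alleles; the
    start->CDS distance is measured on the alternate UTR, where the
    frameshifted ORF lives.
    """
    if edit.net_change == 0 or edit.net_change % 3 == 0:
        return []
    alt = edit.apply(ref_utr)
    rows = []
    for r in find_uaugs(ref_utr):
        rec = scan_orf(r, ref_utr, cds_context)
        body_end = rec.stop_offset + 3 if rec.stop_in_utr else len(ref_utr)
        if edit.ref_len > 0:
            inside = edit.offset < body_end and edit.offset + edit.ref_len > r
        else:
            inside = r < edit.offset < body_end
        if not inside:
            continue
        a0 = _start_intact(ref_utr, alt, edit, r)
        if a0 is None:
            continue
        alt_rec = scan_orf(a0, alt, cds_context)
        rows.append(
            ConsequenceAnnotation(
                consequence=UFRAMESHIFT,
                ref_census=ref_census,
                kozak_context=rec.kozak.context,
                kozak_strength=rec.kozak.strength,
                start_distance_to_cds=len(alt) - a0,
                uorf_subtype=rec.subtype,
                alt_subtype=alt_rec.subtype,
                evidence=evidence_fn(r),
                anchor_offset=r,
            )
        )
    return rows


def annotate_edit(
    ref_utr: str,
    cds_context: str,
    edit: Edit,
    ref_census: Optional[UorfCensus] = None,
    evidence_fn: EvidenceFn = _no_evidence,
) -> list[ConsequenceAnnotation]:
    """Run all five detectors on a UTR-space edit; rows in stable order."""
    cen = ref_census if ref_census is not None else census(ref_utr, cds_context)
    rows = []
    rows += detect_uaug_gained(ref_utr, cds_context, edit, cen)
    rows += detect_uaug_lost(ref_utr, cds_context, edit, cen, evidence_fn)
    rows += detect_ustop_lost(ref_utr, cds_context, edit, cen, evidence_fn)
    rows += detect_ustop_gained(ref_utr, cds_context, edit, cen, evidence_fn)
    rows += detect_uframeshift(ref_utr, cds_context, edit, cen, evidence_fn)
    rows.sort(key=lambda r: (CONSEQUENCE_ORDER[r.consequence], r.anchor_offset))
    return rows


def utr_edit_from_variant(
    utr: SplicedUTR, strand: str, v: VariantRecord
) -> Optional[Edit]:
    """Project a normalized genomic variant into UTR offset space.

    Returns None when the variant does not lie wholly within this UTR's
    exonic sequence (CDS/intronic bases, splice-junction-spanning alleles and
    boundary insertions are all skipped; a notice is logged when the variant
    partially overlaps the UTR).
    """
    p0 = v.pos - 1
    rl = len(v.ref)
    if rl:
        offs = [utr.offset_of(p) for p in range(p0, p0 + rl)]
        hits = [o for o in offs if o is not None]
        if not hits:
            return None
        if len(hits) < rl:
            log.info(
                "variant %s partially overlaps the 5'UTR of %s; skipped",
                v.variant_id, utr.transcript_id,
            )
            return None
        e = min(hits)
        if sorted(hits) != list(range(e, e + rl)):
            log.info(
                "variant %s spans a splice junction in the 5'UTR of %s; skipped",
                v.variant_id, utr.transcript_id,
            )
            return None
        expected = v.ref if strand == "+" else reverse_complement(v.ref)
        if utr.sequence[e : e + rl] != expected:
            log.warning(
                "variant %s: reference allele does not match the %s 5'UTR; skipped",
                v.variant_id, utr.transcript_id,
            )
            return None
        alt_seg = v.alt if strand == "+" else reverse_complement(v.alt)
        return Edit(offset=e, ref_len=rl, alt_seq=alt_seg)
    # pure insertion between genomic p0-1 and p0
    ol, orr = utr.offset_of(p0 - 1), utr.offset_of(p0)
    if ol is None and orr is None:
        return None
    if ol is None or orr is None:
        log.info(
            "insertion %s at a 5'UTR boundary of %s; skipped",
            v.variant_id, utr.transcript_id,
        )
        return None
    if abs(ol - orr) != 1:
        log.info(
            "insertion %s at a splice junction in the 5'UTR of %s; skipped",
            v.variant_id, utr.transcript_id,
        )
        return None
    if strand == "+":
        return Edit(offset=orr, ref_len=0, alt_seq=v.alt)
    return Edit(offset=ol, ref_len=0, alt_seq=reverse_complement(v.alt))


class Annotator:
    """Annotates variants against a fixed transcript set.

    Spliced UTRs, reference censuses and a per-chromosome interval index of
    UTR exon blocks are precomputed once, so per-variant work is bounded by
    the transcripts actually overlapping it — annotation time is linear in
    the number of variants.
    """

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        genome,
        evidence_store=None,
        cds_context_length: int = 999,
        max_variant_len: int = DEFAULT_MAX_VARIANT_LEN,
    ) -> None:
        self.evidence_store = evidence_store
        self.max_variant_len = max_variant_len
        self._slots: list[tuple[TranscriptModel, SplicedUTR, UorfCensus]] = []
        self._index: dict[str, IntervalTree] = {}
        for tx in transcripts:
            utr = extract_spliced_utr(tx, genome, cds_context_length)
            cen = census(utr.sequence, utr.cds_context)
            idx = len(self._slots)
            self._slots.append((tx, utr, cen))
            tree = self._index.setdefault(tx.chrom, IntervalTree())
            for gstart, gend in utr.genomic_blocks():
                tree[gstart:gend] = idx

    @property
    def n_transcripts(self) -> int:
        return len(self._slots)

    def _evidence_fn(self, tx: TranscriptModel, utr: SplicedUTR) -> EvidenceFn:
        store = self.evidence_store
        if store is None:
            return _no_evidence
        return lambda r: store.contains(tx.chrom, utr.genomic_positions[r] + 1, tx.strand)

    def annotate(
        self,
        v: VariantRecord,
        display: Optional[tuple[int, str, str]] = None,
    ) -> list[ConsequenceAnnotation]:
        """All annotation rows for one variant, across all loaded transcripts.

        ``display`` optionally carries the original (pos, ref, alt) as read
        from the VCF, used verbatim in the output columns; by default the
        normalized allele is shown.
        """
        v = normalize_variant(v)
        if not within_size_limit(v, self.max_variant_len):
            log.info("variant %s longer than %d bp; skipped", v.variant_id, self.max_variant_len)
            return []
        tree = self._index.get(v.chrom)
        if tree is None:
            return []
        p0 = v.pos - 1
        # widen by 1 to catch pure insertions via their flanking bases
        candidates = sorted({iv.data for iv in tree[p0 - 1 : p0 + max(len(v.ref), 1) + 1]})
        out_pos, out_ref, out_alt = display if display else (v.pos, v.ref or "-", v.alt or "-")
        rows: list[ConsequenceAnnotation] = []
        for idx in candidates:
            tx, utr, cen = self._slots[idx]
            edit = utr_edit_from_variant(utr, tx.strand, v)
            if edit is None:
                continue
            tx_rows = annotate_edit(
                utr.sequence, utr.cds_context, edit, cen, self._evidence_fn(tx, utr)
            )
            for row in tx_rows:
                row.chrom = v.chrom
                row.pos = out_pos
                row.ref = out_ref
                row.alt = out_alt
                row.transcript_id = tx.transcript_id
                row.gene_id = tx.gene_id
                row.gene_symbol = tx.gene_symbol
            rows.extend(tx_rows)
        rows.sort(
            key=lambda r: (r.transcript_id, CONSEQUENCE_ORDER[r.consequence], r.anchor_offset)
        )
        return rows


def annotate_variant(
    tx_models: Sequence[TranscriptModel],
    v: VariantRecord,
    genome,
    evidence_store=None,
    **kwargs,
) -> list[ConsequenceAnnotation]:
    """One-shot convenience wrapper around :class:`Annotator` for a single variant."""
    return Annotator(tx_models, genome, evidence_store, **kwargs).annotate(v)


_OORF_SUBTYPES = frozenset({INFRAME_OORF, OUTOFFRAME_OORF})


def prioritize_high_impact(
    rows: Iterable[ConsequenceAnnotation],
    gene_list: Optional[set] = None,
) -> list[ConsequenceAnnotation]:
    """High-impact filter for annotation rows.

    Keeps a row when (its gene is in ``gene_list``, if one is given) and
    either (A) the variant's resulting ORF overlaps the CDS — a uAUG_gained
    oORF, a uSTOP_lost with no alternative stop, or a uFrameshift whose
    alternate subtype is an oORF — with a Strong or Moderate Kozak start, or
    (B) it disrupts an existing uORF with documented translation evidence.
    """
    kept = []
    for row in rows:
        if gene_list:
            if row.gene_id not in gene_list and row.gene_symbol not in gene_list:
                continue
        forms_oorf = (
            (row.consequence == UAUG_GAINED and row.uorf_subtype in _OORF_SUBTYPES)
            or (row.consequence == USTOP_LOST and row.alt_stop_exists is False)
            or (row.consequence == UFRAMESHIFT and row.alt_subtype in _OORF_SUBTYPES)
        )
        cond_a = forms_oorf and row.kozak_strength in (STRONG, MODERATE)
        cond_b = row.consequence != UAUG_GAINED and row.evidence is True
        if cond_a or cond_b:
            kept.append(row)
    return kept
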