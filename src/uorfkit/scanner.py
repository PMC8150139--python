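"""Enumeration and classification of upstream ORFs in a 5'UTR sequence.

A uAUG is any ATG triplet in the 5'UTR. Reading codons downstream of it,
either a stop codon (TAA/TAG/TGA) falls wholly inside the UTR — a distinct
uORF — or translation runs into the coding sequence, producing an
overlapping ORF (oORF) that is in-frame with the CDS (an N-terminal
extension) or out-of-frame, depending on (utr_length - start) mod 3.

Start-site strength follows the classical Kozak two-feature rule: a purine
(A/G) at position -3 and a G at +4 relative to the A of the AUG. Both
features -> Strong, exactly one -> Moderate, neither -> Weak. Positions
before the transcript cap are padded with N, which fails both tests; the +4
base of an AUG ending at the UTR/CDS junction is read from the CDS.

All functions here are pure and operate on plain uppercase DNA strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

STRONG = "Strong"
MODERATE = "Moderate"
WEAK = "Weak"

UORF = "uORF"
INFRAME_OORF = "inframe_oORF"
OUTOFFRAME_OORF = "OutOfFrame_oORF"


@dataclass(frozen=True)
class KozakAssessment:
    """7-mer context (-3..+4, AUG at characters 4-6) and its strength class."""

    context: str
    strength: str


@dataclass(frozen=True)
class UorfRecord:
    """One (u)ORF anchored at an AUG of the 5'UTR.

    ``stop_offset`` is the offset of the first base of the first in-frame stop
    codon in the concatenation UTR + CDS context (None if none within the
    scanning horizon); ``stop_in_utr`` is True only when that stop lies wholly
    within the UTR, which is also exactly when ``subtype == "uORF"``.
    """

    start_offset: int
    stop_offset: Optional[int]
    subtype: str
    kozak: KozakAssessment
    stop_in_utr: bool


@dataclass(frozen=True)
class UorfCensus:
    """Counts of existing (u)ORFs in a reference 5'UTR, by subtype."""

    n_uorf: int = 0
    n_inframe_oorf: int = 0
    n_outofframe_oorf: int = 0

    @property
    def total(self) -> int:
        return self.n_uorf + self.n_inframe_oorf + self.n_outofframe_oorf


def find_uaugs(utr_sequence: str) -> list[int]:
    """Ascending offsets of every ATG in the UTR (overlapping hits included)."""
    return [i for i in range(len(utr_sequence) - 2) if utr_sequence[i : i + 3] == "ATG"]


def kozak_assess(utr_sequence: str, cds_context: str, start_offset: int) -> KozakAssessment:
    """Kozak context and strength of the AUG at ``start_offset``."""
    if utr_sequence[start_offset : start_offset + 3] != "ATG":
        raise ValueError(f"no AUG at offset {start_offset}")
    n_utr = len(utr_sequence)
    chars = []
    for p in range(start_offset - 3, start_offset + 4):
        if p < 0:
            chars.append("N")
        elif p < n_utr:
            chars.append(utr_sequence[p])
        elif p - n_utr < len(cds_context):
            chars.append(cds_context[p - n_utr])
        else:
            chars.append("N")
    context = "".join(chars)
    minus3 = context[0] in "AG"
    plus4 = context[6] == "G"
    if minus3 and plus4:
        strength = STRONG
    elif minus3 or plus4:
        strength = MODERATE
    else:
        strength = WEAK
    return KozakAssessment(context=context, strength=strength)


def scan_orf(start_offset: int, utr_sequence: str, cds_context: str) -> UorfRecord:
    """Walk codons from an AUG and classify the resulting (u)ORF.

    The walk proceeds through the UTR and on into ``cds_context`` (the
    scanning horizon). A stop codon straddling the UTR/CDS junction counts as
    not-in-UTR, so it never makes a uORF, but it does terminate an
    out-of-frame oORF.
    """
    if utr_sequence[start_offset : start_offset + 3] != "ATG":
        raise ValueError(f"no AUG at offset {start_offset}")
    n_utr = len(utr_sequence)
    concat = utr_sequence + cds_context
    stop_offset: Optional[int] = None
    stop_in_utr = False
    for i in range(start_offset, len(concat) - 2, 3):
        if concat[i : i + 3] in STOP_CODONS:
            stop_offset = i
            stop_in_utr = i + 3 <= n_utr
            break
    if stop_in_utr:
        subtype = UORF
    elif (n_utr - start_offset) % 3 == 0:
        subtype = INFRAME_OORF
    else:
        subtype = OUTOFFRAME_OORF
    return UorfRecord(
        start_offset=start_offset,
        stop_offset=stop_offset,
        subtype=subtype,
        kozak=kozak_assess(utr_sequence, cds_context, start_offset),
        stop_in_utr=stop_in_utr,
    )


def scan_all_orfs(utr_sequence: str, cds_context: str) -> list[UorfRecord]:
    """One UorfRecord per AUG in the UTR, in ascending start order."""
    return [scan_orf(i, utr_sequence, cds_context) for i in find_uaugs(utr_sequence)]


def census(utr_sequence: str, cds_context: str) -> UorfCensus:
    """Count existing (u)ORFs in a reference 5'UTR, grouped by subtype."""
    n = {UORF: 0, INFRAME_OORF: 0, OUTOFFRAME_OORF: 0}
    for rec in scan_all_orfs(utr_sequence, cds_context):
        n[rec.subtype] += 1
    return UorfCensus(
        n_uorf=n[UORF],
        n_inframe_oorf=n[INFRAME_OORF],
        n_outofframe_oorf=n[OUTOFFRAME_OORF],
    )
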