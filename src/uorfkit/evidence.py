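"""Curated translated-uORF evidence (ribosome-profiling support).

Entries are keyed by (chromosome, 1-based genomic position of the uAUG
first base, strand), so one evidence row supports the same uAUG across every
overlapping transcript. Profiling datasets are incomplete, so evidence is
reported as an annotation and never used as a filter at annotation time.

File contract: a tab-separated file with a header containing at least the
columns ``chrom``, ``start_pos`` (1-based) and ``strand``; extra columns are
ignored, malformed rows are skipped with a warning, duplicates collapse.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("chrom", "start_pos", "strand")


@dataclass
class EvidenceStore:
    """Set of translated-uORF start sites, keyed genomically."""

    entries: set[tuple[str, int, str]] = field(default_factory=set)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def contains(self, chrom: str, pos_1based: int, strand: str) -> bool:
        return (chrom, pos_1based, strand) in self.entries


def load_evidence(tsv_path) -> EvidenceStore:
    """Load a translated-uORF TSV into an :class:`EvidenceStore`."""
    if not os.path.exists(tsv_path):
        raise FileNotFoundError(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence file {tsv_path} lacks columns: {', '.join(missing)}")
    entries: set[tuple[str, int, str]] = set()
    n_bad = n_dup = 0
    for row in df.itertuples(index=False):
        chrom, pos_s, strand = row.chrom, row.start_pos, row.strand
        try:
            pos = int(pos_s)
        except (TypeError, ValueError):
            n_bad += 1
            log.warning("evidence row with non-integer start_pos %r skipped", pos_s)
            continue
        if pos < 1 or strand not in ("+", "-") or not isinstance(chrom, str):
            n_bad += 1
            log.warning("malformed evidence row (%r, %r, %r) skipped", chrom, pos_s, strand)
            continue
        key = (chrom, pos, strand)
        if key in entries:
            n_dup += 1
        else:
            entries.add(key)
    if n_dup:
        log.warning("%d duplicate evidence entries collapsed", n_dup)
    if n_bad:
        log.warning("%d malformed evidence rows skipped", n_bad)
    return EvidenceStore(entries=entries, source_label=str(tsv_path))


def has_evidence(store: EvidenceStore, tx, utr, uorf) -> bool:
    """Whether the uORF's start site has documented translation evidence.

    ``uorf`` is a UorfRecord on the reference 5'UTR of transcript ``tx``; its
    start offset is mapped to a 1-based genomic position through the UTR map.
    """
    gpos = utr.genomic_positions[uorf.start_offset] + 1
    return store.contains(tx.chrom, gpos, tx.strand)
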