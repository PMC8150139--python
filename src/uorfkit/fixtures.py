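"""Seeded generator of self-consistent mini FASTA + GTF + VCF fixture trios.

Two families are provided:

* :func:`make_static_fixtures` — two hand-verified transcripts (F1, an
  AUG-free 5'UTR; F2, a 5'UTR carrying one uORF) with five variants covering
  all five consequence classes, each built on both strands and in one- and
  two-exon versions, together with the expected annotation table.
* :func:`make_random_fixture` — random transcripts and 1-5 bp variants whose
  expected consequences are computed by the independent brute-force oracle
  (never by the engine under test), with rejection sampling so every
  consequence class is represented in large fixtures.

The same seed always produces a byte-identical bundle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import oracle
from .transcripts import reverse_complement

PAD = 50  # flanking genome padding either side of the transcript
INTRON_LEN = 37

_LEFT_PAD = ("TTCTTCTTCA" * 5)[:PAD]
_RIGHT_PAD = ("CTTCTTCTTC" * 5)[:PAD]
_INTRON = "GT" + "C" * (INTRON_LEN - 4) + "AG"

F1_UTR = "GGCACCCTGGAAGTAAGGCGGCTTTCCGGC"
F1_CDS = "ATGGCTGCAGGCGGAAGTGGCGGATCTTAA"
F2_UTR = "GCCATGAAATAGCCGGCTTTCCGGCAAGGC"
F2_CDS = "ATGGCTGCATAA"

# (variant id, UTR offset, replaced length, replacement in transcript orientation)
F1_VARIANTS = [("V1", 6, 1, "A")]
F2_VARIANTS = [
    ("V2", 4, 1, "C"),
    ("V3", 10, 1, "G"),
    ("V4", 6, 1, "T"),
    ("V5", 7, 1, ""),
]

_NA = "NA"


def _template(**kw) -> dict:
    cols = dict.fromkeys(
        [
            "consequence", "existing_uORFs", "existing_InFrame_oORFs",
            "existing_OutOfFrame_oORFs", "KozakContext", "KozakStrength",
            "CapDistanceToStart", "StartDistanceToCDS", "StartDistanceToStop",
            "Type", "AltType", "Evidence", "AltStop", "AltStopDistanceToCDS",
            "FrameWithCDS", "NewStopDistanceToCDS",
        ],
        _NA,
    )
    cols.update({k: str(v) for k, v in kw.items()})
    return cols


# Hand-verified expected rows, in transcript space (genomic fields filled per
# bundle). V3 is deliberately multi-consequence: destroying the uORF's TAG
# also turns the ATA at offsets 8-10 into a new out-of-frame ATG.
F1_TRUTH = {
    "V1": [
        _template(
            consequence="uAUG_gained", existing_uORFs=0, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="ACCATGG", KozakStrength="Strong",
            CapDistanceToStart=6, StartDistanceToCDS=24, Type="inframe_oORF",
        )
    ]
}
F2_TRUTH = {
    "V2": [
        _template(
            consequence="uAUG_lost", existing_uORFs=1, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="GCCATGA", KozakStrength="Moderate",
            StartDistanceToCDS=27, StartDistanceToStop=6, Type="uORF", Evidence=False,
        )
    ],
    "V3": [
        _template(
            consequence="uAUG_gained", existing_uORFs=1, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="GAAATGG", KozakStrength="Strong",
            CapDistanceToStart=8, StartDistanceToCDS=22, Type="OutOfFrame_oORF",
        ),
        _template(
            consequence="uSTOP_lost", existing_uORFs=1, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="GCCATGA", KozakStrength="Moderate",
            Evidence=False, AltStop=False, FrameWithCDS="inFrame",
        ),
    ],
    "V4": [
        _template(
            consequence="uSTOP_gained", existing_uORFs=1, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="GCCATGA", KozakStrength="Moderate",
            StartDistanceToCDS=27, Type="uORF", Evidence=False, NewStopDistanceToCDS=24,
        )
    ],
    "V5": [
        _template(
            consequence="uFrameshift", existing_uORFs=1, existing_InFrame_oORFs=0,
            existing_OutOfFrame_oORFs=0, KozakContext="GCCATGA", KozakStrength="Moderate",
            StartDistanceToCDS=26, Type="uORF", AltType="OutOfFrame_oORF", Evidence=False,
        )
    ],
}


@dataclass
class FixtureBundle:
    """A self-consistent mini genome + annotation + variants, with truth."""

    name: str
    fasta_text: str
    gtf_text: str
    vcf_text: str
    truth_rows: list[dict]
    seed: int
    meta: dict = field(default_factory=dict)

    def write(self, dirpath) -> dict:
        """Write the trio under ``dirpath``; returns the three paths."""
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, text, suffix in (
            ("fasta", self.fasta_text, ".fa"),
            ("gtf", self.gtf_text, ".gtf"),
            ("vcf", self.vcf_text, ".vcf"),
        ):
            p = d / f"{self.name}{suffix}"
            p.write_text(text)
            paths[key] = str(p)
        return paths


def _wrap_fasta(chrom: str, seq: str) -> str:
    lines = [f">{chrom}"]
    lines += [seq[i : i + 60] for i in range(0, len(seq), 60)]
    return "\n".join(lines) + "\n"


def _blocks(boundaries: list[int]) -> list[tuple[int, int]]:
    return list(zip(boundaries[:-1], boundaries[1:]))


class _TranscriptLayout:
    """Arithmetic bookkeeping for one fixture transcript placed on a genome."""

    def __init__(self, chrom, transcript_id, gene_id, gene_symbol,
                 utr, cds, strand, splits):
        self.chrom = chrom
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        self.gene_symbol = gene_symbol
        self.utr, self.cds, self.strand = utr, cds, strand
        self.splits = list(splits)
        tx_seq = utr + cds
        self.tx_seq = tx_seq
        parts, prev = [], 0
        for s in self.splits:
            parts.append(tx_seq[prev:s])
            parts.append(_INTRON)
            prev = s
        parts.append(tx_seq[prev:])
        layout = "".join(parts)
        self.layout_len = len(layout)
        region = layout if strand == "+" else reverse_complement(layout)
        self.chrom_seq = _LEFT_PAD + region + _RIGHT_PAD

    def _layout_off(self, t: int) -> int:
        return t + INTRON_LEN * sum(1 for s in self.splits if s <= t)

    def g(self, t: int) -> int:
        """Genomic 0-based position of transcript offset ``t``."""
        off = self._layout_off(t)
        if self.strand == "+":
            return PAD + off
        return PAD + self.layout_len - 1 - off

    def utr_blocks(self) -> list[tuple[int, int]]:
        """Exon blocks restricted to the UTR, in transcript offsets."""
        bounds = [0] + [s for s in self.splits if s < len(self.utr)] + [len(self.utr)]
        return _blocks(bounds)

    def gtf(self) -> str:
        n = len(self.tx_seq)
        bounds = [0] + self.splits + [n]
        attrs = (
            f'gene_id "{self.gene_id}"; transcript_id "{self.transcript_id}"; '
            f'gene_name "{self.gene_symbol}";'
        )
        feats = []
        for a, b in _blocks(bounds):
            gs = sorted((self.g(a), self.g(b - 1)))
            feats.append((gs[0], "exon", gs[0] + 1, gs[1] + 1, "."))
        cds_lo, cds_hi = len(self.utr), n
        cum = 0
        for a, b in _blocks(bounds):
            ca, cb = max(a, cds_lo), min(b, cds_hi)
            if ca >= cb:
                continue
            frame = (3 - cum % 3) % 3
            cum += cb - ca
            gs = sorted((self.g(ca), self.g(cb - 1)))
            feats.append((gs[0], "CDS", gs[0] + 1, gs[1] + 1, str(frame)))
        feats.sort(key=lambda f: (f[0], f[1]))
        lines = [
            "\t".join(
                [self.chrom, "fixture", kind, str(s1), str(s2), ".", self.strand, frame, attrs]
            )
            for _, kind, s1, s2, frame in feats
        ]
        return "\n".join(lines) + "\n"

    def vcf_record(self, vid: str, t_off: int, ref_len: int, alt_seg: str):
        """(pos1, ref, alt) of an edit given in transcript orientation."""
        cs, g = self.chrom_seq, self.g
        if ref_len == len(alt_seg):  # substitution
            if self.strand == "+":
                pos0 = g(t_off)
                ref = self.tx_seq[t_off : t_off + ref_len]
                alt = alt_seg
            else:
                pos0 = g(t_off + ref_len - 1)
                ref = reverse_complement(self.tx_seq[t_off : t_off + ref_len])
                alt = reverse_complement(alt_seg)
        elif not alt_seg:  # pure deletion, left-anchored
            span = sorted(g(t) for t in range(t_off, t_off + ref_len))
            anchor = span[0] - 1
            ref = cs[anchor : span[-1] + 1]
            alt = cs[anchor]
            pos0 = anchor
        elif ref_len == 0:  # pure insertion, left-anchored
            if self.strand == "+":
                anchor = g(t_off - 1)
                ins = alt_seg
            else:
                anchor = g(t_off)
                ins = reverse_complement(alt_seg)
            ref = cs[anchor]
            alt = ref + ins
            pos0 = anchor
        else:
            raise ValueError("fixture edits must be pure substitutions, insertions or deletions")
        return vid, pos0 + 1, ref, alt


def _vcf_text(chrom: str, chrom_len: int, records) -> str:
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_len}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = [
        "\t".join([chrom, str(pos), vid, ref, alt, ".", ".", "."])
        for vid, pos, ref, alt in records
    ]
    return "\n".join(header + body) + "\n"


def _static_bundle(base: str, utr: str, cds: str, strand: str, n_exons: int,
                   variants, truth_by_vid) -> FixtureBundle:
    splits = [13] if n_exons == 2 else []
    chrom = "chr1"
    lay = _TranscriptLayout(
        chrom, f"TX_{base}", f"GENE_{base}", base, utr, cds, strand, splits
    )
    recs = [lay.vcf_record(vid, o, rl, seg) for vid, o, rl, seg in variants]
    recs.sort(key=lambda r: r[1])
    truth = []
    for vid, pos, ref, alt in recs:
        for tmpl in truth_by_vid[vid]:
            row = dict(tmpl)
            row.update(
                chrom=chrom, pos=str(pos), ref=ref, alt=alt,
                transcript_id=lay.transcript_id, gene_id=lay.gene_id,
            )
            truth.append(row)
    name = f"{base}_{'plus' if strand == '+' else 'minus'}_{n_exons}exon"
    return FixtureBundle(
        name=name,
        fasta_text=_wrap_fasta(chrom, lay.chrom_seq),
        gtf_text=lay.gtf(),
        vcf_text=_vcf_text(chrom, len(lay.chrom_seq), recs),
        truth_rows=truth,
        seed=0,
        meta={
            "chrom": chrom,
            "strand": strand,
            "utr": utr,
            "cds": cds,
            "transcript_id": lay.transcript_id,
            "gene_id": lay.gene_id,
            "tpos": [lay.g(t) for t in range(len(utr + cds))],
            "records": recs,
        },
    )


def make_static_fixtures() -> list[FixtureBundle]:
    """The hand-verified F1/F2 bundles on both strands, 1- and 2-exon."""
    out = []
    for strand in "+-":
        for n_exons in (1, 2):
            out.append(_static_bundle("F1", F1_UTR, F1_CDS, strand, n_exons,
                                      F1_VARIANTS, F1_TRUTH))
            out.append(_static_bundle("F2", F2_UTR, F2_CDS, strand, n_exons,
                                      F2_VARIANTS, F2_TRUTH))
    return out


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_edit(rng: random.Random, lay: _TranscriptLayout):
    """A random minimal 1-5 bp edit wholly inside one UTR exon block, or None."""
    utr = lay.utr
    kind = rng.choices(["snv", "mnv", "ins", "del"], weights=[40, 15, 20, 25])[0]
    blocks = lay.utr_blocks()
    if kind == "snv":
        bs, be = rng.choice(blocks)
        o = rng.randrange(bs, be)
        base = rng.choice([b for b in "ACGT" if b != utr[o]])
        return (o, 1, base)
    if kind == "mnv":
        n = rng.randint(2, 5)
        ok = [(bs, be) for bs, be in blocks if be - bs >= n]
        if not ok:
            return None
        bs, be = rng.choice(ok)
        o = rng.randrange(bs, be - n + 1)
        seg = utr[o : o + n]
        alt = (
            rng.choice([b for b in "ACGT" if b != seg[0]])
            + _random_seq(rng, n - 2)
            + rng.choice([b for b in "ACGT" if b != seg[-1]])
        )
        return (o, n, alt)
    if kind == "ins":
        ok = [(bs, be) for bs, be in blocks if be - bs >= 2]
        if not ok:
            return None
        bs, be = rng.choice(ok)
        o = rng.randrange(bs + 1, be)
        return (o, 0, _random_seq(rng, rng.randint(1, 5)))
    n = rng.randint(1, 5)
    ok = [(bs, be) for bs, be in blocks if be - bs >= n]
    if not ok:
        return None
    bs, be = rng.choice(ok)
    o = rng.randrange(bs, be - n + 1)
    return (o, n, "")


_CLASS_CYCLE = [
    "uAUG_gained", "uAUG_lost", "uSTOP_lost", "uSTOP_gained", "uFrameshift", None,
]


def make_random_fixture(seed: int, n_transcripts: int = 5, n_variants: int = 30) -> FixtureBundle:
    """A random bundle whose truth is computed by the brute-force oracle.

    UTR lengths are drawn from 10-300 nt at GC ~ 0.5 with 1-3 exons per
    transcript (one transcript per chromosome); variants are 1-5 bp edits
    placed in UTRs, with class-balancing rejection sampling so that all five
    consequence classes appear once the fixture is large enough.
    """
    if n_transcripts < 1 or n_variants < 1:
        raise ValueError("n_transcripts and n_variants must be >= 1")
    rng = random.Random(seed)
    layouts = []
    for i in range(n_transcripts):
        utr = _random_seq(rng, rng.randint(10, 300))
        cds = "ATG" + _random_seq(rng, 3 * rng.randint(4, 40)) + "TAA"
        strand = rng.choice("+-")
        n_exons = rng.randint(1, 3)
        splits = (
            sorted(rng.sample(range(1, len(utr + cds)), n_exons - 1))
            if n_exons > 1
            else []
        )
        layouts.append(
            _TranscriptLayout(
                f"chr{i + 1}", f"TX{i + 1:03d}", f"GENE{i + 1:03d}", f"G{i + 1}",
                utr, cds, strand, splits,
            )
        )
    records_by_chrom: dict[str, list] = {lay.chrom: [] for lay in layouts}
    truth = []  # (vid, transcript_id, oracle tuples)
    seen: set[tuple] = set()  # one VCF record per distinct (chrom, pos, ref, alt)
    for j in range(n_variants):
        target = _CLASS_CYCLE[j % len(_CLASS_CYCLE)]
        vid = f"v{j + 1}"
        chosen = None
        for _ in range(300):
            lay = rng.choice(layouts)
            edit = random_edit(rng, lay)
            if edit is None:
                continue
            rec = lay.vcf_record(vid, *edit)
            if (lay.chrom, rec[1], rec[2], rec[3]) in seen:
                continue
            tuples = oracle.classify(lay.utr, lay.cds[:999], *edit)
            if target is None or any(t[0] == target for t in tuples):
                chosen = (lay, rec, tuples)
                break
            if chosen is None:
                chosen = (lay, rec, tuples)  # keep first candidate as fallback
        if chosen is None:
            continue
        lay, rec, tuples = chosen
        seen.add((lay.chrom, rec[1], rec[2], rec[3]))
        records_by_chrom[lay.chrom].append(rec)
        truth.append((vid, lay.transcript_id, tuples))
    fasta = "".join(_wrap_fasta(lay.chrom, lay.chrom_seq) for lay in layouts)
    gtf = "".join(lay.gtf() for lay in layouts)
    header = ["##fileformat=VCFv4.2"]
    header += [
        f"##contig=<ID={lay.chrom},length={len(lay.chrom_seq)}>" for lay in layouts
    ]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    body = []
    records = []
    for lay in layouts:
        recs = sorted(records_by_chrom[lay.chrom], key=lambda r: r[1])
        for vid, pos, ref, alt in recs:
            body.append("\t".join([lay.chrom, str(pos), vid, ref, alt, ".", ".", "."]))
            records.append((lay.chrom, vid, pos, ref, alt))
    return FixtureBundle(
        name=f"random_seed{seed}",
        fasta_text=fasta,
        gtf_text=gtf,
        vcf_text="\n".join(header + body) + "\n",
        truth_rows=[],
        seed=seed,
        meta={
            "oracle_truth": {vid: (tid, tuples) for vid, tid, tuples in truth},
            "records": records,
            "layouts": {
                lay.transcript_id: {
                    "chrom": lay.chrom, "strand": lay.strand,
                    "utr": lay.utr, "cds": lay.cds, "splits": lay.splits,
                }
                for lay in layouts
            },
        },
    )


def make_strand_mirror_pair(seed: int, n_variants: int = 10) -> tuple[FixtureBundle, FixtureBundle]:
    """Two bundles with the same transcript-space content on opposite strands.

    The minus bundle is the reverse-complement mirror of the plus bundle:
    same spliced UTR/CDS, same UTR-space edits, mirrored genome coordinates.
    Annotation rows must agree between the two up to genomic fields.
    """
    rng = random.Random(seed)
    utr = _random_seq(rng, rng.randint(20, 200))
    cds = "ATG" + _random_seq(rng, 3 * rng.randint(4, 20)) + "TAA"
    n_splits = rng.randint(0, 2)
    splits = sorted(rng.sample(range(1, len(utr + cds)), n_splits)) if n_splits else []
    probe = _TranscriptLayout("chr1", "TX_M", "GENE_M", "M", utr, cds, "+", splits)
    edits = []
    for j in range(n_variants):
        e = None
        while e is None:
            e = random_edit(rng, probe)
        edits.append((f"v{j + 1}",) + e)
    out = []
    for strand in "+-":
        lay = _TranscriptLayout("chr1", "TX_M", "GENE_M", "M", utr, cds, strand, splits)
        recs = [lay.vcf_record(*e) for e in edits]
        recs.sort(key=lambda r: r[1])
        truth = {
            vid: oracle.classify(utr, cds[:999], o, rl, seg)
            for vid, o, rl, seg in edits
        }
        out.append(
            FixtureBundle(
                name=f"mirror_{'plus' if strand == '+' else 'minus'}_seed{seed}",
                fasta_text=_wrap_fasta("chr1", lay.chrom_seq),
                gtf_text=lay.gtf(),
                vcf_text=_vcf_text("chr1", len(lay.chrom_seq), recs),
                truth_rows=[],
                seed=seed,
                meta={
                    "records": [("chr1",) + r for r in recs],
                    "oracle_truth": {vid: ("TX_M", t) for vid, t in truth.items()},
                    "utr": utr,
                    "cds": cds,
                    "strand": strand,
                },
            )
        )
    return out[0], out[1]


def random_sequence_cases(seed: int, n: int):
    """Yield (utr, cds_context, edit) triples for sequence-level property tests.

    UTRs of length 10-300 at GC ~ 0.5 with a short CDS context; edits are
    random minimal 1-5 bp substitutions, insertions or deletions.
    """
    rng = random.Random(seed)
    for _ in range(n):
        utr = _random_seq(rng, rng.randint(10, 300))
        cds = "ATG" + _random_seq(rng, 3 * rng.randint(2, 30)) + "TAA"
        lay = _TranscriptLayout("c", "t", "g", "s", utr, cds, "+", [])
        edit = None
        while edit is None:
            edit = random_edit(rng, lay)
        yield utr, cds, edit
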