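"""Transcript model construction, spliced-UTR extraction and coordinate maps."""

import pytest
from pyfaidx import Fasta

from uorfkit import extract_spliced_utr, genomic_to_utr_offset, load_transcripts
from uorfkit.fixtures import F1_CDS, F1_UTR, F2_CDS, F2_UTR
from uorfkit.transcripts import GenomeInterval, reverse_complement


ALL_BUNDLES = [
    f"{base}_{strand}_{n}exon"
    for base in ("F1", "F2")
    for strand in ("plus", "minus")
    for n in (1, 2)
]


@pytest.mark.parametrize("name", ALL_BUNDLES)
def test_spliced_utr_matches_construction(name, load_bundle):
    """The extracted spliced UTR and CDS context equal the planted sequences,
    regardless of strand and exon count (splicing drops intron bases)."""
    bundle, paths, _ = load_bundle(name)
    txs = load_transcripts(paths["gtf"], paths["fasta"])
    assert len(txs) == 1
    tx = txs[0]
    genome = Fasta(paths["fasta"])
    utr = extract_spliced_utr(tx, genome)
    assert utr.sequence == bundle.meta["utr"]
    assert utr.utr_length == len(bundle.meta["utr"])
    assert utr.cds_context == bundle.meta["cds"]
    assert set(utr.sequence) <= set("ACGTN")


@pytest.mark.parametrize("name", ALL_BUNDLES)
def test_coordinate_round_trip(name, load_bundle):
    """genomic_to_utr_offset inverts the genomic_positions map at every offset,
    and positions are strictly monotonic within each exon."""
    bundle, paths, _ = load_bundle(name)
    tx = load_transcripts(paths["gtf"], paths["fasta"])[0]
    utr = extract_spliced_utr(tx, Fasta(paths["fasta"]))
    for i, gpos in enumerate(utr.genomic_positions):
        assert genomic_to_utr_offset(utr, gpos) == i
    step = 1 if tx.strand == "+" else -1
    diffs = {
        b - a for a, b in zip(utr.genomic_positions, utr.genomic_positions[1:])
    }
    assert step in diffs  # consecutive within-exon steps follow the strand


def test_intronic_and_cds_positions_map_to_none(load_bundle):
    bundle, paths, _ = load_bundle("F2_plus_2exon")
    tx = load_transcripts(paths["gtf"], paths["fasta"])[0]
    utr = extract_spliced_utr(tx, Fasta(paths["fasta"]))
    tpos = bundle.meta["tpos"]
    intronic = tpos[12] + 1  # first intron base (split after UTR offset 12)
    assert genomic_to_utr_offset(utr, intronic) is None
    cds_pos = tpos[len(bundle.meta["utr"])]
    assert genomic_to_utr_offset(utr, cds_pos) is None


def test_minus_strand_mirror_yields_identical_utr(load_bundle):
    """A minus-strand mirror transcript produces a byte-identical spliced UTR."""
    _, p_plus, _ = load_bundle("F2_plus_1exon")
    _, p_minus, _ = load_bundle("F2_minus_1exon")
    seqs = []
    for paths in (p_plus, p_minus):
        tx = load_transcripts(paths["gtf"], paths["fasta"])[0]
        seqs.append(extract_spliced_utr(tx, Fasta(paths["fasta"])).sequence)
    assert seqs[0] == seqs[1] == F2_UTR


def _write(tmp_path, fasta, gtf):
    fa = tmp_path / "g.fa"
    fa.write_text(fasta)
    gt = tmp_path / "a.gtf"
    gt.write_text(gtf)
    return str(gt), str(fa)


def test_zero_length_utr_transcript_skipped(tmp_path, caplog):
    """A transcript whose CDS starts at exon base 1 has no 5'UTR and is skipped."""
    seq = "ATG" + "GCA" * 9 + "TAA"
    fasta = f">c1\n{seq}\n"
    attrs = 'gene_id "g"; transcript_id "t";'
    gtf = (
        f"c1\tx\texon\t1\t{len(seq)}\t.\t+\t.\t{attrs}\n"
        f"c1\tx\tCDS\t1\t{len(seq)}\t.\t+\t0\t{attrs}\n"
    )
    with caplog.at_level("WARNING"):
        models = load_transcripts(*_write(tmp_path, fasta, gtf))
    assert models == []
    assert any("zero-length" in r.message for r in caplog.records)


def test_chromosome_missing_from_fasta_skipped(tmp_path, caplog):
    fasta = ">c1\nACGTACGTACGTACGTACGT\n"
    attrs = 'gene_id "g"; transcript_id "t";'
    gtf = (
        f"c2\tx\texon\t1\t20\t.\t+\t.\t{attrs}\n"
        f"c2\tx\tCDS\t10\t20\t.\t+\t0\t{attrs}\n"
    )
    with caplog.at_level("WARNING"):
        models = load_transcripts(*_write(tmp_path, fasta, gtf))
    assert models == []
    assert any("absent from FASTA" in r.message for r in caplog.records)


def test_start_codon_feature_sets_cds_start(tmp_path):
    """An explicit start_codon feature fixes the CDS start even when the GTF
    also lists (possibly differently sorted) CDS intervals."""
    seq = "C" * 9 + "ATG" + "GCA" * 5 + "TAA"
    fasta = f">c1\n{seq}\n"
    attrs = 'gene_id "g"; transcript_id "t";'
    gtf = (
        f"c1\tx\texon\t1\t{len(seq)}\t.\t+\t.\t{attrs}\n"
        f"c1\tx\tCDS\t10\t{len(seq)}\t.\t+\t0\t{attrs}\n"
        f"c1\tx\tstart_codon\t10\t12\t.\t+\t0\t{attrs}\n"
    )
    models = load_transcripts(*_write(tmp_path, fasta, gtf))
    assert len(models) == 1
    assert models[0].cds_start_genomic == 9
    utr = extract_spliced_utr(models[0], Fasta(str(tmp_path / "g.fa")))
    assert utr.sequence == "C" * 9
    assert utr.cds_context.startswith("ATG")


def test_missing_input_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_transcripts(tmp_path / "nope.gtf", tmp_path / "nope.fa")


def test_genome_interval_validation():
    with pytest.raises(ValueError):
        GenomeInterval("c", 5, 5, "+")
    with pytest.raises(ValueError):
        GenomeInterval("c", 0, 5, ".")


def test_reverse_complement_round_trip():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement(reverse_complement(F1_UTR + F1_CDS)) == F1_UTR + F1_CDS
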