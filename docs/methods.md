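# Methods

## Model and procedure

A transcript is modelled by its exon structure, strand and the genomic
position of the first base of its annotated start codon. The spliced 5′UTR
is reconstructed in transcript orientation (offset 0 at the cap, last base
adjacent to the CDS), with a per-base map back to genomic coordinates, and
is followed by a window of spliced CDS ("CDS context") used as the scanning
horizon for ORFs that overlap the coding sequence.

An upstream ORF is anchored at any canonical AUG in the UTR. Codons are
read from that AUG; the first of TAA/TAG/TGA wholly inside the UTR makes a
distinct **uORF**. If no stop falls in the UTR, the ORF overlaps the CDS:
**inframe_oORF** when `(utr_length − start) mod 3 == 0` (an N-terminal
extension terminating at the main stop), else **OutOfFrame_oORF**. A stop
codon straddling the UTR/CDS junction terminates an out-of-frame oORF but
never creates a uORF. Every AUG defines its own ORF even when several share
a stop codon — each start site is independently perturbable, and the census
counts AUGs, not stop-delimited intervals.

Each variant is normalized (shared prefix trimmed first, then shared
suffix), projected into UTR offset space (reverse-complemented on minus
strands), applied to the spliced UTR, and passed through five detectors:

* **uAUG_gained** — an AUG in the alternate UTR whose 3-base window touches
  the edit and whose three bases do not all map to a contiguous reference
  ATG. The mapping is positional identity for same-length substitutions and
  block-shift for indels, so AUGs merely shifted by an upstream indel are
  never called gained.
* **uAUG_lost** — a reference AUG touching the edit that no longer reads
  ATG at its mapped position in the alternate UTR.
* **uSTOP_lost** — a uORF (stop wholly in the UTR, start intact) whose stop
  codon touches the edit and is not a stop at its mapped, in-frame position
  in the alternate allele. The alternative-stop search is confined to the
  alternate 5′UTR, strictly downstream of the old stop position; when no
  alternative exists the row instead reports the frame of the now
  CDS-overlapping ORF (`inFrame`/`outOfFrame`).
* **uSTOP_gained** — a (u)ORF with intact start whose alternate-allele walk
  meets an in-UTR stop that touches the edit and falls strictly before the
  (mapped) reference stop — or meets any in-UTR stop, for oORFs that had
  none.
* **uFrameshift** — an indel with net length change not divisible by three
  whose edited bases fall inside an ORF body (start through the stop's last
  base, through the UTR end for oORFs), start intact. The subtype is
  re-derived on both alleles.

A variant with several consequences, or affecting several uORFs, yields one
row per (transcript × consequence × uORF); rows sort by transcript, then a
fixed consequence order (gained, lost, stop-lost, stop-gained, frameshift),
then start offset, so output is byte-stable.

Distances are measured on the allele where the feature exists: the
alternate UTR for gained features and frameshifted starts, the reference
UTR for lost features. For gained uAUGs, cap→start plus start→CDS always
equals the alternate UTR length. Start→stop distance is first-stop-base
minus first-start-base; it is NA for in-frame oORFs (their stop is the main
CDS stop) and read within the CDS-context horizon for out-of-frame oORFs.

**Kozak strength.** The cited consensus work does not fix a discrete rule,
so the package adopts the conventional two-feature reading: Strong when the
−3 base is A/G **and** the +4 base is G, Moderate when exactly one holds,
Weak otherwise. The 7-mer context (−3..+4) pads with N before the cap
(N fails both tests) and reads the +4 base across the UTR/CDS junction,
since that base exists regardless of the annotation boundary. A
position-weight-matrix score was deliberately not used: the three-way class
is what downstream prioritization consumes.

**Evidence.** Translated-uORF support is keyed by (chromosome, 1-based
genomic position of the uAUG first base, strand) so that one evidence entry
covers the same uAUG in every overlapping transcript. Because profiling
compendia are incomplete, evidence is reported as an annotation, never used
as a filter at annotation time; with no evidence file loaded, disrupting
consequences report `False` and `uAUG_gained` always reports NA (a new uORF
cannot have pre-existing support).

**Prioritization.** A row is high-impact when (A) its resulting ORF
overlaps the CDS — a gained oORF, a stop loss with no alternative stop, or
a frameshift whose alternate subtype is an oORF — and its start site is
Strong or Moderate, or (B) it disrupts an existing uORF with documented
translation evidence. Condition B deliberately does not gate on Kozak
strength: the evidence that the uORF is translated supersedes the sequence
heuristic. An optional gene list (ids or symbols) restricts either route.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_indel_len` | 5 bp | longest allele length annotated; longer variants are counted and skipped (interpreted as `max(len(ref), len(alt))` after trimming) |
| `cds_scan_horizon` | 999 nt | CDS context length for oORF stop scanning; no stop within the horizon reports NA |
| `output_format` | `tsv` | `tsv` or `vcf` (UTRA INFO key, pipe-delimited fields) |

Coordinates are 1-based inclusive in GTF/VCF files and 0-based half-open
everywhere in memory; conversion happens only at the I/O boundary, which is
what keeps the distance fields free of off-by-one ambiguity.

## Scope rules and degenerate inputs

Only variants whose reference bases lie wholly within one transcript's
5′UTR exonic sequence are annotated for that transcript; alleles touching
intron, CDS or a splice junction — and pure insertions at a UTR boundary or
junction, whose placement is ambiguous — are skipped with a logged notice.
Symbolic alleles, reference mismatches and oversize variants are skipped
and counted per reason. Multi-allelic records are decomposed per alternate
allele before normalization. Soft-masked genome bases are uppercased; N
propagates and can never form an AUG or stop. If a fixture VCF contains two
identical records, the VCF writer attaches the same annotation entries to
each (rows are matched to records by chrom/pos/ref/alt).

## Synthetic data

The fixture generator emulates the minimal genomic context the annotator
consumes: short chromosomes with padded, single-transcript loci; spliced
UTRs of 10–300 nt at GC ≈ 0.5 with 1–3 exons; CDSs opening with ATG and
closing with TAA; and 1–5 bp variants placed in UTR exons, rejection-sampled
so all five consequence classes appear in large cohorts. Expected
annotations for random fixtures are computed by a brute-force oracle that
shares no code with the engine (regex start finding and an explicit
base-provenance list, versus the engine's codon walk and arithmetic window
mapping). The generator does not emulate overlapping transcripts sharing a
locus, non-canonical splice sites, repetitive sequence requiring indel
left-alignment conventions, chromosome-scale coordinates or realistic GC
structure — so passing tests demonstrate the correctness of the consequence
logic and coordinate handling, not robustness to annotation pathologies of
real genome builds (those paths are exercised only by the skip rules).

## Verification sizes

The test suite and acceptance script compare engine and oracle on 1000+
seeded random (UTR, variant) pairs, re-annotate 8 static bundles (24
hand-verified rows) byte-for-byte, check invariants on 500-case corpora,
and measure the 1000-vs-100-variant runtime ratio (expected ≈10 for linear
scaling; asserted ≤ 12). These sizes keep the whole suite under a few
seconds while giving every detector double-digit positive counts.

## Known limitations

Only canonical AUG starts are considered; near-cognate starts (CUG, GUG…)
that are known to initiate many translated uORFs are out of scope, as are
IRES/shunting models, 3′UTR variants, variants longer than 5 bp, GFF3 input
and pathogenicity scoring. The alternative-stop search after a stop loss
does not look into the CDS context (a disrupted uORF either re-terminates
in the UTR or is reported as CDS-overlapping with its frame). Identity of
ClinVar-scale cohort statistics depends on the transcript release and
variant snapshot used and is outside the test surface; the tool itself is
transcript-set-agnostic.
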