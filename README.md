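# uorfkit

Transcript-aware annotation of 5′UTR variants that create or disrupt
upstream open reading frames (uORFs).

## The problem

Upstream ORFs are short reading frames in 5′UTRs that start at an upstream
AUG (uAUG) and regulate how efficiently the downstream coding sequence is
translated. Small variants that create or perturb them can substantially
change protein output and cause disease, yet standard variant annotators
label such variants only as "5′UTR" and say nothing about mechanism.

`uorfkit` fills that gap for SNVs, MNVs and 1–5 bp indels. For every
transcript whose 5′UTR contains a variant, it reconstructs the spliced UTR,
applies the alternate allele and detects five consequence classes:

| consequence | meaning |
|---|---|
| `uAUG_gained` | a new upstream AUG (a new uORF or CDS-overlapping ORF) |
| `uAUG_lost` | an existing upstream start codon is destroyed |
| `uSTOP_lost` | the stop codon of an existing uORF is destroyed |
| `uSTOP_gained` | a new in-frame stop shortens an existing (u)ORF |
| `uFrameshift` | a non-multiple-of-three indel shifts a uORF's frame |

Each row reports the number of pre-existing (u)ORFs in the reference UTR,
the Kozak context and strength of the affected start site, the subtype of
the created/disrupted ORF — `uORF` (stop within the UTR), `inframe_oORF`
(N-terminal extension of the CDS) or `OutOfFrame_oORF` — cap/CDS/stop
distances, alternative-stop logic for stop losses, and whether the uORF has
ribosome-profiling evidence of translation. A variant with several
consequences, or touching several uORFs, gets one row per combination.

Kozak strength follows the classical two-feature rule on the −3 and +4
positions around the AUG (`(gcc)gccRccATGG`): purine at −3 **and** G at +4 →
`Strong`; exactly one → `Moderate`; neither → `Weak`.

A prioritization filter keeps the annotations under strongest negative
selection: variants whose resulting ORF overlaps the CDS (gained oORFs,
stop losses with no alternative stop, frameshifts into an oORF) with
Strong/Moderate start sites, or disruptions of uORFs with documented
translation evidence, optionally restricted to a gene list.

## Worked example

`examples/scan_a_utr.py` scans a 30 nt UTR carrying one uORF and previews
the effect of a single SNV:

```text
5'UTR length: 30 nt
existing upstream ORFs: 1 uORF, 0 in-frame oORF, 0 out-of-frame oORF
  uAUG at offset 3: subtype uORF, stop at 9, Kozak GCCATGA (Moderate)

applying SNV at UTR offset 10 (A>G, TAG->TGG):
  uAUG_gained: Kozak GAAATGG (Strong), subtype OutOfFrame_oORF, ...
  uSTOP_lost: Kozak GCCATGA (Moderate), ..., alt stop exists: False, frame with CDS: inFrame
```

One SNV, two consequences: the uORF's stop codon is destroyed (and no
alternative in-frame stop exists, so the ORF now runs into the CDS in
frame), and the same base change creates a new out-of-frame uAUG with a
Strong Kozak context — exactly the kind of variant the prioritization
filter flags.

File-based annotation uses the CLI (or `uorfkit.io.run` from Python):

```bash
uorfkit --vcf variants.vcf --gtf transcripts.gtf --fasta genome.fa \
        --out annotated.tsv            # or --format vcf
```

The TSV has one row per (variant × transcript × consequence × uORF) with 22
fixed columns; VCF output preserves every input record and adds the same
fields as a `UTRA` INFO key (pipe-delimited entries, comma-separated per
consequence). `examples/annotate_fixture_vcf.py` runs this end-to-end on a
bundled fixture; `examples/prioritize_candidates.py` demonstrates the
high-impact filter on a synthetic cohort.

No external data are needed to develop or test: `uorfkit.fixtures` builds
self-consistent mini FASTA+GTF+VCF trios — hand-verified static bundles on
both strands with one- and two-exon UTRs, and seeded random cohorts whose
expected annotations come from an independent brute-force oracle.

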