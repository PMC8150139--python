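"""Scan a 5'UTR for upstream ORFs and preview a variant's consequences.

Works purely in sequence space: takes the spliced 5'UTR of a transcript
(cap-first) plus the first bases of its CDS, reports the existing uORF
census and Kozak contexts, then applies one SNV and shows the consequence
rows it would produce.
"""

from uorfkit import census, find_uaugs, kozak_assess, scan_orf
from uorfkit.engine import Edit, annotate_edit

# a 30 nt 5'UTR carrying one uORF (ATG at offset 3, TAG at offset 9),
# followed by the start of the main CDS
UTR = "GCCATGAAATAGCCGGCTTTCCGGCAAGGC"
CDS = "ATGGCTGCATAA"

cen = census(UTR, CDS)
print(f"5'UTR length: {len(UTR)} nt")
print(
    f"existing upstream ORFs: {cen.n_uorf} uORF, {cen.n_inframe_oorf} in-frame oORF, "
    f"{cen.n_outofframe_oorf} out-of-frame oORF"
)
for start in find_uaugs(UTR):
    rec = scan_orf(start, UTR, CDS)
    k = kozak_assess(UTR, CDS, start)
    print(
        f"  uAUG at offset {start}: subtype {rec.subtype}, stop at {rec.stop_offset}, "
        f"Kozak {k.context} ({k.strength})"
    )

# destroy the uORF's stop codon: TAG -> TGG (an SNV at UTR offset 10)
print("\napplying SNV at UTR offset 10 (A>G, TAG->TGG):")
for row in annotate_edit(UTR, CDS, Edit(10, 1, "G")):
    print(
        f"  {row.consequence}: Kozak {row.kozak_context} ({row.kozak_strength}), "
        f"subtype {row.uorf_subtype}, alt stop exists: {row.alt_stop_exists}, "
        f"frame with CDS: {row.frame_with_cds}"
    )
print(
    "\nThe single SNV has two consequences: it removes the uORF's stop codon\n"
    "(no alternative stop exists, so the disrupted ORF now overlaps the CDS\n"
    "in frame) and, as a side effect, turns the ATA at offsets 8-10 into a\n"
    "new out-of-frame upstream AUG with a Strong Kozak context."
)
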