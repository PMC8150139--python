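"""Brute-force reference classifier for uORF-perturbing edits.

This module re-derives, from first principles, which of the five consequence
classes an edit to a 5'UTR produces. It is deliberately written with
different machinery from the consequence engine — regex start finding, codon
lists built by slicing, and an explicit base-provenance list relating the
two alleles — and shares no code with it, so the two can check each other.

The unit of comparison is a tuple

    (consequence, anchor_offset, uorf_subtype, alt_subtype, kozak_strength, extras)

where ``anchor_offset`` is the UTR offset of the affected start site (on the
alternate allele for uAUG_gained, the reference otherwise) and ``extras``
carries the class-specific distance/flag fields. :func:`project_row` maps an
engine annotation row onto the same tuple space.
"""

from __future__ import annotations

import re
from typing import Optional

_STOPS = {"TAA", "TAG", "TGA"}


def _starts(seq: str) -> list[int]:
    return [m.start() for m in re.finditer(r"(?=ATG)", seq)]


def _orf(utr: str, cds: str, start: int) -> dict:
    full = utr + cds
    codons = [(i, full[i : i + 3]) for i in range(start, len(full) - 2, 3)]
    stop = next((i for i, c in codons if c in _STOPS), None)
    in_utr = stop is not None and stop + 3 <= len(utr)
    if in_utr:
        subtype = "uORF"
    elif (len(utr) - start) % 3 == 0:
        subtype = "inframe_oORF"
    else:
        subtype = "OutOfFrame_oORF"
    return {"start": start, "stop": stop, "in_utr": in_utr, "subtype": subtype}


def _kozak_strength(utr: str, cds: str, start: int) -> str:
    full = utr + cds

    def ch(p: int) -> str:
        return full[p] if 0 <= p < len(full) else "N"

    minus3 = ch(start - 3) in "AG"
    plus4 = ch(start + 3) == "G"
    if minus3 and plus4:
        return "Strong"
    if minus3 or plus4:
        return "Moderate"
    return "Weak"


def _stop_distance(orf: dict) -> Optional[int]:
    if orf["subtype"] == "uORF":
        return orf["stop"] - orf["start"]
    if orf["subtype"] == "OutOfFrame_oORF" and orf["stop"] is not None:
        return orf["stop"] - orf["start"]
    return None


def classify(ref_utr: str, cds_context: str, offset: int, ref_len: int, alt_seq: str):
    """All consequence tuples for one edit, sorted.

    ``offset``/``ref_len``/``alt_seq`` describe the edit in reference UTR
    offset space, already minimal (no shared prefix/suffix between the
    replaced segment and its replacement).
    """
    e, alt_len = offset, len(alt_seq)
    alt = ref_utr[:e] + alt_seq + ref_utr[e + ref_len :]
    n_ref, n_alt = len(ref_utr), len(alt)
    substitution = ref_len == alt_len

    # provenance: for each alt index, the ref index it descends from
    if substitution:
        prov: list[Optional[int]] = list(range(n_alt))
    else:
        prov = list(range(e)) + [None] * alt_len + list(range(e + ref_len, n_ref))
    ref_to_alt = {p: a for a, p in enumerate(prov) if p is not None}
    changed_alt = {a for a, p in enumerate(prov) if p is None or ref_utr[p] != alt[a]}
    alt_gaps = {
        a
        for a in range(n_alt - 1)
        if prov[a] is not None and prov[a + 1] is not None and prov[a + 1] - prov[a] != 1
    }
    changed_ref = {
        r for r in range(n_ref)
        if r not in ref_to_alt or ref_utr[r] != alt[ref_to_alt[r]]
    }
    ref_gaps = {
        r
        for r in range(n_ref - 1)
        if r in ref_to_alt and r + 1 in ref_to_alt
        and ref_to_alt[r + 1] - ref_to_alt[r] != 1
    }

    def touched_alt(a: int, w: int) -> bool:
        return any(i in changed_alt for i in range(a, a + w)) or any(
            j in alt_gaps for j in range(a, a + w - 1)
        )

    def touched_ref(r: int, w: int) -> bool:
        return any(i in changed_ref for i in range(r, r + w)) or any(
            j in ref_gaps for j in range(r, r + w - 1)
        )

    def mapped_start(r: int) -> Optional[int]:
        a0 = ref_to_alt.get(r)
        if a0 is None or alt[a0 : a0 + 3] != "ATG":
            return None
        return a0

    out = []

    # uAUG_gained: alt AUGs touching the edit with no contiguous ref ATG counterpart
    for a in _starts(alt):
        if not touched_alt(a, 3):
            continue
        ps = [prov[a + k] for k in range(3)]
        if (
            None not in ps
            and ps[1] == ps[0] + 1
            and ps[2] == ps[0] + 2
            and ref_utr[ps[0] : ps[0] + 3] == "ATG"
        ):
            continue
        orf = _orf(alt, cds_context, a)
        out.append(
            (
                "uAUG_gained", a, orf["subtype"], None,
                _kozak_strength(alt, cds_context, a),
                (a, n_alt - a, _stop_distance(orf)),
            )
        )

    # uAUG_lost: ref AUGs touching the edit that no longer read ATG
    for r in _starts(ref_utr):
        if not touched_ref(r, 3):
            continue
        if mapped_start(r) is not None:
            continue
        orf = _orf(ref_utr, cds_context, r)
        out.append(
            (
                "uAUG_lost", r, orf["subtype"], None,
                _kozak_strength(ref_utr, cds_context, r),
                (n_ref - r, _stop_distance(orf)),
            )
        )

    # uSTOP_lost / uSTOP_gained / uFrameshift operate on ref ORFs with intact starts
    net = alt_len - ref_len
    for r in _starts(ref_utr):
        orf = _orf(ref_utr, cds_context, r)
        a0 = mapped_start(r)
        strength = _kozak_strength(ref_utr, cds_context, r)

        if orf["subtype"] == "uORF" and a0 is not None:
            p = orf["stop"]
            if touched_ref(p, 3):
                p_alt = ref_to_alt.get(p)
                survived = (
                    p_alt is not None
                    and (p_alt - a0) % 3 == 0
                    and p_alt + 3 <= n_alt
                    and alt[p_alt : p_alt + 3] in _STOPS
                )
                if not survived:
                    threshold = p_alt if p_alt is not None else e + alt_len - 1
                    alt_stop = next(
                        (
                            i
                            for i in range(a0, n_alt - 2, 3)
                            if i > threshold and alt[i : i + 3] in _STOPS
                        ),
                        None,
                    )
                    if alt_stop is not None:
                        extras = (True, n_alt - alt_stop, None)
                    else:
                        frame = "inFrame" if (n_alt - a0) % 3 == 0 else "outOfFrame"
                        extras = (False, None, frame)
                    out.append(("uSTOP_lost", r, None, None, strength, extras))

        if a0 is not None:
            s = next(
                (i for i in range(a0, n_alt - 2, 3) if alt[i : i + 3] in _STOPS), None
            )
            if s is not None and touched_alt(s, 3):
                ok = True
                if orf["subtype"] == "uORF":
                    p_alt = ref_to_alt.get(orf["stop"])
                    ok = p_alt is not None and s < p_alt
                if ok:
                    out.append(
                        (
                            "uSTOP_gained", r, orf["subtype"], None, strength,
                            (n_ref - r, n_alt - s),
                        )
                    )

        if net != 0 and net % 3 != 0:
            body_end = orf["stop"] + 3 if orf["in_utr"] else n_ref
            if ref_len > 0:
                inside = e < body_end and e + ref_len > r
            else:
                inside = r < e < body_end
            if inside and a0 is not None:
                alt_orf = _orf(alt, cds_context, a0)
                out.append(
                    (
                        "uFrameshift", r, orf["subtype"], alt_orf["subtype"], strength,
                        (n_alt - a0,),
                    )
                )

    out.sort(key=lambda t: (t[0], t[1]))
    return out


def project_row(row):
    """Project an engine annotation row onto the oracle's comparison tuples."""
    c = row.consequence
    if c == "uAUG_gained":
        extras = (
            row.cap_distance_to_start,
            row.start_distance_to_cds,
            row.start_distance_to_stop,
        )
    elif c == "uAUG_lost":
        extras = (row.start_distance_to_cds, row.start_distance_to_stop)
    elif c == "uSTOP_lost":
        extras = (row.alt_stop_exists, row.alt_stop_distance_to_cds, row.frame_with_cds)
    elif c == "uSTOP_gained":
        extras = (row.start_distance_to_cds, row.new_stop_distance_to_cds)
    else:
        extras = (row.start_distance_to_cds,)
    return (c, row.anchor_offset, row.uorf_subtype, row.alt_subtype, row.kozak_strength, extras)


def project_rows(rows):
    return sorted(project_row(r) for r in rows)
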