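"""Protein consequence of skipping a single exon.

Given a coding transcript model, removing one internal exon either preserves
the reading frame (coding length skipped is a multiple of 3, giving an
in-frame deletion) or shifts it, typically producing a premature termination
codon. This module performs the reading-frame arithmetic, localizes the new
stop, formats an HGVS-style p. description, and applies the 50-nt rule as a
heuristic flag for nonsense-mediated decay (a premature stop at least 50 nt
upstream of the last exon-exon junction marks the transcript as a likely NMD
substrate).

The skip event itself is taken as given; whether skipping occurs is outside
this module's scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import ConsequenceError, GeneModelError
from .variant_io import GeneModel, GenomeSequence, reverse_complement

# NCBI standard genetic code, codons enumerated in TCAG order
_CODON_BASES = "TCAG"
_CODON_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _CODON_AAS[i1 * 16 + i2 * 4 + i3]
    for i1, b1 in enumerate(_CODON_BASES)
    for i2, b2 in enumerate(_CODON_BASES)
    for i3, b3 in enumerate(_CODON_BASES)
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}
AA1 = {v: k for k, v in AA3.items()}


@dataclass
class Translation:
    protein: str
    stop_reached: bool
    trailing_partial: bool


def translate(cds: str) -> Translation:
    """Standard-code translation, stopping at the first stop codon.

    A trailing partial codon is ignored but flagged.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ConsequenceError("coding sequence shorter than one codon")
    protein = []
    for i in range(0, len(cds) - 2, 3):
        aa = CODON_TABLE.get(cds[i:i + 3])
        if aa is None:
            raise ConsequenceError(f"codon {cds[i:i+3]!r} at offset {i} is not unambiguous DNA")
        if aa == "*":
            return Translation("".join(protein), True, False)
        protein.append(aa)
    return Translation("".join(protein), False, len(cds) % 3 != 0)


def splice_transcript(
    genome: GenomeSequence,
    model: GeneModel,
    skip_exon: Optional[int] = None,
) -> tuple[str, str]:
    """(mRNA, CDS) of the model, optionally with one exon (1-based,
    transcription order) skipped. Minus-strand models are reverse
    complemented; CDS is the coding substring of the mRNA."""
    if not model.is_coding:
        raise ConsequenceError(f"{model.transcript_id}: no CDS bounds")
    exons = list(model.exons)  # genomic order
    if skip_exon is not None:
        order = model.exons_in_transcription_order()
        if not 1 <= skip_exon <= len(order):
            raise GeneModelError(f"{model.transcript_id}: no exon {skip_exon}")
        start_base = model.cds_start if model.strand == "+" else model.cds_end
        s, e = order[skip_exon - 1]
        if s <= start_base <= e:
            raise ConsequenceError(
                f"{model.transcript_id}: exon {skip_exon} contains the start codon"
            )
        exons.remove((s, e))

    mrna_plus = "".join(genome.fetch(model.chrom, s - 1, e) for s, e in exons)
    cds_plus = "".join(
        genome.fetch(model.chrom, max(s, model.cds_start) - 1, min(e, model.cds_end))
        for s, e in exons
        if max(s, model.cds_start) <= min(e, model.cds_end)
    )
    if model.strand == "-":
        return reverse_complement(mrna_plus), reverse_complement(cds_plus)
    return mrna_plus, cds_plus


@dataclass
class ProteinConsequence:
    """Effect of skipping one exon on the encoded protein."""

    transcript_id: str
    skipped_exon_index: int
    skipped_exon_length: int  # bp, genomic exon length
    coding_bases_skipped: int
    frame_preserving: bool
    hgvs_p: str
    first_altered_residue: Optional[int] = None
    ref_residue: Optional[str] = None  # 1-letter code
    novel_residue: Optional[str] = None
    stop_offset: Optional[int] = None  # HGVS fsTer numbering, first altered = 1
    stop_reached: bool = True
    nmd_flag: bool = False


def _coding_len(model: GeneModel, exon: tuple[int, int]) -> int:
    s, e = exon
    lo, hi = max(s, model.cds_start), min(e, model.cds_end)
    return max(0, hi - lo + 1)


def _nmd_flag(model: GeneModel, skip_exon: int, n_coding_codons: int) -> bool:
    """50-nt rule on the skipped transcript: premature stop >= 50 nt upstream
    of the last exon-exon junction."""
    order = [iv for i, iv in enumerate(model.exons_in_transcription_order(), start=1)
             if i != skip_exon]
    if len(order) < 2:
        return False
    lengths = [e - s + 1 for s, e in order]
    # transcript coordinate (0-based) of the first coding base
    start_base = model.cds_start if model.strand == "+" else model.cds_end
    offset = 0
    cds_offset = None
    for (s, e), length in zip(order, lengths):
        if s <= start_base <= e:
            within = (start_base - s) if model.strand == "+" else (e - start_base)
            cds_offset = offset + within
            break
        offset += length
    if cds_offset is None:
        return False
    stop_end = cds_offset + 3 * (n_coding_codons + 1)  # 0-based, exclusive
    last_junction = sum(lengths[:-1])
    return (last_junction - stop_end) >= 50


def predict_exon_skip(
    genome: GenomeSequence, model: GeneModel, exon_index: int
) -> ProteinConsequence:
    """Compare reference and exon-skipped translations and describe the change.

    Frameshifts use HGVS fsTer numbering (first altered residue = position 1,
    so Ter23 places the stop at position 23 of the shifted frame); a
    frameshift whose first shifted codon is already a stop is reported as a
    nonsense change p.(XposTer). In-frame skips are reported as deletions
    (or delins when the junction codon changes). Skipping a wholly non-coding
    exon is "no protein change", p.(=).
    """
    exon = model.exon(exon_index)
    exon_len = exon[1] - exon[0] + 1
    ref_mrna, ref_cds = splice_transcript(genome, model)
    if len(ref_cds) % 3 != 0:
        raise ConsequenceError(
            f"{model.transcript_id}: CDS length {len(ref_cds)} not a multiple of 3"
        )
    coding_skipped = _coding_len(model, exon)
    if coding_skipped == 0:
        return ProteinConsequence(
            transcript_id=model.transcript_id,
            skipped_exon_index=exon_index,
            skipped_exon_length=exon_len,
            coding_bases_skipped=0,
            frame_preserving=True,
            hgvs_p="p.(=)",
        )

    _, skip_cds = splice_transcript(genome, model, skip_exon=exon_index)
    ref_tr = translate(ref_cds)
    skip_tr = translate(skip_cds)
    ref_prot, skip_prot = ref_tr.protein, skip_tr.protein
    frame_preserving = coding_skipped % 3 == 0

    i = 0
    limit = min(len(ref_prot), len(skip_prot))
    while i < limit and ref_prot[i] == skip_prot[i]:
        i += 1

    cons = ProteinConsequence(
        transcript_id=model.transcript_id,
        skipped_exon_index=exon_index,
        skipped_exon_length=exon_len,
        coding_bases_skipped=coding_skipped,
        frame_preserving=frame_preserving,
        hgvs_p="",
        stop_reached=skip_tr.stop_reached,
    )
    cons.nmd_flag = skip_tr.stop_reached and _nmd_flag(model, exon_index, len(skip_prot))

    if not frame_preserving:
        first = i + 1
        ref_aa = ref_prot[i] if i < len(ref_prot) else "*"
        cons.first_altered_residue = first
        cons.ref_residue = ref_aa
        if i >= len(skip_prot):
            # shifted frame opens directly on a stop codon: nonsense form
            cons.novel_residue = "*"
            cons.stop_offset = 1
            cons.hgvs_p = f"p.({AA3[ref_aa]}{first}Ter)"
            return cons
        cons.novel_residue = skip_prot[i]
        if skip_tr.stop_reached:
            cons.stop_offset = len(skip_prot) + 1 - i
            cons.hgvs_p = (
                f"p.({AA3[ref_aa]}{first}{AA3[skip_prot[i]]}fsTer{cons.stop_offset})"
            )
        else:
            cons.hgvs_p = f"p.({AA3[ref_aa]}{first}{AA3[skip_prot[i]]}fsTer?)"
        return cons

    # in-frame skip
    if skip_prot == ref_prot and skip_tr.stop_reached:
        cons.hgvs_p = "p.(=)"
        return cons
    if skip_tr.stop_reached and i >= len(skip_prot) and i < len(ref_prot) and (
        len(skip_prot) < len(ref_prot) - coding_skipped // 3
    ):
        # in-frame skip that fuses a premature stop at the junction
        cons.first_altered_residue = i + 1
        cons.ref_residue = ref_prot[i]
        cons.novel_residue = "*"
        cons.hgvs_p = f"p.({AA3[ref_prot[i]]}{i + 1}Ter)"
        return cons
    k = len(ref_prot) - len(skip_prot)
    cons.first_altered_residue = i + 1
    cons.ref_residue = ref_prot[i] if i < len(ref_prot) else None
    if k >= 1 and skip_prot == ref_prot[:i] + ref_prot[i + k:]:
        if k == 1:
            cons.hgvs_p = f"p.({AA3[ref_prot[i]]}{i + 1}del)"
        else:
            cons.hgvs_p = (
                f"p.({AA3[ref_prot[i]]}{i + 1}_{AA3[ref_prot[i + k - 1]]}{i + k}del)"
            )
        return cons
    # junction codon changed: delins over the minimal differing span
    j_ref, j_skip = len(ref_prot), len(skip_prot)
    while j_ref > i and j_skip > i and ref_prot[j_ref - 1] == skip_prot[j_skip - 1]:
        j_ref -= 1
        j_skip -= 1
    inserted = "".join(AA3[a] for a in skip_prot[i:j_skip]) or "del"
    cons.novel_residue = skip_prot[i] if i < len(skip_prot) else None
    cons.hgvs_p = (
        f"p.({AA3[ref_prot[i]]}{i + 1}_{AA3[ref_prot[j_ref - 1]]}{j_ref}delins{inserted})"
    )
    return cons


_FS_RE = re.compile(r"^p\.\((?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<new>[A-Z][a-z]{2})fsTer(?P<stop>\d+|\?)\)$")
_TER_RE = re.compile(r"^p\.\((?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)Ter\)$")
_DEL_RE = re.compile(
    r"^p\.\((?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?:_(?P<ref2>[A-Z][a-z]{2})(?P<pos2>\d+))?del\)$"
)


def parse_hgvs_p(text: str) -> dict:
    """Parse the p. strings this module emits back into their components."""
    if text == "p.(=)":
        return {"kind": "no_change"}
    m = _FS_RE.match(text)
    if m:
        return {
            "kind": "frameshift",
            "ref_residue": AA1[m["ref"]],
            "position": int(m["pos"]),
            "novel_residue": AA1[m["new"]],
            "stop_offset": None if m["stop"] == "?" else int(m["stop"]),
        }
    m = _TER_RE.match(text)
    if m:
        return {"kind": "nonsense", "ref_residue": AA1[m["ref"]], "position": int(m["pos"])}
    m = _DEL_RE.match(text)
    if m:
        end = int(m["pos2"]) if m["pos2"] else int(m["pos"])
        return {
            "kind": "deletion",
            "ref_residue": AA1[m["ref"]],
            "position": int(m["pos"]),
            "end_position": end,
        }
    if "delins" in text:
        return {"kind": "delins", "text": text}
    raise ConsequenceError(f"unrecognized p. description {text!r}")
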