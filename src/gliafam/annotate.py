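"""Coding annotation of gamma-gliadin sequences.

Classifies a sequence as intact gene or pseudogene, deduces the protein and
its cysteine count, and segments the canonical gamma-gliadin domain
architecture: signal peptide (S), unique N-terminal domain (I), repetitive
domain (II), cysteine-rich domain (III, usually six cysteines), glutamine-rich
domain (IV) and C-terminal domain (V, two conserved cysteines).

The reading frame is anchored on the conserved signal-peptide primer site
(ATG AAG ACC TTA CTC ATC C...), allowing up to two mismatches.  Frameshifts
are detected relative to an alignment with an intact reference profile — the
cumulative indel length turning into a non-multiple of three — rather than by
longest-ORF scanning, which repeat-length polymorphism defeats.  A stop codon
aligned to the reference terminator is the natural stop, not a defect; only
stops strictly before it count as internal.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import align
from .ng86 import STOP_CODONS, translate_codon

#: conserved signal-peptide anchor (the forward primer site); fixes the frame
SIGNAL_ANCHOR = "ATGAAGACCTTACTCATCC"
ANCHOR_MAX_MISMATCHES = 2
#: aligned columns an out-of-frame state must persist to confirm a frameshift
_SHIFT_CONFIRM = 30

DOMAIN_LABELS = ("S", "I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class Defect:
    kind: str  # "internal_stop" | "frameshift"
    position: int  # 0-based nucleotide index in the input sequence


@dataclass
class ReferenceProfile:
    """An intact reference ORF with its domain segmentation.

    ``sequence``: nucleotide ORF including the terminal stop codon;
    ``domains_aa``: label -> (start, end) 0-based half-open amino-acid
    coordinates covering the protein (stop excluded).
    """

    sequence: str
    domains_aa: dict[str, tuple[int, int]]

    @property
    def protein(self) -> str:
        seq = self.sequence
        aas = []
        for i in range(0, len(seq) - 2, 3):
            aa = translate_codon(seq[i : i + 3])
            if aa == "*":
                break
            aas.append(aa)
        return "".join(aas)

    def domain_list(self) -> list[tuple[str, int, int]]:
        return [(lab, *self.domains_aa[lab]) for lab in DOMAIN_LABELS]


@dataclass
class CodingAnnotation:
    frame_offset: int
    is_pseudogene: bool
    defects: list[Defect]
    protein: str
    protein_length: int
    cysteine_count: int
    domains: list[tuple[str, int, int]] = field(default_factory=list)


def count_cysteines(protein: str) -> int:
    """Number of cysteine residues in a protein string."""
    return protein.upper().count("C")


def find_anchor(seq: str, max_mismatches: int = ANCHOR_MAX_MISMATCHES) -> int:
    """Leftmost position of the signal-peptide anchor (<= max_mismatches)."""
    seq = seq.upper()
    k = len(SIGNAL_ANCHOR)
    for i in range(len(seq) - k + 1):
        mism = sum(1 for a, b in zip(seq[i : i + k], SIGNAL_ANCHOR) if a != b)
        if mism <= max_mismatches:
            return i
    raise ValueError("unanchored sequence: signal-peptide anchor not found")


def _aligned_span(row_a: str, row_b: str) -> tuple[int, int]:
    a0 = len(row_a) - len(row_a.lstrip(align.GAP))
    a1 = len(row_a.rstrip(align.GAP))
    b0 = len(row_b) - len(row_b.lstrip(align.GAP))
    b1 = len(row_b.rstrip(align.GAP))
    return max(a0, b0), min(a1, b1)


def annotate_coding(seq: str, reference_profile: ReferenceProfile) -> CodingAnnotation:
    """Annotate one nucleotide sequence against an intact reference ORF."""
    seq = seq.upper()
    offset = find_anchor(seq)
    sub = seq[offset:]
    ref = reference_profile.sequence.upper()
    row_r, row_s = align.align_pair(ref, sub, anchored_left=True)
    start, end = _aligned_span(row_r, row_s)

    n_ref_codons = len(ref) // 3
    defects: list[Defect] = []

    # -- frameshift scan: the cumulative indel length must return to a
    #    multiple of three.  An out-of-frame state is only called a
    #    frameshift when it persists (>= _SHIFT_CONFIRM aligned columns, or
    #    to the end of the aligned span): alignment ambiguity inside the
    #    periodic repeat region can split a whole-unit indel into transient
    #    out-of-frame pieces that are not real defects.
    cum = 0
    in_shift = False
    spos = start - row_s[:start].count(align.GAP)  # sequence coord at span start
    episode: tuple[int, int] | None = None  # (start col, seq position)
    confirmed_cols: list[int] = []
    run = 0
    for col in range(start, end):
        cr, cs = row_r[col], row_s[col]
        if cr == align.GAP:
            cum += 1
            spos += 1
        elif cs == align.GAP:
            cum -= 1
        else:
            spos += 1
        if cum % 3 != 0:
            if in_shift:
                pass  # already confirmed; wait for the frame to recover
            elif episode is None:
                episode = (col, max(spos - 1, 0))
                run = 0
            elif cr != align.GAP and cs != align.GAP:
                run += 1
                if run == _SHIFT_CONFIRM:
                    defects.append(Defect(kind="frameshift", position=offset + episode[1]))
                    confirmed_cols.append(episode[0])
                    episode = None
                    in_shift = True
        else:
            episode = None
            in_shift = False
    if episode is not None:  # persisted to the end of the span
        defects.append(Defect(kind="frameshift", position=offset + episode[1]))
        confirmed_cols.append(episode[0])

    # -- repaired-frame translation: sequence bases are read in triples,
    #    carrying remainders across reference codon boundaries; at each
    #    confirmed frameshift the remainder is dropped to re-synchronise
    #    with the reference frame.  Internal stops are stops strictly
    #    before the reference terminator.
    protein_parts: list[str] = []
    stopped = False
    pending: list[tuple[str, int]] = []  # (base, seq coord)
    rpos = start - row_r[:start].count(align.GAP)  # ref coordinate at span start
    confirmed = set(confirmed_cols)
    resync = False

    def flush(region_ref_codon: int):
        nonlocal pending, stopped, resync
        n = len(pending) // 3
        for k in range(n):
            codon = "".join(b for b, _ in pending[3 * k : 3 * k + 3])
            pos0 = pending[3 * k][1]
            if codon in STOP_CODONS:
                if region_ref_codon < n_ref_codons - 1:
                    defects.append(Defect(kind="internal_stop", position=offset + pos0))
                stopped = True
            elif not stopped and "N" not in codon:
                protein_parts.append(translate_codon(codon))
        pending = [] if resync else pending[3 * n :]
        resync = False

    spos2 = start - row_s[:start].count(align.GAP)
    for col in range(start, end):
        cr, cs = row_r[col], row_s[col]
        if col in confirmed:
            resync = True
        if cr != align.GAP and rpos % 3 == 0:
            flush(rpos // 3 - 1)
        if cs != align.GAP:
            pending.append((cs, spos2))
            spos2 += 1
        if cr != align.GAP:
            rpos += 1
    resync = True  # final flush: discard any trailing partial codon
    flush((rpos - 1) // 3)

    protein = "".join(protein_parts)
    domains = segment_domains(protein, reference_profile) if protein else []
    return CodingAnnotation(
        frame_offset=offset,
        is_pseudogene=bool(defects),
        defects=defects,
        protein=protein,
        protein_length=len(protein),
        cysteine_count=count_cysteines(protein),
        domains=domains,
    )


def segment_domains(
    protein: str, reference_profile: ReferenceProfile
) -> list[tuple[str, int, int]]:
    """Project the reference domain boundaries onto a protein.

    Returns six contiguous, non-overlapping (label, start, end) segments
    covering the protein; a domain whose span is entirely deleted comes out
    with zero length.
    """
    ref_prot = reference_profile.protein
    if protein == ref_prot:
        return reference_profile.domain_list()
    row_r, row_p = align.align_pair(ref_prot, protein, anchored_left=True)

    def domain_of(ref_pos: int) -> str:
        ref_pos = min(max(ref_pos, 0), len(ref_prot) - 1)
        for lab in DOMAIN_LABELS:
            r0, r1 = reference_profile.domains_aa[lab]
            if r0 <= ref_pos < r1:
                return lab
        return DOMAIN_LABELS[-1]

    # attach every query residue to a domain; insertion blocks sitting on a
    # domain boundary go to the adjacent length-variable domain (II or IV)
    variable = {"II", "IV"}
    counts = {lab: 0 for lab in DOMAIN_LABELS}
    rpos = 0
    block = 0  # pending insertion residues at the current boundary
    for cr, cq in zip(row_r, row_p):
        if cr == align.GAP:
            if cq != align.GAP:
                block += 1
            continue
        if block:
            dl, dr = domain_of(rpos - 1), domain_of(rpos)
            if dl == dr:
                target = dl
            elif dr in variable and dl not in variable:
                target = dr
            else:
                target = dl
            counts[target] += block
            block = 0
        if cq != align.GAP:
            counts[domain_of(rpos)] += 1
        rpos += 1
    if block:
        counts[DOMAIN_LABELS[-1]] += block

    out = []
    pos = 0
    for lab in DOMAIN_LABELS:
        out.append((lab, pos, pos + counts[lab]))
        pos += counts[lab]
    return out


def annotation_table(
    annotations: dict[str, CodingAnnotation], genomes: dict[str, str]
) -> pd.DataFrame:
    """Per-sequence annotation summary (TSV-ready)."""
    rows = []
    for sid in sorted(annotations):
        ann = annotations[sid]
        rows.append(
            {
                "id": sid,
                "genome": genomes.get(sid, "other"),
                "is_pseudogene": ann.is_pseudogene,
                "defects": ";".join(f"{d.kind}@{d.position}" for d in ann.defects),
                "protein_length": ann.protein_length,
                "cysteine_count": ann.cysteine_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "genome", "is_pseudogene", "defects", "protein_length", "cysteine_count"],
    )


def pseudogene_fraction(n_pseudogene_sequences: int, n_sequences: int) -> float:
    """Fraction of sequences classified as pseudogene (e.g. 49/335 -> 0.146)."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return n_pseudogene_sequences / n_sequences
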