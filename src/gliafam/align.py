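"""Pairwise global alignment and profile-anchored multiple alignment.

The pairwise scorer is a conventional Needleman–Wunsch (match +1, mismatch -1,
affine gaps: -4 to open, -0.5 to extend) with *free end gaps*, so that partial
clones align to full-length sequences without terminal-gap penalties and the
long repeat-count deletions characteristic of the gene family stay cheaper
than misaligning whole domains.  Multiple alignments are
built by anchoring every sequence to a common profile (a reference sequence)
and stacking the pairwise alignments in profile coordinates — appropriate for
the >=99%-identical members of a contig and for frame-preserving projection
onto a reference open reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

GAP = "-"


def make_aligner(anchored_left: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    aligner.end_insertion_score = 0.0  # free terminal gaps in the target
    aligner.end_deletion_score = 0.0  # free terminal gaps in the query
    if anchored_left:
        # both sequences start at the conserved primer anchor: penalise left
        # end gaps like internal gaps so the periodic repeat region cannot
        # slide the alignment off the signal peptide
        aligner.open_left_gap_score = -4.0
        aligner.extend_left_gap_score = -0.5
    return aligner


_ALIGNER = make_aligner()
_ALIGNER_ANCHORED = make_aligner(anchored_left=True)


def align_pair(a: str, b: str, anchored_left: bool = False) -> tuple[str, str]:
    """Optimal global alignment of two sequences; returns the gapped rows.

    With ``anchored_left`` the left ends are penalised (use when both
    sequences start at the conserved anchor).  Deterministic: the
    highest-scoring alignment reported first by the aligner is used.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _ALIGNER_ANCHORED if anchored_left else _ALIGNER
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def identity_from_rows(row_a: str, row_b: str) -> float:
    """Identity = matches / aligned columns, terminal-gap columns excluded,
    internal gap columns counted as mismatch."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")

    def span(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip(GAP))
        last = len(row.rstrip(GAP))
        return first, last

    a0, a1 = span(row_a)
    b0, b1 = span(row_b)
    start, end = max(a0, b0), min(a1, b1)
    if end <= start:
        return 0.0
    matches = sum(
        1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != GAP
    )
    return matches / (end - start)


@dataclass
class ProfileAlignment:
    """One sequence mapped onto profile coordinates.

    ``bases[p]`` is the sequence base aligned to profile position p (or '-');
    ``insertions[p]`` holds sequence bases falling between profile positions
    p-1 and p (key len(profile) = after the profile end); ``seq_pos[p]`` is
    the 0-based sequence coordinate aligned at p, or -1.
    """

    bases: list[str]
    insertions: dict[int, str] = field(default_factory=dict)
    seq_pos: list[int] = field(default_factory=list)


def map_to_profile(profile: str, seq: str, anchored_left: bool = False) -> ProfileAlignment:
    row_p, row_s = align_pair(profile, seq, anchored_left=anchored_left)
    bases: list[str] = []
    seq_pos: list[int] = []
    insertions: dict[int, str] = {}
    pending: list[str] = []
    spos = 0
    for cp, cs in zip(row_p, row_s):
        if cp == GAP:
            pending.append(cs)
            spos += 1
        else:
            if pending:
                insertions[len(bases)] = "".join(pending)
                pending = []
            bases.append(cs)
            if cs == GAP:
                seq_pos.append(-1)
            else:
                seq_pos.append(spos)
                spos += 1
    if pending:
        insertions[len(bases)] = "".join(pending)
    return ProfileAlignment(bases=bases, insertions=insertions, seq_pos=seq_pos)


def profile_msa(
    seqs: dict[str, str],
    profile: str,
    keep_insertions: bool = True,
    codon_pad: bool = False,
    anchored_left: bool = False,
) -> dict[str, str]:
    """Multiple alignment of ``seqs`` anchored to ``profile``.

    With ``keep_insertions`` the columns between profile positions hold
    insertions (left-justified; padded to codon multiples when ``codon_pad``);
    without it, the alignment is exactly the profile projection (one column
    per profile position), which preserves the reference reading frame.
    """
    maps = {sid: map_to_profile(profile, s, anchored_left=anchored_left) for sid, s in seqs.items()}
    L = len(profile)
    if not keep_insertions:
        return {sid: "".join(m.bases) for sid, m in maps.items()}
    widths = [0] * (L + 1)
    for m in maps.values():
        for p, ins in m.insertions.items():
            widths[p] = max(widths[p], len(ins))
    if codon_pad:
        widths = [w + (-w) % 3 for w in widths]
    out = {}
    for sid, m in maps.items():
        parts = []
        for p in range(L + 1):
            if widths[p]:
                ins = m.insertions.get(p, "")
                parts.append(ins.ljust(widths[p], GAP))
            if p < L:
                parts.append(m.bases[p])
        out[sid] = "".join(parts)
    return out
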