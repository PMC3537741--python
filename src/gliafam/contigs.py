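"""Contig assembly: cluster near-duplicate clones at 99% identity, call consensus.

Cloned gamma-gliadin sequences arrive as redundant sets (many clones per PCR,
several clones per gene).  The data reduction clusters sequences whose global
alignment identity meets a threshold (default 0.99) into contigs by
single-linkage — the most conservative choice, splitting the fewest contigs —
and represents each contig by a column-majority consensus over a
profile-anchored multiple alignment of its members.  Identity excludes
terminal-gap columns, so fragments cluster with full-length clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import pandas as pd

from . import align
from .io import NucleotideRecord

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.99


@dataclass
class Contig:
    """A >=threshold-identity cluster of records with a consensus sequence."""

    members: list[str]
    consensus: str = ""
    threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self):
        if not self.members:
            raise ValueError("contig must have at least one member")


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity in [0, 1].

    Identity = matches / aligned columns with terminal-gap columns excluded
    and internal gap columns counted as mismatches.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    row_a, row_b = align.align_pair(a, b)
    return align.identity_from_rows(row_a, row_b)


def _identity_fast(a: str, b: str) -> float:
    """Alignment identity, short-circuited to Hamming identity for
    equal-length near-identical pairs (where the two coincide)."""
    if len(a) == len(b):
        ham = sum(x == y for x, y in zip(a, b)) / len(a)
        if ham >= 0.95:
            return ham
    return pairwise_identity(a, b)


def cluster_contigs(
    records: list[NucleotideRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[Contig]:
    """Single-linkage clustering of records at a pairwise identity threshold.

    Contigs are the connected components of the graph whose edges join pairs
    with identity >= threshold; output is deterministic, ordered by the
    smallest member id, with members sorted within each contig.  Consensus
    sequences are filled in by :func:`call_consensus`.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1.0], got {threshold}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    seqs = {r.id: r.residues.upper() for r in records}

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    def plausibly_similar(a: str, b: str) -> bool:
        # conservative prescreen: a pair at >= threshold identity has a small
        # infix edit distance (terminal overhangs excluded by HW mode); pairs
        # far beyond that bound cannot reach the threshold
        bound = int(2 * (1.0 - threshold) * min(len(a), len(b))) + 10
        d1 = edlib.align(a, b, task="distance", mode="HW", k=bound)["editDistance"]
        if 0 <= d1 <= bound:
            return True
        d2 = edlib.align(b, a, task="distance", mode="HW", k=bound)["editDistance"]
        return 0 <= d2 <= bound

    ordered = sorted(ids)
    for i, id1 in enumerate(ordered):
        for id2 in ordered[i + 1 :]:
            if find(id1) == find(id2):
                continue  # already linked; skip the alignment
            if not plausibly_similar(seqs[id1], seqs[id2]):
                continue
            if pairwise_identity(seqs[id1], seqs[id2]) >= threshold:
                union(id1, id2)

    clusters: dict[str, list[str]] = {}
    for rid in ordered:
        clusters.setdefault(find(rid), []).append(rid)
    contigs = [
        Contig(members=sorted(members), threshold=threshold)
        for members in clusters.values()
    ]
    contigs.sort(key=lambda c: c.members[0])
    for contig in contigs:
        contig.consensus = call_consensus(contig, seqs)
    return contigs


def call_consensus(contig: Contig, records: dict[str, str] | list[NucleotideRecord]) -> str:
    """Column-wise majority consensus over a profile-anchored alignment of
    the contig members (profile = longest member).

    Gap-majority columns are removed; base ties break alphabetically.
    """
    if isinstance(records, list):
        records = {r.id: r.residues for r in records}
    seqs = {m: records[m].upper() for m in contig.members}
    if len(seqs) == 1:
        return next(iter(seqs.values()))
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        # equal-length members of a >=99%-identity cluster are column-aligned
        # as-is (clone reads differ by substitutions only)
        msa = seqs
    else:
        profile_id = max(seqs, key=lambda m: (len(seqs[m]), m))
        msa = align.profile_msa(seqs, seqs[profile_id], keep_insertions=True)
    ncol = len(next(iter(msa.values())))
    out = []
    for c in range(ncol):
        col = [row[c] for row in msa.values()]
        n_gap = col.count(align.GAP)
        if n_gap * 2 > len(col):
            continue
        bases = sorted(b for b in col if b != align.GAP)
        counts = {b: bases.count(b) for b in set(bases)}
        best = max(counts.values())
        out.append(min(b for b, n in counts.items() if n == best))
    consensus = "".join(out)
    for m, s in seqs.items():
        ident = _identity_fast(s, consensus)
        if ident < contig.threshold:
            logger.warning(
                "contig member %s at %.4f identity to consensus, below threshold %.2f",
                m,
                ident,
                contig.threshold,
            )
    return consensus


def membership_table(contigs: list[Contig], records: list[NucleotideRecord]) -> pd.DataFrame:
    """TSV-ready table (contig_id, member_id, genome, identity_to_consensus)."""
    seqs = {r.id: r.residues for r in records}
    genomes = {r.id: r.genome for r in records}
    rows = []
    for k, contig in enumerate(contigs):
        for m in contig.members:
            rows.append(
                {
                    "contig_id": f"ctg{k:03d}",
                    "member_id": m,
                    "genome": genomes[m],
                    "identity_to_consensus": _identity_fast(seqs[m], contig.consensus),
                }
            )
    return pd.DataFrame(rows)


def contig_genome(contig: Contig, records: list[NucleotideRecord] | dict[str, str]) -> str:
    """Majority genome label among contig members (ties break alphabetically)."""
    if isinstance(records, dict):
        genomes = records
    else:
        genomes = {r.id: r.genome for r in records}
    labels = sorted(genomes[m] for m in contig.members)
    counts = {g: labels.count(g) for g in set(labels)}
    best = max(counts.values())
    return min(g for g, n in counts.items() if n == best)
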