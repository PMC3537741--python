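"""Tests for contig clustering and consensus calling."""

import numpy as np
import pytest

from gliafam import simulate
from gliafam.contigs import (
    Contig,
    call_consensus,
    cluster_contigs,
    contig_genome,
    membership_table,
    pairwise_identity,
)
from gliafam.io import NucleotideRecord
from oracles import nw_align_score

from gliafam.align import align_pair, identity_from_rows


def _rec(i, seq, genome="D"):
    return NucleotideRecord(id=f"r{i:03d}", genome=genome, residues=seq)


def test_identity_trivial_cases():
    assert pairwise_identity("ACGT", "ACGT") == 1.0
    s = "ACGT" * 75
    mutated = s[:10] + ("A" if s[10] != "A" else "C") + s[11:]
    mutated = mutated[:100] + ("G" if s[100] != "G" else "C") + mutated[101:]
    mutated = mutated[:200] + ("T" if s[200] != "T" else "C") + mutated[201:]
    assert pairwise_identity(s, mutated) == pytest.approx(0.99, abs=1e-9)
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def test_identity_excludes_terminal_gaps():
    """A perfect fragment scores 1.0 against the full-length sequence."""
    full = simulate.make_ancestral_gene(1, 909).residues
    fragment = full[100:700]
    assert pairwise_identity(full, fragment) == 1.0


def test_identity_matches_independent_dp_oracle():
    """Alignment score agrees with a brute-force Gotoh DP under the same gap
    policy; identity is exact on substitution-only pairs (unique optimum)."""
    rng = np.random.default_rng(0)
    bases = "ACGT"
    for _ in range(15):
        n = 200
        a = "".join(rng.choice(list(bases), size=n))
        b = list(a)
        k = rng.integers(1, 8)
        pos = rng.choice(n, size=k, replace=False)
        for p in pos:
            b[p] = bases[(bases.index(b[p]) + 1 + rng.integers(3)) % 4]
        b = "".join(b)
        row_a, row_b = align_pair(a, b)
        # package aligner achieves the oracle's optimal score
        score = sum(
            1.0 if x == y else -1.0
            for x, y in zip(row_a, row_b)
            if x != "-" and y != "-"
        )
        assert "-" not in row_a + row_b  # substitution-only: no gaps opened
        assert score == pytest.approx(nw_align_score(a, b))
        assert pairwise_identity(a, b) == pytest.approx((n - len(set(pos))) / n)


def test_identity_with_planted_indel_matches_oracle_score():
    rng = np.random.default_rng(1)
    a = "".join(rng.choice(list("ACGT"), size=240))
    b = a[:100] + a[121:]  # internal 21-bp deletion
    row_a, row_b = align_pair(a, b)
    score = 0.0
    in_gap = False
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            score += -0.5 if in_gap else -4.0
            in_gap = True
        else:
            score += 1.0 if x == y else -1.0
            in_gap = False
    assert score == pytest.approx(nw_align_score(a, b))


def test_cluster_identical_and_below_threshold():
    recs = [_rec(i, "ACGTACGTAC" * 30) for i in range(3)]
    contigs = cluster_contigs(recs, 0.99)
    assert len(contigs) == 1 and len(contigs[0].members) == 3
    # 2 records at 98% identity -> singletons at 0.99
    s = "ACGT" * 25
    t = "TT" + s[2:98] + "GG"
    recs = [_rec(0, s), _rec(1, t)]
    assert pairwise_identity(s, t) < 0.99
    assert len(cluster_contigs(recs, 0.99)) == 2
    with pytest.raises(ValueError):
        cluster_contigs(recs, 0.4)


def test_cluster_partition_and_threshold_monotonicity():
    rng = np.random.default_rng(2)
    cfg = simulate.SimulationConfig(
        seed=9, n_genes_per_group_per_genome=1, clone_reads_per_gene=2, n_outgroups=1
    )
    records, _ = simulate.simulate_family(cfg)
    records = records[:40]
    sizes = []
    for thr in (0.90, 0.99, 1.0):
        contigs = cluster_contigs(records, thr)
        members = sorted(m for c in contigs for m in c.members)
        assert members == sorted(r.id for r in records)  # exact partition
        sizes.append(len(contigs))
    assert sizes == sorted(sizes)  # raising threshold never merges contigs


def test_cluster_recovers_planted_genes():
    """10 genes x 3 reads at 0.2% clone error -> one contig per gene."""
    cfg = simulate.SimulationConfig(
        seed=3,
        clone_reads_per_gene=3,
        clone_error_rate=0.002,
        n_genes_per_group_per_genome=1,
        n_outgroups=0,
    )
    records, truth = simulate.simulate_family(cfg)
    contigs = cluster_contigs(records, 0.99)
    planted = {
        frozenset(truth.records[truth.records.gene_id == g].record_id)
        for g in truth.genes.gene_id
    }
    assert {frozenset(c.members) for c in contigs} == planted


def test_consensus_single_member_and_majority():
    seqs = {"a": "ACGTACGTAC"}
    assert call_consensus(Contig(members=["a"]), seqs) == "ACGTACGTAC"
    seqs = {
        "a": "ACGTACGTAC",
        "b": "ACGTACGTAC",
        "c": "ACGAACGTAC",  # one disagreeing base
    }
    assert call_consensus(Contig(members=["a", "b", "c"]), seqs) == "ACGTACGTAC"


def test_consensus_tie_breaks_alphabetically():
    seqs = {"a": "AAAA", "b": "AACA", "c": "AATA", "d": "AAGA"}
    # column 2: {A:1, C:1, T:1, G:1} -> alphabetical 'A'
    assert call_consensus(Contig(members=list(seqs)), seqs) == "AAAA"


def test_consensus_drops_gap_majority_columns():
    base = simulate.make_ancestral_gene(1, 909).residues
    longer = base[:300] + "CCACAACAACCATTCCCACAA" + base[300:]  # one extra unit
    seqs = {"a": base, "b": base, "c": longer}
    cons = call_consensus(Contig(members=["a", "b", "c"]), seqs)
    assert cons == base  # insertion columns are gap-majority -> removed


def test_consensus_recovers_true_gene_over_many_contigs():
    """Column-majority consensus of 5 error-bearing reads equals the source
    gene in >=99% of simulated contigs."""
    rng = np.random.default_rng(8)
    gene = simulate._build_template(909, False)
    good = 0
    n = 1000
    for k in range(n):
        reads = {
            f"c{k}r{r}": simulate._clone_read(gene, 0.002, rng) for r in range(5)
        }
        good += call_consensus(Contig(members=sorted(reads)), reads) == gene.seq
    assert good / n >= 0.99


def test_reclustering_consensuses_gives_singletons(default_family):
    records, _ = default_family
    contigs = cluster_contigs(records, 0.99)
    cons_recs = [
        NucleotideRecord(id=f"c{k:03d}", genome="D", residues=c.consensus)
        for k, c in enumerate(contigs)
    ]
    # distinct genes are <99% identical, so consensuses stay singletons
    again = cluster_contigs(cons_recs, 0.99)
    assert len(again) == len(cons_recs)


def test_membership_table_and_contig_genome(default_family):
    records, _ = default_family
    contigs = cluster_contigs(records[:12], 0.99)
    table = membership_table(contigs, records[:12])
    assert set(table.columns) == {
        "contig_id",
        "member_id",
        "genome",
        "identity_to_consensus",
    }
    assert (table["identity_to_consensus"] >= 0.99).all()
    assert contig_genome(contigs[0], records[:12]) == records[0].genome
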