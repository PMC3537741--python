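"""Unit and property tests for the NG86 divergence/selection machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliafam import ng86, simulate
from oracles import bf_codon_sites, bf_pair_diffs

SENSE = [c for c in ng86.CODONS if c not in ng86.STOP_CODONS]


@pytest.mark.parametrize(
    "codon,expected_s",
    [("ATG", 0.0), ("TTT", 1 / 3), ("TTA", 2 / 3), ("TGG", 0.0)],
)
def test_codon_sites_known_values(codon, expected_s):
    cs = ng86.codon_sites(codon)
    assert cs.s == pytest.approx(expected_s, abs=1e-12)
    assert cs.s + cs.n == pytest.approx(3.0, abs=1e-12)


def test_codon_sites_conservation_all_sense_codons():
    """s + n = 3 exactly, and s matches direct enumeration, for all 61 codons."""
    for codon in SENSE:
        cs = ng86.codon_sites(codon)
        assert cs.s + cs.n == pytest.approx(3.0, abs=1e-12)
        assert cs.s == pytest.approx(float(bf_codon_sites(codon)), abs=1e-12)


def test_codon_sites_rejects_stops_and_ambiguity():
    with pytest.raises(ValueError):
        ng86.codon_sites("TAA")
    with pytest.raises(ValueError):
        ng86.codon_sites("ANG")


@pytest.mark.parametrize(
    "c1,c2,expected",
    [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),  # Phe -> Leu, single change
        ("TTT", "ATA", (0.5, 1.5)),  # two pathways averaged
        ("TTT", "TTC", (1.0, 0.0)),
    ],
)
def test_codon_pair_differences_known_values(c1, c2, expected):
    assert ng86.codon_pair_differences(c1, c2) == pytest.approx(expected, abs=1e-12)


def test_codon_pair_difference_conservation():
    """sd + nd equals the number of differing positions, all sense pairs."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        c1, c2 = rng.choice(SENSE, size=2)
        sd, nd = ng86.codon_pair_differences(c1, c2)
        assert sd + nd == pytest.approx(
            sum(a != b for a, b in zip(c1, c2)), abs=1e-12
        )


def test_jukes_cantor_closed_form_and_convexity():
    assert ng86.jukes_cantor(0.0) == 0.0
    assert ng86.jukes_cantor(0.3) == pytest.approx(0.3831, abs=5e-5)
    for p in np.linspace(0.01, 0.74, 30):
        assert ng86.jukes_cantor(p) > p
    with pytest.raises(ValueError):
        ng86.jukes_cantor(-0.1)
    with pytest.warns(UserWarning):
        assert np.isnan(ng86.jukes_cantor(0.8))


@given(st.floats(min_value=0.0, max_value=0.74))
@settings(max_examples=50, deadline=None)
def test_jukes_cantor_dominates_p(p):
    d = ng86.jukes_cantor(p)
    assert d >= p


def _random_rows(n_codons, rng, divergence=0.1):
    a_cod = [str(c) for c in rng.choice(SENSE, size=n_codons)]
    b_cod = [str(rng.choice(SENSE)) if rng.random() < divergence else c for c in a_cod]
    return "".join(a_cod), "".join(b_cod)


def test_pair_divergence_identity_and_symmetry():
    rng = np.random.default_rng(1)
    a, b = _random_rows(120, rng)
    same = ng86.pair_divergence(a, a)
    assert same.pS == same.pN == same.p == 0.0
    ab = ng86.pair_divergence(a, b)
    ba = ng86.pair_divergence(b, a)
    assert ab.dS == pytest.approx(ba.dS, abs=1e-12)
    assert ab.dN == pytest.approx(ba.dN, abs=1e-12)
    # site conservation
    assert ab.syn_sites + ab.nonsyn_sites == pytest.approx(3 * ab.n_codons, abs=1e-9)


def test_pair_divergence_pairwise_deletion():
    a = "TTTATG" + "---"
    b = "TTTATGCAA"
    est = ng86.pair_divergence(a, b)
    assert est.n_codons == 2  # gapped codon dropped for this pair
    with pytest.raises(ValueError):
        ng86.pair_divergence("---", "AAA")


def test_group_divergence_identical_sequences():
    rows = ["TTTATGCAACAG" * 10] * 4
    est = ng86.group_divergence(rows, n_bootstrap=100, seed=0)
    assert est.dS == est.dN == est.d == 0.0
    assert est.se_dS == est.se_dN == est.se_d == 0.0
    assert np.isnan(est.ratio)  # dS == 0 -> ratio undefined


def test_group_divergence_ratio_is_ratio_of_means():
    rng = np.random.default_rng(3)
    anc = simulate.random_coding_sequence(150, rng)
    rows = simulate.evolve_codon_star(anc, 5, 0.08, 0.03, rng)
    est = ng86.group_divergence(rows, n_bootstrap=200, seed=1)
    assert est.ratio == pytest.approx(est.dN / est.dS, rel=1e-12)


def test_bootstrap_se_shrinks_with_length():
    """At fixed divergence the codon-column bootstrap SE decays with length."""
    rng = np.random.default_rng(4)
    ses = {}
    for n_codons in (100, 10_000):
        anc = simulate.random_coding_sequence(n_codons, rng)
        rows = simulate.evolve_codon_star(anc, 3, 0.08, 0.03, rng)
        est = ng86.group_divergence(rows, n_bootstrap=200, seed=2)
        ses[n_codons] = est.se_dS
    assert ses[10_000] < ses[100] / 3


def test_z_test_equal_rates_gives_half_p():
    rows = ["TTTATGCAACAG" * 10] * 3  # dS = dN = 0 exactly
    res = ng86.z_test_selection(rows, "purifying", n_bootstrap=100, seed=0)
    assert res.z == 0.0
    assert res.p_value == 0.5


def test_z_test_detects_purifying_selection():
    rng = np.random.default_rng(5)
    anc = simulate.random_coding_sequence(250, rng)
    rows = simulate.evolve_codon_star(anc, 8, 0.09, 0.03, rng)
    res = ng86.z_test_selection(rows, "purifying", n_bootstrap=500, seed=3)
    assert res.p_value < 0.01
    pos = ng86.z_test_selection(rows, "positive", n_bootstrap=500, seed=3)
    assert pos.p_value > 0.5
    with pytest.raises(ValueError):
        ng86.z_test_selection(rows, "banana")


def test_z_test_power_under_purifying_regime():
    """Non-synonymous rate a third of synonymous: rejection in >=80% of runs."""
    rng = np.random.default_rng(6)
    rejected = 0
    n_sims = 100
    for _ in range(n_sims):
        anc = simulate.random_coding_sequence(200, rng)
        rows = simulate.evolve_codon_star(anc, 8, 0.0675, 0.0225, rng)
        res = ng86.z_test_selection(
            rows, "purifying", n_bootstrap=300, seed=int(rng.integers(2**31 - 1))
        )
        rejected += res.p_value < 0.05
    assert rejected / n_sims >= 0.80


def test_ks_ka_scatter_identical_pair_and_slope_formula():
    aligned = {"a": "TTTATG" * 20, "b": "TTTATG" * 20}
    res = ng86.ks_ka_scatter(aligned, {"a": False, "b": False})
    assert res.pairs.iloc[0][["Ks", "Ka"]].tolist() == [0.0, 0.0]
    # slope formula against direct computation
    rng = np.random.default_rng(7)
    x = rng.uniform(0.01, 0.3, 20)
    y = rng.uniform(0.0, 0.15, 20)
    assert ng86.zero_intercept_slope(x, y) == pytest.approx(
        float(np.sum(x * y) / np.sum(x * x)), rel=1e-12
    )


def test_ks_ka_orf_slope_below_pseudogene_slope():
    """Purifying ORFs vs unselected pseudogenes: Ka/Ks trendline is steeper
    for the pseudogene class."""
    rng = np.random.default_rng(8)
    anc = simulate.random_coding_sequence(250, rng)
    orf = simulate.evolve_codon_star(anc, 6, 0.09, 0.03, rng)
    pseudo = simulate.evolve_codon_star(anc, 6, 0.09, 0.09, rng)
    aligned = {f"o{i}": s for i, s in enumerate(orf)}
    aligned.update({f"p{i}": s for i, s in enumerate(pseudo)})
    flags = {k: k.startswith("p") for k in aligned}
    res = ng86.ks_ka_scatter(aligned, flags)
    assert res.slope_orf < res.slope_pseudo
    # mixed pairs are never formed
    assert set(res.pairs["pair_class"]) == {"orf_orf", "pseudo_pseudo"}
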