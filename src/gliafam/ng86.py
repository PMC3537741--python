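"""Nei–Gojobori (1986) synonymous/non-synonymous divergence and selection tests.

This module implements the NG86 counting method: every codon position is
partitioned into fractional synonymous (s) and non-synonymous (n) sites with
s + n = 3, and observed codon differences are partitioned into synonymous and
non-synonymous changes by equal-weight averaging over all minimal mutational
pathways.  Proportions are corrected for multiple hits with the Jukes–Cantor
formula, standard errors come from bootstrapping codon columns, and purifying
selection is tested with the codon-based Z-test on dS − dN.

Conventions (NG86 leaves two choices open; we follow the most common ones and
state them here):

* single-base changes that create a stop codon count as non-synonymous in the
  site tally;
* mutational pathways that pass through a stop codon are excluded from the
  difference tally — unless *every* pathway does, in which case all are kept.

Codons containing an alignment gap, an ambiguity code, or a stop in either
sequence of a pair are excluded for that pair only (pairwise deletion).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = "ACGT"
CODONS: list[str] = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


_AA = np.array([translate_codon(c) for c in CODONS])
_IS_STOP = np.array([c in STOP_CODONS for c in CODONS])


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional synonymous (s) and non-synonymous (n) sites of one codon."""

    s: float
    n: float


def codon_sites(codon: str) -> CodonSiteCounts:
    """NG86 site counts for a sense codon.

    At each of the three positions the fraction of the three possible
    single-base changes that are synonymous contributes to ``s``; changes to
    stop codons are non-synonymous.  ``s + n == 3`` exactly (computed in
    rational arithmetic).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no NG86 site counts: {codon}")
    aa = translate_codon(codon)
    s = Fraction(0)
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                s += Fraction(1, 3)
    return CodonSiteCounts(s=float(s), n=float(3 - s))


def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two sense codons.

    Differences are averaged with equal weight over all minimal mutational
    pathways between the codons; pathways visiting a stop codon are excluded
    when any stop-free pathway exists.  Returns ``(sd, nd)`` with
    ``sd + nd`` equal to the number of differing positions.
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if len(c) != 3 or any(b not in _BASES for b in c):
            raise ValueError(f"not an unambiguous codon: {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon not comparable: {c}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[Fraction, Fraction, bool]:
        sd = Fraction(0)
        nd = Fraction(0)
        via_stop = False
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                via_stop = via_stop or (nxt in STOP_CODONS and nxt != c2)
                nd += 1  # stop transitions are non-synonymous by convention
            elif translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, via_stop

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    clean = [p for p in paths if not p[2]]
    used = clean if clean else paths
    sd = sum(p[0] for p in used) / len(used)
    nd = sum(p[1] for p in used) / len(used)
    return (float(sd), float(nd))


# Precomputed lookup tables over codon indices; stop codons carry NaN and are
# masked out before use.
S_FRAC = np.full(64, np.nan)
for _i, _c in enumerate(CODONS):
    if not _IS_STOP[_i]:
        S_FRAC[_i] = codon_sites(_c).s

SD_TAB = np.full((64, 64), np.nan)
ND_TAB = np.full((64, 64), np.nan)
NDIFF_TAB = np.zeros((64, 64), dtype=np.int8)
for _i, _c1 in enumerate(CODONS):
    for _j, _c2 in enumerate(CODONS):
        NDIFF_TAB[_i, _j] = sum(a != b for a, b in zip(_c1, _c2))
        if not (_IS_STOP[_i] or _IS_STOP[_j]):
            _sd, _nd = codon_pair_differences(_c1, _c2)
            SD_TAB[_i, _j] = _sd
            ND_TAB[_i, _j] = _nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3).

    Returns NaN (with a warning) for saturated proportions p >= 3/4, which
    callers drop from averages.
    """
    if p < 0:
        raise ValueError(f"proportion of differences must be >= 0, got {p}")
    if p >= 0.75:
        warnings.warn(f"saturated proportion p={p:.4f} >= 3/4; distance undefined")
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def _jc_arr(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return np.where(p < 0.75, d, np.nan)


def encode_codon_rows(rows: list[str]) -> np.ndarray:
    """Aligned nucleotide rows -> (n_rows, n_codon_columns) codon index array.

    Codons containing gaps, ambiguity codes, or encoding a stop are marked -1
    (excluded from comparisons involving that row).
    """
    if not rows:
        raise ValueError("no rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("aligned rows must have equal length")
    if length % 3:
        raise ValueError(f"alignment length {length} is not a codon multiple")
    ncod = length // 3
    out = np.full((len(rows), ncod), -1, dtype=np.int32)
    for i, row in enumerate(rows):
        row = row.upper()
        for c in range(ncod):
            sub = row[3 * c : 3 * c + 3]
            idx = CODON_INDEX.get(sub)
            if idx is not None and not _IS_STOP[idx]:
                out[i, c] = idx
    return out


@dataclass(frozen=True)
class PairDivergence:
    pS: float
    pN: float
    p: float
    dS: float
    dN: float
    d: float
    syn_sites: float
    nonsyn_sites: float
    n_codons: int


def _pair_columns(e1: np.ndarray, e2: np.ndarray):
    """Per-codon-column contributions for one pair of encoded rows."""
    valid = (e1 >= 0) & (e2 >= 0)
    i1 = np.where(valid, e1, 0)
    i2 = np.where(valid, e2, 0)
    sd = np.where(valid, SD_TAB[i1, i2], 0.0)
    nd = np.where(valid, ND_TAB[i1, i2], 0.0)
    ss = np.where(valid, (S_FRAC[i1] + S_FRAC[i2]) / 2.0, 0.0)
    ns = np.where(valid, 3.0 - (S_FRAC[i1] + S_FRAC[i2]) / 2.0, 0.0)
    diffs = np.where(valid, NDIFF_TAB[i1, i2], 0).astype(float)
    ntv = 3.0 * valid
    return valid, sd, nd, ss, ns, diffs, ntv


def pair_divergence(a: str, b: str) -> PairDivergence:
    """NG86 divergence between two rows of a codon-aware alignment.

    Gapped/ambiguous/stop codons in either row are pairwise-deleted.  pS and
    pN are JC-corrected to dS and dN; p and d are per-nucleotide quantities
    over the retained codons.
    """
    enc = encode_codon_rows([a, b])
    valid, sd, nd, ss, ns, diffs, ntv = _pair_columns(enc[0], enc[1])
    n_codons = int(valid.sum())
    if n_codons == 0:
        raise ValueError("no comparable codons between the two rows")
    S = float(ss.sum())
    N = float(ns.sum())
    pS = float(sd.sum()) / S
    pN = float(nd.sum()) / N
    p = float(diffs.sum()) / float(ntv.sum())
    return PairDivergence(
        pS=pS,
        pN=pN,
        p=p,
        dS=float(_jc_arr(np.array(pS))),
        dN=float(_jc_arr(np.array(pN))),
        d=float(_jc_arr(np.array(p))),
        syn_sites=S,
        nonsyn_sites=N,
        n_codons=n_codons,
    )


@dataclass(frozen=True)
class DivergenceEstimate:
    """Mean pairwise divergence of a sequence group with bootstrap SEs."""

    dS: float
    dN: float
    d: float
    se_dS: float
    se_dN: float
    se_d: float
    ratio: float
    n_pairs: int
    n_dropped_pairs: int = 0


def dn_ds_ratio(dN: float, dS: float) -> float:
    """dN/dS as the ratio of the group means (the reported-table convention)."""
    if not np.isfinite(dS) or dS <= 0:
        return float("nan")
    return dN / dS


class _GroupProfiles:
    """Stacked per-pair, per-codon-column contribution matrices for a group."""

    def __init__(self, rows: list[str]):
        if len(rows) < 2:
            raise ValueError("need at least 2 sequences")
        enc = encode_codon_rows(rows)
        pairs = list(itertools.combinations(range(len(rows)), 2))
        mats = {k: [] for k in ("sd", "nd", "ss", "ns", "diffs", "ntv")}
        for i, j in pairs:
            _, sd, nd, ss, ns, diffs, ntv = _pair_columns(enc[i], enc[j])
            for key, arr in zip(mats, (sd, nd, ss, ns, diffs, ntv)):
                mats[key].append(arr)
        self.n_pairs = len(pairs)
        self.n_cols = enc.shape[1]
        self.m = {k: np.asarray(v) for k, v in mats.items()}

    def estimates(self, colsum=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pair (dS, dN, d); ``colsum`` maps a (P, C) matrix to pair sums.

        With the default colsum (plain sum over columns) this is the point
        estimate; bootstrap replicates pass weighted sums instead.
        """
        if colsum is None:
            colsum = lambda m: m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pS = colsum(self.m["sd"]) / colsum(self.m["ss"])
            pN = colsum(self.m["nd"]) / colsum(self.m["ns"])
            p = colsum(self.m["diffs"]) / colsum(self.m["ntv"])
        return _jc_arr(pS), _jc_arr(pN), _jc_arr(p)


def _group_point_and_boot(
    rows: list[str], n_bootstrap: int, seed
) -> tuple[dict, np.ndarray, np.ndarray, np.ndarray, int]:
    """Point estimates plus bootstrap replicate means of (dS, dN, d).

    The bootstrap resamples codon columns of the alignment (the same columns
    for every pair within a replicate); pair statistics are recomputed and
    averaged per replicate.
    """
    prof = _GroupProfiles(rows)
    dS_p, dN_p, d_p = prof.estimates()
    dropped = int(np.isnan(dS_p).sum() + np.isnan(dN_p).sum() + np.isnan(d_p).sum())
    if dropped:
        logger.warning("dropped %d undefined pair statistics from group means", dropped)
    if np.all(np.isnan(dS_p)) and np.all(np.isnan(dN_p)):
        raise ValueError("all sequence pairs undefined; cannot estimate divergence")
    point = {
        "dS": float(np.nanmean(dS_p)),
        "dN": float(np.nanmean(dN_p)),
        "d": float(np.nanmean(d_p)),
    }
    rng = np.random.default_rng(seed)
    C = prof.n_cols
    counts = rng.multinomial(C, np.full(C, 1.0 / C), size=n_bootstrap).astype(float)
    colsum = lambda m: m @ counts.T  # (P, B)
    dS_b, dN_b, d_b = prof.estimates(colsum)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN replicates
        boot_dS = np.nanmean(dS_b, axis=0)
        boot_dN = np.nanmean(dN_b, axis=0)
        boot_d = np.nanmean(d_b, axis=0)
    return point, boot_dS, boot_dN, boot_d, prof.n_pairs


def _boot_se(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def group_divergence(
    rows: list[str], n_bootstrap: int = 1000, seed: int | None = None
) -> DivergenceEstimate:
    """Mean pairwise dS, dN and d within a group, with bootstrap SEs.

    Means are taken over all unordered pairs; SEs are standard deviations of
    the group mean over ``n_bootstrap`` codon-column resamples.  Deterministic
    given ``seed``.
    """
    point, bS, bN, bd, n_pairs = _group_point_and_boot(rows, n_bootstrap, seed)
    return DivergenceEstimate(
        dS=point["dS"],
        dN=point["dN"],
        d=point["d"],
        se_dS=_boot_se(bS),
        se_dN=_boot_se(bN),
        se_d=_boot_se(bd),
        ratio=dn_ds_ratio(point["dN"], point["dS"]),
        n_pairs=n_pairs,
    )


@dataclass(frozen=True)
class SelectionTestResult:
    z: float
    p_value: float
    alternative: str


def z_test_selection(
    rows: list[str],
    alternative: str = "purifying",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> SelectionTestResult:
    """Codon-based Z-test for selection on a group of aligned sequences.

    Z = (dS - dN) / SE_boot(dS - dN), with the bootstrap variance taken over
    codon-column resamples.  One-tailed normal p-value for the 'purifying'
    (dS > dN) and 'positive' (dN > dS) alternatives, two-tailed for
    'neutral-deviation'.
    """
    if alternative not in ("purifying", "positive", "neutral-deviation"):
        raise ValueError(f"unknown alternative: {alternative}")
    point, bS, bN, _, _ = _group_point_and_boot(rows, n_bootstrap, seed)
    diff = point["dS"] - point["dN"]
    se = _boot_se(bS - bN)
    if not np.isfinite(se) or se == 0.0:
        if diff == 0.0:
            z = 0.0
            p = 0.5 if alternative != "neutral-deviation" else 1.0
        else:
            z = float(np.sign(diff)) * float("inf")
            p = float("nan")
        return SelectionTestResult(z=z, p_value=p, alternative=alternative)
    z = diff / se
    if alternative == "purifying":
        p = float(stats.norm.sf(z))
    elif alternative == "positive":
        p = float(stats.norm.sf(-z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return SelectionTestResult(z=float(z), p_value=p, alternative=alternative)


@dataclass
class PairwiseKsKa:
    """Pairwise Ks/Ka values per class plus zero-intercept trendline slopes."""

    pairs: pd.DataFrame
    slope_orf: float = float("nan")
    slope_pseudo: float = float("nan")


def zero_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with the intercept fixed at zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    denom = float(np.sum(x * x))
    if x.size == 0 or denom == 0.0:
        return float("nan")
    return float(np.sum(x * y) / denom)


def ks_ka_scatter(aligned: dict[str, str], is_pseudogene: dict[str, bool]) -> PairwiseKsKa:
    """Pairwise Ks (=dS) and Ka (=dN) within the ORF class and the pseudogene
    class, with zero-intercept least-squares trendline slopes of Ka on Ks.

    Mixed ORF/pseudogene pairs are not formed; classes with fewer than two
    members get a missing slope.
    """
    rows = []
    ids = sorted(aligned)
    for i, j in itertools.combinations(ids, 2):
        pi, pj = is_pseudogene[i], is_pseudogene[j]
        if pi != pj:
            continue
        cls = "pseudo_pseudo" if pi else "orf_orf"
        try:
            est = pair_divergence(aligned[i], aligned[j])
        except ValueError:
            continue
        rows.append({"id1": i, "id2": j, "Ks": est.dS, "Ka": est.dN, "pair_class": cls})
    pairs = pd.DataFrame(rows, columns=["id1", "id2", "Ks", "Ka", "pair_class"])
    result = PairwiseKsKa(pairs=pairs)
    for cls, attr in (("orf_orf", "slope_orf"), ("pseudo_pseudo", "slope_pseudo")):
        sub = pairs[pairs["pair_class"] == cls]
        if len(sub) >= 1:
            setattr(result, attr, zero_intercept_slope(sub["Ks"].values, sub["Ka"].values))
    return result
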