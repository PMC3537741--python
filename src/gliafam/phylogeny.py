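"""Distance phylogenetics and supported-group delineation.

Pairwise Jukes–Cantor distances with pairwise deletion, Saitou–Nei neighbour
joining with deterministic tie-breaking, nonparametric bootstrap support on
alignment columns, and calling of sequence groups as maximal supported clades
within the ingroup (default support threshold 0.84).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
MIN_NT = 600
MIN_AA = 200
DEFAULT_SUPPORT_THRESHOLD = 0.84
DEFAULT_TREE_BOOTSTRAP = 500


def filter_by_length(alignment: dict[str, str], min_residues: int) -> dict[str, str]:
    """Drop rows whose non-gap length is below ``min_residues``.

    Mirrors the two-stage exclusion rule: <600 nt for the nucleotide tree,
    <200 aa for the protein tree.  Rows kept at exactly the threshold.
    """
    kept = {}
    for sid, row in alignment.items():
        n = sum(1 for ch in row if ch not in (GAP, "N", "?"))
        if n >= min_residues:
            kept[sid] = row
        else:
            logger.info("filtered %s: %d non-gap residues < %d", sid, n, min_residues)
    if not kept:
        raise ValueError("length filter removed every row")
    return kept


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with NaN marking undefined (saturated) pairs."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diagonal(v), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite], v.T[finite]
        ):
            raise ValueError("matrix must be symmetric")
        self.values = v

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.isnan(self.values[off]).any())


def _encode(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = sorted(alignment)
    L = len(alignment[labels[0]])
    if any(len(alignment[k]) != L for k in labels):
        raise ValueError("alignment rows must have equal length")
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    arr = np.full((len(labels), L), 255, dtype=np.uint8)
    for i, k in enumerate(labels):
        for j, ch in enumerate(alignment[k].upper()):
            arr[i, j] = codes.get(ch, 255)
    return labels, arr


def _p_distances(arr: np.ndarray) -> np.ndarray:
    """Pairwise-deletion p-distance matrix from an encoded alignment."""
    valid = arr < 255
    pair_valid = valid[:, None, :] & valid[None, :, :]
    diffs = (arr[:, None, :] != arr[None, :, :]) & pair_valid
    n_valid = pair_valid.sum(axis=2)
    n_diff = diffs.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n_diff / n_valid
    np.fill_diagonal(p, 0.0)
    return p


def jc_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Jukes–Cantor-corrected nucleotide distances with pairwise deletion.

    Saturated pairs (p >= 3/4) and pairs with no shared sites are NaN.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    labels, arr = _encode(alignment)
    p = _p_distances(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    d = np.where(p < 0.75, d, np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d)


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion (amino-acid trees)."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    labels = sorted(alignment)
    L = len(alignment[labels[0]])
    rows = [alignment[k].upper() for k in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nv = nd = 0
            for a, b in zip(rows[i], rows[j]):
                if a in (GAP, "X", "?") or b in (GAP, "X", "?"):
                    continue
                nv += 1
                nd += a != b
            d[i, j] = d[j, i] = nd / nv if nv else np.nan
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining.

    Deterministic: ties in the Q-criterion break by the lexicographically
    lowest label pair (each cluster is represented by its smallest member
    label).  Negative branch lengths are clamped to zero with the deficit
    transferred to the adjacent branch of the joined pair.
    """
    if D.has_missing:
        raise ValueError("distance matrix has missing entries; impute or drop taxa")
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = dendropy.TaxonNamespace(D.labels)
    nodes = []
    for lab in D.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append({"node": node, "min_label": lab})
    dist = D.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        Q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((nodes[i]["min_label"], nodes[j]["min_label"]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        dij = dist[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ci, cj = nodes[i]["node"], nodes[j]["node"]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        dnew = 0.5 * (dist[i, :] + dist[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_dist = np.zeros((len(keep) + 1, len(keep) + 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[-1, :-1] = dnew[keep]
        new_dist[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [
            {
                "node": parent,
                "min_label": min(nodes[i]["min_label"], nodes[j]["min_label"]),
            }
        ]
        dist = new_dist

    center = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
        lens = [
            (d01 + d02 - d12) / 2.0,
            (d01 + d12 - d02) / 2.0,
            (d02 + d12 - d01) / 2.0,
        ]
        for entry, ln in zip(nodes, lens):
            center.add_child(entry["node"])
            entry["node"].edge.length = max(ln, 0.0)
    else:  # 2 taxa (only reachable from a 2x2 input; kept for completeness)
        for entry in nodes:
            center.add_child(entry["node"])
            entry["node"].edge.length = dist[0, 1] / 2.0

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _nontrivial_splits(tree: dendropy.Tree, all_labels: frozenset) -> set[frozenset]:
    """Canonical nontrivial bipartitions: the side not holding the smallest label."""
    anchor = min(all_labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_labels - below
        if 2 <= len(side) <= len(all_labels) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int = DEFAULT_TREE_BOOTSTRAP,
    seed: int | None = None,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree from the full alignment plus bootstrap split supports.

    Columns are resampled with replacement ``n_reps`` times; support of a
    split is the fraction of replicate NJ trees containing it.  Saturated
    (undefined) distances inside a replicate are imputed with the largest
    finite distance of that replicate.  Deterministic given ``seed`` and
    invariant to the input order of rows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, arr = _encode(alignment)
    all_labels = frozenset(labels)
    main = neighbor_joining(_matrix_from_encoded(labels, arr))
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    L = arr.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(L, size=L)
        rep = neighbor_joining(_matrix_from_encoded(labels, arr[:, idx]))
        for split in _nontrivial_splits(rep, all_labels):
            counts[split] += 1
    supports = {s: c / n_reps for s, c in counts.items()}
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if min(all_labels) not in below else all_labels - below
        node.label = f"{supports.get(side, 0.0):.3f}"
    return main, supports


def _matrix_from_encoded(labels: list[str], arr: np.ndarray) -> DistanceMatrix:
    p = _p_distances(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(len(labels), dtype=bool)
    if np.isnan(d[off]).any():
        finite_max = np.nanmax(d[off]) if np.isfinite(d[off]).any() else 1.0
        logger.warning("imputing saturated distances with max finite %.3f", finite_max)
        d = np.where(np.isnan(d) & off, finite_max, d)
    return DistanceMatrix(labels=labels, values=d)


@dataclass
class GroupAssignment:
    """Supported sequence groups: disjoint sets of ids, keyed by group number."""

    groups: dict[int, set[str]]
    support_threshold: float
    outgroup_ids: set[str] = field(default_factory=set)
    ungrouped: set[str] = field(default_factory=set)

    def label_of(self) -> dict[str, int]:
        out = {}
        for gid, members in self.groups.items():
            for m in members:
                out[m] = gid
        return out


def call_groups(
    tree: dendropy.Tree,
    supports: dict[frozenset, float],
    outgroup_ids: set[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> GroupAssignment:
    """Call groups as maximal supported clades strictly within the ingroup.

    The tree is rooted on the outgroup; proper descendants of the ingroup
    root whose subtending split has bootstrap support >= threshold become
    groups (maximal, non-nested: accepted clades absorb their subclades).
    Sequences in no accepted clade are reported as ungrouped.  Groups are
    numbered 1..k by their smallest member id.
    """
    t = tree.clone(depth=1)
    all_labels = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    og = frozenset(outgroup_ids) & all_labels
    ingroup = all_labels - og
    if not og:
        raise ValueError("no outgroup taxa present in the tree")

    # root at an outgroup leaf so that outgroup-free clades are meaningful
    # even when the outgroup sequences are not monophyletic
    og_leaf = min(
        (lf for lf in t.leaf_node_iter() if lf.taxon.label in og),
        key=lambda lf: lf.taxon.label,
    )
    t.reroot_at_edge(og_leaf.edge, update_bipartitions=False)

    def support_of(node) -> float:
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if min(all_labels) not in below else all_labels - below
        return supports.get(side, 0.0)

    accepted: list[set[str]] = []

    def descend(node):
        for child in node.child_nodes():
            if child.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in child.leaf_iter())
            if (
                not (below & og)
                and below != ingroup
                and support_of(child) >= support_threshold
            ):
                accepted.append(set(below))  # maximal: do not descend
            else:
                descend(child)

    descend(t.seed_node)

    accepted.sort(key=lambda s: min(s))
    groups = {k + 1: members for k, members in enumerate(accepted)}
    grouped = set().union(*accepted) if accepted else set()
    if not groups:
        logger.warning("no supported clades at threshold %.2f", support_threshold)
    return GroupAssignment(
        groups=groups,
        support_threshold=support_threshold,
        outgroup_ids=set(og),
        ungrouped=ingroup - grouped,
    )
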