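"""Group presence matrices and Dollo parsimony gain/loss reconstruction.

Each gamma-gliadin group is a Dollo character on the genome tree: it is
gained exactly once — at the most recent common ancestor of every genome
where it occurs (pseudogene-only occurrences count as presence) — and may be
lost repeatedly.  Losses are placed on the maximal subtrees without any
occurrence, which is the unique minimum-cardinality loss set explaining the
tips; genomes where the group survives only as pseudogenes receive a
pseudogenisation event on their terminal branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import dendropy
import pandas as pd

from .phylogeny import GroupAssignment
from .simulate import GroupEvent

PRESENT = "present"
PSEUDO_ONLY = "pseudogene_only"
ABSENT = "absent"

_STATE_TOKENS = {"1": PRESENT, "P": PSEUDO_ONLY, "0": ABSENT}
_TOKEN_OF = {v: k for k, v in _STATE_TOKENS.items()}


@dataclass
class PresenceMatrix:
    """Group-by-genome occurrence states with per-cell annotations.

    ``states``: DataFrame indexed by group id, columns = genome labels, cells
    in {present, pseudogene_only, absent}; ``nine_cys``: same-shaped boolean
    DataFrame flagging cells whose intact genes all carry nine cysteines.
    """

    states: pd.DataFrame
    nine_cys: pd.DataFrame

    def __post_init__(self):
        bad = set(self.states.values.ravel()) - {PRESENT, PSEUDO_ONLY, ABSENT}
        if bad:
            raise ValueError(f"invalid presence states: {bad}")
        if not self.states.index.equals(self.nine_cys.index) or not self.states.columns.equals(
            self.nine_cys.columns
        ):
            raise ValueError("states and nine_cys must share index/columns")

    def to_tsv(self, path) -> None:
        df = self.states.copy()
        for g in df.index:
            for c in df.columns:
                tok = _TOKEN_OF[df.loc[g, c]]
                if self.nine_cys.loc[g, c]:
                    tok += ":9cys"
                df.loc[g, c] = tok
        df.to_csv(path, sep="\t", index_label="group")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="group", dtype=str)
        states = raw.copy()
        nine = raw.copy()
        for g in raw.index:
            for c in raw.columns:
                tok = str(raw.loc[g, c]).strip()
                nine.loc[g, c] = tok.endswith(":9cys")
                states.loc[g, c] = _STATE_TOKENS[tok.split(":")[0]]
        return cls(states=states, nine_cys=nine.astype(bool))


def build_presence_matrix(
    assignment: GroupAssignment, annotations: pd.DataFrame
) -> PresenceMatrix:
    """Summarise called groups into a presence matrix.

    ``annotations`` has one row per sequence id with columns ``id``,
    ``genome``, ``is_pseudogene`` and ``cysteine_count``.  A cell is present
    if the genome holds any intact gene of the group, pseudogene_only if only
    pseudogenes, absent otherwise; the nine-cysteine flag is set when all the
    cell's intact genes have exactly nine cysteines.
    """
    ann = annotations.set_index("id")
    genomes = sorted(ann["genome"].unique())
    groups = sorted(assignment.groups)
    states = pd.DataFrame(ABSENT, index=groups, columns=genomes)
    nine = pd.DataFrame(False, index=groups, columns=genomes)
    for gid, members in assignment.groups.items():
        sub = ann.loc[[m for m in members if m in ann.index]]
        for genome, rows in sub.groupby("genome"):
            intact = rows[~rows["is_pseudogene"]]
            if len(intact):
                states.loc[gid, genome] = PRESENT
                nine.loc[gid, genome] = bool((intact["cysteine_count"] == 9).all())
            elif len(rows):
                states.loc[gid, genome] = PSEUDO_ONLY
    return PresenceMatrix(states=states, nine_cys=nine)


@dataclass
class GainLossScenario:
    """Events and ancestral states of a Dollo reconstruction.

    Branches are identified by the tip set below them; ``ancestral_states``
    maps each node's tip set to the set of groups present at that node;
    ``cost`` counts all events (gains + losses + pseudogenisations).
    """

    events: list[GroupEvent]
    ancestral_states: dict[frozenset, set] = field(default_factory=dict)
    cost: int = 0

    def events_of_kind(self, kind: str) -> list[GroupEvent]:
        return [e for e in self.events if e.kind == kind]


def dollo_reconstruct(matrix: PresenceMatrix, genome_tree: dendropy.Tree) -> GainLossScenario:
    """Single-gain Dollo reconstruction of group gains/losses on a rooted tree.

    Pseudogene-only cells count as lineage presence for gain placement and
    add a pseudogenisation event on the tip's terminal branch; groups absent
    everywhere contribute no events.
    """
    tree = genome_tree
    tree.is_rooted = True
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    extra = set(matrix.states.columns) - tips
    if extra:
        raise ValueError(f"matrix columns missing from the tree: {sorted(extra)}")

    clade_of = {}
    for node in tree.preorder_node_iter():
        clade_of[node] = frozenset(lf.taxon.label for lf in node.leaf_iter())

    events: list[GroupEvent] = []
    presence_at: dict[frozenset, set] = {clade_of[n]: set() for n in tree.preorder_node_iter()}

    for gid in matrix.states.index:
        row = matrix.states.loc[gid]
        occupied = {c for c in matrix.states.columns if row[c] != ABSENT}
        if not occupied:
            continue
        if len(occupied) == 1:
            gain_node = tree.find_node_for_taxon(
                next(t for t in tree.taxon_namespace if t.label in occupied)
            )
        else:
            gain_node = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in occupied])
        events.append(GroupEvent(clade=clade_of[gain_node], group_id=gid, kind="gain"))

        def mark(node):
            presence_at[clade_of[node]].add(gid)
            for child in node.child_nodes():
                if clade_of[child] & occupied:
                    mark(child)
                else:
                    events.append(
                        GroupEvent(clade=clade_of[child], group_id=gid, kind="loss")
                    )

        mark(gain_node)
        for tip in sorted(occupied):
            if row[tip] == PSEUDO_ONLY:
                events.append(
                    GroupEvent(clade=frozenset({tip}), group_id=gid, kind="pseudogenisation")
                )

    internal_states = {
        clade_of[n]: presence_at[clade_of[n]]
        for n in tree.preorder_node_iter()
    }
    return GainLossScenario(
        events=events, ancestral_states=internal_states, cost=len(events)
    )


def scenario_table(scenario: GainLossScenario) -> pd.DataFrame:
    rows = [
        {
            "branch": ",".join(sorted(e.clade)),
            "group_id": e.group_id,
            "kind": e.kind,
        }
        for e in scenario.events
    ]
    return pd.DataFrame(rows, columns=["branch", "group_id", "kind"])


# ---------------------------------------------------------------------------
# shipped fixtures: the reference genome tree and group-occurrence matrix
# ---------------------------------------------------------------------------


def reference_genome_tree() -> dendropy.Tree:
    """Rooted genome/genus guide tree over the 12 Aegilops/Triticum genome
    types plus the related genera Lophopyrum, Crithopsis and Dasypyrum."""
    text = resources.files("gliafam.data").joinpath("genome_tree.nwk").read_text()
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def reference_presence_matrix() -> PresenceMatrix:
    """The published occurrence pattern of the six gamma-gliadin groups."""
    with resources.as_file(
        resources.files("gliafam.data").joinpath("presence_matrix.tsv")
    ) as path:
        return PresenceMatrix.from_tsv(path)


def aegilops_triticum_mrca_groups(scenario: GainLossScenario, tree: dendropy.Tree) -> set:
    """Groups reconstructed at the MRCA of the Aegilops/Triticum genomes
    (all tips except the outgroup genera)."""
    outgenera = {"Lophopyrum", "Crithopsis", "Dasypyrum"}
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ingroup = frozenset(tips - outgenera)
    if ingroup not in scenario.ancestral_states:
        raise ValueError("ingroup MRCA node not found in the scenario")
    return set(scenario.ancestral_states[ingroup])
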