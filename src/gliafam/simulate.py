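"""Synthetic gamma-gliadin gene families with known truth.

The generator emulates the structure of the gamma-gliadin multigene family so
that every downstream stage (contig clustering, pseudogene annotation,
divergence estimation, group calling, gain/loss reconstruction) can be tested
against a known answer:

* genes are built from the canonical domain architecture — signal peptide (S,
  starting with the conserved primer site), unique N-terminal domain (I),
  repetitive domain (II) of tandem 21-bp glutamine/proline-rich units,
  cysteine-rich domain (III, six cysteines), glutamine-rich domain (IV) and
  C-terminal domain (V, two cysteines) — full ORFs of 648–1089 bp;
* groups in ``nine_cys_groups`` carry a ninth cysteine encoded TGC at a fixed
  position where the other groups carry TCC;
* length variation arises from whole-repeat-unit insertions/deletions in
  domain II, so the frame is preserved unless a frameshift is drawn
  explicitly;
* gene groups are gained, lost and pseudogenised on a genome tree according
  to a per-branch event model whose default encodes the published pattern of
  six groups across the eight Aegilops/Triticum genomes;
* pseudogenisation plants an internal stop codon (probability 0.5) or a
  +/-1 bp frameshift;
* point substitutions are uniform (Jukes–Cantor-like); on intact lineages
  substitutions creating stop codons or cysteines are rejected, a stylised
  purifying selection that keeps the truth labels exact;
* each tip gene is emitted as several near-duplicate clone reads with
  independent per-base errors.

All randomness flows from a single integer seed; two runs with the same seed
produce byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .annotate import SIGNAL_ANCHOR, ReferenceProfile
from .io import NucleotideRecord
from .ng86 import CODON_INDEX, CODONS, S_FRAC, STOP_CODONS, translate_codon

# ---------------------------------------------------------------------------
# gene template
# ---------------------------------------------------------------------------

#: signal peptide: the conserved primer site completed to 20 hydrophobic codons
_SIGNAL_NT = SIGNAL_ANCHOR + "TT" + "GCTCTCGTTGCTGCTACCGCTACCATTGCCGTTGCTCTC"
#: unique N-terminal domain I (12 aa)
_DOMAIN_I_NT = "AACATGCAAGTTGATCCTAGTGGTCAAGTTCAATGG"
#: one repeat unit of domain II: PQQPFPQ (21 bp, glutamine/proline-rich)
REPEAT_UNIT = "CCACAACAACCATTCCCACAA"
REPEAT_UNIT_AA = 7
_DOMAIN_III_AA = 100
_DOMAIN_V_AA = 40
#: cysteine codon offsets (aa) within III and V
_CYS_III = (10, 25, 40, 55, 70, 85)
_CYS_V = (10, 30)
#: offset (aa) within III of the TCC/TGC site carrying the ninth cysteine
_NINE_CYS_OFFSET = 95
_STOP_NT = "TAA"
_IV_MIN_AA = 4
_FIXED_AA = 20 + 12 + _DOMAIN_III_AA + _DOMAIN_V_AA  # S + I + III + V

MIN_ORF_BP = 648
MAX_ORF_BP = 1089

#: deterministic per-group template divergence (fraction of mutable codons)
_GROUP_DIVERGENCE = 0.10
_GROUP_SEED_BASE = 104729

_FILLER_CODONS = ("CAA", "CCG", "CAG", "ATC", "TTG", "CAT", "TCA", "GGT", "GTC", "AAC")


def _filler(n_codons: int, phase: int = 0) -> str:
    return "".join(
        _FILLER_CODONS[(phase + i) % len(_FILLER_CODONS)] for i in range(n_codons)
    )


@dataclass
class _Gene:
    """An evolving gene: sequence plus live coordinates of its landmarks."""

    seq: str
    bounds: dict[str, tuple[int, int]]  # nt coords of S, I, II, III, IV, V
    cys_nt: list[int]  # codon start positions of the 8 structural cysteines
    var_nt: int  # codon start of the TCC/TGC ninth-cysteine site
    n_units: int
    frame_ok: bool = True
    defects: list[tuple[str, int]] = field(default_factory=list)

    def clone(self) -> "_Gene":
        return _Gene(
            seq=self.seq,
            bounds=dict(self.bounds),
            cys_nt=list(self.cys_nt),
            var_nt=self.var_nt,
            n_units=self.n_units,
            frame_ok=self.frame_ok,
            defects=list(self.defects),
        )

    @property
    def is_pseudogene(self) -> bool:
        return bool(self.defects)


def _build_template(length_bp: int, nine_cys: bool) -> _Gene:
    if length_bp % 3:
        raise ValueError(f"length_bp must be a codon multiple, got {length_bp}")
    if not MIN_ORF_BP <= length_bp <= MAX_ORF_BP:
        raise ValueError(
            f"length_bp must be within [{MIN_ORF_BP}, {MAX_ORF_BP}], got {length_bp}"
        )
    var_aa = length_bp // 3 - 1 - _FIXED_AA
    n_units = max(1, (var_aa - _IV_MIN_AA) // REPEAT_UNIT_AA)
    iv_aa = var_aa - n_units * REPEAT_UNIT_AA

    iii_codons = [_filler(1, phase=i) for i in range(_DOMAIN_III_AA)]
    for off in _CYS_III:
        iii_codons[off] = "TGT"
    iii_codons[_NINE_CYS_OFFSET] = "TGC" if nine_cys else "TCC"
    v_codons = [_filler(1, phase=i + 3) for i in range(_DOMAIN_V_AA)]
    for off in _CYS_V:
        v_codons[off] = "TGT"

    parts = [
        _SIGNAL_NT,
        _DOMAIN_I_NT,
        REPEAT_UNIT * n_units,
        "".join(iii_codons),
        "".join("CAA" if i % 2 == 0 else "CAG" for i in range(iv_aa)),
        "".join(v_codons),
        _STOP_NT,
    ]
    lens = [len(p) for p in parts]
    starts = [0] + list(itertools.accumulate(lens))
    bounds = {
        lab: (starts[i], starts[i + 1])
        for i, lab in enumerate(("S", "I", "II", "III", "IV", "V"))
    }
    iii0 = bounds["III"][0]
    v0 = bounds["V"][0]
    gene = _Gene(
        seq="".join(parts),
        bounds=bounds,
        cys_nt=[iii0 + 3 * o for o in _CYS_III] + [v0 + 3 * o for o in _CYS_V],
        var_nt=iii0 + 3 * _NINE_CYS_OFFSET,
        n_units=n_units,
    )
    assert len(gene.seq) == length_bp
    return gene


def _protected_nt(gene: _Gene) -> set[int]:
    prot = set(range(len(SIGNAL_ANCHOR)))
    for c in gene.cys_nt:
        prot.update(range(c, c + 3))
    prot.update(range(gene.var_nt, gene.var_nt + 3))
    prot.update(range(len(gene.seq) - 3, len(gene.seq)))  # terminal stop
    return prot


_BASES = "ACGT"


def _point_mutate(
    gene: _Gene,
    n_events: int,
    rng: np.random.Generator,
    nonsyn_acceptance: float = 1.0,
) -> None:
    """Apply ``n_events`` uniform substitutions.

    On intact lineages changes creating stop codons or cysteines are
    rejected, and non-synonymous changes are accepted with probability
    ``nonsyn_acceptance`` (stylised purifying selection); pseudogenised
    lineages evolve without constraint.
    """
    seq = list(gene.seq)
    protected = _protected_nt(gene)
    intact = gene.frame_ok and not gene.defects
    for _ in range(n_events):
        for _try in range(500):
            pos = int(rng.integers(len(seq)))
            if pos in protected:
                continue
            alt = _BASES[int(rng.integers(4))]
            if alt == seq[pos]:
                continue
            if intact:
                if _creates_bad_codon_from(seq, pos, alt):
                    continue
                if nonsyn_acceptance < 1.0:
                    c0 = 3 * (pos // 3)
                    codon = "".join(seq[c0 : c0 + 3])
                    if len(codon) == 3 and codon not in STOP_CODONS:
                        mut = codon[: pos - c0] + alt + codon[pos - c0 + 1 :]
                        if translate_codon(mut) != translate_codon(codon):
                            if rng.random() > nonsyn_acceptance:
                                continue
            seq[pos] = alt
            break
    gene.seq = "".join(seq)


def _creates_bad_codon_from(seq: list[str], pos: int, alt: str) -> bool:
    c0 = 3 * (pos // 3)
    codon = seq[c0 : c0 + 3]
    codon[pos - c0] = alt
    mut = "".join(codon)
    if len(mut) < 3:
        return False
    return mut in STOP_CODONS or (mut not in STOP_CODONS and translate_codon(mut) == "C")


def _shift_coords(gene: _Gene, at: int, delta: int) -> None:
    gene.bounds = {
        lab: (s + delta if s >= at else s, e + delta if e > at else e)
        for lab, (s, e) in gene.bounds.items()
    }
    gene.cys_nt = [c + delta if c >= at else c for c in gene.cys_nt]
    if gene.var_nt >= at:
        gene.var_nt += delta


def _unit_indels(gene: _Gene, rate: float, rng: np.random.Generator) -> None:
    """Whole-repeat-unit tandem insertions/deletions in domain II."""
    ii0, _ = gene.bounds["II"]
    n_ins = int(rng.binomial(gene.n_units, rate))
    for _ in range(n_ins):
        u = int(rng.integers(gene.n_units))
        start = ii0 + 21 * u
        unit = gene.seq[start : start + 21]
        ins_at = start + 21
        gene.seq = gene.seq[:ins_at] + unit + gene.seq[ins_at:]
        _shift_coords(gene, ins_at, 21)
        gene.n_units += 1
    n_del = int(rng.binomial(gene.n_units, rate)) if gene.n_units > 1 else 0
    for _ in range(n_del):
        if gene.n_units <= 1:
            break
        u = int(rng.integers(gene.n_units))
        start = ii0 + 21 * u
        gene.seq = gene.seq[:start] + gene.seq[start + 21 :]
        _shift_coords(gene, start + 21, -21)
        gene.n_units -= 1


def _pseudogenise(gene: _Gene, rng: np.random.Generator) -> None:
    """Plant a nonsense codon (p=0.5) or a +/-1 bp frameshift in domain IV."""
    if rng.random() < 0.5:
        iii0, iii1 = gene.bounds["III"]
        protected = {gene.var_nt} | set(gene.cys_nt)
        for _try in range(100):
            cidx = int(rng.integers(iii0 // 3, iii1 // 3))
            if 3 * cidx not in protected:
                break
        pos = 3 * cidx
        gene.seq = gene.seq[:pos] + "TAA" + gene.seq[pos + 3 :]
        gene.defects.append(("internal_stop", pos))
    else:
        iv0, iv1 = gene.bounds["IV"]
        pos = int(rng.integers(iv0, iv1))
        if rng.random() < 0.5:
            gene.seq = gene.seq[:pos] + "A" + gene.seq[pos:]
            _shift_coords(gene, pos, 1)
        else:
            gene.seq = gene.seq[: pos] + gene.seq[pos + 1 :]
            _shift_coords(gene, pos + 1, -1)
        gene.frame_ok = False
        gene.defects.append(("frameshift", pos))


# ---------------------------------------------------------------------------
# public template API
# ---------------------------------------------------------------------------

DEFAULT_NINE_CYS_GROUPS = frozenset({5, 6})


def _group_gene(group_id: int, length_bp: int, nine_cys_groups=DEFAULT_NINE_CYS_GROUPS) -> _Gene:
    gene = _build_template(length_bp, nine_cys=group_id in nine_cys_groups)
    if group_id == 0:
        return gene  # plain template (reference profile / outgroup ancestor)
    rng = np.random.default_rng(_GROUP_SEED_BASE + group_id)
    seq = list(gene.seq)
    protected = _protected_nt(gene)
    # each group's diagnostic substitutions fall in its own codon class, so
    # the six groups radiate star-like from the template: no alignment column
    # carries shared derived states for two groups, and between-group clades
    # draw no bootstrap support
    residue_class = (group_id - 1) % 6
    class_rate = min(_GROUP_DIVERGENCE * 6, 0.9)
    for c0 in range(0, len(seq) - 2, 3):
        if (c0 // 3) % 6 != residue_class:
            continue
        if c0 in protected or rng.random() >= class_rate:
            continue
        for _try in range(50):
            off = int(rng.integers(3))
            pos = c0 + off
            if pos in protected:
                continue
            alt = _BASES[int(rng.integers(4))]
            if alt == seq[pos] or _creates_bad_codon_from(seq, pos, alt):
                continue
            seq[pos] = alt
            break
    gene.seq = "".join(seq)
    return gene


def make_ancestral_gene(
    group_id: int,
    length_bp: int,
    nine_cys_groups=DEFAULT_NINE_CYS_GROUPS,
) -> NucleotideRecord:
    """Ancestral gamma-gliadin-like ORF for one group.

    The ORF starts with the literal signal-peptide primer site, contains the
    full domain architecture with a single terminal stop, and carries the
    ninth cysteine (TGC at the fixed TCC site) iff ``group_id`` is in
    ``nine_cys_groups``.
    """
    gene = _group_gene(group_id, length_bp, nine_cys_groups)
    return NucleotideRecord(
        id=f"anc|g{group_id}", genome="other", residues=gene.seq, source="simulated"
    )


def reference_profile(length_bp: int = 909) -> ReferenceProfile:
    """Intact reference ORF (plain template) with its domain boundaries."""
    gene = _build_template(length_bp, nine_cys=False)
    domains_aa = {lab: (s // 3, e // 3) for lab, (s, e) in gene.bounds.items()}
    return ReferenceProfile(sequence=gene.seq, domains_aa=domains_aa)


# ---------------------------------------------------------------------------
# family simulation on a genome tree
# ---------------------------------------------------------------------------

DEFAULT_GENOME_TREE = (
    "(((C:0.020,U:0.020):0.012,(M:0.020,N:0.020):0.012):0.010,"
    "(T:0.030,(D:0.022,S:0.022):0.010):0.010,A:0.032);"
)

ALL_DEFAULT_TIPS = frozenset("ACDMNSTU")


@dataclass(frozen=True)
class GroupEvent:
    """A gain/loss/pseudogenisation of one group on one branch.

    The branch is identified by the set of tip labels below it; the full tip
    set denotes the root (groups present in the family's common ancestor).
    """

    clade: frozenset
    group_id: int
    kind: str  # "gain" | "loss" | "pseudogenisation"

    def __post_init__(self):
        if self.kind not in ("gain", "loss", "pseudogenisation"):
            raise ValueError(f"unknown event kind {self.kind!r}")


def default_group_model() -> list[GroupEvent]:
    """Per-branch event model encoding the published six-group pattern over
    the eight Aegilops/Triticum genomes (A, C, D, M, N, S, T, U)."""
    f = frozenset
    E = GroupEvent
    return [
        # group 1: ancestral; kept in D and S, pseudogenised in U and M
        E(ALL_DEFAULT_TIPS, 1, "gain"),
        E(f("C"), 1, "loss"),
        E(f("N"), 1, "loss"),
        E(f("T"), 1, "loss"),
        E(f("A"), 1, "loss"),
        E(f("U"), 1, "pseudogenisation"),
        E(f("M"), 1, "pseudogenisation"),
        # group 2: the T-D-S lineage
        E(f("TDS"), 2, "gain"),
        # group 3: Ae. caudata specific
        E(f("C"), 3, "gain"),
        # group 4: ancestral; kept in A, M and N
        E(ALL_DEFAULT_TIPS, 4, "gain"),
        E(f("CU"), 4, "loss"),
        E(f("TDS"), 4, "loss"),
        # group 5: the C-U-M-N lineage, lost in C and M
        E(f("CUMN"), 5, "gain"),
        E(f("C"), 5, "loss"),
        E(f("M"), 5, "loss"),
        # group 6: ancestral, lost only in the A genome
        E(ALL_DEFAULT_TIPS, 6, "gain"),
        E(f("A"), 6, "loss"),
    ]


DEFAULT_GROUP_LENGTHS = {1: 1020, 2: 903, 3: 888, 4: 939, 5: 909, 6: 909}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gamma-gliadin family."""

    seed: int
    genome_tree: str = DEFAULT_GENOME_TREE
    group_model: list[GroupEvent] = field(default_factory=default_group_model)
    group_lengths: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_LENGTHS))
    n_genes_per_group_per_genome: int = 2
    point_sub_rate: float = 1.0
    repeat_indel_rate: float = 0.005
    clone_reads_per_gene: int = 3
    clone_error_rate: float = 0.002
    nonsyn_acceptance: float = 1.0 / 3.0
    nine_cys_groups: frozenset = DEFAULT_NINE_CYS_GROUPS
    n_outgroups: int = 3
    outgroup_divergence: float = 0.35

    def validate(self) -> None:
        for name in ("repeat_indel_rate", "clone_error_rate", "nonsyn_acceptance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.point_sub_rate < 0 or self.outgroup_divergence < 0:
            raise ValueError("rates must be non-negative")
        if self.n_genes_per_group_per_genome < 1 or self.clone_reads_per_gene < 1:
            raise ValueError("counts must be >= 1")
        tree = dendropy.Tree.get(data=self.genome_tree, schema="newick")
        tips = [t.label for t in tree.taxon_namespace]
        if len(tips) != len(set(tips)):
            raise ValueError("genome tree tips must carry unique labels")


@dataclass
class TruthTable:
    """Ground truth for a simulated family.

    ``records``: one row per emitted sequence (record_id, genome, group_id,
    gene_id, is_pseudogene); ``genes``: one row per distinct tip gene;
    ``events``: the planted per-branch event list; ``genome_tree``: newick.
    """

    records: pd.DataFrame
    genes: pd.DataFrame
    events: list[GroupEvent]
    genome_tree: str


def _clade(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def simulate_family(config: SimulationConfig) -> tuple[list[NucleotideRecord], TruthTable]:
    """Evolve a gamma-gliadin family down the genome tree.

    Returns the emitted clone reads and the truth table.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(
        data=config.genome_tree, schema="newick", preserve_underscores=True
    )
    events_by_clade: dict[frozenset, list[GroupEvent]] = {}
    for ev in config.group_model:
        events_by_clade.setdefault(frozenset(ev.clade), []).append(ev)

    root_clade = _clade(tree.seed_node)
    records: list[NucleotideRecord] = []
    rec_rows: list[dict] = []
    gene_rows: list[dict] = []

    def new_copies(group_id: int) -> dict[tuple[int, int], _Gene]:
        length = config.group_lengths.get(group_id, 909)
        base = _group_gene(group_id, length, config.nine_cys_groups)
        return {
            (group_id, k): base.clone()
            for k in range(config.n_genes_per_group_per_genome)
        }

    def apply_branch(genes: dict, node) -> dict:
        clade = _clade(node)
        evs = sorted(
            events_by_clade.get(clade, []), key=lambda e: (e.group_id, e.kind)
        )
        out = {k: g.clone() for k, g in genes.items()}
        for ev in evs:
            if ev.kind == "loss":
                out = {k: g for k, g in out.items() if k[0] != ev.group_id}
            elif ev.kind == "gain":
                out.update(new_copies(ev.group_id))
        bl = (node.edge.length or 0.0) * config.point_sub_rate
        for key in sorted(out):
            gene = out[key]
            if bl > 0:
                n_sub = int(rng.poisson(bl * len(gene.seq)))
                _point_mutate(gene, n_sub, rng, config.nonsyn_acceptance)
                _unit_indels(gene, config.repeat_indel_rate, rng)
        for ev in evs:
            if ev.kind == "pseudogenisation":
                for key in sorted(out):
                    if key[0] == ev.group_id:
                        _pseudogenise(out[key], rng)
        return out

    def emit(genome: str, genes: dict) -> None:
        for (group_id, copy), gene in sorted(genes.items()):
            gene_id = f"g{group_id}c{copy}"
            gene_rows.append(
                {
                    "genome": genome,
                    "gene_id": f"{genome}|{gene_id}",
                    "group_id": group_id,
                    "is_pseudogene": gene.is_pseudogene,
                    "length_bp": len(gene.seq),
                }
            )
            for r in range(config.clone_reads_per_gene):
                seq = _clone_read(gene, config.clone_error_rate, rng)
                rid = f"{genome}|{gene_id}|r{r}"
                records.append(
                    NucleotideRecord(id=rid, genome=genome, residues=seq, source="simulated")
                )
                rec_rows.append(
                    {
                        "record_id": rid,
                        "genome": genome,
                        "group_id": group_id,
                        "gene_id": f"{genome}|{gene_id}",
                        "is_pseudogene": gene.is_pseudogene,
                    }
                )

    def visit(node, genes: dict) -> None:
        children = sorted(node.child_nodes(), key=lambda n: min(_clade(n)))
        for child in children:
            child_genes = apply_branch(genes, child)
            if child.is_leaf():
                emit(child.taxon.label, child_genes)
            else:
                visit(child, child_genes)

    root_genes: dict[tuple[int, int], _Gene] = {}
    for ev in sorted(
        events_by_clade.get(root_clade, []), key=lambda e: (e.group_id, e.kind)
    ):
        if ev.kind == "gain":
            root_genes.update(new_copies(ev.group_id))
    visit(tree.seed_node, root_genes)

    # outgroup sequences (hordein/secalin analogues): heavily diverged copies
    # of the plain template
    for k in range(config.n_outgroups):
        gene = _build_template(909, nine_cys=False)
        n_sub = int(rng.poisson(config.outgroup_divergence * len(gene.seq)))
        _point_mutate(gene, n_sub, rng)
        rid = f"OG|out{k}|r0"
        records.append(
            NucleotideRecord(id=rid, genome="OG", residues=gene.seq, source="simulated")
        )
        rec_rows.append(
            {
                "record_id": rid,
                "genome": "OG",
                "group_id": 0,
                "gene_id": f"OG|out{k}",
                "is_pseudogene": False,
            }
        )
        gene_rows.append(
            {
                "genome": "OG",
                "gene_id": f"OG|out{k}",
                "group_id": 0,
                "is_pseudogene": False,
                "length_bp": len(gene.seq),
            }
        )

    truth = TruthTable(
        records=pd.DataFrame(rec_rows),
        genes=pd.DataFrame(gene_rows),
        events=list(config.group_model),
        genome_tree=config.genome_tree,
    )
    return records, truth


def _clone_read(gene: _Gene, error_rate: float, rng: np.random.Generator) -> str:
    seq = list(gene.seq)
    if error_rate > 0:
        n_err = int(rng.binomial(len(seq), error_rate))
        intact = not gene.defects
        for _ in range(n_err):
            for _try in range(100):
                pos = int(rng.integers(len(seq)))
                alt = _BASES[int(rng.integers(4))]
                if alt == seq[pos]:
                    continue
                if intact and _creates_bad_codon_from(seq, pos, alt):
                    continue
                seq[pos] = alt
                break
    return "".join(seq)


# ---------------------------------------------------------------------------
# star-phylogeny codon evolver (calibration utility)
# ---------------------------------------------------------------------------


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random sequence of sense codons."""
    sense = [c for c in CODONS if c not in STOP_CODONS]
    return "".join(sense[int(rng.integers(len(sense)))] for _ in range(n_codons))


def evolve_codon_star(
    ancestor: str,
    n_seqs: int,
    syn_per_syn_site: float,
    nonsyn_per_nonsyn_site: float,
    rng: np.random.Generator,
) -> list[str]:
    """Evolve ``n_seqs`` descendants of ``ancestor`` on a star phylogeny.

    Synonymous and non-synonymous substitution events are drawn as Poisson
    counts at the given per-site rates (sites in the NG86 sense) and applied
    as uniform random single-base changes of the matching class; changes
    through stop codons are rejected.  Expected pairwise divergence is twice
    the per-branch rate, so targets dS, dN correspond to rates dS/2, dN/2.
    """
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be a codon multiple")
    codons = [ancestor[i : i + 3].upper() for i in range(0, len(ancestor), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestor must be stop-free")
    s_sites = float(sum(S_FRAC[CODON_INDEX[c]] for c in codons))
    n_sites = 3.0 * len(codons) - s_sites

    def apply_events(seq: list[str], n_events: int, synonymous: bool) -> None:
        for _ in range(n_events):
            for _try in range(500):
                ci = int(rng.integers(len(seq)))
                pos = int(rng.integers(3))
                alt = _BASES[int(rng.integers(4))]
                codon = seq[ci]
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue
                is_syn = translate_codon(mut) == translate_codon(codon)
                if is_syn != synonymous:
                    continue
                seq[ci] = mut
                break

    out = []
    for _ in range(n_seqs):
        seq = list(codons)
        apply_events(seq, int(rng.poisson(syn_per_syn_site * s_sites)), True)
        apply_events(seq, int(rng.poisson(nonsyn_per_nonsyn_site * n_sites)), False)
        out.append("".join(seq))
    return out
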