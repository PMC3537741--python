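"""End-to-end orchestration: simulate/load -> cluster -> annotate -> align ->
tree -> groups -> divergence/selection -> presence -> gain/loss -> report.

Every stage is deterministic given the config seed; outputs are stamped with
the seed and a hash of the configuration.  A stage failure aborts the run
with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import annotate as ann_mod
from . import contigs as contig_mod
from . import gainloss as gl_mod
from . import ng86
from . import phylogeny as phy_mod
from .align import profile_msa
from .io import NucleotideRecord, read_fasta, write_fasta
from .simulate import SimulationConfig, TruthTable, reference_profile, simulate_family

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int
    input_fasta: str | None = None  # if unset, a family is simulated
    simulation: SimulationConfig | None = None
    identity_threshold: float = 0.99
    support_threshold: float = 0.84
    min_nt: int = phy_mod.MIN_NT
    min_aa: int = phy_mod.MIN_AA
    n_bootstrap: int = 1000
    tree_bootstrap: int = phy_mod.DEFAULT_TREE_BOOTSTRAP
    genome_tree: str | None = None  # newick for the gain/loss stage
    reference_length: int = 909

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError(
                f"identity_threshold must be in (0.5, 1.0], got {self.identity_threshold}"
            )
        if not 0.0 < self.support_threshold <= 1.0:
            raise ValueError(
                f"support_threshold must be in (0, 1], got {self.support_threshold}"
            )
        if self.min_nt <= 0 or self.min_aa <= 0:
            raise ValueError("length filters must be positive")
        if self.n_bootstrap < 1 or self.tree_bootstrap < 1:
            raise ValueError("bootstrap replicate counts must be >= 1")
        if self.simulation is not None:
            self.simulation.validate()

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    seed: int
    config_hash: str
    records: list
    truth: TruthTable | None
    contigs: list
    membership: pd.DataFrame
    annotations: dict
    annotation_df: pd.DataFrame
    alignment: dict
    tree: dendropy.Tree
    supports: dict
    assignment: phy_mod.GroupAssignment
    divergence: pd.DataFrame
    kska: ng86.PairwiseKsKa
    presence: gl_mod.PresenceMatrix
    scenario: gl_mod.GainLossScenario
    genome_summary: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    chash = config.config_hash()
    stage = "configure"
    try:
        stage = "simulate" if config.input_fasta is None else "load"
        truth = None
        if config.input_fasta is None:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            records, truth = simulate_family(sim)
        else:
            records = read_fasta(config.input_fasta)

        stage = "cluster"
        ctgs = contig_mod.cluster_contigs(records, config.identity_threshold)
        membership = contig_mod.membership_table(ctgs, records)
        contig_ids = [f"ctg{k:03d}" for k in range(len(ctgs))]
        genome_of = {
            cid: contig_mod.contig_genome(c, records) for cid, c in zip(contig_ids, ctgs)
        }
        consensus = {cid: c.consensus for cid, c in zip(contig_ids, ctgs)}

        stage = "annotate"
        profile = reference_profile(config.reference_length)
        annotations = {cid: ann_mod.annotate_coding(s, profile) for cid, s in consensus.items()}
        annotation_df = ann_mod.annotation_table(annotations, genome_of)

        stage = "align"
        aln = profile_msa(consensus, profile.sequence, keep_insertions=False, anchored_left=True)
        aln = phy_mod.filter_by_length(aln, config.min_nt)

        stage = "tree"
        tree, supports = phy_mod.bootstrap_support(
            aln, n_reps=config.tree_bootstrap, seed=config.seed
        )

        stage = "groups"
        outgroup_ids = {cid for cid, g in genome_of.items() if g == "OG" and cid in aln}
        assignment = phy_mod.call_groups(
            tree, supports, outgroup_ids, config.support_threshold
        )

        stage = "diverge"
        div_rows = []
        rng = np.random.default_rng(config.seed)
        for gid in sorted(assignment.groups):
            members = sorted(assignment.groups[gid] & set(aln))
            if len(members) < 2:
                continue
            rows = [aln[m] for m in members]
            sub_seed = int(rng.integers(2**31 - 1))
            est = ng86.group_divergence(rows, n_bootstrap=config.n_bootstrap, seed=sub_seed)
            zres = ng86.z_test_selection(
                rows, "purifying", n_bootstrap=config.n_bootstrap, seed=sub_seed
            )
            div_rows.append(
                {
                    "group": gid,
                    "n_seqs": len(members),
                    "dS": est.dS,
                    "se_dS": est.se_dS,
                    "dN": est.dN,
                    "se_dN": est.se_dN,
                    "d": est.d,
                    "se_d": est.se_d,
                    "dN_dS": est.ratio,
                    "z_purifying": zres.z,
                    "p_purifying": zres.p_value,
                }
            )
        grouped_ids = sorted(set().union(*assignment.groups.values())) if assignment.groups else []
        overall = sorted(set(grouped_ids) & set(aln))
        if len(overall) >= 2:
            rows = [aln[m] for m in overall]
            sub_seed = int(rng.integers(2**31 - 1))
            est = ng86.group_divergence(rows, n_bootstrap=config.n_bootstrap, seed=sub_seed)
            zres = ng86.z_test_selection(
                rows, "purifying", n_bootstrap=config.n_bootstrap, seed=sub_seed
            )
            div_rows.append(
                {
                    "group": "overall",
                    "n_seqs": len(overall),
                    "dS": est.dS,
                    "se_dS": est.se_dS,
                    "dN": est.dN,
                    "se_dN": est.se_dN,
                    "d": est.d,
                    "se_d": est.se_d,
                    "dN_dS": est.ratio,
                    "z_purifying": zres.z,
                    "p_purifying": zres.p_value,
                }
            )
        divergence = pd.DataFrame(div_rows)

        stage = "kska"
        ingroup_aln = {
            cid: row for cid, row in aln.items() if cid not in outgroup_ids
        }
        flags = {cid: annotations[cid].is_pseudogene for cid in ingroup_aln}
        kska = ng86.ks_ka_scatter(ingroup_aln, flags)

        stage = "presence"
        ann_rows = annotation_df[annotation_df["genome"] != "OG"].copy()
        presence = gl_mod.build_presence_matrix(
            assignment,
            ann_rows.assign(
                cysteine_count=[annotations[i].cysteine_count for i in ann_rows["id"]]
            ),
        )

        stage = "gainloss"
        gl_newick = config.genome_tree
        if gl_newick is None and truth is not None:
            gl_newick = truth.genome_tree
        if gl_newick is None:
            raise ValueError("genome_tree is required when running from a FASTA input")
        gtree = dendropy.Tree.get(
            data=gl_newick, schema="newick", preserve_underscores=True
        )
        tips = {lf.taxon.label for lf in gtree.leaf_node_iter()}
        keep_cols = [c for c in presence.states.columns if c in tips]
        matrix = gl_mod.PresenceMatrix(
            states=presence.states[keep_cols], nine_cys=presence.nine_cys[keep_cols]
        )
        scenario = gl_mod.dollo_reconstruct(matrix, gtree)

        stage = "report"
        genome_summary = _genome_summary(records, ctgs, contig_ids, genome_of, annotations)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        seed=config.seed,
        config_hash=chash,
        records=records,
        truth=truth,
        contigs=ctgs,
        membership=membership,
        annotations=annotations,
        annotation_df=annotation_df,
        alignment=aln,
        tree=tree,
        supports=supports,
        assignment=assignment,
        divergence=divergence,
        kska=kska,
        presence=presence,
        scenario=scenario,
        genome_summary=genome_summary,
    )


def _genome_summary(records, ctgs, contig_ids, genome_of, annotations) -> pd.DataFrame:
    """Per-genome counts: sequences, contigs, intact genes, pseudogene
    contigs, and consensus length range."""
    recs = pd.DataFrame({"id": [r.id for r in records], "genome": [r.genome for r in records]})
    rows = []
    for genome in sorted(recs["genome"].unique()):
        cids = [cid for cid in contig_ids if genome_of[cid] == genome]
        n_pseudo = sum(annotations[cid].is_pseudogene for cid in cids)
        lengths = [
            len(c.consensus) for cid, c in zip(contig_ids, ctgs) if cid in cids
        ]
        rows.append(
            {
                "genome": genome,
                "n_seq": int((recs["genome"] == genome).sum()),
                "n_contigs": len(cids),
                "genes": len(cids) - n_pseudo,
                "pseudogenes": n_pseudo,
                "length_bp": f"{min(lengths)}-{max(lengths)}" if lengths else "",
            }
        )
    return pd.DataFrame(rows)


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write the report bundle (TSV/FASTA/newick/JSON), stamped with the
    config hash and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={result.config_hash} seed={result.seed}\n"

    def tsv(df: pd.DataFrame, name: str):
        with open(outdir / name, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", index=False)

    tsv(result.membership, "contigs.tsv")
    tsv(result.annotation_df, "annotations.tsv")
    tsv(result.divergence, "divergence.tsv")
    tsv(result.genome_summary, "genome_summary.tsv")
    tsv(result.kska.pairs, "kska_pairs.tsv")
    tsv(gl_mod.scenario_table(result.scenario), "gainloss_events.tsv")
    groups_df = pd.DataFrame(
        [
            {"sequence_id": m, "group_id": gid}
            for gid, members in sorted(result.assignment.groups.items())
            for m in sorted(members)
        ]
    )
    tsv(groups_df, "groups.tsv")
    result.presence.to_tsv(outdir / "presence.tsv")
    write_fasta({f"ctg{k:03d}": c.consensus for k, c in enumerate(result.contigs)},
                outdir / "consensus.fasta")
    result.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    meta = {
        "seed": result.seed,
        "config_hash": result.config_hash,
        "n_records": len(result.records),
        "n_contigs": len(result.contigs),
        "n_groups": len(result.assignment.groups),
        "slope_orf": result.kska.slope_orf,
        "slope_pseudo": result.kska.slope_pseudo,
        "gainloss_cost": result.scenario.cost,
    }
    (outdir / "report.json").write_text(json.dumps(meta, indent=2, default=float))
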