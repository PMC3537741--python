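# gliafam

Tools for studying the evolution of the **gamma-gliadin multigene family**
across *Aegilops* and *Triticum* genomes (A, B/S, C, D, M, N, T, U).
Gamma-gliadins are prolamin seed-storage proteins encoded by the *Gli-1*
loci; they form a diverse family of genes with a conserved domain
architecture — a signal peptide (S), a unique N-terminal domain (I), a
repetitive glutamine/proline-rich domain (II), a cysteine-rich domain (III),
a glutamine-rich domain (IV) and a C-terminal domain (V) — with eight
conserved cysteines (six in III, two in V), plus a widespread nine-cysteine
variant created by a single TCC→TGC change.

The package is aimed at molecular evolution researchers working with cloned
multigene-family sequences. It implements the full analysis chain:

1. **Contig assembly** (`gliafam.contigs`) — single-linkage clustering of
   redundant clone sequences at 99% global-alignment identity and
   column-majority consensus calling.
2. **Coding annotation** (`gliafam.annotate`) — frame anchoring on the
   conserved signal-peptide primer site, pseudogene classification by
   internal stop codons and frameshifts (detected against an intact
   reference profile), protein deduction, cysteine counting, and domain
   segmentation.
3. **Divergence and selection** (`gliafam.ng86`) — Nei–Gojobori (1986)
   synonymous/non-synonymous site and difference counting with pathway
   averaging, Jukes–Cantor correction, pairwise deletion, codon-column
   bootstrap standard errors, the codon-based Z-test for purifying
   selection, and Ks/Ka scatter with zero-intercept trendlines for ORF
   versus pseudogene pairs.
4. **Phylogenetic grouping** (`gliafam.phylogeny`) — JC distance matrices,
   Saitou–Nei neighbour joining with deterministic tie-breaking, bootstrap
   split supports, the ≥600 nt / ≥200 aa alignment-length filters, and
   group calling as maximal supported clades (support ≥ 0.84) within the
   ingroup.
5. **Gain/loss reconstruction** (`gliafam.gainloss`) — group-by-genome
   presence matrices (states present / pseudogene-only / absent, with
   nine-cysteine annotations) and single-gain **Dollo parsimony** on a
   genome guide tree, including the shipped reference tree and occurrence
   matrix for the twelve *Aegilops/Triticum* genome types plus
   *Lophopyrum*, *Crithopsis* and *Dasypyrum*.
6. **Synthetic families** (`gliafam.simulate`) — a generator that evolves
   gamma-gliadin-like genes (648–1089 bp ORFs, whole-repeat-unit length
   variation, planted pseudogenisation events, clone-read redundancy) down
   a genome tree with known truth, so every stage can be validated end to
   end.

The central quantities follow the field's standard notation: per-codon
synonymous site counts `s` with `s + n = 3`; proportions `p_S = Σs_d/ΣS` and
`p_N = Σn_d/ΣN`; distances `d = −(3/4)·ln(1 − 4p/3)`; the selection statistic
`Z = (d_S − d_N)/SE_boot(d_S − d_N)` with a one-tailed normal p-value.

## Worked example

Build one nine-cysteine ancestral gene and annotate it:

```python
>>> from gliafam import make_ancestral_gene, annotate_coding, reference_profile
>>> rec = make_ancestral_gene(6, 909)          # group 6, 909-bp ORF
>>> ann = annotate_coding(rec.residues, reference_profile(909))
>>> ann.protein_length, ann.cysteine_count, ann.is_pseudogene
(302, 9, False)
```

A 909-bp open reading frame encodes a 302-residue protein (including the
signal peptide, excluding the stop), and the group-6 gene carries the ninth
cysteine.

Run the full pipeline on a simulated family (six groups over eight genomes,
with planted pseudogenes and clone redundancy) and inspect the per-group
divergence table:

```python
>>> from gliafam.pipeline import PipelineConfig, run_pipeline
>>> res = run_pipeline(PipelineConfig(seed=1, tree_bootstrap=300, n_bootstrap=500))
>>> print(res.divergence[["group", "n_seqs", "dS", "se_dS", "dN", "se_dN",
...                       "dN_dS", "p_purifying"]].round(3).to_string(index=False))
  group  n_seqs    dS  se_dS    dN  se_dN  dN_dS  p_purifying
      1       6 0.152  0.019 0.046  0.005  0.304        0.000
      2       2 0.054  0.018 0.030  0.007  0.563        0.107
      3      14 0.196  0.016 0.058  0.004  0.297        0.000
      4       8 0.128  0.014 0.056  0.005  0.441        0.000
      5       6 0.164  0.019 0.066  0.007  0.399        0.000
      6       4 0.216  0.026 0.064  0.007  0.297        0.000
overall      40 0.213  0.013 0.101  0.005  0.476        0.000
```

Each row gives the mean pairwise synonymous (`dS`) and non-synonymous
(`dN`) divergence within one called group with codon-bootstrap standard
errors; `dN_dS` well below 1 and small `p_purifying` indicate purifying
selection, as expected for genes evolving under constraint (group 2 has
only two members here, hence the weak test). Called group numbers are
arbitrary labels assigned by tree position, not the simulator's truth ids.

Reconstructing gains and losses of the called groups on the genome tree
then yields the ancestral complement of the family; on the shipped
reference matrix and guide tree the *Aegilops/Triticum* ancestor carries
exactly four groups:

```python
>>> from gliafam import gainloss as gl
>>> tree = gl.reference_genome_tree()
>>> sc = gl.dollo_reconstruct(gl.reference_presence_matrix(), tree)
>>> sorted(gl.aegilops_triticum_mrca_groups(sc, tree))
[1, 2, 4, 6]
```

A command-line interface mirrors the stages (`glia simulate`, `glia
cluster`, `glia annotate`, `glia diverge`, `glia tree`, `glia groups`,
`glia gainloss`, `glia run`); see `glia --help`.

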