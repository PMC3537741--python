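# Methods

This note documents the models, conventions and numerical choices behind
`gliafam`, and what the synthetic-data validation does and does not show.

## The gene family being modelled

Gamma-gliadins are prolamin storage proteins of wheat and its wild
relatives, encoded by a multigene family at the *Gli-1* loci. Full open
reading frames span 648–1089 bp (215–362 aa including the signal peptide);
length variation is concentrated in the repetitive domain II (tandem
glutamine/proline-rich units) and the glutamine-rich domain IV. Most
proteins carry eight cysteines (six in domain III, two in V); a conserved
nine-cysteine variant, created by a single TCC→TGC change at a fixed
position, occurs across the *Aegilops* genomes and is of interest as a
putative chain terminator in gluten network formation. The family falls
into six sequence groups distributed unevenly over the diploid genomes
(A, B/S, C, D, M, N, T, U), some groups surviving only as pseudogenes in
particular genomes.

## Contig assembly

Cloned sequences are redundant (several clones per gene, possibly carrying
PCR or sequencing errors). Records are clustered by **single linkage** on
pairwise global-alignment identity at a 0.99 threshold: single linkage is
the most conservative choice (it splits the fewest contigs), and the
member-versus-consensus identity invariant is consequently checked as a
warning rather than an error. Identity is matches divided by aligned
columns with terminal-gap columns excluded (so fragments cluster with
full-length clones) and internal gap columns counted as mismatches.

The pairwise scorer is Needleman–Wunsch with match +1, mismatch −1, affine
gaps (−4 open, −0.5 extend) and free end gaps. Affine gaps matter here:
whole-repeat-unit indels of 21 bp (or several units) must stay cheaper than
misaligning entire domains, and a linear gap cost makes the periodic repeat
region slide instead. For comparisons in which both sequences begin at the
conserved primer site, left end gaps are penalised like internal gaps
("anchored" mode) so the periodic repeats cannot shift the alignment off
the signal peptide. An edit-distance prescreen (edlib, infix mode) skips
the full alignment for pairs that cannot plausibly reach the identity
threshold; it is conservative by a factor of two over the threshold bound.

Consensus is column-majority over a profile alignment anchored to the
longest member, with gap-majority columns removed and base ties broken
alphabetically. Equal-length members (clone reads differ by substitutions
only) are columnwise-aligned as-is. With three reads per contig, two
same-column errors produce an unresolvable three-way tie, which caps
perfect-consensus recovery near 98–99%; at the redundancy typical of cloned
data (about five reads per contig) recovery is complete, and the consensus
test runs at five reads.

## Coding annotation

The reading frame is fixed by the conserved signal-peptide anchor
(`ATGAAGACCTTACTCATCC`, the forward-primer site), allowing up to two
mismatches; a sequence without the anchor is rejected. Defects are called
against an intact reference profile:

* **Internal stops** — codons translating to a stop strictly before the
  reference terminator; a stop aligned to the final reference codon is the
  natural terminator, not a defect.
* **Frameshifts** — the cumulative indel length of the
  sequence-to-reference alignment becoming a non-multiple of three.
  Alignment ambiguity inside the repeat region can split a whole-unit indel
  into transient out-of-frame pieces, so an out-of-frame state is only
  called a frameshift when it persists for at least 30 aligned columns (or
  to the end of the aligned span). Compensating frameshift pairs closer
  together than that window would be missed; the simulator does not
  generate them.

Translation reads the sequence in triples, carrying remainders across
reference codon boundaries and re-synchronising (dropping the partial
codon) at each confirmed frameshift — a "repaired frame" that makes the
deduced protein exact for intact genes of any repeat count and reasonable
for pseudogenes. Domain segmentation projects the reference boundaries
through a protein-level alignment; insertion blocks that land on a domain
boundary are attributed to the adjacent length-variable domain (II or IV),
which keeps repeat-unit gain inside domain II. Coordinates are 0-based,
half-open throughout. Protein lengths always include the signal peptide.

## NG86 divergence and selection

Site counting, pathway-averaged difference counting, and the Jukes–Cantor
correction follow the classical counting method. Two conventions the
original method leaves open are fixed as follows (the common choice in
standard implementations): single-base changes to stop codons count as
non-synonymous sites, and mutational pathways through stop codons are
excluded from difference counting unless every pathway passes through a
stop. Codons containing a gap, an ambiguity code, or a stop in either
sequence of a pair are excluded for that pair only (pairwise deletion).
Site and difference tables over all 64×64 codon pairs are precomputed in
rational arithmetic at import, so `s + n = 3` holds exactly and long
alignments reduce to table lookups.

Group divergence is the mean over all unordered pairs of dS, dN and d
(overall distance per nucleotide). Standard errors are standard deviations
of the group mean over bootstrap replicates that resample **codon columns**
(the same columns for every pair within a replicate); replicates are drawn
as multinomial column counts, which reduces each replicate to one matrix
product. dN/dS is reported as the ratio of the group means, not the mean of
per-pair ratios — the convention that reproduces a divergence table's ratio
column from its dS and dN columns. Saturated pairs (p ≥ 3/4) are dropped
from means with a logged count.

The codon-based Z-test computes `Z = (dS − dN) / SE_boot(dS − dN)` with a
one-tailed normal p-value for the purifying (dS > dN) or positive
alternatives, two-tailed for deviation from neutrality. When the bootstrap
variance is exactly zero the p-value is reported missing, except in the
degenerate dS = dN case where Z = 0 and p = 0.5. Calibration under neutral
simulation gives a type-I error slightly below nominal (≈0.03–0.05 at
α = 0.05 for 8 sequences × 200 codons) — the bootstrap-normal approximation
is mildly conservative at these sizes — with essentially full power against
a 3:1 synonymous:non-synonymous rate ratio at within-group divergences
around 0.07–0.09.

Ks/Ka scatter pairs are formed within the ORF class and within the
pseudogene class only; trendlines are zero-intercept least squares,
slope = Σ(Ks·Ka)/Σ(Ks²) per class, missing for classes with fewer than two
sequences.

## Distance trees and group calling

Nucleotide distances are JC-corrected p-distances with pairwise deletion;
protein trees use uncorrected p-distances. Rows shorter than 600 non-gap nt
(200 aa for protein alignments) are removed before tree building, with
rows kept at exactly the threshold. Neighbour joining is the Saitou–Nei
algorithm with two determinism rules: Q-criterion ties break by the
lexicographically lowest pair of cluster labels (each cluster represented
by its smallest member), and negative branch lengths are clamped to zero
with the deficit transferred to the adjacent branch of the joined pair. On
additive matrices the true topology is recovered exactly. Missing
(saturated) entries make `neighbor_joining` raise; inside bootstrap
replicates they are imputed with the replicate's largest finite distance,
with a warning.

Support is the nonparametric bootstrap over alignment columns (default 500
replicates) on the NJ tree — the support measure to which the 0.84 calling
threshold is applied. Groups are called on the tree rooted at an outgroup
leaf: the **maximal supported clades that contain no outgroup sequence**
(excluding the full ingroup itself), so accepted clades absorb their
supported subclades and every sequence belongs to at most one group.
Rooting at a leaf rather than an outgroup ancestor keeps the rule
well-defined when the outgroup sequences are not monophyletic. Raising the
threshold refines the partition (each stricter-threshold group nests inside
a looser-threshold group) but can *increase* the number of groups, since a
disqualified large clade may expose several supported subclades; the
refinement property is what the test suite asserts.

## Presence matrices and Dollo reconstruction

A presence matrix cell is `present` if the genome holds any intact gene of
the group, `pseudogene_only` if only pseudogenes, else `absent`; a
nine-cysteine flag marks cells whose intact genes all have exactly nine
cysteines. Each group is a Dollo character: one gain at the MRCA of all
non-absent genomes (pseudogene-only counts as presence), losses on the
maximal subtrees with no occurrence — the unique minimum-cardinality loss
set — and a pseudogenisation event on the terminal branch of each
pseudogene-only genome. Cost is the total event count. Equally parsimonious
alternative timings of a loss along a pendant path are not enumerated; the
canonical maximal-subtree placement is reported. Gene order on the
chromosome and within-group duplications are not modelled.

The shipped guide tree places the C–U and M–N genome pairs together, the T
genome with the D/S lineage, the A genome as the least-resolved ingroup
branch, and the genera *Lophopyrum*, *Crithopsis* and *Dasypyrum* outside
*Aegilops/Triticum*; it is data (`gliafam/data/genome_tree.nwk`) and can be
replaced by the user. The shipped occurrence matrix follows the
evolutionary model of the family: group 5 is scored in the four Sitopsis
S-genomes, where it forms the conserved nine-cysteine type; the divergent
eight-cysteine group-5-like sequences of the U and N genomes are treated as
not establishing presence for the single-gain model (scoring them as
presence would force the group-5 gain to the *Aegilops/Triticum* ancestor,
contradicting the family's reconstructed history in which the ancestor
carried groups 1, 2, 4 and 6 only). On this fixture the reconstruction
places exactly those four groups at the ingroup MRCA.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions for all end-to-end validation.

* **Templates.** Genes are assembled from the domain architecture with a
  literal primer-site prefix, a 21-bp PQQPFPQ repeat unit in domain II,
  six cysteines in III and two in V at fixed offsets, a TCC/TGC variant
  site in III (TGC for groups 5 and 6), glutamine codons in IV, and one
  terminal stop. Any codon-multiple length in 648–1089 bp is realised by
  the repeat count and the IV length. Default group lengths: 1020, 903,
  888, 939, 909, 909 bp for groups 1–6.
* **Group radiation.** Each group's ancestral gene derives from the
  template by substitutions confined to a group-specific codon class
  (codon index mod 6), at an expected 10% of codons. This makes the six
  groups a star radiation in which no alignment column carries shared
  derived states of two groups, so between-group clades attract no
  bootstrap support and the group structure is identifiable — the regime
  was fixed by pilot runs of the grouping stage. Outgroup sequences
  (hordein/secalin analogues) are independent heavy mutations of the
  template (0.35 substitutions/site) and need not be monophyletic.
* **Evolution along the genome tree.** Per branch, each gene receives
  Poisson(branch length × rate scale × length) uniform substitutions; on
  intact lineages changes creating stop codons or cysteines are rejected
  and non-synonymous changes are accepted with probability 1/3 (a stylised
  purifying selection matching observed within-group dN/dS ≈ 0.27–0.47),
  while pseudogenised lineages are unselected. Domain II gains or loses
  whole tandem repeat units (probability 0.005 per unit per branch), so
  frame is preserved unless a frameshift is drawn explicitly. Default
  terminal branch lengths of 0.02–0.03 give within-group divergences of
  roughly 0.04–0.10.
* **Events.** The default per-branch model encodes the six-group pattern
  over the eight genomes: groups 1, 4 and 6 ancestral, group 2 gained on
  the T–D–S lineage, group 3 on the *Ae. caudata* branch, group 5 on the
  C–U–M–N lineage, with the losses that yield the observed occupancy and
  pseudogenisation of group 1 in the U and M genomes. Pseudogenisation
  plants an internal stop (probability 0.5, at a random domain-III codon)
  or a ±1 bp frameshift in domain IV. Default events are placed only where
  Dollo reconstruction can identify them (losses at maximal absent
  subtrees, pseudogenisation on terminal branches), so end-to-end event
  recovery is a meaningful exact check.
* **Clone reads.** Each tip gene is emitted as 3 reads (real cloned data
  averaged ≈5.7 reads per contig) with independent per-base errors at
  0.002; errors on intact genes never create in-frame stops, keeping the
  truth pseudogene labels exact at any error rate.
* **Determinism.** One `numpy` generator seeded from the config drives all
  randomness in a fixed traversal order; equal seeds give byte-identical
  FASTA.

**What passing tests show — and do not show.** The generator emulates the
family's architecture, group structure, selection contrast and clone
redundancy, but not real codon usage, empirical repeat-motif heterogeneity,
PCR chimeras, alignment uncertainty from non-repeat indels, or
rate variation across sites and lineages. End-to-end recovery (exact
contigs, Rand index 1.0 grouping, exact event recovery) therefore
demonstrates internal correctness of the pipeline under the modelled data
regime, not expected performance on arbitrary real data, where group
boundaries can be less crisp and support values lower.

## Problem sizes and calibration checks

The validation suite uses these sizes, chosen to make each check
statistically meaningful at interactive runtimes: NG86 oracle agreement on
1000 random codon pairs and 100 random 200-codon pairs (agreement to
numerical precision, ≤1e−9); NJ topology recovery on 100 random additive
8-taxon matrices; divergence recovery at the most polymorphic group's
regime (dS = 0.19, dN = 0.065; 6 sequences × 300 codons, 20 replicates,
1000 bootstrap replicates, two-SE criterion — nominal joint coverage is
itself ≈90%, so the observed rate fluctuates around that value); Z-test
type-I calibration over 500 neutral simulations and power over 100
purifying simulations (8 × 200 codons); consensus recovery over 1000
simulated contigs of five reads; and one full pipeline run on the default
family (six groups, eight genomes, 43 genes, 123 reads).
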