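# Methods

## The evolutionary model

The package reasons about a lineage that underwent two whole-genome
duplications (1R, 2R) in close succession, separated and followed by
chromosome fusions, with duplicate genes subsequently lost during
rediploidisation. The stem is discretised into ordered epochs
(`chordate → pre1R → 1R → inter1R2R → 2R → vertebrata → euteleostomi →
amniota`); gene families are copy trees in which each WGD replaces a live
copy by two children tagged with the duplication epoch, and extant lineages
branch off the stem at declared epochs. Under this model a pre-1R
chromosome leaves four post-2R chromosomes (a tetrad); an inter-WGD fusion
makes two tetrads share the two WGD copies of the fused chromosome; a
post-2R fusion joins two tetrads through a single chromosome; an inter-WGD
fission splits one pre-duplication chromosome's content over two tetrads.

Three structural consequences of the model are used as hard constraints
during inference: two tetrads can share at most two CARs; a CAR can belong
to at most two tetrads; and no ohnolog family can connect more than four
CARs of non-trivial size.

## Simulator

`simulate_scenario` runs the stem forward and emits descendant genomes plus
a fully replayable event history. Defaults are the study conditions of the
inferred vertebrate scenario at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_chordate_chromosomes` | 17 | pre-duplication chromosomes |
| `genes_per_chromosome` | (50, 70) | uniform, ≈60 genes per chromosome |
| `inter_wgd_fusions` | 7 | fusions between 1R and 2R |
| `post2r_fusions_early/late` | 4 / 1 | dated before the bony-vertebrate / amniote ancestor |
| `retention` | 0.35 | per-copy duplicate survival during rediploidisation (≥1 copy per family kept) |
| `n_per_clade` | 2 | descendants per clade of the target ancestor |
| `n_outgroups` | 2 | lineages diverging at the bony-vertebrate ancestor |
| `branch_inversions/_translocations` | 2 / 1 | rearrangements per terminal branch (geometric inversion spans, mean 8) |

Fusion plans are drawn under identifiability constraints: each inter-WGD
fusion joins copies of two distinct pre-1R chromosomes, no pre-1R
chromosome participates in two inter-WGD fusions, and a post-2R fusion
never joins a pre-1R pair already joined between the WGDs. This mirrors the
configuration of the inferred history, in which every event leaves a
separately resolvable CAR-sharing pattern; degenerate configurations
(e.g. the same chromosome pair fused twice) are unidentifiable in principle
and are not part of the study conditions. Rediploidisation is applied once
on the stem (the descendant clades of a 300-My-old ancestor share most of
their ohnolog complement), while the optional fragmented cyclostome-like
lineage branches right after 2R and loses duplicates independently — the
feature the orthology-pattern diagnostic depends on.

What the generator deliberately does not emulate: sequence evolution,
small-scale (tandem/segmental) duplication, gene gain, micro-chromosome
base-composition effects, and assembly error in descendant genomes. Passing
recovery tests therefore demonstrate the statistical machinery under the
model's own noise sources (duplicate loss and rearrangement), not
robustness to annotation artefacts of real genome assemblies.

## Reconstruction

Ancestral genes at the target epoch are family copies alive by tree
structure with at least one extant descendant in the target's own
descendant clades. Adjacencies are immediate neighbours only (after
dropping unmapped genes); an adjacency is conserved regardless of a joint
strand flip, and relative orientations are tallied and propagated to CAR
orientations by majority. Comparisons are all cross-clade genome pairs plus
descendant–outgroup pairs; a within-clade variant
(`include_within_clade=True`) serves as the alternative reconstruction
used as corroborating evidence when merging CAR fragments. Linearisation is
greedy by decreasing weight with lexicographic tie-breaks, so builds are
bit-reproducible; it is a heuristic (not an optimal path cover), which is
the behaviour the field's graph-parsimony reconstructions use.

Gene-based N50 is the smallest length L such that CARs of length ≥ L hold
at least half of all genes; the chromosome-size filter keeps CARs strictly
larger than `min_car_len` (default 50 genes at full scale). For simulated
genomes `RunConfig.scaled` re-expresses the size thresholds relative to the
expected post-2R chromosome size (≈40% of the mean chromosome for the
chromosome-size cut, ≈20% for the family-span floor), preserving the
proportions the defaults have on chromosome-scale data.

## Ohnolog detection

The synteny window N = 45 genes and the same-CAR floor 2N = 90 are the
published operating point and both boundaries are inclusive. Consensus
building is greedy and permanent: the seed is the intersection of the
rank-0 lists; remaining pairs are batched by support signature (how many
and which source lists contain them) and accepted unless the pair crosses
families, violates the same-CAR floor, or would push its family network
beyond four CARs of ≥ `min_car_genes_for_span` (default 10) genes. The
span rule is re-checked after every batch. Order sensitivity is confined to
ties within a batch; batches and pairs are processed in sorted order so
runs are reproducible.

## The ohnology test

For an unordered CAR pair, the focal side is the CAR with fewer total
ohnolog links (ties by id) — a deterministic choice that makes the matrix
symmetric. The test compares the focal CAR's link share landing on the
partner against the partner's share of ohnolog-bearing genes outside the
focal CAR: a one-sided two-sample proportion test, χ² with continuity
correction, numerically matching R's `prop.test(..., alternative =
"greater")`. A CAR with no links yields p = 1. A Monte-Carlo placement
test (`permutation_ohnology_test`) is provided for small counts and serves
as the independent calibration oracle; under a permutation null the raw
test rejects at slightly under the nominal rate (the continuity correction
is conservative). Bonferroni multiplies by the number of unordered pairs
among link-bearing CARs.

## Tetrad assembly

Maximal cliques (size ≥ 3) of the Bonferroni-significant partner graph
among chromosome-size CARs seed the tetrads; 4-cliques stand as they are.
Because a true tetrad edge can fall just short of significance at desk
scale, assembly also seeds from Bonferroni-significant edges not inside any
clique. Seeds grow one CAR at a time under a combined-evidence rule: a
candidate needs one Bonferroni-significant edge or two uncorrected-
significant edges towards the current members, a Fisher-combined p over all
member edges below 1e-4 (stringent, guarding the multiplicity of candidate
scans), and must not create a tetrad sharing ≥ 3 CARs with an established
tetrad. Candidates are ranked by breadth of compatibility (raw p ≤ 0.5
towards every member, i.e. at least the expected number of shared pairs)
before strength — the strongest edges always belong to CARs shared with an
adjacent tetrad and a strength-first ranking systematically steals members
across tetrads. Growth is globally greedy (largest seeds, then strongest
evidence first) so established tetrads constrain weaker seeds; candidate
ties leave a seed unresolved rather than guessing. Finished tetrads are
deduplicated, subsets dropped, and two consistency passes enforce the
model constraints (pairwise overlap ≤ 2, membership multiplicity ≤ 2) by
shedding the least-supported claimant.

Fragment merging requires (i) co-membership in the alternative
reconstruction or identical modal descendant-chromosome homology, (ii) a
common significantly ohnologous partner, and (iii) no significant ohnology
between the fragments themselves (that would make them WGD copies);
outgroup homology and double-conserved-synteny agreement are recorded as
supporting evidence. Every merge and split emits an audit row. Chimeric
CARs are split only where the dominant ohnolog-partner track and the
homology track switch within `split_window` (default 10 genes) of each
other, with both flanks ≥ 80% pure.

## Scenario inference

Tetrad–CLG assignment reports, per (tetrad, CLG), the CLG's *coverage* (the
fraction of its families with a descendant in the tetrad) and the tetrad's
*purity*; the predominant CLG must reach 50% purity and double the
runner-up, else the tetrad stays unassigned (small tetrads legitimately
fail this). Fusion/fission discrimination contrasts the majority CLGs of
the members each tetrad does **not** share: distinct CLGs ⇒ inter-WGD
fusion, one CLG split over both ⇒ fission, anything below 50% purity ⇒
unresolved with both hypotheses reported. The chordate-epoch fusion
signature requires two CLGs each > 75% covered by one tetrad *and* that
tetrad to be each CLG's unique best home — without the uniqueness clause a
CAR shared with an adjacent tetrad imports the neighbour's linkage group
and mimics the signature.

Post-2R fusions are CARs joining two tetrads as a single junction. Dating
is by parsimony under the no-convergent-fusion assumption: a junction
mapping to a single chromosome in any lineage diverging at epoch e proves
the fusion predates e, so the event is placed just before the earliest
divergence showing the joined state; splits in later-diverging lineages are
logged as lineage-specific synteny disruptions. The default scenario
carries two outgroups so that one outgroup's incidental rearrangement at a
junction cannot flip a date.

The timeline is pure arithmetic (pre-1R count = tetrad count; WGDs double;
fusions subtract at their epoch; fissions add) and is validated for
self-consistency. Pre-duplication genes are assigned to a pre-1R
chromosome when the tetrads owning their placed descendants' CARs intersect
in exactly one tetrad; on shared CARs only consensus ohnologs are
informative.

For fragmented descendants, orthologs are genes descending from the same
ancestral copy at the fragmented lineage's divergence epoch; each scaffold
is attributed to the CAR with its maximal ortholog count (minimum 2), and
scaffolds sharing an attributed CAR form a scaffold group. A lineage
sharing both WGDs shows a modal 1:4 chromosome-group:scaffold-group ratio,
a lineage sharing one WGD 1:2.

## Numerical and reproducibility choices

All randomness flows from one integer seed through `numpy` seed sequences
with per-stage substreams; identical seeds give byte-identical outputs.
Positions are 0-based with half-open spans. Ties are broken
lexicographically everywhere a choice is arbitrary. Degenerate inputs are
defined rather than fatal where the science allows (zero-link CARs test at
p = 1; an empty adjacency graph linearises to no CARs); contract violations
(empty clades, malformed files, inconsistent timelines) raise.

Test and validation problem sizes: the scenario-recovery suite runs 20
replicates of the default desk-scale history (≈1 000 pre-1R genes,
≈1 600 ancestral genes, 6–8 extant genomes; under a second per replicate);
the partner-statistic and fission controls use 100–150 genes per
chromosome, sizes chosen a priori so that expected shared-ohnolog counts
per tetrad edge (≈12–18) give the tests near-certain power at the
strictest threshold swept.

## Known limitations

- Power at desk scale is finite: with ~60 genes per chromosome and 35%
  retention, a junction half-chromosome occasionally shares too few
  ohnologs to be linked (in ~5% of replicates one dated fusion or tetrad
  member is missed). The recovery criterion is therefore statistical, not
  per-replicate.
- The greedy consensus and greedy tetrad growth do not backtrack; the
  consistency passes remove contradictions but cannot resurrect a member
  lost to an earlier wrong acceptance.
- Linkage-group discrimination assumes CLGs are clean partitions of the
  family universe; noisy CLG definitions would blur the fusion/fission
  contrast well before it flips.
- The simulator's rearrangement model (inversions + reciprocal
  translocations) omits transpositions and duplicative transfers by
  design; the reconstruction has no special handling for them either.
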