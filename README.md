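# paleokaryo

Reconstruction of early vertebrate karyotype evolution from extant gene
orders: ancestral gene-order reconstruction into Contiguous Ancestral
Regions (CARs), detection of whole-genome-duplication paralogues
(*ohnologs*), statistical assembly of duplicated-chromosome *tetrads*, and
inference of the chromosome fusion/fission scenario around the two ancient
whole-genome duplications (1R and 2R) that preceded the vertebrate
radiation.

The package is aimed at comparative genomicists studying ancient polyploidy
and karyotype evolution, and ships a forward genome-evolution simulator so
that every stage of the inference chain can be validated by parameter
recovery against a known history.

## The method

1. **Ancestral gene order.** Ancestral genes at a target ancestor (e.g. the
   amniote ancestor) are inferred from epoch-labelled gene-family trees. An
   adjacency graph is built over them: an edge joins two genes whenever
   their descendants are immediate neighbours in both genomes of an
   informative comparison (one genome from each descendant clade, or a
   descendant against an outgroup), weighted by the number of comparisons
   conserving the adjacency. Greedy linearisation along edges of decreasing
   weight (degree ≤ 2, no cycles) yields the CARs.

2. **Ohnolog detection.** Candidate ohnologs are same-family ancestral gene
   pairs whose duplication dates to the 1R–2R window. A pair on CARs
   (c₁, c₂) is retained ("list A") only if a second candidate pair from a
   different family lies within *N* = 45 gene positions on both CARs;
   same-CAR pairs must be ≥ 2N = 90 positions apart (tandem-duplicate
   guard). A consensus list grows greedily from the intersection of
   high-confidence lists under the two-WGD compatibility constraint: no
   ohnolog family may connect more than four CARs of ≥ 10 genes.

3. **Tetrads.** For every CAR pair a one-sided two-proportion test
   (χ², continuity-corrected, matching R's `prop.test`) asks whether the
   two CARs share more ohnolog pairs than expected from their gene content;
   Bonferroni correction runs over all tested pairs. After two WGDs every
   CAR should have three significant partners, and maximal cliques of the
   partner graph are the tetrads — triads and uncovered significant edges
   are grown to four members on combined (Fisher) evidence, fragmented CARs
   are merged and chimeric CARs split under explicit evidence rules.

4. **Scenario.** Tetrads sharing two CARs record an inter-WGD fusion or
   fission; an unduplicated outgroup proto-karyotype (chordate linkage
   groups, CLGs) discriminates the two. A single CAR joining two tetrads is
   a post-2R fusion, dated by parsimony over descendant/outgroup chromosome
   homologies. The events yield a karyotype timeline (each WGD doubles the
   count, each fusion subtracts one) and a per-gene assignment to pre-1R
   chromosomes.

## Worked example

```python
from paleokaryo import AncestralKaryotypeModel, simulate_scenario

sim = simulate_scenario(seed=1)          # 17 pre-1R chromosomes, 1R,
                                         # 7 fusions, 2R, 4+1 dated fusions,
                                         # 35% duplicate retention
model = AncestralKaryotypeModel.from_simulation(sim)
results = model.fit()
print(results.summary())
```

```
Ancestral karyotype reconstruction
==========================================
ancestral genes                     1534
CAR segments                        49
CAR N50 (genes)                     40
chromosome-size CARs                49
candidate ohnolog pairs             694
synteny-supported pairs (list A)    694
consensus ohnolog pairs             694
consensus ohnolog genes             976
ohnolog families                    424
  pairs / triplets / quartets       310 / 100 / 14
tetrads (pre-1R chromosomes)        17
mean ohnolog partners per CAR       3.469
------------------------------------------
Karyotype timeline (chromosomes):
  pre1R         17
  post1R        34
  inter1R2R     27
  post2R        54
  euteleostomi  50
  amniota       49
Events: fusion_interWGD=7, fusion_post2R=5
```

Reading the output: the 1534 ancestral genes are ordered into 49 CARs that
coincide with the 49 true ancestral chromosomes; 694 consensus ohnolog
pairs group into 424 families (the 310/100/14 split of pairs, triplets and
quartets reflects duplicate survival at 35% retention); the partner test
links the CARs into 17 tetrads — one per pre-1R chromosome — and the event
classification recovers all seven inter-WGD fusions and the five dated
post-2R fusions, giving the karyotype series 17 → 34 → 27 → 54 → 50 → 49.

The same pipeline runs from files via the CLI:

```bash
paleokaryo simulate --seed 1 --out sim/
paleokaryo reconstruct --genomes sim/genomes --families sim/families.tsv \
    --clades "a:a1,a2;b:b1,b2" --outgroups outgroup1,outgroup2 \
    --clgs sim/clgs.tsv --divergence sim/divergence.json --out fit/
paleokaryo report --scenario fit/scenario.json
```

## Layout

- `paleokaryo.sim` — forward simulator (WGDs, fusions, fissions, duplicate
  loss, inversions/translocations) with replayable ground-truth histories
- `paleokaryo.reconstruction` — ancestral genes, adjacency graph, CARs
- `paleokaryo.ohnologs` — candidate pairs, synteny filter, consensus
- `paleokaryo.tetrads` — proportion test, partner graph, tetrad assembly,
  CAR merge/split
- `paleokaryo.scenario` — CLG assignment, fusion/fission classification,
  dating, timeline, orthology-pattern diagnostics
- `paleokaryo.model` — `AncestralKaryotypeModel.fit()` →
  `KaryotypeResults`
- `paleokaryo.io` / `paleokaryo.cli` — file dialects, configuration, CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
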