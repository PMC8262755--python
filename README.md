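# bgcmine

Rule-based mining of microbial genomes for secondary-metabolite
**biosynthetic gene clusters (BGCs)**: detection of cluster types from
profile-HMM domain hits, explicit assembly-line module reconstruction for
NRPS/PKS megaenzymes, a three-part cluster-comparison score, RiPP
precursor/RRE annotation, and a JSON *sideloading* format so external
cluster predictors can feed their results into the same downstream
analyses.

The intended users are natural-product genome miners who want a small,
fully inspectable engine whose every stage — rules, distances, score
formulas — is explicit and testable, rather than a monolithic pipeline.

## The model

**Detection.** Each of the 71 bundled cluster types is a *detection rule*:
a boolean condition over profile hits (`cds(...)` for single-gene
co-occurrence, `minimum(n, [...])` for counting, `and`/`or`/`not`) plus two
distances in kb — the *cutoff* (maximum gap between consecutive core genes
jointly satisfying the condition) and the *neighbourhood* (flanking
extension).  A satisfied rule yields a **protocluster** (core + 
neighbourhood); protoclusters whose neighbourhoods overlap merge
transitively into **regions**, with candidate-cluster kinds
(`chemical-hybrid`, `interleaved`, `neighbouring`, `single`) describing how
their cores relate.  Rules carry a strictness tier
(`strict < relaxed < loose`); weak-evidence rules such as `RRE-containing`
and `RiPP-like` only fire from the relaxed tier up.

**Modules.** Within NRPS / modular type I PKS / trans-AT PKS genes, ordered
domains are folded into modules by a small grammar: a module opens at C or
KS (A/AT may open a loading module at the start of a line), accumulates
modification domains (KR, DH, ER, MT, E), and closes at the first carrier
domain (PCP/ACP); TE attaches to the final module; a PKS module closed
without AT is a trans-AT module.  A module left open at a gene's end merges
with the head of the next gene when the genes are adjacent, same-strand and
≤ 2 kb apart — a *split* module.  Monomers (gly, ser, val, mal, mmal) come
from an exact-match signature table on the A/AT domain peptide; unknown
signatures honestly report `?`.

**Comparison.** A query cluster is scored against reference entries
(MIBiG-style JSON) with three parts, each scaled to [0, 1]:

* *identity* — mean best-hit local-alignment identity over the query's
  proteins (greedy mutually-best one-to-one pairing; pairs under 30 %
  identity or 25 % coverage discarded; unpaired proteins count 0);
* *synteny* — longest common subsequence of paired reference gene indices
  walked in query gene order, over the number of pairs, taking the better
  of the two reference orientations;
* *components* — Jaccard index of the biosynthetic component inventories
  (detection profiles hit, functional classes, smCOG classes, NRPS/PKS
  domain classes).

The final score is the **geometric mean** of the parts, so one missing
aspect annihilates inflated single-part matches.

**Sideloading.** External predictions enter as a validated JSON document
(`src/bgcmine/data/sideload.schema.json`); sideloaded protoclusters rejoin
region building exactly like native ones, with tool provenance retained.

## Worked example

Synthetic genomes with planted clusters are first-class citizens
(`bgcmine make-fixture`, or the API for full control of gene contents):

```python
import bgcmine as bm

spec = bm.FixtureSpec(seed=11, planted_clusters=[
    bm.PlantedCluster("NRPS", domain_strings=["C-A:gly-PCP-C-A:ser-PCP-TE"]),
    bm.PlantedCluster("terpene")], decoy_cds_count=14)
fx = bm.make_fixture(spec)
paths = bm.write_fixture(fx, "demo")
doc = bm.run_pipeline(paths["genbank"],
                      bm.PipelineOptions(strictness="strict",
                                         hit_table=paths["hit_table"]))
```

Walking the resulting document prints:

```
region 1: NRPS core 10134..10716 (1 gene)
region 2: terpene core 83969..84131 (1 gene)
module: C-A-PCP | type nrps | complete True | monomer gly
module: C-A-PCP-TE | type nrps | complete True | monomer ser
```

Two regions are detected, exactly matching the two planted clusters (the
14 decoy genes trigger nothing).  The bimodular NRPS gene is resolved into
two complete C-A-PCP modules — the second carrying the chain-releasing
thioesterase — with monomers read off the adenylation-domain signatures:
the predicted product is a Gly-Ser dipeptide.

The same run from the shell:

```bash
bgcmine make-fixture --seed 11 --rule NRPS --rule terpene --output-dir demo
bgcmine detect demo/fixture1.gbk --strictness strict \
    --hit-table demo/fixture1.hits.tsv --output-dir demo/out
# -> 2 region(s) written to demo/out/results.json
```

`bgcmine detect` also accepts `--sideload FILE` (repeatable), a reference
database via `--cc-db`, and `--strictness {strict,relaxed,loose}`; see
`bgcmine --help`.

## Layout

```
src/bgcmine/
  core.py       shared data model, interval arithmetic (0-based half-open)
  profiles.py   profile catalogue, hit-table parsing, scanner backends
  rules.py      rule DSL, evaluation, protocluster/region building
  modules.py    NRPS/PKS domain classification and module assembly
  compare.py    three-part cluster comparison
  sideload.py   external-annotation JSON validation and merging
  ripp.py       RiPP precursor candidates and RRE annotation
  fixtures.py   synthetic-genome generation with exact planted truth
  genbank.py    GenBank / FASTA+GFF3 I/O boundary
  pipeline.py   end-to-end pipeline and canonical results JSON
  cli.py        command-line interface
  data/         profile catalogue, 71-rule catalogue, lookup tables, schema
docs/methods.md   modelling choices, defaults, and limitations
```
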