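# Methods

This note records how bgcmine's models work, which parameters matter, what
the synthetic fixtures do and do not emulate, and where the design was
genuinely open.

## Coordinates and records

All internal coordinates are 0-based half-open (nucleotide bp on records,
amino acids on proteins).  The GenBank boundary (`genbank.py`) is the only
place the 1-based inclusive convention appears, and a parse → serialize →
parse round-trip preserves every interval exactly.  Only CDS and source
features are modelled.  Circular records are treated as linear: detection
windows never wrap the origin.  A cluster actually straddling the origin of
a circular chromosome would be reported as two truncated pieces — a known
limitation chosen over the complexity of wrap-around interval arithmetic.

## Profile hits

Hits come from a whitespace-delimited table (a column subset of HMMER's
domtblout: target, profile, full-sequence bitscore, E-value, ali-from,
ali-to) or from a pluggable scanner backend.  Per-profile gathering cutoffs
are applied with ≥ semantics (ties at the cutoff are kept, matching common
gathering-threshold practice).  Two filtered views exist deliberately:

* **rule view** — best hit per (CDS, profile); what a detection condition
  consumes, since conditions only ask about presence;
* **domain view** — every above-cutoff hit; what module assembly consumes,
  since one megaenzyme gene legitimately carries the same domain profile
  several times (e.g. two C domains in a bimodular NRPS gene).

The bundled catalogue's cutoffs (8.0 bits) are placeholders calibrated to
the bundled naive scanner, whose bitscore is the signature length (10).
They are not calibrated gathering thresholds for real pHMMs; a production
deployment binds a real HMM engine to the backend contract and supplies its
own cutoffs.

## Detection rules

A rule is `RULE name / CATEGORY / STRICTNESS / CUTOFF kb / NEIGHBOURHOOD kb
/ CONDITIONS expr`.  The condition grammar offers `and`, `or`, `not`,
`cds(...)` (subtree must hold on one gene alone), and `minimum(n, [...])`
(≥ n distinct listed profiles in the group).  Operator precedence is the
conventional `not > and > or`; parentheses override.

Evaluation semantics: the *candidate* genes of a rule are those hit by any
profile the condition references at positive polarity (profiles only under
`not` do not recruit candidates).  Candidates are chained along the genome;
a gap over `cutoff_kb` between the end of one candidate and the start of
the next breaks the chain.  Each maximal chain whose gene set satisfies the
condition becomes one core; cores are disjoint by construction.  For
monotone conditions (no `not`) this provably equals taking the maximal
satisfying gene subsets under the same distance constraint, which is what
the test suite's exhaustive oracle enumerates.  With `not`, maximality is
not well-defined (a superset can lose satisfaction), so negation is
specified at chain level and covered by targeted unit tests rather than the
randomized oracle battery.

Geometry: the core interval spans the outermost core genes; the
neighbourhood extends it by `neighbourhood_kb` per side, clipped to the
record.  Distances are measured between nearest gene ends; neighbourhoods
from core bounds.

**The 71-type catalogue.**  Cluster-type names that are publicly
well-known in the genome-mining field are used verbatim (t1pks, t2pks, t3pks, transAT-PKS, NRPS,
terpene, lassopeptide, thiopeptide, siderophore, ectoine, the lanthipeptide
classes i–v, lipolanthine, thioamitides, ranthipeptide, epipeptide,
cyclic-lactone-autoinducer, spliceotide, thioamide-NRP,
tropodithietic-acid, prodigiosin, NAPAA, pyrrolidine, redox-cofactor,
RiPP-like, RRE-containing, sactipeptide — which absorbs the old
head-to-tail type — and so on); their conditions and the remaining names
are this package's reconstructions over its own profile vocabulary, not
copies of any curated rule files.  No fidelity beyond the type names is
claimed.  `RiPP-like` (the replacement for the deprecated "bacteriocin"
category) and `RRE-containing` sit in the relaxed tier because their
profiles are individually insufficient evidence of a cluster; `other` and
`halogenated` are loose-tier.  Strictness S admits rules with tier ≤ S.

Candidate-cluster kinds inside a region: overlapping cores of assembly-line
products ({t1pks, transAT-PKS(-like), PKS-like, NRPS(-like)}) form
`chemical-hybrid` candidates; other core overlaps are `interleaved`;
co-regional protoclusters sharing only neighbourhoods are `neighbouring`;
a lone protocluster is `single`.

## Module assembly

Domain classes (C, A, PCP, E, KS, AT, KR, DH, ER, MT, ACP, TE, other) come
from a bundled profile→class table.  The module grammar — open at C/KS (or
A/AT for the loading module at the very start of a line), accumulate
modifiers, close at the first carrier, TE attaches to the final module,
KS-without-AT closes a trans-AT module — is this package's formalisation;
it is the smallest grammar that reproduces split modules and trans-AT
architecture.  An opener arriving before a carrier aborts the open module
(reported incomplete).  No module can contain two carriers.

Cross-gene (split) modules: consecutive genes both carrying assembly-line
domains merge into one domain sequence when adjacent in the record (no gene
between them), same strand, and ≤ 2 kb apart (`SPLIT_GAP_BP`).  Because
cross-gene assembly literally runs on the concatenated sequence, split
assembly is equivalent to single-protein assembly by construction; the
equivalence test exercises the chaining conditions (strand, gap,
intervening genes).  A gene whose hits are all class `other` does not
bridge a line.  Genes of one assembly line interleaved with unrelated genes
are ordered purely by genomic position.

Monomer prediction is an exact-match lookup of the A/AT domain's spanned
peptide in a signature table; substrate-specific adenylation/acyltransferase
variants (A_gly, A_ser, A_val, AT_mal, AT_mmal) carry the table's
signatures, generic A/AT domains return `?`.  This is intentionally a
lookup, not a trained predictor.

## Cluster comparison

The final score for a query/reference pair is the geometric mean of three
parts in [0, 1].  The part definitions (mean best-hit identity over query
proteins; orientation-max longest-increasing-subsequence fraction of paired
reference indices; Jaccard on component tags) are this package's own
design, chosen to satisfy the published constraints: an alignment part, a
gene-synteny part, a presence/absence-of-components part, each scaled to
[0, 1], combined by geometric mean.  Consequences worth knowing:

* self-comparison scores exactly 1.0 (all parts are 1 by construction);
* the geometric mean lies between the smallest and largest part and is
  annihilated by any zero part — no epsilon smoothing;
* comparison is query-normalised and therefore directional; no symmetry is
  claimed.

Pairing uses local Smith-Waterman with BLOSUM62 (gap open −10, extend
−0.5) through biopython; identity is identities over aligned columns and
coverage is the aligned fraction of the shorter sequence.  Pairs under
30 % identity or 25 % coverage are discarded — standard homology
heuristics, configurable at module level.  Pairing is greedy
mutually-best: repeatedly take the globally highest-identity remaining
pair.  Ties break lexicographically, so rankings are invariant under
database permutation.

## Sideloading

Documents are validated structurally (required tool name/version,
well-formed 0-based half-open intervals, neighbourhood containing core,
string-valued details) with errors naming the offending record and feature
index; the shipped JSON-Schema file documents the dialect.  Field names are
this repository's documented dialect of the format.  Merging rebuilds
regions from the union of native and sideloaded features with full
transitive closure over protocluster neighbourhoods *and* subregions, which
makes merging order-independent and idempotent (de-duplication key: tool,
record, interval, product/label).  Unknown record ids warn and skip.  A
sideloaded protocluster covering no annotated gene is kept as a subregion
(it cannot carry a core gene set).

## RiPP annotation

Precursor candidates are ORFs of ≤ 120 aa inside a RiPP protocluster
neighbourhood (`short-orf`), additionally flagged `near-core` within 10
CDS positions of a core gene.  Both thresholds are documented defaults.
Leader/core split prediction is a deliberately tiny cleavage-motif table
(double-glycine-type GG/GA, searched in the leader half); without a match
the split stays unknown — class-specific cleavage models are out of scope.
RRE (RiPP recognition element) hits are the catalogue profiles tagged
`source_tag=RRE`; each profile hit yields exactly one annotation marked
with RiPP-protocluster containment, and the same profiles drive the
relaxed-tier `RRE-containing` rule for novel-cluster discovery.

## Synthetic fixtures

Fixture genomes embed planted clusters whose proteins contain the naive
scanner's signature peptides for exactly the profiles their rule needs
(derived mechanically from the rule's condition, or from explicit
domain strings for assembly-line genes), back-translated into the
nucleotide sequence with a fixed codon choice.  Background/decoy proteins
draw from an alphabet without tryptophan while every signature contains
one, so decoys can never hit a profile and the planted truth is exact.
Layout: clusters are separated by 65 kb (beyond every rule's cutoff and
neighbourhood), intra-cluster gaps default to 300 bp, decoys are spread
around clusters with 0.3–1.5 kb spacing.  One seeded generator drives
everything; fixed seed means byte-identical files.

Random recovery experiments draw from the *cleanly plantable* strict rules:
a rule qualifies when detection on its canonical planted cluster alone
returns exactly that rule with exactly the planted core.  Two strict rules
are excluded automatically because their conditions nest inside broader
rules' (lipolanthine ⊃ lanthipeptide-class-iii, thioamide-NRP ⊃ NRPS), so
planting them necessarily also fires the broader rule — a real property of
nested rule catalogues, not a detection error.

What fixtures do **not** emulate: real pHMM score distributions and partial
hits, overlapping genes, frameshifts, contig breaks, GC-realistic sequence,
or homology between decoys and cluster genes.  Passing recovery tests
therefore demonstrates the correctness of the rule/geometry machinery, not
sensitivity or specificity on real genomes.

## Determinism

Results JSON is canonical: sorted keys, fixed indentation, floats rounded
to 6 decimals, lists ordered by record and coordinate.  Identical inputs
and options produce byte-identical output; `scripts/acceptance.py` verifies
this end to end.  Problem sizes there (200 oracle cases, 50 planted
genomes, 25 self-comparisons, 1000 split strings, 20 sideload documents)
keep the whole script under a minute on one CPU while exercising every
subsystem.
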