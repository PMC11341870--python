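# Methods

## The mining procedure

`kkpscan` searches annotated genomes for three-gene KKP modules: a
PP2C-family Ser/Thr phosphatase (PF13672 / COG0631) next to two
eukaryotic-like Ser/Thr kinases (PF00069 / COG0515) whose C-termini carry,
respectively, a cold shock domain (CSD, PF00313) and a forkhead-associated
domain (FHA, PF00498). The search has three stages:

1. **Triplet enumeration.** On each contig, every window of three CDS at
   consecutive CDS ranks is tested. All three genes must share a strand,
   and their roles must read phosphatase–kinase–kinase in transcription
   order (ascending coordinates on `+`, descending on `-`). tRNA/rRNA
   features are retained in the gene table but do not enter or break
   windows — the search is about protein-coding domain content.
2. **Length filter.** Every gene must satisfy 900 bp < length < 1300 bp,
   strictly at both bounds. The filter applies to all three genes; a
   short gene adds `LEN_SHORT`, a long one `LEN_LONG`.
3. **Architecture filter.** Between the two kinase genes there must be
   exactly one CSD-fused and one FHA-fused kinase; which position carries
   which accessory is not constrained. Violations add `NO_CSD`,
   `NO_FHA`, and/or `DUP_ACCESSORY`.

A candidate with an empty rejection list is *authentic*; its components
are exported as `pfpC_like` (phosphatase), `pfkA_like` (CSD kinase) and
`pfkB_like` (FHA kinase).

**Pattern order.** The module is named kinase–kinase–phosphatase after its
operon, but the natural search statement is phosphatase-first; the two
readings are mirror images whenever strand annotation is ambiguous. The
scanner therefore accepts both transcription-order patterns by default
(`--pattern both`), records which one matched, and can be restricted to
`PKK` or `KKP`. Under `both`, strand conventions cannot silently flip
results: the accepted window set is invariant under reverse-complementing
a genome (a property the test suite checks explicitly).

**Adjacency.** "Neighboring" means strictly consecutive CDS ranks — no
intervening CDS. No intragenic bp cap is applied on top of rank adjacency;
an optional cap exists for unusually gappy annotations.

## Role calling from domain hits

Per-domain hits (HMMER3 `--domtblout` dialect) are filtered at an
independent E-value of 1e-5 — the conventional Pfam screening cutoff; the
sources this pipeline ingests state no threshold of their own — and
resolved greedily: hits are accepted in descending bitscore order
(ties broken by alignment position, then accession) and rejected when they
overlap an accepted segment by more than 15 aa. This makes the
architecture a deterministic, input-order-independent function of the hit
set, and raising the E-value cutoff can only add segments.

Roles: a kinase segment plus a CSD (FHA) segment **starting strictly after
the kinase segment ends** gives `Pkinase_CSD` (`Pkinase_FHA`) — the
accessory domains of interest are C-terminal, so an N-terminal accessory
does not confer the fused role. A kinase with both accessories is assigned
by the higher-bitscore accessory and logged. `PP2C` requires a phosphatase
segment and no kinase segment; `Psu` (PF07455, the P4 polarity suppression
protein used as a satellite-prophage marker) applies only in the absence
of kinase/phosphatase segments, with a warning on co-occurrence. A single
global E-value cutoff covers all families; the accessory domains get no
separate threshold.

## Genomic context

Categories are assigned with precedence
`prophage > P4_prophage > MGE_linked > other`; all gathered evidence is
retained regardless of the winning category, and the categories partition
the cluster set.

- **prophage** — the cluster span overlaps a predicted prophage interval
  by ≥ 1 bp. Boundary predictions are imprecise, so partial overlap
  counts; `--prophage-containment` switches to full containment.
- **P4_prophage** — no interval, but a Psu-role gene within 20 CDS ranks
  of a cluster gene. Automated predictors frequently miss the ~11 kb P4
  satellites; 20 CDS comfortably spans one P4 genome. The window is
  configurable; Psu is not required to be co-strand with the cluster.
- **MGE_linked** — an annotated mobile-genetic-element gene (integrase,
  transposase, restriction–modification, toxin–antitoxin, phage gene)
  within 5 genes **or** 3000 bp — OR semantics, gene distance measured by
  contig rank from the nearest cluster gene, bp distance from the cluster
  span. Enlarging either window is monotone: it can only add evidence.

The summary table reports counts and fractions per category, overall and
per taxon, and states the MGE-linked share of non-prophage clusters as an
"x out of y" string.

## Protein-identity families

Pairwise identity is computed from a global affine-gap alignment with
BLOSUM62 (gap open −10, extend −1): identity = identical aligned pairs /
alignment columns, so gap columns count against identity. This is the
stricter of the common conventions; `--identity-denominator shorter`
divides by the shorter ungapped length instead. The aligned pair is
ordered canonically before alignment so that identity(a, b) ≡
identity(b, a) even when equal-scoring alignments differ in column count.

Cluster-level similarity is the arithmetic mean of the three component
identities (pfkA–pfkA, pfkB–pfkB, pfpC–pfpC); `identity_min` is available
as a conservative alternative. Families are single-linkage connected
components above the threshold (default 90%), numbered deterministically
by smallest member id; the representative is the member with the longest
total protein length, ties to the smallest id.

## Tree annotation

Tree inference is consumed, not performed. A Newick tree of PfkA-like
kinases is rerooted on the edge above the smallest clade containing the
configured outgroup (e.g. three eukaryotic Ser/Thr kinases); rerooting
preserves the leaf set and all unrooted bipartitions. Each clade label is
seeded by reference leaves and extended to the maximal subtree containing
no other clade's references and no outgroup leaf — so unlabeled sister
lineages are absorbed into the nearest labelled clade, and only leaves
separated from every clade by the root or by foreign references remain
`unassigned`. Nested references across clades raise a monophyly error
naming the offending leaves.

## Pairwise region alignment

The aligner is a Gotoh global affine-gap DP (numba kernel) with:

- **Gap cost** `gap_open + L * gap_extend` for a gap of length L (BLAST
  convention — the first gap character pays one extension). Defaults for
  DNA: match +1, mismatch −2, open −5, extend −1 (megablast-class); no
  particular scheme is canonical for prophage comparisons, so all four
  are configurable.
- **Deterministic tie-breaking** at equal score: substitution over gap,
  gap in the second sequence over gap in the first.
- **Banding**: sequences longer than 5 kb default to a 256-wide diagonal
  band (widened to cover any length difference), which keeps ~12 kb
  prophage-scale alignments fast; a band narrower than the length
  difference is a configuration error, and the banded score equals the
  unbanded one whenever the optimal path stays in band.
- **Terminal gaps are penalized** (true global alignment); identity is
  matches / columns as above.

The gap-run inventory lists maximal gap runs per sequence with the run
length, alignment column, and the 10 residues immediately 5′ of the run
in the gapped sequence's own ungapped coordinates — enough to localize,
e.g., a single 18 bp deletion between two otherwise near-identical
prophage copies.

## The synthetic-data generator

The generator emulates an annotated-genome screening universe at desk
scale: per genome, ~100 CDS with log-normal lengths (median ≈ 950 bp,
σ = 0.35 on the log scale — typical bacterial gene lengths), uniform
random strands, 20–200 bp intergenic gaps, a couple of tRNAs, and
background roles of 95% `other`, 3% lone kinase, 2% lone phosphatase to
create near-miss structure. Planted items occupy well-separated blocks
(35 CDS apart) with role-neutral buffer genes, so each item's outcome is
attributable to its own construction:

- **Authentic clusters** get in-band lengths (950–1269 bp), a random
  shared strand, a random CSD/FHA kinase order, and an intended context:
  a prophage interval around the span, a Psu gene 7 CDS away (P4), an
  MGE-table gene 2 CDS away, or nothing. The default context mix —
  80% prophage, 10.5% P4, 5.8% MGE-linked, 3.7% other — reproduces the
  situation where ~90% of modules sit in temperate phages and ~60% of
  the remainder are MGE-linked.
- **Decoys**, one class per planted item, each violating exactly one
  rule. The expected scanner outcome per class is fixed in
  `DECOY_EXPECTATIONS` ahead of everything else: `WRONG_ORDER`,
  `MIXED_STRAND`, `NON_ADJACENT` and `KK_PAIR_ONLY` must produce no
  candidate at all; `LEN_OUT`, `NO_CSD` and `NO_FHA` must each produce
  exactly one rejected candidate carrying exactly the planted rejection
  code.
- **Identity families**: planned members substitute disjoint position
  sets of an ancestor protein, sized so every realized gapless pairwise
  identity lands within one substitution of the target — exact for even
  substitution counts (e.g. 90% on 300 aa = 15 + 15 disjoint changes).

All randomness flows from one seed; per-genome substreams are derived by
counter, so identical configs are byte-identical and extending a dataset
never perturbs earlier genomes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genome sequences are uniform random DNA
(coding sequence does not translate to the emitted proteins; no GC or
codon structure); domain-hit E-values/bitscores are drawn from simple
ranges rather than from profile-HMM score distributions; prophage
intervals are exact around planted items rather than noisy predictions;
and real screens inherit whatever systematic errors their upstream
annotation, prophage prediction, and MGE databases carry. The tests
establish the correctness of the mining logic, not the field performance
of upstream predictors.

## Problem sizes and numerical choices

The acceptance script (`scripts/acceptance.py`) runs: 50 genomes for
scanner-vs-oracle equivalence; 10 independent 6-genome batteries for
planted-truth recall/precision and context recovery; 2 decoys per class
for discrimination; 500 random short pairs plus 100 planted-indel trials
(1–50 bp in 2 kb) for the aligner; 5 family-plan trials; and one large
planted screen of 911 authentic clusters among 1000 candidates across 420
genomes — sizes chosen so the whole report recomputes from scratch in
well under a minute on one CPU while still exercising every code path at
a few thousand windows per batch. All sub-seeds derive from the single
`--seed` argument.

Degenerate inputs are defined rather than special-cased: an empty genome
set yields empty tables and exit code 0; zero candidates make the
authentic fraction *undefined* (`None`), never 0; empty interval or MGE
files mean "no evidence of that kind"; a 0/0 context summary reports NaN
fractions.

## Known limitations

- GenBank input relies on `locus_tag`/`gene` qualifiers for identifiers;
  records without them are skipped.
- The triplet scanner assumes one gene per CDS feature (no join/fuzzy
  locations beyond what the parsers normalize).
- Identity families in the generator are gapless by construction; indel
  divergence between family members is not simulated.
- The clade annotator requires the outgroup to be separable from the
  ingroup on the given topology; trees whose outgroup is paraphyletic
  through the root are rejected rather than silently resolved.
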