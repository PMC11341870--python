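# kkpscan

Mining prophage-encoded **kinase–kinase–phosphatase (KKP) modules** from
annotated bacterial genomes.

KKP modules are tripartite gene clusters that couple prophage quiescence to
host physiology: two eukaryotic-like Ser/Thr kinases — a *pfkA*-like kinase
carrying a C-terminal cold shock domain (CSD, PF00313) and a *pfkB*-like
kinase carrying a C-terminal forkhead-associated domain (FHA, PF00498) —
together with a *pfpC*-like PP2C-family Ser/Thr phosphatase (PF13672 /
COG0631). They behave as a toxin–antitoxin-like phage defense and
lysogeny-control system and are carried by temperate phages (P2 and its P4
satellite, Mu-like, and filamentous Pf-like prophages) across Gram-negative
bacteria.

`kkpscan` is for comparative genomicists who want to screen annotated
genome collections for these modules. It implements:

- **Triplet mining** — enumerate consecutive, same-strand gene triplets
  whose roles read phosphatase–kinase–kinase in transcription order
  (`PKK`, `KKP`, or both orders), then filter by gene length
  (every gene strictly between 900 and 1300 bp) and by kinase domain
  architecture (exactly one CSD-fused plus one FHA-fused kinase). A
  triplet passing all filters is an *authentic* KKP cluster; every
  rejected candidate carries machine-readable rejection codes
  (`LEN_SHORT`, `LEN_LONG`, `NO_CSD`, `NO_FHA`, `DUP_ACCESSORY`).
- **Domain-architecture calling** from HMMER3 `--domtblout` tables:
  greedy bitscore-ranked segment resolution and a deterministic role
  vocabulary (`PP2C`, `Pkinase_CSD`, `Pkinase_FHA`, `Pkinase_plain`,
  `Psu`, `other`).
- **Genomic-context classification** with precedence
  prophage > P4 prophage > MGE-linked > other: overlap with predicted
  prophage intervals (BED/TSV, e.g. VirSorter exports), rescue of P4
  satellites via the Psu marker (PF07455), and mobile-genetic-element
  adjacency within 5 genes or 3000 bp (OR semantics, mobileOG-style gene
  tables).
- **Family grouping** by pairwise protein identity (global BLOSUM62
  alignment; single-linkage components above 90% mean identity of the
  three components) and **clade annotation** of an externally built
  PfkA-kinase tree (outgroup rerooting + reference-leaf clades, iTOL
  export).
- **Region comparison** — banded global affine-gap (Gotoh) alignment
  with a gap-run inventory, e.g. to show that two co-resident Pf
  prophages differ only by one short internal deletion.
- A **synthetic-data generator** that emits GFF3 + FASTA + domtblout +
  BED + MGE TSV batteries with planted authentic clusters, seven typed
  decoy classes, planted genomic contexts and identity families, plus a
  truth table — so the whole pipeline is testable offline.

## Worked example

Generate a small synthetic battery and run the full pipeline:

```bash
kkpscan simulate --seed 7 --n-genomes 4 --n-authentic 4 -o sim
printf 'genome_id\tgff\tdomtbl\tprophage_bed\tmge_tsv\n' > manifest.tsv
for g in G0000 G0001 G0002 G0003; do
  printf "$g\tsim/$g.gff\tsim/$g.domtbl\tsim/${g}_prophage.bed\tsim/${g}_mge.tsv\n"
done >> manifest.tsv
kkpscan run --manifest manifest.tsv -o out
```

The run log reports the filter cascade:

```json
{
  "candidates": 7,
  "length_pass": 6,
  "architecture_pass": 4,
  "authentic": 4,
  "contexts": {"prophage": 3, "P4_prophage": 1, "MGE_linked": 0, "other": 3}
}
```

Seven triplets matched the phosphatase–kinase–kinase pattern; one failed
the 900–1300 bp length band, two more lacked the CSD/FHA accessory pairing,
and the four planted authentic clusters survived every filter. Of those
four, three overlap a predicted prophage interval and one was rescued as a
P4 satellite by a nearby Psu gene (`out/summary.tsv`):

```text
taxon  category     count  fraction  mge_among_non_prophage
all    prophage     3      0.75
all    P4_prophage  1      0.25
all    MGE_linked   0      0.0       0 out of 0
all    other        0      0.0
```

`out/clusters.tsv` records one row per candidate with the component
assignment — e.g. cluster `G0000|G0000_c1|11-13` on the minus strand has
`pfpC_like=G0000_g00012`, `pfkA_like=G0000_g00011` (CSD kinase) and
`pfkB_like=G0000_g00010` (FHA kinase).

Other subcommands: `kkpscan scan` (one genome, candidates only),
`kkpscan classify` (scan + contexts), `kkpscan families`,
`kkpscan tree-annotate`, `kkpscan compare`, `kkpscan simulate`.

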