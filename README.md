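# plastomics

Comparative plastome (chloroplast genome) analysis toolkit:

* **structure** — inverted-repeat detection, LSC/IRb/SSC/IRa quadripartite
  partitioning, per-region GC content, junction gene contexts, gene/intron
  inventory;
* **repeats** — microsatellites (SSRs) under per-unit-size copy thresholds
  (10/5/4/3/3/3 for mono–hexa), dispersed repeat pairs in four categories
  (forward, reverse, complement, palindromic; ≥30 bp, ≤3 mismatches),
  tandem repeat arrays scored +2/−7/−7 against a majority-rule consensus
  (report threshold 80, period ≤ 500);
* **hotspots** — homologous gene/spacer extraction across annotated
  genomes, built-in progressive affine-gap alignment (or import of external
  alignments), the variable-site percentage
  `100·(S + I) / (L_aln − L_indel + I)`, top-k hotspot ranking and
  genus/family set combination;
* **selection** — Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction as
  a simple positive-selection screen;
* **phylo** — p-distances (pairwise deletion), neighbor joining,
  Robinson–Foulds distance, and a species-cluster exclusivity check for
  candidate barcode markers;
* **simulate** — synthetic quadripartite plastomes with planted genes,
  SSRs and repeats, evolved along a newick tree with region-specific rate
  multipliers and an indel process, plus machine-readable truth for
  parameter-recovery testing.

## CLI

```bash
plastomics --out OUT --seed 1 structure genomes/*.gb --min-ir 1000
plastomics --out OUT ssr genomes/*.gb
plastomics --out OUT repeats genomes/*.gb --max-out 100
plastomics --out OUT hotspots genomes/*.gb --level genus -k 7
plastomics --out OUT dnds genomes/*.gb --genes all
plastomics --out OUT --seed 42 simulate --preset hotspot
plastomics --out OUT phylocheck genomes/*.gb \
    --markers rpoB-trnC-GCA,trnT-GGU-psbD,ycf1 --species-map map.tsv
```

Outputs are TSV tables plus JSON sidecars with run parameters.

## Conventions

Internal coordinates are 0-based half-open on a circular axis (GenBank I/O
converts at the boundary). Ambiguity codes other than N become N on ingest.
Dispersed-repeat maximality is budget-based: a reported pair cannot be
extended in either direction without exceeding the mismatch budget; results
are provably identical to a brute-force enumeration of the definition
(property-tested). Indel events in the variability statistic count one per
maximal run of gap-containing columns, and gap columns are excluded from
the substitution census.
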