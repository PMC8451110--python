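# nsltpkit

Genome-wide identification, classification and characterization of plant
**non-specific lipid transfer proteins (nsLTPs)** — small, basic, secreted
proteins built around the eight-cysteine motif (8CM)

```
C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C
```

nsLTPs shuttle lipids, build cuticle and respond to abiotic stress; in
cereals such as barley (*Hordeum vulgare*) and its Tibetan hulless
cultivar Qingke the family comprises dozens of genes in four types
(1, 2, D and G).  `nsltpkit` is for researchers who need a reproducible,
scriptable version of the classic gene-family workflow: from a pool of
candidate protein sequences and gene annotations to a typed nsLTP
catalog, physicochemical tables, a neighbour-joining phylogeny,
duplication/cluster maps, promoter cis-element profiles and
stress-expression summaries — plus a synthetic-cohort generator with a
ground-truth manifest so every stage can be validated offline.

## What it computes

- **Screening funnel** (`nsltpkit.screen`): candidates are kept only if
  they carry a bounded-spacing 8CM and an N-terminal signal sequence,
  are not proline/histidine/glycine-rich between signal and motif, and
  do not resemble storage-protein/inhibitor exemplars.  GPI-anchored
  proteins are retained and flagged (they are the type G members).
  Per-stage accounting is conserved exactly.
- **Physicochemistry** (`nsltpkit.physchem`): molecular weight (average
  masses), isoelectric point pI (Bjellqvist pKa set, bisection on the
  Henderson–Hasselbalch net charge), Guruprasad instability index, Ikai
  aliphatic index and GRAVY (mean Kyte–Doolittle hydropathy).
- **Classification** (`nsltpkit.classify`): type assignment from GPI
  status, inter-cysteine spacing g1..g5, intron count of the linked gene
  model and identity to exemplars; cysteine-anchored 8CM alignment and
  CXC polarity summary.
- **Phylogeny** (`nsltpkit.phylo`): p-distances with pairwise deletion,
  Saitou–Nei neighbour-joining with deterministic tie-breaks, and
  column-bootstrap support values.
- **Genome context** (`nsltpkit.genome_context`): intron offsets
  relative to the 8th-Cys codon (strand-invariant), chromosome maps,
  tandem-duplication clusters and segmental-duplication candidates.
- **Promoters** (`nsltpkit.promoter_scan`): 1.5 kb upstream of the
  translation start, scanned on both strands with IUPAC-degenerate
  consensus strings from an editable PlantCARE-style catalog.
- **Expression** (`nsltpkit.expression`): 2^−ΔΔCt relative expression
  with Welch-test significance stars, FPKM heatmap transforms and
  tissue-specificity calls.
- **Synthetic cohorts** (`nsltpkit.synthetic_data`): deterministic
  generator for proteins, genomes + GFF3, promoters and expression
  tables with a cross-referenced truth manifest.

The package ships a transcribed catalog of the published barley/Qingke
family (75 proteins: 40 HvLTPs, 35 HtLTPs) as
`nsltpkit/data/nsltp_catalog.tsv`, loadable with
`nsltpkit.io.load_nsltp_catalog()`.

## Worked example

Generate a synthetic cohort shaped like the barley family, screen it,
and type the survivors:

```bash
nsltpkit simulate --seed 11 --out-dir sim
nsltpkit screen --proteins sim/proteins.faa --out-dir out
# -> accepted 40/160
nsltpkit classify --candidates sim/proteins.faa --gff sim/genes.gff3 --out typed.tsv
# -> typed 40 proteins
head -3 typed.tsv
# id      type  confidence  spacing         cxc_x  polarity
# LTP1.1  1     0.0         8-14-21-23-12   R      hydrophilic
# LTP1.2  1     0.0         8-14-21-23-12   R      hydrophilic
```

The screen starts from 160 candidates and excludes 107 cysteine-deficient,
11 signal-less and 2 proline-rich proteins, accepting 40 — the funnel
shape of the published barley family — and the classifier partitions the
survivors 16/5/11/8 into types 1/2/D/G.

Summarizing the packaged catalog:

```python
from nsltpkit.io import load_nsltp_catalog
from nsltpkit.physchem import summarize_cohort

cat = load_nsltp_catalog().rename(columns={"aa": "length", "mass": "mw"})
print(summarize_cohort(cat, groups=cat["source"]))
```

```
                     mean      min       max
group    metric
barley   mw      13344.00  9206.81  19981.15
         pi          8.07     3.74      9.88
qingke   mw      13238.00  9206.81  19981.15
         pi          7.94     3.74      9.88
combined length    132.00    91.00    200.00
```

i.e. the barley members average 13,344 Da at pI 8.07, the Qingke
orthologues 13,238 Da at pI 7.94, and the whole family averages 132
mature residues (91–200 aa) with masses 9,206.81–19,981.15 Da.

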