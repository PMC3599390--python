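# nbslrr

Annotation and evolutionary analysis of plant **NBS-LRR disease-resistance
genes** (nucleotide-binding site / leucine-rich repeat), the largest family
of plant R-genes. The package targets genome-wide surveys of the kind done
for cucurbit crops: given a genome with gene models and protein sequences it
locates the family's conserved motifs, classifies each protein's domain
architecture, maps the chromosomal organisation of the family (clusters,
tandem and segmental duplicates, intron structure), reconstructs the
TIR-/CC-family phylogeny of the conserved NBS cores, and simulates the
degenerate-PCR strategy used to mine resistance-gene homologues (RGHs) from
unsequenced relatives. A synthetic-genome generator with planted ground
truth makes every stage testable without any external database.

## What it computes

* **Motif scanning** — a library of 40 degenerate protein consensus motifs
  (20 per family context) covering the N-terminal CC motifs (C1–C3) and TIR
  motifs (T1–T4), the NBS-domain core (P-loop, RNBS-A, kinase-2, RNBS-B,
  RNBS-C, GLPL, RNBS-D, MHDV/MHDL, plus CNBS-1/2 and TNBS-1) and seven
  LRR/C-terminal motifs (L1–L7). A window of protein *s* at offset *i* is
  scored against motif positions with conservation weights
  *w<sub>j</sub>* ∈ {1, 0.5, 0}:

      score(i) = Σ_j w_j · [ s_{i+j} ∈ allowed_j ]  /  Σ_j w_j

  and the best window per motif above a threshold (default 0.6) is reported.
* **Architecture classification** — domain calls (TIR, CC, NBS, LRR, RPW8)
  from motif-hit quorums plus a heptad-periodicity coiled-coil detector,
  mapped deterministically onto the seven letter codes TNL, CNL, TN, CN, N,
  NL and RPW8-NL. The TIR-vs-CC family is independently predicted from the
  kinase-2 motif's diagnostic terminal residue (D → TIR, W → CC, anything
  else undetermined), and the conserved P-loop→GLPL core is extracted for
  phylogeny.
* **Genome structure** — intron counts and phases (phase = cumulative CDS
  length upstream mod 3); gene clusters by the positional rule *adjacent NBS
  genes < 200 kb apart with fewer than eight non-NBS genes between them*;
  duplicate pairs from pairwise protein identity (≥ 0.7, best partner per
  gene), tandem when the pair shares a cluster, segmental otherwise.
* **Phylogeny** — MAFFT alignment of P-loop→GLPL cores, p-distances with
  pairwise deletion of gaps, neighbor joining (Saitou–Nei) with
  deterministic tie-breaking, column bootstrap (default 1000 replicates,
  supports reported above 50%), TIR/CC family partitioning from anchor
  leaves, and a comparative mode that places query cores against a labelled
  reference panel (e.g. *Arabidopsis* N1–N4 / At-TIR-NBS subfamilies).
* **In-silico PCR** — IUPAC degenerate primer matching on both strands,
  exhaustive amplicon enumeration with size filtering (default 300–800 bp
  around the classical ~500 bp NBS fragment), and RGH screening of products
  (reading-frame translation, internal-stop pseudogene exclusion,
  P-loop→GLPL presence).
* **Catalog audit** — a transcription of the published cucurbit
  NBS/RGH accession table with range expansion, per-species and per-family
  counts, and pseudogene/incomplete-core exclusion flags.

## Worked example

Run the full pipeline on the default synthetic genome (seven chromosomes,
57 planted NBS genes in the observed architecture proportions, nine clusters
of 2–10 genes, seven tandem and four segmental duplicate pairs, plus ~345
non-NBS filler genes):

```python
from nbslrr.pipeline import RunConfig, run_full
from nbslrr.synthetic import SyntheticConfig

res = run_full(RunConfig(outdir="out", seed=1,
                         synthetic=SyntheticConfig(seed=1),
                         bootstrap_replicates=100))
print(res["summary"])
print(len(res["clusters"]), len(res["duplications"]),
      res["partition"].boundary_support)
```

prints

```
{'CNL': 17, 'unclassified': 345, 'RPW8-NL': 3, 'NL': 22, 'TNL': 11,
 'TN': 2, 'CN': 1, 'N': 1, 'total': 402}
9 11 100.0
```

Reading this: all 57 NBS genes are recovered in their planted categories
(the 345 "unclassified" entries are the non-NBS filler genes; one planted
NL slot was generated as the diverged copy of an RPW8-NL gene, so the truth
marginals are RPW8-NL: 3, NL: 22). The nine planted clusters and all eleven
duplicate pairs are detected, and the TIR/CC family split in the NJ tree of
the P-loop→GLPL cores has 100% bootstrap support. `out/` holds the full
report bundle (architectures, clusters, duplications, intron stats, newick
tree, family partition, manifest).

The same stages are available from the shell:

```
nbslrr synth --seed 1 --out out/synth
nbslrr annotate --proteins out/synth/proteins.fa --out out/arch.tsv
nbslrr catalog audit
nbslrr full --seed 1 --out out/full
```

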