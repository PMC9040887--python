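# glycomine

Resistance-guided genome mining of **HTH_42 DNA glycosylases** in
*Streptomyces*. Biosynthetic gene clusters (BGCs) that make DNA-damaging
natural products often carry a self-resistance gene; a DNA glycosylase of
the AlkZ/YcaQ (HTH_42) superfamily embedded in a cluster is therefore a
marker that the cluster's product is a genotoxin. `glycomine` implements the
computational side of this mining strategy as a tested, reusable pipeline
for microbial genomics:

- **Motif classification** — each candidate protein is assigned to a
  subfamily by the residue classes of its catalytic motif, located by
  global pairwise alignment to a reference anchor (BLOSUM62, affine gaps):
  **YQL** = QΦD, **AZL** = (Q/H)ΦQ, **AZL2** = HΦ(S/T)(D/E), with Φ an
  aliphatic residue {A,V,L,I,M}. Homology hits are pre-filtered at
  e-value ≤ 1e−4, identity ≥ 25%, subject coverage > 75%.
- **BGC proximity** — signed shortest base-pair distance from each homolog
  gene to the nearest cluster on the same scaffold (< 2 Mbp); a gene is
  *inside* a cluster when within 5 genes or 2 kb of its boundary. Subfamily
  distance distributions are compared by a chi-square test on landmark bins.
- **Copy-number census** — per-genome subfamily counts, copy-number
  frequency spectra, YQL/AZL coincidence tables, and pairwise one-way
  ANOVA of copy-number variance.
- **Neighborhood analysis** — the five nearest genes on each side of a
  focal homolog, assigned to metabolism / signaling–cell function /
  genetic information processing, with inside-vs-outside category ratios.
- **Clade conservation** — mean root-to-tip branch lengths per clade on an
  externally built tree, and mean pairwise percent identity/similarity.
- **Kinetics** — single-turnover glycosylase time courses
  `P(t) = A(1 − e^{−kt})`, the lag-time Hill equation
  `lag = min_lag + (max_lag − min_lag)/[1 + (IC50/[I])^h]`, percent-survival
  IC50 fits, and fold changes.
- **Synthetic data** — a generator that plants subfamily genes at exact
  distances, gene ranks and motif offsets in multi-scaffold genomes (plus
  noisy assay curves), so every stage is validated against known ground
  truth without downloads.

## Worked example

Simulate 100 genomes with the study-structure planting plan (49% YQL /
43% AZL / 8% AZL2; AZL genes inside or near clusters with a mean planted
distance of 2.3 kb, YQL and AZL2 genes 20–30 kb away) and run the full
pipeline:

```bash
glycomine simulate --out-dir sim --seed 3 --n-genomes 100
glycomine run-all --in-dir sim --out-dir out
```

`out/summary.tsv` then shows the recovered subfamily mix and
`out/distance_summary.tsv` the distance statistics:

```
subfamily     count  percent        subfamily  n   mean_abs
YQL           98     49.0           YQL        98  25000.2
AZL           86     43.0           AZL        86   2300.0
AZL2          16      8.0           AZL2       16  25000.8
```

i.e. the classifier recovers every planted subfamily label (49/43/8), AZL
genes sit on average 2.3 kb from their nearest cluster while YQL genes
average 25 kb, and `out/chi_square.tsv` reports the YQL–AZL distance
distributions as significantly different (P = 1.2e−39 on this run, well
below 0.0001). `out/census.tsv`, `out/coincidence.tsv` and `out/anova.tsv`
hold the copy-number census and its statistics; `out/neighbors.tsv` and
`out/category_ratios.tsv` the neighborhood analysis.

Kinetic fits from the library:

```python
>>> import numpy as np
>>> from glycomine.kinetics import fit_single_exponential
>>> t = np.array([0.08, 0.17, 0.33, 0.67, 1, 2, 4, 8, 15, 30, 60])
>>> fit_single_exponential(t, 1 - np.exp(-7.8 * t)).k
7.8
```

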