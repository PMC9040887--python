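# Methods

This note records the models, conventions and numerical choices behind
`glycomine`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinates and formats

All intervals are held internally as 0-based half-open on named scaffolds.
GFF3 is read as 1-based inclusive and converted; BED passes through
unchanged; the writers invert the readers exactly, and round-tripping is
asserted bit-exactly in tests. Gene identity is taken from `locus_tag`,
then `ID`, then `protein_id`, then a deterministic synthetic ordinal
(`<scaffold>_gNNNN`) — a fixed priority order chosen because public
assemblies mix annotation styles. Strand `?` is permitted (cluster
intervals and some features are unstranded). BLAST tabular coverage is the
aligned subject span divided by the subject length, which must be supplied
alongside the hit table.

## Subfamily classification

The three catalytic motifs are ordered residue-class constraints:
YQL = [Q][Φ][D], AZL = [Q/H][Φ][Q], AZL2 = [H][Φ][S/T][D/E], with the
aliphatic set Φ defaulting to {A, V, L, I, M}. The set is configurable; the
conservative five-residue default reflects the aliphatic positions seen in
subfamily sequence logos. The patterns are mutually exclusive (disjoint
final-position classes), which the suite verifies exhaustively over all
8,000 trigrams.

Because motif-like trigrams arise by chance (an AZL-type trigram has
probability 10/8000 per position), the catalytic window is located by
global pairwise alignment (BLOSUM62, gap open −11, extend −1) of the query
to a reference anchor whose catalytic position is known, not by scanning
the raw sequence; a regex-style scan remains available as an explicit
anchor-free fallback. A query is tried against every anchor (convention:
AZL anchor first); a classified call beats UNCLASSIFIED, then the higher
alignment score wins, and exact ties break toward the first-listed anchor —
arbitrary but fixed. Three-residue windows are tested as YQL then AZL;
windows that fail both are re-extracted at length four and tested as AZL2.
Hit filtering applies the e-value and identity cutoffs inclusively
(≤ 1e−4, ≥ 25%) and coverage strictly (> 0.75); the boundary behavior is
pinned in tests.

The shipped reference anchors are synthetic stand-ins for the AlkZ and
YcaQ reference proteins: generated sequences with the catalytic window at
a known offset (the AZL anchor places QΦQ at residue 40, mirroring the
AlkZ Q41/Q43 numbering). Real reference sequences can be supplied as a
FASTA plus a window-position table.

## Proximity to clusters

Distance is the gap between the closest interval boundaries; any overlap
(including half-open adjacency) is distance 0. This boundary-gap reading is
the simplest consistent interpretation of a "shortest base-pair distance"
and is pinned by tests. The sign is defined in scaffold coordinates:
positive when the gene lies on the lower-coordinate (5′) side of the
cluster — cluster strand is undefined, so the scaffold frame is the only
consistent one. Only clusters on the gene's own scaffold and strictly
closer than 2 Mbp qualify; genes with no qualifying cluster are reported
as unassigned rather than dropped. Ties on |distance| break toward the 5′
side, then lexicographic cluster id.

The membership rule is a disjunction of sufficient conditions: inside iff
distance 0, or |distance| ≤ 2 kb, or ≤ 5 annotated genes lie strictly
between the facing boundaries (any strand, counted on the facing side
only; a gene counts when its whole interval fits in the gap). Monotonicity
— shrinking either quantity never flips inside to outside — is property
tested.

Distance distributions are compared with a classical (uncorrected) Pearson
chi-square on a shared binning. The default landmark edges
{0, 2 kb, 20 kb, 100 kb, ∞} come from the analysis's own thresholds
(inside bin, the 2-kb rule, the 20-kb depletion zone, the display range);
the binning is configurable and recorded with every result, and the
resulting P value should be read as "the distributions differ", not as a
reproduction of any particular published statistic.

## Census and ANOVA

Copy-number spectra are reported per clade with genomes carrying ≥ 1 copy
as the denominator; a flag switches to the all-genomes denominator (adding
a 0 bin). Counts of five and above pool into a "5+" bin. The pairwise
one-way ANOVA takes per-genome copy counts *including* zero-count genomes
by default — published analyses are typically silent on this choice, so it
is explicit and flagged here; with two groups F = t² (asserted against the
pooled two-sample t on random pairs).

## Neighborhoods

"Nearest five genes on each side" is by gene rank on the scaffold, not
base-pair distance (matching the open-reading-frame convention of
neighbor tables), truncated at scaffold ends. Category assignment is a
first-match-wins ordered keyword table over the product annotation;
transport/defense keywords outrank broader enzymatic ones so that, e.g.,
"ABC transporter permease" is not absorbed into metabolism. Single
assignment per gene is the default because it conserves counts; a
multi-count mode replicates the convention of counting a multi-term
protein into each of its categories, and outputs are labeled by mode.

## Conservation metrics

Mean root-to-tip length is the arithmetic mean over a clade's leaves of
the root-to-leaf branch-length sums on a rooted tree; an unrooted input is
refused with an instruction to midpoint-root (a midpoint rooter is
provided). The published subfamily values are means-vs-medians ambiguous,
so comparisons should be qualitative (the divergent clade is deeper).
Pairwise similarity counts substitution-matrix-positive residue pairs
(BLOSUM62 by default; the matrix name is recorded in the output), with
columns gapped in either member excluded from that pair's denominator
(an all-columns denominator is available behind a flag).

## Kinetics

The time-course model is P(t) = A(1 − e^(−kt)) with no offset — the assay
measures fraction product from zero; an offset variant is deliberately not
the default. Fits are bounded least squares (k, A ≥ 0, A ≤ 1.05) with a
deterministic 5-point log-spaced multistart on k and objective tolerance
1e−10, so refits are identical. When the first time point already sits at
≥ 95% of the fitted plateau, the rate is only bounded from below by the
data and the fit is flagged as a lower bound rather than a point estimate.
Standard errors come from the Jacobian at the optimum.

The Hill fits use the four-parameter forms given in the module docstring,
parameterized internally as (min, span ≥ 0, log IC50, h) so the ordering
min ≤ max and IC50 > 0 are structural; the multistart covers log-spaced
IC50 starts across the positive dose range crossed with h ∈ {1, 2}. At
dose = IC50 both forms predict the exact min/max midpoint (asserted
analytically in tests), and fitted IC50s are scale-equivariant in dose.
Lag time is estimated by the standard geometric construction — the tangent
at the point of maximal log-linear slope (3-point local fit) intersected
with the baseline OD; a curve never exceeding twice its baseline returns
the final time point as a "no growth" sentinel.

## Synthetic data

The generator is the validation instrument: it plants what the analysis
must recover. Each planted gene gets its own cluster "unit" on the main
scaffold — cluster interval, internal biosynthesis-flavored genes, the
planted gene at an exact boundary gap (or inside the cluster) with an
exact number of intervening genes — with ≥ 300 kb margins between units so
the nearest cluster is unambiguous, plus decoy clusters and a clusterless
background scaffold per genome. Planted proteins are derived from the
reference anchors by point mutation at rate 0.25 outside a conserved
±4-residue catalytic surround, with random padding to move the window
offset; accidental motifs outside the planted window are removed by
bounded rejection sampling. Infeasible plans (e.g. six intervening genes
in a 500-bp gap) fail validation before any file is written.

The default study-structure plan for 100 genomes: 98 YQL copies
(88 genomes ×1, 5 ×2), 86 AZL copies (13/16/8/3/1 genomes at 1–5 copies),
16 AZL2 copies (14 ×1, 1 ×2) — a 49/43/8 mix with single-copy-dominant
YQL/AZL2 and multi-copy AZL. AZL placements are half inside clusters, a
quarter within 2 kb, a quarter 4–11 kb out, with the outside gaps adjusted
so the planted mean |distance| is exactly 2.3 kb; YQL and AZL2 gaps are
uniform ~20.5–29.5 kb (mean centered at 25 kb) with ≥ 6 intervening genes.
These sizes run end-to-end in a few seconds, so the default test suite and
the acceptance script use them directly. Assay data are drawn from the fit
models themselves at the measured parameter values (kcat 7.8/0.8/0.04
min⁻¹, growth IC50 5.9/3.9 μM, survival IC50 48.1/11.1 μM) with Gaussian
noise of 2% of each response's scale.

What this does *not* show: the genomes have no real nucleotide content, no
phylogenetic correlation between genomes, no annotation noise, and the
planted proteins diverge from the anchors by a homogeneous substitution
process. Passing the end-to-end recovery therefore demonstrates internal
correctness of the pipeline's logic and statistics, not robustness to the
curation problems of real assemblies (truncated genes, pseudogenes,
mixed annotation vocabularies), which the hit filters and the
minimum-length/keyword knobs only approximate.

## Known limitations

- The classifier assumes candidate proteins are alignable to one of the
  anchors; highly divergent homologs may fall to the regex fallback, which
  cannot distinguish chance trigrams from catalytic ones.
- The chi-square binning and the ANOVA zero-inclusion convention are
  explicit choices; results are comparable across runs of this package but
  not necessarily to other implementations without matching them.
- Neighborhood categories come from a keyword table, not a live GO
  annotation service; unknown/hypothetical products are a category of
  their own and typically dominate real genomes.
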