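# Methods

`epistitch` designs compact PhIP-Seq peptide libraries by displaying only
protein regions predicted to contain linear B-cell epitopes, and analyzes the
resulting screens at the level of antigen sources (phages). This note
documents the models, the tunable parameters, the synthetic data used to
validate the pipeline, and the numerical choices made where the design was
genuinely open.

## Composition features

A peptide is represented by 556 raw counts in five blocks: 20 single
amino-acid counts, 400 ordered adjacent amino-acid pair counts, 11 counts
over the DIAMOND reduced alphabet ({KREDQN}, {C}, {G}, {H}, {ILV}, {M}, {F},
{Y}, {W}, {P}, {STA}), 121 ordered adjacent DIAMOND-pair counts, and 4
side-chain class counts (positive {K,R,H}, negative {D,E}, polar uncharged
{S,T,N,Q,C,Y}, nonpolar {G,A,V,L,I,P,F,M,W}). Counts are not normalized by
length; for a 15-mer, single-letter blocks sum to 15 and pair blocks to 14.
Feature order is alphabetical within each block so serialized models are
stable. The assignment of C and Y to the polar class is the common textbook
convention but is configurable through `AlphabetScheme`, since conventions
differ. Positional encodings are deliberately absent: composition, not
position, is the signal this classifier exploits.

## Epitope classifier

A scikit-learn random forest (100 trees, impurity splits, all other
hyperparameters at their defaults, `random_state=42`) is trained on balanced
scan-library data. Positives are sub-peptides with a positive log
hit-fold-change in at least two cohort samples; negatives are sub-peptides
reactive in no sample, ranked by descending bead-only background counts
(summed across bead replicates, ties broken lexicographically) and taken to
match the positive count. Sub-peptides reactive in exactly one sample belong
to neither class. Train/test splitting assigns whole wildtype-parent groups
to the test side (seeded random group order, stopping at ceil(5% of
examples)), so near-duplicate sequences never straddle the split. Out-of-bag
probabilities summarize internal performance; peptides longer than the model
length are scored by the mean probability over all length-k windows.

## Library design

Three modes over clustered protein sets (the first sequence of each cluster
is its representative; phage memberships are unioned over members):

* **tile** — uniform 56-mers overlapping by 28 aa; when the length is not a
  multiple of 28, a full 56-mer anchored at the C-terminus is appended.
  Proteins shorter than 56 aa are skipped with a warning.
* **epitopes** — every 15-mer window with epitope probability > 0.5,
  deduplicated across clusters (membership union, maximum probability).
* **stitched** — per cluster, greedy selection of non-overlapping windows
  above the cutoff (highest probability first, ties to the smaller start);
  identical 15-mers across clusters are merged before position assignment.
  With m selected epitopes, n = floor(m/3) peptides are built and peptide j
  carries ranks (j, n+j, 2n+j) at positions 1-3, spreading top epitopes over
  first positions; leftover ranks are discarded, and clusters with fewer
  than three passing windows are dropped (and reported). Epitopes are joined
  with GGGGS linkers into 55-aa constructs.

The coverage statistic is epitope-bearing residues per representative-
proteome residue: 56 per tile, 15 per epitope peptide, 45 per stitched
peptide.

## Oligo encoding

Reverse translation samples codons from an E. coli K-12 usage table
restricted to codons with relative frequency >= 0.1, with weights
renormalized over the survivors. EcoRI (GAATTC) and HindIII (AAGCTT) sites —
the vector cloning sites — are removed by resampling synonymous codons
overlapping each site (bounded retries). Inserts are brought to 168 nt:
56-aa tiles fill it exactly, 55-aa stitched constructs gain one terminal
stop (56 codon positions), and 15-mers are padded with three stop codons
plus pseudo-random filler that avoids the forbidden sites and homopolymer
runs over 8 nt. Padding sits 3' of the coding region so the open reading
frame is intact. 16-nt PCR adapters yield 200-nt oligos. A second dialect
(120-nt inserts, a fixed linker-DNA pad, different 3' adapter) covers
scan-style sub-libraries in which each peptide is synthesized with and
without a terminal stop, doubling the count. Per-peptide random streams are
derived from the master seed and the peptide sequence, so identical
sequences encode identically and output does not depend on row order. When
padding cannot avoid a junction site (all stop codons begin with T, so a
coding region ending in AAGCT always forms a HindIII site), the coding
region is redrawn.

## Reactivity analysis

Hits are peptide-sample cells with count > 15, fold change > 5 and
p < 0.001, all strict. Fold changes and p-values normally come from an
external count model; the bundled `simple_fold_test` (depth-scaled mock
ratio with a pseudocount, Poisson upper tail) is a deliberately simple,
monotone stand-in so the pipeline runs end to end on raw counts.

The phage aggregate reactivity (PhAR) score for a phage with k peptides in a
sample standardizes the observed mean log2 fold-change against the empirical
mean and SD of 1,000 random k-peptide sets drawn without replacement from
the sub-library pool. The procedure iterates at most 7 times: phages scoring
above 1 leave the null pool (per sample by default; a global mode removes on
the across-sample mean score), and a peptide leaves only when every phage it
serves has been removed. Only phages with >= 25 peptides are scored. If the
null SD degenerates (constant pool), the score is defined as 0. Within one
sample and iteration, all phages share the same 1,000 seeded pool
permutations, from which each phage's size-k prefix sets are taken — draws
remain uniform without-replacement samples per phage, at a fraction of the
cost. Under a global null the per-cell scores are approximately standard
normal, so roughly 16% of cells exceed 1 by chance; phage-level summaries
therefore use the mean score across samples, for which exceedance above 1 is
rare under the null.

Alanine-scan epitope localization works on difference curves (wildtype minus
variant reactivity over the 54 triple-substitution positions). Curves with
exactly one contiguous disruption run (above half the wildtype reactivity)
are aligned on the run midpoint and averaged; the epitope width is the
smallest centered span holding 80% of the mean curve's positive mass,
growing greedily toward the heavier side. A width-w epitope probed with
3-mer substitutions produces a disruption run of w+2 positions, so the
reference value for recovered widths is that convolution profile passed
through the same width measure.

## Synthetic data

The generators emulate the data shapes the toolkit consumes, not their full
biological complexity.

* **Proteomes** — uniform background composition; a configurable fraction of
  proteins is shared verbatim across 2-4 phages (metagenomic phage databases
  are homology-heavy); epitope intervals (default width 14 aa, Poisson count
  at 1 per 100 aa) carry a multiplicative composition shift toward K (+2.0
  log units), S/T/A (+1.2) and other charged residues (+0.8) and away from
  hydrophobics (-1.2). The magnitudes make planted epitopes strongly
  separable by composition alone — the premise the classifier probes — since
  strict containment labelling puts near-complete epitope overlaps in the
  negative class and a weak shift would cap even a Bayes-optimal composition
  score near chance.
* **Scan libraries** — a k-mer is reactive in a sample iff it fully contains
  the planted epitope and the sample is seropositive (per-epitope Bernoulli,
  default 0.3); alanine variants lose reactivity iff their 3-mer intersects
  the epitope; reactive values sit near log-hfc 2.5 with configurable noise
  and a small spurious single-sample rate.
* **Counts** — gamma-Poisson around a per-peptide abundance at mean depth
  100 reads per peptide with overdispersion 0.3; mock-IP columns are pure
  background; enriched cells (peptide covers an epitope the sample is
  seropositive for; stitched peptides are enriched if any of their three
  sources is) gain a 16-fold mean shift. The conditional relative variance
  scales as 1/depth, which the tests exploit.

What passing tests show — and do not show: the classifier recovers a planted
composition signal (held-out AUC ~0.8 at n = 2,000, versus ~0.5 with
shuffled labels), not that real epitopes are this separable; real scan data
carry sequence-family structure, partial-containment reactivity and
display-efficiency artifacts the generator omits. The phage-level detection
benchmark (sensitivity and null exceedance of mean PhAR scores on a 50-phage
screen) is run without protein sharing because shared proteins carry planted
epitopes into other phages, which then genuinely react — "null phage" would
be ill-defined; homology bookkeeping is tested separately.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen to make the
statistics stable: 2,000 balanced classifier examples from ~3,000 wildtypes,
a 3,000-peptide pool with 50 phages and 20 samples for score calibration,
a 50-phage / 400-protein screen for detection, and 60 wildtypes for width
recovery. Ties in greedy selection break toward the smaller start
coordinate; equal-probability merged epitopes keep the maximum occurrence
probability; coordinates are 0-based half-open internally with 1-based
display columns in manifests. Known limitations: no phylogenetic structure
among phages, no read-level simulation, no affinity model, and the bundled
count test is not a dispersion-estimating replacement for a full
differential-count model.
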