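# epistitch

Epitope-prioritized PhIP-Seq peptide library design and phage-level
antibody-reactivity analysis.

Phage ImmunoPrecipitation Sequencing (PhIP-Seq) profiles a serum sample's
antibody repertoire against a synthetic peptide library displayed on phage.
Uniform tiling of a large proteome (56-aa peptides overlapping by 28) is
robust but wasteful: in practice ~90% of tiled peptides are never bound by
antibodies. For antigen spaces too large to tile — such as the gut phage
proteome — `epistitch` compresses the library by displaying only regions
predicted to contain linear B-cell epitopes, three per synthesized peptide.

The toolkit is aimed at groups designing PhIP-Seq libraries and analyzing
their screens, and covers four stages:

1. **Composition features** — each peptide becomes 556 raw counts: 20
   amino-acid counts, 400 ordered adjacent pair counts, 11 counts over the
   DIAMOND reduced alphabet (e.g. {S,T,A}, {K,R,E,D,Q,N}), 121 reduced-pair
   counts and 4 side-chain class counts.
2. **Epitope classifier** — a 100-tree random forest over those features,
   trained on scan-library reactivity (balanced positives/negatives, split
   by wildtype parent so near-duplicates never straddle train/test), scoring
   each 15-mer window of a protein with an epitope probability.
3. **Library design** — uniform tiling, individual predicted epitopes, or
   *stitching*: per protein cluster, the non-overlapping 15-mers with
   probability > 0.5 are greedily selected, deduplicated across clusters,
   and packed three per 55-aa construct with GGGGS linkers; with n
   constructs, peptide j carries the epitopes ranked j, n+j, 2n+j. Encoding
   produces synthesis-ready 200-nt oligos: codon-usage-weighted reverse
   translation (E. coli table, frequency >= 0.1), EcoRI/HindIII recoding,
   stop-codon/random padding to a 168-nt insert, and 16-nt PCR adapters.
4. **Reactivity analysis** — hit calling (count > 15, fold change > 5,
   p < 0.001), and the phage aggregate reactivity (PhAR) score: for a phage
   with k peptides, the observed mean log2 fold-change standardized against
   1,000 random k-peptide sets from the same sub-library,

       z(phage, sample) = (obs mean - null mean) / null SD,

   iterated up to 7 rounds with peptides of phages scoring > 1 removed from
   the null pool. Protein-recovery metrics and alanine-scan epitope
   localization round out the evaluation.

A seeded synthetic-data module (`epistitch.synth`) generates proteomes with
shared (homologous) proteins and composition-shifted planted epitopes,
scan-library reactivity tables, and overdispersed PhIP-Seq count matrices
with mock-IP background, so the whole pipeline is testable without any
external data. See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from epistitch import featurize_peptide
from epistitch.classifier import split_by_wildtype, train_model, roc_curve
from epistitch.design import design_library
from epistitch.encoding import encode_library
from epistitch.reactivity import call_hits, pharscore, simple_fold_test
from epistitch.synth import (SynthConfig, classifier_fixture,
                             generate_proteome, simulate_phipseq)

fv = featurize_peptide("KSTAKSTAKSTAKST")
print("features:", len(fv), "| K =", fv["K"], "| d_STA =", fv["d_STA"])

# train the epitope classifier on planted-epitope scan data
examples = classifier_fixture(2000, seed=7)
train_set, test_set = split_by_wildtype(examples, test_fraction=0.05, seed=7)
model = train_model(train_set, k=15, seed=42)
probs = model.predict_many([ex.seq for ex in test_set])
_, _, auc = roc_curve([ex.label for ex in test_set], probs)
print(f"classifier: OOB AUC = {model.oob_auc:.2f}, held-out AUC = {auc:.2f}")

# design: uniform tiling vs epitope stitching on a synthetic phage proteome
config = SynthConfig(seed=11, n_phages=10, proteins_per_phage=5,
                     protein_length_range=(150, 250), epitope_rate=2.0)
proteome = generate_proteome(config)
tiles = design_library(proteome.proteins, mode="tile")
stitched = design_library(proteome.proteins, scorer=model.predict_many,
                          mode="stitched")
print(f"tiling: {len(tiles.manifest)} peptides, coverage {tiles.coverage:.2f}")
print(f"stitched: {len(stitched.manifest)} peptides, coverage "
      f"{stitched.coverage:.2f}, compression "
      f"{len(stitched.manifest) / len(tiles.manifest):.2f}")
oligos = encode_library(stitched.manifest, seed=11)
print(f"oligos: {len(oligos)} x {len(oligos[0].full_oligo)} nt")
```

prints (output from this exact script):

```
features: 556 | K = 4 | d_STA = 11
classifier: OOB AUC = 0.76, held-out AUC = 0.82
tiling: 315 peptides, coverage 1.85
stitched: 56 peptides, coverage 0.26, compression 0.18
oligos: 56 x 200 nt
```

The classifier separates planted composition-shifted epitopes from
background well above chance; stitching represents the same 50 proteins with
about one fifth of the peptides (45 epitope-bearing residues per construct
instead of a full second tiling pass), and every synthesis oligo is exactly
200 nt. Scoring a simulated screen of the tiled library then recovers the
planted reactive phages:

```python
config = SynthConfig(seed=11, n_phages=10, proteins_per_phage=5,
                     protein_length_range=(150, 250), epitope_rate=2.0,
                     reactive_phage_fraction=0.3, seroprevalence=0.6,
                     cohort_size=12, shared_protein_fraction=0.0)
proteome = generate_proteome(config)
tiles = design_library(proteome.proteins, mode="tile")
sim = simulate_phipseq(tiles.manifest, proteome.epitopes, config)
log2fc, pvals = simple_fold_test(sim.counts, sim.mock)
hits = call_hits(sim.counts, log2fc, pvals)
scores = pharscore(log2fc, tiles.manifest[["peptide_id", "phage_ids"]], seed=11)
print(scores.mean_scores().sort_values(ascending=False).head(4).round(2))
```

```
phage_002    4.73
phage_000    4.47
phage_001    3.99
phage_009    0.57
```

The three planted phages (phage_000..002) score far above the removal
threshold of 1; unplanted phages stay near 0.

## Command line

The same stages are exposed as subcommands of `epistitch`:

```sh
epistitch featurize peptides.fasta -o features.tsv
epistitch train scan_reactivity.tsv --model-out model.joblib
epistitch predict model.joblib proteins.fasta -o probs.tsv
epistitch design proteins.fasta --membership map.tsv --mode stitched \
    --model model.joblib --manifest-out manifest.tsv --fasta-out peptides.fasta
epistitch encode manifest.tsv --fasta-out oligos.fasta --seed 1
epistitch score --counts counts.tsv --mock mock.tsv --phage-map map.tsv \
    --scores-out pharscores.tsv
epistitch simulate --seed 1 --out-prefix synth/run1
epistitch evaluate --truth-hits truth.tsv --test-hits test.tsv --out metrics.tsv
```

Inputs are plain FASTA and TSV: protein membership maps (`protein_id`,
`group_id`, semicolon-joined `phage_ids`), peptide-by-sample count /
log2-fold-change matrices, and `amino_acid, codon, fraction` codon tables.

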