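# Methods

`dtibench` builds and evaluates drug–target interaction (DTI) benchmark
datasets under controlled similarity leakage. This note records the models
and procedures it implements, the parameters that matter, the design choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Data model

A bioactivity dataset is a set of (compound, protein, activity) records with
activities in pChEMBL/pKd units (−log10 of a molar IC50/EC50/Ki/Kd).
Duplicate measurements of the same (compound, protein) pair are aggregated
by their **median** on load — the median is robust to outlying assays and
consistent with the median-centric conventions used elsewhere in the package
(median thresholds, median-corrected metrics). Protein similarity is a
binary relation given by cluster co-membership (UniRef50-style, roughly 50%
sequence identity); compound similarity is Tanimoto over 1024-bit ECFP4
fingerprints, binarized at ≥ 0.5 (inclusive, matching the convention for
the 0.3 compound-centric clustering threshold as well).

Sequence sanitization: sequences are uppercased; entries with more than 10%
non-canonical residues are rejected, otherwise the non-canonical residues
are dropped with a warning so descriptor computation sees only the 20-letter
alphabet.

## Splitting strategies

Three train/test splits of increasing difficulty:

1. **random** — uniform record-level assignment. Similar compounds and
   proteins appear on both sides; performance estimates are optimistic.
2. **dissimilar-compound** — connected components of the binarized
   compound-similarity graph are assigned whole to train or test, so no
   cross-fold compound pair reaches Tanimoto 0.5. Proteins may still be
   shared.
3. **fully-dissimilar** — a heterogeneous network with protein, compound
   nodes and typed edges (protein–protein similarity, compound–compound
   similarity, bioactivity) is split by whole connected components, so no
   similarity relation of either kind crosses folds, directly or
   transitively.

Real bioactivity networks form a giant component, so the fully-dissimilar
strategy prunes it iteratively: Louvain community detection (seeded,
resolution 1.0 by default) runs on the largest component; bioactivity edges
crossing communities are discarded; for compound-similarity edges crossing
communities, the endpoint compound with fewer bioactivity records is removed
(ties broken lexicographically — removing the less-connected node minimizes
data loss) and its records discarded; components are then recomputed. Rounds
repeat (cap 10) until some component assignment reaches the target test
fraction. Protein clusters are contracted to super-nodes **before**
community detection, so Louvain can never separate same-cluster proteins —
this removes, by construction, the case of a protein-similarity edge
crossing communities, which edge/node removal alone would not handle.

**Component-to-fold assignment.** Components must be assigned whole. The
package computes the achievable test-fold size closest to the target
(`test_fraction`, default 0.15, tolerance ±0.05) by subset-sum dynamic
programming over component record counts, and reconstructs the subset along
a seeded, largest-first component order. This is preferred over a pure
greedy pass because greedy assignment can overshoot badly when one
component is large; the DP finds the feasible split nearest the requested
ratio (and raises, reporting the achievable fractions, when none is within
tolerance after the pruning-round cap). Train and test are always both
nonempty when any valid assignment exists.

**Harmonization.** Records discarded by the fully-dissimilar strategy can
be propagated into the other splits so that all three strategies score
models on exactly the same record universe, making their results directly
comparable.

Louvain itself comes from networkx (`community.louvain_communities`),
seeded per pruning round for determinism.

## Dataset filters

`filter_censored` removes records whose activity equals the censoring floor
exactly (default pKd = 5, tolerance 1e−9): these encode "no activity at the
maximum assayed dose", not an affinity, and bias regression models toward
predicting the floor.

`filter_uninformative` removes every bioactivity of a compound or target
whose profile a model could memorize: (a) one-sided — all records on one
side of the activity threshold (active means activity **strictly greater**
than the threshold); (b) active:inactive ratio above 4 or below 1/4;
(c) sample standard deviation below 0.3 pChEMBL units. The threshold may be
a number or `"median"`, which resolves once to the median activity of the
input table. Passes are repeated — each pass evaluates all entities against
the same snapshot, then removes the union of flagged entities' records —
until no entity is flagged. A single pass is not sufficient: removing one
entity's records changes other entities' profiles, so a second application
of a single-pass filter would remove more. Iterating to the fixed point
makes the filter idempotent and guarantees the returned table actually
satisfies all three rules. Each removal is attributed in the
`FilterReport` to the first rule that fired (one-sided → ratio → low-sd).

`build_compound_centric` forms the small-scale classification datasets:
compounds within Tanimoto 0.3 of a center compound pool their bioactivities
per protein (median aggregation, since multiple cluster members may report
the same target), and a protein is labelled active when the aggregate
exceeds pChEMBL 5 (boundary value inactive). `augment_negatives` balances
classes by admitting candidate proteins whose maximum similarity to current
positives is below 50% and to current negatives — including negatives added
earlier in the same call — below 80%; candidate order is a seeded shuffle
because no natural order exists.

## Featurization

* **ECFP4**: radius-2 Morgan fingerprints hashed to 1024 bits via RDKit.
  Bit assignment is toolkit-specific, but every similarity threshold in the
  package operates on Tanimoto values, which are stable under any consistent
  mapping; precomputed fingerprint tables are accepted everywhere.
  The all-zero/all-zero Tanimoto is defined as 0.0 (the formula is 0/0;
  "dissimilar" is the conservative choice).
* **dde** (400-d): dipeptide composition standardized against the mean and
  variance expected from standard-genetic-code codon usage,
  DDE_i = (Dc_i − Tm_i)/√Tv_i with Tm_i = (C_a/61)(C_b/61) over the 61
  sense codons and Tv_i = Tm_i(1 − Tm_i)/(N − 1).
* **taap** (10-d): per-property sums of residue values over the sequence.
  The ten scales are embedded with their AAindex-style accessions
  (CIDH920105 normalized average hydrophobicity, BHAR880101 average
  flexibility, CHAM820101 polarizability, CHAM820102 free energy of
  solution in water, CHOC760101 residue accessible surface area in
  tripeptide, BIGC670101 residue volume, CHAM810101 steric parameter,
  DAYM780201 relative mutability, HOPT810101 hydrophilicity, KRIW790103
  side-chain volume). These accessions are this package's documented
  choices for the named properties and are frozen by golden tests.
* **spmap** (|centers|-d): k-mer (k = 5) distributions over cluster centers
  fitted by greedy leader clustering — k-mers visited in descending
  frequency (ties lexicographic) become new centers when their best
  ungapped BLOSUM62 score against every existing center is below the score
  threshold (default 8.0), optionally capped. Transformation assigns each
  k-mer to its best-scoring center (ties to the lexicographically smallest
  center) and normalizes counts to sum to 1. Greedy leader clustering is
  used for determinism and O(n·centers) cost; the resulting dimension is
  dataset-dependent. BLOSUM62 is loaded from biopython.
* **random200 / random compound fingerprints**: the noise baselines — 200
  i.i.d. U(0,1) values per protein, and Bernoulli(0.1) bit vectors per
  compound (matching the ~10% bit density of real ECFP4 fingerprints).
  Models built on these quantify how much real feature information a
  pipeline exploits.

Descriptors requiring external resources (PSSM profiles, Pfam domains,
learned embeddings) are consumed as precomputed vector tables through
`read_vector_table`; precomputed protein–protein similarity matrices stand
in for alignment-based similarity.

## Models

* **PCM regression**: random forest, 100 trees, one third of the features
  considered per split, seeded; input is the concatenation of a protein
  feature vector and a compound fingerprint per record
  (`protein_only`/`compound_only` modes cover the baselines that drop one
  side).
* **Target feature-based classification**: nested cross-validation with a
  stratified 5-fold outer loop and a (up to) 10-fold inner grid search.
  RF grid: 200 trees, √p features; SVM-RBF grid: C ∈ {1, 10, 100},
  γ ∈ {0.001, 0.01, 0.1, 1}. The inner selection metric is MCC (robust to
  the class imbalance these datasets can retain), outer folds are
  stratified to preserve the engineered class balance, and features are
  standardized on each training fold for the SVM only (RF is
  scale-invariant).

## Metrics

Standard confusion-matrix scores (accuracy, precision, recall, F1, MCC;
zero-denominator cases return 0.0 by convention), RMSE, and tie-safe
Spearman rank correlation (Pearson of average ranks; equal to the classic
1 − 6ΣD²/(n(n²−1)) form when there are no ties). Binarization labels a
value active iff it is **strictly above** the cutoff.

Corrected variants address regression models whose prediction distribution
is systematically offset (common under hard splits, where models regress
toward the training mean): `median_shift` translates predictions so their
median equals the true median — rank-preserving, hence Spearman-invariant —
and `median_corrected_rmse` / `median_corrected_mcc` score the shifted
predictions. Note RMSE after the shift is not necessarily smaller; only the
median equality is guaranteed.

`multiclass_mcc` bins true and predicted values into six fixed pChEMBL
classes — (−∞, 5.0), [5.0, 5.5), [5.5, 6.0), [6.0, 6.5), [6.5, 7.0),
[7.0, ∞); half-open, lower-inclusive — and averages the six one-vs-rest
binary MCCs (degenerate classes contribute 0.0). The single multi-category
R_k coefficient is available behind a flag (`macro=False`) as an
alternative aggregation.

## Diagnostics

* **Applicability domain**: per test item, the mean similarity of its k = 5
  most similar training items (Tanimoto for compounds; precomputed matrices
  for proteins, since alignment is out of scope), joined with absolute
  errors to estimate where predictions are reliable.
* **Distribution shift**: per-feature two-sample tests between train and
  test — Kolmogorov–Smirnov (asymptotic p-values, α = 0.01) for continuous
  features, chi-square without continuity correction (α = 0.001, stricter
  because the test is sensitive at fingerprint sample sizes) for binary
  bits; bits constant across both folds are skipped and reported. Under a
  random split the expected significant count is ≈ α × dimension.
* **Prediction agreement**: percent of records two models place in the same
  6-bin activity class, assembled into a symmetric matrix with a
  100-percent diagonal and ordered by average-linkage clustering on
  (100 − agreement) distances.
* **2-D embedding**: a thin seeded wrapper over scikit-learn t-SNE
  (perplexity 30 by default) for visual exploration of feature spaces.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline needs without
any download:

* **Compounds**: each family has a template fingerprint (bits set with
  probability 0.1 over 1024 bits); members flip each bit independently with
  probability 0.01. Within-family Tanimoto is high (≈ 0.8–0.9), between-
  family low (≈ 0.05–0.1), giving a clean similarity separation.
* **Proteins**: each cluster has a random ancestor sequence (200 residues);
  members apply i.i.d. point substitutions at rate 0.05. The cluster map is
  the ground-truth similarity relation.
* **Bioactivities**: activity = 6.5 + family effect + cluster effect +
  (family × cluster) interaction + N(0, 0.3), with effects drawn once per
  level from centered Gaussians (SDs 0.8 / 0.8 / 0.5 pChEMBL units).
  Activities below the censoring floor (5.0) are recorded exactly at the
  floor, reproducing the Davis-style censoring artifact. The interaction
  term is what makes the fully-dissimilar split genuinely hard: for unseen
  families *and* clusters, no training information constrains the
  interaction.
* **Assay bias**: the probability that a pair is measured is `density`
  (0.25) on average but varies by (family, cluster) cell via
  Gamma(0.15, 1/0.15) weights (mean 1). This mimics how chemical series
  are assayed against related target panels and gives the bioactivity
  network the modular structure real datasets have. With uniform
  measurement the network is a near-expander and community pruning must
  discard almost all records to disconnect it, leaving folds too small to
  score; with the bias, the fully-dissimilar split typically retains
  35–50% of records. Setting `assay_bias = 0` restores uniform
  measurement.
* **Scale**: defaults are 30 compound families × 8 members and 15 protein
  clusters × 4 members (≈ 2000 measured records), chosen so the dissimilar
  test folds span enough (family, cluster) cells for stable statistics
  while a full 5-seed, 3-split benchmark finishes in about a minute on one
  CPU.

What the synthetic benchmark shows: the split-difficulty ordering (held-out
Spearman: random ≈ 0.94 ≫ dissimilar-compound ≈ 0.2–0.4 > fully-dissimilar
≈ 0), the collapse of all-noise baselines to |Spearman| < 0.1, zero
similarity leakage across folds, and the exactness of metrics and filters
against brute-force oracles. What it does not show: real chemistry (the
fingerprints have no valence structure and no SMILES), realistic sequence
evolution (i.i.d. substitutions only), assay noise heterogeneity, or the
absolute performance levels attainable on curated ChEMBL-scale data — the
synthetic effect structure is far simpler than real structure–activity
landscapes. Single-seed scores on the hard splits are noisy because a
dissimilar test fold spans few independent (family, cluster) cells; all
stochastic comparisons are therefore made on means over 5 seeds.

## Numerical conventions

* Inclusive (≥) similarity thresholds everywhere.
* Degenerate metric denominators → 0.0; all-zero Tanimoto → 0.0.
* Exact floor equality (|x − floor| ≤ 1e−9) for censoring removal.
* Seeded randomness throughout: the generator derives independent streams
  per stage from its seed; Louvain is seeded per pruning round; component
  assignment, candidate shuffles and model fits take explicit seeds.
  Identical configurations reproduce outputs bit-for-bit.

## Known limitations

* The fully-dissimilar split can discard a large share of records — that is
  inherent to disconnecting a similarity network, not an implementation
  artifact — and the achieved test fraction can deviate from the request
  within the stated tolerance.
* Greedy leader clustering for spmap depends on k-mer frequency order;
  different reference sets give different (deterministic) center sets.
* The taap scales are transcriptions of published per-residue property
  tables; their accession identifiers document intent, and tests freeze the
  embedded values rather than asserting agreement with any external
  database copy.
* `filter_uninformative` evaluates compounds and targets jointly to a fixed
  point; on pathological inputs (many mutually dependent marginal entities)
  it can empty the table, which is reported rather than prevented.
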