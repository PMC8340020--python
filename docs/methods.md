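# Methods

## Data model and preprocessing

Input is AIRR Rearrangement TSV (MiAIRR columns `sequence_id`, `junction`,
`junction_aa`, `v_call`, `j_call`, `duplicate_count`, plus extension columns
`subject_id` and `cohort_label`), or FASTA with `key=value` metadata on the
description line. Nucleotide junctions are translated in frame 1 with the
standard genetic code (Biopython); rows whose translation contains a stop
(`*`, non-productive rearrangement) or an ambiguous residue (`X`) are
dropped and tallied in an ingest report, because the embedding vocabulary is
defined over the 20 standard residues only.

CDR3 junctions begin and end with nearly constant residues (the
cysteine-anchored head, the tryptophan/phenylalanine-anchored tail). These
carry no discriminative information and are removed before tokenization by a
`TrimConfig` (default head = 2, tail = 3). Descriptions of the conserved
flanks vary — some views of the heavy-chain logo suggest ~3 leading and ~4
trailing residues — so the trim is an explicit, everywhere-visible parameter,
and the trim used at training time is serialized inside every saved model so
that applying a model always trims exactly the way its training did.
Gene-family labels come from the first listed call (`IGHV3-23*01,...` →
family `IGHV3`, gene `IGHV3-23`); taking the first call is deterministic and
matches common practice for multi-assignments.

## Embedding

Tokenization is non-overlapping from offset 0: a trimmed sequence of length
L yields ⌊L/n⌋ n-grams and discards the remainder. The training corpus
contains exactly one tokenized line per sequence, in input order; shifted
variants enter only at embedding time.

The embedding is skip-gram with negative sampling, implemented directly in
numpy (initialization U(−0.5, 0.5)/d on the input layer, zeros on the output
layer; unigram^0.75 noise distribution; linearly decaying learning rate
0.025 → 1e-4; mini-batched vectorized updates). Defaults: n = 3, d = 100,
window 25 (larger than any tokenized CDR3, so the whole sequence is
context), min_count = 2, 5 epochs, 5 negatives. Epochs and negative-sampling
rate are conventional word2vec settings; they are configurable. Training is
deterministic given the seed (single worker, one numpy RNG).

A sequence is embedded by the shift-average rule: the n shifted variants
(drop 0 … n−1 leading residues) are each tokenized, all token vectors are
summed, and the sum is divided by the total token count over all variants
(variants too short to yield a token contribute to neither numerator nor
denominator). For the 12-residue example `ASLEMATIEDAA` with n = 3 the
variants have 4 + 3 + 3 = 10 tokens, so the denominator is 10; a length-n
sequence reduces to its own token vector. Any out-of-vocabulary token makes
the whole sequence non-embeddable — a distinct signal, handled by
skip-and-count at the pipeline level. With min_count = 2 the fraction of
non-embeddable sequences falls as the corpus grows (≈12 % at a 40 k-sequence
corpus of the default synthetic composition; real deep-sequenced corpora
leave well under a few percent uncovered).

Persistence uses the text word-vector format (`"<vocab> <dim>"` header, one
`token v1 … vd` line each, full `repr` precision) plus a JSON sidecar with
hyper-parameters, trim and token counts; loading validates header/row
consistency.

## Word-level validation

All vocabulary 3-grams are embedded and reduced to 2-D with t-SNE
(perplexity min(30, (m−1)/3), PCA initialization, 1000 iterations, seeded).
Properties of each 3-gram are computed directly from scale tables shipped as
data files: mean Kyte–Doolittle hydropathy (gravy), mean Zimmerman
bulkiness, mean Grantham polarity, the Ikai aliphatic index per residue
((A + 2.9 V + 3.9 (I+L))/L), Henderson–Hasselbalch net charge at pH 7.4 with
EMBOSS side-chain pKs (termini excluded) per residue, and acidic (D,E),
basic (R,H,K) and aromatic (F,W,Y,H) content fractions — histidine counts as
both basic and aromatic. "Normalized" is read as per-residue throughout.

Clustering is k-means at depth two (k1 top-level clusters, each split into
k2; Lloyd's algorithm, 10 restarts, Euclidean distance, seeded). 20 × 20 on
the 8000-gram set gives 400 clusters of mean size 20; a 6 × 30 alternative
gives 180. An optional silhouette-score grid search selects (k1, k2) when no
prior choice exists. A top-level cluster smaller than k2 keeps fewer
sub-clusters and the honest total is reported with a warning.

Homogeneity is quantified two ways. (1) The pooled within-cluster variance
s_p² = Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1) (Bessel-corrected weights; singleton clusters
excluded from both sums) is compared with the overall sample variance; the
ratio general/pooled exceeds 1 when the property is more homogeneous inside
clusters. (2) Within-cluster absolute property differences are compared with
all-pairs differences by a one-sided Mann–Whitney U test (alternative:
within < all).

Moran's I uses binary distance-band weights exactly as defined: w_ij = 1 iff
0 < ‖p_i − p_j‖ < d_x (strict inequality, zero diagonal, no row
standardization), I = (n/S0)·(zᵀWz)/(zᵀz) on the centered attribute.
Constant attributes and empty weight matrices raise distinct errors; a
profile over a distance list skips bands with S0 = 0 with a warning. The
implementation is row-chunked (O(chunk·n) memory) and is verified in the
tests against an O(n²) double-loop oracle to 1e-10.

## Sequence-level validation

Embedded, trimmed CDR3s are labeled with the IGHV family of the adjacent
germline segment (default families IGHV1/IGHV3/IGHV4, the most common
heavy-chain families), down-sampled to the same count per family without
replacement, PCA-reduced (fit on the training split only — the safe,
leak-free choice), split 75/25 stratified, and scored by macro-averaged F1
(classes are balanced by construction, so macro ≈ micro) for a decision
tree, a random forest (both at library defaults, deliberately unoptimized)
and 3-NN. The split indices are returned as a manifest so the held-out
evaluation is auditable. A dimension sweep repeats the evaluation across PCA
dimensionalities on the same split.

## Repertoire-level classification

Embedded sequences are grouped by (V gene, J gene, CDR3 length) — the
conventional approximation to clonal partitions. Within each group the
per-dimension standard deviations over the group's vectors form the "std
vector", and the complete-linkage dendrogram (full 100-dimensional Euclidean
distances, no reduction) is cut at t = 0.65·‖std vector‖₂, which guarantees
a maximum intra-cluster pairwise distance of t. A group of identical vectors
has t = 0 and collapses to one cluster; singleton groups are singleton
clusters. QC removes clusters with fewer than 10 sequences or with strictly
more than 90 % of members from one subject.

Feature extraction: for each cluster and cohort, the sum over that cohort's
subjects of the squared relative frequency (subject's count in the cluster /
subject's total retained sequences). A cluster is selected when the cohort
sums differ by strictly more than a margin, in a configurable direction
(default: either direction), and only if it spans more than one subject and
contains at least one sequence observed in more than one raw read
(duplicate_count > 1; when duplicate counts are absent they default to 1,
which disables that sub-filter with a warning). The prose this rule derives
from is ambiguous between "sum of squared frequencies" and "square of summed
frequencies"; the implemented reading follows the sentence order (square,
then sum within cohort).

The margin is an absolute number and therefore scale-dependent: the
published value 0.5 belongs to deeply sequenced cohorts where single clones
can dominate a repertoire. At the synthetic scale used here (2000 sequences
per subject) per-subject cluster frequencies are O(10⁻³) and every cohort
sum difference is ≪ 0.5, so the synthetic studies run with margin = 0 (any
strict excess) and leave the real selection pressure to the next step. The
feature table holds squared per-subject counts for the selected clusters; a
random forest ranks columns by impurity importance and the top 18 are kept;
an L2 logistic regression (C = 0.003) makes the final call.

Evaluation is repeated cross-validation: each repeat holds out one randomly
drawn subject per cohort, and **all** label-dependent steps — cluster
selection, random-forest ranking, logistic fit — are redone on the training
subjects only, so no information about the held-out pair leaks into feature
choice. Accuracy is correct predictions over 2·repeats. The random-label
control permutes the training labels per repeat while keeping held-out truth
fixed. A fold whose training data selects no cluster falls back to a
constant prediction (first cohort), which scores exactly 0.5 on the balanced
held-out pair.

## Synthetic data

The generator emulates per-subject heavy-chain repertoires: junctions
`"CA" + core + "DYW"` (so the default 2/3 trim strips exactly the conserved
flanks), lengths 9–24 with mode 15 (shifted binomial pmf), V genes drawn
within families IGHV1/IGHV3/IGHV4 at 0.30/0.45/0.25 (IGHV3 most frequent,
as in human repertoires), J genes skewed toward IGHJ4/IGHJ6, duplicate
counts geometric (p = 0.5). Core residues come from a per-family
exponentially tilted distribution p_f(a) ∝ exp(β·t_f(a)) with a fixed
standard-normal preference vector t_f per family (keyed by CRC32 of the
family name, stable across runs); β = 0 severs all family–composition
association. Background diversity is organized into clones (zipf-distributed
sizes, capped at 20; members are point-substitution variants of a parent,
Poisson(0.8) substitutions). Planted cohort structure: five shared
V/J/length motif archetypes whose members (one substitution from the motif)
appear in every subject at baseline frequency 0.002 and in cohort-A subjects
at an excess δ (default 0.005); δ = 0 removes the cohort signal. Defaults
are 10 subjects per cohort × 2000 sequences, matching the two-cohort design
the repertoire classifier targets. The generator is a pure function of its
config — identical seeds give byte-identical TSVs — and writes a
ground-truth manifest (archetypes, per-subject planted counts, family
distributions).

### Study scales

- **Repertoire study**: generator defaults (20 subjects, 40 k sequences),
  20 CV repeats, margin 0 (see above), plus the shuffled-label control on
  the same clusters and a δ = 0 replicate.
- **V-family study**: 5 subjects per cohort × 2000 sequences for vocabulary
  coverage, **clone-free** (effectively all clone sizes 1): clonal
  near-duplicates that straddle a random train/test split let neighbor
  classifiers memorize the family label through sequence identity rather
  than composition, which is a leakage artifact of the evaluation, not a
  property of the embedding. 1000 balanced samples per family, 10
  balance/split seeds per bias setting.

### What the synthetic studies do and do not show

They demonstrate that the implementation is correct and that each pipeline
stage recovers exactly the structure it targets: composition bias is
learnable at the sequence level if and only if β > 0, and planted
cohort-enriched clusters drive repertoire classification if and only if
δ > 0, with shuffled-label controls at chance. They do not demonstrate
performance on real repertoires: real V(D)J recombination statistics
(IGoR-style generation probabilities, somatic hypermutation targeting,
allele-level usage), sequencing error, and clinical heterogeneity are not
modeled, and published F1/accuracy figures on patient cohorts depend on
those data sets.

## Numerical choices and degenerate inputs

- Strict inequalities throughout where the rules state them: Moran weights
  (0 < d < d_x), QC dominance (> 90 %), selection margin (> margin).
- Pooled variance on all-singleton clusterings, Moran's I on constant
  attributes or empty weight matrices, embedding of too-short sequences, and
  training on an empty/fully-filtered corpus raise typed errors rather than
  returning NaN.
- k-means restarts: 10; t-SNE seeded with PCA initialization; all
  stochastic steps accept explicit seeds and the CLI records them in a
  manifest sufficient to replay any run.

## Known limitations

- The skip-gram trainer is a compact vectorized implementation tuned for
  corpora up to a few hundred thousand short sentences; very large corpora
  would want asynchronous (hogwild) updates in a compiled kernel.
- Only two-cohort classification is implemented at the repertoire level;
  the selection margin is absolute rather than scale-free by design
  fidelity, so users must set it to match their sequencing depth.
- Overlapping tokenization is accepted in configuration but deliberately
  not exercised; non-overlapping splitting is used throughout.
- Nucleotide-level embedding models are out of scope.
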