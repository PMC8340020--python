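# cdr3vec

Word-embedding analysis of adaptive immune receptor repertoires (AIRR-seq).
`cdr3vec` treats the hypervariable CDR3 region of a B/T-cell receptor as a
*sentence* whose *words* are fixed-length amino-acid n-grams (default n = 3),
trains a skip-gram (word2vec-style) embedding on a corpus of CDR3s, and uses
the resulting vector space at three levels:

- **word level** — do embedded 3-grams cluster by their biophysicochemical
  properties (hydropathy, bulkiness, polarity, charge, ...)? Quantified by
  pooled-variance ratios, Mann–Whitney distance tests and Moran's I spatial
  autocorrelation in the t-SNE plane.
- **sequence level** — can the IGHV gene family of the *adjacent* germline
  segment be predicted from the embedded, flank-trimmed CDR3 alone
  (decision tree / random forest / 3-NN on PCA-reduced vectors, macro-F1)?
- **repertoire level** — can whole repertoires be stratified into clinical
  cohorts? Embedded CDR3s are grouped by V gene / J gene / CDR3 length,
  complete-linkage clustered at a threshold of 0.65·‖std vector‖, QC-filtered,
  turned into a subjects × clusters table of squared counts, reduced to the
  18 most informative features by a random forest, and classified with an
  L2 logistic regression (C = 0.003) under repeated
  leave-one-subject-per-cohort-out cross-validation.

It is aimed at computational immunologists who have annotated AIRR
Rearrangement TSV files (MiAIRR columns) and want a low-dimensional,
information-preserving numeric representation of their sequences. A
synthetic-repertoire generator with controllable family-composition bias and
planted cohort-enriched clusters makes every stage testable without any
sequencing data.

## The model

Given a corpus of trimmed CDR3 amino-acid sequences split into
non-overlapping n-grams, skip-gram training with negative sampling learns a
vector v(w) ∈ ℝ^d (d = 100) for every n-gram w occurring at least twice. A
whole sequence S is embedded by the shift-average rule: build the n shifted
variants of S (drop 0, 1, …, n−1 leading residues), tokenize each
non-overlappingly, and set

    Vec(S) = ( Σ_variants Σ_tokens v(token) ) / (total token count).

A sequence of exactly n residues therefore embeds to exactly its token's
vector; a sequence containing any out-of-vocabulary n-gram is not embeddable
and is skipped with a report.

## Worked example

The whole pipeline runs from the command line on simulated data:

```bash
cdr3vec simulate --out sim --seed 7 --subjects-per-cohort 6 --sequences-per-subject 2000
cdr3vec build-corpus --input sim/repertoires.tsv --out corpus.txt
cdr3vec train --corpus corpus.txt --out model.txt --seed 7
cdr3vec repertoire-classify --model model.txt --input sim/repertoires.tsv \
    --out rep --repeats 20 --margin 0 --seed 7
cdr3vec repertoire-classify --model model.txt --input sim/repertoires.tsv \
    --out rep-shuffled --repeats 20 --margin 0 --seed 7 --shuffle-labels
```

which logs:

```
wrote 24000 records to sim/repertoires.tsv
corpus: 24000 sentences, 72136 tokens, 6745 distinct, 0 skipped (0 rows dropped at ingest)
trained vocabulary of 5597 tokens, saved to model.txt
accuracy over 20 repeats: 0.950 (clusters kept 486, removed {'size': 3021, 'dominance': 27})
accuracy over 20 repeats: 0.400 (clusters kept 486, removed {'size': 3021, 'dominance': 27})
```

Reading: 24 000 synthetic CDR3 junctions from 12 subjects (6 per cohort)
yield a 72 k-token corpus covering 6 745 of the 8 000 possible 3-grams, of
which 5 597 clear the minimum-frequency filter. After grouping, linkage
clustering and QC (clusters under 10 sequences or >90 % from one subject are
dropped), 486 clusters feed the classifier: held-out subjects are assigned
to the correct cohort 95 % of the time, while the label-shuffled control sits
at chance (0.40) — the cohort signal is real, not overfitting. Each run also
writes a `manifest.json` from which it can be replayed exactly.

The same model serves the other two levels via `cdr3vec word-analysis`
(per-gram 2-D coordinates, cluster homogeneity table, Moran profile) and
`cdr3vec vfamily-classify` (per-classifier macro-F1 with an auditable split
manifest). Library users can do the same through the scikit-learn-style
estimators `CDR3Embedder`, `TwoLevelKMeans`, `VFamilyClassifier` and
`RepertoireClassifier`.

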