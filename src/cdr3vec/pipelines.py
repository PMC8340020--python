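"""End-to-end study runners on synthetic repertoires.

These wire the full method together — simulate, trim, train the embedding,
embed, cluster, classify — and are what the higher-level evaluations (and the
reproduction script) call.  Study scales:

- Repertoire study: generator defaults (10 subjects per cohort, 2000
  sequences each), margin 0 at this repertoire scale (per-subject cluster
  frequencies are O(1e-3), so the absolute margin of 0.5 used for
  deep-sequenced cohorts would select nothing; the random-forest elimination
  step carries the selection burden).
- V-family study: clone-free repertoires (each sequence drawn independently),
  because clonal near-duplicates straddling a random train/test split leak
  the family label through memorization rather than composition; 5 subjects
  per cohort x 2000 sequences gives the vocabulary coverage the embedding
  needs, and 1000 balanced samples per family feed the classifiers.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ttest_ind

from .airr_io import TrimConfig, get_v_family, trim_cdr3
from .embedding import CDR3Embedder, embed_sequences
from .repertoire import classify_repertoires_cv, cluster_all_groups, qc_filter_clusters
from .seqlevel import SeqLevelConfig, balance_by_family, train_eval_family_classifier
from .synthetic import SyntheticConfig, generate_repertoires


def _embed_synthetic(cfg: SyntheticConfig, model_seed: int):
    """Generate per cfg, train an embedding on the trimmed corpus, embed it."""
    records, _ = generate_repertoires(cfg)
    trim = TrimConfig()
    seqs = [trim_cdr3(r.cdr3_aa, trim) for r in records]
    model = CDR3Embedder(seed=model_seed, trim=trim).fit(seqs)
    mat, kept, _ = embed_sequences(model, seqs)
    return [records[i] for i in kept], mat, model


def repertoire_study(
    delta: float = 0.005,
    seed: int = 0,
    repeats: int = 20,
    margin: float = 0.0,
    n_subjects_per_cohort: int = 10,
    n_sequences_per_subject: int = 2000,
) -> dict:
    """Two-cohort classification with planted effect ``delta`` plus the
    label-shuffled control on the same clusters.

    Returns accuracies, per-repeat accuracy lists, and the two-tailed Welch
    t-test p-value comparing per-repeat accuracy against the shuffled run.
    """
    cfg = SyntheticConfig(
        n_subjects_per_cohort=n_subjects_per_cohort,
        n_sequences_per_subject=n_sequences_per_subject,
        planted_effect=delta,
        seed=seed,
    )
    records, mat, _ = _embed_synthetic(cfg, model_seed=seed)
    clusters = cluster_all_groups(records, mat)
    surviving, removed = qc_filter_clusters(clusters)
    labels = {r.subject_id: r.cohort_label for r in records}
    totals: dict[str, int] = {}
    for r in records:
        totals[r.subject_id] = totals.get(r.subject_id, 0) + 1
    real = classify_repertoires_cv(
        surviving, labels, totals, repeats=repeats, margin=margin, seed=seed + 1
    )
    control = classify_repertoires_cv(
        surviving, labels, totals, repeats=repeats, margin=margin, seed=seed + 1,
        shuffle_labels=True,
    )
    per_repeat = [o["n_correct"] / 2 for o in real["outcomes"]]
    per_repeat_control = [o["n_correct"] / 2 for o in control["outcomes"]]
    if np.var(per_repeat) + np.var(per_repeat_control) > 0:
        _, p = ttest_ind(per_repeat, per_repeat_control, equal_var=False)
    else:  # degenerate: both runs constant
        p = 0.0 if per_repeat[0] != per_repeat_control[0] else 1.0
    return {
        "accuracy": real["accuracy"],
        "shuffled_accuracy": control["accuracy"],
        "per_repeat": per_repeat,
        "per_repeat_shuffled": per_repeat_control,
        "welch_p": float(p),
        "n_clusters_kept": len(surviving),
        "clusters_removed": removed,
    }


def vfamily_study(
    beta: float = 1.0,
    seed: int = 0,
    n_seeds: int = 10,
    per_family_n: int = 1000,
) -> dict:
    """IGHV-family classification over ``n_seeds`` balance/split seeds.

    One embedding is trained per composition-bias setting; the seeds vary the
    balanced sampling and the train/test split.  Mean F1 is averaged over the
    three classifiers.
    """
    cfg = SyntheticConfig(
        n_subjects_per_cohort=5,
        n_sequences_per_subject=2000,
        family_composition_bias=beta,
        clone_size_exponent=50.0,  # clone-free: independent sequences
        seed=seed,
    )
    records, mat, model = _embed_synthetic(cfg, model_seed=seed)
    fams = np.array([get_v_family(r.v_call) for r in records])
    f1s = []
    for s in range(n_seeds):
        c = SeqLevelConfig(per_family_n=per_family_n, seed=seed + s)
        Xb, yb = balance_by_family(mat, fams, c)
        res = train_eval_family_classifier(Xb, yb, c)
        f1s.append(float(np.mean(list(res["scores"].values()))))
    f1s_arr = np.asarray(f1s)
    return {
        "f1_per_seed": f1s,
        "mean_f1": float(f1s_arr.mean()),
        "std_f1": float(f1s_arr.std(ddof=1)),
        "chance": 1 / 3,
    }
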