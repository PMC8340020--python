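"""Synthetic AIRR-seq repertoires with controllable statistical structure.

The generator emulates the shape of per-subject BCR heavy-chain repertoires:
CDR3 junctions with conserved flanks (a "CA" head and a "DYW" tail, so the
default head=2/tail=3 trim is meaningful), V/J gene calls drawn across IGHV
families, within-subject clonal expansions (point-substitution variants of a
parent junction, power-law clone sizes), and — for the repertoire-level
classifier — planted clusters: shared V/J/length junction motifs inserted
into every subject at a baseline frequency and into cohort-A subjects at a
configurable excess frequency delta.

Family-composition bias: each family has a fixed residue-preference vector
(deterministic per family name) and core residues are drawn from an
exponentially tilted distribution p_f(a) proportional to exp(beta * t_f(a)).
beta = 0 removes all association between family label and CDR3 composition;
delta = 0 removes all cohort signal.  Both null controls are used by the
test-suite.

The generator is a pure function of its config: the same seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import binom

from .airr_io import AA20, RearrangementRecord, write_rearrangements
from .errors import ConfigError

#: one fixed codon per residue, for nucleotide junctions that translate back
#: to the amino-acid junction exactly
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_GENES = {
    "IGHV1": ("IGHV1-2", "IGHV1-8", "IGHV1-18", "IGHV1-69"),
    "IGHV3": ("IGHV3-7", "IGHV3-9", "IGHV3-21", "IGHV3-23", "IGHV3-30", "IGHV3-48"),
    "IGHV4": ("IGHV4-4", "IGHV4-34", "IGHV4-39", "IGHV4-59"),
    "IGHV5": ("IGHV5-51",),
    "IGHV6": ("IGHV6-1",),
}
_J_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")
_J_PROBS = (0.03, 0.05, 0.10, 0.42, 0.12, 0.28)

_HEAD = "CA"   # conserved junction head (trimmed by head=2)
_TAIL = "DYW"  # conserved junction tail ending in tryptophan (trimmed by tail=3)


def _default_lengths() -> dict[int, float]:
    """Junction lengths 9-24 with mode 15 (shifted binomial pmf)."""
    ks = np.arange(16)
    pmf = binom.pmf(ks, 15, 0.4)
    pmf = pmf / pmf.sum()
    return {int(9 + k): float(p) for k, p in zip(ks, pmf)}


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects_per_cohort: int = 10
    n_sequences_per_subject: int = 2000
    cohort_labels: tuple[str, str] = ("SC", "CI")
    v_families: Mapping[str, float] = field(
        default_factory=lambda: {"IGHV1": 0.30, "IGHV3": 0.45, "IGHV4": 0.25}
    )
    family_composition_bias: float = 1.0  # beta
    cdr3_length_distribution: Mapping[int, float] = field(default_factory=_default_lengths)
    n_planted_clusters: int = 5
    planted_effect: float = 0.005  # delta: excess planted frequency in cohort A
    planted_base_freq: float = 0.002
    clone_size_exponent: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_effect < 0 or self.family_composition_bias < 0:
            raise ValueError("delta and beta must be >= 0")
        if abs(sum(self.v_families.values()) - 1.0) > 1e-9:
            raise ValueError("v_families probabilities must sum to 1")
        if abs(sum(self.cdr3_length_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("cdr3_length_distribution must sum to 1")
        planted_load = self.n_planted_clusters * (self.planted_base_freq + self.planted_effect)
        if planted_load >= 0.5:
            raise ConfigError(
                f"planted clusters would occupy {planted_load:.0%} of each repertoire"
            )


def family_aa_distribution(family: str, beta: float) -> np.ndarray:
    """Exponentially tilted residue distribution for one family.

    The 20-long preference vector t_f is standard normal, drawn from an RNG
    keyed by CRC32 of the family name, so it is stable across runs and
    independent of the simulation seed; p_f(a) ~ exp(beta * t_f(a)).
    """
    key = zlib.crc32(f"tilt:{family}".encode())
    tilt = np.random.default_rng(key).standard_normal(len(AA20))
    w = np.exp(beta * tilt)
    return w / w.sum()


def sample_v_families(
    rng: np.random.Generator, n: int, v_families: Mapping[str, float]
) -> np.ndarray:
    fams = sorted(v_families)
    probs = np.array([v_families[f] for f in fams])
    return np.array(fams, dtype=object)[rng.choice(len(fams), size=n, p=probs)]


def _nt(junction_aa: str) -> str:
    return "".join(_CODON[a] for a in junction_aa)


def _substitute(core: str, n_subs: int, rng: np.random.Generator) -> str:
    """Point-substitute n_subs random positions with a different residue."""
    if n_subs <= 0 or not core:
        return core
    chars = list(core)
    positions = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for pos in positions:
        choices = [a for a in AA20 if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _draw_core(length: int, p: np.ndarray, rng: np.random.Generator) -> str:
    codes = rng.choice(len(AA20), size=length, p=p)
    return "".join(AA20[c] for c in codes)


def generate_repertoires(
    cfg: SyntheticConfig = SyntheticConfig(),
    out_tsv: str | Path | None = None,
    out_manifest: str | Path | None = None,
) -> tuple[list[RearrangementRecord], dict]:
    """Generate per-subject repertoires and the ground-truth manifest.

    Cohort A is ``cfg.cohort_labels[0]`` and receives the planted excess.
    When ``out_tsv`` is given the records are also written as AIRR TSV (and
    the manifest as JSON next to it or at ``out_manifest``).
    """
    rng = np.random.default_rng(cfg.seed)
    fams = sorted(cfg.v_families)
    fam_probs = np.array([cfg.v_families[f] for f in fams])
    fam_dist = {f: family_aa_distribution(f, cfg.family_composition_bias) for f in fams}
    lengths = np.array(sorted(cfg.cdr3_length_distribution))
    length_probs = np.array([cfg.cdr3_length_distribution[l] for l in lengths])
    flank = len(_HEAD) + len(_TAIL)
    if lengths.min() <= flank:
        raise ConfigError(f"junction lengths must exceed the conserved flanks ({flank})")

    def draw_family() -> str:
        return fams[rng.choice(len(fams), p=fam_probs)]

    def draw_duplicate_count() -> int:
        return int(rng.geometric(0.5))

    # -- planted cluster archetypes (shared across subjects) ---------------
    planted = []
    for p in range(cfg.n_planted_clusters):
        fam = draw_family()
        v_gene = _GENES[fam][rng.integers(len(_GENES[fam]))]
        j_gene = _J_GENES[rng.choice(len(_J_GENES), p=np.array(_J_PROBS))]
        length = int(rng.integers(13, 18))  # mid-range so cores are informative
        core = _draw_core(length - flank, fam_dist[fam], rng)
        planted.append(
            {
                "motif_id": f"planted_{p}",
                "family": fam,
                "v_call": f"{v_gene}*01",
                "j_call": f"{j_gene}*01",
                "junction_length": length,
                "core": core,
                "per_subject_counts": {},
            }
        )

    subjects: list[tuple[str, str]] = []
    for c, label in enumerate(cfg.cohort_labels):
        for s in range(cfg.n_subjects_per_cohort):
            subjects.append((f"subj_{label}_{s:02d}", label))

    records: list[RearrangementRecord] = []
    clone_log: list[dict] = []
    for subject_id, label in subjects:
        n_total = cfg.n_sequences_per_subject
        made = 0
        seq_no = 0

        def add(junction_aa: str, v_call: str, j_call: str, dup: int) -> None:
            nonlocal made, seq_no
            records.append(
                RearrangementRecord(
                    sequence_id=f"{subject_id}_seq{seq_no:06d}",
                    v_call=v_call,
                    j_call=j_call,
                    subject_id=subject_id,
                    junction_nt=_nt(junction_aa),
                    cdr3_aa=junction_aa,
                    cohort_label=label,
                    duplicate_count=dup,
                )
            )
            made += 1
            seq_no += 1

        # planted members first
        for arch in planted:
            freq = cfg.planted_base_freq
            if label == cfg.cohort_labels[0]:
                freq += cfg.planted_effect
            count = int(rng.binomial(n_total, freq))
            arch["per_subject_counts"][subject_id] = count
            for _ in range(count):
                core = _substitute(arch["core"], 1, rng)
                add(_HEAD + core + _TAIL, arch["v_call"], arch["j_call"], draw_duplicate_count())

        # background clones fill the remainder
        while made < n_total:
            size = min(int(rng.zipf(cfg.clone_size_exponent)), 20, n_total - made)
            fam = draw_family()
            v_gene = _GENES[fam][rng.integers(len(_GENES[fam]))]
            j_gene = _J_GENES[rng.choice(len(_J_GENES), p=np.array(_J_PROBS))]
            length = int(lengths[rng.choice(len(lengths), p=length_probs)])
            parent = _draw_core(length - flank, fam_dist[fam], rng)
            clone_log.append({"subject_id": subject_id, "size": size, "family": fam})
            for k in range(size):
                core = parent if k == 0 else _substitute(parent, int(rng.poisson(0.8)), rng)
                add(_HEAD + core + _TAIL, f"{v_gene}*01", f"{j_gene}*01", draw_duplicate_count())

    manifest = {
        "config": {
            "n_subjects_per_cohort": cfg.n_subjects_per_cohort,
            "n_sequences_per_subject": cfg.n_sequences_per_subject,
            "cohort_labels": list(cfg.cohort_labels),
            "v_families": dict(cfg.v_families),
            "family_composition_bias": cfg.family_composition_bias,
            "n_planted_clusters": cfg.n_planted_clusters,
            "planted_effect": cfg.planted_effect,
            "planted_base_freq": cfg.planted_base_freq,
            "clone_size_exponent": cfg.clone_size_exponent,
            "seed": cfg.seed,
        },
        "subjects": [{"subject_id": s, "cohort_label": l} for s, l in subjects],
        "planted": planted,
        "family_aa_distributions": {f: fam_dist[f].tolist() for f in fams},
        "n_clones": len(clone_log),
    }
    if out_tsv is not None:
        out_tsv = Path(out_tsv)
        write_rearrangements(records, out_tsv)
        import json

        manifest_path = (
            Path(out_manifest) if out_manifest is not None
            else out_tsv.with_suffix(".manifest.json")
        )
        manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return records, manifest


def generate_combinatorial_3grams() -> list[str]:
    """All 20^3 = 8000 amino-acid 3-grams in lexicographic order."""
    alphabet = sorted(AA20)
    return ["".join(t) for t in itertools.product(alphabet, repeat=3)]
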