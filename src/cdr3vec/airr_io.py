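"""Reading, writing and preprocessing of AIRR rearrangement data.

The canonical interchange format is the AIRR Rearrangement TSV (MiAIRR column
names: ``sequence_id``, ``junction``, ``junction_aa``, ``v_call``, ``j_call``,
``duplicate_count``, with extension columns ``subject_id`` and
``cohort_label``).  A FASTA convenience reader accepts metadata encoded as
``key=value`` pairs on the description line.

CDR3 junctions begin and end with short, nearly constant stretches (the
cysteine-anchored "CA(R)" head and the tryptophan/phenylalanine-anchored
tail).  :func:`trim_cdr3` removes a configurable number of residues from each
end so that downstream embedding sees only the hypervariable core; the same
:class:`TrimConfig` must be used when a model is trained and when it is
applied, so it is carried inside every saved model.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, FormatError, FrameError, TooShortError, VCallParseError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_SET = frozenset(AA20)
_AA_EXTENDED_SET = _AA20_SET | {"*", "X"}
_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

#: MiAIRR columns written by :func:`write_rearrangements`, in order.
AIRR_COLUMNS = (
    "sequence_id",
    "junction",
    "junction_aa",
    "v_call",
    "j_call",
    "duplicate_count",
    "subject_id",
    "cohort_label",
)

_VFAM_RE = re.compile(r"^((?:IG[HKL]|TR[ABDG])V)(\d+)")
_GENE_RE = re.compile(r"^((?:IG[HKL]|TR[ABDG])[VJ][\w.\-/]*)")


@dataclass(frozen=True)
class TrimConfig:
    """Number of residues removed from each end of a CDR3 before tokenizing."""

    head: int = 2
    tail: int = 3

    def __post_init__(self) -> None:
        if self.head < 0 or self.tail < 0:
            raise ValueError("trim head/tail must be non-negative")


@dataclass
class RearrangementRecord:
    """One receptor rearrangement: junction, gene calls and provenance."""

    sequence_id: str
    v_call: str
    j_call: str
    subject_id: str = ""
    junction_nt: str | None = None
    cdr3_aa: str | None = None
    cohort_label: str | None = None
    duplicate_count: int = 1


@dataclass
class IngestReport:
    """Bookkeeping for :func:`read_rearrangements`: what was kept and why rows fell out."""

    n_read: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def translate_junction(junction_nt: str) -> str:
    """Translate a nucleotide junction in frame 1 with the standard code.

    Ambiguous codons (e.g. containing ``N``) translate to ``'X'``; internal
    stops translate to ``'*'``.  Raises :class:`FrameError` when the length is
    not a multiple of 3.
    """
    if len(junction_nt) % 3 != 0:
        raise FrameError(
            f"junction length {len(junction_nt)} is not divisible by 3"
        )
    if not junction_nt:
        return ""
    bad = set(junction_nt.upper()) - _IUPAC_NT
    if bad:
        raise AlphabetError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return str(Seq(junction_nt).translate())


def trim_cdr3(cdr3_aa: str, cfg: TrimConfig = TrimConfig()) -> str:
    """Remove the conserved flanks: ``cfg.head`` leading and ``cfg.tail`` trailing residues."""
    if len(cdr3_aa) <= cfg.head + cfg.tail:
        raise TooShortError(
            f"sequence of length {len(cdr3_aa)} cannot be trimmed by "
            f"head={cfg.head}, tail={cfg.tail}"
        )
    return cdr3_aa[cfg.head : len(cdr3_aa) - cfg.tail] if cfg.tail else cdr3_aa[cfg.head :]


def get_v_family(v_call: str) -> str:
    """Gene family of the first listed call, e.g. ``"IGHV3-23*01" -> "IGHV3"``."""
    first = v_call.split(",")[0].strip()
    m = _VFAM_RE.match(first)
    if m is None:
        raise VCallParseError(f"cannot parse gene family from {v_call!r}")
    return m.group(1) + m.group(2)


def get_gene(call: str) -> str:
    """Gene token of the first listed call without the allele,
    e.g. ``"IGHV3-23*01,IGHV3-23D*01" -> "IGHV3-23"``."""
    first = call.split(",")[0].strip().split("*")[0]
    m = _GENE_RE.match(first)
    if m is None:
        raise VCallParseError(f"cannot parse gene from {call!r}")
    return m.group(1)


def _valid_aa(seq: str) -> bool:
    return bool(seq) and set(seq) <= _AA20_SET


def _coerce_count(value) -> int:
    try:
        count = int(float(value))
    except (TypeError, ValueError):
        return 1
    return max(count, 1)


def _record_from_row(row: dict) -> tuple[RearrangementRecord | None, str | None]:
    """Build a record from a raw mapping; returns (record, drop_reason)."""
    junction = str(row.get("junction") or "") or None
    cdr3_aa = str(row.get("junction_aa") or "") or None
    if junction is not None and set(junction.upper()) - _IUPAC_NT:
        return None, "invalid_nucleotide"
    if cdr3_aa is None and junction is not None:
        try:
            cdr3_aa = translate_junction(junction)
        except FrameError:
            return None, "frame_error"
        except AlphabetError:
            return None, "invalid_nucleotide"
    if cdr3_aa is None:
        return None, "no_junction"
    if set(cdr3_aa) - _AA_EXTENDED_SET:
        return None, "invalid_amino_acid"
    if not _valid_aa(cdr3_aa):
        # contains '*' (non-productive) or 'X' (ambiguous), or is empty
        return None, "nonstandard_residue"
    rec = RearrangementRecord(
        sequence_id=str(row.get("sequence_id", "")),
        v_call=str(row.get("v_call", "")),
        j_call=str(row.get("j_call", "")),
        subject_id=str(row.get("subject_id") or ""),
        junction_nt=junction,
        cdr3_aa=cdr3_aa,
        cohort_label=(str(row["cohort_label"]) if row.get("cohort_label") not in (None, "") else None),
        duplicate_count=_coerce_count(row.get("duplicate_count", 1)),
    )
    return rec, None


def read_rearrangements(
    path: str | Path, format: str = "airr-tsv"
) -> tuple[list[RearrangementRecord], IngestReport]:
    """Read rearrangements from an AIRR TSV or an annotated FASTA.

    Rows whose junction fails character checks, cannot be translated in
    frame, or whose translation contains a stop or ambiguous residue are
    dropped and tallied in the returned :class:`IngestReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "airr-tsv":
        rows = _read_airr_tsv(path)
    elif format == "fasta":
        rows = _read_fasta(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    report = IngestReport()
    records: list[RearrangementRecord] = []
    for row in rows:
        report.n_read += 1
        rec, reason = _record_from_row(row)
        if rec is None:
            report.dropped[reason] += 1
        else:
            records.append(rec)
    report.n_kept = len(records)
    if report.n_read == 0:
        warnings.warn(f"{path}: no rearrangement rows found", stacklevel=2)
    return records, report


def _read_airr_tsv(path: Path) -> Iterable[dict]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = {"sequence_id", "v_call", "j_call"} - set(df.columns)
    if missing:
        raise FormatError(f"missing mandatory AIRR column(s): {sorted(missing)}")
    if "junction" not in df.columns and "junction_aa" not in df.columns:
        raise FormatError("missing mandatory AIRR column(s): need junction or junction_aa")
    return df.to_dict(orient="records")


def _read_fasta(path: Path) -> Iterable[dict]:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta: dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key] = value
        seq = str(rec.seq).upper()
        row = {
            "sequence_id": rec.id,
            "v_call": meta.get("v_call", ""),
            "j_call": meta.get("j_call", ""),
            "subject_id": meta.get("subject_id", meta.get("subject", "")),
            "cohort_label": meta.get("cohort_label", meta.get("cohort")),
            "duplicate_count": meta.get("duplicate_count", 1),
        }
        # Sequences over {A,C,G,T,U,N} are nucleotide junctions; anything else
        # is taken to be an amino-acid CDR3.
        if set(seq) <= set("ACGTUN"):
            row["junction"] = seq
        else:
            row["junction_aa"] = seq
        rows.append(row)
    return rows


def write_rearrangements(records: Sequence[RearrangementRecord], path: str | Path) -> None:
    """Write records as AIRR Rearrangement TSV (columns in :data:`AIRR_COLUMNS` order)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "junction": rec.junction_nt or "",
                "junction_aa": rec.cdr3_aa or "",
                "v_call": rec.v_call,
                "j_call": rec.j_call,
                "duplicate_count": rec.duplicate_count,
                "subject_id": rec.subject_id,
                "cohort_label": rec.cohort_label or "",
            }
        )
    df = pd.DataFrame(rows, columns=list(AIRR_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
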