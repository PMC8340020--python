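"""Biophysicochemical properties of amino-acid strings.

Eight per-sequence properties used to validate the word-level embedding:

- gravy: mean Kyte-Doolittle hydropathy
- bulkiness: mean Zimmerman bulkiness
- polarity: mean Grantham polarity
- aliphatic: Ikai aliphatic index normalized per residue,
  (A + 2.9 V + 3.9 (I+L)) / length
- charge: Henderson-Hasselbalch net charge at pH 7.4 (EMBOSS pK values,
  termini excluded) per residue
- acidic / basic / aromatic: side-chain content fractions

Histidine counts as both basic and aromatic.  Scales live in two-column text
files under ``data/scales`` so they can be swapped without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .airr_io import _AA20_SET
from .errors import AlphabetError

_SCALE_CACHE: dict[str, dict[str, float]] = {}


def _load_scale(name: str) -> dict[str, float]:
    if name not in _SCALE_CACHE:
        text = (
            resources.files("cdr3vec.data.scales").joinpath(f"{name}.tsv").read_text()
        )
        scale = {}
        for line in text.strip().splitlines():
            parts = line.split("\t")
            scale[parts[0]] = float(parts[1])
        _SCALE_CACHE[name] = scale
    return _SCALE_CACHE[name]


def _load_pk() -> tuple[dict[str, float], dict[str, float]]:
    """EMBOSS side-chain pKs split into (acidic, basic) groups."""
    if "_pk" not in _SCALE_CACHE:
        text = resources.files("cdr3vec.data.scales").joinpath("pk_emboss.tsv").read_text()
        acid, base = {}, {}
        for line in text.strip().splitlines():
            res, pk, kind = line.split("\t")
            (acid if kind == "acid" else base)[res] = float(pk)
        _SCALE_CACHE["_pk"] = (acid, base)  # type: ignore[assignment]
    return _SCALE_CACHE["_pk"]  # type: ignore[return-value]


_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}
_ACIDIC = set("DE")
_BASIC = set("RHK")
_AROMATIC = set("FWYH")

PROPERTY_NAMES = (
    "gravy",
    "bulkiness",
    "polarity",
    "aliphatic",
    "charge",
    "acidic",
    "basic",
    "aromatic",
)


@dataclass(frozen=True)
class PropertyVector:
    gravy: float
    bulkiness: float
    polarity: float
    aliphatic: float
    charge: float
    acidic: float
    basic: float
    aromatic: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def net_charge(seq: str, ph: float = 7.4) -> float:
    """Henderson-Hasselbalch net side-chain charge (termini excluded)."""
    acid, base = _load_pk()
    positive = sum(seq.count(res) / (1.0 + 10 ** (ph - pk)) for res, pk in base.items())
    negative = sum(seq.count(res) / (1.0 + 10 ** (pk - ph)) for res, pk in acid.items())
    return positive - negative


def compute_properties(seq: str, ph: float = 7.4) -> PropertyVector:
    """The 8-property vector of a non-empty 20-letter amino-acid string."""
    if not seq:
        raise AlphabetError("empty sequence")
    bad = set(seq) - _AA20_SET
    if bad:
        raise AlphabetError(f"non-standard residues: {sorted(bad)}")
    n = len(seq)
    hydro = _load_scale("hydropathy_kyte_doolittle")
    bulk = _load_scale("bulkiness_zimmerman")
    polar = _load_scale("polarity_grantham")
    return PropertyVector(
        gravy=sum(hydro[a] for a in seq) / n,
        bulkiness=sum(bulk[a] for a in seq) / n,
        polarity=sum(polar[a] for a in seq) / n,
        aliphatic=sum(_ALIPHATIC_WEIGHTS.get(a, 0.0) for a in seq) / n,
        charge=net_charge(seq, ph) / n,
        acidic=sum(seq.count(a) for a in _ACIDIC) / n,
        basic=sum(seq.count(a) for a in _BASIC) / n,
        aromatic=sum(seq.count(a) for a in _AROMATIC) / n,
    )


def property_table(grams: Sequence[str]) -> pd.DataFrame:
    """One :class:`PropertyVector` row per gram (index = the gram strings,
    duplicates allowed)."""
    rows = [compute_properties(g).as_dict() for g in grams]
    return pd.DataFrame(rows, index=list(grams), columns=list(PROPERTY_NAMES))


def property_values(grams: Sequence[str], name: str) -> Mapping[int, float]:
    """Convenience: one named property per gram, keyed by position."""
    return {i: getattr(compute_properties(g), name) for i, g in enumerate(grams)}
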