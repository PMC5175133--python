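"""Sequence feature extraction: 20D amino-acid composition and the 188D vector.

The 188D vector concatenates the 20 amino-acid frequencies (AAC, alphabetical
A..Y) with, for each of the 8 physicochemical properties in the fixed order of
:mod:`profam.ctd_groupings`, 21 CTD features: 3 class compositions, 3
class-pair transition frequencies, and 15 distribution features (5 positional
quantiles per class). 20 + 8 x 21 = 188.

Distribution features are fractional positions in [0, 1]: for a class with
n occurrences in a sequence of length L, the 1-based positions of its 1st,
ceil(0.25 n)-th, ceil(0.50 n)-th, ceil(0.75 n)-th and n-th residues, each
divided by L; all five are 0 when the class is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ctd_groupings import PROPERTY_GROUPINGS, PropertyGrouping
from .seqio import CANONICAL_AA, ProteinRecord

MODES = ("20D", "188D")

_QUANTILE_TAGS = ("d1", "d25", "d50", "d75", "d100")


def feature_names(mode: str) -> list[str]:
    """Ordered feature labels for a mode; the 188D layout is fixed."""
    names = [f"aac_{aa}" for aa in CANONICAL_AA]
    if mode == "20D":
        return names
    if mode != "188D":
        raise ValueError(f"unknown feature mode {mode!r}")
    for prop in PROPERTY_GROUPINGS:
        p = prop.name
        names += [f"{p}_c{g}" for g in (1, 2, 3)]
        names += [f"{p}_t{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3))]
        for g in (1, 2, 3):
            names += [f"{p}_g{g}_{q}" for q in _QUANTILE_TAGS]
    return names


@dataclass(frozen=True)
class FeatureVector:
    mode: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = 20 if self.mode == "20D" else 188
        if len(self.names) != expected or len(self.values) != expected:
            raise ValueError(f"mode {self.mode} expects {expected} features")


def aac20(seq: str) -> np.ndarray:
    """Amino-acid composition: frequency of each residue, alphabetical order."""
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    counts = np.fromiter((seq.count(aa) for aa in CANONICAL_AA), dtype=float, count=20)
    return counts / L


def _group_codes(seq: str, grouping: PropertyGrouping) -> np.ndarray:
    idx = grouping.group_index()
    return np.fromiter((idx[c] for c in seq), dtype=np.int8, count=len(seq))


def ctd_composition(seq: str, grouping: PropertyGrouping) -> np.ndarray:
    """Fraction of residues in each of the grouping's 3 classes (sums to 1)."""
    if not seq:
        raise ValueError("empty sequence")
    codes = _group_codes(seq, grouping)
    return np.bincount(codes, minlength=3).astype(float) / len(seq)


def ctd_transition(seq: str, grouping: PropertyGrouping) -> np.ndarray:
    """Adjacent cross-class transition frequencies for pairs (1,2), (1,3), (2,3).

    Counts adjacent positions whose residues fall in the two different
    classes (either order), divided by L-1. Defined as zeros for L=1.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) == 1:
        return np.zeros(3)
    codes = _group_codes(seq, grouping)
    a, b = codes[:-1], codes[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = np.zeros(3)
    for k, (g1, g2) in enumerate(((0, 1), (0, 2), (1, 2))):
        out[k] = np.count_nonzero((lo == g1) & (hi == g2))
    return out / (len(seq) - 1)


def ctd_distribution(seq: str, grouping: PropertyGrouping) -> np.ndarray:
    """15 positional-quantile features (5 per class), as fractions of L."""
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    codes = _group_codes(seq, grouping)
    out = np.zeros(15)
    for g in range(3):
        positions = np.flatnonzero(codes == g) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        picks = [
            positions[0],
            positions[math.ceil(0.25 * n) - 1],
            positions[math.ceil(0.50 * n) - 1],
            positions[math.ceil(0.75 * n) - 1],
            positions[-1],
        ]
        out[5 * g : 5 * g + 5] = np.asarray(picks, dtype=float) / L
    return out


def extract_20d(seq: str) -> FeatureVector:
    return FeatureVector("20D", tuple(feature_names("20D")), aac20(seq))


def extract_188d(seq: str) -> FeatureVector:
    """Full 188D vector: AAC then 21 CTD features per property."""
    if len(seq) < 2:
        raise ValueError("188D extraction needs sequence length >= 2")
    blocks = [aac20(seq)]
    for prop in PROPERTY_GROUPINGS:
        blocks.append(ctd_composition(seq, prop))
        blocks.append(ctd_transition(seq, prop))
        blocks.append(ctd_distribution(seq, prop))
    return FeatureVector("188D", tuple(feature_names("188D")), np.concatenate(blocks))


def extract_matrix(
    records: list[ProteinRecord], mode: str = "188D", label: str | int | None = None
) -> pd.DataFrame:
    """Feature matrix for a record list: one row per record, stable order.

    The index holds record ids; a ``label`` column is prepended when a class
    tag is given. Records violating the mode's length precondition raise an
    error naming the offending id.
    """
    if not records:
        raise ValueError("no records")
    if mode not in MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    extractor = extract_188d if mode == "188D" else extract_20d
    rows, ids = [], []
    for rec in records:
        try:
            rows.append(extractor(rec.sequence).values)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    df = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"), columns=feature_names(mode))
    if label is not None:
        df.insert(0, "label", label)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Export a feature matrix as TSV with a header row and the id index."""
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
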