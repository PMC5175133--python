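"""Deterministic generators of synthetic inputs for every pipeline stage.

Real training data for a protein-family classifier comes from database
searches that cannot be redistributed, so these generators produce sequence
families, alignments and Ct tables with the statistical structure each stage
assumes: two families distinguishable by compositional bias and/or a shared
motif, clade-structured gap-free alignments for tree building, and shifted
log-scale Ct measurements for the expression statistics. Every generator is
a pure function of its specification plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import CANONICAL_AA, Alignment, ProteinRecord

_AA = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one synthetic protein family.

    ``bias_strength`` moves that much total probability mass from the
    uniform background onto ``bias_residues`` (spread evenly across them),
    emulating the compositional signature that separates real families.
    ``motif``, when set, is embedded once at a random position in every
    sequence.
    """

    n: int = 100
    length_range: tuple[int, int] = (80, 300)
    background: tuple[float, ...] | None = None  # 20 frequencies, A..Y; None = uniform
    motif: str | None = None
    bias_residues: str = ""
    bias_strength: float = 0.0
    id_prefix: str = "seq"
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        if self.background is not None:
            freqs = np.asarray(self.background, dtype=float)
            if len(freqs) != 20 or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
                raise ValueError("background must be 20 non-negative frequencies summing to 1")
        else:
            freqs = np.full(20, 1 / 20)
        if self.bias_strength > 0:
            if not self.bias_residues:
                raise ValueError("bias_strength > 0 requires bias_residues")
            target = np.array([aa in self.bias_residues for aa in CANONICAL_AA])
            freqs = freqs * (1.0 - self.bias_strength)
            freqs[target] += self.bias_strength / target.sum()
        return freqs


def gen_family(spec: FamilySpec) -> list[ProteinRecord]:
    """Draw ``spec.n`` i.i.d. sequences from the (biased) background.

    Lengths are uniform over ``length_range``; the motif, when given, is
    inserted by overwriting a random window. Reproducible from the seed.
    """
    lo, hi = spec.length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    if spec.motif is not None:
        if len(spec.motif) > lo:
            raise ValueError("motif longer than minimum sequence length")
        if set(spec.motif) - set(CANONICAL_AA):
            raise ValueError("motif contains non-canonical residues")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    records = []
    for i in range(spec.n):
        L = int(rng.integers(lo, hi + 1))
        letters = rng.choice(_AA, size=L, p=freqs)
        if spec.motif is not None:
            start = int(rng.integers(0, L - len(spec.motif) + 1))
            letters[start : start + len(spec.motif)] = list(spec.motif)
        records.append(ProteinRecord(id=f"{spec.id_prefix}{i:04d}", sequence="".join(letters)))
    return records


def gen_two_families(
    n_pos: int = 200,
    n_neg: int = 200,
    length_range: tuple[int, int] = (80, 300),
    bias_residues: str = "KRH",
    bias_strength: float = 0.18,
    motif: str | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Positive family (biased composition, optional motif) and a uniform
    negative family — the synthetic stand-in for a family-vs-control dataset."""
    pos = gen_family(FamilySpec(
        n=n_pos, length_range=length_range, bias_residues=bias_residues,
        bias_strength=bias_strength, motif=motif, id_prefix="pos", seed=seed,
    ))
    neg = gen_family(FamilySpec(
        n=n_neg, length_range=length_range, id_prefix="neg", seed=seed + 1,
    ))
    return pos, neg


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a uniformly random *different* residue."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def gen_alignment(
    n_clades: int = 4,
    leaves_per_clade: int = 3,
    length: int = 300,
    within_divergence: float = 0.02,
    between_divergence: float = 0.4,
    seed: int = 0,
) -> Alignment:
    """Gap-free alignment with clade structure for tree-building tests.

    Clade ancestors evolve along a chain (each mutated from the previous at
    the between rate), so the inter-clade topology is a resolved ladder
    rather than a star; leaves are mutated from their clade ancestor at the
    within rate. Leaf names are ``c<clade>_l<leaf>``.
    """
    if not (0.0 <= within_divergence < 1.0) or not (0.0 < between_divergence < 1.0):
        raise ValueError("divergence rates must lie in [0, 1)")
    if between_divergence <= within_divergence:
        raise ValueError("between_divergence must exceed within_divergence")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_AA, size=length)
    ids, rows = [], []
    for ci in range(n_clades):
        ancestor = _mutate(ancestor, between_divergence, rng)
        for li in range(leaves_per_clade):
            leaf = _mutate(ancestor, within_divergence, rng)
            ids.append(f"c{ci}_l{li}")
            rows.append("".join(leaf))
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def gen_ct_table(
    n_per_group: int = 8,
    genes: tuple[str, ...] = ("GENE1",),
    effect_dct: dict[str, float] | float = 0.0,
    noise_sd: float = 0.5,
    base_dct: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table for the expression statistics.

    Control dCt ~ Normal(base_dct, noise_sd); case dCt is shifted by the
    per-gene effect (negative effect = higher expression in cases). The
    reference-gene Ct is fixed at 20 cycles, so ct_target = 20 + dCt.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    effects = (
        {g: float(effect_dct) for g in genes} if np.isscalar(effect_dct) else dict(effect_dct)
    )
    rows = []
    for gene in genes:
        eff = effects.get(gene, 0.0)
        for group, shift in (("control", 0.0), ("case", eff)):
            dct = base_dct + shift + rng.normal(0.0, noise_sd, size=n_per_group)
            for i, v in enumerate(dct):
                rows.append({
                    "sample_id": f"{group[:4]}{i:02d}",
                    "group": group,
                    "gene": gene,
                    "ct_target": 20.0 + float(v),
                    "ct_reference": 20.0,
                })
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct_target", "ct_reference"])
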