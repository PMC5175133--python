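"""Comparative-Ct relative expression and nonparametric group comparison.

Relative expression follows the comparative threshold-cycle method: the
target gene's Ct is normalised to a housekeeping reference within the same
sample (dCt = Ct_target - Ct_reference) and reported as 2**(-dCt). Group
differences (e.g. tumour vs adjacent normal tissue) are tested with an
unpaired two-sided Mann-Whitney U test; the exact null distribution is
enumerated for small samples, with a tie-corrected, continuity-corrected
normal approximation for larger ones.

Also included: primer %GC composition QC for qPCR primer panels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

CT_COLUMNS = ("sample_id", "group", "gene", "ct_target", "ct_reference")
GROUPS = ("case", "control")

EXACT_LIMIT = 16  # auto uses full enumeration up to this pooled size

_DNA = frozenset("ACGT")


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerRecord:
    """A primer oligo: name, DNA sequence, optional expected %GC."""

    name: str
    sequence: str
    expected_gc: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise QpcrError(f"primer {self.name!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _DNA
        if bad:
            raise QpcrError(f"primer {self.name!r} has non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class ExpressionResult:
    """Two-group comparison of a gene's 2^-dCt relative expression."""

    gene: str
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    se_case: float
    se_control: float
    u_statistic: float
    p_value: float
    stars: str  # '**' p<0.01, '*' p<0.05, 'NS' otherwise

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_case": self.n_case, "n_control": self.n_control,
            "mean_case": self.mean_case, "mean_control": self.mean_control,
            "se_case": self.se_case, "se_control": self.se_control,
            "U": self.u_statistic, "p": self.p_value, "stars": self.stars,
        }


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2**-(ct_target - ct_reference); decreasing in target Ct."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise QpcrError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    diff = x[:, None] - y[None, :]
    return float(np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))


def _midranks(values: np.ndarray) -> list[float]:
    from scipy.stats import rankdata

    return list(rankdata(values))


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (x vs y) and its two-sided p-value.

    U = #{(i, j): x_i > y_j} + 0.5 #{ties}. ``exact`` enumerates all
    C(m+n, m) assignments of the pooled values (correct under ties);
    ``normal-approx`` uses the tie-corrected variance with a 0.5 continuity
    correction; ``auto`` switches at a pooled size of 16. The two-sided p is
    2 * min(P(U' <= U), P(U' >= U)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise QpcrError("both groups must be non-empty")
    if method not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown method {method!r}")
    m, n = len(x), len(y)
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if m + n <= EXACT_LIMIT else "normal-approx"

    if method == "exact":
        # U for a relabelling equals the midrank sum of its x-positions minus
        # m(m+1)/2 (the identity holds under ties), so enumeration only needs
        # rank sums over all C(m+n, m) label arrangements.
        pooled = np.concatenate([x, y])
        ranks = _midranks(pooled)
        shift = m * (m + 1) / 2.0
        total = math.comb(m + n, m)
        le = ge = 0
        for combo in itertools.combinations(range(m + n), m):
            u_perm = sum(ranks[k] for k in combo) - shift
            if u_perm <= u + 1e-12:
                le += 1
            if u_perm >= u - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u, p

    mu = m * n / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = m + n
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return u, p


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample_id, group, gene, ct_target, ct_reference."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise QpcrError(f"unknown groups {sorted(bad_group)}; expected {GROUPS}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any() or (vals >= 60).any():
            raise QpcrError(f"{col} values must lie in (0, 60)")
    if df.duplicated(subset=["sample_id", "gene"]).any():
        raise QpcrError("duplicate (sample_id, gene) rows")
    return df


def compare_groups(table: pd.DataFrame, gene: str, method: str = "auto") -> ExpressionResult:
    """Case-vs-control comparison of a gene's relative expression.

    Reports per-group mean and standard error of 2^-dCt, the U statistic for
    case vs control, the two-sided p and the significance stars.
    """
    sub = table[table["gene"] == gene]
    expr = {}
    for group in GROUPS:
        rows = sub[sub["group"] == group]
        if rows.empty:
            raise QpcrError(f"gene {gene!r} has no {group} samples")
        expr[group] = np.array([
            relative_expression(t, r)
            for t, r in zip(rows["ct_target"], rows["ct_reference"])
        ])
    case, control = expr["case"], expr["control"]
    u, p = mann_whitney_u(case, control, method=method)

    def se(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0

    return ExpressionResult(
        gene=gene,
        n_case=len(case), n_control=len(control),
        mean_case=float(case.mean()), mean_control=float(control.mean()),
        se_case=se(case), se_control=se(control),
        u_statistic=u, p_value=p, stars=significance_stars(p),
    )


def primer_gc(p: PrimerRecord | str) -> float:
    """Percent G+C of a primer, e.g. 45.5 for a 10/22 GC oligo."""
    seq = (p.sequence if isinstance(p, PrimerRecord) else p).upper()
    if not seq:
        raise QpcrError("empty primer sequence")
    bad = set(seq) - _DNA
    if bad:
        raise QpcrError(f"non-DNA characters {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def primer_gc_display(p: PrimerRecord | str) -> float:
    """%GC rounded to one decimal, the conventional panel-table precision."""
    return round(primer_gc(p), 1)
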