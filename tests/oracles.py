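"""Independent brute-force implementations used as oracles.

These are deliberately written with plain Python loops and dictionaries —
no shared code with the package — so that agreement with the package is a
genuine two-route check.
"""

from __future__ import annotations

import math

from profam.ctd_groupings import PROPERTY_GROUPINGS
from profam.seqio import CANONICAL_AA


def lcs_matches(a: str, b: str) -> int:
    """Maximum identical aligned pairs under match=+1, mismatch=0, gap=0
    global alignment — i.e. the longest common subsequence, by textbook DP."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[n]


def brute_identity(a: str, b: str) -> float:
    return lcs_matches(a, b) / min(len(a), len(b))


def brute_188d(seq: str) -> list[float]:
    """Second implementation of the 188D vector: AAC then, per property,
    3 compositions, 3 transitions, 15 distribution quantiles."""
    L = len(seq)
    out: list[float] = []
    for aa in CANONICAL_AA:
        out.append(sum(1 for c in seq if c == aa) / L)
    for prop in PROPERTY_GROUPINGS:
        which = {}
        for gi, letters in enumerate(prop.groups):
            for aa in letters:
                which[aa] = gi
        codes = [which[c] for c in seq]
        # composition
        for g in range(3):
            out.append(sum(1 for c in codes if c == g) / L)
        # transitions for unordered pairs (0,1), (0,2), (1,2)
        for g1, g2 in ((0, 1), (0, 2), (1, 2)):
            count = 0
            for k in range(L - 1):
                pair = {codes[k], codes[k + 1]}
                if pair == {g1, g2}:
                    count += 1
            out.append(count / (L - 1) if L > 1 else 0.0)
        # distribution quantile positions
        for g in range(3):
            positions = [k + 1 for k, c in enumerate(codes) if c == g]
            if not positions:
                out.extend([0.0] * 5)
                continue
            ng = len(positions)
            for q in (None, 0.25, 0.50, 0.75, 1.0):
                if q is None:
                    idx = 1
                else:
                    idx = math.ceil(q * ng)
                out.append(positions[idx - 1] / L)
    return out


def brute_auc(scores, labels, positive=1) -> float:
    """All-pairs O(n^2) AUC: P(s_pos > s_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_mwu(x, y) -> tuple[float, float]:
    """Naive Mann-Whitney: pairwise U count, then exact two-sided p by
    enumerating every assignment of the pooled values to the x slots."""
    import itertools

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    m, n = len(x), len(y)
    u_obs = u_of(x, y)
    pooled = list(x) + list(y)
    le = ge = total = 0
    for combo in itertools.combinations(range(m + n), m):
        chosen = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(m + n) if i not in chosen]
        u = u_of(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    return u_obs, min(1.0, 2.0 * min(le, ge) / total)


def brute_p_distance(row_i: str, row_j: str) -> float:
    """Site-by-site pairwise-deletion p-distance."""
    comparable = 0
    diffs = 0
    for a, b in zip(row_i, row_j):
        if a != "-" and b != "-":
            comparable += 1
            if a != b:
                diffs += 1
    return diffs / comparable
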