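"""Independent brute-force oracles used only by the tests.

Each function here re-derives an expected value by enumeration or direct
dynamic programming, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def sw_affine_score(
    query: str, ref: str, match: int = 1, mismatch: int = -2, open_: int = 5, extend: int = 2
) -> int:
    """Best local alignment score, full O(nm) DP with affine gaps.

    A gap of length k costs open_ + extend*k (first gapped base costs
    open_+extend). Plus strand only; callers handle the reverse complement.
    """
    n, m = len(ref), len(query)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (ref consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (query consumed)
    best = 0
    first = open_ + extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i - 1][j] - extend, H[i - 1][j] - first)
            F[i][j] = max(F[i][j - 1] - extend, H[i][j - 1] - first)
            s = match if ref[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def sw_affine_score_both_strands(query: str, ref: str, **kw) -> int:
    return max(sw_affine_score(query, ref, **kw), sw_affine_score(revcomp(query), ref, **kw))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Table [[a, b], [c, d]]; margins fixed; all tables whose probability
    does not exceed the observed one (standard relative tolerance 1e-7
    for floating ties) contribute.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    weights = {
        k: comb(r1, k) * comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = weights[a]
    total = sum(w for w in weights.values() if w <= obs * (1 + 1e-7))
    return total / denom


def wilcoxon_two_sided(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Tie-free data assumed. The U statistic of x is compared with its full
    permutation null distribution (every choice of |x| ranks out of n).
    """
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(1, n + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    mean_u = n1 * (n - n1) / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-9)
    return extreme / len(us)


def cox_grid_beta(
    x: list[float], time: list[float], status: list[int], lo: float = -5, hi: float = 5, tol: float = 1e-6
) -> float:
    """1-D grid/ternary search maximizer of the Breslow partial likelihood."""
    import math

    def loglik(beta: float) -> float:
        ll = 0.0
        for i, (ti, si) in enumerate(zip(time, status)):
            if si != 1:
                continue
            risk = sum(math.exp(beta * xj) for xj, tj in zip(x, time) if tj >= ti)
            ll += beta * x[i] - math.log(risk)
        return ll

    a, b = lo, hi
    while b - a > tol:
        m1 = a + (b - a) / 3
        m2 = b - (b - a) / 3
        if loglik(m1) < loglik(m2):
            a = m1
        else:
            b = m2
    return (a + b) / 2


def transitive_closure_clusters(barcodes: list[str], threshold: float) -> list[frozenset[str]]:
    """Partition by the transitive closure of pairwise identity > threshold."""

    def ident(p: str, q: str) -> float:
        return sum(1 for u, v in zip(p, q) if u == v and u != "N") / len(p)

    parent = {b: b for b in barcodes}

    def find(b):
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        return b

    for p, q in itertools.combinations(barcodes, 2):
        if ident(p, q) > threshold:
            parent[find(p)] = find(q)
    groups: dict[str, set[str]] = {}
    for b in barcodes:
        groups.setdefault(find(b), set()).add(b)
    return [frozenset(g) for g in groups.values()]


def stratify_brute_force(score, lct, time, status, target=0.5, horizon=36.0):
    """Exhaustive search over all observed threshold pairs.

    Returns (score_thr, lct_thr, met) under the documented preference:
    reach the target 36-month fatality rate in the high/high group,
    maximize its size, then higher rate, then lower thresholds.
    """
    best = None
    for s_thr in sorted(set(score)):
        for l_thr in sorted(set(lct)):
            idx = [i for i in range(len(score)) if score[i] >= s_thr and lct[i] >= l_thr]
            if not idx:
                continue
            rate = sum(1 for i in idx if status[i] == 1 and time[i] <= horizon) / len(idx)
            met = rate >= target
            key = (met, len(idx) if met else 0, rate, -s_thr, -l_thr)
            if best is None or key > best[0]:
                best = (key, s_thr, l_thr, met)
    return best[1], best[2], best[3]


def find_repeat_windows_scan(transcript: str, repeat: str, min_len: int = 30) -> list[tuple[int, int]]:
    """Maximal transcript windows that are exact substrings of a repeat
    (either strand), found by exhaustive scanning."""
    both = (repeat, revcomp(repeat))

    def hit(s: str) -> bool:
        return any(s in r for r in both)

    wins = []
    for i in range(len(transcript) - min_len + 1):
        j = i + min_len
        if not hit(transcript[i:j]):
            continue
        while j < len(transcript) and hit(transcript[i : j + 1]):
            j += 1
        wins.append((i, j))
    return [
        (s, e)
        for s, e in wins
        if not any(s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2 in wins)
    ]
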