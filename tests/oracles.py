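"""Independent brute-force oracles used by the test suite.

Everything here is deliberately re-implemented from first principles —
simple, quadratic where convenient, and structurally unlike the package
code it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_repeat_count(
    seq: str, patterns: Sequence[str], include_revcomp: bool = True
) -> int:
    """Greedy left-to-right non-overlapping count, character by character."""
    pats = list(patterns)
    if include_revcomp:
        for p in list(patterns):
            rc = naive_revcomp(p)
            if rc not in pats:
                pats.append(rc)
    count = 0
    i = 0
    while i + 6 <= len(seq):
        matched = False
        for p in pats:
            ok = True
            for j in range(6):
                if seq[i + j] != p[j]:
                    ok = False
                    break
            if ok:
                matched = True
                break
        if matched:
            count += 1
            i += 6
        else:
            i += 1
    return count


def naive_gc(seq: str):
    valid = [b for b in seq if b != "N"]
    if not valid:
        return None
    return sum(1 for b in valid if b in "GC") / len(valid)


def naive_profile(
    sequences: Sequence[str],
    patterns: Sequence[str],
    threshold: int,
    gc_low: float,
    gc_high: float,
    include_revcomp: bool = True,
) -> Tuple[int, int, int, List[bool]]:
    """(n_total, n_telomeric, n_gc_matched, per-read telomeric flags)."""
    n_tel = 0
    n_gc = 0
    flags: List[bool] = []
    for seq in sequences:
        telo = naive_repeat_count(seq, patterns, include_revcomp) >= threshold
        flags.append(telo)
        if telo:
            n_tel += 1
        gc = naive_gc(seq)
        if gc is not None and gc_low <= gc <= gc_high:
            n_gc += 1
    return len(sequences), n_tel, n_gc, flags


# ---------------------------------------------------------------------------
# Fisher's exact test by exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p by integer-exact enumeration over tables at fixed margins.

    The probability of a table is C(r1, a) C(r2, c1-a) / C(N, c1); summing
    those with probability <= the observed one reduces to an exact integer
    comparison of the numerators.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(nums)
    return sum(v for v in nums if v <= obs) / total


def fisher_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def all_tables(max_n: int):
    """Yield every 2x2 table (a, b, c, d) with 1 <= a+b+c+d <= max_n."""
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    yield a, b, c, d


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


def wilcoxon_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Tie-free data only; quadratic/combinatorial, for tiny samples.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "tie-free data required"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    mean_w = n * (n + m + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_normal_z(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-free Wilcoxon normal-approximation z, no continuity correction."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    w = sum(ranks[v] for v in x)
    mean_w = n * (n + m + 1) / 2
    var_w = n * m * (n + m + 1) / 12
    return (w - mean_w) / math.sqrt(var_w)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def classical_km(times: Sequence[float], events: Sequence[bool]):
    """Untruncated product-limit estimator: (event_times, survival)."""
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e})
    s = 1.0
    out_t, out_s = [], []
    for t in distinct:
        at_risk = sum(1 for tt, _ in pairs if tt >= t)
        d = sum(1 for tt, e in pairs if e and tt == t)
        s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


# ---------------------------------------------------------------------------
# Mutual exclusivity: exact two-gene null
# ---------------------------------------------------------------------------


def mutex_exact_p_two_genes(n: int, k1: int, k2: int, observed_coverage: int) -> float:
    """P(coverage >= observed) when two genes are independently permuted.

    Coverage = k1 + k2 - overlap with overlap ~ Hypergeometric(n, k1, k2).
    """
    p = 0.0
    denom = math.comb(n, k2)
    for ov in range(max(0, k1 + k2 - n), min(k1, k2) + 1):
        cov = k1 + k2 - ov
        if cov >= observed_coverage:
            p += math.comb(k1, ov) * math.comb(n - k1, k2 - ov) / denom
    return p
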