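"""Rank-based group comparisons and a permutation mutual-exclusivity test.

Wilcoxon rank-sum for two groups; Dunn's test (pairwise z statistics on
joint midranks with a tie correction) with Bonferroni for multi-group
comparisons, optionally restricted to comparisons against a reference
group such as wild-type; alteration-combination grouping for assessing
additive effects of co-occurring alterations; and a coverage-statistic
permutation test for mutual exclusivity of alterations.

The mutual-exclusivity statistic is *coverage* — the number of samples
carrying at least one alteration among the tested genes. Under mutual
exclusivity alterations spread across distinct samples, maximising
coverage relative to the independence null, which is simulated by
permuting each gene's column independently (preserving per-gene
alteration frequencies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Genes canonically associated with telomere maintenance (ALT and
#: telomerase pathways) plus the candidate genes tracked by default.
CANONICAL_GENES = ("ATRX", "DAXX", "TERTp", "TERC")
CANDIDATE_GENES = ("RAD21", "HGF")


def _validate_groups(groups: Dict[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic of ``x`` (midranks for ties) and the
    two-sided p-value: exact enumeration when both samples have n <= 10
    and there are no ties, otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(combined)) < len(combined)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return w, float(res.pvalue)


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    z_statistic: float
    p_value: float
    p_adjusted: float


def dunn_test(
    groups: Dict[str, Sequence[float]],
    reference: Optional[str] = None,
) -> List[PairwiseTestResult]:
    """Dunn's pairwise multiple-comparison test on joint midranks.

    For a pair (i, j): z = (meanrank_i - meanrank_j) / sqrt(
    [N(N+1)/12 - sum(t^3 - t)/(12(N-1))] * (1/n_i + 1/n_j)), with t the
    tie-group sizes over the pooled sample; two-sided p from the standard
    normal. Bonferroni counts only the comparisons reported: all pairs, or
    only the pairs against ``reference`` when given.
    """
    _validate_groups(groups)
    if reference is not None and reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    labels = list(groups)
    sizes = {g: len(groups[g]) for g in labels}
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks: Dict[str, float] = {}
    offset = 0
    for g in labels:
        mean_ranks[g] = float(ranks[offset : offset + sizes[g]].mean())
        offset += sizes[g]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    if reference is None:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        pairs = [(g, reference) for g in labels if g != reference]

    k = len(pairs)
    out: List[PairwiseTestResult] = []
    for ga, gb in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(PairwiseTestResult(ga, gb, z, min(1.0, p), min(1.0, p * k)))
    return out


def combo_groups(
    alterations: pd.DataFrame,
    values: Sequence[float],
    genes: Optional[Sequence[str]] = None,
    min_group_size: int = 5,
) -> Dict[str, np.ndarray]:
    """Group values by alteration-combination label.

    ``alterations`` is a samples x genes boolean DataFrame. Each sample is
    labelled by its altered genes in column order, e.g. "RAD21+/TERC+",
    or "WT" when none of the tracked genes is altered. Combinations with
    fewer than ``min_group_size`` samples are dropped (not pooled).
    """
    if genes is None:
        genes = list(alterations.columns)
    missing = [g for g in genes if g not in alterations.columns]
    if missing:
        raise ValueError(f"genes not in alteration matrix: {missing}")
    values = np.asarray(values, dtype=float)
    if len(values) != len(alterations):
        raise ValueError("values and alteration matrix have different lengths")
    sub = alterations[list(genes)].astype(bool).to_numpy()
    labels = []
    for row in sub:
        altered = [g for g, flag in zip(genes, row) if flag]
        labels.append("/".join(f"{g}+" for g in altered) if altered else "WT")
    grouped: Dict[str, List[float]] = {}
    for lab, v in zip(labels, values):
        grouped.setdefault(lab, []).append(v)
    return {
        lab: np.asarray(vv, dtype=float)
        for lab, vv in grouped.items()
        if len(vv) >= min_group_size
    }


@dataclass(frozen=True)
class MutexResult:
    observed_coverage: int
    n_perm: int
    p_value: float
    seed: int
    genes_used: Tuple[str, ...]


def mutual_exclusivity_perm(
    matrix: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> MutexResult:
    """Right-tailed permutation test for mutual exclusivity.

    Statistic: coverage (samples with >= 1 alteration among the genes).
    Null: each gene's column independently permuted across samples. The
    p-value uses the add-one estimator (1 + #{perm >= obs}) / (n_perm + 1)
    and is reproducible under a fixed seed. Genes never altered are
    excluded with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if genes is None:
        genes = list(matrix.columns)
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise ValueError(f"genes not in alteration matrix: {missing}")
    sub = matrix[list(genes)].astype(bool)
    keep = [g for g in genes if sub[g].any()]
    dropped = sorted(set(genes) - set(keep))
    if dropped:
        logger.warning("genes never altered, excluded: %s", dropped)
    if len(keep) < 2:
        raise ValueError("need >= 2 genes with at least one alteration")
    arr = sub[keep].to_numpy()
    observed = int(arr.any(axis=1).sum())
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permuted(arr, axis=0)  # permutes each column independently
        if int(perm.any(axis=1).sum()) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return MutexResult(observed, n_perm, p, seed, tuple(keep))
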