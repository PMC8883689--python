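"""Quartile-dichotomised enrichment screen for high telomeric content.

Within each disease group, samples in the top quartile of TRPM are labelled
"high" and samples in the bottom quartile "low" (middle samples are set
aside). For every feature (gene or cytoband), a 2x2 table of altered/WT vs
high/low is tested with Fisher's exact test; p-values are Bonferroni
corrected across the family of tests actually performed. A feature is
reported as a screen hit when it is enriched (adjusted p below alpha AND
odds ratio above 1) in at least ``min_diseases`` distinct disease groups —
the multi-disease requirement selects features with a pan-cancer rather
than single-histology effect.

The band-level variant runs the same machinery over an ordered list of
cytobands and extracts the *minimal region*: the maximal run of
consecutive significantly enriched bands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

ALTERED = "altered"
WILD_TYPE = "wild_type"

HIGH = "high"
LOW = "low"
MIDDLE = "middle"


@dataclass
class CohortRecord:
    """One sample entering the screen.

    ``alterations`` maps feature name to "altered"/"wild_type"; "altered"
    encodes known or likely pathogenic events only — variants of unknown
    significance belong to the wild-type stratum.
    """

    sample_id: str
    disease_group: str
    trpm: Optional[float]
    alterations: Dict[str, str] = field(default_factory=dict)
    age: Optional[float] = None
    tumor_purity: Optional[float] = None
    terra: Optional[float] = None


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a=altered&high, b=altered&low, c=WT&high, d=WT&low."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty contingency table")


@dataclass
class EnrichmentResult:
    feature: str
    disease_group: str
    table: ContingencyTable
    odds_ratio: float  # nan when undefined (zero margin or 0/0)
    p_value: float
    p_adjusted: float = 1.0


@dataclass(frozen=True)
class ScreenHit:
    feature: str
    supporting_diseases: frozenset[str]

    @property
    def n_diseases(self) -> int:
        return len(self.supporting_diseases)


@dataclass
class RegionResult:
    """Ordered per-band results plus the minimal significant region."""

    band_results: List[EnrichmentResult]
    minimal_region: Optional[Tuple[str, str]]  # (start_label, end_label)


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    min_diseases: int = 2
    min_group_size: int = 40
    bonferroni: str = "global"  # or "per-disease"
    band_mode: str = "bottom-quartile"  # or "rest"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.bonferroni not in ("global", "per-disease"):
            raise ValueError("bonferroni must be 'global' or 'per-disease'")
        if self.band_mode not in ("bottom-quartile", "rest"):
            raise ValueError("band_mode must be 'bottom-quartile' or 'rest'")


def dichotomize(records: Sequence[CohortRecord]) -> Dict[str, str]:
    """Label each sample high/low/middle by TRPM quartile within one disease.

    Q1 and Q3 use the linear-interpolation quantile definition; boundaries
    are inclusive (>= Q3 is high, <= Q1 is low). A sample qualifying for
    both (possible only when Q1 == Q3) is labelled middle, so fully
    degenerate groups produce no high/low samples at all.
    """
    values = np.array([r.trpm for r in records], dtype=float)
    if len(values) == 0:
        return {}
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    labels: Dict[str, str] = {}
    for rec, v in zip(records, values):
        is_high = v >= q3
        is_low = v <= q1
        if is_high and not is_low:
            labels[rec.sample_id] = HIGH
        elif is_low and not is_high:
            labels[rec.sample_id] = LOW
        else:
            labels[rec.sample_id] = MIDDLE
    return labels


def odds_ratio(table: ContingencyTable) -> float:
    """Sample cross-product ratio ad/bc; +inf when bc=0 and ad>0; nan for 0/0."""
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def fisher_exact(table: ContingencyTable) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p_value): the sample cross-product OR (not the
    conditional MLE) and the two-sided hypergeometric p (sum of table
    probabilities <= the observed probability at fixed margins). A zero row
    or column margin yields p=1 and an undefined (nan) odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio(table), float(p)


def build_table(
    records: Sequence[CohortRecord],
    labels: Dict[str, str],
    feature: str,
    comparator: str = LOW,
) -> ContingencyTable:
    """2x2 table of a feature for one disease's labelled samples.

    ``comparator`` is "low" (top vs bottom quartile) or "rest" (top
    quartile vs everything else). Samples whose alteration status for the
    feature is missing are excluded.
    """
    a = b = c = d = 0
    for rec in records:
        status = rec.alterations.get(feature)
        if status is None:
            continue
        lab = labels.get(rec.sample_id)
        if lab == HIGH:
            in_high, in_cmp = True, False
        elif comparator == LOW:
            in_high, in_cmp = False, lab == LOW
        else:  # vs rest: everyone not in the top quartile
            in_high, in_cmp = False, lab in (LOW, MIDDLE)
        if not (in_high or in_cmp):
            continue
        altered = status == ALTERED
        if altered and in_high:
            a += 1
        elif altered:
            b += 1
        elif in_high:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


@dataclass
class FeatureScreenOutcome:
    results: List[EnrichmentResult]
    hits: List[ScreenHit]
    skipped_diseases: Dict[str, str]
    n_excluded_missing_trpm: int = 0


def _split_by_disease(
    cohort: Sequence[CohortRecord], config: ScreenConfig
) -> Tuple[Dict[str, List[CohortRecord]], Dict[str, str], int]:
    """Partition records by disease, applying TRPM and group-size filters."""
    n_missing = 0
    groups: Dict[str, List[CohortRecord]] = {}
    for rec in cohort:
        if rec.trpm is None or not np.isfinite(rec.trpm):
            n_missing += 1
            continue
        groups.setdefault(rec.disease_group, []).append(rec)
    if n_missing:
        logger.info("excluded %d samples with undefined TRPM", n_missing)
    skipped: Dict[str, str] = {}
    kept: Dict[str, List[CohortRecord]] = {}
    for disease, recs in groups.items():
        if len(recs) < config.min_group_size:
            skipped[disease] = (
                f"{len(recs)} samples < min_group_size {config.min_group_size}"
            )
            logger.info("skipping %s: %s", disease, skipped[disease])
            continue
        kept[disease] = recs
    return kept, skipped, n_missing


def run_feature_screen(
    cohort: Sequence[CohortRecord],
    features: Optional[Sequence[str]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> FeatureScreenOutcome:
    """Per-(feature, disease) Fisher screen with Bonferroni and the hit filter.

    Hits are features enriched (p_adjusted < alpha and OR > 1) in at least
    ``config.min_diseases`` distinct disease groups. The Bonferroni family
    is every test actually performed (global, the conservative reading) or
    per-disease when configured.
    """
    if features is None:
        seen: dict[str, None] = {}
        for rec in cohort:
            for f in rec.alterations:
                seen.setdefault(f)
        features = list(seen)

    kept, skipped, n_missing = _split_by_disease(cohort, config)

    results: List[EnrichmentResult] = []
    for disease, recs in sorted(kept.items()):
        labels = dichotomize(recs)
        n_high = sum(1 for v in labels.values() if v == HIGH)
        n_low = sum(1 for v in labels.values() if v == LOW)
        if n_high == 0 or n_low == 0:
            skipped[disease] = "degenerate TRPM distribution (no high/low quartile)"
            logger.info("skipping %s: %s", disease, skipped[disease])
            continue
        for feature in features:
            table = build_table(recs, labels, feature, comparator=LOW)
            or_, p = fisher_exact(table)
            results.append(EnrichmentResult(feature, disease, table, or_, p))

    _apply_bonferroni(results, config)

    support: Dict[str, set] = {}
    for r in results:
        if r.p_adjusted < config.alpha and r.odds_ratio > 1:
            support.setdefault(r.feature, set()).add(r.disease_group)
    hits = [
        ScreenHit(feature=f, supporting_diseases=frozenset(dd))
        for f, dd in sorted(support.items())
        if len(dd) >= config.min_diseases
    ]
    return FeatureScreenOutcome(results, hits, skipped, n_missing)


def _apply_bonferroni(results: List[EnrichmentResult], config: ScreenConfig) -> None:
    if config.bonferroni == "global":
        m = len(results)
        for r in results:
            r.p_adjusted = min(1.0, r.p_value * m)
    else:
        per: Dict[str, int] = {}
        for r in results:
            per[r.disease_group] = per.get(r.disease_group, 0) + 1
        for r in results:
            r.p_adjusted = min(1.0, r.p_value * per[r.disease_group])


def run_band_screen(
    cohort: Sequence[CohortRecord],
    ordered_bands: Sequence[str],
    config: ScreenConfig = ScreenConfig(),
) -> RegionResult:
    """Band-level enrichment over an ordered band list, pooled across the cohort.

    Each band name must appear as a feature in the records' alterations
    (amplified -> "altered"). The comparator group is the bottom quartile by
    default ("rest" compares top quartile vs all remaining samples).
    Bonferroni is applied across the bands tested. The minimal region is
    the maximal run of consecutive bands with p_adjusted < alpha and
    OR > 1; ties between equal-length runs break toward the run containing
    the smallest adjusted p.
    """
    recs = [r for r in cohort if r.trpm is not None and np.isfinite(r.trpm)]
    if not recs:
        return RegionResult([], None)
    labels = dichotomize(recs)
    comparator = LOW if config.band_mode == "bottom-quartile" else "rest"
    results: List[EnrichmentResult] = []
    for band in ordered_bands:
        table = build_table(recs, labels, band, comparator=comparator)
        or_, p = fisher_exact(table)
        results.append(EnrichmentResult(band, "pooled", table, or_, p))
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_value * m)

    sig = [r.p_adjusted < config.alpha and r.odds_ratio > 1 for r in results]
    region = _maximal_run(results, sig)
    return RegionResult(results, region)


def _maximal_run(
    results: Sequence[EnrichmentResult], sig: Sequence[bool]
) -> Optional[Tuple[str, str]]:
    """Longest run of consecutive significant bands; ties -> smaller min p_adj."""
    best: Optional[Tuple[int, int]] = None
    best_p = math.inf
    i = 0
    n = len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        run_p = min(r.p_adjusted for r in results[i : j + 1])
        length = j - i + 1
        if best is None or length > (best[1] - best[0] + 1) or (
            length == (best[1] - best[0] + 1) and run_p < best_p
        ):
            best = (i, j)
            best_p = run_p
        i = j + 1
    if best is None:
        return None
    return results[best[0]].feature, results[best[1]].feature
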