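"""Tabular readers/writers shared across the pipeline.

All tables are headered, tab-delimited UTF-8 with NA for missing values;
nested results are JSON. Band features are prefixed ``band:`` when merged
into a cohort table so gene and band columns cannot collide.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .groupstats import MutexResult, PairwiseTestResult
from .screen import (
    CohortRecord,
    EnrichmentResult,
    RegionResult,
    ScreenHit,
)

BAND_PREFIX = "band:"
_META_COLS = ("sample_id", "disease_group", "trpm", "age", "tumor_purity", "terra")


def write_cohort_tsv(
    records: Sequence[CohortRecord],
    path: Union[str, Path],
    feature_order: Optional[Sequence[str]] = None,
) -> None:
    if feature_order is None:
        seen: dict[str, None] = {}
        for r in records:
            for f in r.alterations:
                seen.setdefault(f)
        feature_order = list(seen)
    rows = []
    for r in records:
        row: Dict[str, object] = {
            "sample_id": r.sample_id,
            "disease_group": r.disease_group,
            "trpm": r.trpm,
            "age": r.age,
            "tumor_purity": r.tumor_purity,
            "terra": r.terra,
        }
        for f in feature_order:
            row[f] = r.alterations.get(f)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLS) + list(feature_order))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path: Union[str, Path]) -> List[CohortRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    features = [c for c in df.columns if c not in _META_COLS]
    out: List[CohortRecord] = []
    for _, row in df.iterrows():
        alterations = {
            f: row[f] for f in features if isinstance(row[f], str)
        }

        def opt(col: str) -> Optional[float]:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        out.append(
            CohortRecord(
                sample_id=str(row["sample_id"]),
                disease_group=str(row["disease_group"]),
                trpm=opt("trpm"),
                alterations=alterations,
                age=opt("age"),
                tumor_purity=opt("tumor_purity"),
                terra=opt("terra"),
            )
        )
    return out


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tdisease_group\ta\tb\tc\td\todds_ratio\tp_value\tp_adjusted\n")
        for r in results:
            t = r.table
            fh.write(
                f"{r.feature}\t{r.disease_group}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{_fmt(r.odds_ratio)}\t{_fmt(r.p_value)}\t{_fmt(r.p_adjusted)}\n"
            )


def write_hits_json(hits: Sequence[ScreenHit], path: Union[str, Path]) -> None:
    payload = [
        {
            "feature": h.feature,
            "supporting_diseases": sorted(h.supporting_diseases),
            "n_diseases": h.n_diseases,
        }
        for h in hits
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_region_json(region: RegionResult, path: Union[str, Path]) -> None:
    payload = {
        "minimal_region": (
            None
            if region.minimal_region is None
            else {"start_label": region.minimal_region[0], "end_label": region.minimal_region[1]}
        ),
        "bands": [
            {
                "band": r.feature,
                "odds_ratio": None if math.isnan(r.odds_ratio) else
                ("inf" if math.isinf(r.odds_ratio) else r.odds_ratio),
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in region.band_results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_pairwise_tsv(
    results: Iterable[PairwiseTestResult], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("group_a\tgroup_b\tz_statistic\tp_value\tp_adjusted\n")
        for r in results:
            fh.write(
                f"{r.group_a}\t{r.group_b}\t{_fmt(r.z_statistic)}\t"
                f"{_fmt(r.p_value)}\t{_fmt(r.p_adjusted)}\n"
            )


def write_mutex_json(result: MutexResult, path: Union[str, Path]) -> None:
    payload = {
        "observed_coverage": result.observed_coverage,
        "n_perm": result.n_perm,
        "p": result.p_value,
        "seed": result.seed,
        "genes_used": list(result.genes_used),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
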