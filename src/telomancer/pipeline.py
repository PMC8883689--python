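"""End-to-end orchestration: simulate -> screen -> stats -> survival.

``run_pipeline`` performs no computation of its own; it wires the module
APIs together, derives per-stage seeds from one master seed (so reruns of
the same config are byte-identical), and writes every stage's outputs plus
the resolved configuration into a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import groupstats, io, screen, survival, synth
from .screen import ALTERED, ScreenConfig
from .telocontent import RepeatParams, compute_profile, write_profile_tsv

logger = logging.getLogger(__name__)


@dataclass(frozen=True, kw_only=True)
class RunConfig:
    """Configuration of a full synthetic run; serialisable to JSON."""

    seed: int
    out_dir: str
    n_reads: int = 50_000
    read_telomere_fraction: float = 0.01
    screen_config: ScreenConfig = ScreenConfig(min_group_size=40)
    repeat_params: RepeatParams = RepeatParams()
    cohort: Optional[synth.CohortSimParams] = None
    segments: Optional[synth.SegmentSimParams] = None
    survival_params: Optional[synth.SurvSimParams] = None
    mutex_n_perm: int = 999


def default_config(seed: int, out_dir: str) -> RunConfig:
    """A demonstration-scale configuration exercising every stage."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    diseases = tuple(
        synth.DiseaseSpec(name=n, n_samples=300)
        for n in ("breast", "prostate", "lung_adeno")
    )
    genes = tuple(
        [synth.GeneSpec(name=g, frequency=0.08) for g in groupstats.CANONICAL_GENES]
        + [synth.GeneSpec(name=g, frequency=0.10) for g in groupstats.CANDIDATE_GENES]
        + [synth.GeneSpec(name=f"null{i}", frequency=0.10) for i in range(6)]
    )
    planted = tuple(
        ((g, d.name), 2.5) for g in ("RAD21",) for d in diseases
    )
    cohort = synth.CohortSimParams(
        diseases=diseases,
        genes=genes,
        planted_effects=planted,
        exclusivity_group=("ATRX", "DAXX", "TERTp", "TERC", "RAD21"),
        seed=seeds[0],
    )
    segments = synth.default_segment_params(seed=seeds[1])
    surv = synth.SurvSimParams(seed=seeds[2])
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        cohort=cohort,
        segments=segments,
        survival_params=surv,
    )


def _resolve(config: RunConfig) -> RunConfig:
    if config.cohort is not None and config.segments is not None and config.survival_params is not None:
        return config
    base = default_config(config.seed, config.out_dir)
    return dataclasses.replace(
        config,
        cohort=config.cohort or base.cohort,
        segments=config.segments or base.segments,
        survival_params=config.survival_params or base.survival_params,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory."""
    config = _resolve(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(("reads", "mutex"), ss.spawn(2))
    }

    # Stage 1: reads -> telomeric-content profile.
    reads = synth.gen_reads(
        synth.ReadSimParams(
            n_reads=config.n_reads,
            telomere_fraction=config.read_telomere_fraction,
            seed=stage_seed["reads"],
        )
    )
    from .telocontent import profile_from_matrix

    profile = profile_from_matrix(
        reads.matrix, reads.lengths, config.repeat_params, "simulated_sample"
    )
    write_profile_tsv([profile], out / "telomere_profile.tsv")

    # Stage 2: cohort simulation + gene screen.
    records, truth = synth.gen_cohort(config.cohort)
    io.write_cohort_tsv(records, out / "cohort.tsv")
    outcome = screen.run_feature_screen(records, config=config.screen_config)
    io.write_enrichment_tsv(outcome.results, out / "screen_results.tsv")
    io.write_hits_json(outcome.hits, out / "screen_hits.json")

    # Stage 3: segments -> band screen -> minimal region.
    seg = synth.gen_segments(config.segments)
    band_cohort = seg.to_cohort()
    region = screen.run_band_screen(
        band_cohort, seg.band_labels(), config=config.screen_config
    )
    io.write_region_json(region, out / "band_region.json")

    # Stage 4: group statistics on the simulated cohort.
    genes = list(truth.alterations.columns)
    values = np.array([r.trpm for r in records])
    groups = groupstats.combo_groups(truth.alterations, values, genes=genes)
    if "WT" in groups and len(groups) >= 2:
        dunn = groupstats.dunn_test(groups, reference="WT")
        io.write_pairwise_tsv(dunn, out / "dunn_vs_wt.tsv")
    excl = [g for g in config.cohort.exclusivity_group if truth.alterations[g].any()]
    if len(excl) >= 2:
        mutex = groupstats.mutual_exclusivity_perm(
            truth.alterations,
            genes=excl,
            n_perm=config.mutex_n_perm,
            seed=stage_seed["mutex"],
        )
        io.write_mutex_json(mutex, out / "mutual_exclusivity.json")

    # Stage 5: survival.
    surv_records, surv_truth = synth.gen_survival(config.survival_params)
    groups_present = sorted({r.group for r in surv_records})
    surv_payload: Dict[str, object] = {"groups": {}}
    for g in groups_present:
        curve = survival.km_fit([r for r in surv_records if r.group == g])
        med = survival.median_survival(curve)
        lo, hi = survival.median_survival_ci(curve)
        surv_payload["groups"][g] = {
            "median_os": med,
            "ci_low": lo,
            "ci_high": hi,
            "n": curve.n_records,
        }
        survival.write_curve_tsv(curve, out / f"km_curve_{g}.tsv", group=g)
    if len(groups_present) == 2:
        chi2, p = survival.logrank(surv_records, *groups_present)
        surv_payload["logrank"] = {"chi_square": chi2, "p": p}
    (out / "survival.json").write_text(json.dumps(surv_payload, indent=2) + "\n")

    (out / "resolved_config.json").write_text(
        json.dumps(
            {"version": __version__, "config": _config_to_jsonable(config)}, indent=2
        )
        + "\n"
    )
    return out


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _config_to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_config_to_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _config_to_jsonable(v) for k, v in obj.items()}
    return obj
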