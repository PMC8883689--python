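"""Quartile dichotomisation, Fisher testing, hit filter and minimal region."""

import math

import numpy as np
import pytest

from oracles import all_tables, fisher_enum, fisher_or

from telomancer.screen import (
    ALTERED,
    HIGH,
    LOW,
    MIDDLE,
    WILD_TYPE,
    CohortRecord,
    ContingencyTable,
    ScreenConfig,
    dichotomize,
    fisher_exact,
    run_band_screen,
    run_feature_screen,
)
from telomancer import synth


def _records(trpms, disease="d", alterations=None):
    return [
        CohortRecord(
            sample_id=f"{disease}{i}",
            disease_group=disease,
            trpm=float(v),
            alterations=dict(alterations[i]) if alterations else {},
        )
        for i, v in enumerate(trpms)
    ]


class TestDichotomize:
    def test_one_to_eight(self):
        labels = dichotomize(_records(range(1, 9)))
        lows = {s for s, l in labels.items() if l == LOW}
        highs = {s for s, l in labels.items() if l == HIGH}
        assert lows == {"d0", "d1"}   # trpm 1, 2 (Q1 = 2.75)
        assert highs == {"d6", "d7"}  # trpm 7, 8 (Q3 = 6.25)

    def test_all_equal_degenerate(self):
        labels = dichotomize(_records([5.0] * 10))
        assert set(labels.values()) == {MIDDLE}

    def test_four_distinct(self):
        labels = dichotomize(_records([10, 20, 30, 40]))
        assert sum(1 for v in labels.values() if v == HIGH) == 1
        assert sum(1 for v in labels.values() if v == LOW) == 1

    def test_monotone_transform_invariance(self, rng):
        vals = rng.lognormal(7, 1, 60)
        base = dichotomize(_records(vals))
        transformed = dichotomize(_records(np.log(vals)))
        assert base == transformed

    def test_order_invariance(self, rng):
        vals = list(rng.lognormal(7, 1, 40))
        recs = _records(vals)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert dichotomize(recs) == dichotomize(shuffled)


class TestFisher:
    def test_fully_separated(self):
        or_, p = fisher_exact(ContingencyTable(5, 0, 0, 5))
        assert math.isinf(or_)
        assert p == pytest.approx(1 / 126)

    def test_independent(self):
        or_, p = fisher_exact(ContingencyTable(2, 2, 2, 2))
        assert or_ == 1.0
        assert p == 1.0

    def test_eight_two(self):
        or_, p = fisher_exact(ContingencyTable(8, 2, 2, 8))
        assert or_ == 16.0
        assert p == pytest.approx(fisher_enum(8, 2, 2, 8))

    def test_zero_margin(self):
        or_, p = fisher_exact(ContingencyTable(0, 0, 3, 4))
        assert math.isnan(or_)
        assert p == 1.0

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 41))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            or_, p = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_enum(int(a), int(b), int(c), int(d)), abs=1e-12)
            oracle_or = fisher_or(int(a), int(b), int(c), int(d))
            if math.isnan(oracle_or):
                assert math.isnan(or_)
            else:
                assert or_ == oracle_or


def _planted_cohort(seed, delta=6.0, n_per=200, n_dis=3, n_genes=18):
    diseases = tuple(synth.DiseaseSpec(name=f"d{i}", n_samples=n_per) for i in range(n_dis))
    genes = tuple(synth.GeneSpec(name=f"g{i}", frequency=0.10) for i in range(n_genes))
    planted = tuple((("g0", d.name), delta) for d in diseases)
    records, truth = synth.gen_cohort(
        synth.CohortSimParams(diseases=diseases, genes=genes, planted_effects=planted, seed=seed)
    )
    return records, truth


class TestFeatureScreen:
    def test_planted_feature_sole_hit(self):
        records, _ = _planted_cohort(seed=42)
        out = run_feature_screen(records)
        assert {h.feature for h in out.hits} == {"g0"}
        assert all(h.n_diseases >= 2 for h in out.hits)

    def test_all_wild_type_never_hit(self):
        records, _ = _planted_cohort(seed=43)
        for r in records:
            r.alterations["dead_gene"] = WILD_TYPE
        out = run_feature_screen(records)
        dead = [r for r in out.results if r.feature == "dead_gene"]
        assert dead and all(r.p_value == 1.0 for r in dead)
        assert "dead_gene" not in {h.feature for h in out.hits}

    def test_single_disease_enrichment_not_a_hit(self):
        # Extreme association in exactly one disease group.
        alts = []
        trpms = []
        for i in range(80):
            high = i < 40
            trpms.append(1000.0 + i + (5000.0 if high else 0.0))
            alts.append({"g": ALTERED if high else WILD_TYPE})
        records = _records(trpms, disease="only", alterations=alts)
        out = run_feature_screen(records, features=["g"])
        assert any(r.p_adjusted < 0.05 and r.odds_ratio > 1 for r in out.results)
        assert out.hits == []

    def test_small_disease_skipped_with_reason(self):
        records = _records(range(10), disease="tiny")
        out = run_feature_screen(records, features=["g"])
        assert "tiny" in out.skipped_diseases
        assert out.results == []

    def test_undefined_trpm_excluded(self):
        records, _ = _planted_cohort(seed=44, n_dis=1)
        records[0].trpm = None
        out = run_feature_screen(records)
        assert out.n_excluded_missing_trpm == 1

    def test_determinism(self):
        records, _ = _planted_cohort(seed=45)
        out1 = run_feature_screen(records)
        out2 = run_feature_screen(records)
        assert [(r.feature, r.disease_group, r.p_value, r.p_adjusted) for r in out1.results] == [
            (r.feature, r.disease_group, r.p_value, r.p_adjusted) for r in out2.results
        ]

    def test_alpha_monotonicity(self):
        records, _ = _planted_cohort(seed=46)
        strict = {h.feature for h in run_feature_screen(records, config=ScreenConfig(alpha=0.05)).hits}
        loose = {h.feature for h in run_feature_screen(records, config=ScreenConfig(alpha=1.0)).hits}
        assert strict <= loose

    def test_per_disease_bonferroni(self):
        records, _ = _planted_cohort(seed=47, n_dis=2, n_genes=5)
        glob = run_feature_screen(records, config=ScreenConfig(bonferroni="global"))
        per = run_feature_screen(records, config=ScreenConfig(bonferroni="per-disease"))
        m_global = len(glob.results)
        for rg, rp in zip(glob.results, per.results):
            assert rg.p_adjusted == pytest.approx(min(1.0, rg.p_value * m_global))
            assert rp.p_adjusted == pytest.approx(min(1.0, rp.p_value * 5))


class TestBandScreen:
    def test_no_amplification_empty_region(self):
        recs = _records(np.linspace(100, 5000, 200))
        for r in recs:
            r.alterations = {"q1": WILD_TYPE, "q2": WILD_TYPE}
        region = run_band_screen(recs, ["q1", "q2"])
        assert region.minimal_region is None
        assert all(r.p_value == 1.0 for r in region.band_results)

    def test_single_significant_band(self, rng):
        n = 400
        trpm = rng.lognormal(7, 0.8, n)
        amp = rng.random(n) < 0.10
        trpm[amp] *= 3.0
        recs = []
        for i in range(n):
            alts = {
                "q1": ALTERED if rng.random() < 0.2 else WILD_TYPE,
                "q2": ALTERED if amp[i] else WILD_TYPE,
                "q3": ALTERED if rng.random() < 0.2 else WILD_TYPE,
            }
            recs.append(CohortRecord(f"s{i}", "pooled", float(trpm[i]), alts))
        region = run_band_screen(recs, ["q1", "q2", "q3"])
        assert region.minimal_region == ("q2", "q2")

    def test_planted_region_recovered(self):
        params = synth.default_segment_params(seed=314)
        res = synth.gen_segments(params)
        region = run_band_screen(res.to_cohort(), res.band_labels())
        assert region.minimal_region == (res.causal_bands[0], res.causal_bands[-1])

    def test_vs_rest_mode_runs(self):
        params = synth.default_segment_params(seed=315)
        res = synth.gen_segments(params)
        region = run_band_screen(
            res.to_cohort(), res.band_labels(), config=ScreenConfig(band_mode="rest")
        )
        sig = {r.feature for r in region.band_results if r.p_adjusted < 0.05 and r.odds_ratio > 1}
        assert set(res.causal_bands) <= sig
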