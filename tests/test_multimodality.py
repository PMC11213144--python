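"""Model ranking, per-electrode decisions, test battery, region summaries."""
import numpy as np
import pandas as pd
import pytest

from neurofuse.features import ModelSpec
from neurofuse.multimodality import (
    AlignmentAnalysis,
    decide_electrode,
    rank_models,
    region_summary,
    run_comparison,
    run_multimodality_tests,
    trained_vs_random,
)

N_BINS = 30


def make_analysis(alignment, model_data, n_elec=1):
    """Fabricate an AlignmentAnalysis.

    ``model_data``: name -> (spec, surviving mask (n_elec, N_BINS) or count,
    score level).  Scores are constant at the given level over all bins.
    """
    specs, surviving, scores, ci = {}, {}, {}, {}
    for name, (spec, surv, level) in model_data.items():
        specs[name] = spec
        if isinstance(surv, (int, np.integer)):
            mask = np.zeros((n_elec, N_BINS), bool)
            mask[:, :surv] = True
        else:
            mask = np.asarray(surv, bool)
        surviving[name] = mask
        scores[name] = np.full((n_elec, N_BINS), float(level))
        ci[name] = np.where(mask, 0.05, -0.05)
    return AlignmentAnalysis(
        alignment=alignment,
        electrode_ids=[f"E{i}" for i in range(n_elec)],
        specs=specs,
        surviving=surviving,
        test_scores=scores,
        val_ci_low=ci,
        n_bins=N_BINS,
    )


MM = ModelSpec("mm", "x", "multimodal", True)
MM2 = ModelSpec("mm2", "x", "multimodal", True)
UNI = ModelSpec("uni", "x", "vision", True)
LIN = ModelSpec("lin", "x", "linear_integration", True)


class TestRankModels:
    def test_bin_mean_ordering_matches_sort_oracle(self, rng):
        analysis = make_analysis("language", {
            "a": (MM, 12, 0.0), "b": (UNI, 12, 0.0),
            "c": (MM2, 12, 0.0), "d": (LIN, 12, 0.0),
        })
        levels = {"a": 0.3, "b": 0.2, "c": 0.45, "d": 0.1}
        for name, lvl in levels.items():
            analysis.test_scores[name] = np.full((1, N_BINS), lvl)
            analysis.test_scores[name][0, :12] += rng.normal(0, 0.01, 12)
        ranked = rank_models(analysis, 0)
        oracle = sorted(
            levels,
            key=lambda m: -np.mean(analysis.test_scores[m][0, analysis.surviving[m][0]]),
        )
        assert ranked == oracle

    def test_model_without_surviving_bins_removed(self):
        analysis = make_analysis("language", {"a": (MM, 12, 0.3), "b": (UNI, 0, 0.9)})
        assert rank_models(analysis, 0) == ["a"]

    def test_tie_breaks_lexicographic(self):
        analysis = make_analysis("language", {"b": (MM, 12, 0.3), "a": (UNI, 12, 0.3)})
        assert rank_models(analysis, 0) == ["a", "b"]


class TestDecideElectrode:
    def test_sole_surviving_candidate_wins_by_default(self):
        analysis = make_analysis("language", {"mm": (MM, 12, 0.3), "uni": (UNI, 0, 0.0)})
        out = decide_electrode(analysis, 0, ["mm"], ["uni"])
        assert out.status == "default_pass" and out.passed and out.won_by_default

    def test_sole_surviving_competitor_fails_by_default(self):
        analysis = make_analysis("language", {"mm": (MM, 4, 0.3), "uni": (UNI, 15, 0.3)})
        out = decide_electrode(analysis, 0, ["mm"], ["uni"])
        assert out.status == "default_fail" and not out.passed

    def test_no_eligible_model_excluded(self):
        analysis = make_analysis("language", {"mm": (MM, 4, 0.3), "uni": (UNI, 9, 0.3)})
        out = decide_electrode(analysis, 0, ["mm"], ["uni"])
        assert out.status == "excluded"

    def test_top_ranked_competitor_fails_without_test(self):
        analysis = make_analysis("language", {"mm": (MM, 12, 0.2), "uni": (UNI, 12, 0.5)})
        out = decide_electrode(analysis, 0, ["mm"], ["uni"])
        assert not out.passed and out.winner == "uni"

    def test_candidate_beating_competitor_significant(self, rng):
        analysis = make_analysis("language", {"mm": (MM, 15, 0.0), "uni": (UNI, 15, 0.0)})
        analysis.test_scores["mm"][0] = 0.5 + rng.normal(0, 0.01, N_BINS)
        analysis.test_scores["uni"][0] = 0.3 + rng.normal(0, 0.01, N_BINS)
        df, outcomes = run_comparison(analysis, ["mm"], ["uni"], B2=500)
        assert outcomes[0].status == "compared"
        assert outcomes[0].passed
        assert df.loc[0, "q"] <= 0.05

    def test_candidate_without_margin_not_significant(self, rng):
        analysis = make_analysis("language", {"mm": (MM, 20, 0.0), "uni": (UNI, 20, 0.0)})
        noise = rng.normal(0, 0.1, N_BINS)
        analysis.test_scores["mm"][0] = 0.3 + noise + 0.001
        analysis.test_scores["uni"][0] = 0.3 + rng.normal(0, 0.1, N_BINS)
        df, outcomes = run_comparison(analysis, ["mm"], ["uni"], B2=500)
        for o in outcomes:
            if o.status == "compared":
                assert o.passed == (o.diff_test.significant and o.diff_test.mean_diff > 0)

    def test_too_few_shared_bins_skipped(self):
        surv_a = np.zeros((1, N_BINS), bool); surv_a[0, :12] = True
        surv_b = np.zeros((1, N_BINS), bool); surv_b[0, 20:] = True  # 10 bins, disjoint
        analysis = make_analysis("language", {
            "mm": (MM, surv_a, 0.5), "uni": (UNI, surv_b, 0.3)})
        out = decide_electrode(analysis, 0, ["mm"], ["uni"])
        assert out.status == "skipped" and not out.passed

    def test_irrelevant_candidate_never_surviving_changes_nothing(self):
        base = make_analysis("language", {"mm": (MM, 12, 0.4), "uni": (UNI, 0, 0.0)})
        extra = make_analysis("language", {
            "mm": (MM, 12, 0.4), "uni": (UNI, 0, 0.0), "mm2": (MM2, 0, 0.9)})
        a = decide_electrode(base, 0, ["mm"], ["uni"])
        b = decide_electrode(extra, 0, ["mm", "mm2"], ["uni"])
        assert (a.status, a.passed, a.winner) == (b.status, b.passed, b.winner)


def _two_alignment_world(rng):
    """Three electrodes: 0 multimodal both alignments, 1 multimodal in
    language only, 2 nothing survives."""
    def analysis(alignment):
        n_elec = 3
        surv_mm = np.zeros((n_elec, N_BINS), bool)
        surv_mm[0, :15] = True
        if alignment == "language":
            surv_mm[1, :15] = True
        surv_uni = np.zeros((n_elec, N_BINS), bool)
        data = {
            "slip-combo-vision": (
                ModelSpec("slip-combo-vision", "vit", "multimodal", True,
                          "vision_encoder"), surv_mm, 0.5),
            "slip-simclr": (ModelSpec("slip-simclr", "vit", "vision", True),
                            surv_uni, 0.0),
            "simcse": (ModelSpec("simcse", "t", "language", True), surv_uni, 0.0),
            "multiconcat": (LIN, surv_uni, 0.0),
            "multilin": (ModelSpec("multilin", "x", "linear_integration", True),
                         surv_uni, 0.0),
        }
        return make_analysis(alignment, data, n_elec=n_elec)
    return {"language": analysis("language"), "vision": analysis("vision")}


class TestBattery:
    def test_label_inclusion_invariants(self, rng):
        analyses = _two_alignment_world(rng)
        result = run_multimodality_tests(analyses, B2=300)
        lab = result.labels
        assert (lab["strict"] <= lab["weak"]).all()
        assert (lab["strict_slip"] <= lab["weak_slip"]).all()
        assert (lab["nonlinear"] <= lab["strict"]).all()

    def test_weak_vs_strict_membership(self, rng):
        result = run_multimodality_tests(_two_alignment_world(rng), B2=300)
        lab = result.labels.set_index("electrode_id")
        assert lab.loc["E0", "strict"]
        assert lab.loc["E1", "weak"] and not lab.loc["E1", "strict"]
        assert not lab.loc["E2", "weak"]
        # SLIP contrast: combo survives, simclr shows no signal
        assert lab.loc["E0", "strict_slip"]
        # linear baselines show no signal -> beaten by default in test 5
        assert lab.loc["E0", "nonlinear"]


class TestTrainedVsRandom:
    def test_trained_wins_when_random_uninformative(self):
        data = {
            "mm": (MM, 15, 0.4),
            "mm-random": (ModelSpec("mm-random", "x", "multimodal", False), 0, 0.0),
        }
        analysis = make_analysis("language", data)
        df = trained_vs_random(analysis)
        assert df.loc[0, "winner_is_trained"]
        assert df.loc[0, "mean_score_diff"] == pytest.approx(0.4)

    def test_identical_models_not_significant(self, rng):
        scores = 0.3 + rng.normal(0, 0.05, N_BINS)
        data = {
            "mm": (MM, 15, 0.0),
            "mm-random": (ModelSpec("mm-random", "x", "multimodal", False), 15, 0.0),
        }
        analysis = make_analysis("language", data)
        analysis.test_scores["mm"][0] = scores
        analysis.test_scores["mm-random"][0] = scores.copy()
        df = trained_vs_random(analysis, B2=300)
        assert not (df["status"].eq("compared") & df["passed"]).any()


class TestRegionSummary:
    def labels(self, n, passing):
        flags = np.zeros(n, bool)
        flags[:passing] = True
        return pd.DataFrame({
            "electrode_id": [f"E{i}" for i in range(n)], "weak": flags})

    def table(self, n, region="superiortemporal"):
        return pd.DataFrame({
            "electrode_id": [f"E{i}" for i in range(n)], "dkt_region": region})

    def test_three_of_twelve_is_25_percent(self):
        out = region_summary(self.labels(12, 3), self.table(12))
        assert out.loc[0, "pct_weak"] == pytest.approx(25.0)
        assert out.loc[0, "n_weak"] == 3

    def test_zero_passers_zero_percent(self):
        out = region_summary(self.labels(5, 0), self.table(5))
        assert out.loc[0, "pct_weak"] == 0.0

    def test_unlabeled_electrode_raises_with_ids(self):
        table = self.table(4).iloc[:3]
        with pytest.raises(ValueError, match="E3"):
            region_summary(self.labels(4, 1), table)

    def test_percentages_recompute_from_label_file(self, rng):
        n = 40
        labels = pd.DataFrame({
            "electrode_id": [f"E{i}" for i in range(n)],
            "weak": rng.uniform(size=n) < 0.3,
        })
        table = pd.DataFrame({
            "electrode_id": labels["electrode_id"],
            "dkt_region": [["a", "b"][i % 2] for i in range(n)],
        })
        out = region_summary(labels, table).set_index("dkt_region")
        merged = labels.merge(table, on="electrode_id")
        for region, sub in merged.groupby("dkt_region"):
            assert out.loc[region, "n_weak"] == sub["weak"].sum()
            assert out.loc[region, "pct_weak"] == pytest.approx(
                100 * sub["weak"].mean())
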