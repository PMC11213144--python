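"""Model ranking, the multimodality test battery, and region summaries.

Per electrode and alignment, models are ranked by their mean bootstrapped
test-split score over the bins that survive validation-CI filtering.  An
electrode "prefers" a candidate model class when either (a) every model with
at least ``min_bins`` surviving bins belongs to the candidate side (win by
default -- the paper's single-surviving-model rule generalized to one-sided
survival), or (b) the top-ranked model is a candidate and a paired
bin-bootstrap against the best-ranked competitor is significant after
Benjamini-Hochberg correction across electrodes.

The battery, in order of stringency:

1. weak: any multimodal or linearly-integrated model beats all unimodal
   models in either alignment;
2. weak SLIP: the multimodally-trained vision tower beats its
   architecture/data-matched unimodal control in either alignment;
3. strict: test 1 in both alignments;
4. strict SLIP: test 2 in both alignments;
5. non-linear integration: among strict passers, the best multimodal model
   also beats both linear-integration baselines (both alignments).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinnedResponses
from .encoding import FoldPlan, DEFAULT_LAMBDA_GRID, encode_bank
from .features import FeatureSet, ModelSpec, effective_modality
from .inference import (
    BootstrapResult,
    DiffTest,
    Resamples,
    bh_fdr,
    bootstrap_encode,
    draw_resamples,
    filter_bins,
    paired_bin_bootstrap,
)

logger = logging.getLogger(__name__)

SLIP_CANDIDATE = "slip-combo-vision"
SLIP_COMPETITOR = "slip-simclr"


# ---------------------------------------------------------------------------
# per-alignment analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignmentAnalysis:
    """Filtered, bootstrapped encoding outcomes for one alignment."""

    alignment: str
    electrode_ids: list[str]
    specs: dict[str, ModelSpec]
    surviving: dict[str, np.ndarray]  # model -> (n_elec, n_bins) bool
    test_scores: dict[str, np.ndarray]  # model -> (n_elec, n_bins) bootstrap mean
    val_ci_low: dict[str, np.ndarray]
    n_bins: int

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    @property
    def model_names(self) -> list[str]:
        return list(self.specs)

    def surviving_count(self, model: str, e: int) -> int:
        return int(self.surviving[model][e].sum())


def analyze_alignment(
    feature_sets: Mapping[str, FeatureSet],
    responses: BinnedResponses,
    plan: FoldPlan,
    B: int = 1000,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    selection: str = "electrode",
    refit_selection: bool = True,
    alignment: str | None = None,
) -> AlignmentAnalysis:
    """Encode + bootstrap every model against every electrode.

    The same event resamples (drawn once from ``seed``) are applied to every
    model so that per-resample scores are comparable across models.
    """
    n_elec, n_events, n_bins = responses.data.shape
    if n_events != plan.n_events:
        raise ValueError("responses and fold plan disagree on event count")
    resamples = draw_resamples(n_events, plan, B, seed)
    surviving, test_scores, val_ci_low = {}, {}, {}
    Y = np.moveaxis(responses.data, 1, 0).reshape(n_events, n_elec * n_bins)
    groups = np.repeat(np.arange(n_elec), n_bins)
    for name, fs in feature_sets.items():
        if list(fs.event_ids) != list(responses.event_ids):
            raise ValueError(f"event ids of model {name!r} do not match responses")
        boot = bootstrap_encode(
            fs.matrices(),
            Y,
            plan,
            resamples=resamples,
            lambda_grid=lambda_grid,
            selection=selection,
            groups=groups,
            refit_selection=refit_selection,
        )
        surviving[name] = filter_bins(boot, shape=(n_elec, n_bins))
        test_scores[name] = boot.mean("test").reshape(n_elec, n_bins)
        val_ci_low[name] = boot.ci["validation"][:, 0].reshape(n_elec, n_bins)
        logger.info(
            "model %s: %.1f surviving bins/electrode on average",
            name,
            surviving[name].sum(axis=1).mean(),
        )
    return AlignmentAnalysis(
        alignment=alignment or responses_alignment_guess(responses),
        electrode_ids=list(responses.electrode_ids),
        specs={name: fs.model for name, fs in feature_sets.items()},
        surviving=surviving,
        test_scores=test_scores,
        val_ci_low=val_ci_low,
        n_bins=n_bins,
    )


def responses_alignment_guess(responses: BinnedResponses) -> str:
    first = str(responses.event_ids[0]) if len(responses.event_ids) else ""
    return "vision" if first.startswith("vis") else "language"


# ---------------------------------------------------------------------------
# ranking and per-electrode decisions
# ---------------------------------------------------------------------------

def rank_models(
    analysis: AlignmentAnalysis, e: int, models: Sequence[str] | None = None
) -> list[str]:
    """Models with surviving bins, ordered by mean test score over their own
    surviving bins (descending); ties break lexicographically by name."""
    models = list(models) if models is not None else analysis.model_names
    scored = []
    for m in models:
        mask = analysis.surviving[m][e]
        if not mask.any():
            continue  # model removed from this electrode's analysis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            score = float(np.nanmean(analysis.test_scores[m][e, mask]))
        scored.append((m, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [m for m, _ in scored]


@dataclass
class ComparisonOutcome:
    electrode_id: str
    alignment: str
    status: str  # excluded | default_pass | default_fail | compared | skipped
    winner: str | None = None
    runner_up: str | None = None
    won_by_default: bool = False
    diff_test: DiffTest | None = None
    reason: str = ""
    passed: bool = False


def decide_electrode(
    analysis: AlignmentAnalysis,
    e: int,
    candidate_set: Sequence[str],
    competitor_set: Sequence[str],
    min_bins: int = 10,
    B2: int = 1000,
    seed: int = 0,
) -> ComparisonOutcome:
    """Does a candidate-class model beat the competitor class on electrode e?

    The returned outcome is provisional for ``status == "compared"``: its
    ``diff_test.p_value`` still needs family-wise FDR correction before
    ``passed`` is final (see :func:`run_comparison`).
    """
    eid = analysis.electrode_ids[e]
    candidates = [m for m in candidate_set if m in analysis.specs]
    competitors = [m for m in competitor_set if m in analysis.specs]
    pool = candidates + competitors
    eligible = [m for m in pool if analysis.surviving_count(m, e) >= min_bins]
    if not eligible:
        return ComparisonOutcome(eid, analysis.alignment, "excluded",
                                 reason="no model has enough surviving bins")
    cand_e = [m for m in eligible if m in candidates]
    comp_e = [m for m in eligible if m in competitors]
    ranked = rank_models(analysis, e, eligible)
    if cand_e and not comp_e:
        return ComparisonOutcome(eid, analysis.alignment, "default_pass",
                                 winner=ranked[0], won_by_default=True, passed=True)
    if comp_e and not cand_e:
        return ComparisonOutcome(eid, analysis.alignment, "default_fail",
                                 winner=ranked[0], won_by_default=True, passed=False)
    top = ranked[0]
    if top not in candidates:
        runner = next((m for m in ranked[1:]), None)
        return ComparisonOutcome(eid, analysis.alignment, "compared_fail_rank",
                                 winner=top, runner_up=runner, passed=False,
                                 reason="top-ranked model is not a candidate")
    best_comp = next(m for m in ranked if m in competitors)
    shared = analysis.surviving[top][e] & analysis.surviving[best_comp][e]
    if int(shared.sum()) < min_bins:
        return ComparisonOutcome(eid, analysis.alignment, "skipped",
                                 winner=top, runner_up=best_comp, passed=False,
                                 reason=f"only {int(shared.sum())} shared bins")
    dt = paired_bin_bootstrap(
        analysis.test_scores[top][e, shared],
        analysis.test_scores[best_comp][e, shared],
        B2=B2,
        seed=seed,
        model_a=top,
        model_b=best_comp,
    )
    return ComparisonOutcome(eid, analysis.alignment, "compared",
                             winner=top, runner_up=best_comp, diff_test=dt)


def _electrode_seed(seed: int, e: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, salt, e]).generate_state(1)[0] % (2**31))


def run_comparison(
    analysis: AlignmentAnalysis,
    candidate_set: Sequence[str],
    competitor_set: Sequence[str],
    alpha: float = 0.05,
    min_bins: int = 10,
    B2: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ComparisonOutcome]]:
    """Decide every electrode and BH-correct the compared p-values.

    The electrodes of one (test, alignment) analysis form one FDR family.
    """
    outcomes = [
        decide_electrode(analysis, e, candidate_set, competitor_set,
                         min_bins=min_bins, B2=B2, seed=_electrode_seed(seed, e))
        for e in range(analysis.n_electrodes)
    ]
    compared = [o for o in outcomes if o.status == "compared"]
    if compared:
        q, reject = bh_fdr([o.diff_test.p_value for o in compared], alpha=alpha)
        for o, qi, rej in zip(compared, q, reject):
            o.diff_test.q_value = float(qi)
            o.diff_test.significant = bool(rej)
            o.passed = bool(rej) and o.diff_test.mean_diff > 0
    rows = []
    for o in outcomes:
        dt = o.diff_test
        rows.append({
            "electrode_id": o.electrode_id,
            "alignment": o.alignment,
            "status": o.status,
            "winner": o.winner,
            "runner_up": o.runner_up,
            "won_by_default": o.won_by_default,
            "n_shared_bins": dt.n_bins if dt else np.nan,
            "mean_diff": dt.mean_diff if dt else np.nan,
            "ci_low": dt.ci[0] if dt else np.nan,
            "ci_high": dt.ci[1] if dt else np.nan,
            "p": dt.p_value if dt else np.nan,
            "q": dt.q_value if dt else np.nan,
            "passed": o.passed,
            "reason": o.reason,
        })
    return pd.DataFrame(rows), outcomes


def run_nonlinear_comparison(
    analysis: AlignmentAnalysis,
    multimodal_models: Sequence[str],
    linear_models: Sequence[str],
    restrict_to: Sequence[str],
    alpha: float = 0.05,
    min_bins: int = 10,
    B2: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Test 5 inner loop: best multimodal model must beat BOTH linear models.

    Run only on ``restrict_to`` electrode ids (the strict-test passers).  A
    linear baseline with fewer than ``min_bins`` surviving bins is beaten by
    default; otherwise a paired bin bootstrap is required, BH-corrected over
    all (electrode, baseline) tests of this alignment as one family.
    """
    restrict = set(restrict_to)
    records: list[dict] = []
    pending: list[tuple[int, DiffTest]] = []
    for e in range(analysis.n_electrodes):
        eid = analysis.electrode_ids[e]
        if eid not in restrict:
            continue
        mm_eligible = [
            m for m in multimodal_models if analysis.surviving_count(m, e) >= min_bins
        ]
        if not mm_eligible:
            records.append({"electrode_id": eid, "passed": False,
                            "best_multimodal": None,
                            "reason": "no multimodal model has enough surviving bins"})
            continue
        best_mm = rank_models(analysis, e, mm_eligible)[0]
        rec = {"electrode_id": eid, "best_multimodal": best_mm, "passed": True,
               "reason": ""}
        for j, lin in enumerate(linear_models):
            if lin not in analysis.specs:
                continue
            if analysis.surviving_count(lin, e) < min_bins:
                rec[f"beats_{lin}"] = True  # baseline shows no signal
                continue
            shared = analysis.surviving[best_mm][e] & analysis.surviving[lin][e]
            if int(shared.sum()) < min_bins:
                rec[f"beats_{lin}"] = False
                rec["reason"] = f"too few shared bins with {lin}"
                continue
            dt = paired_bin_bootstrap(
                analysis.test_scores[best_mm][e, shared],
                analysis.test_scores[lin][e, shared],
                B2=B2,
                seed=_electrode_seed(seed, e, salt=j + 1),
                model_a=best_mm,
                model_b=lin,
            )
            rec[f"beats_{lin}"] = dt  # placeholder, resolved after FDR
            pending.append((len(records), dt))
        records.append(rec)
    if pending:
        q, reject = bh_fdr([dt.p_value for _, dt in pending], alpha=alpha)
        for (_, dt), qi, rej in zip(pending, q, reject):
            dt.q_value = float(qi)
            dt.significant = bool(rej)
    for rec in records:
        for key in list(rec):
            if isinstance(rec[key], DiffTest):
                dt = rec[key]
                rec[key] = bool(dt.significant and dt.mean_diff > 0)
        beats = [v for k, v in rec.items() if k.startswith("beats_")]
        rec["passed"] = bool(rec["passed"] and beats and all(beats))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# the five-test battery
# ---------------------------------------------------------------------------

def _model_classes(specs: Mapping[str, ModelSpec]):
    eff = {name: effective_modality(s) for name, s in specs.items()}
    integration = [n for n, m in eff.items() if m in ("multimodal", "linear_integration")]
    unimodal = [n for n, m in eff.items() if m in ("vision", "language")]
    multimodal_only = [n for n, m in eff.items() if m == "multimodal"]
    linear = [n for n, m in eff.items() if m == "linear_integration"]
    return integration, unimodal, multimodal_only, linear


@dataclass
class MultimodalityResult:
    labels: pd.DataFrame
    comparisons: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def run_multimodality_tests(
    analyses: Mapping[str, AlignmentAnalysis],
    alpha: float = 0.05,
    min_bins: int = 10,
    B2: int = 1000,
    seed: int = 0,
    slip_candidate: str = SLIP_CANDIDATE,
    slip_competitor: str = SLIP_COMPETITOR,
) -> MultimodalityResult:
    """Run the five multimodality tests across both alignments."""
    if set(analyses) != {"language", "vision"}:
        raise ValueError("analyses must cover exactly the language and vision alignments")
    first = analyses["language"]
    electrode_ids = first.electrode_ids
    for a in analyses.values():
        if a.electrode_ids != electrode_ids:
            raise ValueError("alignments must share the electrode axis")

    comparisons: dict[str, pd.DataFrame] = {}
    labels = pd.DataFrame({"electrode_id": electrode_ids})

    best_mm: dict[str, list] = {}
    for align, analysis in analyses.items():
        integration, unimodal, multimodal_only, linear = _model_classes(analysis.specs)
        weak_df, _ = run_comparison(
            analysis, integration, unimodal,
            alpha=alpha, min_bins=min_bins, B2=B2, seed=seed,
        )
        comparisons[f"weak_{align}"] = weak_df
        labels[f"weak_{align}"] = weak_df["passed"].to_numpy()

        if slip_candidate in analysis.specs and slip_competitor in analysis.specs:
            slip_df, _ = run_comparison(
                analysis, [slip_candidate], [slip_competitor],
                alpha=alpha, min_bins=min_bins, B2=B2, seed=seed + 1,
            )
            comparisons[f"weak_slip_{align}"] = slip_df
            labels[f"weak_slip_{align}"] = slip_df["passed"].to_numpy()
        else:
            labels[f"weak_slip_{align}"] = False

        best = []
        for e in range(analysis.n_electrodes):
            ranked = rank_models(analysis, e, multimodal_only)
            best.append(ranked[0] if ranked else None)
        best_mm[align] = best
        labels[f"best_multimodal_{align}"] = best

    labels["weak"] = labels["weak_language"] | labels["weak_vision"]
    labels["weak_slip"] = labels["weak_slip_language"] | labels["weak_slip_vision"]
    labels["strict"] = labels["weak_language"] & labels["weak_vision"]
    labels["strict_slip"] = labels["weak_slip_language"] & labels["weak_slip_vision"]

    strict_ids = labels.loc[labels["strict"], "electrode_id"].tolist()
    nonlinear_both = pd.Series(False, index=labels.index)
    for align, analysis in analyses.items():
        integration, unimodal, multimodal_only, linear = _model_classes(analysis.specs)
        nl_df = run_nonlinear_comparison(
            analysis, multimodal_only, linear, strict_ids,
            alpha=alpha, min_bins=min_bins, B2=B2, seed=seed + 7,
        )
        comparisons[f"nonlinear_{align}"] = nl_df
        passed_ids = set(nl_df.loc[nl_df["passed"], "electrode_id"]) if len(nl_df) else set()
        labels[f"nonlinear_{align}"] = labels["electrode_id"].isin(passed_ids)
    labels["nonlinear"] = (
        labels["strict"] & labels["nonlinear_language"] & labels["nonlinear_vision"]
    )
    return MultimodalityResult(labels=labels, comparisons=comparisons)


# ---------------------------------------------------------------------------
# trained vs randomly-initialized comparison
# ---------------------------------------------------------------------------

def trained_vs_random(
    analysis: AlignmentAnalysis,
    alpha: float = 0.05,
    min_bins: int = 10,
    B2: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per electrode: does the best trained model beat the best random one?

    Candidates are trained models, competitors their randomly initialized
    variants.  The returned frame adds the per-electrode mean test-score
    difference between the winning trained model and the best random model
    over the winner's surviving bins.
    """
    trained = [m for m, s in analysis.specs.items() if s.trained]
    untrained = [m for m, s in analysis.specs.items() if not s.trained]
    df, outcomes = run_comparison(
        analysis, trained, untrained, alpha=alpha, min_bins=min_bins, B2=B2, seed=seed
    )
    diffs = []
    for e, o in enumerate(outcomes):
        if o.winner is None or o.winner not in trained:
            diffs.append(np.nan)
            continue
        mask = analysis.surviving[o.winner][e]
        ranked_random = rank_models(analysis, e, untrained)
        if ranked_random:
            other = ranked_random[0]
        else:
            # no random model survives anywhere: compare against the best
            # unfiltered random mean
            other = max(
                untrained,
                key=lambda m: np.nan_to_num(
                    np.nanmean(analysis.test_scores[m][e]), nan=-np.inf
                ),
                default=None,
            )
        if other is None:
            diffs.append(np.nan)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            d = float(
                np.nanmean(analysis.test_scores[o.winner][e, mask])
                - np.nanmean(analysis.test_scores[other][e, mask])
            )
        diffs.append(d)
    df = df.copy()
    df["winner_is_trained"] = df["winner"].isin(trained)
    df["mean_score_diff"] = diffs
    df["decided"] = df["status"].isin(["default_pass", "default_fail",
                                       "compared", "compared_fail_rank"])
    return df


# ---------------------------------------------------------------------------
# region aggregation
# ---------------------------------------------------------------------------

DEFAULT_TEST_COLUMNS = (
    "weak_language", "weak_vision", "weak",
    "weak_slip_language", "weak_slip_vision", "weak_slip",
    "strict", "strict_slip", "nonlinear",
)


def region_summary(
    labels: pd.DataFrame,
    electrode_table: pd.DataFrame,
    test_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-DKT-region counts and percentages of passing electrodes.

    ``electrode_table`` needs columns ``electrode_id`` and ``dkt_region``;
    every electrode in ``labels`` must have a region label.
    """
    if test_columns is None:
        test_columns = [c for c in DEFAULT_TEST_COLUMNS if c in labels.columns]
    merged = labels.merge(electrode_table[["electrode_id", "dkt_region"]],
                          on="electrode_id", how="left")
    missing = merged.loc[
        merged["dkt_region"].isna() | (merged["dkt_region"] == ""), "electrode_id"
    ].tolist()
    if missing:
        raise ValueError(f"electrodes without region label: {missing}")
    rows = []
    for region, sub in merged.groupby("dkt_region", sort=True):
        row = {"dkt_region": region, "n_electrodes": len(sub)}
        for col in test_columns:
            n = int(sub[col].sum())
            row[f"n_{col}"] = n
            row[f"pct_{col}"] = 100.0 * n / len(sub)
        rows.append(row)
    out = pd.DataFrame(rows)
    zero = out[[c for c in out.columns if c.startswith("n_") and c != "n_electrodes"]]
    if len(zero):
        flagged = out.loc[(zero.sum(axis=1) == 0), "dkt_region"].tolist()
        if flagged:
            logger.info("regions with zero passing electrodes: %s", flagged)
    return out


def plot_region_summary(summary: pd.DataFrame, test: str = "weak", ax=None):
    """Bar chart of per-region pass percentages for one test."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    col = f"pct_{test}"
    ax.bar(summary["dkt_region"], summary[col])
    ax.set_ylabel(f"% electrodes passing {test}")
    ax.set_xticklabels(summary["dkt_region"], rotation=45, ha="right")
    return ax
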