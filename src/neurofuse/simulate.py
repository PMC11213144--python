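"""Synthetic world with known ground truth for end-to-end pipeline testing.

The generator emulates the structure of the real inputs without any real
data: two alignment datasets of image-text events, latent stimulus features
per event (a vision latent v, a language latent l, a nonlinearly integrated
latent m, and the linear concatenation c = [v; l]), electrode responses with
Gaussian temporal gain profiles and modality-specific tuning, and feature
providers standing in for trained and randomly-initialized networks.

The multimodal latent is m_k = tanh(v' A_k l) with fixed random bilinear
forms A_k: it is (exactly) linearly uncorrelated with v, l and c, so an
electrode tuned to m is invisible to unimodal and linear-integration
features -- the contrast the non-linear integration test needs.

Bin noise is generated on the 25 ms micro-bin grid and averaged over the 8
micro-bins each 200 ms bin covers, so neighbouring bins share noise exactly
as overlapping sliding windows do.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinGrid, BinnedResponses, make_bin_grid
from .encoding import DEFAULT_LAMBDA_GRID, FoldPlan, contiguous_folds, encode_bank
from .events import AlignmentDataset, build_language_events, build_vision_events
from .features import (
    FeatureSet,
    ModelSpec,
    build_multiconcat,
    build_multilin,
    random_orthonormal_projection,
)
from .multimodality import (
    AlignmentAnalysis,
    MultimodalityResult,
    analyze_alignment,
    rank_models,
    region_summary,
    run_multimodality_tests,
    trained_vs_random,
)
from .features import effective_modality

ELECTRODE_TYPES = ("vision", "language", "multimodal", "linear", "noise")

DKT_REGIONS = (
    "superiortemporal", "middletemporal", "inferiorparietal", "lateraloccipital",
    "precentral", "rostralmiddlefrontal", "supramarginal", "fusiform",
)


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic experiment.

    ``snr`` is the ratio of signal standard deviation to noise standard
    deviation at the peak-gain bin.
    """

    n_events: int = 400
    d_v: int = 16
    d_l: int = 16
    d_m: int = 16
    n_electrodes: dict = field(
        default_factory=lambda: {t: 8 for t in ELECTRODE_TYPES}
    )
    snr: float = 4.0
    peak_bin: int = 80  # bin starting at the event onset
    tau_bins: float = 8.0  # Gaussian gain width, 25 ms units (200 ms)
    n_layers: int = 3
    layer_noise: tuple = (1.0, 0.25, 0.5)
    feature_dim: int = 16
    n_bootstrap: int = 100
    n_bin_bootstrap: int = 1000
    n_folds: int = 5
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    alpha: float = 0.05
    min_bins: int = 10

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        counts = dict(self.n_electrodes)
        for t, c in counts.items():
            if t not in ELECTRODE_TYPES:
                raise ValueError(f"unknown electrode type {t!r}")
            if c < 0:
                raise ValueError("electrode counts must be >= 0")
        for t in ELECTRODE_TYPES:
            counts.setdefault(t, 0)
        if sum(counts.values()) < 1:
            raise ValueError("need at least one electrode")
        self.n_electrodes = counts

    @property
    def total_electrodes(self) -> int:
        return sum(self.n_electrodes.values())


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# world: events and latents
# ---------------------------------------------------------------------------

@dataclass
class WorldAlignment:
    dataset: AlignmentDataset
    latents: dict  # {"v": (n, d_v), "l": (n, d_l), "m": (n, d_m), "c": (n, d_v+d_l)}


@dataclass
class World:
    config: SyntheticConfig
    seed: int
    alignments: dict  # alignment -> WorldAlignment
    bilinear_forms: np.ndarray  # (d_m, d_v, d_l)


def _synthetic_tables(n_events: int, words_per_sentence: int = 8):
    """Word, frame and scene-cut annotation tables for a synthetic movie."""
    n_words = n_events + words_per_sentence
    onsets = 3000.0 + 1000.0 * np.arange(n_words)
    word_table = pd.DataFrame({
        "word": [f"word{i}" for i in range(n_words)],
        "sentence_id": [i // words_per_sentence for i in range(n_words)],
        "sentence_text": [
            f"sentence {i // words_per_sentence}" for i in range(n_words)
        ],
        "onset_ms": onsets,
    })
    duration = onsets[-1] + 3000.0
    frame_times = np.arange(0.0, duration, 40.0)  # 25 fps
    frame_index = pd.DataFrame({
        "frame_id": [f"frame{i:06d}" for i in range(len(frame_times))],
        "time_ms": frame_times,
    })
    cut_times = 3500.0 + 1000.0 * np.arange(n_events)
    scene_cuts = pd.DataFrame({
        "cut_id": [f"cut{i:05d}" for i in range(n_events)],
        "time_ms": cut_times,
    })
    return word_table, frame_index, scene_cuts


def generate_world(cfg: SyntheticConfig, seed: int) -> World:
    """Events and latent stimulus features for both alignments.

    v and l are independent standard normal per event; m_k = tanh(v' A_k l)
    with seeded random bilinear forms A_k scaled so the argument has unit
    variance; c is the concatenation [v; l].
    """
    s_forms, s_lang, s_vis = _child_seeds(seed, 3)
    rng_forms = np.random.default_rng(s_forms)
    A = rng_forms.standard_normal((cfg.d_m, cfg.d_v, cfg.d_l)) / np.sqrt(
        cfg.d_v * cfg.d_l
    )
    word_table, frame_index, scene_cuts = _synthetic_tables(cfg.n_events)
    datasets = {
        "language": build_language_events(
            word_table.iloc[: cfg.n_events], frame_index, movie_id="synthetic"
        ),
        "vision": build_vision_events(scene_cuts, word_table, movie_id="synthetic"),
    }
    alignments = {}
    for align, s in (("language", s_lang), ("vision", s_vis)):
        ds = datasets[align]
        rng = np.random.default_rng(s)
        v = rng.standard_normal((ds.n_events, cfg.d_v))
        l = rng.standard_normal((ds.n_events, cfg.d_l))
        m = np.tanh(np.einsum("ei,kij,ej->ek", v, A, l))
        c = np.concatenate([v, l], axis=1)
        alignments[align] = WorldAlignment(
            dataset=ds, latents={"v": v, "l": l, "m": m, "c": c}
        )
    return World(config=cfg, seed=seed, alignments=alignments, bilinear_forms=A)


# ---------------------------------------------------------------------------
# ground truth electrodes and responses
# ---------------------------------------------------------------------------

_TYPE_TO_LATENT = {
    "vision": "v", "language": "l", "multimodal": "m", "linear": "c", "noise": None,
}


@dataclass
class GroundTruth:
    table: pd.DataFrame  # electrode_id, type, subject, dkt_region
    weights: dict  # electrode_id -> (d,) array (empty for noise)
    gain_bins: np.ndarray  # (n_bins,) bin-level gain profile
    gain_micro: np.ndarray

    @property
    def electrode_ids(self) -> list[str]:
        return self.table["electrode_id"].tolist()

    def types(self) -> pd.Series:
        return self.table.set_index("electrode_id")["type"]

    def to_json(self, path) -> None:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "weights": {k: np.asarray(v).tolist() for k, v in self.weights.items()},
            "gain_bins": self.gain_bins.tolist(),
            "gain_micro": self.gain_micro.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            table=pd.DataFrame(payload["table"]),
            weights={k: np.asarray(v) for k, v in payload["weights"].items()},
            gain_bins=np.asarray(payload["gain_bins"]),
            gain_micro=np.asarray(payload["gain_micro"]),
        )


def _micro_geometry(grid: BinGrid) -> tuple[int, int]:
    m, rem = divmod(grid.bin_ms, grid.stride_ms)
    if rem:
        raise ValueError("synthetic generator needs bin_ms divisible by stride_ms")
    m = int(m)
    return m, grid.n_bins + m - 1


def synthesize_ground_truth(
    cfg: SyntheticConfig, grid: BinGrid, seed: int
) -> GroundTruth:
    """Electrode bank: tuning type, generating weights and gain profile."""
    rng = np.random.default_rng(seed)
    m, n_micro = _micro_geometry(grid)
    j0 = cfg.peak_bin + (m - 1) / 2.0
    g_micro = np.exp(-((np.arange(n_micro) - j0) ** 2) / (2.0 * cfg.tau_bins**2))
    csum = np.concatenate([[0.0], np.cumsum(g_micro)])
    g_bins = (csum[m:] - csum[:-m]) / m
    dims = {"v": cfg.d_v, "l": cfg.d_l, "m": cfg.d_m, "c": cfg.d_v + cfg.d_l}
    rows, weights = [], {}
    e = 0
    for etype in ELECTRODE_TYPES:
        for _ in range(cfg.n_electrodes[etype]):
            eid = f"E{e:03d}"
            latent = _TYPE_TO_LATENT[etype]
            w = (
                rng.standard_normal(dims[latent]) if latent is not None
                else np.zeros(0)
            )
            rows.append({
                "electrode_id": eid,
                "type": etype,
                "subject": f"S{e % 4}",
                "dkt_region": DKT_REGIONS[e % len(DKT_REGIONS)],
            })
            weights[eid] = w
            e += 1
    return GroundTruth(
        table=pd.DataFrame(rows), weights=weights, gain_bins=g_bins, gain_micro=g_micro
    )


def synthesize_responses(
    world_alignment: WorldAlignment,
    truth: GroundTruth,
    grid: BinGrid,
    cfg: SyntheticConfig,
    seed: int,
) -> BinnedResponses:
    """Binned electrode activity: gain-profiled tuning signal plus noise.

    y[e, ev, b] = g(b) * s_e(ev) + noise, where s_e is the electrode's unit-
    variance tuning signal (w_e' z_type) and the noise standard deviation is
    set so that signal sd / noise sd at the peak-gain bin equals ``cfg.snr``.
    Noise is drawn per 25 ms micro-bin and averaged over each 200 ms bin.
    """
    rng = np.random.default_rng(seed)
    latents = world_alignment.latents
    ds = world_alignment.dataset
    n_events = ds.n_events
    m, n_micro = _micro_geometry(grid)
    ids = truth.electrode_ids
    n_elec = len(ids)
    s = np.zeros((n_elec, n_events))
    types = truth.types()
    for i, eid in enumerate(ids):
        latent = _TYPE_TO_LATENT[types[eid]]
        if latent is None:
            continue
        raw = latents[latent] @ truth.weights[eid]
        sd = raw.std()
        s[i] = raw / sd if sd > 0 else raw
    peak_gain = truth.gain_bins.max()
    sigma_micro = peak_gain * np.sqrt(m) / cfg.snr
    micro = (
        truth.gain_micro[None, None, :] * s[:, :, None]
        + rng.normal(0.0, sigma_micro, size=(n_elec, n_events, n_micro))
    )
    csum = np.concatenate(
        [np.zeros((n_elec, n_events, 1)), np.cumsum(micro, axis=-1)], axis=-1
    )
    data = (csum[..., m:] - csum[..., :-m]) / m
    return BinnedResponses(
        data=data, grid=grid, electrode_ids=ids, event_ids=ds.event_ids
    )


# ---------------------------------------------------------------------------
# feature providers
# ---------------------------------------------------------------------------

_TRAINED_SOURCES = {
    "slip-simclr": ("v", "vit", "vision", None),
    "slip-combo-vision": ("m", "vit", "multimodal", "vision_encoder"),
    "simcse": ("l", "transformer", "language", None),
    "albef": ("m", "cross-attention", "multimodal", None),
}


def default_model_specs() -> list[ModelSpec]:
    specs = []
    for name, (_, fam, modality, side) in _TRAINED_SOURCES.items():
        specs.append(ModelSpec(name, fam, modality, True, side))
        specs.append(ModelSpec(f"{name}-random", fam, modality, False, side))
    specs.append(ModelSpec("multiconcat", "linear_integration", "linear_integration", True))
    specs.append(ModelSpec("multilin", "linear_integration", "linear_integration", True))
    return specs


def synthesize_feature_providers(
    world: World, cfg: SyntheticConfig, seed: int
) -> dict:
    """Per alignment, a feature store: trained providers are noisy linear
    maps of the matching latent with one map per layer (layer noise levels
    differ so layer selection is meaningful); random-init providers are pure
    white noise with the same shapes; the two linear-integration baselines
    are built from the trained unimodal providers.

    The projection matrices are shared across alignments (a model is one set
    of weights); feature noise is alignment-specific.
    """
    s_proj, s_noise, s_multilin = _child_seeds(seed, 3)
    rng_proj = np.random.default_rng(s_proj)
    dims = {"v": cfg.d_v, "l": cfg.d_l, "m": cfg.d_m}
    projections = {
        name: [
            rng_proj.standard_normal((dims[src], cfg.feature_dim)) / np.sqrt(dims[src])
            for _ in range(cfg.n_layers)
        ]
        for name, (src, _, _, _) in _TRAINED_SOURCES.items()
    }
    noise_rng = np.random.default_rng(s_noise)
    multilin_proj = random_orthonormal_projection(
        2 * cfg.feature_dim, cfg.feature_dim, s_multilin
    )
    stores = {}
    for align, wa in world.alignments.items():
        n = wa.dataset.n_events
        event_ids = wa.dataset.event_ids
        sets: dict[str, FeatureSet] = {}
        for name, (src, fam, modality, side) in _TRAINED_SOURCES.items():
            z = wa.latents[src]
            layers = {}
            for j in range(cfg.n_layers):
                noise_sd = cfg.layer_noise[j % len(cfg.layer_noise)]
                layers[f"layer{j}"] = (
                    z @ projections[name][j]
                    + noise_sd * noise_rng.standard_normal((n, cfg.feature_dim))
                )
            sets[name] = FeatureSet(
                model=ModelSpec(name, fam, modality, True, side),
                layers=layers,
                event_ids=event_ids,
            )
            rnd_layers = {
                f"layer{j}": noise_rng.standard_normal((n, cfg.feature_dim))
                for j in range(cfg.n_layers)
            }
            sets[f"{name}-random"] = FeatureSet(
                model=ModelSpec(f"{name}-random", fam, modality, False, side),
                layers=rnd_layers,
                event_ids=event_ids,
            )
        concat = build_multiconcat(sets["slip-simclr"], sets["simcse"])
        sets["multiconcat"] = concat
        sets["multilin"] = build_multilin(concat, multilin_proj)
        stores[align] = sets
    return stores


# ---------------------------------------------------------------------------
# end-to-end pipeline and recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: SyntheticConfig
    seed: int
    world: World
    truth: GroundTruth
    analyses: dict  # alignment -> AlignmentAnalysis
    tests: MultimodalityResult
    trained_vs_random: dict  # alignment -> DataFrame
    regions: pd.DataFrame

    @property
    def labels(self) -> pd.DataFrame:
        return self.tests.labels


def run_pipeline(
    cfg: SyntheticConfig,
    seed: int,
    grid: BinGrid | None = None,
    refit_selection: bool = True,
    run_trained_vs_random: bool = True,
) -> PipelineResult:
    """Simulate the world and push it through the full analysis."""
    grid = grid or make_bin_grid()
    s_world, s_truth, s_resp_l, s_resp_v, s_feat, s_boot, s_tests, s_tvr = _child_seeds(
        seed, 8
    )
    world = generate_world(cfg, s_world)
    truth = synthesize_ground_truth(cfg, grid, s_truth)
    providers = synthesize_feature_providers(world, cfg, s_feat)
    plan = contiguous_folds(cfg.n_events, cfg.n_folds)
    analyses = {}
    for align, s_resp in (("language", s_resp_l), ("vision", s_resp_v)):
        responses = synthesize_responses(world.alignments[align], truth, grid, cfg, s_resp)
        analyses[align] = analyze_alignment(
            providers[align],
            responses,
            plan,
            B=cfg.n_bootstrap,
            seed=s_boot,
            lambda_grid=cfg.lambda_grid,
            refit_selection=refit_selection,
            alignment=align,
        )
    tests = run_multimodality_tests(
        analyses,
        alpha=cfg.alpha,
        min_bins=cfg.min_bins,
        B2=cfg.n_bin_bootstrap,
        seed=s_tests,
    )
    tvr = {}
    if run_trained_vs_random:
        for align, analysis in analyses.items():
            tvr[align] = trained_vs_random(
                analysis, alpha=cfg.alpha, min_bins=cfg.min_bins,
                B2=cfg.n_bin_bootstrap, seed=s_tvr,
            )
    regions = region_summary(tests.labels, truth.table)
    return PipelineResult(
        config=cfg, seed=seed, world=world, truth=truth, analyses=analyses,
        tests=tests, trained_vs_random=tvr, regions=regions,
    )


@dataclass
class TestRecovery:
    tpr: float
    fpr: float
    n_positives: int
    n_negatives: int


@dataclass
class RecoveryReport:
    """Ground-truth recovery rates of the test battery.

    For the weak and strict tests the negative class excludes ground-truth
    linear electrodes: by the tests' own definitions a linearly-integrating
    site is a true integration site, so its pass rate is reported separately
    (``linear_pass_rate``).  ``linear_nonlinear_fail_rate`` is the fraction
    of linear electrodes that do NOT pass the non-linear integration test.
    """

    tests: dict  # test name -> TestRecovery
    linear_pass_rate: dict  # test name -> rate among linear electrodes
    linear_nonlinear_fail_rate: float
    winner_match_rate: float
    confusion: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"test": t, "tpr": r.tpr, "fpr": r.fpr,
                 "n_pos": r.n_positives, "n_neg": r.n_negatives}
                for t, r in self.tests.items()
            ]
        )


_NEGATIVES = {
    "weak": ("vision", "language", "noise"),
    "strict": ("vision", "language", "noise"),
    "weak_slip": ("vision", "language", "linear", "noise"),
    "strict_slip": ("vision", "language", "linear", "noise"),
    "nonlinear": ("vision", "language", "noise"),
}

_TYPE_TO_CLASS = {
    "vision": "vision", "language": "language",
    "multimodal": "multimodal", "linear": "linear_integration",
}


def evaluate_recovery(
    labels: pd.DataFrame,
    truth: GroundTruth,
    analyses: Mapping[str, AlignmentAnalysis] | None = None,
) -> RecoveryReport:
    """Score the label table against the generating ground truth."""
    merged = labels.merge(truth.table[["electrode_id", "type"]], on="electrode_id")
    if len(merged) != len(labels):
        missing = set(labels["electrode_id"]) - set(truth.table["electrode_id"])
        raise ValueError(f"electrodes missing from ground truth: {sorted(missing)}")
    tests, linear_rate = {}, {}
    for test, negatives in _NEGATIVES.items():
        if test not in merged.columns:
            continue
        pos = merged["type"] == "multimodal"
        neg = merged["type"].isin(negatives)
        tests[test] = TestRecovery(
            tpr=float(merged.loc[pos, test].mean()) if pos.any() else float("nan"),
            fpr=float(merged.loc[neg, test].mean()) if neg.any() else float("nan"),
            n_positives=int(pos.sum()),
            n_negatives=int(neg.sum()),
        )
        lin = merged["type"] == "linear"
        linear_rate[test] = (
            float(merged.loc[lin, test].mean()) if lin.any() else float("nan")
        )
    lin = merged["type"] == "linear"
    if "nonlinear" in merged.columns and lin.any():
        nl_fail = float(1.0 - merged.loc[lin, "nonlinear"].mean())
    else:
        nl_fail = float("nan")

    match_rate = float("nan")
    confusion = pd.DataFrame()
    if analyses:
        rows = []
        types = truth.types()
        for align, analysis in analyses.items():
            for e, eid in enumerate(analysis.electrode_ids):
                etype = types[eid]
                ranked = rank_models(analysis, e)
                if not ranked:
                    winner_class = "none"
                else:
                    winner_class = effective_modality(analysis.specs[ranked[0]])
                rows.append({"alignment": align, "electrode_id": eid,
                             "type": etype, "winner_class": winner_class})
        conf_long = pd.DataFrame(rows)
        confusion = pd.crosstab(conf_long["type"], conf_long["winner_class"])
        signal = conf_long[conf_long["type"] != "noise"].copy()
        signal["expected"] = signal["type"].map(_TYPE_TO_CLASS)
        decided = signal[signal["winner_class"] != "none"]
        if len(decided):
            match_rate = float(
                (decided["winner_class"] == decided["expected"]).mean()
            )
    return RecoveryReport(
        tests=tests,
        linear_pass_rate=linear_rate,
        linear_nonlinear_fail_rate=nl_fail,
        winner_match_rate=match_rate,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# bootstrap-coverage calibration experiment
# ---------------------------------------------------------------------------

def coverage_experiment(
    n_replicates: int = 200,
    n_events: int = 200,
    B: int = 500,
    snr: float = 1.0,
    n_features: int = 8,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> pd.DataFrame:
    """Coverage of the bootstrap CI for the test-split correlation.

    Each replicate simulates one electrode with a single time bin: responses
    y = Xw + noise with X iid standard normal, so the population correlation
    of the ideal predictor is snr / sqrt(1 + snr^2) in closed form.  The
    full encode + event-bootstrap machinery produces the 95% CI for the
    test-split r; the replicate covers if the true correlation falls inside.
    """
    from .inference import bootstrap_encode, draw_resamples

    rho_true = snr / np.sqrt(1.0 + snr**2)
    plan = contiguous_folds(n_events, 5)
    seeds = _child_seeds(seed, 2 * n_replicates)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seeds[2 * rep])
        X = rng.standard_normal((n_events, n_features))
        w = rng.standard_normal(n_features)
        w *= 1.0 / np.linalg.norm(w)
        signal = X @ w
        y = signal + rng.normal(0.0, 1.0 / snr, size=n_events)
        boot = bootstrap_encode(
            [X], y[:, None], plan,
            B=B, seed=seeds[2 * rep + 1], lambda_grid=lambda_grid,
        )
        lo, hi = boot.ci["test"][0]
        rows.append({
            "replicate": rep, "rho_true": rho_true, "ci_low": lo, "ci_high": hi,
            "covered": bool(lo <= rho_true <= hi),
        })
    return pd.DataFrame(rows)
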