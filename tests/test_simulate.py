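"""Synthetic world: determinism, nonlinearity of the integrated latent,
provider informativeness, and ground-truth recovery plumbing."""
import numpy as np
import pandas as pd
import pytest

from neurofuse.binning import make_bin_grid
from neurofuse.encoding import contiguous_folds, encode_electrode
from neurofuse.features import load_feature_set, save_feature_set
from neurofuse.simulate import (
    GroundTruth,
    SyntheticConfig,
    evaluate_recovery,
    generate_world,
    run_pipeline,
    synthesize_feature_providers,
    synthesize_ground_truth,
    synthesize_responses,
)

CFG_SMALL = SyntheticConfig(
    n_events=200,
    n_electrodes={t: 1 for t in ("vision", "language", "multimodal", "linear", "noise")},
    n_bootstrap=20,
    n_bin_bootstrap=200,
)


class TestWorld:
    def test_deterministic_given_seed(self):
        w1 = generate_world(CFG_SMALL, 5)
        w2 = generate_world(CFG_SMALL, 5)
        for align in ("language", "vision"):
            for key in ("v", "l", "m", "c"):
                assert np.array_equal(
                    w1.alignments[align].latents[key],
                    w2.alignments[align].latents[key],
                )
            assert (
                w1.alignments[align].dataset.event_ids
                == w2.alignments[align].dataset.event_ids
            )

    def test_event_counts_and_alignment_tags(self):
        w = generate_world(CFG_SMALL, 5)
        assert w.alignments["language"].dataset.n_events == 200
        assert w.alignments["vision"].dataset.n_events == 200
        assert w.alignments["vision"].dataset.alignment == "vision"

    def test_integrated_latent_uncorrelated_with_unimodal_coordinates(self):
        cfg = SyntheticConfig(n_events=400)
        w = generate_world(cfg, 9)
        lat = w.alignments["language"].latents
        rs = []
        for k in range(cfg.d_m):
            for coord in (lat["v"].T, lat["l"].T):
                for x in coord:
                    rs.append(abs(np.corrcoef(lat["m"][:, k], x)[0, 1]))
        assert np.mean(np.array(rs) < 0.3) >= 0.9

    def test_integrated_latent_not_linearly_decodable(self):
        # least-squares regression of m on c leaves most variance unexplained
        cfg = SyntheticConfig(n_events=400)
        w = generate_world(cfg, 9)
        lat = w.alignments["vision"].latents
        c = np.column_stack([lat["c"], np.ones(400)])
        coef, *_ = np.linalg.lstsq(c, lat["m"], rcond=None)
        resid = lat["m"] - c @ coef
        frac = resid.var(axis=0) / lat["m"].var(axis=0)
        assert frac.mean() >= 0.5


class TestResponses:
    def setup_method(self):
        self.grid = make_bin_grid()
        self.world = generate_world(CFG_SMALL, 5)
        self.truth = synthesize_ground_truth(CFG_SMALL, self.grid, 6)

    def test_deterministic(self):
        a = synthesize_responses(self.world.alignments["language"], self.truth,
                                 self.grid, CFG_SMALL, 7)
        b = synthesize_responses(self.world.alignments["language"], self.truth,
                                 self.grid, CFG_SMALL, 7)
        assert np.array_equal(a.data, b.data)

    def test_shapes_and_snr_calibration(self):
        resp = synthesize_responses(self.world.alignments["language"], self.truth,
                                    self.grid, CFG_SMALL, 7)
        assert resp.data.shape == (5, 200, 161)
        types = self.truth.types()
        i_noise = [i for i, e in enumerate(self.truth.electrode_ids)
                   if types[e] == "noise"][0]
        peak = int(np.argmax(self.truth.gain_bins))
        noise_sd = resp.data[i_noise, :, peak].std()
        # noise sd at the peak bin ~ peak gain / snr
        assert noise_sd == pytest.approx(self.truth.gain_bins.max() / CFG_SMALL.snr,
                                         rel=0.2)

    def test_neighbouring_bins_share_noise(self):
        resp = synthesize_responses(self.world.alignments["language"], self.truth,
                                    self.grid, CFG_SMALL, 7)
        types = self.truth.types()
        i_noise = [i for i, e in enumerate(self.truth.electrode_ids)
                   if types[e] == "noise"][0]
        x = resp.data[i_noise]
        r_adj = np.corrcoef(x[:, 80], x[:, 81])[0, 1]
        r_far = np.corrcoef(x[:, 80], x[:, 120])[0, 1]
        assert r_adj > 0.8  # overlapping 200 ms windows, 25 ms apart
        assert abs(r_far) < 0.2

    def test_noise_electrode_encoding_near_zero(self):
        resp = synthesize_responses(self.world.alignments["language"], self.truth,
                                    self.grid, CFG_SMALL, 7)
        providers = synthesize_feature_providers(self.world, CFG_SMALL, 8)
        types = self.truth.types()
        i_noise = [i for i, e in enumerate(self.truth.electrode_ids)
                   if types[e] == "noise"][0]
        plan = contiguous_folds(200, 5)
        res = encode_electrode(providers["language"]["slip-simclr"],
                               resp.data[i_noise], plan)
        assert abs(np.nanmean(res.scores("test"))) < 0.1


class TestProviders:
    def test_trained_vision_provider_predicts_vision_electrode(self):
        grid = make_bin_grid()
        world = generate_world(CFG_SMALL, 5)
        truth = synthesize_ground_truth(CFG_SMALL, grid, 6)
        resp = synthesize_responses(world.alignments["language"], truth, grid,
                                    CFG_SMALL, 7)
        providers = synthesize_feature_providers(world, CFG_SMALL, 8)
        types = truth.types()
        i_vis = [i for i, e in enumerate(truth.electrode_ids)
                 if types[e] == "vision"][0]
        peak = int(np.argmax(truth.gain_bins))
        plan = contiguous_folds(200, 5)
        res = encode_electrode(providers["language"]["slip-simclr"],
                               resp.data[i_vis], plan)
        assert res.scores("test")[peak] > 0.5
        rnd = encode_electrode(providers["language"]["slip-simclr-random"],
                               resp.data[i_vis], plan)
        assert abs(np.nanmean(rnd.scores("test"))) < 0.1

    def test_round_trip_through_feature_store(self, tmp_path):
        world = generate_world(CFG_SMALL, 5)
        providers = synthesize_feature_providers(world, CFG_SMALL, 8)
        store = tmp_path / "features.h5"
        fs = providers["vision"]["multiconcat"]
        save_feature_set(store, fs)
        back = load_feature_set(store, "multiconcat", event_ids=fs.event_ids)
        for lid in fs.layer_ids:
            assert np.array_equal(back.layers[lid], fs.layers[lid])
        assert back.model == fs.model

    def test_manifest_covers_modality_classes(self):
        world = generate_world(CFG_SMALL, 5)
        providers = synthesize_feature_providers(world, CFG_SMALL, 8)
        specs = {n: fs.model for n, fs in providers["language"].items()}
        from neurofuse.features import effective_modality
        eff = {n: effective_modality(s) for n, s in specs.items()}
        assert eff["slip-combo-vision"] == "multimodal"
        assert eff["slip-combo-vision-random"] == "vision"  # untrained dual encoder
        assert eff["multiconcat"] == "linear_integration"
        assert set(eff.values()) >= {"vision", "language", "multimodal",
                                     "linear_integration"}


class TestPipelineAndRecovery:
    def test_small_end_to_end_run(self):
        res = run_pipeline(CFG_SMALL, seed=3)
        lab = res.labels
        assert (lab["strict"] <= lab["weak"]).all()
        assert (lab["nonlinear"] <= lab["strict"]).all()
        assert len(lab) == CFG_SMALL.total_electrodes
        # identical seed reproduces identical labels
        res2 = run_pipeline(CFG_SMALL, seed=3)
        pd.testing.assert_frame_equal(lab, res2.labels)

    def test_recovery_rates_from_fabricated_labels(self):
        truth_table = pd.DataFrame({
            "electrode_id": [f"E{i}" for i in range(6)],
            "type": ["multimodal", "multimodal", "vision", "language", "linear",
                     "noise"],
            "subject": "S0",
            "dkt_region": "fusiform",
        })
        truth = GroundTruth(table=truth_table, weights={},
                            gain_bins=np.ones(3), gain_micro=np.ones(3))
        labels = pd.DataFrame({
            "electrode_id": truth_table["electrode_id"],
            "weak": [True, False, True, False, True, False],
            "strict": [True, False, False, False, True, False],
            "weak_slip": [True, True, False, False, False, False],
            "strict_slip": [False] * 6,
            "nonlinear": [True, False, False, False, False, False],
        })
        rep = evaluate_recovery(labels, truth)
        assert rep.tests["weak"].tpr == pytest.approx(0.5)
        # linear electrode excluded from weak-test negatives
        assert rep.tests["weak"].fpr == pytest.approx(1 / 3)
        assert rep.linear_pass_rate["weak"] == 1.0
        assert rep.linear_nonlinear_fail_rate == 1.0
        assert rep.tests["weak_slip"].fpr == 0.0

    def test_recovery_id_mismatch_errors(self):
        truth = GroundTruth(
            table=pd.DataFrame({"electrode_id": ["E0"], "type": ["noise"],
                                "subject": "S0", "dkt_region": "fusiform"}),
            weights={}, gain_bins=np.ones(3), gain_micro=np.ones(3))
        labels = pd.DataFrame({"electrode_id": ["E0", "E1"],
                               "weak": [False, False]})
        with pytest.raises(ValueError, match="E1"):
            evaluate_recovery(labels, truth)

    def test_ground_truth_json_round_trip(self, tmp_path):
        grid = make_bin_grid()
        truth = synthesize_ground_truth(CFG_SMALL, grid, 6)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        pd.testing.assert_frame_equal(back.table, truth.table)
        for eid in truth.electrode_ids:
            assert np.allclose(back.weights[eid], truth.weights[eid])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(snr=0.0)
        with pytest.raises(ValueError):
            SyntheticConfig(n_electrodes={"vision": -1})
        with pytest.raises(ValueError):
            SyntheticConfig(n_electrodes={t: 0 for t in ("vision", "noise")})
        cfg = SyntheticConfig(n_electrodes={"noise": 4})
        assert cfg.total_electrodes == 4
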