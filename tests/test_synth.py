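"""Generator tests: player sampling, truth laws, trace synthesis, datasets."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from servechain import synth
from servechain.kinematics import SEGMENTS
from servechain.synth import (
    GenerationConfig,
    OutcomeModel,
    discretize_accuracy,
    draw_serve_truth,
    generate_dataset,
    generate_outcomes,
    load_generation_config,
    sample_players,
    simulate_regression_dataset,
    simulate_serves,
    synthesize_traces,
)


class TestSamplePlayers:
    def test_requires_positive_count(self, population):
        with pytest.raises(ValueError, match="n_players"):
            sample_players(0, population, seed=1)

    def test_deterministic_given_seed(self, population):
        a = sample_players(8, population, seed=1)
        b = sample_players(8, population, seed=1)
        assert a == b
        assert len(a) == 8

    def test_zero_between_player_variance_means_zero_offsets(self):
        params = synth.default_population_params(rho_between=0.0)
        for p in sample_players(5, params, seed=2):
            assert all(p.peak_offset(s, "first", params) == 0.0 for s in SEGMENTS)
            assert p.timing_offset("pelvis_trunk", "first", params) == 0.0

    def test_offset_variance_matches_configured_share(self, population):
        # Monte-Carlo: var of player offsets -> rho_b * total variance
        players = sample_players(2000, population, seed=7)
        offsets = np.array([p.peak_offset("pelvis", "first", population)
                            for p in players])
        target = population.rho_between * population.first.peaks_dps["pelvis"][1] ** 2
        assert np.var(offsets, ddof=1) == pytest.approx(target, rel=0.05)


class TestDrawServeTruth:
    def test_timing_law_mean_recovered(self, population):
        # long-run mean of (t_trunk - t_pelvis) -> configured -28.3 ms
        rng = np.random.default_rng(3)
        players = sample_players(400, population, seed=4)
        dts = [draw_serve_truth(p, "first", population, rng).timing_pelvis_trunk_ms
               for p in players for _ in range(5)]
        se = np.std(dts, ddof=1) / np.sqrt(len(dts))
        assert np.mean(dts) == pytest.approx(-28.3, abs=3 * se + 0.5)

    def test_peak_law_mean_recovered(self, population):
        rng = np.random.default_rng(5)
        players = sample_players(500, population, seed=6)
        peaks = [draw_serve_truth(p, "first", population, rng).peak_dps["pelvis"]
                 for p in players for _ in range(20)]
        se = np.std(peaks, ddof=1) / np.sqrt(len(peaks))
        assert np.mean(peaks) == pytest.approx(586.8, abs=3 * se)

    def test_degenerate_sds_recover_population_means(self):
        params = synth.default_population_params()
        tiny = {
            "first": {"peaks_dps": {s: [params.first.peaks_dps[s][0], 1e-9]
                                    for s in SEGMENTS},
                      "timings_ms": {k: [params.first.timings_ms[k][0], 1e-9]
                                     for k in ("pelvis_trunk", "trunk_upper_arm")}},
        }
        degenerate = synth.load_generation_config({"population": tiny}).population
        profile = sample_players(1, degenerate, seed=1)[0]
        truth = draw_serve_truth(profile, "first", degenerate, seed=2)
        for seg in SEGMENTS:
            assert truth.peak_dps[seg] == pytest.approx(
                degenerate.first.peaks_dps[seg][0], abs=1e-6)
        # peak times snap to the 1 ms grid, so timings match within 1 sample
        assert truth.timing_pelvis_trunk_ms == pytest.approx(-28.3, abs=1.0)
        assert truth.timing_trunk_upper_arm_ms == pytest.approx(124.5, abs=1.0)

    def test_eq1_holds_exactly_on_truth(self, population):
        profile = sample_players(1, population, seed=9)[0]
        truth = draw_serve_truth(profile, "second", population, seed=10)
        assert truth.timing_pelvis_trunk_ms == \
            truth.peak_time_ms["trunk"] - truth.peak_time_ms["pelvis"]
        assert truth.timing_trunk_upper_arm_ms == \
            truth.peak_time_ms["upper_arm"] - truth.peak_time_ms["trunk"]
        assert all(0 < t < population.window_ms for t in truth.peak_time_ms.values())


class TestSynthesizeTraces:
    def test_noise_free_norm_peaks_exactly_at_truth(self, quiet_population):
        profile = sample_players(1, quiet_population, seed=11)[0]
        truth = draw_serve_truth(profile, "first", quiet_population, seed=12)
        traces = synthesize_traces(truth, quiet_population, seed=13)
        for seg in SEGMENTS:
            norm = np.linalg.norm(traces[seg].w, axis=1)
            i = int(np.argmax(norm))
            assert norm[i] == pytest.approx(truth.peak_dps[seg], abs=1e-9)
            assert traces[seg].t_ms[i] == truth.peak_time_ms[seg]

    def test_calibrated_arm_peak_does_not_clip(self, population):
        truth = synth.KinematicTruth({"pelvis": 586.8, "trunk": 897.2,
                                      "upper_arm": 3206.6},
                                     {"pelvis": 728.0, "trunk": 700.0,
                                      "upper_arm": 824.0})
        traces = synthesize_traces(truth, population, seed=2)
        assert not traces["upper_arm"].clipped.any()

    def test_over_range_peak_raises_clipping_flags(self):
        params = synth.default_population_params(
            sensor_range_dps={"pelvis": 4000.0, "trunk": 4000.0, "upper_arm": 4000.0})
        truth = synth.KinematicTruth({"pelvis": 500.0, "trunk": 900.0,
                                      "upper_arm": 5000.0},
                                     {"pelvis": 728.0, "trunk": 700.0,
                                      "upper_arm": 824.0})
        traces = synthesize_traces(truth, params, seed=3)
        assert traces["upper_arm"].clipped.sum() >= 1
        assert np.abs(traces["upper_arm"].w).max() <= 4000.0

    def test_pulse_centre_outside_window_rejected(self, population):
        truth = synth.KinematicTruth({s: 500.0 for s in SEGMENTS},
                                     {"pelvis": 1700.0, "trunk": 700.0,
                                      "upper_arm": 800.0})
        with pytest.raises(ValueError, match="window"):
            synthesize_traces(truth, population, seed=4)


class TestGenerateOutcomes:
    def test_constant_model(self, population):
        profile = sample_players(1, population, seed=1)[0]
        truth = draw_serve_truth(profile, "first", population, seed=2)
        model = OutcomeModel("ball_speed_kph", "peak_trunk", b0=150.0, b1=0.0,
                             resid_sd=1e-12, player_sd=0.0)
        assert generate_outcomes(truth, profile, model, seed=3) == pytest.approx(150.0)

    def test_unknown_predictor_rejected(self, population):
        profile = sample_players(1, population, seed=1)[0]
        truth = draw_serve_truth(profile, "first", population, seed=2)
        model = OutcomeModel("ball_speed_kph", "peak_racket", 0.0, 1.0,
                             resid_sd=1.0, player_sd=0.0)
        with pytest.raises(ValueError, match="predictor"):
            generate_outcomes(truth, profile, model, seed=3)

    def test_large_sample_ols_recovers_slope(self, population):
        model = synth.default_outcome_models()["ball_speed_kph"]["first"]
        y, x, _ = simulate_regression_dataset(model, "first", population,
                                              n_players=2000, serves_per_player=25,
                                              seed=17)
        slope, _ = np.polyfit(x, y, 1)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        se = np.std(resid, ddof=2) / (np.std(x) * np.sqrt(len(x)))
        assert slope == pytest.approx(model.b1, abs=3 * se)

    @pytest.mark.parametrize("value,expected", [(-0.4, 0), (0.6, 1), (2.1, 3),
                                                (4.6, 6), (8.0, 9), (12.0, 9)])
    def test_discretize_to_nearest_admissible_score(self, value, expected):
        assert discretize_accuracy(value) == expected

    def test_outcome_icc_matches_variance_ratio(self, population):
        # intraclass correlation -> player_sd^2 / (player_sd^2 + resid_sd^2)
        model = OutcomeModel("ball_speed_kph", "peak_trunk", b0=150.0, b1=0.0,
                             resid_sd=4.0, player_sd=3.0)
        y, _, cluster = simulate_regression_dataset(model, "first", population,
                                                    n_players=1500,
                                                    serves_per_player=8, seed=23)
        df = pd.DataFrame({"y": y, "g": cluster})
        between = df.groupby("g")["y"].mean().var(ddof=1) - 16.0 / 8
        total = between + 16.0
        icc = between / total
        assert icc == pytest.approx(9.0 / 25.0, abs=0.04)


class TestDatasets:
    def test_default_shape(self):
        ds = simulate_serves(GenerationConfig(), seed=0, with_traces=False)
        assert len(ds.manifest) == 384
        assert ds.manifest.groupby("serve_type").size().to_dict() == \
            {"first": 192, "second": 192}
        assert sorted(ds.manifest["target"].unique()) == ["T", "body", "wide"]

    def test_serves_are_paired_first_then_second(self, tiny_config):
        ds = simulate_serves(tiny_config, seed=1, with_traces=False)
        for _, sub in ds.manifest.groupby("player_id"):
            types = sub.sort_values("serve_idx")["serve_type"].tolist()
            assert types == ["first", "second"] * tiny_config.serves_per_type

    def test_unregistered_rate(self):
        cfg = GenerationConfig(n_players=20, serves_per_type=24, drop_rate=0.11)
        ds = simulate_serves(cfg, seed=5, with_traces=False)
        frac = ds.manifest["ball_speed_kph"].isna().mean()
        assert frac == pytest.approx(0.11, abs=0.03)

    def test_bounce_scores_round_trip_through_scoring(self, tiny_config):
        from servechain.scoring import BouncePoint, score_bounce
        zones = tiny_config.zone_config()
        ds = simulate_serves(tiny_config, seed=2, with_traces=False)
        for row in ds.manifest.itertuples():
            p = BouncePoint(row.bounce_x_m, row.bounce_y_m, row.side)
            assert score_bounce(p, row.serve_type, row.target, zones) == \
                row.accuracy_points

    def test_dataset_on_disk_is_byte_identical_across_runs(self, tmp_path, tiny_config):
        def digest(root: Path) -> dict:
            return {p.relative_to(root): hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(root.rglob("*.csv"))}
        generate_dataset(tiny_config, seed=9, out_dir=tmp_path / "a")
        generate_dataset(tiny_config, seed=9, out_dir=tmp_path / "b")
        da, db = digest(tmp_path / "a"), digest(tmp_path / "b")
        assert list(da.values()) == list(db.values())
        n_traces = len(list((tmp_path / "a" / "traces").glob("*.csv")))
        assert n_traces == 2 * 3 * 2 * 3  # players x pairs x types x segments

    def test_refuses_to_overwrite_without_force(self, tmp_path, tiny_config):
        out = tmp_path / "ds"
        generate_dataset(tiny_config, seed=1, out_dir=out)
        with pytest.raises(FileExistsError):
            generate_dataset(tiny_config, seed=1, out_dir=out)
        generate_dataset(tiny_config, seed=1, out_dir=out, force=True)


class TestGenerationConfig:
    def test_yaml_overrides(self, tmp_path):
        doc = """
n_players: 3
serves_per_type: 4
drop_rate: 0.0
population:
  rho_between: 0.3
  noise_sd_dps: 2.0
  first:
    peaks_dps:
      pelvis: [600.0, 50.0]
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(doc)
        cfg = load_generation_config(path)
        assert cfg.n_players == 3
        assert cfg.population.rho_between == 0.3
        assert cfg.population.first.peaks_dps["pelvis"] == (600.0, 50.0)
        # untouched values keep the published calibration
        assert cfg.population.first.peaks_dps["trunk"] == (897.2, 152.9)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            load_generation_config({"n_player": 3})
        with pytest.raises(ValueError, match="unknown"):
            load_generation_config({"population": {"rho": 0.5}})

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho_between"):
            synth.default_population_params(rho_between=1.0)
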