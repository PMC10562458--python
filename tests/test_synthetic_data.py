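"""Generator contracts: ground truth consistency and determinism."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as cc_label

from zfscreen import (
    BehaviorSimConfig,
    HeartSimConfig,
    ScreenSimConfig,
    TrunkSimConfig,
    make_behavior_track,
    make_heart_movie,
    make_qpcr_dataset,
    make_screen_dataset,
    make_trunk_image,
)
from zfscreen.cardio_quant import count_local_maxima


class TestHeartMovie:
    def test_truth_trace_has_one_diastole_per_beat(self):
        movie = make_heart_movie(HeartSimConfig(fps=20, n_frames=100, beat_rate=2))
        # 5 s at 2 beats/s
        assert movie.true_beat_count == 10
        n, _ = count_local_maxima(movie.area_trace["ventricle_area"].to_numpy())
        assert n == 10

    def test_constant_area_when_edv_equals_esv(self):
        movie = make_heart_movie(HeartSimConfig(edv=500, esv=500))
        areas = movie.area_trace["ventricle_area"].to_numpy()
        assert np.allclose(areas, 500)
        assert movie.true_ef == 0.0
        assert movie.true_beat_count == 0

    def test_true_ef_is_the_ef_formula(self):
        movie = make_heart_movie(HeartSimConfig(edv=100, esv=40, image_shape=(64, 64)))
        assert movie.true_ef == pytest.approx(60.0, abs=1e-12)

    @pytest.mark.parametrize("edv,esv", [(3000, 600), (2500, 2000), (1000, 0)])
    def test_ground_truth_ef_consistency(self, edv, esv):
        movie = make_heart_movie(HeartSimConfig(edv=edv, esv=esv))
        assert movie.true_ef == pytest.approx((edv - esv) / edv * 100, abs=1e-12)

    def test_seed_determinism_bit_identical(self):
        cfg = HeartSimConfig(noise_sd=5.0, seed=42)
        a = make_heart_movie(cfg)
        b = make_heart_movie(cfg)
        assert np.array_equal(a.stack, b.stack)
        pd.testing.assert_frame_equal(a.area_trace, b.area_trace)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_heart_movie(HeartSimConfig(fps=20, beat_rate=10.0))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HeartSimConfig(n_frames=1).validate()
        with pytest.raises(ValueError):
            HeartSimConfig(edv=100, esv=200).validate()
        with pytest.raises(ValueError):
            HeartSimConfig(noise_sd=-1).validate()


class TestTrunkImage:
    def test_mask_has_configured_component_count(self, default_trunk):
        assert default_trunk.config.n_isv == 12
        n_components = cc_label(default_trunk.label_mask > 0).max()
        assert n_components == 12

    def test_zero_isvs_empty_mask(self):
        trunk = make_trunk_image(TrunkSimConfig(n_isv=0))
        assert trunk.label_mask.max() == 0
        assert len(trunk.truth) == 0

    def test_band_row_crosses_all_stripes(self, default_trunk):
        row = default_trunk.label_mask[default_trunk.band_row]
        assert len(set(row[row > 0])) == 12

    def test_stripe_axes_match_pixel_pca_oracle(self):
        # independent oracle: PCA of each component's pixel coordinates,
        # axis length via the ellipse second-moment convention (4 sqrt(lambda))
        trunk = make_trunk_image(TrunkSimConfig(n_isv=5, isv_length=100, isv_width=10))
        for lab in range(1, 6):
            ys, xs = np.nonzero(trunk.label_mask == lab)
            cov = np.cov(np.vstack([ys, xs]))
            major = 4 * np.sqrt(np.linalg.eigvalsh(cov).max())
            assert major == pytest.approx(100, abs=1.0)

    def test_overflowing_stripes_rejected(self):
        with pytest.raises(ValueError, match="overflow|fit"):
            make_trunk_image(TrunkSimConfig(n_isv=30, image_shape=(200, 300)))


class TestBehaviorTrack:
    def test_default_schedule_yields_150_bins(self):
        track = make_behavior_track(BehaviorSimConfig())
        assert len(track) == 150  # 30 accommodation + 6 x (10 dark + 10 bright)

    def test_noise_free_velocities_exact(self):
        track = make_behavior_track(BehaviorSimConfig(v_dark=5, v_bright=2, noise_sd=0))
        assert track.loc[track.phase == "dark", "velocity"].median() == 5
        assert (track.loc[track.phase == "bright", "velocity"] == 2).all()
        assert (track.loc[track.phase == "accommodation", "velocity"] == 5).all()

    def test_same_seed_identical(self):
        cfg = BehaviorSimConfig(noise_sd=1.0, seed=7)
        pd.testing.assert_frame_equal(
            make_behavior_track(cfg), make_behavior_track(cfg)
        )

    def test_schedule_conservation(self):
        cfg = BehaviorSimConfig()
        track = make_behavior_track(cfg)
        assert len(track) == cfg.schedule.total_minutes


class TestScreenDataset:
    def test_every_plate_has_controls(self):
        records, _ = make_screen_dataset(ScreenSimConfig(n_compounds=12, seed=1))
        for _, sub in records.groupby("experiment_id"):
            assert (sub["treatment"] == "DMSO").any()

    def test_zero_mortality_means_no_dead(self):
        records, _ = make_screen_dataset(
            ScreenSimConfig(mortality_prob=0.0, seed=2)
        )
        assert records["alive"].all()

    def test_dead_larvae_carry_no_metrics(self):
        records, _ = make_screen_dataset(
            ScreenSimConfig(mortality_prob=0.5, seed=3)
        )
        dead = records[~records["alive"]]
        assert len(dead) > 0
        assert dead["heart_rate_bpm"].isna().all()
        assert dead["body_length_um"].isna().all()

    def test_determinism(self):
        cfg = ScreenSimConfig(seed=4, mortality_prob=0.1, effusion_prob=0.1)
        a, _ = make_screen_dataset(cfg)
        b, _ = make_screen_dataset(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_halved_heart_rate_recovered_as_fold_change(self):
        from zfscreen import run_screen

        cfg = ScreenSimConfig(
            n_compounds=1,
            n_larvae_per_group=10,
            effects={"compound_001": {"heart_rate_bpm": 0.5}},
            seed=5,
        )
        records, _ = make_screen_dataset(cfg)
        res = run_screen(records, metrics=["heart_rate_bpm"])
        fc = res["fold_change"].iloc[0]
        assert fc == pytest.approx(0.5, rel=0.10)


class TestQpcrDataset:
    def test_noise_free_fold_changes_round_trip(self):
        from zfscreen import fold_change_ddct

        table = make_qpcr_dataset(
            ["mxa"], ["base", "treated"], {"treated": {"mxa": 4.0}}, sd=0.0
        )
        fc = fold_change_ddct(table, "mxa", baseline_group="base")
        treated = fc[fc.group == "treated"]
        assert np.allclose(treated["fold_change"], 4.0)
        assert np.allclose(treated["ddct"], -2.0)  # FC 4 = 2^2
        base = fc[fc.group == "base"]
        assert np.allclose(base["fold_change"], 1.0)

    def test_six_replicate_pools_per_group(self):
        table = make_qpcr_dataset(["mxa"], ["a", "b"], {})
        assert table.groupby("group")["sample_id"].nunique().eq(6).all()

    def test_reference_gene_present_for_every_sample(self):
        table = make_qpcr_dataset(["mxa", "il1b"], ["a", "b"], {})
        by_sample = table[table.gene == "rps11"].groupby("sample_id").size()
        assert set(by_sample.index) == set(table["sample_id"].unique())

    def test_reference_in_targets_rejected(self):
        with pytest.raises(ValueError):
            make_qpcr_dataset(["rps11"], ["a"], {})
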