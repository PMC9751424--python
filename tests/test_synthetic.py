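import dataclasses

import numpy as np
import pytest

from meibomorph.errors import ValidationError
from meibomorph.morphometry import gland_shapes, gland_height, summarize_eyelid
from meibomorph.synthetic import (
    CohortConfig,
    EffectFactors,
    EyelidParams,
    GlandSpec,
    generate_cohort,
    render_eyelid,
    render_gland,
    simulate_cohort,
)
from meibomorph.calibration import calibration_config


class TestRenderGland:
    def test_straight_stripe_is_exact_rectangle(self):
        rows, cols = render_gland(GlandSpec(50, 1.0, 0.0, 0.0, 10.0, 3), (60, 21))
        assert rows.size == 50 * 3
        assert rows.min() == 3 and rows.max() == 52
        assert cols.min() == 9 and cols.max() == 11

    def test_rendering_is_seed_free_deterministic(self):
        spec = GlandSpec(40, 2.5, 4.0, 1.5, 30.0, 2)
        a = render_gland(spec, (50, 60))
        b = render_gland(spec, (50, 60))
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_vertical_extent_equals_length_via_pipeline(self):
        from meibomorph.io_masks import label_map_from_array

        spec = GlandSpec(120, 3.0, 5.0, 2.0, 40.0, 5)
        rows, cols = render_gland(spec, (140, 80))
        assert rows.max() - rows.min() + 1 == 120
        arr = np.zeros((140, 80), np.uint8)
        arr[rows, cols] = 1
        shape = gland_shapes(label_map_from_array(arr))[0]
        assert gland_height(shape) == 120

    def test_out_of_canvas_rejected(self):
        with pytest.raises(ValidationError):
            render_gland(GlandSpec(50, 1.0, 0.0, 0.0, 10.0, 3), (40, 21))
        with pytest.raises(ValidationError):
            render_gland(GlandSpec(20, 5.0, 0.0, 0.0, 3.0, 0), (30, 10))

    def test_disconnecting_slope_rejected(self):
        # huge amplitude with many periods on a narrow stripe tears rows apart
        with pytest.raises(ValidationError):
            render_gland(GlandSpec(30, 0.5, 14.0, 6.0, 30.0, 2), (40, 60))


class TestRenderEyelid:
    def test_density_forced_arithmetic(self):
        # 3 straight 50x3 glands in a 200x200 canvas with margin 25:
        # tarsus (200-50)^2 = 22500 px, glands 450 px
        specs = [GlandSpec(50, 1.0, 0.0, 0.0, 60.0 + 40 * i, 40) for i in range(3)]
        _, labels, tarsus, truth = render_eyelid(specs, (200, 200), 25, 140, 110, 0.0)
        assert truth["density"] == pytest.approx(450 / 22500)
        assert labels.pixel_count() == 450

    def test_noiseless_vagueness_is_exact_contrast(self):
        from meibomorph.vagueness import vagueness_value

        specs = [GlandSpec(40, 3.0, 2.0, 1.0, 30.0 + 25 * i, 10) for i in range(2)]
        image, labels, tarsus, truth = render_eyelid(specs, (80, 90), 5, 140.0, 112.0, 0.0)
        res = vagueness_value(image, labels, tarsus)
        assert res.vagueness == pytest.approx(140.0 - 112.0, abs=1e-12)

    def test_label_count_matches_specs(self):
        specs = [GlandSpec(30, 2.0, 1.0, 1.0, 15.0 + 18 * i, 8) for i in range(4)]
        _, labels, _, truth = render_eyelid(specs, (60, 100), 4, 140, 112, 0)
        assert labels.n_glands == 4
        assert truth["n_glands"] == 4

    def test_overlapping_glands_rejected(self):
        specs = [GlandSpec(30, 3.0, 0.0, 0.0, 20.0, 8), GlandSpec(30, 3.0, 0.0, 0.0, 22.0, 8)]
        with pytest.raises(ValidationError):
            render_eyelid(specs, (60, 60), 4, 140, 112, 0)

    def test_gap_below_two_px_rejected(self):
        specs = [GlandSpec(30, 1.0, 0.0, 0.0, 20.0, 8), GlandSpec(30, 1.0, 0.0, 0.0, 23.0, 8)]
        with pytest.raises(ValidationError):
            render_eyelid(specs, (60, 60), 4, 140, 112, 0)

    def test_gland_outside_tarsus_rejected(self):
        specs = [GlandSpec(30, 2.0, 0.0, 0.0, 3.0, 8)]
        with pytest.raises(ValidationError):
            render_eyelid(specs, (60, 60), 5, 140, 112, 0)

    def test_ground_truth_density_matches_pipeline_exactly(self):
        from meibomorph.morphometry import eyelid_density

        specs = [GlandSpec(45, 2.5, 3.0, 2.0, 20.0 + 22 * i, 7) for i in range(3)]
        _, labels, tarsus, truth = render_eyelid(specs, (70, 90), 4, 140, 112, 5.0,
                                                 rng=np.random.default_rng(7))
        assert eyelid_density(labels, tarsus) == truth["density"]


class TestCohort:
    def test_null_effects_give_identically_distributed_groups(self):
        cfg = calibration_config(seed=3, n_subjects=1)
        samples = list(simulate_cohort(cfg))
        assert len(samples) == 4  # 2 eyelids x 2 roles
        roles = {(s.meta.eye_role, s.meta.eyelid) for s in samples}
        assert roles == {("research", "upper"), ("research", "lower"),
                         ("control", "upper"), ("control", "lower")}
        # same subject-level parameter draws up to jitter: gland counts equal
        by = {(s.meta.eye_role, s.meta.eyelid): s for s in samples}
        for lid in ("upper", "lower"):
            assert by[("research", lid)].labels.n_glands == by[("control", lid)].labels.n_glands

    def test_effects_scale_research_heights(self):
        cfg = dataclasses.replace(
            calibration_config(seed=4, n_subjects=3),
            group_effects=EffectFactors(length=0.7),
        )
        heights = {"research": [], "control": []}
        for s in simulate_cohort(cfg):
            mean_len = np.mean([g["length_px"] for g in s.ground_truth["glands"]])
            heights[s.meta.eye_role].append(mean_len)
        assert np.mean(heights["research"]) < 0.85 * np.mean(heights["control"])

    def test_ground_truth_extents_equal_pipeline_heights(self):
        cfg = calibration_config(seed=5, n_subjects=1)
        for s in simulate_cohort(cfg):
            shapes = gland_shapes(s.labels)
            for shape, g in zip(shapes, s.ground_truth["glands"]):
                assert gland_height(shape) == g["length_px"]
                assert shape.area_px == g["area_px"]

    def test_ground_truth_mean_height_matches_summary_exactly(self):
        cfg = calibration_config(seed=6, n_subjects=1)
        s = next(iter(simulate_cohort(cfg)))
        summary = summarize_eyelid(s.labels, s.tarsus, s.meta.eyelid)
        truth_mean = np.mean([g["length_px"] for g in s.ground_truth["glands"]])
        assert summary.mean_height_px == truth_mean
        assert summary.density == s.ground_truth["density"]

    def test_fragmentation_splits_glands(self):
        cfg = dataclasses.replace(calibration_config(seed=8, n_subjects=1), fragmentation_prob=1.0)
        s = next(iter(simulate_cohort(cfg)))
        base = calibration_config(seed=8, n_subjects=1)
        s0 = next(iter(simulate_cohort(base)))
        assert s.labels.n_glands > s0.labels.n_glands

    def test_interval_and_covariates_present(self):
        for s in simulate_cohort(calibration_config(seed=9, n_subjects=2)):
            assert s.meta.interval_months > 0
            assert s.meta.tbut_s > 0
            assert s.meta.tmh_mm > 0


class TestDeterminism:
    def test_same_seed_bit_identical_cohort_dirs(self, tmp_path):
        cfg = calibration_config(seed=11, n_subjects=2)
        a = generate_cohort(cfg, tmp_path / "a")
        b = generate_cohort(cfg, tmp_path / "b")
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_different_seeds_differ(self, tmp_path):
        a = generate_cohort(calibration_config(seed=1, n_subjects=1), tmp_path / "a")
        b = generate_cohort(calibration_config(seed=2, n_subjects=1), tmp_path / "b")
        assert (a / "ground_truth.json").read_bytes() != (b / "ground_truth.json").read_bytes()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = dataclasses.replace(
            CohortConfig(),
            group_effects=EffectFactors(length=0.85, width=0.94),
            upper=EyelidParams(120.0, 15.0, 9.0, 1.0, 5.0, 1.0),
        )
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert CohortConfig.from_yaml(p) == cfg
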