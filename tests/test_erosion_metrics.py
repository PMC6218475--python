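import numpy as np
import pandas as pd
import pytest

from osteoerode.erosion_metrics import (
    REPORT_COLUMNS,
    ErosionParams,
    ErosionReport,
    erosion_percent,
    fill_pores,
    full_pores,
    normalize_report,
    per_bone_report,
    surface_shell,
)
from osteoerode.phantom import PhantomSpec, Pit, generate_phantom
from osteoerode.segmentation import label_bones
from osteoerode.volume_io import BoneMask, LabeledBones

from conftest import TUBE
from oracles import brute_fill_pores, brute_min_distances, brute_surface_shell

PARAMS = ErosionParams(closing_radius_vox=6.0, surface_distance_vox=6.0)


def random_mask(seed, shape=(32, 32, 32), density=0.3):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < density


class TestFillPores:
    def test_solid_cube_unchanged_for_any_radius(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[5:26, 5:26, 5:26] = True
        for radius in (1.5, 3.0, 6.0, 10.0):
            out = fill_pores(BoneMask(data=data), ErosionParams(radius, 5.0))
            np.testing.assert_array_equal(out.data, data)

    @pytest.mark.parametrize("radius", [1.5, 3.0, 8.0])
    def test_enclosed_27_voxel_cavity_filled_exactly(self, radius):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[5:26, 5:26, 5:26] = True
        data[12:15, 12:15, 12:15] = False  # 3x3x3 enclosed cavity
        out = fill_pores(BoneMask(data=data), ErosionParams(radius, 5.0))
        assert int(out.data.sum()) - int(data.sum()) == 27

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("radius", [1.5, 2.0, 2.5])
    def test_matches_brute_force_oracle(self, seed, radius):
        data = random_mask(seed)
        out = fill_pores(BoneMask(data=data), ErosionParams(radius, 5.0))
        expected = brute_fill_pores(data, radius, background_connectivity=6)
        np.testing.assert_array_equal(out.data, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_extensive_and_idempotent(self, seed):
        data = random_mask(seed)
        params = ErosionParams(2.5, 5.0)
        once = fill_pores(BoneMask(data=data), params)
        assert (once.data | data).sum() == once.data.sum()  # superset of input
        twice = fill_pores(once, params)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fill_pores(BoneMask(data=np.zeros((4, 4, 4), dtype=bool)), ErosionParams(1.5, 2.0))

    def test_oversized_structuring_element_rejected(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[4, 4, 4] = True
        with pytest.raises(ValueError, match="diameter"):
            fill_pores(BoneMask(data=data), ErosionParams(20.0, 2.0))


class TestSurfaceShell:
    def test_matches_pairwise_distance_oracle(self):
        data = np.zeros((14, 14, 14), dtype=bool)
        zz, yy, xx = np.indices(data.shape)
        data[(zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2 <= 25] = True  # solid ball r=5
        for distance in (1.0, 2.0, 3.5):
            shell = surface_shell(BoneMask(data=data), distance)
            np.testing.assert_array_equal(shell.data, brute_surface_shell(data, distance))

    def test_saturates_to_whole_volume(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[4:6, 4:6, 4:6] = True
        shell = surface_shell(BoneMask(data=data), distance_vox=20.0)
        assert shell.data.all()

    def test_monotone_in_distance(self):
        data = random_mask(7, shape=(16, 16, 16))
        prev = np.zeros_like(data)
        for d in (1.0, 2.0, 4.0, 8.0):
            shell = surface_shell(BoneMask(data=data), d).data
            assert (shell | prev).sum() == shell.sum()  # nested
            prev = shell


class TestErosionPercent:
    def test_intact_regularized_phantom_is_exactly_zero(self, intact_tube):
        mask, _ = intact_tube
        percent, filled, bone = erosion_percent(mask, PARAMS)
        assert percent == 0.0
        assert filled == 0
        assert bone == mask.count()

    def test_pit_recovery_within_tolerance(self, pitted_tube):
        mask, truth = pitted_tube
        percent, _, _ = erosion_percent(mask, PARAMS)
        expected = 100.0 * truth.expected_erosion_fraction
        assert percent == pytest.approx(expected, rel=0.15)

    def test_deep_cavity_contributes_zero_to_erosion(self, cavity_tube):
        mask, truth = cavity_tube
        params = ErosionParams(closing_radius_vox=6.0, surface_distance_vox=2.0)
        percent, filled, _ = erosion_percent(mask, params)
        assert filled == 0
        assert percent == 0.0
        # ...while full pores count the cavity in full
        _, pore_voxels = full_pores(mask, params)
        assert pore_voxels >= truth.expected_full_pore_voxels

    def test_range_and_denominator_modes(self, pitted_tube):
        mask, _ = pitted_tube
        pv, filled, bone = erosion_percent(mask, PARAMS, denominator="volume")
        ps, filled_s, _ = erosion_percent(mask, PARAMS, denominator="surface")
        assert 0.0 <= pv <= 100.0
        assert filled_s == filled
        assert ps > pv  # surface voxel count is smaller than volume
        with pytest.raises(ValueError):
            erosion_percent(mask, PARAMS, denominator="area")

    def test_monotone_in_added_pit(self):
        base = dict(**TUBE, regularize_radius_vox=6.0)
        pits = [Pit(center_direction=(0, 0, 1), radius_vox=3.0),
                Pit(center_direction=(0, 1, 0), radius_vox=3.0)]
        results = []
        for n in (0, 1, 2):
            _, mask, _ = generate_phantom(PhantomSpec(**base, pits=pits[:n]))
            results.append(erosion_percent(mask, PARAMS)[0])
        assert results[0] <= results[1] <= results[2]


class TestFullPores:
    def test_invariant_to_surface_distance(self, cavity_tube):
        mask, _ = cavity_tube
        values = {
            full_pores(mask, ErosionParams(6.0, d))
            for d in (2.0, 5.0, 10.0)
        }
        assert len(values) == 1

    def test_convex_solid_has_no_pores(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[4:16, 4:16, 4:16] = True
        for radius in (1.5, 4.0):
            percent, voxels = full_pores(BoneMask(data=data), ErosionParams(radius, 3.0))
            assert (percent, voxels) == (0.0, 0)

    def test_shell_restricted_count_never_exceeds_full_pores(self, cavity_tube):
        mask, _ = cavity_tube
        for d in (1.0, 3.0, 8.0):
            params = ErosionParams(6.0, d)
            _, filled_in_shell, _ = erosion_percent(mask, params)
            _, pore_voxels = full_pores(mask, params)
            assert filled_in_shell <= pore_voxels


class TestPerBoneReport:
    def test_single_label_equals_whole(self, pitted_tube):
        mask, _ = pitted_tube
        labels = LabeledBones(data=mask.data.astype(np.int32), label_names={1: "bone"})
        report = per_bone_report(mask, labels, PARAMS)
        row1, whole = report.row(1), report.row("whole")
        for col in ("bone_voxels", "filled_voxels_in_shell", "erosion_percent",
                    "full_pore_voxels", "full_pore_percent"):
            assert row1[col] == whole[col]

    def test_two_shells_pits_only_in_a(self, two_shells):
        mask, labels, truth_a, _ = two_shells
        report = per_bone_report(mask, labels, PARAMS)
        assert report.row(2)["erosion_percent"] == 0.0
        assert report.row(2)["full_pore_voxels"] == 0
        assert report.row(1)["filled_voxels_in_shell"] > 0

    def test_per_label_counts_sum_to_whole(self, two_shells):
        mask, labels, _, _ = two_shells
        report = per_bone_report(mask, labels, PARAMS)
        per_label = report.table[report.table["label"] != "whole"]
        whole = report.row("whole")
        assert per_label["filled_voxels_in_shell"].sum() == whole["filled_voxels_in_shell"]
        assert per_label["full_pore_voxels"].sum() == whole["full_pore_voxels"]
        assert per_label["bone_voxels"].sum() == whole["bone_voxels"]

    def test_params_echoed_in_every_row(self, two_shells):
        mask, labels, _, _ = two_shells
        report = per_bone_report(mask, labels, PARAMS)
        assert (report.table["closing_radius_vox"] == PARAMS.closing_radius_vox).all()
        assert (report.table["surface_distance_vox"] == PARAMS.surface_distance_vox).all()
        assert list(report.table.columns) == REPORT_COLUMNS

    def test_labels_outside_mask_rejected(self, pitted_tube):
        mask, _ = pitted_tube
        bad = LabeledBones(data=np.ones(mask.shape, dtype=np.int32))
        with pytest.raises(ValueError, match="label_bones"):
            per_bone_report(mask, bad, PARAMS)

    def test_shape_mismatch_rejected(self, pitted_tube):
        mask, _ = pitted_tube
        labels = LabeledBones(data=np.zeros((4, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError, match="shape"):
            per_bone_report(mask, labels, PARAMS)

    def test_csv_round_trip(self, two_shells, tmp_path):
        mask, labels, _, _ = two_shells
        report = per_bone_report(mask, labels, PARAMS)
        path = report.to_csv(tmp_path / "report.csv")
        back = ErosionReport.from_csv(path)
        assert list(back.table.columns) == REPORT_COLUMNS
        assert back.params.closing_radius_vox == PARAMS.closing_radius_vox
        pd.testing.assert_frame_equal(
            back.table.astype({"label": str}),
            report.table.astype({"label": str}),
            check_dtype=False,
        )


def make_report(erosion_by_label: dict, params=PARAMS) -> ErosionReport:
    rows = []
    for label, pct in erosion_by_label.items():
        rows.append({
            "label": label, "bone_name": str(label), "bone_voxels": 1000,
            "filled_voxels_in_shell": int(10 * pct), "erosion_percent": pct,
            "full_pore_voxels": 0, "full_pore_percent": 0.0,
            "normalized_erosion": np.nan,
            "closing_radius_vox": params.closing_radius_vox,
            "surface_distance_vox": params.surface_distance_vox,
        })
    return ErosionReport(table=pd.DataFrame(rows, columns=REPORT_COLUMNS), params=params)


class TestNormalize:
    def test_self_normalization_is_one(self):
        report = make_report({1: 2.5, 2: 4.0})
        out = normalize_report(report, [make_report({1: 2.5, 2: 4.0})])
        assert out.row(1)["normalized_erosion"] == pytest.approx(1.0)
        assert out.row(2)["normalized_erosion"] == pytest.approx(1.0)

    def test_mean_baseline_arithmetic(self):
        report = make_report({1: 4.0, 2: 4.0})
        baselines = [make_report({1: 1.0, 2: 4.0}), make_report({1: 3.0, 2: 4.0})]
        out = normalize_report(report, baselines)
        assert out.row(1)["normalized_erosion"] == pytest.approx(2.0)  # mean baseline 2%
        assert out.row(2)["normalized_erosion"] == pytest.approx(1.0)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_report(make_report({1: 1.0}), [])

    def test_zero_baseline_flagged_not_infinite(self):
        out = normalize_report(make_report({1: 2.0}), [make_report({1: 0.0})])
        assert np.isnan(out.row(1)["normalized_erosion"])
        assert "1" in out.flags

    def test_label_missing_from_baseline_flagged(self):
        out = normalize_report(make_report({1: 2.0, 2: 3.0}), [make_report({1: 2.0})])
        assert np.isnan(out.row(2)["normalized_erosion"])
        assert "2" in out.flags
        assert out.row(1)["normalized_erosion"] == pytest.approx(1.0)

    def test_mismatched_params_rejected(self):
        other = ErosionParams(closing_radius_vox=3.0, surface_distance_vox=6.0)
        with pytest.raises(ValueError, match="params"):
            normalize_report(make_report({1: 1.0}), [make_report({1: 1.0}, params=other)])


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ErosionParams(closing_radius_vox=0.5, surface_distance_vox=5.0)
        with pytest.raises(ValueError):
            ErosionParams(closing_radius_vox=5.0, surface_distance_vox=0.0)
        with pytest.raises(ValueError):
            ErosionParams(closing_radius_vox=5.0, surface_distance_vox=5.0, connectivity=18)
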