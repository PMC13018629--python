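"""Capsule geometry, mask measurement, and outlier filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from sizedyn.geometry import (
    FilterCriteria,
    apply_hard_filters,
    capsule_area,
    derive_geometry,
    log_sigma_filter,
    measure_mask,
    summarize,
    surface_and_volume,
    width_from_area_length,
)
from sizedyn.simulate import render_mask


class TestWidthInversion:
    @pytest.mark.parametrize(
        "area, length, expected_w",
        [
            (math.pi / 4.0, 1.0, 1.0),  # sphere limit: circle of diameter 1
            (3.0 + math.pi / 4.0, 4.0, 1.0),  # forward capsule area, inverted
        ],
    )
    def test_known_widths(self, area, length, expected_w):
        assert width_from_area_length(area, length) == pytest.approx(expected_w, rel=1e-12)

    @given(
        w=st.floats(0.2, 3.0),
        extra=st.floats(0.0, 8.0),
    )
    def test_round_trip(self, w, extra):
        """Inverting the capsule area of any valid (L, w) recovers w."""
        L = w + extra
        area = capsule_area(L, w)
        assert width_from_area_length(area, L) == pytest.approx(w, rel=1e-9)

    def test_inadmissible_inputs_yield_nan(self):
        # area larger than any capsule of this length can have
        assert np.isnan(width_from_area_length(10.0, 1.0))
        assert np.isnan(width_from_area_length(-1.0, 1.0))
        assert np.isnan(width_from_area_length(1.0, -2.0))

    def test_vectorized(self):
        w = width_from_area_length(
            np.array([math.pi / 4.0, 10.0]), np.array([1.0, 1.0])
        )
        assert w[0] == pytest.approx(1.0)
        assert np.isnan(w[1])


class TestSurfaceVolume:
    def test_sphere_limit(self):
        surface, volume = surface_and_volume(1.0, 1.0)
        assert volume == pytest.approx(math.pi / 6.0, rel=1e-15)
        assert surface == pytest.approx(math.pi, rel=1e-15)
        # projected area at the sphere limit is the circle area
        assert capsule_area(1.0, 1.0) == pytest.approx(math.pi / 4.0, rel=1e-15)

    def test_direct_substitution(self):
        surface, volume = surface_and_volume(4.0, 1.0)
        assert volume == pytest.approx(11.0 * math.pi / 12.0, rel=1e-15)
        assert surface == pytest.approx(4.0 * math.pi, rel=1e-15)

    def test_monte_carlo_voxel_oracle(self, rng):
        """Rejection-sampled volume of an L=3, w=1 capsule matches the formula."""
        n = 400_000
        pts = np.column_stack(
            [
                rng.uniform(-1.5, 1.5, n),
                rng.uniform(-0.5, 0.5, n),
                rng.uniform(-0.5, 0.5, n),
            ]
        )
        axis = np.clip(pts[:, 0], -1.0, 1.0)  # segment half-length (L-w)/2
        inside = (pts[:, 0] - axis) ** 2 + pts[:, 1] ** 2 + pts[:, 2] ** 2 <= 0.25
        v_mc = inside.mean() * 3.0
        _, v_analytic = surface_and_volume(3.0, 1.0)
        assert v_mc == pytest.approx(v_analytic, rel=5e-3)

    def test_width_above_length_rejected(self):
        with pytest.raises(ValueError):
            surface_and_volume(1.0, 2.0)

    @given(
        w=st.floats(0.3, 2.0),
        dL=st.floats(0.01, 5.0),
        dw=st.floats(0.01, 1.0),
    )
    def test_volume_monotonicity(self, w, dL, dw):
        L = w + dw + dL  # keep w + dw <= L
        _, v = surface_and_volume(L, w)
        _, v_longer = surface_and_volume(L + dL, w)
        _, v_wider = surface_and_volume(L, w + dw)
        assert v_longer > v
        assert v_wider > v


def _rotated_rectangle(l_px, w_px, angle_deg, n=100):
    c = (np.arange(n) + 0.5) - n / 2
    x, y = np.meshgrid(c, c)
    th = math.radians(angle_deg)
    xr = math.cos(th) * x + math.sin(th) * y
    yr = -math.sin(th) * x + math.cos(th) * y
    return (np.abs(xr) <= l_px / 2) & (np.abs(yr) <= w_px / 2)


class TestMeasureMask:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 5:45] = True  # 10 x 40 pixels
        area, length = measure_mask(mask, 0.005)
        assert area == pytest.approx(2.0)
        assert length == pytest.approx(40.0 * math.sqrt(0.005), rel=1e-12)

    @pytest.mark.parametrize("angle", [15, 30, 45, 60])
    def test_rotation_invariance(self, angle):
        px = math.sqrt(0.005)
        _, l0 = measure_mask(_rotated_rectangle(40, 10, 0), 0.005)
        _, l1 = measure_mask(_rotated_rectangle(40, 10, angle), 0.005)
        assert abs(l1 - l0) < px

    def test_rendered_capsule_area(self):
        mask = render_mask(4.0, 1.0, 30.0, 0.005)
        area, _ = measure_mask(mask, 0.005)
        assert area == pytest.approx(capsule_area(4.0, 1.0), rel=0.02)

    def test_render_measure_invert_width(self):
        """Full round trip: render a capsule, measure the mask, invert the width."""
        px = math.sqrt(0.005)
        mask = render_mask(4.0, 1.0, 30.0, 0.005)
        area, length = measure_mask(mask, 0.005)
        w = width_from_area_length(area, length)
        assert abs(w - 1.0) < 2.0 * px

    def test_empty_and_split_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_mask(np.zeros((5, 5), dtype=bool))
        two = np.zeros((10, 10), dtype=bool)
        two[1:3, 1:3] = True
        two[7:9, 7:9] = True
        with pytest.raises(ValueError, match="components"):
            measure_mask(two)


def _records(**cols):
    return pd.DataFrame(cols)


class TestHardFilters:
    def test_all_criteria_met(self):
        df = _records(width_um=[0.5], length_um=[2.0], projected_area_um2=[1.0])
        kept, log = apply_hard_filters(df)
        assert len(kept) == 1 and len(log) == 0

    def test_aspect_breach(self):
        df = _records(width_um=[0.5], length_um=[4.0], projected_area_um2=[1.9])
        kept, log = apply_hard_filters(df)
        assert len(kept) == 0
        assert log["reason"].tolist() == ["aspect"]

    def test_against_brute_force(self, rng):
        n = 2000
        df = _records(
            width_um=rng.uniform(0.1, 1.5, n),
            length_um=rng.uniform(0.5, 12.0, n),
            projected_area_um2=rng.uniform(0.2, 6.0, n),
        )
        kept, log = apply_hard_filters(df)
        w, L, a = (df[c].to_numpy() for c in ("width_um", "length_um", "projected_area_um2"))
        expected = (
            (w > 0.35) & (L > 1.05) & (L < 10) & (L / w > 1) & (L / w < 7) & (a > 0.73)
        )
        assert len(kept) == expected.sum()
        assert len(kept) + len(log) == n

    def test_idempotent(self, rng):
        n = 500
        df = _records(
            width_um=rng.uniform(0.1, 1.5, n),
            length_um=rng.uniform(0.5, 12.0, n),
            projected_area_um2=rng.uniform(0.2, 6.0, n),
        )
        once, _ = apply_hard_filters(df)
        twice, log2 = apply_hard_filters(once)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(min_length_um=5.0, max_length_um=2.0)
        with pytest.raises(ValueError):
            FilterCriteria(min_width_um=-1.0)


class TestLogSigmaFilter:
    def test_equal_volumes_all_kept(self):
        df = pd.DataFrame({"volume_um3": [2.0] * 10})
        assert len(log_sigma_filter(df)) == 10

    def test_planted_outlier_removed(self, rng):
        lv = rng.normal(0.0, 0.1, 500)
        lv[0] = lv.mean() + 5.0 * lv.std()
        df = pd.DataFrame({"volume_um3": np.exp(lv)})
        kept = log_sigma_filter(df)
        assert 0 not in kept.index
        assert len(kept) >= 495

    def test_small_group_passthrough(self):
        df = pd.DataFrame({"volume_um3": [1.0, 100.0]})
        assert len(log_sigma_filter(df)) == 2


class TestSummarize:
    BASE_COLS = dict(length_um=1.0, width_um=1.0, sv_ratio_per_um=1.0)

    def test_single_record(self):
        df = pd.DataFrame(
            {"condition": ["a"], "time_h": [0.0], "volume_um3": [2.5], **self.BASE_COLS}
        )
        s = summarize(df, seed=0)
        assert s.loc[0, "mean_volume_um3"] == 2.5
        assert s.loc[0, "sd_volume_um3"] == 0.0
        assert s.loc[0, "n_cells"] == 1

    def test_identical_groups_identical_summaries(self, rng):
        v = rng.lognormal(0.0, 0.3, 50)
        frames = []
        for cond in ("a", "b"):
            frames.append(
                pd.DataFrame(
                    {"condition": cond, "time_h": 1.0, "volume_um3": v, **self.BASE_COLS}
                )
            )
        s = summarize(pd.concat(frames, ignore_index=True), seed=7)
        a = s[s.condition == "a"].drop(columns="condition").reset_index(drop=True)
        b = s[s.condition == "b"].drop(columns="condition").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_coverage(self, rng):
        """95% bootstrap CI on a log-normal mean covers the truth ~95% of the time."""
        true_mean = math.exp(0.5**2 / 2.0)
        hits = 0
        reps = 150
        for rep in range(reps):
            v = rng.lognormal(0.0, 0.5, 500)
            df = pd.DataFrame(
                {"condition": "c", "time_h": 0.0, "volume_um3": v, **self.BASE_COLS}
            )
            s = summarize(df, bootstrap_reps=400, seed=rep)
            hits += (
                abs(s.loc[0, "mean_volume_um3"] - true_mean)
                <= s.loc[0, "ci_halfwidth_volume"]
            )
        assert 0.88 <= hits / reps <= 0.99


class TestDeriveGeometry:
    def test_adds_columns_and_rejects_inadmissible(self):
        df = pd.DataFrame(
            {
                "cell_id": ["ok", "bad"],
                "condition": ["c", "c"],
                "time_h": [0.0, 0.0],
                "projected_area_um2": [capsule_area(3.0, 0.8), 50.0],
                "length_um": [3.0, 1.0],
            }
        )
        out, rejected = derive_geometry(df)
        assert out["cell_id"].tolist() == ["ok"]
        assert_allclose(out["width_um"].to_numpy(), [0.8], rtol=1e-9)
        assert rejected["reason"].tolist() == ["no_admissible_width"]
        expected_sv = out["surface_um2"] / out["volume_um3"]
        assert_allclose(out["sv_ratio_per_um"].to_numpy(), expected_sv, rtol=1e-12)


class TestCellRecord:
    def test_derive_fills_capsule_fields(self):
        from sizedyn.geometry import CellRecord

        rec = CellRecord("c1", 0.0, "LB", capsule_area(3.0, 0.8), 3.0).derive()
        assert rec.width_um == pytest.approx(0.8, rel=1e-9)
        expected_surface, expected_volume = surface_and_volume(3.0, rec.width_um)
        assert rec.surface_um2 == pytest.approx(expected_surface)
        assert rec.volume_um3 == pytest.approx(expected_volume)

    def test_derive_rejects_inadmissible(self):
        from sizedyn.geometry import CellRecord

        with pytest.raises(ValueError, match="no admissible"):
            CellRecord("c1", 0.0, "LB", 50.0, 1.0).derive()


class TestGroupedLogSigma:
    def test_outliers_removed_per_group(self, rng):
        from sizedyn.geometry import grouped_log_sigma_filter

        frames = []
        for t in (0.0, 1.0):
            lv = rng.normal(0.0, 0.1, 200)
            lv[0] = 2.0  # gross outlier in each group
            frames.append(
                pd.DataFrame(
                    {"condition": "c", "time_h": t, "volume_um3": np.exp(lv)}
                )
            )
        df = pd.concat(frames, ignore_index=True)
        kept = grouped_log_sigma_filter(df)
        assert len(kept) == len(df) - 2
        assert kept.groupby("time_h").size().tolist() == [199, 199]
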