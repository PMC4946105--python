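import math
import warnings

import numpy as np
import pytest

from ctcscan.data import load_reference_table
from ctcscan.fafish import (
    MAX_Z_STACKS,
    NATIVE,
    NATIVE_COPY_GAIN,
    NON_INTERPRETABLE,
    REARRANGED,
    BreakApartRules,
    FishSpot3D,
    NonInterpretableError,
    ScanConfig,
    SpotCountTable,
    SpotDetectionParams,
    build_spot_count_table,
    call_break_apart,
    countable_spots,
    detect_spots,
    detection_rate,
    multi_exposure_fuse,
    step_sweep,
    zstack_sweep,
)
from ctcscan.image import FISH_GREEN, FISH_RED, ZStackSeries
from ctcscan.simulate import (
    ExposureModel,
    FocalSurface,
    SimFishSpot,
    SimulatedCell,
    render_zstack,
)


def _spot(x, y, z=0.0, channel=FISH_RED, **kw):
    defaults = dict(peak_intensity=100.0, lateral_diameter_um=1.0, z_extent=3)
    defaults.update(kw)
    return FishSpot3D(x_um=x, y_um=y, z_um=z, channel=channel, **defaults)


def _fish_cell(spots):
    cell = SimulatedCell(
        center_um=(0.0, 0.0),
        nucleus_area_um2=200.0,
        nucleus_thickness_um=4.0,
        type_label="ctc",
        marker_levels={},
    )
    cell.fish_spots = spots
    return cell


class TestScanConfig:
    def test_defaults(self):
        cfg = ScanConfig()
        assert cfg.n_stacks == 30 and cfg.step_um == 0.6
        assert cfg.span_um == pytest.approx(17.4)
        assert cfg.n_focus_points == 9

    def test_scanner_limit_30(self):
        with pytest.raises(ValueError):
            ScanConfig(n_stacks=31)
        ScanConfig(n_stacks=MAX_Z_STACKS)  # allowed

    def test_exposure_range(self):
        with pytest.raises(ValueError):
            ScanConfig(exposures_ms={FISH_RED: (4.0,)})
        with pytest.raises(ValueError):
            ScanConfig(exposures_ms={FISH_RED: (101.0,)})
        with pytest.raises(ValueError):
            ScanConfig(exposures_ms={FISH_RED: (10.0, 20.0, 30.0, 40.0)})

    def test_exposure_setting_space(self):
        # 3 exposures on 2 channels -> 9; on 3 channels -> 27
        assert ScanConfig().n_exposure_settings == 9
        three = ScanConfig(
            exposures_ms={c: (10.0, 30.0, 90.0) for c in (FISH_RED, FISH_GREEN, "aqua")}
        )
        assert three.n_exposure_settings == 27


class TestDetectSpots:
    def test_empty_stack(self):
        stack = ZStackSeries(np.zeros((0, 4, 4), dtype=np.uint8), 0.2, 0.6)
        assert detect_spots(stack) == []
        blank = ZStackSeries(np.full((5, 32, 32), 8, dtype=np.uint8), 0.2, 0.6)
        assert detect_spots(blank) == []

    def test_planted_spots_recovered_with_positions(self):
        rng = np.random.default_rng(2)
        spots = []
        # 16 well-separated spots inside the comb span
        grid = [(-7.5 + 5 * i, -7.5 + 5 * j) for i in range(4) for j in range(4)]
        for gx, gy in grid:
            spots.append(SimFishSpot(gx, gy, float(rng.uniform(-5, 5)), FISH_RED, amplitude=4.0))
        cell = _fish_cell(spots)
        stack = render_zstack(
            [cell], FocalSurface.flat(), n_stacks=30, step_um=0.6, channel=FISH_RED,
            fov_um=24.0, rng=np.random.default_rng(3),
        )
        detected = detect_spots(stack)
        assert len(detected) == 16
        truth = np.array([(s.x_um + 12.0, s.y_um + 12.0) for s in spots])
        got = np.array([(s.x_um, s.y_um) for s in detected])
        d = np.linalg.norm(truth[:, None, :] - got[None, :, :], axis=-1)
        # each planted spot has a detection within 1 px laterally
        assert (d.min(axis=1) <= stack.pixel_size_um).all()

    def test_close_pair_merged_with_flag(self):
        # 0.3 um apart: below lateral resolution -> one spot, flagged
        pair = [SimFishSpot(-0.15, 0.0, 0.0, FISH_RED), SimFishSpot(0.15, 0.0, 0.0, FISH_RED)]
        singles = [SimFishSpot(5.0, 5.0, 0.0, FISH_RED), SimFishSpot(-5.0, 5.0, 0.0, FISH_RED),
                   SimFishSpot(5.0, -5.0, 0.0, FISH_RED)]
        cell = _fish_cell(pair + singles)
        stack = render_zstack([cell], FocalSurface.flat(), n_stacks=15, step_um=0.6, channel=FISH_RED)
        detected = detect_spots(stack)
        assert len(detected) == 4  # pair collapsed
        merged = [s for s in detected if s.may_be_merged]
        assert len(merged) == 1
        # the merged one is the pair (near the FOV centre)
        assert math.hypot(merged[0].x_um - 12.0, merged[0].y_um - 12.0) < 1.0

    def test_saturated_everywhere_non_interpretable(self):
        stack = ZStackSeries(np.full((5, 32, 32), 255, dtype=np.uint8), 0.2, 0.6)
        with pytest.raises(NonInterpretableError):
            detect_spots(stack)


class TestMultiExposureFuse:
    def test_tie_breaks_to_lowest_exposure(self):
        spots = [_spot(1.0, 1.0), _spot(3.0, 3.0)]
        result = multi_exposure_fuse({20.0: list(spots), 50.0: list(spots), 100.0: list(spots)})
        assert result.exposure_ms == 20.0
        assert len(result.spots) == 2

    def test_all_non_interpretable(self):
        err = NonInterpretableError("focus failure")
        with pytest.raises(NonInterpretableError):
            multi_exposure_fuse({20.0: err, 50.0: err})

    def test_mid_exposure_beats_bloomed_high(self):
        # bright pair 1.2 um apart + a dim extra spot: the lowest exposure
        # misses the dim spot, the highest saturates the pair into bloomed
        # blobs; the middle exposure wins
        model = ExposureModel(read_noise_sd=0.0)
        cell = _fish_cell(
            [
                SimFishSpot(-0.6, 0.0, 0.0, FISH_RED, amplitude=5.0),
                SimFishSpot(0.6, 0.0, 0.0, FISH_RED, amplitude=5.0),
                SimFishSpot(5.0, 5.0, 0.0, FISH_RED, amplitude=0.4),
            ]
        )
        params = SpotDetectionParams(response_threshold=3.0)
        detections = {}
        for exposure in (10.0, 40.0, 100.0):
            stack = render_zstack(
                [cell], FocalSurface.flat(), n_stacks=15, step_um=0.6,
                channel=FISH_RED, exposure_ms=exposure, model=model,
            )
            detections[exposure] = detect_spots(stack, params)
        result = multi_exposure_fuse(detections)
        assert result.exposure_ms == 40.0

    def test_chosen_count_maximal_randomized(self):
        # definitional property, brute-forced on random spot lists
        rng = np.random.default_rng(11)
        for _ in range(100):
            detections = {}
            for exposure in (10.0, 40.0, 100.0):
                n = int(rng.integers(0, 8))
                detections[exposure] = [
                    _spot(float(rng.uniform(0, 20)), float(rng.uniform(0, 20)),
                          saturated=bool(rng.uniform() < 0.2), may_be_merged=bool(rng.uniform() < 0.2))
                    for _ in range(n)
                ]
            result = multi_exposure_fuse(detections)
            counts = {e: len(countable_spots(s)) for e, s in detections.items()}
            assert counts[result.exposure_ms] == max(counts.values())
            ties = [e for e, c in counts.items() if c == counts[result.exposure_ms]]
            assert result.exposure_ms == min(ties)


class TestCallBreakApart:
    def _pairs(self, n, sep=0.2, spacing=5.0):
        red, green = [], []
        for i in range(n):
            x = i * spacing
            red.append(_spot(x, 0.0))
            green.append(_spot(x + sep, 0.0, channel=FISH_GREEN))
        return red, green

    def test_two_fused_pairs_native(self):
        red, green = self._pairs(2)
        call = call_break_apart(red, green)
        assert call.verdict == NATIVE
        assert call.fused_pairs == 2 and call.split_pairs == 0

    def test_split_pair_rearranged(self):
        red, green = self._pairs(1)
        red.append(_spot(20.0, 0.0))
        green.append(_spot(20.0, 8.0, channel=FISH_GREEN))  # 8 um apart: split
        call = call_break_apart(red, green)
        assert call.verdict == REARRANGED
        assert call.fused_pairs == 1 and call.split_pairs == 1

    def test_five_fused_pairs_copy_gain(self):
        red, green = self._pairs(5)
        call = call_break_apart(red, green)
        assert call.verdict == NATIVE_COPY_GAIN
        assert call.fused_pairs == 5

    def test_isolated_single_colour_rearranged(self):
        red, green = self._pairs(2)
        red.append(_spot(30.0, 0.0))
        call = call_break_apart(red, green)
        assert call.verdict == REARRANGED
        assert call.isolated == 1

    def test_empty_both_channels_non_interpretable(self):
        call = call_break_apart([], [])
        assert call.verdict == NON_INTERPRETABLE
        assert call.reason

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            BreakApartRules(d_fuse_um=2.0, d_split_um=1.0)


class TestSpotCountTable:
    def test_single_entry_table(self):
        t = SpotCountTable.from_records([("cell1", "s30", 4)])
        assert detection_rate(t, "s30") == 100
        assert t.df.loc["cell1", "s30"] == 4.0

    def test_duplicate_entry_rejected(self):
        with pytest.raises(ValueError):
            SpotCountTable.from_records([("c", "s", 4), ("c", "s", 5)])

    def test_unknown_setting(self):
        t = SpotCountTable.from_records([("c", "s", 4)])
        with pytest.raises(KeyError):
            detection_rate(t, "other")

    def test_tie_row_counts_for_every_setting(self):
        # all-equal row is "best" at every setting
        records = [("c", s, 10) for s in (5, 10, 15, 20, 25, 30)]
        t = SpotCountTable.from_records(records)
        for s in (5, 10, 15, 20, 25, 30):
            assert detection_rate(t, s) == 100

    def test_ni_ignored_in_row_max(self):
        # n.i. at one setting does not disqualify the row elsewhere
        t = SpotCountTable.from_records([("c", 5, None), ("c", 30, 7)])
        assert detection_rate(t, 30) == 100
        assert detection_rate(t, 5) == 0

    def test_fully_missing_rows_dropped_with_warning(self):
        t = SpotCountTable.from_records(
            [("a", 5, None), ("a", 30, None), ("b", 5, 1), ("b", 30, 2)]
        )
        with pytest.warns(UserWarning, match="dropped"):
            assert detection_rate(t, 30) == 100

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(13)
        settings = [5, 10, 15, 20, 25, 30]
        for _ in range(50):
            n_cells = int(rng.integers(1, 12))
            records = []
            for ci in range(n_cells):
                for s in settings:
                    v = None if rng.uniform() < 0.15 else int(rng.integers(0, 40))
                    records.append((ci, s, v))
            t = SpotCountTable.from_records(records)
            for s in settings:
                # oracle: enumerate row maxima by hand
                k = n = 0
                for ci in range(n_cells):
                    row = {s2: v for (c2, s2, v) in records if c2 == ci}
                    obs = [v for v in row.values() if v is not None]
                    if not obs:
                        continue
                    n += 1
                    if row[s] is not None and row[s] == max(obs):
                        k += 1
                if n == 0:
                    continue
                expected = math.floor(100.0 * k / n + 0.5)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    assert detection_rate(t, s) == expected

    def test_scale_free(self):
        records = [("a", 5, 3), ("a", 30, 9), ("b", 5, 8), ("b", 30, 4)]
        scaled = [(c, s, v * 7) for c, s, v in records]
        for s in (5, 30):
            assert detection_rate(SpotCountTable.from_records(records), s) == detection_rate(
                SpotCountTable.from_records(scaled), s
            )

    def test_equality_including_missing(self):
        a = SpotCountTable.from_records([("c", 5, None), ("c", 30, 2)])
        b = SpotCountTable.from_records([("c", 5, None), ("c", 30, 2)])
        assert a == b

    def test_build_spot_count_table(self):
        t = build_spot_count_table(["x"], ["s"], lambda cell, setting: 4)
        assert t.df.iloc[0, 0] == 4.0
        with pytest.raises(ValueError):
            build_spot_count_table(["x"], ["s", "s"], lambda cell, setting: 4)


class TestReferenceTables:
    def test_step_table_dimensions(self):
        t = load_reference_table("step_alk")
        assert t.df.shape == (24, 4)
        assert list(t.df.columns) == [0.5, 0.6, 0.7, 0.8]

    def test_zstack_table_dimensions(self):
        for key in ("zstacks_alk", "zstacks_ros1", "zstacks_erg"):
            t = load_reference_table(key)
            assert t.df.shape == (22, 6)
            assert list(t.df.columns) == [5, 10, 15, 20, 25, 30]

    def test_unknown_key(self):
        with pytest.raises(KeyError):
            load_reference_table("nope")


class TestSweeps:
    def test_flat_cohort_all_settings_equal(self):
        # degenerate: spots at the focus plane are captured by any comb
        res = zstack_sweep(
            stacks=(5, 30), n_cells=4, spots_per_channel=4, nucleus_thickness_um=0.01, seed=3
        )
        assert res.rates[5] == res.rates[30] == 100

    def test_thirty_stacks_beats_five(self):
        res = zstack_sweep(stacks=(5, 30), n_cells=6, spots_per_channel=6, seed=4)
        assert res.rates[30] >= res.rates[5]
        assert res.capture_fraction[30] >= res.capture_fraction[5]

    def test_row_counts_non_decreasing_on_average(self):
        res = zstack_sweep(stacks=(5, 15, 30), n_cells=6, spots_per_channel=6, seed=5)
        means = res.table.df.mean()
        assert means[5] <= means[15] <= means[30]

    def test_detected_never_exceeds_planted(self):
        res = zstack_sweep(stacks=(30,), n_cells=6, spots_per_channel=6, seed=6)
        assert (res.table.df.to_numpy() <= 6 + 1).all()  # +1: rare noise blob

    def test_reproducible(self):
        a = zstack_sweep(stacks=(5, 30), n_cells=4, seed=8)
        b = zstack_sweep(stacks=(5, 30), n_cells=4, seed=8)
        assert a.rates == b.rates
        assert a.table == b.table

    def test_step_sweep_runs(self):
        res = step_sweep(steps=(0.5, 0.8), n_cells=4, seed=9)
        assert set(res.rates) == {0.5, 0.8}
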