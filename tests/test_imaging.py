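"""Dual-view TIRF movie analysis: registration, detection, traces, histograms."""

import numpy as np
import pandas as pd
import pytest

from vesifret import synthetic_data as sd
from vesifret.errors import ConfigurationError, DomainError, RegistrationError
from vesifret.photophysics import FretParams
from vesifret.single_vesicle_imaging import (
    EfretHistogram,
    SpotTable,
    VesicleMovie,
    analyze_movie,
    build_histogram,
    compare_conditions,
    detect_spots,
    extract_traces,
    split_and_register,
    split_movie,
    trace_efret,
    traces_to_efret_table,
)


def _spot_image(shape, positions, brightness, sigma=1.0, background=100.0,
                seed=0, noise_sd=2.0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, background)
    for (y, x), b in zip(positions, brightness):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        img += b * np.exp(-((rr - y) ** 2 + (cc - x) ** 2) / (2 * sigma**2)) / (
            2 * np.pi * sigma**2
        )
    if noise_sd:
        img = img + rng.normal(0, noise_sd, shape)
    return img


class TestSplitAndRegister:
    def _movie_with_shift(self, dy, dx, seed=0, noise_sd=1.0):
        rng = np.random.default_rng(seed)
        half = np.zeros((40, 60))
        pos = [(12, 15), (25, 40), (30, 20), (10, 45)]
        half = _spot_image((40, 60), pos, [500] * 4, seed=seed, noise_sd=0)
        from scipy import ndimage
        shifted = ndimage.shift(half, (dy, dx), order=3, mode="nearest")
        frames = np.concatenate(
            [half[None], shifted[None]], axis=2
        ) + rng.normal(0, noise_sd, (1, 40, 120))
        return VesicleMovie(frames=frames, dualview_axis="col")

    def test_integer_shift_recovered_exactly(self):
        movie = self._movie_with_shift(3, -2, noise_sd=0.0)
        _, _, (dy, dx) = split_and_register(movie)
        assert (dy, dx) == (-3.0, 2.0)

    def test_subpixel_shift_recovered(self):
        movie = self._movie_with_shift(1.5, 0.25, seed=2, noise_sd=1.0)
        _, _, (dy, dx) = split_and_register(movie)
        assert dy == pytest.approx(-1.5, abs=0.2)
        assert dx == pytest.approx(-0.25, abs=0.2)

    def test_identical_halves_give_identity(self):
        movie = self._movie_with_shift(0, 0, noise_sd=0.0)
        _, _, (dy, dx) = split_and_register(movie)
        assert (dy, dx) == (0.0, 0.0)

    def test_featureless_channels_raise_with_identity_transform(self):
        movie = VesicleMovie(frames=np.full((2, 20, 40), 100.0))
        with pytest.raises(RegistrationError) as err:
            split_and_register(movie)
        assert err.value.transform == (0.0, 0.0)

    def test_odd_split_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            VesicleMovie(frames=np.zeros((1, 20, 41)))


class TestDetectSpots:
    def test_blank_noise_image_yields_no_spots(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 2, (100, 100))
        assert len(detect_spots(img)) == 0

    def test_synthetic_spots_all_found_within_one_pixel(self):
        rng = np.random.default_rng(1)
        positions = [(10 + 17 * (i // 5), 10 + 17 * (i % 5)) for i in range(20)]
        img = _spot_image((100, 100), positions, [400] * 20, seed=1)
        spots = detect_spots(img)
        assert len(spots) == 20
        found = spots.table[["y", "x"]].to_numpy()
        for py, px in positions:
            dist = np.min(np.hypot(found[:, 0] - py, found[:, 1] - px))
            assert dist < 1.0

    def test_threshold_above_brightest_peak_yields_none(self):
        positions = [(20, 20), (40, 60)]
        img = _spot_image((80, 80), positions, [400, 300], seed=3)
        assert len(detect_spots(img, threshold_k=1e6)) == 0


class TestExtractTraces:
    def _single_spot_setup(self, value=None, brightness=1000.0, background=50.0,
                           n_frames=10, seed=4, noise=False):
        shape = (n_frames, 40, 40)
        rng = np.random.default_rng(seed)
        if value is not None:
            stack = np.full(shape, value, dtype=float)
        else:
            frame = _spot_image((40, 40), [(20, 20)], [brightness],
                                background=background, noise_sd=0)
            stack = np.repeat(frame[None], n_frames, axis=0)
            if noise:
                stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        spots = SpotTable(pd.DataFrame(
            [{"id": 0, "x": 20.0, "y": 20.0, "quality": 1.0}]
        ))
        return stack, spots

    def test_flat_field_background_cancels(self):
        stack, spots = self._single_spot_setup(value=137.0)
        traces = extract_traces(stack, stack, spots)
        assert np.allclose(traces.traces["donor"], 0.0, atol=1e-9)
        assert np.allclose(traces.traces["acceptor"], 0.0, atol=1e-9)

    def test_known_brightness_recovered(self):
        stack, spots = self._single_spot_setup(brightness=1000.0, noise=True)
        traces = extract_traces(stack, stack, spots)
        mean = traces.traces["donor"].mean()
        assert mean == pytest.approx(1000.0, rel=0.05)

    def test_linearity_under_pixel_scaling(self):
        stack, spots = self._single_spot_setup(brightness=800.0)
        t1 = extract_traces(stack, stack, spots)
        t2 = extract_traces(2 * stack, 2 * stack, spots)
        assert np.allclose(t2.traces["donor"], 2 * t1.traces["donor"], rtol=1e-9)

    def test_edge_spot_dropped_with_record(self):
        stack, _ = self._single_spot_setup(value=100.0)
        spots = SpotTable(pd.DataFrame(
            [{"id": 0, "x": 2.0, "y": 2.0, "quality": 1.0},
             {"id": 1, "x": 20.0, "y": 20.0, "quality": 1.0}]
        ))
        traces = extract_traces(stack, stack, spots)
        assert traces.dropped_spots == [0]
        assert set(traces.traces["spot"]) == {1}


class TestTraceEfret:
    def test_constant_trace_arithmetic(self):
        assert trace_efret(np.full(10, 30.0), np.full(10, 70.0)) == pytest.approx(0.7)

    def test_equal_fluctuating_channels_give_half(self):
        rng = np.random.default_rng(7)
        trace = rng.uniform(10, 100, 500)
        assert trace_efret(trace, trace) == pytest.approx(0.5)

    def test_shot_noise_around_truth(self):
        rng = np.random.default_rng(9)
        total = 2000.0
        donor = rng.poisson(total * 0.55, 500).astype(float)
        acceptor = rng.poisson(total * 0.45, 500).astype(float)
        assert trace_efret(donor, acceptor) == pytest.approx(0.45, abs=0.02)

    def test_nonpositive_total_flagged(self):
        with pytest.raises(DomainError):
            trace_efret(np.zeros(5), np.zeros(5))


class TestBuildHistogram:
    def test_degenerate_single_bin(self):
        hist = build_histogram(np.full(50, 0.45))
        occupied = np.nonzero(hist.counts)[0]
        assert occupied.size == 1
        lo, hi = hist.bin_edges[occupied[0]], hist.bin_edges[occupied[0] + 1]
        assert lo <= hist.mean <= hi

    def test_gaussian_population_mean_recovered(self):
        rng = np.random.default_rng(3)
        e = np.clip(rng.normal(0.45, 0.05, 2000), 0, 1)
        hist = build_histogram(e)
        assert hist.mean == pytest.approx(0.45, abs=0.01)
        assert hist.counts.sum() == 2000

    def test_peak_04_maps_to_57_nm(self):
        rng = np.random.default_rng(4)
        e = np.clip(rng.normal(0.40, 0.04, 3000), 0, 1)
        hist = build_histogram(e, FretParams(5.3))
        assert round(hist.mean_separation_nm, 1) == pytest.approx(5.7, abs=0.1)

    def test_too_few_vesicles_returns_unfitted(self):
        hist = build_histogram(np.array([0.4, 0.5, 0.6]))
        assert not hist.fitted
        assert hist.counts.sum() == 3

    def test_bin_width_is_001(self):
        hist = build_histogram(np.full(20, 0.5))
        assert np.allclose(np.diff(hist.bin_edges), 0.01)
        assert hist.bin_edges.size == 101


def _hist_at(mean, n=2000, sd=0.05, seed=0, total_intensity=None):
    rng = np.random.default_rng(seed)
    e = np.clip(rng.normal(mean, sd, n), 0, 1)
    totals = None
    if total_intensity is not None:
        totals = rng.normal(total_intensity, 0.02 * total_intensity, n)
    return build_histogram(e, total_intensities=totals)


class TestCompareConditions:
    def test_identical_histograms_no_effect(self):
        h = _hist_at(0.45, seed=1)
        report = compare_conditions(h, h, h)
        assert report["verdict"] == "no effect"
        assert report["delta_after"] == 0.0

    def test_persistent_shift_is_irreversible(self):
        report = compare_conditions(
            _hist_at(0.42, seed=1), _hist_at(0.53, seed=2), _hist_at(0.53, seed=3),
            shift_threshold=0.03,
        )
        assert report["verdict"] == "irreversible"

    def test_recovered_shift_is_reversible(self):
        report = compare_conditions(
            _hist_at(0.40, seed=1), _hist_at(0.60, seed=2), _hist_at(0.40, seed=3),
            shift_threshold=0.03,
        )
        assert report["verdict"] == "reversible"

    def test_intensity_change_flagged(self):
        report = compare_conditions(
            _hist_at(0.40, seed=1, total_intensity=1000),
            _hist_at(0.60, seed=2, total_intensity=600),
            _hist_at(0.40, seed=3, total_intensity=1000),
            shift_threshold=0.03,
        )
        assert report["intensity_flags"]["after"]
        assert report["vesicles_intact"] is False

    def test_unfitted_histogram_rejected(self):
        bad = build_histogram(np.array([0.4, 0.5]))
        with pytest.raises(ConfigurationError):
            compare_conditions(bad, _hist_at(0.5), _hist_at(0.5))


class TestEndToEnd:
    def test_histogram_mean_matches_generated_truth(self, small_movie):
        movie, truth = small_movie
        result = analyze_movie(movie)
        hist = result["histogram"]
        assert hist.fitted
        assert hist.mean == pytest.approx(0.45, abs=0.02)

    def test_registration_recovers_generator_shift(self, small_movie):
        movie, truth = small_movie
        _, _, (dy, dx) = split_and_register(movie)
        true_dy, true_dx = truth.params["channel_shift_px"]
        # registration maps acceptor back onto donor: minus the true shift
        assert dy == pytest.approx(-true_dy, abs=0.2)
        assert dx == pytest.approx(-true_dx, abs=0.2)

    def test_histogram_counts_match_unflagged_vesicles(self, small_movie):
        movie, _ = small_movie
        result = analyze_movie(movie)
        n_ok = int((~result["efret_table"]["flagged"]).sum())
        assert result["histogram"].counts.sum() == n_ok
        assert result["histogram"].n_vesicles == n_ok

    def test_integer_translation_equivariance(self, small_movie):
        # shifting the whole movie by an integer vector must leave the
        # extracted traces unchanged (spots move with the field)
        movie, _ = small_movie
        rolled = VesicleMovie(
            frames=np.roll(movie.frames, (5, 7), axis=(1, 2)),
            dualview_axis="col",
        )
        r1 = analyze_movie(movie)
        r2 = analyze_movie(rolled)
        t1 = r1["efret_table"].sort_values("e_fret")["e_fret"].to_numpy()
        t2 = r2["efret_table"].sort_values("e_fret")["e_fret"].to_numpy()
        assert t1.size == t2.size
        assert np.allclose(t1, t2, atol=1e-3)
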