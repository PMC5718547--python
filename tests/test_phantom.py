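import numpy as np
import pytest

import cinecompare as cc
from cinecompare.errors import PeakDetectionError


def test_trajectory_analytic_points(desk_config):
    cfg = desk_config
    assert cc.trajectory(cfg, 0.0) == cfg.diaphragm_rest_position
    assert cc.trajectory(cfg, cfg.breathing_period / 2) == pytest.approx(
        cfg.diaphragm_rest_position - cfg.motion_amplitude
    )


def test_trajectory_periodicity(desk_config):
    rng = np.random.default_rng(0)
    t = rng.uniform(0, 100, 100)
    np.testing.assert_allclose(
        cc.trajectory(desk_config, t + desk_config.breathing_period),
        cc.trajectory(desk_config, t),
        atol=1e-9,
    )


def test_render_static_above_dome(desk_config):
    # far above the diaphragm for all t: the slice is time-independent
    z = desk_config.diaphragm_rest_position + 60.0
    a = cc.render_slice(desk_config, z, 0.0)
    b = cc.render_slice(desk_config, z, 1.7)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_render_dome_moves_with_time(desk_config):
    cfg = desk_config
    z = cfg.diaphragm_rest_position - 10.0
    exhale = cc.render_slice(cfg, z, 0.0)  # apex high -> more diaphragm at this z
    inhale = cc.render_slice(cfg, z, cfg.breathing_period / 2)  # apex low
    n_dia_exhale = np.sum(exhale.pixels == cfg.diaphragm_hu)
    n_dia_inhale = np.sum(inhale.pixels == cfg.diaphragm_hu)
    assert n_dia_exhale > n_dia_inhale
    assert np.sum(exhale.pixels == cfg.lung_hu) < np.sum(inhale.pixels == cfg.lung_hu)


def test_render_determinism(desk_config):
    a = cc.render_slice(desk_config, 80.0, 1.0)
    b = cc.render_slice(desk_config, 80.0, 1.0)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    na = cc.render_slice(desk_config, 80.0, 1.0, rng=np.random.default_rng(3))
    nb = cc.render_slice(desk_config, 80.0, 1.0, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(na.pixels, nb.pixels)
    assert not np.array_equal(na.pixels, a.pixels)  # noise actually applied


def test_simulate_cine_counts():
    cfg = cc.PhantomConfig(image_size=16, pixel_spacing=24.0, n_couch=4,
                           slices_per_couch=8, cine_duration_per_couch=5.0,
                           frame_interval=0.5)
    cine, trace, peaks = cc.simulate_cine(cfg, seed=0)
    assert cine.n_couch == 4
    assert all(len(f) == 10 for f in cine.couch_frames)
    assert sum(len(f) for f in cine.couch_frames) == 40
    # acquisition spans 20 s = 5 periods; trace extends one period each side
    n_periods = (trace.times[-1] - trace.times[0]) / cfg.breathing_period
    assert abs(len(peaks) - n_periods) <= 1
    assert trace.times[0] < 0.0 < cine.couch_frames[0][0].acquisition_time + 1e-9
    # every frame lies strictly inside the peak span
    t_all = [f.acquisition_time for frames in cine.couch_frames for f in frames]
    assert peaks.peak_times[0] < min(t_all) and max(t_all) < peaks.peak_times[-1]


def test_simulate_cine_deterministic(small_config):
    a, _, _ = cc.simulate_cine(small_config, seed=7)
    b, _, _ = cc.simulate_cine(small_config, seed=7)
    for fa, fb in zip(a.couch_frames, b.couch_frames):
        for xa, xb in zip(fa, fb):
            assert xa.acquisition_time == xb.acquisition_time
            for sa, sb in zip(xa.slices, xb.slices):
                np.testing.assert_array_equal(sa.pixels, sb.pixels)


def test_trace_peaks_are_surrogate_maxima(small_config):
    _, trace, peaks = cc.simulate_cine(small_config, seed=0)
    top = trace.amplitudes.max()
    for p in peaks.peak_times:
        i = np.argmin(np.abs(trace.times - p))
        assert trace.amplitudes[i] == pytest.approx(top, rel=1e-3)


def test_phase_sort_exact_phases(small_config):
    cine, _, peaks = cc.simulate_cine(small_config, seed=0)
    pa = cc.PhaseAssignment(peaks)
    image_set = cc.phase_sort(cine, pa)
    assert image_set.n_phases == 10
    assert image_set.n_couch == small_config.n_couch
    # each selected frame is the circularly closest one per bin and couch
    for b, vol in enumerate(image_set.volumes):
        label = vol.phase_label
        for n, block in enumerate(vol.couch_blocks):
            frames = cine.couch_frames[n]
            phases = pa([f.acquisition_time for f in frames])
            diff = np.abs(phases - label)
            circ = np.minimum(diff, 100 - diff)
            chosen = pa(block[0].acquisition_time)
            d = min(abs(chosen - label), 100 - abs(chosen - label))
            assert d == pytest.approx(circ.min())


def test_phase_sort_missing_peak_changes_selection(small_config):
    cine, _, peaks = cc.simulate_cine(small_config, seed=0)
    interior = peaks.peak_times[len(peaks) // 2]
    edited = cc.edit_peaks(peaks, delete=[interior])
    a = cc.phase_sort(cine, cc.PhaseAssignment(peaks))
    b = cc.phase_sort(cine, cc.PhaseAssignment(edited))
    ta = cc.imageset_to_array(a)[2]
    tb = cc.imageset_to_array(b)[2]
    assert np.any(ta != tb)


def test_validation_pair_zero_corruption(small_config):
    pair = cc.make_validation_pair(small_config, 0, 0, seed=3)
    assert not pair.changed_blocks.any()
    report = cc.compare_sets(pair.set_original, pair.set_recalculated)
    assert report.overall_score == 0.0
    assert np.all(report.residual.delta == 0.0)


def test_validation_pair_changed_blocks_bound_nonzero_residual(default_pair):
    report = cc.compare_sets(default_pair.set_original, default_pair.set_recalculated)
    delta = report.residual.delta
    n_couch = default_pair.set_original.n_couch
    for b in range(delta.shape[0]):
        allowed = set(default_pair.injected_transitions[b])
        nonzero = set(np.flatnonzero(delta[b]) + 1)
        assert nonzero <= allowed
        # and a phase with no changed block has an all-zero row
        if not default_pair.changed_blocks[b].any():
            assert not nonzero
    assert default_pair.changed_blocks.shape == (10, n_couch)


def test_validation_pair_deterministic(small_config):
    a = cc.make_validation_pair(small_config, 2, 1, seed=11)
    b = cc.make_validation_pair(small_config, 2, 1, seed=11)
    np.testing.assert_array_equal(a.corrupted_peaks.peak_times, b.corrupted_peaks.peak_times)
    np.testing.assert_array_equal(
        cc.imageset_to_array(a.set_original)[0], cc.imageset_to_array(b.set_original)[0]
    )


def test_validation_pair_corruption_limits(small_config):
    with pytest.raises(PeakDetectionError):
        cc.make_validation_pair(small_config, 1000, 0, seed=0)
    with pytest.raises(ValueError):
        cc.make_validation_pair(small_config, -1, 0, seed=0)


def test_score_monotone_in_missed_peaks(desk_config):
    """Median comparison score over seeds is non-decreasing in corruption."""
    medians = []
    for missed in (0, 1, 3):
        scores = [
            cc.compare_sets(p.set_original, p.set_recalculated).overall_score
            for p in (
                cc.make_validation_pair(desk_config, missed, 0, seed=s)
                for s in range(1, 9)
            )
        ]
        medians.append(np.median(scores))
    assert medians[0] <= medians[1] <= medians[2]
    assert medians[0] == 0.0


def test_config_validation():
    with pytest.raises(ValueError):
        cc.PhantomConfig(image_size=8)
    with pytest.raises(ValueError):
        cc.PhantomConfig(cine_duration_per_couch=1.0, breathing_period=4.0)
    with pytest.raises(ValueError):
        cc.PhantomConfig(motion_exponent=3)
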