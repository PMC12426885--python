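"""Water classification, thickness ratios and waterfront tracking."""

import numpy as np
import pytest

from dtvtomo.phantom import build_phantom
from dtvtomo.projector import VolumeImage
from dtvtomo.reference_data import GREY_VALUE_SUMMARY
from dtvtomo.scenes import filling_timeline_scene
from dtvtomo.waterfront import (classify_water, front_height, front_uncertainty,
                                halfway_threshold, segment_vessels,
                                thickness_ratio, track_vessels,
                                vessel_ratio_profile)


def test_halfway_threshold_from_published_means():
    water = GREY_VALUE_SUMMARY["regularised_pr"]["water"][0]
    air = GREY_VALUE_SUMMARY["regularised_pr"]["air"][0]
    assert halfway_threshold(water * 1e-7, air * 1e-7) == pytest.approx(2.07e-7)


def test_classify_water_basics():
    v = np.zeros((4, 8, 8))
    mask = np.zeros((4, 8, 8), bool)
    mask[:, 2:6, 2:6] = True
    assert not classify_water(v, v, mask, 0.5).any()
    u = v.copy()
    u[:2, 3, 3] = 1.0
    got = classify_water(u, v, mask, 0.5)
    assert got.sum() == 2
    u[:, 0, 0] = 9.0  # outside the vessel mask: ignored
    assert classify_water(u, v, mask, 0.5).sum() == 2
    with pytest.raises(ValueError):
        classify_water(u, v, mask, 0.0)


def test_classification_error_rate_under_noise():
    """Noise sd of one sixth of the class gap misclassifies < 0.2% (3 sigma)."""
    rng = np.random.default_rng(0)
    gap = 4.14e-7
    n = 200_000
    vessel = np.ones((2, n // 2, 1), bool)
    v = np.zeros((2, n // 2, 1))
    u = np.zeros((2, n // 2, 1))
    u[0] = gap  # water half
    noisy = u + (gap / 6) * rng.standard_normal(u.shape)
    got = classify_water(noisy, v, vessel, halfway_threshold(gap, 0.0))
    err = np.count_nonzero(got != (u > 0)) / u.size
    assert err < 0.002


def test_thickness_ratio_cases():
    vessel = np.zeros((6, 4, 4), bool)
    vessel[:, 1:3, 1:3] = True
    water = np.zeros_like(vessel)
    assert np.nanmax(thickness_ratio(water, vessel, axis=1)) == 0.0
    R_full = thickness_ratio(vessel, vessel, axis=1)
    assert np.nanmin(R_full[np.isfinite(R_full)]) == 1.0
    # half-filled along z: step at the front within one voxel
    water[:3] = vessel[:3]
    R = vessel_ratio_profile(water, vessel)
    np.testing.assert_array_equal(R, [1, 1, 1, 0, 0, 0])
    # ratio undefined where the vessel has no thickness
    out = thickness_ratio(water, np.zeros_like(vessel), axis=1)
    assert np.all(np.isnan(out))


def test_front_height_persistence_rule():
    R = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
    assert front_height(R, 0.1, persistence=3) == 3.0
    # an air-inclusion dip below the front does not end the water column
    R_dip = np.array([1, 1, 0, 1, 1, 1, 0, 0, 0, 0], float)
    assert front_height(R_dip, 0.1, persistence=3) == 6.0
    # a droplet inside the window postpones the front conservatively past it
    R2 = np.array([1, 1, 1, 0, 0, 0.5, 0, 0, 0, 0], float)
    assert front_height(R2, 0.1, persistence=3) == 6.0
    # sustained water above a gap moves the front above it
    R3 = np.array([1, 1, 1, 0, 1, 1, 1, 1, 0, 0], float)
    assert front_height(R3, 0.1, persistence=3) == 8.0
    assert front_height(np.zeros(10), 0.1, persistence=3) == 0.0
    # never satisfied: the vessel top is returned
    assert front_height(np.ones(10), 0.1, persistence=3) == 10.0
    with pytest.raises(ValueError):
        front_height(np.full(5, np.nan), 0.1, 2)
    with pytest.raises(ValueError):
        front_height(R, 0.1, persistence=0)


def test_front_height_monotone_in_ratio_threshold():
    """A laxer (higher) ratio threshold can only lower the detected front."""
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=60),
           st.integers(1, 5))
    def check(profile, persistence):
        R = np.array(profile)
        h_tight = front_height(R, 0.05, persistence)
        h_mid = front_height(R, 0.10, persistence)
        h_lax = front_height(R, 0.15, persistence)
        assert h_lax <= h_mid <= h_tight

    check()


def test_front_height_local_to_persistence_window():
    """Fluctuations strictly above the window cannot move the front."""
    R = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0.9, 0.2], float)
    base = front_height(R, 0.1, persistence=3)
    R_quiet = R.copy()
    R_quiet[8:] = 0.0
    assert base == front_height(R_quiet, 0.1, persistence=3) == 2.0


def test_front_uncertainty_brackets():
    # sharp step: zero-width interval
    R = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], float)
    lo, hi = front_uncertainty(R, (0.05, 0.15), persistence=3)
    assert lo == hi == 4.0
    # linear ramp R = 1 - z/L: crossings at 0.85 L and 0.95 L
    L = 200
    z = np.arange(L)
    ramp = 1 - z / L
    lo, hi = front_uncertainty(ramp, (0.05, 0.15), persistence=5)
    assert lo == pytest.approx(0.85 * L, abs=1.5)
    assert hi == pytest.approx(0.95 * L, abs=1.5)
    mid = front_height(ramp, 0.1, persistence=5)
    assert lo <= mid <= hi
    with pytest.raises(ValueError):
        front_uncertainty(ramp, (0.0, 0.15), 5)


def test_segment_vessels_recovers_count():
    ph = build_phantom(4, (24, 64, 64), 10.5, seed=6)
    from dtvtomo.phantom import optics_maps

    delta, _ = optics_maps(ph)
    yy, xx = ph._inplane_coords()
    wood_region = np.broadcast_to(xx ** 2 + yy ** 2 <= ph.wood_radius_um ** 2,
                                  ph.grid_shape)
    labels = segment_vessels(VolumeImage(delta, 10.5, "delta"), wood_region)
    assert len([i for i in np.unique(labels) if i != 0]) == 4


@pytest.fixture(scope="module")
def timeline_scene():
    return filling_timeline_scene(seed=12, grid=(64, 48, 48), n_vessels=4,
                                  t_max=144.0, dt=9.0)


def test_static_timeline_fronts_at_base(timeline_scene):
    sc = timeline_scene
    static = [(t, sc["reference"]) for t in (0.0, 9.0, 18.0)]
    tracks, summary = track_vessels(static, sc["reference_clean"],
                                    sc["vessel_labels"], sc["threshold"],
                                    voxel_size=10.5)
    for tr in tracks:
        assert np.all(tr.heights_um <= 10.5)  # never above one voxel


def test_tracked_fronts_monotone_and_sqrt_like(timeline_scene):
    sc = timeline_scene
    tracks, summary = track_vessels(sc["timeline"], sc["reference_clean"],
                                    sc["vessel_labels"], sc["threshold"],
                                    voxel_size=10.5)
    assert summary["n_vessels"] == 4
    # cohort stats equal direct recomputation from the stacked heights
    mat = summary["height_matrix_um"]
    np.testing.assert_allclose(summary["median_um"], np.median(mat, axis=0))
    np.testing.assert_allclose(summary["std_um"], mat.std(axis=0))
    jumped = sc["jumped_vessel_label"]
    for tr in tracks:
        assert np.all(np.diff(tr.heights_um) >= -10.5)
        assert np.all(tr.bounds_um[:, 0] <= tr.heights_um + 1e-9)
        assert np.all(tr.heights_um <= tr.bounds_um[:, 1] + 1e-9)
        if tr.vessel_id == jumped:
            continue
        # exponent of h ~ t^p from the non-jump vessels
        t = tr.times[1:]
        h = tr.heights_um[1:]
        ok = (h > 20) & (h < 0.9 * h.max() + 1)
        if ok.sum() >= 5:
            p = np.polyfit(np.log(t[ok]), np.log(h[ok]), 1)[0]
            assert p == pytest.approx(0.5, abs=0.08)


def test_separation_jump_detected_at_programmed_height(timeline_scene):
    sc = timeline_scene
    tracks, _ = track_vessels(sc["timeline"], sc["reference_clean"],
                              sc["vessel_labels"], sc["threshold"],
                              voxel_size=10.5)
    tr = next(t for t in tracks if t.vessel_id == sc["jumped_vessel_label"])
    # sqrt-time-normalised advance rate estimates the fill constant k_i; the
    # programmed separation triples it, so the first interval whose rate
    # clearly exceeds the pre-jump baseline marks the event
    rate = np.diff(tr.heights_um) / np.diff(np.sqrt(tr.times))
    baseline = np.median(rate[:4])
    k = int(np.flatnonzero(rate > 2.0 * baseline)[0])
    dt = tr.times[1] - tr.times[0]
    assert abs(tr.times[k] - sc["jump_time"]) <= dt + 1e-9
    # ... and from the programmed height
    fill = sc["schedule"].fills[sc["jumped_vessel_label"] - 1]
    h_event = fill.height(sc["jump_time"])
    assert tr.heights_um[k] == pytest.approx(h_event, abs=3 * 10.5)
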