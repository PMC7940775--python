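"""GPS mobility metrics: closed forms, conservation, and naive-oracle parity."""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from dyadsense.ebm_io import GpsFix
from dyadsense.mobility import (
    EARTH_RADIUS_M,
    build_heatmap,
    estimate_home,
    farthest_distance_from_home,
    fraction_time_outside_home,
    haversine,
    mobility_features,
    radius_of_movement,
    spherical_centroid,
)
from dyadsense.synth import ScheduleConfig, simulate_week

PID = "SS0001"
DAY = date(2019, 6, 5)
M_PER_DEG = EARTH_RADIUS_M * math.pi / 180.0


def _fix(hh, mm, lat, lon):
    return GpsFix(PID, datetime(2019, 6, 5, hh, mm), lat, lon)


# ---------------------------------------------------------------------------
# haversine
# ---------------------------------------------------------------------------


def test_haversine_identical_points_zero():
    assert haversine(27.7, 85.3, 27.7, 85.3) == 0.0


def test_haversine_one_degree_meridian():
    # closed form: one degree of a great circle = R * pi/180
    assert haversine(0.0, 0.0, 0.0, 1.0) == pytest.approx(111_195, abs=1)
    assert haversine(0.0, 0.0, 1.0, 0.0) == pytest.approx(111_195, abs=1)


def test_haversine_symmetric():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.uniform(-80, 80, 2)
        b = rng.uniform(-170, 170, 2)
        assert haversine(a[0], b[0], a[1], b[1]) == pytest.approx(
            haversine(a[1], b[1], a[0], b[0])
        )


# ---------------------------------------------------------------------------
# radius of movement (radius of gyration)
# ---------------------------------------------------------------------------


def test_radius_single_fix_zero():
    assert radius_of_movement([_fix(9, 0, 27.7, 85.3)]) == pytest.approx(0.0, abs=1e-6)


def test_radius_two_fixes_half_distance():
    a, b = _fix(9, 0, 27.7, 85.3), _fix(10, 0, 27.71, 85.3)
    d = haversine(27.7, 85.3, 27.71, 85.3)
    assert radius_of_movement([a, b]) == pytest.approx(d / 2, rel=1e-6)


def test_radius_empty_missing():
    assert radius_of_movement([]) is None


def test_radius_permutation_invariant():
    rng = np.random.default_rng(4)
    fixes = [
        _fix(h, 0, 27.7 + rng.uniform(-0.01, 0.01), 85.3 + rng.uniform(-0.01, 0.01))
        for h in range(10)
    ]
    r = radius_of_movement(fixes)
    perm = [fixes[i] for i in rng.permutation(10)]
    assert radius_of_movement(perm) == pytest.approx(r)
    assert farthest_distance_from_home(perm, estimate_home(fixes)) == pytest.approx(
        farthest_distance_from_home(fixes, estimate_home(fixes))
    )


def test_radius_translation_invariant_within_tenth_percent():
    rng = np.random.default_rng(9)
    fixes = [
        _fix(h, 0, 27.7 + rng.uniform(-0.02, 0.02), 85.3 + rng.uniform(-0.02, 0.02))
        for h in range(12)
    ]
    shifted = [GpsFix(PID, f.timestamp, f.lat + 0.01, f.lon + 0.01) for f in fixes]
    r0, r1 = radius_of_movement(fixes), radius_of_movement(shifted)
    assert abs(r1 - r0) / r0 < 0.001


def test_metrics_match_naive_recomputation():
    """Vectorized metrics equal a plain-python O(n) recomputation."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(1, 30))
        fixes = [
            _fix(int(rng.integers(0, 24)), int(rng.integers(0, 60)),
                 27.7 + rng.uniform(-0.05, 0.05), 85.3 + rng.uniform(-0.05, 0.05))
            for _ in range(n)
        ]
        lat_c, lon_c = spherical_centroid(
            np.array([f.lat for f in fixes]), np.array([f.lon for f in fixes])
        )
        naive_r = math.sqrt(
            sum(haversine(f.lat, f.lon, lat_c, lon_c) ** 2 for f in fixes) / n
        )
        assert radius_of_movement(fixes) == pytest.approx(naive_r, rel=1e-9)
        home = estimate_home(fixes)
        naive_far = max(haversine(f.lat, f.lon, home.lat, home.lon) for f in fixes)
        assert farthest_distance_from_home(fixes, home) == pytest.approx(naive_far, rel=1e-9)
        last = {}
        for f in sorted(fixes, key=lambda f: f.timestamp):
            last[(f.timestamp.hour * 60 + f.timestamp.minute) // 15] = f
        naive_frac = sum(
            1 for f in last.values() if haversine(f.lat, f.lon, home.lat, home.lon) > 100.0
        ) / len(last)
        assert fraction_time_outside_home(fixes, home) == pytest.approx(naive_frac)


# ---------------------------------------------------------------------------
# home and time outside
# ---------------------------------------------------------------------------


def test_home_from_constant_fixes():
    fixes = [_fix(h, 0, 27.7, 85.3) for h in range(6)]
    home = estimate_home(fixes)
    assert (home.lat, home.lon) == (pytest.approx(27.7), pytest.approx(85.3))
    assert home.support == 6


def test_home_missing_without_fixes():
    assert estimate_home([]) is None


def test_farthest_distance_examples():
    home = estimate_home([_fix(1, 0, 27.7, 85.3)])
    at_home = [_fix(9, 0, 27.7, 85.3)]
    assert farthest_distance_from_home(at_home, home) == pytest.approx(0.0, abs=1e-6)
    away = at_home + [_fix(10, 0, 27.7 + 500.0 / M_PER_DEG, 85.3)]
    assert farthest_distance_from_home(away, home) == pytest.approx(500.0, abs=1.0)
    assert farthest_distance_from_home(away, None) is None


def test_fraction_outside_extremes():
    home = estimate_home([_fix(1, 0, 27.7, 85.3)])
    at_home = [_fix(9, m, 27.7, 85.3) for m in (0, 15, 30)]
    assert fraction_time_outside_home(at_home, home) == 0.0
    away = [_fix(9, m, 27.7 + 1000.0 / M_PER_DEG, 85.3) for m in (0, 15, 30)]
    assert fraction_time_outside_home(away, home) == 1.0
    assert fraction_time_outside_home([], home) is None


def test_fraction_outside_partial_day():
    # 4-hour outing in a 12-observed-hour day, one fix per 15-min bin
    home_lat, home_lon = 27.7, 85.3
    fixes = []
    for h in range(8, 20):
        for m in (0, 15, 30, 45):
            away = 10 <= h < 14
            lat = home_lat + (2000.0 / M_PER_DEG if away else 0.0)
            fixes.append(_fix(h, m, lat, home_lon))
    home = estimate_home([_fix(1, 0, home_lat, home_lon)] + fixes)
    frac = fraction_time_outside_home(fixes, home)
    assert frac == pytest.approx(4 / 12, abs=1 / 48)


# ---------------------------------------------------------------------------
# heat map
# ---------------------------------------------------------------------------


def test_heatmap_conserves_fix_count():
    rng = np.random.default_rng(21)
    fixes = [
        _fix(int(rng.integers(0, 24)), int(rng.integers(0, 60)),
             27.7 + rng.uniform(0, 0.01), 85.3 + rng.uniform(0, 0.01))
        for _ in range(57)
    ]
    assert build_heatmap(fixes).total == 57


def test_heatmap_single_point_single_cell():
    grid = build_heatmap([_fix(9, 0, 27.7, 85.3)] * 3)
    assert grid.counts.shape == (1, 1)
    assert grid.total == 3


def test_heatmap_two_clusters_two_maxima():
    near = [_fix(9, m, 27.7, 85.3) for m in range(5)]
    far = [_fix(10, m, 27.71, 85.31) for m in range(3)]
    grid = build_heatmap(near + far)
    flat = np.sort(grid.counts.ravel())[::-1]
    assert flat[0] == 5 and flat[1] == 3 and flat[2] == 0


def test_heatmap_empty_rejected():
    with pytest.raises(ValueError):
        build_heatmap([])


def test_home_recovered_within_one_cell_on_simulated_week(tmp_path):
    cfg = ScheduleConfig(seed=23)
    result = simulate_week(cfg)
    fixes = [f for sim in result.days for f in sim.gps]
    home = estimate_home(fixes)
    err = haversine(home.lat, home.lon, cfg.home_lat, cfg.home_lon)
    cell_diag = 0.0005 * M_PER_DEG * math.sqrt(2)
    assert err <= cell_diag


def test_mobility_features_bundle(default_config):
    result = simulate_week(default_config)
    fixes = [f for sim in result.days for f in sim.gps]
    home = estimate_home(fixes)
    feats = mobility_features(fixes, home, DAY)
    assert feats.n_fixes == len([f for f in fixes if f.timestamp.date() == DAY])
    assert feats.radius_of_movement_m >= 0
    assert 0 <= feats.fraction_time_outside_home <= 1
    # the single 1500 m trip bounds the farthest distance
    assert feats.farthest_distance_from_home_m == pytest.approx(1500.0, abs=5.0)
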