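"""Snapping, shaft extrapolation/interpolation, and the geometric fallback.

Ground truth comes from the synthetic trajectory fixtures; the snapping
tie-break is checked against an exhaustive candidate enumeration oracle.
"""

import numpy as np
import pytest

from ieloc.errors import SnapFailure
from ieloc.localize import ThresholdSpec
from ieloc.synthetic import make_shaft_fixture, make_trajectory, render_ct
from ieloc.trajectory import (SnapConfig, extrapolate_shaft, geometric_interpolate,
                              interpolate_shaft, snap_to_density)
from ieloc.volume import voxel_to_world


def _cfg(**kw):
    kw.setdefault("threshold", ThresholdSpec(absolute=200.0))
    return SnapConfig(**kw)


def test_snap_recovers_displaced_blob():
    center = np.array([20.0, 20.0, 20.0])
    vol = render_ct([center], shape=(80, 80, 80), voxel_size=0.5, noise_sd=0.0, seed=0)
    predicted = center + np.array([1.2, 0.0, 0.0])
    got = snap_to_density(vol, predicted, _cfg())
    np.testing.assert_allclose(got, center, atol=0.05)


def test_snap_exclusion_rule():
    """The only density within reach lies 0.5 mm from a used contact; with a
    1.5 mm exclusion radius that candidate is rejected."""
    center = np.array([20.0, 20.0, 20.0])
    vol = render_ct([center], shape=(80, 80, 80), voxel_size=0.5, noise_sd=0.0, seed=0)
    used = [center + np.array([0.5, 0.0, 0.0])]
    with pytest.raises(SnapFailure):
        snap_to_density(vol, center + np.array([1.0, 0.0, 0.0]), _cfg(), used=used)


def test_snap_tie_broken_by_distance():
    """Two equal-peak blobs at 0.8 and 1.6 mm from the prediction: the nearer
    wins.  Oracle: exhaustive enumeration of admissible voxels."""
    near = np.array([20.8, 20.0, 20.0])
    far = np.array([18.4, 20.0, 20.0])  # opposite side: 1.6 mm from predicted
    predicted = np.array([20.0, 20.0, 20.0])
    vol = render_ct([near, far], shape=(80, 80, 80), voxel_size=0.4, noise_sd=0.0,
                    sigma=0.4, seed=0)
    got = snap_to_density(vol, predicted, _cfg())
    # oracle: best admissible voxel by (intensity desc, distance asc)
    idx = np.array(list(np.ndindex(vol.shape)), dtype=float)
    world = voxel_to_world(vol, idx)
    d = np.linalg.norm(world - predicted, axis=1)
    inten = vol.data.ravel()
    ok = (d <= 2.0) & (inten > 200.0)
    order = np.lexsort((d[ok], -inten[ok]))
    oracle_seed = world[ok][order[0]]
    assert np.linalg.norm(oracle_seed - near) < np.linalg.norm(oracle_seed - far)
    # the snapped contact belongs to the nearer blob (refinement may shade
    # toward the far blob's tail but never crosses to it)
    assert np.linalg.norm(got - near) < np.linalg.norm(got - far)
    assert np.linalg.norm(got - near) < 0.5


def test_snap_failure_in_empty_region():
    vol = render_ct([(20.0, 20.0, 20.0)], shape=(80, 80, 80), voxel_size=0.5,
                    noise_sd=0.0, seed=0)
    with pytest.raises(SnapFailure):
        snap_to_density(vol, np.array([8.0, 8.0, 8.0]), _cfg())


def test_extrapolate_straight_shaft(straight_shaft):
    fx = straight_shaft
    pts, prov = extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 8)
    assert pts.shape == (8, 3)
    err = np.linalg.norm(pts - fx.truth, axis=1)
    assert err.max() < 0.2
    assert prov[:2] == ["refined", "refined"]
    assert set(prov[2:]) == {"extrapolated"}


def test_extrapolate_arc_shaft(arc_shaft):
    fx = arc_shaft
    pts, _ = extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 12)
    rms = np.sqrt(np.mean(np.sum((pts - fx.truth) ** 2, axis=1)))
    assert rms < 0.5


def test_extrapolate_two_contacts_only(straight_shaft):
    fx = straight_shaft
    pts, prov = extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 2)
    assert pts.shape == (2, 3)
    assert prov == ["refined", "refined"]
    assert np.linalg.norm(pts - fx.truth[:2], axis=1).max() < 0.2


def test_extrapolate_fallback_on_missing_density(straight_shaft):
    """Asking for more contacts than were implanted: predictions beyond the
    shaft tip find no density and fall back to pure geometry."""
    fx = straight_shaft
    pts, prov = extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 10,
                                  _cfg(threshold=ThresholdSpec(absolute=200.0)))
    assert len(pts) == 10
    assert prov[-1] == "geometric-fallback"


def test_interpolate_straight_even_spacing():
    fx = make_shaft_fixture(n=10, spacing=3.5, shape=(112, 112, 112), seed=13)
    pts, _ = interpolate_shaft(fx.volume, fx.truth[0], fx.truth[-1], 10)
    err = np.linalg.norm(pts - fx.truth, axis=1)
    assert err.max() < 0.2


def test_interpolate_two_contacts(straight_shaft):
    fx = straight_shaft
    pts, prov = interpolate_shaft(fx.volume, fx.truth[0], fx.truth[-1], 2)
    assert prov == ["refined", "refined"]
    np.testing.assert_allclose(pts, fx.truth[[0, -1]], atol=0.2)


def test_interpolate_occipital_strip_90_degree_arc():
    """Planar arc turning 90 degrees over 8 contacts — the bent subdural
    strip scenario — is recovered end to end."""
    r = 8 * 3.5 / (np.pi / 2) / (8 / 7)  # 7 gaps of 3.5 mm spanning 90 deg
    truth = make_trajectory((20.0, 16.0, 18.0), (0, 1, 0), 8, 3.5,
                            curvature_radius=7 * 3.5 / (np.pi / 2),
                            plane_normal=(1, 0, 0))
    vol = render_ct(truth, shape=(96, 96, 96), voxel_size=0.5, seed=14)
    pts, _ = interpolate_shaft(vol, truth[0], truth[-1], 8)
    rms = np.sqrt(np.mean(np.sum((pts - truth) ** 2, axis=1)))
    assert rms < 0.7


def test_interpolate_matches_geometric_on_straight_shaft():
    """With no curvature the CT-guided march agrees with pure geometric
    interpolation followed by refinement."""
    fx = make_shaft_fixture(n=8, spacing=3.5, seed=15, noise_sd=0.0)
    pts, _ = interpolate_shaft(fx.volume, fx.truth[0], fx.truth[-1], 8)
    geo = geometric_interpolate(fx.truth[0], fx.truth[-1], 8)
    assert np.linalg.norm(pts - geo, axis=1).max() < 0.2


def test_no_duplicate_contacts(arc_shaft):
    fx = arc_shaft
    for pts, _ in (extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 12),
                   interpolate_shaft(fx.volume, fx.truth[0], fx.truth[-1], 12)):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1.5  # exclusion radius


def test_geometric_interpolate_arithmetic():
    pts = geometric_interpolate((0, 0, 0), (0, 0, 9), 4)
    np.testing.assert_allclose(pts[:, 2], [0, 3, 6, 9], atol=1e-12)
    np.testing.assert_allclose(pts[:, :2], 0, atol=1e-12)
    pts2 = geometric_interpolate((1, 2, 3), (4, 5, 6), 2)
    np.testing.assert_allclose(pts2, [(1, 2, 3), (4, 5, 6)], atol=1e-12)


def test_geometric_interpolate_spacing_definition(rng):
    a, b = rng.uniform(-50, 50, (2, 3))
    n = 7
    pts = geometric_interpolate(a, b, n)
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    np.testing.assert_allclose(gaps, np.linalg.norm(b - a) / (n - 1), atol=1e-9)


def test_invalid_arguments(straight_shaft):
    fx = straight_shaft
    with pytest.raises(ValueError):
        extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[0], 8)
    with pytest.raises(ValueError):
        extrapolate_shaft(fx.volume, fx.truth[0], fx.truth[1], 1)
    with pytest.raises(ValueError):
        SnapConfig(search_radius=-1.0)
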