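import numpy as np
import pytest
from scipy import ndimage

from gliovasc import synthetic as syn
from gliovasc import walls
from gliovasc.io import MultiChannelVolume

VOX = (0.5, 0.5, 0.5)


def _const_volume(value=7.0, shape=(8, 16, 16)):
    return MultiChannelVolume(channels={"COLIV": np.full(shape, value, np.float32)},
                              voxel_size=VOX)


def test_extract_optical_slice_averages_planes():
    vol = _const_volume()
    vol["COLIV"][3] = 10.0
    vol["COLIV"][4] = 20.0
    # 1-um slice at 0.5-um pitch averages exactly 2 planes
    sl = walls.extract_optical_slice(vol, "COLIV", 3)
    np.testing.assert_allclose(sl, 15.0)
    with pytest.raises(IndexError):
        walls.extract_optical_slice(vol, "COLIV", 7)
    np.testing.assert_allclose(walls.extract_optical_slice(_const_volume(), "COLIV", 2), 7.0)


def test_trace_wall_lines_capacity_and_determinism():
    # disk with circumference ~ 2*pi*40 = 251 um: 5 disjoint 40-um arcs fit
    mask = np.zeros((200, 200), bool)
    yy, xx = np.ogrid[:200, :200]
    mask[(yy - 100) ** 2 + (xx - 100) ** 2 <= 80 ** 2] = True
    lines = walls.trace_wall_lines(mask, (0.5, 0.5), n_lines=5, line_length=40.0, seed=3)
    assert len(lines) == 5
    again = walls.trace_wall_lines(mask, (0.5, 0.5), n_lines=5, line_length=40.0, seed=3)
    for a, b in zip(lines, again):
        np.testing.assert_array_equal(a, b)
    # smaller disk (circumference ~ 125 um) only fits 3 lines
    small = np.zeros((120, 120), bool)
    yy, xx = np.ogrid[:120, :120]
    small[(yy - 60) ** 2 + (xx - 60) ** 2 <= 40 ** 2] = True
    few = walls.trace_wall_lines(small, (0.5, 0.5), n_lines=5, line_length=40.0, seed=3)
    assert 0 < len(few) < 5


def test_profile_luminance_constant_and_ramp():
    img = np.full((50, 120), 7.0)
    line = np.column_stack([np.full(50, 12.0), np.linspace(2, 52, 50)])  # um
    prof = walls.profile_luminance(img, line, (0.5, 0.5))
    np.testing.assert_allclose(prof.relative, 1.0)
    assert np.all(np.diff(prof.positions) > 0)
    # linear ramp 0 -> 100 along x maps to a linear relative profile 0 -> 1
    ramp = np.tile(np.linspace(0, 100, 120), (50, 1))
    prof2 = walls.profile_luminance(ramp, line, (0.5, 0.5))
    rel = prof2.relative
    np.testing.assert_allclose(rel, np.linspace(rel[0], 1.0, len(rel)), atol=1e-6)
    with pytest.raises(ValueError):
        walls.profile_luminance(img, line[:1], (0.5, 0.5))


def test_harmonize_truncates_to_first_27_um():
    img = np.full((50, 120), 5.0)
    line = np.column_stack([np.full(90, 12.0), np.linspace(2, 46, 90)])
    prof = walls.profile_luminance(img, line, (0.5, 0.5), step=1.0)  # 40+ um
    matrix, pos = walls.harmonize_profiles([prof], keep_length=27.0)
    assert matrix.shape == (1, 27)
    assert pos[-1] < 27.0
    short = walls.profile_luminance(img, line[:40], (0.5, 0.5))  # ~20 um
    with pytest.raises(ValueError, match="shorter"):
        walls.harmonize_profiles([short], keep_length=27.0)
    with pytest.raises(ValueError):
        walls.harmonize_profiles([prof], keep_length=0.0)


def test_fenestration_metric_closed_forms():
    assert walls.fenestration_metric(np.ones((3, 27))).mean_sd == 0.0
    alternating = np.tile([0.0, 1.0], 14)[None, :27]
    res = walls.fenestration_metric(alternating)
    assert res.per_profile_sd[0] == pytest.approx(0.5, abs=0.02)


def test_metric_invariant_to_intensity_scaling():
    rng = np.random.default_rng(2)
    img = rng.random((60, 200)) * 50
    line = np.column_stack([np.full(80, 15.0), np.linspace(2, 42, 80)])
    p1 = walls.profile_luminance(img, line, (0.5, 0.5))
    p2 = walls.profile_luminance(img * 123.4, line, (0.5, 0.5))
    np.testing.assert_allclose(p1.relative, p2.relative, atol=1e-12)


def test_sd_increases_with_gap_fraction():
    """Fenestration dial: mean relative-fluorescence SD of wall traces rises
    strictly with the rendered gap fraction."""
    spec = syn.straight_tube_spec((24, 48, 192), radius=8.0, orientation="x")
    tree = syn.build_vessel_tree(spec)
    means = []
    for g in (0.0, 0.25, 0.5):
        vol, gt = syn.render_volume(tree, syn.RenderParams(gap_fraction=g), seed=11)
        zmid = vol.shape[0] // 2
        filled = ndimage.binary_fill_holes(gt.ideal_masks["VESSEL"])
        profs = []
        for dz in (-2, 2):
            sl = walls.extract_optical_slice(vol, "COLIV", zmid + dz)
            m2 = ndimage.binary_erosion(filled[zmid + dz], iterations=2)
            lines = walls.trace_wall_lines(m2, (0.5, 0.5), n_lines=5,
                                           line_length=40.0, seed=100 + dz)
            profs += [walls.profile_luminance(sl, ln, (0.5, 0.5)) for ln in lines]
        matrix, _ = walls.harmonize_profiles([p for p in profs if p.length >= 27.0])
        means.append(walls.fenestration_metric(matrix).mean_sd)
    assert means[0] <= 0.02
    assert means[0] < means[1] < means[2]
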