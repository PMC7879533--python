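import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from gliovasc import segmentation as seg
from gliovasc import synthetic as syn

VOX = (0.5, 0.5, 0.5)


def _sphere(shape, center, r):
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= r ** 2


def test_make_mask_counts_units():
    img = np.zeros((40, 40, 40), np.float32)
    img[_sphere(img.shape, (12, 12, 12), 8)] = 1.0
    img[_sphere(img.shape, (28, 28, 28), 8)] = 1.0
    mask = seg.make_mask(img, VOX, method="absolute", threshold=0.5, smoothing=0.0)
    assert mask.n_units == 2
    # single tube-like object
    img2 = np.zeros((20, 20, 60), np.float32)
    img2[8:12, 8:12, 5:55] = 1.0
    mask2 = seg.make_mask(img2, VOX, method="absolute", threshold=0.5, smoothing=0.0)
    assert mask2.n_units == 1
    assert mask2.threshold == 0.5


def test_make_mask_empty_result_is_legal():
    mask = seg.make_mask(np.zeros((10, 10, 10), np.float32), VOX)
    assert mask.n_units == 0


@given(st.floats(min_value=0.1, max_value=0.9))
@settings(max_examples=20, deadline=None)
def test_mask_volume_is_threshold_monotone(thr):
    rng = np.random.default_rng(7)
    img = rng.random((16, 16, 16)).astype(np.float32)
    lo = seg.make_mask(img, VOX, method="absolute", threshold=thr,
                       min_unit_volume=0.0, smoothing=0.0)
    hi = seg.make_mask(img, VOX, method="absolute", threshold=min(thr + 0.05, 1.0),
                       min_unit_volume=0.0, smoothing=0.0)
    assert hi.binary.sum() <= lo.binary.sum()


def test_surface_stats_sphere_against_closed_form():
    # r = 10 um at 0.5 um voxels
    shape = (60, 60, 60)
    binary = _sphere(shape, (30, 30, 30), 20)  # 20 voxels = 10 um
    mask = seg.binary_label_mask(binary, VOX)
    st_ = seg.surface_stats(mask)
    assert st_.unit_count == 1
    assert st_.surface_area_um2 == pytest.approx(4 * np.pi * 100, rel=0.05)
    assert st_.volume_um3 == pytest.approx(4 / 3 * np.pi * 1000, rel=0.03)


def test_surface_stats_cube_volume_exact():
    binary = np.zeros((30, 30, 30), bool)
    binary[5:25, 5:25, 5:25] = True  # 20^3 voxels at 0.5 um -> 1000 um3
    st_ = seg.surface_stats(seg.binary_label_mask(binary, VOX))
    assert st_.volume_um3 == 1000.0


def test_surface_stats_additive_over_disjoint_units():
    binary = np.zeros((40, 40, 80), bool)
    binary |= _sphere(binary.shape, (20, 20, 20), 10)
    b2 = np.zeros_like(binary)
    b2 |= _sphere(binary.shape, (20, 20, 60), 12)
    both = seg.surface_stats(seg.binary_label_mask(binary | b2, VOX))
    s1 = seg.surface_stats(seg.binary_label_mask(binary, VOX))
    s2 = seg.surface_stats(seg.binary_label_mask(b2, VOX))
    assert both.unit_count == 2
    assert both.volume_um3 == pytest.approx(s1.volume_um3 + s2.volume_um3)
    assert both.surface_area_um2 == pytest.approx(
        s1.surface_area_um2 + s2.surface_area_um2, rel=1e-6)


def test_surface_stats_empty_mask():
    st_ = seg.surface_stats(seg.binary_label_mask(np.zeros((5, 5, 5), bool), VOX))
    assert (st_.unit_count, st_.surface_area_um2, st_.volume_um3) == (0, 0.0, 0.0)


def test_detect_nuclei_empty_volume():
    assert seg.detect_nuclei(np.zeros((20, 20, 20)), VOX, 7.0) == []


def test_detect_nuclei_recovers_rendered_nuclei(nuclei_render):
    volume, gt = nuclei_render
    spots = seg.detect_nuclei(volume["DAPI"], volume.voxel_size, expected_diameter=7.0)
    assert len(spots) == len(gt.nuclei)
    d, _ = cKDTree(gt.nuclei).query([s.centroid for s in spots])
    assert d.max() <= 0.5  # within one voxel


def test_detect_nuclei_scale_invariant(nuclei_render):
    volume, _ = nuclei_render
    a = seg.detect_nuclei(volume["DAPI"], volume.voxel_size, 7.0)
    b = seg.detect_nuclei(volume["DAPI"] * 37.5, volume.voxel_size, 7.0)
    assert len(a) == len(b)


def test_detect_nuclei_with_noise(nuclei_render):
    volume, gt = nuclei_render
    noisy = syn.apply_optics(volume, (0.75, 0.35, 0.35), (1.0, 2.0), seed=5)
    spots = seg.detect_nuclei(noisy["DAPI"], volume.voxel_size, 7.0)
    assert len(spots) == pytest.approx(len(gt.nuclei), rel=0.02)


def test_dissector_counts_exclusion_rules():
    # uniform grid of spots, one per box interior
    extent = (40.0, 40.0, 40.0)
    spots = [seg.Spot((10.0 + 20 * i, 10.0 + 20 * j, 10.0 + 20 * k), 7.0, 1.0)
             for i in range(2) for j in range(2) for k in range(2)]
    res = seg.dissector_counts(spots, extent, box_size=20.0, guard=0.0)
    assert res.counts.sum() == len(spots)
    assert np.all(res.counts == 1)
    # guard zone excludes border spots; each spot counts at most once
    spots.append(seg.Spot((1.0, 1.0, 1.0), 7.0, 1.0))
    res2 = seg.dissector_counts(spots, extent, box_size=18.0, guard=2.0)
    assert res2.counts.sum() <= len(spots)
    assert res2.n_excluded >= 1


def test_dissector_mean_matches_poisson_density(rng):
    extent = (60.0, 100.0, 100.0)
    lam = 0.002  # spots per um3
    n = rng.poisson(lam * np.prod(extent))
    pts = rng.random((n, 3)) * np.array(extent)
    spots = [seg.Spot(tuple(p), 7.0, 1.0) for p in pts]
    res = seg.dissector_counts(spots, extent, box_size=20.0, guard=2.0)
    assert abs(res.mean - lam * 20 ** 3) <= 2 * res.sem + 1e-9
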