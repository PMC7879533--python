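import copy

import numpy as np
import pytest
from scipy.spatial import cKDTree

from gliovasc import histocytometry as hc
from gliovasc import segmentation as seg
from gliovasc.io import MultiChannelVolume

VOX = (1.0, 1.0, 1.0)


def _cell_volume(n_nuclei):
    """One Iba-1 blob containing n nuclei, on a 1-µm grid."""
    shape = (24, 24, 40)
    iba = np.zeros(shape, np.float32)
    dapi = np.zeros(shape, np.float32)
    iba[8:16, 8:16, 8:32] = 100.0
    centers = [(12, 12, 12), (12, 12, 28)][:n_nuclei]
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    for c in centers:
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        dapi += 100.0 * np.exp(-r2 / (2 * 1.75 ** 2))
    mhc = iba.copy()
    return MultiChannelVolume(channels={"IBA1": iba, "DAPI": dapi, "MHCII": mhc},
                              voxel_size=VOX)


def test_one_blob_one_nucleus_one_cell():
    cells = hc.segment_cells(_cell_volume(1))
    assert len(cells) == 1
    assert cells[0].mean_intensity["MHCII"] > 0


def test_one_blob_two_nuclei_split_at_seed_boundary():
    cells = hc.segment_cells(_cell_volume(2))
    assert len(cells) == 2
    # near-equal split; the equidistant tie plane goes to one seed whole
    vols = sorted(c.volume_um3 for c in cells)
    total = sum(vols)
    assert vols[0] >= 0.4 * total


def test_no_nuclei_raises():
    vol = _cell_volume(1)
    vol.channels["DAPI"][:] = 0.0
    with pytest.raises(ValueError, match="nuclei"):
        hc.segment_cells(vol)


def test_rendered_gamms_recovered_with_mixture_intensities(myeloid_render):
    volume, gt = myeloid_render
    cells = hc.segment_cells(volume)
    assert len(cells) == pytest.approx(len(gt.myeloid), rel=0.02)
    gt_pts = np.array([m["centroid"] for m in gt.myeloid])
    gt_val = np.array([m["mhc2_intensity"] for m in gt.myeloid])
    d, idx = cKDTree(gt_pts).query([c.centroid for c in cells])
    assert d.max() < 2.0
    meas = np.array([c.mean_intensity["MHCII"] for c in cells])
    r = np.corrcoef(meas, gt_val[idx])[0, 1]
    assert r > 0.95


def test_gate_mhc2_mixture_and_scale_invariance(myeloid_render):
    volume, gt = myeloid_render
    cells = hc.segment_cells(volume)
    cells, frac = hc.gate_mhc2(cells)
    assert frac == pytest.approx(0.50, abs=0.03)
    scaled = copy.deepcopy(cells)
    for c in scaled:
        c.mean_intensity["MHCII"] *= 11.7
    _, frac2 = hc.gate_mhc2(scaled)
    assert frac2 == frac


def test_gate_errors():
    cells = [hc.CellRecord(cell_id=i, centroid=(0, 0, 0), volume_um3=100,
                           mean_intensity={"MHCII": 5.0}) for i in range(4)]
    with pytest.raises(ValueError, match="variance"):
        hc.gate_mhc2(cells)
    gated, frac = hc.gate_mhc2(cells, method="absolute", threshold=10.0)
    assert frac == 0.0
    assert all(c.gate == "MHCII_Low" for c in gated)


def test_partition_niches_recovers_block_layout():
    shape = (20, 40, 40)
    gfap = np.zeros(shape, np.float32)
    mhc = np.zeros(shape, np.float32)
    gfap[:, :20, :] = 100.0
    mhc[:, 20:, :] = 100.0
    nm = hc.partition_niches(gfap, mhc, VOX, smoothing=3.0)
    want = np.where(np.arange(40)[None, :, None] < 20, hc.NICHE_NEST,
                    hc.NICHE_STROMA) * np.ones(shape, np.uint8)
    agreement = (nm.labels == want).mean()
    assert agreement >= 0.95
    # classes partition the volume exactly
    counts = [(nm.labels == c).sum() for c in (0, 1, 2)]
    assert sum(counts) == np.prod(shape)


def test_partition_all_background_when_channels_empty():
    nm = hc.partition_niches(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)), VOX)
    assert (nm.labels == hc.NICHE_BACKGROUND).all()
    with pytest.raises(ZeroDivisionError):
        hc.tsr(nm)


def test_tsr_equals_voxel_count_ratio():
    labels = np.zeros((10, 10, 34), np.uint8)
    labels[:, :, :33] = hc.NICHE_NEST   # 3300 voxels
    labels[:, :, 33:] = hc.NICHE_STROMA  # 100 voxels
    nm = hc.NicheMap(labels=labels, voxel_size=VOX, smoothing_um=0.0)
    assert hc.tsr(nm) == pytest.approx(33.0)
    labels2 = np.zeros((10, 10, 10), np.uint8)
    labels2[:5] = hc.NICHE_NEST
    labels2[5:] = hc.NICHE_STROMA
    assert hc.tsr(hc.NicheMap(labels=labels2, voxel_size=VOX, smoothing_um=0.0)) == 1.0


def test_per_niche_vessels_attribution():
    shape = (20, 40, 40)
    labels = np.full(shape, hc.NICHE_STROMA, np.uint8)
    labels[:, :20, :] = hc.NICHE_NEST
    nm = hc.NicheMap(labels=labels, voxel_size=VOX, smoothing_um=0.0)
    vessel = np.zeros(shape, bool)
    vessel[8:12, 25:35, 8:32] = True  # entirely in stroma
    mask = seg.binary_label_mask(vessel, VOX)
    out = hc.per_niche_vessels(nm, mask)
    assert out["tumor_nest"]["vessel_volume_um3"] == 0.0
    assert out["stroma"]["vessel_volume_um3"] == pytest.approx(vessel.sum() * 1.0)
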