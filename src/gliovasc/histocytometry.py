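"""3D histocytometry of glioma-associated microglia/macrophages (GAMMs) and
the tumor-nest / stroma partition.

Flow-cytometry-style gating is performed on cells segmented in the imaging
volume: Iba-1+ cells are split by nearest DAPI seed, each cell carries its
mean intensity per channel, and a 1D gate on mean MHCII separates
MHCII-High (stromal phenotype) from MHCII-Low GAMMs. The tumor nest (GFAP-
rich) and stroma (MHCII-rich) are mapped as mutually exclusive niches by a
smoothed-density argmax with a joint background class; the tumor-stroma
ratio (TSR) is their volume ratio, and vessels can be attributed per niche.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .io import MultiChannelVolume
from .morphometry import SkeletonGraph
from .segmentation import LabelMask, binary_label_mask, detect_nuclei, make_mask, surface_stats

NICHE_BACKGROUND, NICHE_NEST, NICHE_STROMA = 0, 1, 2
_NICHE_NAMES = {NICHE_BACKGROUND: "background", NICHE_NEST: "tumor_nest", NICHE_STROMA: "stroma"}


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple              # (z, y, x) µm
    volume_um3: float
    mean_intensity: dict         # channel -> mean over the cell's voxels
    gate: str = "ungated"        # "MHCII_High" | "MHCII_Low" | "ungated"


@dataclass
class NicheMap:
    """Labeled grid over {background, tumor_nest, stroma}."""

    labels: np.ndarray
    voxel_size: tuple
    smoothing_um: float

    def volume_um3(self, niche: int) -> float:
        return float(np.sum(self.labels == niche)) * float(np.prod(self.voxel_size))


def segment_cells(
    volume: MultiChannelVolume,
    min_cell_volume: float = 50.0,
    nucleus_diameter: float = 7.0,
    iba_channel: str = "IBA1",
    dapi_channel: str = "DAPI",
    mask: LabelMask | None = None,
) -> list[CellRecord]:
    """Nucleus-seeded segmentation of myeloid cells.

    The Iba-1 mask is split by assigning each mask voxel to its nearest DAPI
    seed (detected nuclei); per-cell mean intensity is computed for every
    channel in the volume. Cells below ``min_cell_volume`` µm³ are dropped.
    """
    volume.require(iba_channel, dapi_channel)
    voxel = np.asarray(volume.voxel_size)
    if mask is None:
        mask = make_mask(volume[iba_channel], voxel, min_unit_volume=min_cell_volume,
                         source_channel=iba_channel)
    binary = mask.binary
    if not binary.any():
        return []
    seeds = detect_nuclei(volume[dapi_channel], voxel, nucleus_diameter)
    seed_pts = np.array([s.centroid for s in seeds]) if seeds else np.zeros((0, 3))
    # only seeds that could plausibly seed an Iba-1 cell: inside or near the mask
    if len(seed_pts):
        edt_out = ndimage.distance_transform_edt(~binary, sampling=voxel)
        idx = np.clip(np.round(seed_pts / voxel).astype(int), 0, np.array(binary.shape) - 1)
        near = edt_out[tuple(idx.T)] <= nucleus_diameter / 2
        seed_pts = seed_pts[near]
    if not len(seed_pts):
        raise ValueError("no DAPI nuclei found to seed cell segmentation")

    vox_idx = np.argwhere(binary)
    tree = cKDTree(seed_pts)
    _, owner = tree.query(vox_idx * voxel)
    voxvol = float(np.prod(voxel))
    cells: list[CellRecord] = []
    cid = 0
    for s in range(len(seed_pts)):
        sel = vox_idx[owner == s]
        vol = len(sel) * voxvol
        if vol < min_cell_volume:
            continue
        cid += 1
        coords = tuple(sel.T)
        means = {
            name: float(volume[name][coords].mean()) for name in volume.channel_names
        }
        centroid = tuple((sel.mean(axis=0) * voxel).tolist())
        cells.append(CellRecord(cell_id=cid, centroid=centroid,
                                volume_um3=vol, mean_intensity=means))
    return cells


def gate_mhc2(
    cells: list[CellRecord],
    method: str = "otsu",
    threshold: float | None = None,
    channel: str = "MHCII",
) -> tuple[list[CellRecord], float]:
    """1D gate on per-cell mean MHCII; returns the cells (gates set) and the
    MHCII-High fraction. Otsu gating is scale-invariant; an absolute
    threshold is available as an override."""
    values = np.array([c.mean_intensity[channel] for c in cells])
    if method == "otsu":
        if len(cells) < 2:
            raise ValueError("automatic gating needs at least 2 cells")
        if np.ptp(values) == 0:
            raise ValueError(
                "zero variance in MHCII means: Otsu gating undefined, "
                "use method='absolute' with an explicit threshold"
            )
        thr = float(threshold_otsu(values))
    elif method == "absolute":
        if threshold is None:
            raise ValueError("absolute gating needs an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown gating method {method!r}")
    n_high = 0
    for c in cells:
        high = c.mean_intensity[channel] > thr
        c.gate = "MHCII_High" if high else "MHCII_Low"
        n_high += int(high)
    return cells, n_high / len(cells) if cells else 0.0


def partition_niches(
    gfap_channel: np.ndarray,
    mhc2_channel: np.ndarray,
    voxel_size,
    smoothing: float = 10.0,
    background_quantile: float = 0.5,
) -> NicheMap:
    """Mutually exclusive tumor-nest / stroma map from smoothed densities.

    Each channel is smoothed at σ = ``smoothing`` µm and rescaled to [0, 1]
    (by a robust 99.5th-percentile maximum of its positive values, clipped).
    Voxels where both rescaled densities fall below ``background_quantile``
    are background; all others take the argmax class, with ties going to
    the tumor nest. The classes partition the volume exactly.
    """
    voxel = np.asarray(voxel_size, float)
    sig = smoothing / voxel

    def density(ch):
        d = ndimage.gaussian_filter(np.asarray(ch, np.float32), sigma=sig)
        pos = d[d > 0]
        if pos.size == 0:
            return np.zeros_like(d)
        return np.clip(d / np.percentile(pos, 99.5), 0.0, 1.0)

    g = density(gfap_channel)
    m = density(mhc2_channel)
    labels = np.where(g >= m, NICHE_NEST, NICHE_STROMA).astype(np.uint8)
    labels[(g < background_quantile) & (m < background_quantile)] = NICHE_BACKGROUND
    return NicheMap(labels=labels, voxel_size=tuple(float(v) for v in voxel),
                    smoothing_um=float(smoothing))


def tsr(niche_map: NicheMap) -> float:
    """Tumor-stroma ratio: tumor-nest volume / stroma volume (µm³/µm³)."""
    nest = niche_map.volume_um3(NICHE_NEST)
    stroma = niche_map.volume_um3(NICHE_STROMA)
    if stroma == 0:
        raise ZeroDivisionError("stroma volume is zero: TSR undefined")
    return nest / stroma


def per_niche_vessels(
    niche_map: NicheMap,
    coliv_mask: LabelMask,
    skeleton: SkeletonGraph | None = None,
) -> dict:
    """Vessel volume, surface area and median caliber attributed per niche.

    Vessel voxels take the niche of the voxel they occupy; skeleton
    centerline points take the niche containing them, and their diameters
    (2 × radius) summarize per-niche caliber.
    """
    if niche_map.labels.shape != coliv_mask.binary.shape:
        raise ValueError("niche map and vessel mask are on different grids")
    voxel = np.asarray(niche_map.voxel_size)
    out = {}
    for code in (NICHE_NEST, NICHE_STROMA):
        sel = (niche_map.labels == code) & coliv_mask.binary
        stats = surface_stats(binary_label_mask(sel, niche_map.voxel_size))
        entry = {
            "vessel_volume_um3": stats.volume_um3,
            "vessel_surface_um2": stats.surface_area_um2,
            "median_caliber_um": float("nan"),
        }
        if skeleton is not None and skeleton.edges:
            diams = []
            shape = np.array(niche_map.labels.shape)
            for e in skeleton.edges:
                idx = np.clip(np.round(e.path / voxel).astype(int), 0, shape - 1)
                in_niche = niche_map.labels[tuple(idx.T)] == code
                diams.extend((2.0 * e.radii[in_niche]).tolist())
            if diams:
                entry["median_caliber_um"] = float(np.median(diams))
        out[_NICHE_NAMES[code]] = entry
    return out
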