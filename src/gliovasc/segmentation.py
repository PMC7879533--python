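"""Channel segmentation: isosurface-style masks, surface/volume statistics,
nucleus spot detection and stereological dissector counting.

A "unit" is a connected component of a thresholded channel — the
indivisible cell-size particle expressing a given marker. Surface area is
measured on a triangulated isosurface of each unit (marching cubes at the
0.5 level of the binary mask, anisotropy-aware); volume is voxel counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes, mesh_surface_area

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), bool)


@dataclass
class LabelMask:
    """Labeled 3D mask: 0 = background, units labeled 1..N contiguously."""

    labels: np.ndarray
    voxel_size: tuple
    source_channel: str = ""
    threshold: float = float("nan")
    min_unit_volume: float = 0.0

    @property
    def n_units(self) -> int:
        return int(self.labels.max())

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class SurfaceStats:
    """Totals and per-unit isosurface statistics (areas µm², volumes µm³)."""

    unit_count: int
    surface_area_um2: float
    volume_um3: float
    per_unit: list = field(default_factory=list)


@dataclass
class Spot:
    """A detected cell-size spot (e.g. one nucleus)."""

    centroid: tuple          # (z, y, x) µm
    diameter: float          # µm (the detection scale)
    intensity: float


def make_mask(
    channel: np.ndarray,
    voxel_size,
    method: str = "otsu",
    threshold: float | None = None,
    min_unit_volume: float = 50.0,
    smoothing: float = 0.5,
    source_channel: str = "",
) -> LabelMask:
    """Threshold a channel into a labeled unit mask.

    Gaussian pre-smoothing (σ in µm), Otsu or absolute thresholding,
    26-connected components, then removal of units below ``min_unit_volume``
    µm³. The threshold actually used is recorded on the mask.
    """
    voxel = tuple(float(v) for v in voxel_size)
    img = np.asarray(channel, np.float32)
    if smoothing > 0:
        img = ndimage.gaussian_filter(img, sigma=np.asarray(smoothing) / np.asarray(voxel))
    if method == "absolute":
        if threshold is None:
            raise ValueError("absolute thresholding needs an explicit threshold")
        thr = float(threshold)
    elif method == "otsu":
        if img.max() == img.min():
            thr = float(img.max())  # constant channel -> empty mask
        else:
            thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    binary = img > thr
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n:
        voxvol = float(np.prod(voxel))
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts * voxvol >= min_unit_volume)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, labels.dtype)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    if labels.max() == 0:
        logger.info("make_mask(%s): empty result at threshold %.4g", source_channel, thr)
    return LabelMask(
        labels=labels, voxel_size=voxel, source_channel=source_channel,
        threshold=thr, min_unit_volume=min_unit_volume,
    )


def binary_label_mask(binary: np.ndarray, voxel_size, source_channel: str = "") -> LabelMask:
    """Wrap an already-binary mask (e.g. a ground-truth mask) as a LabelMask."""
    labels, _ = ndimage.label(np.asarray(binary, bool), structure=_CONN26)
    return LabelMask(labels=labels, voxel_size=tuple(float(v) for v in voxel_size),
                     source_channel=source_channel, threshold=0.5)


def _unit_area(binary: np.ndarray, voxel) -> float:
    """Triangulated isosurface area of one binary unit at the 0.5 level.

    The binary mask is smoothed by one voxel before triangulation: raw
    binary marching cubes overestimates curved surfaces by ~8% (staircase
    artifact), while the smoothed 0.5-level set tracks the true interface.
    """
    padded = np.pad(binary.astype(np.float32), 2)
    if padded.max() == 0:
        return 0.0
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    if smoothed.max() <= 0.5:  # unit too thin to survive smoothing
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(voxel))
    return float(mesh_surface_area(verts, faces))


def surface_stats(mask: LabelMask) -> SurfaceStats:
    """Surface area and volume, total and per unit."""
    n = mask.n_units
    if n == 0:
        return SurfaceStats(0, 0.0, 0.0, [])
    voxvol = mask.voxel_volume
    per_unit = []
    objects = ndimage.find_objects(mask.labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        unit = mask.labels[sl] == lab
        vol = float(unit.sum()) * voxvol
        area = _unit_area(unit, mask.voxel_size)
        per_unit.append({"unit": lab, "surface_area_um2": area, "volume_um3": vol})
    return SurfaceStats(
        unit_count=len(per_unit),
        surface_area_um2=float(sum(u["surface_area_um2"] for u in per_unit)),
        volume_um3=float(sum(u["volume_um3"] for u in per_unit)),
        per_unit=per_unit,
    )


def detect_nuclei(
    channel: np.ndarray,
    voxel_size,
    expected_diameter: float = 7.0,
    min_separation: float | None = None,
    relative_threshold: float = 0.2,
) -> list[Spot]:
    """Scale-matched blob detection (Laplacian of Gaussian) of cell nuclei.

    The LoG scale is matched to ``expected_diameter`` (σ = diameter/4, the
    rendering convention for a Gaussian-sphere nucleus); local maxima closer
    than ``min_separation`` (default 0.7 × diameter) are suppressed and the
    response threshold is relative, so the count is invariant to global
    intensity scaling. Spots are returned sorted by intensity, brightest
    first.
    """
    voxel = np.asarray(voxel_size, float)
    if expected_diameter <= 2 * voxel.max():
        raise ValueError("expected_diameter must exceed twice the voxel pitch")
    if min_separation is None:
        min_separation = 0.7 * expected_diameter
    img = np.asarray(channel, np.float64)
    if img.size == 0 or img.max() <= 0:
        return []
    sigma_vox = (expected_diameter / 4.0) / voxel
    response = -ndimage.gaussian_laplace(img, sigma=sigma_vox)
    rmax = response.max()
    if rmax <= 0:
        return []
    # candidate maxima on a small footprint, then exact Euclidean greedy
    # suppression at min_separation (Chebyshev-only suppression would drop
    # diagonal neighbors)
    cand = peak_local_max(
        response, min_distance=2, threshold_abs=relative_threshold * rmax,
        exclude_border=False,
    )
    order = np.argsort(-response[tuple(cand.T)])
    cand_um = cand[order] * voxel
    kept: list[int] = []
    kept_pts: list[np.ndarray] = []
    for i, p in enumerate(cand_um):
        if kept_pts:
            d2 = np.sum((np.array(kept_pts) - p) ** 2, axis=1)
            if d2.min() < min_separation ** 2:
                continue
        kept.append(i)
        kept_pts.append(p)
    peaks = cand[order][kept]
    spots = [
        Spot(
            centroid=tuple(float(c) for c in p * voxel),
            diameter=float(expected_diameter),
            intensity=float(img[tuple(p)]),
        )
        for p in peaks
    ]
    spots.sort(key=lambda s: -s.intensity)
    return spots


@dataclass
class DissectorResult:
    counts: np.ndarray        # count per 3D dissector box
    mean: float
    sem: float
    box_size: float
    n_boxes: int
    n_excluded: int           # spots outside the counting grid / in guard zones


def dissector_counts(
    spots: list[Spot],
    extent,
    box_size: float,
    guard: float = 0.0,
) -> DissectorResult:
    """Unbiased 3D stereological dissector counting.

    The volume inside a guard margin is tiled with half-open boxes; a spot
    counts in exactly one box (its containing box) and spots in the guard
    zone or beyond the last full box are excluded, which implements the
    counting-frame exclusion planes.
    """
    extent = np.asarray(extent, float)
    nb = np.floor((extent - 2 * guard) / box_size).astype(int)
    if np.any(nb < 1):
        raise ValueError(f"box_size {box_size} µm does not fit extent {extent.tolist()}")
    counts = np.zeros(tuple(nb), np.int64)
    excluded = 0
    for s in spots:
        idx = np.floor((np.asarray(s.centroid) - guard) / box_size).astype(int)
        if np.all(idx >= 0) and np.all(idx < nb):
            counts[tuple(idx)] += 1
        else:
            excluded += 1
    flat = counts.ravel()
    mean = float(flat.mean())
    sem = float(flat.std(ddof=1) / np.sqrt(flat.size)) if flat.size > 1 else 0.0
    return DissectorResult(
        counts=counts, mean=mean, sem=sem, box_size=float(box_size),
        n_boxes=int(flat.size), n_excluded=excluded,
    )
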