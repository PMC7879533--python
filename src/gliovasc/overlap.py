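"""COL-IV / CD31 surface coincidence — the blood–tumor-barrier multilayer
readout.

In healthy cortex the endothelial lining (CD31) and the basement membrane
(COL-IV) are apposed layers and their isosurfaces overlap almost
completely; fenestrated tumor vessels lose this coincidence. Overlap is computed
voxelwise on the two masks (the paper's procedure builds a voxel
colocalization channel and isosurfaces it); percentages are reported
relative to each structure and to their union, plus the Venn triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import LabelMask, binary_label_mask, surface_stats


@dataclass
class OverlapResult:
    area_A_um2: float
    area_B_um2: float
    volume_A_um3: float
    volume_B_um3: float
    volume_AB_um3: float           # strict voxel intersection
    area_AB_um2: float             # isosurface area of the intersection shell
    overlap_fraction_A: float      # fraction of A within tolerance of B
    overlap_fraction_B: float
    overlap_fraction_union: float
    venn_um3: dict                 # {"A_only": ..., "AB": ..., "B_only": ...}
    dilation_tolerance_um: float


def masked_channel(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero intensities outside the mask (artifact suppression before
    colocalization)."""
    channel = np.asarray(channel)
    mask = np.asarray(mask).astype(bool)
    if channel.shape != mask.shape:
        raise ValueError(f"shape mismatch: channel {channel.shape} vs mask {mask.shape}")
    return np.where(mask, channel, np.zeros((), dtype=channel.dtype))


def _as_binary(mask) -> tuple[np.ndarray, tuple]:
    if isinstance(mask, LabelMask):
        return mask.binary, mask.voxel_size
    raise TypeError("overlap_masks expects LabelMask inputs (use binary_label_mask)")


def _within(mask: np.ndarray, other: np.ndarray, tol: float, voxel) -> np.ndarray:
    """Voxels of ``mask`` lying within ``tol`` µm of ``other``."""
    if tol <= 0:
        return mask & other
    if not other.any():
        return np.zeros_like(mask)
    d = ndimage.distance_transform_edt(~other, sampling=voxel)
    return mask & (d <= tol)


def overlap_masks(
    mask_A: LabelMask,
    mask_B: LabelMask,
    dilation_tolerance: float = 0.0,
) -> OverlapResult:
    """Voxel-based overlap of two masks with an optional symmetric distance
    tolerance (membrane and endothelium are apposed, not identical, layers).

    ``overlap_fraction_A`` is the fraction of A's voxels within the
    tolerance of B (and vice versa); at tolerance 0 both reduce to the
    strict intersection. The Venn triple and ``volume_AB`` always use the
    strict intersection, so they are symmetric in the argument order.
    """
    a, va = _as_binary(mask_A)
    b, vb = _as_binary(mask_B)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if tuple(va) != tuple(vb):
        raise ValueError(f"voxel size mismatch: {va} vs {vb}")
    if dilation_tolerance < 0:
        raise ValueError("dilation_tolerance must be >= 0")
    voxvol = float(np.prod(va))
    nA, nB = int(a.sum()), int(b.sum())
    strict = a & b
    nAB = int(strict.sum())
    a_near_b = int(_within(a, b, dilation_tolerance, va).sum())
    b_near_a = int(_within(b, a, dilation_tolerance, va).sum())
    union = nA + nB - nAB
    stats_A = surface_stats(mask_A)
    stats_B = surface_stats(mask_B)
    stats_AB = surface_stats(binary_label_mask(strict, va))
    return OverlapResult(
        area_A_um2=stats_A.surface_area_um2,
        area_B_um2=stats_B.surface_area_um2,
        volume_A_um3=nA * voxvol,
        volume_B_um3=nB * voxvol,
        volume_AB_um3=nAB * voxvol,
        area_AB_um2=stats_AB.surface_area_um2,
        overlap_fraction_A=a_near_b / nA if nA else 0.0,
        overlap_fraction_B=b_near_a / nB if nB else 0.0,
        overlap_fraction_union=nAB / union if union else 0.0,
        venn_um3={
            "A_only": (nA - nAB) * voxvol,
            "AB": nAB * voxvol,
            "B_only": (nB - nAB) * voxvol,
        },
        dilation_tolerance_um=float(dilation_tolerance),
    )


def colocalization_histogram(
    channel_A: np.ndarray,
    channel_B: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
    bins: int = 64,
) -> dict:
    """2D joint intensity histogram of two channels over the union of their
    masks, with marginal sums."""
    a = np.asarray(channel_A, float)
    b = np.asarray(channel_B, float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if masks is not None:
        sel = np.asarray(masks[0], bool) | np.asarray(masks[1], bool)
    else:
        sel = np.ones(a.shape, bool)
    av, bv = a[sel], b[sel]
    if av.size == 0:
        hist = np.zeros((bins, bins))
        edges = np.linspace(0, 1, bins + 1)
        return {"hist": hist, "edges_A": edges, "edges_B": edges,
                "marginal_A": hist.sum(1), "marginal_B": hist.sum(0)}
    hist, ea, eb = np.histogram2d(av, bv, bins=bins)
    return {"hist": hist, "edges_A": ea, "edges_B": eb,
            "marginal_A": hist.sum(axis=1), "marginal_B": hist.sum(axis=0)}
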