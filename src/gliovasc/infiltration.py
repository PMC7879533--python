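"""T-cell counting and extravasation classification.

CD3+ cells are detected as spots (requiring a coincident DAPI nucleus — a
T cell must have a nucleus), their distance to the nearest endothelium
(CD31 mask surface) is read off an anisotropy-aware Euclidean distance
transform, and each cell is classified as *extravasating* (in contact with
the endothelium, distance <= the contact threshold, default 2 µm) or
*migrated* into the parenchyma. Distances are centroid-to-mask-surface and
are 0 for centroids inside or touching the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import LabelMask, detect_nuclei

DEFAULT_CONTACT_THRESHOLD = 2.0  # µm


@dataclass
class TCellRecord:
    centroid: tuple                  # (z, y, x) µm
    intensity: float = 0.0
    distance_um: float | None = None
    status: str | None = None        # "extravasating" | "migrated"


def detect_tcells(
    cd3_channel: np.ndarray,
    dapi_channel: np.ndarray,
    voxel_size,
    expected_diameter: float = 7.0,
) -> list[TCellRecord]:
    """Spot-detect CD3 cells, keeping only those with a DAPI nucleus within
    one cell radius."""
    cd3_spots = detect_nuclei(cd3_channel, voxel_size, expected_diameter)
    if not cd3_spots:
        return []
    dapi_spots = detect_nuclei(dapi_channel, voxel_size, expected_diameter)
    if not dapi_spots:
        return []
    nuclei = np.array([s.centroid for s in dapi_spots])
    radius = expected_diameter / 2.0
    records = []
    for s in cd3_spots:
        d2 = np.sum((nuclei - np.asarray(s.centroid)) ** 2, axis=1)
        if d2.min() <= radius ** 2:
            records.append(TCellRecord(centroid=s.centroid, intensity=s.intensity))
    return records


def distance_to_endothelium(
    records: list[TCellRecord],
    cd31_mask: LabelMask,
    voxel_size=None,
) -> list[TCellRecord]:
    """Attach the distance from each centroid to the CD31 mask surface."""
    binary = cd31_mask.binary
    voxel = np.asarray(voxel_size if voxel_size is not None else cd31_mask.voxel_size, float)
    if not binary.any():
        raise ValueError(
            f"endothelium mask {cd31_mask.source_channel or 'CD31'!r} is empty: "
            "distances are undefined"
        )
    edt = ndimage.distance_transform_edt(~binary, sampling=voxel)
    shape = np.array(binary.shape)
    for r in records:
        idx = np.clip(np.round(np.asarray(r.centroid) / voxel).astype(int), 0, shape - 1)
        r.distance_um = float(edt[tuple(idx)])
    return records


def classify_infiltration(
    records: list[TCellRecord],
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> dict:
    """Threshold distances into extravasating vs migrated; distance
    statistics (mean ± SEM) are over migrated cells only."""
    if any(r.distance_um is None for r in records):
        raise ValueError("distances not computed: run distance_to_endothelium first")
    for r in records:
        r.status = "extravasating" if r.distance_um <= contact_threshold else "migrated"
    migrated = np.array([r.distance_um for r in records if r.status == "migrated"])
    n_mig = len(migrated)
    return {
        "extravasating": sum(1 for r in records if r.status == "extravasating"),
        "migrated": n_mig,
        "migrated_distance_mean_um": float(migrated.mean()) if n_mig else float("nan"),
        "migrated_distance_sem_um": (
            float(migrated.std(ddof=1) / np.sqrt(n_mig)) if n_mig > 1 else 0.0
        ),
        "contact_threshold_um": float(contact_threshold),
    }
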