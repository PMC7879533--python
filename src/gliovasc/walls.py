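"""Basement-membrane integrity from luminance profiles along vessel walls.

An intact basement membrane shows uniform COL-IV fluorescence along the
vessel wall; fenestration shows up as drastic peaks and valleys. The
readout: trace 40-µm lines along vessel walls in single 1-µm optical
slices, sample the fluorescence along each line, normalize each profile to
its own maximum ("relative fluorescence"), harmonize all profiles to their
first 27 µm, and summarize each as the population standard deviation of
relative fluorescence. The group SD rises monotonically with the fraction
of wall surface removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .io import MultiChannelVolume

logger = logging.getLogger(__name__)


@dataclass
class LuminanceProfile:
    """Arc-length-parameterized intensity trace along one wall segment."""

    positions: np.ndarray    # µm, strictly increasing from 0
    raw: np.ndarray
    relative: np.ndarray     # raw / max(raw), in [0, 1]
    slice_index: int = -1
    trace_id: int = -1

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0


def extract_optical_slice(
    volume: MultiChannelVolume,
    channel: str,
    z_index: int,
    slice_thickness: float = 1.0,
) -> np.ndarray:
    """One optical slice of the given physical thickness.

    When the z pitch is below ``slice_thickness``, the arithmetic mean of
    the planes starting at ``z_index`` and spanning the thickness is taken.
    """
    volume.require(channel)
    data = volume[channel]
    nz = data.shape[0]
    n_planes = max(1, int(round(slice_thickness / volume.voxel_size[0])))
    if z_index < 0 or z_index + n_planes > nz:
        raise IndexError(
            f"z_index {z_index} (+{n_planes} planes) out of range for {nz} planes"
        )
    return data[z_index:z_index + n_planes].mean(axis=0)


def trace_wall_lines(
    mask_2d: np.ndarray,
    voxel_yx,
    n_lines: int = 5,
    line_length: float = 40.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Boundary-following polylines of fixed arc length along a 2D mask.

    Contours of the mask (the vessel walls) are tiled with disjoint arcs of
    ``line_length`` µm; the starting phase on each contour is seeded. If the
    available boundary holds fewer than ``n_lines`` arcs, the shortfall is
    logged as a warning and fewer lines are returned. Each polyline is an
    (m, 2) array of (y, x) µm positions.
    """
    vy, vx = (float(v) for v in voxel_yx)
    rng = np.random.default_rng(seed)
    contours = find_contours(np.asarray(mask_2d, float), 0.5)
    contours = [c * np.array([vy, vx]) for c in contours]

    def arc_lengths(c):
        steps = np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1))
        return np.concatenate([[0.0], np.cumsum(steps)])

    scored = sorted(contours, key=lambda c: -arc_lengths(c)[-1])
    lines: list[np.ndarray] = []
    for c in scored:
        if len(lines) >= n_lines:
            break
        s = arc_lengths(c)
        total = s[-1]
        capacity = int(total // line_length)
        if capacity == 0:
            continue
        start = rng.uniform(0.0, total)
        for k in range(min(capacity, n_lines - len(lines))):
            a = (start + k * line_length) % total
            lines.append(_resample_arc(c, s, a, line_length))
    if len(lines) < n_lines:
        logger.warning(
            "trace_wall_lines: boundary supports only %d of %d requested lines",
            len(lines), n_lines,
        )
    return lines


def _resample_arc(contour: np.ndarray, s: np.ndarray, start: float, length: float,
                  step: float = 0.25) -> np.ndarray:
    """Points along a (possibly wrapping) arc of a closed contour."""
    total = s[-1]
    t = (start + np.arange(0.0, length + step / 2, step)) % total
    y = np.interp(t, s, contour[:, 0], period=None)
    x = np.interp(t, s, contour[:, 1], period=None)
    return np.column_stack([y, x])


def profile_luminance(
    image: np.ndarray,
    polyline: np.ndarray,
    voxel_yx,
    step: float = 1.0,
) -> LuminanceProfile:
    """Bilinear intensity samples at arc-length steps along a polyline.

    Relative intensity is the raw value divided by the profile's own
    maximum, giving a scale-invariant trace in [0, 1].
    """
    polyline = np.asarray(polyline, float)
    if polyline.ndim != 2 or len(polyline) < 2:
        raise ValueError("polyline must contain at least 2 points")
    vy, vx = (float(v) for v in voxel_yx)
    steps = np.sqrt((np.diff(polyline, axis=0) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(steps)])
    positions = np.arange(0.0, s[-1] + 1e-9, step)
    y = np.interp(positions, s, polyline[:, 0]) / vy
    x = np.interp(positions, s, polyline[:, 1]) / vx
    raw = ndimage.map_coordinates(np.asarray(image, float), [y, x], order=1, mode="nearest")
    peak = raw.max()
    relative = raw / peak if peak > 0 else np.zeros_like(raw)
    return LuminanceProfile(positions=positions, raw=raw, relative=relative)


def harmonize_profiles(
    profiles: list[LuminanceProfile],
    keep_length: float = 27.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate every profile to its first ``keep_length`` µm of arc length.

    Profiles shorter than ``keep_length`` violate the harmonization
    precondition and raise with a diagnostic naming the offenders. Returns
    ``(matrix, positions)`` where matrix rows are relative-fluorescence
    traces of equal length.
    """
    if keep_length <= 0:
        raise ValueError("keep_length must be > 0")
    if not profiles:
        raise ValueError("no profiles to harmonize")
    short = [i for i, p in enumerate(profiles) if p.length < keep_length]
    if short:
        raise ValueError(
            f"profiles {short} are shorter than keep_length={keep_length} µm"
        )
    n_keep = min(int(np.sum(p.positions < keep_length)) for p in profiles)
    matrix = np.stack([p.relative[:n_keep] for p in profiles])
    return matrix, profiles[0].positions[:n_keep]


@dataclass
class FenestrationResult:
    per_profile_sd: np.ndarray
    mean_sd: float
    sem_sd: float


def fenestration_metric(profile_matrix: np.ndarray) -> FenestrationResult:
    """Population SD of relative fluorescence per profile, with the group
    mean ± SEM. Uniform walls give 0; fenestrated walls give large values."""
    m = np.asarray(profile_matrix, float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("profile matrix must be 2D with at least one profile")
    sds = m.std(axis=1, ddof=0)
    sem = float(sds.std(ddof=1) / np.sqrt(len(sds))) if len(sds) > 1 else 0.0
    return FenestrationResult(per_profile_sd=sds, mean_sd=float(sds.mean()), sem_sd=sem)
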