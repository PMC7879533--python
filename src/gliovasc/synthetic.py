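"""Synthetic multichannel confocal volumes with full ground truth.

Emulates 60-µm-thick immunolabeled tissue blocks of cortex/glioblastoma:
a vessel tree rendered as a collagen-IV basement-membrane shell with
controllable fenestration (gap) fraction, a CD31 endothelial lining with a
controllable coincidence fraction, DAPI nuclei, CD3 T cells placed at
requested distances from the endothelium, Iba-1 myeloid cells whose MHCII
intensity follows a two-component Gaussian mixture, and a GFAP channel in
either scattered-astrocyte or tumor-mass mode. Optics (Gaussian PSF blur and
Poisson–Gaussian noise) are applied as a separate, optional stage.

All coordinates are (z, y, x) micrometres; voxel centers sit at
``index * voxel_size``. Every stochastic choice flows from one seed through
named substreams, so equal seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import MultiChannelVolume

# substream indices of the per-seed SeedSequence spawn
_STREAM_GAPS = 0
_STREAM_CD31 = 1
_STREAM_NUCLEI = 2
_STREAM_TCELLS = 3
_STREAM_MYELOID = 4
_STREAM_GFAP = 5

DEFAULT_INTENSITY = 100.0


# ---------------------------------------------------------------------------
# tree specification and validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSpec:
    """Declarative vessel-tree geometry.

    segments: list of ``(start, end, radius)`` with start/end (z, y, x) in µm.
    branch_nodes: list of ``(position, daughter_count)``; a node with k
        daughters has k + 1 incident segments (one parent).
    extent: physical volume size (z, y, x) in µm.
    """

    segments: tuple
    branch_nodes: tuple
    extent: tuple

    @staticmethod
    def make(segments, branch_nodes, extent) -> "TreeSpec":
        segs = tuple(
            (tuple(float(v) for v in a), tuple(float(v) for v in b), float(r))
            for a, b, r in segments
        )
        nodes = tuple((tuple(float(v) for v in p), int(k)) for p, k in branch_nodes)
        return TreeSpec(segs, nodes, tuple(float(v) for v in extent))


@dataclass
class VesselTree:
    """A validated, connected centerline tree ready for rendering."""

    spec: TreeSpec
    starts: np.ndarray  # (n, 3) µm
    ends: np.ndarray    # (n, 3) µm
    radii: np.ndarray   # (n,) µm

    @property
    def extent(self) -> tuple[float, float, float]:
        return self.spec.extent

    @property
    def branch_nodes(self) -> tuple:
        return self.spec.branch_nodes

    def branch_class_counts(self) -> dict[str, int]:
        """Ground-truth junction taxonomy: 2 daughters = primary, 3 =
        secondary, >= 4 = tertiary."""
        counts = {"primary": 0, "secondary": 0, "tertiary": 0}
        for _, k in self.spec.branch_nodes:
            if k == 2:
                counts["primary"] += 1
            elif k == 3:
                counts["secondary"] += 1
            else:
                counts["tertiary"] += 1
        return counts


def _segment_segment_distance(a1, b1, a2, b2) -> float:
    """Minimum distance between two 3D segments."""
    a1, b1, a2, b2 = (np.asarray(v, float) for v in (a1, b1, a2, b2))
    d1, d2, r = b1 - a1, b2 - a2, a1 - a2
    A, B, C = d1 @ d1, d1 @ d2, d2 @ d2
    D, E = d1 @ r, d2 @ r
    den = A * C - B * B
    s = np.clip((B * E - C * D) / den, 0.0, 1.0) if den > 1e-12 else 0.0
    t = (B * s + E) / C if C > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((B * t - D) / A, 0.0, 1.0) if A > 1e-12 else 0.0
    return float(np.linalg.norm(a1 + s * d1 - (a2 + t * d2)))


def build_vessel_tree(spec: TreeSpec, seed: int = 0) -> VesselTree:
    """Validate a :class:`TreeSpec` and return a renderable tree.

    Checks the spec invariants (positive radii, points inside the extent,
    daughter counts >= 2), centerline connectivity, consistency of declared
    branch nodes with segment incidence, and rejects non-adjacent segments
    that pass closer than the sum of their radii.
    """
    if not spec.segments:
        return VesselTree(spec, np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))
    starts = np.array([s[0] for s in spec.segments], float)
    ends = np.array([s[1] for s in spec.segments], float)
    radii = np.array([s[2] for s in spec.segments], float)
    extent = np.asarray(spec.extent, float)

    if np.any(radii <= 0):
        raise ValueError("all segment radii must be > 0")
    pts = np.vstack([starts, ends])
    if np.any(pts < -1e-9) or np.any(pts > extent + 1e-9):
        raise ValueError("segment endpoints must lie inside the extent")
    for pos, k in spec.branch_nodes:
        if k < 2:
            raise ValueError(f"branch node at {pos} has daughter_count {k} < 2")
        incident = sum(
            np.allclose(starts[i], pos) or np.allclose(ends[i], pos)
            for i in range(len(radii))
        )
        if incident != k + 1:
            raise ValueError(
                f"branch node at {pos} declares {k} daughters but has "
                f"{incident} incident segments (expected {k + 1})"
            )

    # connectivity over shared endpoints
    key = lambda p: tuple(np.round(np.asarray(p, float), 6))
    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(starts, ends):
        ra, rb = find(key(a)), find(key(b))
        if ra != rb:
            parent[ra] = rb
    roots = {find(key(p)) for p in pts}
    if len(roots) > 1:
        raise ValueError(f"tree is disconnected ({len(roots)} components)")

    # non-adjacent segments must not come closer than the sum of radii
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            shared = any(
                np.allclose(p, q)
                for p in (starts[i], ends[i])
                for q in (starts[j], ends[j])
            )
            if shared:
                continue
            d = _segment_segment_distance(starts[i], ends[i], starts[j], ends[j])
            if d < radii[i] + radii[j]:
                raise ValueError(
                    f"segments {i} and {j} overlap: centerline distance "
                    f"{d:.2f} µm < sum of radii {radii[i] + radii[j]:.2f} µm"
                )
    return VesselTree(spec, starts, ends, radii)


def straight_tube_spec(
    extent: Sequence[float],
    radius: float,
    orientation: str = "x",
    margin: float | None = None,
) -> TreeSpec:
    """One straight vessel through the volume interior.

    orientation: "x" (in-plane), "diag45" (45° in the x–y plane), or
    "oblique" (a non-axis-aligned 3D direction). The default margin keeps
    the capsule end caps (and hence a closed membrane) inside the volume.
    """
    if margin is None:
        margin = radius + 6.0
    ez, ey, ex = (float(v) for v in extent)
    c = np.array([ez / 2, ey / 2, ex / 2])
    if orientation == "x":
        a = np.array([c[0], c[1], margin])
        b = np.array([c[0], c[1], ex - margin])
    elif orientation == "diag45":
        h = min(ey, ex) / 2 - margin
        a, b = c - np.array([0, h, h]), c + np.array([0, h, h])
    elif orientation == "oblique":
        d = np.array([0.35, 0.65, 0.675])
        d /= np.linalg.norm(d)
        h = min((np.array([ez, ey, ex]) / 2 - margin) / np.abs(d))
        a, b = c - h * d, c + h * d
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return TreeSpec.make([(a, b, radius)], [], (ez, ey, ex))


def make_branching_tree(
    extent: Sequence[float],
    n_primary: int = 4,
    n_secondary: int = 1,
    n_tertiary: int = 0,
    trunk_radius: float = 3.0,
    branch_radius: float = 2.0,
    branch_length: float = 16.0,
) -> TreeSpec:
    """Deterministic connected tree with a requested junction taxonomy.

    Trunks run along y in the mid-z plane, joined at their starts by a spine
    along x (so the tree is one connected component); side branches emanate
    diagonally. Spine–trunk tee joints are themselves primary junctions and
    are included in the returned ground truth.
    """
    ez, ey, ex = (float(v) for v in extent)
    margin = 8.0
    z0 = ez / 2
    spacing_j, y0, tail_len = 24.0, 28.0, 12.0
    per_trunk = max(1, int((ey - y0 - margin - tail_len) // spacing_j))
    wanted = (["tertiary"] * n_tertiary + ["secondary"] * n_secondary
              + ["primary"] * n_primary)
    n_trunks = math.ceil(len(wanted) / per_trunk) if wanted else 1
    xs = np.linspace(margin + branch_length, ex - margin - branch_length, max(n_trunks, 2))
    if n_trunks > len(xs):
        raise ValueError("extent too small for the requested junction count")
    xs = xs[:n_trunks]

    segments, nodes = [], []
    dirs = [np.array(v, float) for v in
            [(0.55, 0.35, 0.65), (-0.55, 0.35, -0.65), (0.55, 0.35, -0.65),
             (-0.55, 0.35, 0.65), (0.8, 0.45, 0.0), (-0.8, 0.45, 0.0)]]
    for d in dirs:
        d /= np.linalg.norm(d)
    qi = 0  # queue index into wanted
    di = 0  # rotating direction index
    for t, x0 in enumerate(xs):
        prev = np.array([z0, y0, x0])
        nj = min(per_trunk, len(wanted) - qi)
        for j in range(nj):
            pos = np.array([z0, y0 + (j + 1) * spacing_j, x0])
            segments.append((prev, pos, trunk_radius))
            cls = wanted[qi]
            qi += 1
            k_side = {"primary": 1, "secondary": 2, "tertiary": 3}[cls]
            for s in range(k_side):
                d = dirs[(di + s) % len(dirs)]
                tip = pos + branch_length * d
                tip[0] = np.clip(tip[0], margin, ez - margin)
                segments.append((pos, tip, branch_radius))
            di += 1
            # trunk continues beyond the last junction so every junction has
            # a through-branch (daughters = emanating - 1 = k_side + 1)
            nodes.append((pos, k_side + 1))
            prev = pos
        # terminal tail so the last junction keeps its through-branch
        segments.append((prev, prev + np.array([0, tail_len, 0]), trunk_radius))
    # spine joining trunk starts; interior tee joints are primary junctions
    for t in range(len(xs) - 1):
        a = np.array([z0, y0, xs[t]])
        b = np.array([z0, y0, xs[t + 1]])
        segments.append((a, b, trunk_radius))
        if t > 0:
            nodes.append((a, 2))
    return TreeSpec.make(segments, nodes, (ez, ey, ex))


# ---------------------------------------------------------------------------
# render parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """Two-component Gaussian mixture for per-cell MHCII intensity."""

    mean_low: float = 20.0
    sd_low: float = 5.0
    mean_high: float = 50.0
    sd_high: float = 5.0
    weight_high: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValueError("weight_high must be in [0, 1]")


@dataclass(frozen=True)
class MyeloidSpec:
    n_cells: int = 0
    mhc2_mix: MixtureSpec = field(default_factory=MixtureSpec)
    cell_diameter: float = 10.0


@dataclass(frozen=True)
class RenderParams:
    """Rendering dials for :func:`render_volume` (all lengths in µm)."""

    voxel_size: tuple = (0.5, 0.5, 0.5)
    shell_thickness: float = 1.5   # COL-IV basement-membrane wall
    endo_thickness: float = 1.5    # CD31 endothelial lining
    gap_fraction: float = 0.0      # fraction of COL-IV surface patches removed
    endo_coincidence: float = 1.0  # fraction of CD31 coincident with COL-IV
    patch_size: float = 2.0        # surface patch edge, µm
    n_nuclei: int = 0
    nucleus_diameter: float = 7.0
    tcell_distances: tuple = ()
    tcell_diameter: float = 7.0
    myeloid_spec: MyeloidSpec | None = None
    gfap_mode: str | None = None   # "protoplasmic" | "tumor_mass"
    intensity: float = DEFAULT_INTENSITY

    def __post_init__(self):
        for name in ("gap_fraction", "endo_coincidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shell_thickness <= 0 or self.endo_thickness <= 0:
            raise ValueError("shell/endo thickness must be > 0")
        if self.n_nuclei < 0 or (self.myeloid_spec and self.myeloid_spec.n_cells < 0):
            raise ValueError("counts must be >= 0")
        if self.gfap_mode not in (None, "protoplasmic", "tumor_mass"):
            raise ValueError(f"unknown gfap_mode {self.gfap_mode!r}")


@dataclass
class GroundTruth:
    """Everything the renderer knows, for downstream oracles."""

    tree: VesselTree
    ideal_masks: dict                  # channel name -> bool (z, y, x)
    nuclei: np.ndarray                 # (n, 3) µm centroids (parenchymal)
    tcells: list                       # dicts: centroid, true_distance
    myeloid: list                      # dicts: centroid, mhc2_intensity, component
    gap_fraction_true: float           # zeroed / total shell patch count
    n_patches: int
    n_gapped: int
    overlap: dict                      # voxel-count overlap fractions of ideal masks
    niche_nest: np.ndarray | None
    niche_stroma: np.ndarray | None

    def summary(self) -> dict:
        return {
            "branch_classes": self.tree.branch_class_counts(),
            "n_nuclei": int(len(self.nuclei)),
            "n_tcells": len(self.tcells),
            "n_myeloid": len(self.myeloid),
            "gap_fraction_true": self.gap_fraction_true,
            "overlap": self.overlap,
        }


# ---------------------------------------------------------------------------
# geometry rasterization
# ---------------------------------------------------------------------------

def _grid_shape(extent, voxel) -> tuple[int, int, int]:
    return tuple(int(round(e / v)) for e, v in zip(extent, voxel))


def _surface_distance(tree: VesselTree, shape, voxel, pad: float) -> np.ndarray:
    """Signed distance to the vessel outer surface (negative inside), valid
    within ``pad`` µm of each capsule; +inf elsewhere."""
    surf = np.full(shape, np.inf, np.float32)
    voxel = np.asarray(voxel, float)
    for a, b, r in zip(tree.starts, tree.ends, tree.radii):
        lo = np.maximum(np.floor((np.minimum(a, b) - r - pad) / voxel).astype(int), 0)
        hi = np.minimum(np.ceil((np.maximum(a, b) + r + pad) / voxel).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz = (np.arange(lo[0], hi[0]) * voxel[0])[:, None, None]
        yy = (np.arange(lo[1], hi[1]) * voxel[1])[None, :, None]
        xx = (np.arange(lo[2], hi[2]) * voxel[2])[None, None, :]
        ab = b - a
        L2 = float(ab @ ab)
        if L2 < 1e-12:
            d2 = (zz - a[0]) ** 2 + (yy - a[1]) ** 2 + (xx - a[2]) ** 2
        else:
            t = ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]) / L2
            np.clip(t, 0.0, 1.0, out=t)
            d2 = ((zz - (a[0] + t * ab[0])) ** 2
                  + (yy - (a[1] + t * ab[1])) ** 2
                  + (xx - (a[2] + t * ab[2])) ** 2)
        s = np.sqrt(d2, dtype=np.float32) - np.float32(r)
        region = surf[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.minimum(region, s, out=region)
    return surf


def _patch_ids(coords_vox: tuple, voxel, patch_size: float) -> np.ndarray:
    """Map voxel coordinates to 2-µm-block patch identifiers."""
    ids = 0
    mult = 1
    for ax in (2, 1, 0):
        n = np.floor_divide((coords_vox[ax] * voxel[ax]).astype(np.float64), patch_size).astype(np.int64)
        ids = ids + n * mult
        mult *= 1 << 21
    return ids


def _add_blob(channel: np.ndarray, center, sigma: float, amplitude: float, voxel) -> None:
    """Add a Gaussian blob (σ in µm) at a physical center."""
    voxel = np.asarray(voxel, float)
    c = np.asarray(center, float)
    lo = np.maximum(np.floor((c - 4 * sigma) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((c + 4 * sigma) / voxel).astype(int) + 1, channel.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * voxel[0] - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * voxel[1] - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * voxel[2] - c[2])[None, None, :]
    g = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / (2 * sigma ** 2))
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (amplitude * g).astype(channel.dtype)


def _add_soft_sphere(channel: np.ndarray, center, radius: float, amplitude: float,
                     voxel, edge: float = 0.5) -> None:
    """Add a uniform-intensity sphere with a smooth (linear ramp) edge —
    the cell-body model for membrane/cytoplasmic markers."""
    voxel = np.asarray(voxel, float)
    c = np.asarray(center, float)
    reach = radius + edge
    lo = np.maximum(np.floor((c - reach) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((c + reach) / voxel).astype(int) + 1, channel.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * voxel[0] - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * voxel[1] - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * voxel[2] - c[2])[None, None, :]
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    w = np.clip((radius + edge - r) / edge, 0.0, 1.0)
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (amplitude * w).astype(channel.dtype)


def _sphere_mask(mask: np.ndarray, center, radius: float, voxel) -> None:
    voxel = np.asarray(voxel, float)
    c = np.asarray(center, float)
    lo = np.maximum(np.floor((c - radius) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((c + radius) / voxel).astype(int) + 1, mask.shape)
    zz = (np.arange(lo[0], hi[0]) * voxel[0] - c[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * voxel[1] - c[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * voxel[2] - c[2])[None, None, :]
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= (zz ** 2 + yy ** 2 + xx ** 2) <= radius ** 2


def _place_points(
    rng: np.random.Generator,
    n: int,
    extent,
    min_dist: float,
    margin: float,
    forbidden: np.ndarray | None,
    voxel,
    region: tuple | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Rejection-sample n points with a minimum pairwise center distance,
    outside a forbidden mask, at least ``margin`` from the volume faces."""
    extent = np.asarray(extent, float)
    lo = np.full(3, margin)
    hi = extent - margin
    if region is not None:
        lo = np.maximum(lo, region[0])
        hi = np.minimum(hi, region[1])
    if np.any(hi <= lo):
        raise ValueError("placement region is empty")
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n and tries < max_tries:
        tries += 1
        batch = lo + rng.random((max(4 * (n - len(accepted)), 16), 3)) * (hi - lo)
        for p in batch:
            if forbidden is not None:
                idx = tuple(np.round(p / np.asarray(voxel)).astype(int))
                if forbidden[idx]:
                    continue
            if accepted:
                d2 = np.sum((np.array(accepted) - p) ** 2, axis=1)
                if d2.min() < min_dist ** 2:
                    continue
            accepted.append(p)
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise ValueError(
            f"could only place {len(accepted)}/{n} points at min distance "
            f"{min_dist} µm; lower the count or the separation"
        )
    return np.array(accepted)


# ---------------------------------------------------------------------------
# main renderers
# ---------------------------------------------------------------------------

def render_volume(
    tree: VesselTree, params: RenderParams, seed: int
) -> tuple[MultiChannelVolume, GroundTruth]:
    """Rasterize a vessel tree plus cellular content into ideal (noise-free,
    blur-free) channels, returning the volume and its full ground truth.

    The COL-IV channel is a tube shell with ``gap_fraction`` of its 2-µm
    surface patches zeroed (fenestration); the CD31 channel is a lining of
    which ``endo_coincidence`` (by voxel count) is coincident with the COL-IV
    shell support and the remainder is displaced to just beneath the
    membrane. Apply :func:`apply_optics` afterwards for blur and noise.
    """
    voxel = np.asarray(params.voxel_size, float)
    if np.any(voxel <= 0):
        raise ValueError("voxel_size must be positive")
    extent = np.asarray(tree.extent, float)
    shape = _grid_shape(extent, voxel)
    nvox = int(np.prod(shape))
    if nvox > 3e8:
        raise MemoryError(f"volume of {nvox} voxels exceeds the configured budget")

    if len(tree.radii):
        if params.shell_thickness >= tree.radii.min() or params.endo_thickness >= tree.radii.min():
            raise ValueError("shell/endo thickness must be smaller than the smallest vessel radius")
        if params.endo_coincidence < 1.0 and (
            params.shell_thickness + params.endo_thickness >= tree.radii.min()
        ):
            raise ValueError(
                "displaced CD31 band needs shell_thickness + endo_thickness "
                "< min vessel radius"
            )

    streams = np.random.SeedSequence(seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]

    channels = {
        name: np.zeros(shape, np.float32)
        for name in ("DAPI", "GFAP", "COLIV", "CD31", "IBA1", "MHCII", "CD3")
    }
    ideal: dict[str, np.ndarray] = {}

    # --- vessel shells -----------------------------------------------------
    shell_t, endo_t = params.shell_thickness, params.endo_thickness
    pad = shell_t + endo_t + 1.0
    if len(tree.radii):
        surf = _surface_distance(tree, shape, voxel, pad)
        vessel = surf <= 0
        shell = vessel & (surf > -shell_t)
        inner = (surf <= -shell_t) & (surf > -(shell_t + endo_t))
    else:
        surf = None
        vessel = np.zeros(shape, bool)
        shell = np.zeros(shape, bool)
        inner = np.zeros(shape, bool)
    ideal["VESSEL"] = vessel

    # fenestration: Bernoulli gap per surface patch, coupled across
    # gap_fraction values through a per-patch uniform draw
    n_patches = n_gapped = 0
    coliv = shell.copy()
    if shell.any():
        sc = np.nonzero(shell)
        sid = _patch_ids(sc, voxel, params.patch_size)
        uniq, inv = np.unique(sid, return_inverse=True)
        n_patches = len(uniq)
        u = rngs[_STREAM_GAPS].random(n_patches)
        gapped = u < params.gap_fraction
        n_gapped = int(gapped.sum())
        gap_vox = gapped[inv]
        coliv[sc[0][gap_vox], sc[1][gap_vox], sc[2][gap_vox]] = False
    ideal["COLIV"] = coliv

    # CD31: coincident patches share the shell support; the rest is displaced
    # inward. Patch assignment targets the voxel-count coincidence fraction.
    cd31 = np.zeros(shape, bool)
    if shell.any():
        ic = np.nonzero(inner)
        iid = _patch_ids(ic, voxel, params.patch_size)
        all_uniq = np.unique(np.concatenate([uniq, np.unique(iid)])) if len(iid) else uniq
        pos = {pid: i for i, pid in enumerate(all_uniq)}
        c_cnt = np.zeros(len(all_uniq), np.int64)
        d_cnt = np.zeros(len(all_uniq), np.int64)
        np.add.at(c_cnt, [pos[p] for p in uniq], np.bincount(inv, minlength=n_patches))
        if len(iid):
            iu, icnt = np.unique(iid, return_counts=True)
            np.add.at(d_cnt, [pos[p] for p in iu], icnt)
        f = params.endo_coincidence
        coincident = np.zeros(len(all_uniq), bool)
        if f >= 1.0:
            coincident[:] = True
        elif f > 0.0:
            order = rngs[_STREAM_CD31].permutation(len(all_uniq))
            C = D = 0
            for i in order:
                if C + D == 0 or C / (C + D) < f:
                    coincident[i] = True
                    C += c_cnt[i]
                else:
                    D += d_cnt[i]
        shell_co = coincident[np.searchsorted(all_uniq, sid)]
        cd31[sc[0][shell_co], sc[1][shell_co], sc[2][shell_co]] = True
        if len(iid):
            inner_disp = ~coincident[np.searchsorted(all_uniq, iid)]
            cd31[ic[0][inner_disp], ic[1][inner_disp], ic[2][inner_disp]] = True
    ideal["CD31"] = cd31

    I0 = params.intensity
    channels["COLIV"][coliv] = I0
    channels["CD31"][cd31] = I0

    # --- GFAP niches -------------------------------------------------------
    niche_nest = niche_stroma = None
    stroma_region = None
    if params.gfap_mode == "tumor_mass":
        ysplit = extent[1] / 2
        yidx = int(round(ysplit / voxel[1]))
        nest = np.zeros(shape, bool)
        nest[:, :yidx, :] = True
        niche_nest, niche_stroma = nest, ~nest
        channels["GFAP"][nest] += I0
        channels["MHCII"][~nest] += 0.6 * I0  # diffuse stromal MHCII
        ideal["GFAP"] = nest.copy()
        stroma_region = (np.array([0.0, ysplit, 0.0]), extent.copy())
    elif params.gfap_mode == "protoplasmic":
        gr = rngs[_STREAM_GFAP]
        n_astro = max(3, int(np.prod(extent) / 6e4))
        pts = _place_points(gr, n_astro, extent, min_dist=15.0, margin=8.0,
                            forbidden=vessel, voxel=voxel)
        gmask = np.zeros(shape, bool)
        for p in pts:
            _add_blob(channels["GFAP"], p, sigma=4.0, amplitude=I0, voxel=voxel)
            _sphere_mask(gmask, p, 8.0, voxel)
        ideal["GFAP"] = gmask

    # --- nuclei ------------------------------------------------------------
    dapi_mask = np.zeros(shape, bool)
    nuc_sigma = params.nucleus_diameter / 4.0
    nuclei = np.zeros((0, 3))
    if params.n_nuclei:
        nuclei = _place_points(
            rngs[_STREAM_NUCLEI], params.n_nuclei, extent,
            min_dist=params.nucleus_diameter, margin=params.nucleus_diameter,
            forbidden=vessel, voxel=voxel,
        )
        for p in nuclei:
            _add_blob(channels["DAPI"], p, nuc_sigma, I0, voxel)
            _sphere_mask(dapi_mask, p, params.nucleus_diameter / 2, voxel)

    # --- T cells at requested distances from the endothelium ---------------
    tcells: list[dict] = []
    cd3_mask = np.zeros(shape, bool)
    if params.tcell_distances:
        if not cd31.any():
            raise ValueError("tcell_distances given but the CD31 mask is empty")
        edt = ndimage.distance_transform_edt(~cd31, sampling=voxel)
        tol = max(voxel) / 2
        rt = rngs[_STREAM_TCELLS]
        placed: list[np.ndarray] = []
        margin = params.tcell_diameter
        for d in params.tcell_distances:
            cand = np.argwhere(np.abs(edt - d) <= tol)
            cand = cand[np.all((cand * voxel >= margin)
                               & (cand * voxel <= extent - margin), axis=1)]
            if placed is not None and len(placed):
                keep = np.ones(len(cand), bool)
                for q in placed:
                    keep &= np.sum((cand * voxel - q) ** 2, axis=1) >= (2 * margin) ** 2
                cand = cand[keep]
            if not len(cand):
                raise ValueError(
                    f"requested T-cell distance {d} µm is unreachable inside the extent"
                )
            # prefer candidates closest to the requested distance
            err = np.abs(edt[tuple(cand.T)] - d)
            best = cand[err <= err.min() + 1e-9]
            p = best[rt.integers(len(best))] * voxel
            placed.append(p)
            true_d = float(edt[tuple(np.round(p / voxel).astype(int))])
            tcells.append({"centroid": p.tolist(), "true_distance": true_d})
            _add_soft_sphere(channels["CD3"], p, params.tcell_diameter / 2, I0, voxel)
            _add_blob(channels["DAPI"], p, nuc_sigma, I0, voxel)
            _sphere_mask(cd3_mask, p, params.tcell_diameter / 2, voxel)
            _sphere_mask(dapi_mask, p, params.nucleus_diameter / 2, voxel)

    # --- myeloid cells with mixture MHCII ----------------------------------
    myeloid: list[dict] = []
    iba_mask = np.zeros(shape, bool)
    if params.myeloid_spec and params.myeloid_spec.n_cells:
        ms = params.myeloid_spec
        rm = rngs[_STREAM_MYELOID]
        pts = _place_points(
            rm, ms.n_cells, extent, min_dist=ms.cell_diameter,
            margin=ms.cell_diameter, forbidden=vessel, voxel=voxel,
            region=stroma_region,
        )
        comp = rm.random(ms.n_cells) < ms.mhc2_mix.weight_high
        mhc = np.where(
            comp,
            rm.normal(ms.mhc2_mix.mean_high, ms.mhc2_mix.sd_high, ms.n_cells),
            rm.normal(ms.mhc2_mix.mean_low, ms.mhc2_mix.sd_low, ms.n_cells),
        )
        mhc = np.clip(mhc, 0.0, None)
        r_cell = ms.cell_diameter / 2
        for p, hi_flag, m in zip(pts, comp, mhc):
            _add_soft_sphere(channels["IBA1"], p, r_cell, I0, voxel)
            _add_soft_sphere(channels["MHCII"], p, r_cell, float(m), voxel)
            _add_blob(channels["DAPI"], p, nuc_sigma, I0, voxel)
            _sphere_mask(iba_mask, p, ms.cell_diameter / 2, voxel)
            _sphere_mask(dapi_mask, p, params.nucleus_diameter / 2, voxel)
            myeloid.append({
                "centroid": p.tolist(),
                "mhc2_intensity": float(m),
                "component": "high" if hi_flag else "low",
            })

    ideal["DAPI"] = dapi_mask
    ideal["CD3"] = cd3_mask
    ideal["IBA1"] = iba_mask

    va, vb = int(coliv.sum()), int(cd31.sum())
    vab = int((coliv & cd31).sum())
    overlap = {
        "fraction_coliv": vab / va if va else 0.0,
        "fraction_cd31": vab / vb if vb else 0.0,
        "fraction_union": vab / (va + vb - vab) if (va + vb - vab) else 0.0,
    }

    volume = MultiChannelVolume(channels=channels, voxel_size=tuple(voxel))
    gt = GroundTruth(
        tree=tree, ideal_masks=ideal, nuclei=nuclei, tcells=tcells,
        myeloid=myeloid,
        gap_fraction_true=(n_gapped / n_patches if n_patches else 0.0),
        n_patches=n_patches, n_gapped=n_gapped, overlap=overlap,
        niche_nest=niche_nest, niche_stroma=niche_stroma,
    )
    return volume, gt


def apply_optics(
    volume: MultiChannelVolume,
    psf_sigmas: float | Sequence[float],
    noise: tuple[float, float],
    seed: int,
) -> MultiChannelVolume:
    """Blur with a Gaussian PSF and corrupt with Poisson-scaled plus additive
    Gaussian noise.

    psf_sigmas: scalar or (z, y, x) σ in µm (0 disables blur).
    noise: ``(poisson_scale, gaussian_sd)`` — intensities are scaled by
    ``poisson_scale`` (expected photon count per intensity unit 1), Poisson
    sampled, rescaled, then Gaussian read noise of the given sd is added.
    Output is clipped to be non-negative.
    """
    sig = np.broadcast_to(np.asarray(psf_sigmas, float), (3,)).copy()
    pscale, gsd = (float(v) for v in noise)
    if np.any(sig < 0) or pscale < 0 or gsd < 0:
        raise ValueError("PSF sigmas and noise parameters must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(7)[6])
    voxel = np.asarray(volume.voxel_size)
    out = {}
    for name in volume.channel_names:
        ch = volume[name].astype(np.float32)
        if np.any(sig > 0):
            ch = ndimage.gaussian_filter(ch, sigma=sig / voxel)
        if pscale > 0:
            ch = rng.poisson(np.clip(ch, 0, None) * pscale).astype(np.float32) / pscale
        if gsd > 0:
            ch = ch + rng.normal(0.0, gsd, ch.shape).astype(np.float32)
        if pscale > 0 or gsd > 0:
            np.clip(ch, 0.0, None, out=ch)
        out[name] = ch
    return MultiChannelVolume(channels=out, voxel_size=volume.voxel_size)
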