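"""Multichannel volume container and TIFF / table I/O.

The package-wide conventions live here: arrays are indexed ``(c, z, y, x)``
with 0-based voxel indices, physical coordinates are voxel-center positions
in micrometres, and ``voxel_size`` is ordered ``(z, y, x)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: canonical channel vocabulary (stain combinations used throughout)
KNOWN_CHANNELS = ("DAPI", "GFAP", "COLIV", "CD31", "IBA1", "MHCII", "CD3")

CSV_SCHEMA_VERSION = "1"


@dataclass
class MultiChannelVolume:
    """A named stack of co-registered 3D intensity grids.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"COLIV"``) to a 3D array of shape
        ``(z, y, x)``. All channels must share one shape.
    voxel_size
        Physical voxel spacing ``(z, y, x)`` in micrometres; all components
        must be positive.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    dtype: np.dtype = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("volume must contain at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z, y, x), got shape {shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.dtype is None:
            self.dtype = next(iter(self.channels.values())).dtype

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the grid in µm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"volume lacks required channel(s) {missing}; has {list(self.channels)}")

    def stack(self) -> np.ndarray:
        """Channels stacked into a (c, z, y, x) array."""
        return np.stack([self.channels[n] for n in self.channel_names])


def write_volume(volume: MultiChannelVolume, path: str | Path) -> Path:
    """Write a volume to OME-TIFF with voxel size in the metadata.

    Lossless for the array dtype; axes are stored as CZYX.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    vz, vy, vx = volume.voxel_size
    data = volume.stack()
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(volume.channel_names)},
        },
    )
    return path


def _voxel_size_from_ome(xml: str | None) -> tuple[float, float, float] | None:
    if not xml:
        return None
    try:
        meta = tifffile.xml2dict(xml)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        return (
            float(pixels["PhysicalSizeZ"]),
            float(pixels["PhysicalSizeY"]),
            float(pixels["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_volume(
    path: str | Path,
    channel_names: Sequence[str],
    voxel_size: tuple[float, float, float] | None = None,
) -> MultiChannelVolume:
    """Read a TIFF / OME-TIFF stack into a :class:`MultiChannelVolume`.

    Axes are normalized to (c, z, y, x). The voxel size is taken from the
    OME metadata; an explicit ``voxel_size`` override wins and is logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_vs = _voxel_size_from_ome(tif.ome_metadata)

    if data.ndim == 3:  # single-channel stack
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret array of shape {data.shape} as (c, z, y, x)")
    # OME CZYX may round-trip as ZCYX depending on writer; disambiguate by channel count
    if data.shape[0] != len(channel_names) and data.shape[1] == len(channel_names):
        data = np.swapaxes(data, 0, 1)
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"channel count mismatch: file has {data.shape[0]} channels, "
            f"caller named {len(channel_names)}: {list(channel_names)}"
        )

    if voxel_size is not None:
        if meta_vs is not None and tuple(voxel_size) != meta_vs:
            logger.info("voxel size override %s replaces metadata %s", voxel_size, meta_vs)
        vs = tuple(float(v) for v in voxel_size)
    elif meta_vs is not None:
        vs = meta_vs
    else:
        raise ValueError(f"{path} carries no voxel size metadata and no override was given")

    channels = {name: np.ascontiguousarray(data[i]) for i, name in enumerate(channel_names)}
    return MultiChannelVolume(channels=channels, voxel_size=vs)


def export_stats(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    *,
    allow_empty: bool = False,
    columns: Sequence[str] | None = None,
    comments: Mapping[str, str] | None = None,
) -> Path:
    """Export measurement records to CSV, one row per measured object.

    Column order is stable (insertion order of the first record unless
    ``columns`` is given); units are part of the column names (``um2``,
    ``um3``, ``um``). A schema-version comment is written as the first line
    and validated by :func:`read_stats`.
    """
    path = Path(path)
    records = list(records)
    if not records and not allow_empty:
        raise ValueError("no records to export (pass allow_empty=True for a header-only CSV)")
    if columns is None:
        columns = list(records[0].keys()) if records else []
    df = pd.DataFrame.from_records(records, columns=list(columns))
    with open(path, "w", newline="") as fh:
        fh.write(f"# gliovasc-csv-schema={CSV_SCHEMA_VERSION}\n")
        for key, value in (comments or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def read_stats(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_stats`, validating the schema tag."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# gliovasc-csv-schema="):
            raise ValueError(f"{path} is not a gliovasc stats CSV (missing schema line)")
        version = first.strip().split("=", 1)[1]
        if version != CSV_SCHEMA_VERSION:
            raise ValueError(f"unsupported stats CSV schema {version!r}")
        return pd.read_csv(fh, comment="#")


def write_json(obj: object, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, no timestamps)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o: object):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
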