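"""Reading and writing movies, label volumes, tables, and run configs.

On-disk movie layout is fixed to ``(t, c, z, y, x)`` (OME ``TCZYX``), stored
as OME-TIFF or Zarr with voxel-size and frame-interval metadata. All tables
are plain CSV; duration columns carry an explicit ``_min`` suffix and
positions are in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
import zarr

from .config import RunConfig, SimulationConfig

log = logging.getLogger(__name__)

__all__ = [
    "VolumeFrame",
    "Movie",
    "read_movie",
    "write_movie",
    "read_labels",
    "write_labels",
    "write_tables",
    "read_table",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class VolumeFrame:
    """One 3D intensity grid for one channel at one time point."""

    intensities: np.ndarray  # (z, y, x), non-negative
    voxel_size_um: Tuple[float, float, float]  # (dx, dy, dz)
    channel: int
    frame: int
    time_s: float

    def __post_init__(self):
        if self.intensities.ndim != 3:
            raise ValueError("VolumeFrame expects a 3D grid")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size_zyx(self) -> Tuple[float, float, float]:
        dx, dy, dz = self.voxel_size_um
        return (dz, dy, dx)

    @property
    def axial_extent_um(self) -> float:
        return self.intensities.shape[0] * self.voxel_size_um[2]


@dataclass
class Movie:
    """In-memory movie: data shaped (t, c, z, y, x) plus physical metadata."""

    data: np.ndarray
    voxel_size_um: Tuple[float, float, float]  # (dx, dy, dz)
    frame_interval_s: float

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("movie data must be (t, c, z, y, x)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int, channel: int) -> VolumeFrame:
        return VolumeFrame(
            intensities=self.data[t, channel],
            voxel_size_um=self.voxel_size_um,
            channel=channel,
            frame=t,
            time_s=t * self.frame_interval_s,
        )

    def frames(self, channel: int):
        """Ordered VolumeFrame sequence for one channel."""
        return [self.frame(t, channel) for t in range(self.n_frames)]

    def swap_channels(self, mapping: Mapping[str, int]) -> "Movie":
        """Reorder channels so index 0 = mapping['tf'], 1 = mapping['ms2']."""
        order = [mapping["tf"], mapping["ms2"]]
        return Movie(self.data[:, order], self.voxel_size_um, self.frame_interval_s)


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as OME-TIFF (``.tif``/``.tiff``) or Zarr (``.zarr``)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        dx, dy, dz = movie.voxel_size_um
        tifffile.imwrite(
            path,
            movie.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "TCZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeY": dy,
                "PhysicalSizeZ": dz,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZUnit": "µm",
                "TimeIncrement": movie.frame_interval_s,
                "TimeIncrementUnit": "s",
            },
        )
    elif path.suffix == ".zarr":
        group = zarr.open_group(str(path), mode="w")
        arr = group.create_array(
            "data", shape=movie.data.shape, dtype=movie.data.dtype
        )
        arr[:] = movie.data
        group.attrs["axes"] = "TCZYX"
        group.attrs["voxel_size_um"] = list(movie.voxel_size_um)
        group.attrs["frame_interval_s"] = movie.frame_interval_s
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")
    return path


def read_movie(
    path: str | Path,
    voxel_size_um: Optional[Tuple[float, float, float]] = None,
    frame_interval_s: Optional[float] = None,
) -> Movie:
    """Read an OME-TIFF or Zarr movie into ``(t, c, z, y, x)`` order.

    Voxel size is taken from file metadata; a ``voxel_size_um`` argument is
    used as a fallback only. If neither source provides it, this is a hard
    error — every downstream metric is in physical units.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            meta_vs, meta_dt = _ome_physical_sizes(tf)
        data = _to_tczyx(data, axes)
    elif path.suffix == ".zarr":
        group = zarr.open_group(str(path), mode="r")
        data = np.asarray(group["data"])
        attrs = dict(group.attrs)
        vs = attrs.get("voxel_size_um")
        meta_vs = tuple(vs) if vs else None
        meta_dt = attrs.get("frame_interval_s")
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")

    vs = meta_vs or voxel_size_um
    if vs is None:
        raise ValueError(
            f"{path}: voxel size missing from both metadata and config; "
            "physical-unit metrics would be wrong"
        )
    dt = meta_dt or frame_interval_s or 0.0
    return Movie(data=data, voxel_size_um=tuple(vs), frame_interval_s=float(dt))


def _ome_physical_sizes(tf: tifffile.TiffFile):
    vs = None
    dt = None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None:
            x = px.get("PhysicalSizeX")
            y = px.get("PhysicalSizeY")
            z = px.get("PhysicalSizeZ")
            if x and y and z:
                vs = (float(x), float(y), float(z))
            ti = px.get("TimeIncrement")
            if ti:
                dt = float(ti)
    except Exception:  # noqa: BLE001 - metadata is best-effort
        pass
    return vs, dt


def _to_tczyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand a tifffile series into TCZYX."""
    axes = axes.upper()
    for missing in "TCZ":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "TCZYX"]
    return np.transpose(data, order)


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label volume/series as TIFF or Zarr."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, labels.astype(np.int32))
    elif path.suffix == ".zarr":
        group = zarr.open_group(str(path), mode="w")
        arr = group.create_array("labels", shape=labels.shape, dtype=np.int32)
        arr[:] = labels.astype(np.int32)
    else:
        raise ValueError(f"unsupported label format: {path.suffix}")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    if path.suffix == ".zarr":
        return np.asarray(zarr.open_group(str(path), mode="r")["labels"])
    raise ValueError(f"unsupported label format: {path.suffix}")


# ---------------------------------------------------------------------------
# tables and configs
# ---------------------------------------------------------------------------


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> Dict[str, Path]:
    """Write one CSV per record kind. Empty frames become header-only files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, frame in tables.items():
        p = out_dir / f"{kind}.csv"
        # %.17g preserves float64 values exactly across the round trip
        frame.to_csv(p, index=False, float_format="%.17g")
        paths[kind] = p
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Turn a list of dataclass records into a DataFrame (empty-safe)."""
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def save_config(config, path: str | Path) -> Path:
    """Serialize a pydantic config (RunConfig or SimulationConfig) to
    YAML or JSON based on suffix; the seed travels with the config."""
    path = Path(path)
    payload = config.model_dump(mode="json")
    payload["__config_type__"] = type(config).__name__
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    return path


def load_config(path: str | Path):
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
    elif path.suffix == ".json":
        payload = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    kind = payload.pop("__config_type__", "RunConfig")
    cls = {"RunConfig": RunConfig, "SimulationConfig": SimulationConfig}[kind]
    return cls.model_validate(payload)
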