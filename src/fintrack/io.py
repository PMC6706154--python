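"""Dataset ingest and session persistence.

Confocal time-lapse experiments arrive as directories of single-plane
greyscale TIFFs organised by channel (BF brightfield, RED 561 nm probe,
GREEN 488 nm macrophage reporter), acquisition position, time frame and
z-section.  This module standardises them into in-memory ``TimeLapse``
containers, converts frame indices to minutes post injury (MPI), and
round-trips user inputs (imaging metadata, algorithm parameters, ROIs)
through human-readable YAML session files.

Conventions: frame labels in file names are 1-based (``T0001`` is frame
index 0); all in-memory indices are 0-based.  Pixel coordinates are
0-based with x rightward, y downward, z by stack index.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
import yaml

log = logging.getLogger("fintrack")

SESSION_SCHEMA_VERSION = "1"

#: metadata fields a session file must carry
_METADATA_FIELDS = (
    "mpi_start", "sampling", "lateral_res", "z_spacing",
    "bpp", "n_z", "n_frames", "channels",
)


class LayoutError(ValueError):
    """Dataset directory does not match the expected layout."""


class FormatError(ValueError):
    """Image file content contradicts the declared metadata."""


class SessionError(ValueError):
    """Session file is missing, incomplete or of an unknown schema."""


@dataclass(frozen=True)
class ImagingMetadata:
    """Per-experiment acquisition constants.

    Parameters
    ----------
    mpi_start:
        Minutes post injury of frame 0 (min).
    sampling:
        Minutes per time frame (min/frame).
    lateral_res:
        Microns per pixel in x and y (μm/px).
    z_spacing:
        Microns between z-sections (μm).
    bpp:
        Bits per pixel of the stored TIFFs (8 or 16).
    n_z:
        Number of z-sections per time frame.
    n_frames:
        Number of time frames.
    channels:
        Ordered channel labels, e.g. ``("BF", "RED", "GREEN")``.
    """

    mpi_start: float = 25.0
    sampling: float = 1.0
    lateral_res: float = 1.64
    z_spacing: float = 10.0
    bpp: int = 16
    n_z: int = 7
    n_frames: int = 90
    channels: tuple[str, ...] = ("BF", "RED", "GREEN")

    def __post_init__(self) -> None:
        if self.sampling <= 0:
            raise ValueError("sampling must be > 0")
        if self.lateral_res <= 0:
            raise ValueError("lateral_res must be > 0")
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        if self.bpp not in (8, 16):
            raise ValueError(f"bpp must be 8 or 16, got {self.bpp}")
        if self.n_z < 1 or self.n_frames < 1:
            raise ValueError("n_z and n_frames must be >= 1")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def intensity_max(self) -> int:
        return 2 ** self.bpp - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bpp == 8 else np.uint16)

    def to_dict(self) -> dict:
        return {
            "mpi_start": float(self.mpi_start),
            "sampling": float(self.sampling),
            "lateral_res": float(self.lateral_res),
            "z_spacing": float(self.z_spacing),
            "bpp": int(self.bpp),
            "n_z": int(self.n_z),
            "n_frames": int(self.n_frames),
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImagingMetadata":
        missing = [f for f in _METADATA_FIELDS if f not in d]
        if missing:
            raise SessionError(f"metadata missing field(s): {', '.join(missing)}")
        return cls(
            mpi_start=float(d["mpi_start"]), sampling=float(d["sampling"]),
            lateral_res=float(d["lateral_res"]), z_spacing=float(d["z_spacing"]),
            bpp=int(d["bpp"]), n_z=int(d["n_z"]), n_frames=int(d["n_frames"]),
            channels=tuple(d["channels"]),
        )


@dataclass(frozen=True)
class DatasetLayout:
    """Binds (channel, position, frame, z) tuples to file paths.

    ``pattern`` is a Python format string over ``channel``, ``position``,
    ``frame`` (1-based label number) and ``z`` (0-based section index).
    """

    pattern: str = "{channel}/{position}/T{frame:04d}_Z{z}.tif"
    positions: tuple[str, ...] = ("P0",)
    experiment: str = "exp"

    def relpath(self, channel: str, position: str, frame_index: int, z: int) -> Path:
        return Path(self.pattern.format(
            channel=channel, position=position, frame=frame_index + 1, z=z))


@dataclass
class VolumeFrame:
    """One channel's z-stack at one time frame (z × y × x)."""

    index: int
    channel: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeFrame data must be 3-D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TimeLapse:
    """Ordered VolumeFrames of one channel plus acquisition metadata."""

    metadata: ImagingMetadata
    channel: str
    frames: list[VolumeFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, fr in enumerate(self.frames):
            if fr.index != i:
                raise ValueError(f"frame at slot {i} has index {fr.index}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> VolumeFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


@dataclass
class IngestResult:
    """Outcome of :func:`ingest_dataset`."""

    lapses: dict[str, TimeLapse]
    n_files: int
    ignored: list[str]


def frame_to_mpi(frame_index: int, metadata: ImagingMetadata) -> float:
    """Minutes post injury of a 0-based frame index."""
    if not 0 <= frame_index < metadata.n_frames:
        raise IndexError(
            f"frame_index {frame_index} out of range [0, {metadata.n_frames})")
    return metadata.mpi_start + frame_index * metadata.sampling


def mpi_to_frame(mpi: float, metadata: ImagingMetadata) -> int:
    """Nearest frame index for an MPI value; bounds-checked."""
    idx = int(round((mpi - metadata.mpi_start) / metadata.sampling))
    if not 0 <= idx < metadata.n_frames:
        raise IndexError(f"MPI {mpi} outside the imaged span")
    return idx


def _read_plane(path: Path, metadata: ImagingMetadata) -> np.ndarray:
    plane = tifffile.imread(path)
    if plane.ndim != 2:
        raise FormatError(f"{path}: expected a single-plane greyscale TIFF, "
                          f"got shape {plane.shape}")
    if plane.dtype.itemsize * 8 != metadata.bpp:
        raise FormatError(f"{path}: bit depth {plane.dtype.itemsize * 8} "
                          f"does not match metadata bpp={metadata.bpp}")
    return plane


def ingest_dataset(
    root: str | Path,
    metadata: ImagingMetadata,
    layout: DatasetLayout | None = None,
    position: str | None = None,
    strict: bool = False,
) -> IngestResult:
    """Read a TIFF time-lapse directory into one :class:`TimeLapse` per channel.

    Every (channel, frame, z) combination must resolve to exactly one file;
    missing files are enumerated in a :class:`LayoutError`, never silently
    skipped.  Unknown extra files are ignored with a logged warning (an
    error under ``strict=True``).
    """
    root = Path(root)
    layout = layout or DatasetLayout()
    position = position or layout.positions[0]

    missing: list[tuple[str, str, int]] = []
    expected: set[Path] = set()
    lapses: dict[str, TimeLapse] = {}
    n_files = 0
    shape0: tuple[int, int] | None = None

    for channel in metadata.channels:
        frames: list[VolumeFrame] = []
        for t in range(metadata.n_frames):
            planes = []
            for z in range(metadata.n_z):
                rel = layout.relpath(channel, position, t, z)
                expected.add(root / rel)
                path = root / rel
                if not path.is_file():
                    missing.append((channel, f"T{t + 1:04d}", z))
                    planes = None
                    break
                plane = _read_plane(path, metadata)
                if shape0 is None:
                    shape0 = plane.shape
                elif plane.shape != shape0:
                    raise FormatError(
                        f"{path}: plane shape {plane.shape} differs from {shape0}")
                planes.append(plane)
                n_files += 1
            if planes is not None:
                frames.append(VolumeFrame(t, channel, np.stack(planes)))
        lapses[channel] = TimeLapse(metadata, channel, frames) if not missing else None

    if missing:
        listed = "; ".join(f"({c}, {t}, z={z})" for c, t, z in missing[:20])
        raise LayoutError(f"{len(missing)} missing file(s): {listed}")

    ignored = sorted(
        str(p.relative_to(root))
        for p in root.rglob("*") if p.is_file() and p not in expected
    )
    if ignored:
        if strict:
            raise LayoutError(f"{len(ignored)} unexpected file(s): {ignored[:10]}")
        log.warning("ignoring %d unexpected file(s) under %s", len(ignored), root)

    log.info("ingested %d files from %s", n_files, root)
    return IngestResult(lapses, n_files, ignored)


def export_dataset(
    lapses: Mapping[str, TimeLapse],
    root: str | Path,
    layout: DatasetLayout | None = None,
    position: str | None = None,
) -> int:
    """Write TimeLapses back to the standardized single-plane TIFF layout.

    Returns the number of files written.  The pixel payload is written
    bit-identically, so ingest → export round-trips checksums.
    """
    root = Path(root)
    layout = layout or DatasetLayout()
    position = position or layout.positions[0]
    n = 0
    for channel, lapse in lapses.items():
        for frame in lapse:
            for z in range(frame.data.shape[0]):
                path = root / layout.relpath(channel, position, frame.index, z)
                path.parent.mkdir(parents=True, exist_ok=True)
                tifffile.imwrite(path, frame.data[z])
                n += 1
    return n


def file_checksums(root: str | Path) -> dict[str, str]:
    """md5 of every file under root, keyed by relative path (for round-trip tests)."""
    root = Path(root)
    return {
        str(p.relative_to(root)): hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*")) if p.is_file()
    }


# ---------------------------------------------------------------------------
# Session files
# ---------------------------------------------------------------------------

def save_session(session: Mapping, path: str | Path) -> Path:
    """Persist user inputs (metadata + algorithm parameters) to YAML.

    The file carries a schema version; :func:`load_session` refuses files
    from an unknown schema rather than guessing a migration.
    """
    path = Path(path)
    payload = dict(session)
    payload.setdefault("schema_version", SESSION_SCHEMA_VERSION)
    if "metadata" in payload and isinstance(payload["metadata"], ImagingMetadata):
        payload["metadata"] = payload["metadata"].to_dict()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_session(path: str | Path) -> dict:
    """Load and validate a session file; metadata is re-hydrated and checked."""
    path = Path(path)
    if not path.is_file():
        raise SessionError(f"no session file at {path}")
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict):
        raise SessionError(f"{path}: not a mapping")
    version = str(payload.get("schema_version"))
    if version != SESSION_SCHEMA_VERSION:
        raise SessionError(
            f"{path}: schema version {version!r} requires migration to "
            f"{SESSION_SCHEMA_VERSION!r}")
    if "metadata" in payload:
        payload["metadata"] = ImagingMetadata.from_dict(payload["metadata"])
    return payload
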