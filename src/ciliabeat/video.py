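"""Movie containers, frame-rate decimation, and line-ROI kymograph extraction.

This module mirrors the classic ImageJ workflow for ciliary video analysis:
a high-speed grayscale recording is loaded as a :class:`MovieStack`, a line
ROI is drawn through the beating cilia, and a "reslice" along that line at
every frame yields a :class:`Kymograph` — a position × time image in which
periodic ciliary motion appears as waves whose temporal spacing encodes the
beat frequency.

Down-sampling to a lower frame rate is pure frame decimation
(nearest-index selection), emulating what a slower camera would have
captured; no temporal averaging ("shutter blur") is applied.

Coordinates are 0-based pixel centers, x to the right, y down.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MovieStack",
    "LineROI",
    "Kymograph",
    "read_movie",
    "write_movie",
    "downsample",
    "downsample_kymograph",
    "decimation_indices",
    "extract_kymograph",
    "save_kymograph",
    "load_kymograph",
    "save_roi",
    "load_roi",
]

#: Default physical pixel size of the reference imaging setup, in µm/px.
DEFAULT_PIXEL_SIZE_UM = 0.104


@dataclass
class MovieStack:
    """A time-ordered stack of grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensities, either floats in [0, 1] or integer counts.
    fps : float
        Acquisition frame rate in frames per second.
    pixel_size : float
        Physical pixel size in µm/px.
    provenance : str
        Free text describing the source file or generator parameters.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                f"frames must be a (T, H, W) stack with T >= 1, got shape {self.frames.shape}"
            )
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Recording duration in seconds (T / fps)."""
        return self.n_frames / self.fps


@dataclass
class LineROI:
    """A polyline region of interest in pixel coordinates.

    ``vertices`` is an (N, 2) array of (x, y) pixel-center coordinates
    (N >= 2).  ``width`` is the number of perpendicular samples averaged
    at each position along the line (>= 1), mirroring ImageJ's wide line.
    """

    vertices: np.ndarray
    width: int = 1

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N >= 2, 2) array of (x, y) coordinates")
        if int(self.width) < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        self.width = int(self.width)

    def length(self) -> float:
        """Total polyline arc length in pixels."""
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    def to_dict(self) -> dict:
        return {"vertices": self.vertices.tolist(), "width": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "LineROI":
        return cls(vertices=np.asarray(d["vertices"], dtype=float), width=int(d["width"]))


@dataclass
class Kymograph:
    """Position × time intensity image extracted along a line ROI.

    ``values`` has shape (P, T): P positions along the ROI, T time frames.
    ``source_fps`` is the frame rate of the movie the columns were sampled
    from — the denominator quantity of the beat-frequency calculation.
    """

    values: np.ndarray
    source_fps: float
    roi: LineROI | None = None
    cilium_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError(
                f"values must be a (P >= 1, T >= 2) array, got shape {self.values.shape}"
            )
        if not self.source_fps > 0:
            raise ValueError(f"source_fps must be positive, got {self.source_fps}")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.source_fps


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------

def write_movie(stack: MovieStack, path: str | Path) -> Path:
    """Write a movie as a multi-page grayscale TIFF with fps metadata.

    Frames are written with their in-memory dtype, so write→read is a
    lossless round trip.  AVI output is not supported (no codec backend);
    use TIFF.
    """
    path = Path(path)
    if path.suffix.lower() == ".avi":
        raise ValueError(
            "AVI writing is not supported (no video codec backend available); "
            "write a multi-page TIFF (.tif/.tiff) instead"
        )
    meta = {
        "fps": float(stack.fps),
        "pixel_size_um": float(stack.pixel_size),
        "provenance": stack.provenance,
    }
    tifffile.imwrite(path, stack.frames, metadata=meta,
                     photometric="minisblack")
    return path


def read_movie(path: str | Path, fps: float | None = None,
               pixel_size: float | None = None) -> MovieStack:
    """Read a multi-page TIFF movie.

    ``fps`` (and optionally ``pixel_size``) override or supply values missing
    from the file metadata.  Raises a clear error when the frame rate can be
    found in neither place.
    """
    path = Path(path)
    if path.suffix.lower() == ".avi":
        raise ValueError(
            "AVI reading is not supported (no video codec backend available); "
            "convert the recording to multi-page TIFF first"
        )
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if frames.ndim == 2:
        frames = frames[None]
    file_fps = meta.get("fps")
    eff_fps = fps if fps is not None else file_fps
    if eff_fps is None:
        raise ValueError(
            f"{path}: no 'fps' metadata found and no fps override given; "
            "pass fps explicitly"
        )
    eff_px = pixel_size if pixel_size is not None else meta.get(
        "pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
    return MovieStack(frames=frames, fps=float(eff_fps), pixel_size=float(eff_px),
                      provenance=str(meta.get("provenance", str(path))))


# ---------------------------------------------------------------------------
# Frame-rate decimation
# ---------------------------------------------------------------------------

def decimation_indices(n_frames: int, fps: float, target_fps: float) -> np.ndarray:
    """Frame indices a slower camera would have captured.

    Maps output frame j to source frame round(j * fps / target_fps), for
    j = 0 .. round(target_fps * duration) - 1, clipped to the valid range.
    """
    if not 0 < target_fps <= fps:
        raise ValueError(
            f"target_fps must be in (0, {fps}] (no upsampling), got {target_fps}"
        )
    duration = n_frames / fps
    n_out = int(round(target_fps * duration))
    j = np.arange(n_out)
    idx = np.rint(j * fps / target_fps).astype(int)
    return np.minimum(idx, n_frames - 1)


def downsample(stack: MovieStack, target_fps: float) -> MovieStack:
    """Decimate a movie to a lower frame rate by nearest-index frame selection.

    No temporal averaging is performed; the result is the subset of original
    frames the slower camera would have recorded.
    """
    idx = decimation_indices(stack.n_frames, stack.fps, target_fps)
    logger.debug("downsample %s -> %s fps: indices %s", stack.fps, target_fps, idx)
    return MovieStack(
        frames=stack.frames[idx],
        fps=float(target_fps),
        pixel_size=stack.pixel_size,
        provenance=f"{stack.provenance} | decimated {stack.fps}->{target_fps} fps",
    )


def downsample_kymograph(kymo: Kymograph, target_fps: float) -> Kymograph:
    """Decimate a kymograph's time axis exactly as :func:`downsample` would
    decimate the movie it came from (the two operations commute)."""
    idx = decimation_indices(kymo.n_frames, kymo.source_fps, target_fps)
    return Kymograph(
        values=kymo.values[:, idx],
        source_fps=float(target_fps),
        roi=kymo.roi,
        cilium_id=kymo.cilium_id,
    )


# ---------------------------------------------------------------------------
# Kymograph extraction ("reslice")
# ---------------------------------------------------------------------------

def _sample_points(roi: LineROI) -> tuple[np.ndarray, np.ndarray]:
    """Positions along the polyline at ~unit-pixel spacing and their unit
    normals. Returns (points (P,2) xy, normals (P,2) xy)."""
    verts = roi.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("polyline has zero-length segments")
    total = float(seg_len.sum())
    n_samples = int(round(total)) + 1
    dist = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    seg_idx = np.clip(np.searchsorted(cum, dist, side="right") - 1, 0, len(seg) - 1)
    frac = (dist - cum[seg_idx]) / seg_len[seg_idx]
    pts = verts[seg_idx] + frac[:, None] * seg[seg_idx]
    tang = seg[seg_idx] / seg_len[seg_idx, None]
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    return pts, normals


def extract_kymograph(stack: MovieStack, roi: LineROI,
                      cilium_id: str = "") -> Kymograph:
    """Reslice a movie along a line ROI into a position × time kymograph.

    Intensity is sampled at unit-pixel spacing along the polyline by
    bilinear interpolation and averaged across ``roi.width`` samples taken
    perpendicular to the line (edge values replicated at frame borders).
    """
    T, H, W = stack.shape
    v = roi.vertices
    if np.any(v[:, 0] < 0) or np.any(v[:, 0] > W - 1) or \
       np.any(v[:, 1] < 0) or np.any(v[:, 1] > H - 1):
        raise ValueError(
            f"ROI vertices out of frame bounds (frame {W}x{H}, "
            f"x range [{v[:,0].min()}, {v[:,0].max()}], "
            f"y range [{v[:,1].min()}, {v[:,1].max()}])"
        )
    pts, normals = _sample_points(roi)
    offsets = np.arange(roi.width) - (roi.width - 1) / 2.0
    # coords: (width, P, 2) in (x, y)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    P = pts.shape[0]
    wN = roi.width
    tgrid = np.broadcast_to(np.arange(T)[:, None, None], (T, wN, P))
    ygrid = np.broadcast_to(coords[None, :, :, 1], (T, wN, P))
    xgrid = np.broadcast_to(coords[None, :, :, 0], (T, wN, P))
    frames = np.asarray(stack.frames, dtype=float)
    sampled = ndimage.map_coordinates(
        frames, [tgrid, ygrid, xgrid], order=1, mode="nearest")
    values = sampled.mean(axis=1).T  # (P, T)
    return Kymograph(values=values, source_fps=stack.fps, roi=roi,
                     cilium_id=cilium_id)


# ---------------------------------------------------------------------------
# Kymograph / ROI file formats
# ---------------------------------------------------------------------------

def save_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    """Write a kymograph image plus a JSON sidecar.

    The image is transposed to the ImageJ reslice convention (rows = frames,
    columns = positions along the line); TIFF keeps float values, PNG is
    scaled to 16-bit.  The sidecar (<path>.json) carries source_fps, ROI and
    cilium_id, and notes the orientation.
    """
    path = Path(path)
    img = np.asarray(kymo.values).T  # time down, position across
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        lo, hi = float(img.min()), float(img.max())
        scale = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        iio.imwrite(path, (scale * 65535).astype(np.uint16))
    else:
        tifffile.imwrite(path, img.astype(np.float32),
                         photometric="minisblack")
    sidecar = {
        "source_fps": float(kymo.source_fps),
        "roi": kymo.roi.to_dict() if kymo.roi is not None else None,
        "cilium_id": kymo.cilium_id,
        "orientation": "rows=time frames, columns=positions along line",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_kymograph(path: str | Path, source_fps: float | None = None) -> Kymograph:
    """Read a kymograph written by :func:`save_kymograph` (TIFF only for
    lossless values).  The JSON sidecar supplies metadata; ``source_fps``
    overrides it."""
    path = Path(path)
    img = tifffile.imread(path)
    sidecar_path = Path(str(path) + ".json")
    meta: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    fps = source_fps if source_fps is not None else meta.get("source_fps")
    if fps is None:
        raise ValueError(f"{path}: no source_fps in sidecar and no override given")
    roi = LineROI.from_dict(meta["roi"]) if meta.get("roi") else None
    return Kymograph(values=np.asarray(img, dtype=float).T, source_fps=float(fps),
                     roi=roi, cilium_id=str(meta.get("cilium_id", "")))


def save_roi(roi: LineROI, path: str | Path) -> Path:
    """Write a line ROI as a two-column x,y CSV with a width comment line."""
    path = Path(path)
    lines = [f"# width: {roi.width}", "x,y"]
    lines += [f"{x},{y}" for x, y in roi.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path


def load_roi(path: str | Path) -> LineROI:
    """Read a line ROI written by :func:`save_roi`."""
    path = Path(path)
    width = 1
    verts: list[tuple[float, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "width" in line:
                width = int(line.split(":")[1])
            continue
        if line.lower().startswith("x"):
            continue
        x, y = line.split(",")
        verts.append((float(x), float(y)))
    return LineROI(vertices=np.asarray(verts), width=width)
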