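"""Core data types and file I/O for polar IVOCT pullbacks.

A pullback is an ordered stack of 16-bit polar frames.  Rows are A-lines
(the angular axis, wrapping: row 0 is adjacent to row ``n_alines - 1``),
columns are depth samples with the catheter at column 0.  Clinical
frequency-domain OCT frames are 504 A-lines by 960 depth samples; both
dimensions are free here so that down-scaled phantoms use the same code
paths.

File formats are deliberately plain: multipage grayscale TIFF or raw
binary with a YAML sidecar for images, CSV (``frame,aline,depth,kind``)
for strut annotations and detection results, YAML for parameters.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Reference clinical frame geometry (A-lines, depth samples).
REFERENCE_SHAPE = (504, 960)

VALID_KINDS = ("bright", "non_bright", "guide_wire_removed", "outside_segment_removed")


@dataclass(frozen=True)
class StrutRecord:
    """One detected or annotated strut position.

    ``aline``/``depth`` locate the middle point of the strut's front
    (luminal) edge.  ``kind`` distinguishes regular bright-spot struts,
    recovered non-bright struts, and detections re-flagged by the
    false-positive filters (kept for auditability, excluded from strut
    counts).
    """

    frame: int
    aline: int
    depth: int
    kind: str = "bright"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown strut kind {self.kind!r}")
        if self.aline < 0 or self.depth < 0 or self.frame < 0:
            raise ValueError("strut coordinates must be non-negative")

    @property
    def active(self) -> bool:
        """True when the record still counts as a strut detection."""
        return self.kind in ("bright", "non_bright")


@dataclass(frozen=True)
class Frame:
    """A single polar frame: ``pixels[aline_row, depth_column]``."""

    pixels: np.ndarray
    frame_index: int = 0

    @property
    def n_alines(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[1]


class Pullback:
    """An ordered stack of same-shaped 16-bit polar frames.

    Internally a ``(n_frames, n_alines, n_depth)`` array.  Intensities
    must be non-negative and representable in 16 bits.
    """

    def __init__(self, stack: np.ndarray, pixel_size_mm: float | None = 0.005):
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError(f"pullback stack must be 3D, got shape {stack.shape}")
        if stack.size == 0:
            raise ValueError("pullback stack is empty")
        if np.issubdtype(stack.dtype, np.floating):
            raise TypeError("pullback intensities must be integers")
        if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
            raise ValueError("pullback intensities must fit in unsigned 16 bits")
        self.stack = stack.astype(np.uint16, copy=False)
        self.pixel_size_mm = pixel_size_mm

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def n_alines(self) -> int:
        return self.stack.shape[1]

    @property
    def n_depth(self) -> int:
        return self.stack.shape[2]

    def frame(self, index: int) -> Frame:
        return Frame(self.stack[index], frame_index=index)

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pullback):
            return NotImplemented
        return self.stack.shape == other.stack.shape and bool(
            np.array_equal(self.stack, other.stack)
        )


@dataclass
class DetectionParameters:
    """All tunables of the detection pipeline.

    The pixel-valued defaults are calibrated for the reference clinical
    geometry (504 A-lines x 960 depth samples); :meth:`scaled_for`
    rescales them for other frame sizes.

    Attributes
    ----------
    noise_percentile:
        Fraction of the global pullback histogram treated as noise;
        pixels below the corresponding order statistic are zeroed.
    shadow_intensity_percentile:
        Percentile of the ROI histogram defining the maximum intensity a
        shadow pixel may have.
    sliding_shadow_size:
        Length (depth pixels) of the window of continuously-low pixels
        that qualifies as a trailing shadow.
    slope_threshold:
        Peak-to-shadow intensity slope (intensity units per depth pixel,
        negative) at or below which an A-line peak becomes a candidate.
    gaussian_sigma:
        Smoothing scale (pixels) before shadow-edge detection.
    edge_length_threshold:
        Minimum depth extent (pixels) of an accepted shadow edge.
    edge_response_threshold:
        Absolute compass-response threshold; ``None`` means Otsu on the
        positive responses of each frame.
    edge_contrast_ratio:
        Minimum bright-side/dark-side mean-intensity ratio across an
        accepted shadow edge (the dark side must really be a shadow).
    clustering_distance_threshold:
        Candidates closer than this (wrap-aware Euclidean pixels) merge
        into one cluster.
    guide_wire_distance_threshold:
        Maximum frame-to-frame displacement (pixels) of a guide-wire
        track.
    acceptance_distance:
        Matching tolerance (pixels) between detections and reference
        positions; also used when flagging detections on the guide-wire
        track.
    line_row_fraction, line_search_fraction:
        Catheter-artifact detector: a depth column of the z-minimum
        image is a "line" when at least ``line_row_fraction`` of its
        rows exceed the noise floor; only the leftmost
        ``line_search_fraction`` of columns are searched.
    non_bright_depth_back, non_bright_depth_forward:
        Depth window (pixels before/after the shadow-edge start
        columns) searched when recovering a non-bright strut.
    min_non_bright_pixels:
        Minimum supra-threshold pixels for a non-bright strut.
    min_track_fraction:
        Fraction of frames a chained track must cover to be accepted as
        the guide wire.
    segment_min_count, segment_smooth_window:
        Stented-segment detector: frames whose moving-averaged strut
        count reaches ``segment_min_count`` belong to the segment.
    """

    noise_percentile: float = 0.05
    shadow_intensity_percentile: float = 0.89
    sliding_shadow_size: int = 30
    slope_threshold: float = -48.0
    gaussian_sigma: float = 1.5
    edge_length_threshold: int = 100
    edge_response_threshold: float | None = None
    edge_contrast_ratio: float = 2.0
    clustering_distance_threshold: float = 4.0
    guide_wire_distance_threshold: float = 40.0
    acceptance_distance: float = 10.0
    line_row_fraction: float = 0.95
    line_search_fraction: float = 0.25
    non_bright_depth_back: int = 10
    non_bright_depth_forward: int = 30
    min_non_bright_pixels: int = 2
    min_track_fraction: float = 0.8
    segment_min_count: float = 3.0
    segment_smooth_window: int = 5
    pixel_size_mm: float = 0.005

    def __post_init__(self) -> None:
        for name in ("noise_percentile", "shadow_intensity_percentile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.slope_threshold >= 0:
            raise ValueError("slope_threshold must be negative")
        for name in (
            "sliding_shadow_size",
            "edge_length_threshold",
            "clustering_distance_threshold",
            "guide_wire_distance_threshold",
            "acceptance_distance",
            "gaussian_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **changes) -> "DetectionParameters":
        return dataclasses.replace(self, **changes)

    def scaled_for(self, n_alines: int, n_depth: int) -> "DetectionParameters":
        """Rescale pixel-valued parameters for a non-reference frame size.

        Depth-axis windows (sliding shadow, edge length, non-bright
        search) scale with the depth-sample ratio; the slope threshold
        scales inversely (the same intensity drop happens over fewer
        pixels).  Isotropic distances (guide wire, acceptance) scale
        with the mean of both axis ratios.  The clustering threshold is
        left alone: candidate pixels of one strut sit on consecutive
        A-lines at any sampling, so their spacing does not shrink with
        the frame.
        """
        ref_alines, ref_depth = REFERENCE_SHAPE
        sd = n_depth / ref_depth
        si = 0.5 * (n_alines / ref_alines + n_depth / ref_depth)
        if abs(sd - 1.0) < 1e-9 and abs(si - 1.0) < 1e-9:
            return self.replace()
        return self.replace(
            sliding_shadow_size=max(2, round(self.sliding_shadow_size * sd)),
            edge_length_threshold=max(4, round(self.edge_length_threshold * sd)),
            slope_threshold=self.slope_threshold / sd,
            guide_wire_distance_threshold=max(
                2.0, round(self.guide_wire_distance_threshold * si)
            ),
            acceptance_distance=max(2.0, round(self.acceptance_distance * si)),
            non_bright_depth_back=max(2, round(self.non_bright_depth_back * sd)),
            non_bright_depth_forward=max(3, round(self.non_bright_depth_forward * sd)),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "DetectionParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Pullback I/O
# ---------------------------------------------------------------------------

def read_pullback(path: str | os.PathLike, fmt: str | None = None) -> Pullback:
    """Read a polar pullback from TIFF or raw binary + YAML sidecar.

    ``fmt`` is ``"tiff_stack"`` or ``"raw_binary_with_sidecar"``; when
    ``None`` it is inferred from the extension (``.tif``/``.tiff`` vs
    anything else with a ``<path>.yaml`` sidecar).  Pixel values are
    preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "tiff_stack" if path.suffix.lower() in (".tif", ".tiff") else "raw_binary_with_sidecar"
    if fmt == "tiff_stack":
        stack = tifffile.imread(path)
        if stack.ndim == 2:  # single-page stack
            stack = stack[None]
        return Pullback(stack)
    if fmt == "raw_binary_with_sidecar":
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw binary sidecar not found: {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        shape = (int(meta["n_frames"]), int(meta["n_alines"]), int(meta["n_depth"]))
        dtype = np.dtype(meta.get("dtype", "uint16"))
        if dtype.itemsize != 2 or dtype.kind != "u":
            raise ValueError(
                f"raw pullbacks must be unsigned 16-bit, sidecar says {dtype}"
            )
        dtype = dtype.newbyteorder(
            "<" if meta.get("byte_order", "little") == "little" else ">"
        )
        data = np.fromfile(path, dtype=dtype)
        expected = shape[0] * shape[1] * shape[2]
        if data.size != expected:
            raise ValueError(
                f"raw file holds {data.size} values but sidecar shape {shape} "
                f"needs {expected}"
            )
        return Pullback(data.reshape(shape).astype(np.uint16))
    raise ValueError(f"unknown pullback format {fmt!r}")


def write_pullback(pullback: Pullback, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a pullback as multipage TIFF or raw binary + sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = "tiff_stack" if path.suffix.lower() in (".tif", ".tiff") else "raw_binary_with_sidecar"
    if fmt == "tiff_stack":
        tifffile.imwrite(path, pullback.stack, photometric="minisblack")
        return
    if fmt == "raw_binary_with_sidecar":
        pullback.stack.astype("<u2").tofile(path)
        meta = {
            "n_frames": pullback.n_frames,
            "n_alines": pullback.n_alines,
            "n_depth": pullback.n_depth,
            "dtype": "uint16",
            "byte_order": "little",
        }
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        return
    raise ValueError(f"unknown pullback format {fmt!r}")


# ---------------------------------------------------------------------------
# Annotation / detection I/O
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | os.PathLike, shape: tuple[int, int] | None = None
) -> list[StrutRecord]:
    """Read strut records from a CSV with columns ``frame,aline,depth[,kind]``.

    ``shape`` optionally validates coordinates against ``(n_alines,
    n_depth)``.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path)
    required = {"frame", "aline", "depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if df[list(required)].isna().any().any():
        raise ValueError(f"{path}: malformed rows with missing coordinates")
    records = []
    for row in df.itertuples(index=False):
        rec = StrutRecord(
            frame=int(row.frame),
            aline=int(row.aline),
            depth=int(row.depth),
            kind=str(getattr(row, "kind", "bright")),
        )
        if shape is not None:
            n_alines, n_depth = shape
            if not (0 <= rec.aline < n_alines and 0 <= rec.depth < n_depth):
                raise ValueError(
                    f"{path}: record {rec} outside frame shape {shape}"
                )
        records.append(rec)
    return records


def write_detections(records: Sequence[StrutRecord], path: str | os.PathLike) -> None:
    """Write strut records as CSV, sorted by (frame, aline, depth)."""
    ordered = sorted(records, key=lambda r: (r.frame, r.aline, r.depth, r.kind))
    df = pd.DataFrame(
        [(r.frame, r.aline, r.depth, r.kind) for r in ordered],
        columns=["frame", "aline", "depth", "kind"],
    )
    df.to_csv(path, index=False)


def wrap_row_delta(r1: float, r2: float, n_alines: int) -> float:
    """Wrap-aware angular row difference: min(|d|, n - |d|)."""
    d = abs(r1 - r2) % n_alines
    return min(d, n_alines - d)


def wrap_distance(
    a: tuple[float, float], b: tuple[float, float], n_alines: int
) -> float:
    """Euclidean pixel distance with wrap-aware row component.

    Points are ``(aline_row, depth_column)``.
    """
    dr = wrap_row_delta(a[0], b[0], n_alines)
    return math.hypot(dr, a[1] - b[1])
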