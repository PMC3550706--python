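"""Synthetic polar IVOCT phantoms with known strut ground truth.

The generator emulates the image structure the detector relies on, at a
desk-scale geometry (default 64 frames x 128 A-lines x 256 depth
samples, scaled down from the clinical 504 x 960):

* speckled vessel tissue starting at a per-row lumen radius, decaying
  exponentially with depth; the lumen varies along the pullback and
  around the circumference so that no tissue column is frame-constant;
* struts as bright blobs with full-depth trailing shadows; status
  variants: apposed (on the lumen boundary), covered (under a thin
  neointimal layer), malapposed (detached, in front of the lumen), and
  non-bright (deep under thick tissue, too dim for the slope test but
  above the shadow-intensity threshold);
* an optional guide wire: bright, closer to the catheter than any
  strut, drifting slowly and continuously across frames;
* catheter ring artifacts as frame-constant bright vertical lines at
  the low-depth side;
* empty (non-stented) frames before and after the stented range.

Speckle is multiplicative gamma noise (mean 1, shape from the requested
coefficient of variation), the standard stand-in for coherent-imaging
speckle; the background is additive exponential noise.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from octstrut.pullback_io import Pullback, StrutRecord

#: Depth offsets (pixels, relative to the local lumen radius) and blob
#: brightness by strut status at the default desk-scale geometry.
STATUS_DEPTH_OFFSET = {
    "apposed": 0,
    "covered": 6,
    "malapposed": -10,
    "non_bright": 25,
}
STATUS_BRIGHTNESS = {
    "apposed": 12000.0,
    "covered": 8000.0,
    "malapposed": 12000.0,
    "non_bright": 1100.0,
}


@dataclass(frozen=True)
class StrutSpec:
    """One strut: an A-line band over a frame range with a status."""

    frame_lo: int
    frame_hi: int  # inclusive
    aline: int
    status: str = "apposed"
    brightness: float | None = None
    width_alines: int = 5
    thickness_px: int = 3
    depth_offset: int | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUS_DEPTH_OFFSET:
            raise ValueError(f"unknown strut status {self.status!r}")
        if self.frame_hi < self.frame_lo:
            raise ValueError("frame_hi must be >= frame_lo")

    @property
    def offset(self) -> int:
        return self.depth_offset if self.depth_offset is not None else STATUS_DEPTH_OFFSET[self.status]

    @property
    def intensity(self) -> float:
        return self.brightness if self.brightness is not None else STATUS_BRIGHTNESS[self.status]


@dataclass(frozen=True)
class GuideWireSpec:
    start_aline: float = 6.0
    drift_per_frame: float = 0.15
    depth: int = 18
    brightness: float = 15000.0
    width_alines: int = 3
    thickness_px: int = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic pullback."""

    n_frames: int = 64
    n_alines: int = 128
    n_depth: int = 256
    lumen_radius_px: float = 60.0
    lumen_z_amplitude: float = 18.0
    lumen_ecc_amplitude: float = 7.0
    tissue_peak_intensity: float = 1200.0
    attenuation_per_px: float = 0.015
    speckle_cv: float = 0.3
    strut_layout: tuple[StrutSpec, ...] = ()
    guide_wire: GuideWireSpec | None = None
    catheter_artifact_columns: tuple[int, ...] = (8, 9, 14)
    catheter_artifact_intensity: float = 3000.0
    non_stented_margins: tuple[int, int] = (8, 8)
    noise_floor_level: float = 25.0
    shadow_floor_factor: float = 0.03
    allow_overlap: bool = False
    seed: int = 0

    def lumen_radius(self, frame: int, rows: np.ndarray) -> np.ndarray:
        """Per-row lumen radius of one frame (pixels from the catheter)."""
        z = self.lumen_z_amplitude * math.sin(2.0 * math.pi * frame / max(1, self.n_frames))
        ecc = self.lumen_ecc_amplitude * np.sin(
            2.0 * math.pi * rows / self.n_alines + 0.13 * frame
        )
        return self.lumen_radius_px + z + ecc


class GuideWireTruth(NamedTuple):
    entries: dict[int, tuple[int, int]]  # frame -> (aline, depth)


def _strut_rows(aline: int, width: int, n_alines: int) -> list[int]:
    half = width // 2
    return [(aline + k) % n_alines for k in range(-half, width - half)]


def generate_pullback(
    spec: PhantomSpec,
) -> tuple[Pullback, list[StrutRecord], GuideWireTruth | None]:
    """Render the phantom; returns (pullback, strut truth, guide-wire truth).

    Deterministic for a fixed ``spec.seed``.  Raises when two struts (or
    a strut and the guide wire) occupy the same A-line in one frame,
    which would violate the single-strut-per-A-line assumption, unless
    ``spec.allow_overlap`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    n_f, n_a, n_d = spec.n_frames, spec.n_alines, spec.n_depth
    rows = np.arange(n_a)
    cols = np.arange(n_d)
    stack = np.zeros((n_f, n_a, n_d), dtype=np.uint16)
    truth: list[StrutRecord] = []
    gw_entries: dict[int, tuple[int, int]] = {}

    cv = spec.speckle_cv
    gamma_shape = 1.0 / (cv * cv) if cv > 0 else None

    for f in range(n_f):
        radius = spec.lumen_radius(f, rows)
        depth_from_lumen = cols[None, :] - radius[:, None]
        img = np.where(
            depth_from_lumen >= 0,
            spec.tissue_peak_intensity
            * np.exp(-spec.attenuation_per_px * np.maximum(depth_from_lumen, 0.0)),
            0.0,
        )

        occupied: dict[int, str] = {}

        def claim(row_list: list[int], label: str) -> None:
            for r in row_list:
                if r in occupied and not spec.allow_overlap:
                    raise ValueError(
                        f"frame {f}: A-line {r} holds both {occupied[r]} and "
                        f"{label}; one strut per A-line is assumed"
                    )
                occupied[r] = label

        # blobs applied after shadows so a blob is never shadowed by itself
        blobs: list[tuple[list[int], int, int, float]] = []

        for s_idx, s in enumerate(spec.strut_layout):
            if not (s.frame_lo <= f <= s.frame_hi):
                continue
            s_rows = _strut_rows(s.aline, s.width_alines, n_a)
            claim(s_rows, f"strut{s_idx}")
            center_front = int(round(radius[s.aline] + s.offset))
            for r in s_rows:
                front = int(round(radius[r] + s.offset))
                front = max(0, min(n_d - 1, front))
                back = min(n_d, front + s.thickness_px)
                img[r, back:] *= spec.shadow_floor_factor
                blobs.append(([r], front, back, s.intensity))
            truth.append(
                StrutRecord(frame=f, aline=s.aline, depth=min(n_d - 1, center_front))
            )

        if spec.guide_wire is not None:
            gw = spec.guide_wire
            gw_row = int(round(gw.start_aline + gw.drift_per_frame * f)) % n_a
            g_rows = _strut_rows(gw_row, gw.width_alines, n_a)
            claim(g_rows, "guide_wire")
            front = gw.depth
            back = min(n_d, front + gw.thickness_px)
            for r in g_rows:
                img[r, back:] *= spec.shadow_floor_factor
                blobs.append(([r], front, back, gw.brightness))
            gw_entries[f] = (gw_row, front)

        for b_rows, front, back, brightness in blobs:
            for r in b_rows:
                taper = 1.0 - 0.25 * np.arange(back - front)
                img[r, front:back] = np.maximum(img[r, front:back], brightness * taper)

        if gamma_shape is not None:
            img *= rng.gamma(gamma_shape, 1.0 / gamma_shape, size=img.shape)
        img += rng.exponential(spec.noise_floor_level, size=img.shape)

        for c in spec.catheter_artifact_columns:
            if 0 <= c < n_d:
                img[:, c] = spec.catheter_artifact_intensity

        stack[f] = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    gw_truth = GuideWireTruth(entries=gw_entries) if gw_entries else None
    return Pullback(stack), truth, gw_truth


def default_strut_layout(
    spec_frames: int = 64,
    margins: tuple[int, int] = (8, 8),
    n_struts: int = 8,
    first_aline: int = 24,
    spacing: int = 13,
    status: str = "apposed",
    brightness: float | None = None,
) -> tuple[StrutSpec, ...]:
    """A ring of evenly spaced struts over the stented frame range."""
    lo, hi = margins[0], spec_frames - margins[1] - 1
    return tuple(
        StrutSpec(
            frame_lo=lo,
            frame_hi=hi,
            aline=first_aline + spacing * k,
            status=status,
            brightness=brightness,
        )
        for k in range(n_struts)
    )


class SuiteEntry(NamedTuple):
    spec: PhantomSpec
    expects: dict


def standard_phantom_suite(seed: int = 0) -> dict[str, SuiteEntry]:
    """Canned phantom scenarios mirroring the validation categories.

    Covers the strut-status categories (apposed, covered, malapposed,
    non-bright) and an image-quality contrast (the low-quality spec has
    3x the speckle and dimmer struts), plus guide-wire present/absent
    variants for the false-positive filter contracts.
    """
    base = PhantomSpec(seed=seed, guide_wire=GuideWireSpec())
    layout = lambda status, brightness=None: default_strut_layout(  # noqa: E731
        base.n_frames, base.non_stented_margins, status=status, brightness=brightness
    )
    suite = {
        "high_quality_apposed": SuiteEntry(
            replace(base, strut_layout=layout("apposed")),
            {"has_guide_wire": True, "struts_per_frame": 8},
        ),
        "covered": SuiteEntry(
            replace(base, strut_layout=layout("covered"), seed=seed + 1),
            {"has_guide_wire": True, "struts_per_frame": 8},
        ),
        "malapposed": SuiteEntry(
            replace(base, strut_layout=layout("malapposed"), seed=seed + 2),
            {"has_guide_wire": True, "struts_per_frame": 8},
        ),
        "low_quality": SuiteEntry(
            replace(
                base,
                strut_layout=layout("apposed", brightness=7000.0),
                speckle_cv=0.9,
                seed=seed + 3,
            ),
            {"has_guide_wire": True, "struts_per_frame": 8, "low_quality": True},
        ),
        "non_bright": SuiteEntry(
            replace(
                base,
                strut_layout=default_strut_layout(status="apposed")[:6]
                + tuple(
                    replace(s, status="non_bright", brightness=None)
                    for s in default_strut_layout(status="non_bright")[6:]
                ),
                seed=seed + 4,
            ),
            {"has_guide_wire": True, "struts_per_frame": 8, "non_bright_struts": 2},
        ),
        "guide_wire_free": SuiteEntry(
            replace(base, strut_layout=layout("apposed"), guide_wire=None, seed=seed + 5),
            {"has_guide_wire": False, "struts_per_frame": 8},
        ),
    }
    return suite
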