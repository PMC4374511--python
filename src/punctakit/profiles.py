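"""Line-scan intensity profiles and their extraction from micrographs.

A "line scan" is the 1D fluorescence trace sampled along a traced neuronal
cord. Quantification downstream (punctum calling, enrichment) operates only
on this representation, so this module defines the profile container, the
polyline trace, and the image-to-profile conversion.

Conventions used throughout the package:

* pixel coordinates are 0-based with ``x`` = column and ``y`` = row,
  measured at pixel centers;
* interpolation is bilinear;
* the profile is sampled at arc-length steps of one pixel, so the position
  spacing in µm equals the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["Polyline", "IntensityProfile", "extract_profile", "mask_regions"]


@dataclass(frozen=True)
class Polyline:
    """An ordered open polygonal trace in pixel coordinates.

    ``vertices`` is an ``(n, 2)`` float array of ``(x, y)`` pairs with
    ``x`` = column, ``y`` = row. At least two vertices are required and
    consecutive vertices must be distinct.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("polyline needs an (n >= 2, 2) array of (x, y) vertices")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive polyline vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.vertices, axis=0).T)

    @property
    def length_px(self) -> float:
        """Total arc length in pixels."""
        return float(self.segment_lengths.sum())

    def point_at(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Points and unit tangents at arc-length positions ``s`` (pixels).

        Tangents are the direction of the segment each position falls on;
        positions exactly at an interior vertex take the following segment.
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        seg_len = self.segment_lengths
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        v = self.vertices
        d = v[idx + 1] - v[idx]
        pts = v[idx] + frac[:, None] * d
        tangents = d / seg_len[idx][:, None]
        return pts, tangents

    def bounds_ok(self, shape: tuple[int, int]) -> bool:
        rows, cols = shape
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return bool(
            (x >= 0).all() and (x <= cols - 1).all() and (y >= 0).all() and (y <= rows - 1).all()
        )


@dataclass
class IntensityProfile:
    """A calibrated 1D fluorescence trace along a cord.

    positions_um
        Strictly increasing, uniformly spaced arc-length coordinates (µm).
    intensities
        Fluorescence in arbitrary units.
    pixel_size_um
        Physical size of one pixel (µm); equals the position spacing.
    exclude_mask
        True where a sample is excluded from quantification (cell bodies,
        out-of-bounds samples, other artifacts).
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float
    exclude_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != inten.shape or pos.size == 0:
            raise ValueError("positions and intensities must be equal-length 1D arrays")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if pos.size > 1:
            d = np.diff(pos)
            if np.any(d <= 0):
                raise ValueError("positions must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError("positions must be uniformly spaced")
        if self.exclude_mask is None:
            mask = np.zeros(pos.size, dtype=bool)
        else:
            mask = np.asarray(self.exclude_mask, dtype=bool)
            if mask.shape != pos.shape:
                raise ValueError("exclude_mask length must match positions")
        self.positions_um = pos
        self.intensities = inten
        self.exclude_mask = mask

    def __len__(self) -> int:
        return self.positions_um.size

    @property
    def spacing_um(self) -> float:
        if len(self) > 1:
            return float(self.positions_um[1] - self.positions_um[0])
        return self.pixel_size_um

    @property
    def span_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])


def extract_profile(
    image: np.ndarray,
    trace: Polyline,
    pixel_size_um: float,
    half_width_px: int = 2,
    aggregate: str = "max",
) -> IntensityProfile:
    """Sample a 2D image along a trace into a calibrated line-scan profile.

    The trace is sampled at arc-length steps of one pixel. At each sample the
    reported intensity aggregates ``2 * half_width_px + 1`` bilinear samples
    taken along the local perpendicular; the default aggregate is the
    maximum, which is robust to sub-pixel tracing error on thin cords
    (``aggregate="mean"`` is available). Perpendicular samples falling
    outside the image are ignored by the aggregate; samples with *no*
    in-bounds contribution are flagged in ``exclude_mask`` rather than
    dropped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a single-plane 2D grayscale array")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if half_width_px < 0:
        raise ValueError("half_width_px must be >= 0")
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    if not trace.bounds_ok(img.shape):
        raise ValueError("trace vertices fall outside the image bounds")

    n = int(np.floor(trace.length_px)) + 1
    s = np.arange(n, dtype=float)
    pts, tangents = trace.point_at(s)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(-half_width_px, half_width_px + 1, dtype=float)

    # (n_offsets, n_samples, 2) sample coordinates in (x, y)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows, cols = coords[..., 1], coords[..., 0]
    inb = (rows >= 0) & (rows <= img.shape[0] - 1) & (cols >= 0) & (cols <= img.shape[1] - 1)
    values = map_coordinates(img, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    values = values.reshape(rows.shape)
    values = np.where(inb, values, np.nan)

    with np.errstate(all="ignore"):
        if aggregate == "max":
            inten = np.nanmax(values, axis=0)
        else:
            inten = np.nanmean(values, axis=0)
    excluded = ~inb.any(axis=0)
    inten = np.where(excluded, 0.0, inten)

    return IntensityProfile(
        positions_um=s * pixel_size_um,
        intensities=inten,
        pixel_size_um=pixel_size_um,
        exclude_mask=excluded,
    )


def mask_regions(
    profile: IntensityProfile, intervals_um: list[tuple[float, float]]
) -> IntensityProfile:
    """Return a copy with ``exclude_mask`` set on the union of intervals.

    Intervals are ``(start, end)`` in µm, inclusive of samples whose center
    falls inside. Masked samples are excluded from peak detection and from
    all PF/IPF sums downstream. An inverted interval (start >= end) is
    rejected.
    """
    mask = profile.exclude_mask.copy()
    pos = profile.positions_um
    for start, end in intervals_um:
        if start >= end:
            raise ValueError(f"inverted interval ({start}, {end}): start must be < end")
        mask |= (pos >= start) & (pos <= end)
    return replace(profile, exclude_mask=mask)
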