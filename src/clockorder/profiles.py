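"""Axial intensity profiles and their quantification from images.

The measurement model follows standard practice for quantifying fluorescent
wave patterns in the pre-somitic mesoderm (PSM): a rectangular region of
interest is placed with its axes parallel to the rostro-caudal and
medial-lateral axes, the image is background-subtracted and thresholded at
the level of a no-primary-antibody control, intensity is averaged across the
medial-lateral extent at each rostro-caudal pixel, and the axial coordinate
is rescaled so that the caudal-most point of the PSM sits at 0 with one unit
equal to the length of the last-formed somite pair.  Profiles are finally
min-max normalized onto [0, 1] so that samples of different brightness can be
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateProfileError,
    InvalidGridError,
    NoOverlapError,
    RoiError,
    TooFewSamplesError,
)

__all__ = [
    "AxialProfile",
    "SampleSet",
    "RoiSpec",
    "BackgroundModel",
    "extract_axial_profile",
    "minmax_normalize",
    "resample_to_grid",
]


def _check_grid(positions: np.ndarray) -> None:
    if positions.ndim != 1 or positions.size < 2:
        raise InvalidGridError("axial grid needs at least 2 positions")
    if not np.all(np.diff(positions) > 0):
        raise InvalidGridError("axial grid must be strictly increasing")


@dataclass(frozen=True)
class AxialProfile:
    """One sample's intensity as a function of rostro-caudal position.

    Positions are in somite-pair unit lengths with 0 at the caudal origin,
    increasing rostrally.  ``raw`` is True until min-max normalization has
    mapped the intensities onto [0, 1].
    """

    sample_id: str
    positions: np.ndarray
    intensities: np.ndarray
    raw: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        _check_grid(self.positions)
        if self.positions.shape != self.intensities.shape:
            raise InvalidGridError("positions and intensities must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidGridError("intensities must be finite")

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class SampleSet:
    """N profiles resampled onto a shared M-point axial grid.

    ``matrix`` is N x M: one row per sample, one column per axial position.
    This is the unordered input to time ordering; row order carries no
    temporal meaning until an ordering has been inferred.
    """

    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if m.ndim != 2:
            raise InvalidGridError("matrix must be 2-D (samples x positions)")
        n, width = m.shape
        if n < 3:
            raise TooFewSamplesError(
                f"need at least 3 samples for autocorrelation-based ordering, got {n}"
            )
        if width < 4:
            raise InvalidGridError(f"need at least 4 axial positions, got {width}")
        if len(self.sample_ids) != n:
            raise InvalidGridError("sample_ids length must match matrix rows")
        if len(set(self.sample_ids)) != n:
            raise InvalidGridError("sample_ids must be unique")
        _check_grid(self.positions)
        if self.positions.size != width:
            raise InvalidGridError("positions length must match matrix columns")
        if not np.all(np.isfinite(m)):
            raise InvalidGridError("matrix entries must be finite")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]

    def profiles(self) -> list[AxialProfile]:
        """Split the matrix back into per-sample profiles."""
        return [
            AxialProfile(sid, self.positions.copy(), row.copy())
            for sid, row in zip(self.sample_ids, self.matrix)
        ]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular quantification region in image pixel coordinates.

    ``row_range``/``col_range`` are half-open pixel index ranges (like numpy
    slices).  ``axis_orientation`` says which rectangle axis runs
    rostro-caudally: ``"cols"`` means columns are axial positions and rows
    span the medial-lateral extent, ``"rows"`` the transpose.
    ``caudal_origin_px`` is the pixel index, along the rostro-caudal axis, of
    the caudal-most point of the PSM; ``somite_unit_px`` is the last-formed
    somite-pair length in pixels.
    """

    row_range: tuple[int, int]
    col_range: tuple[int, int]
    caudal_origin_px: float
    somite_unit_px: float
    axis_orientation: str = "cols"

    def __post_init__(self) -> None:
        if self.somite_unit_px <= 0:
            raise RoiError("somite_unit_px must be positive")
        if self.row_range[1] <= self.row_range[0] or self.col_range[1] <= self.col_range[0]:
            raise RoiError("ROI rectangle is degenerate")
        if self.axis_orientation not in ("rows", "cols"):
            raise RoiError("axis_orientation must be 'rows' or 'cols'")


@dataclass(frozen=True)
class BackgroundModel:
    """Background subtraction plus no-primary-control thresholding."""

    background_value: float = 0.0
    control_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.background_value < 0 or self.control_threshold < 0:
            raise RoiError("background_value and control_threshold must be >= 0")


def extract_axial_profile(
    image: np.ndarray, roi: RoiSpec, bg: BackgroundModel, sample_id: str = "sample"
) -> AxialProfile:
    """Quantify a grayscale image into a raw axial intensity profile.

    Pipeline: crop to ROI, subtract ``background_value`` (floored at 0), zero
    pixels below ``control_threshold``, average medial-laterally, rescale the
    axial coordinate to somite-pair units with the caudal origin at 0.  The
    result is *not* min-max normalized (``raw=True``); apply
    :func:`minmax_normalize` afterwards.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise RoiError("image must be a 2-D grayscale array")
    (r0, r1), (c0, c1) = roi.row_range, roi.col_range
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        raise RoiError(
            f"ROI rows {roi.row_range} cols {roi.col_range} outside image {img.shape}"
        )
    crop = img[r0:r1, c0:c1]

    crop = np.clip(crop - bg.background_value, 0.0, None)
    crop = np.where(crop < bg.control_threshold, 0.0, crop)

    axial_axis = 1 if roi.axis_orientation == "cols" else 0
    profile = crop.mean(axis=1 - axial_axis)

    start = roi.col_range[0] if roi.axis_orientation == "cols" else roi.row_range[0]
    px = start + np.arange(profile.size, dtype=float)  # pixel centres along RC axis
    positions_px = px - roi.caudal_origin_px
    # Caudal origin must sit at 0 with positions increasing rostrally; if the
    # origin lies at the high-index end of the ROI, flip the axis.
    if positions_px.mean() < 0:
        positions_px = -positions_px[::-1]
        profile = profile[::-1]
    positions = positions_px / roi.somite_unit_px
    return AxialProfile(sample_id, positions, profile, raw=True)


def minmax_normalize(profile: AxialProfile) -> AxialProfile:
    """Affinely map a profile's intensities onto [0, 1].

    Raises :class:`DegenerateProfileError` for constant profiles, which carry
    no wave information and would otherwise divide by zero.  Idempotent on
    already-normalized profiles.
    """
    y = profile.intensities
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise DegenerateProfileError(
            f"profile {profile.sample_id!r} is constant ({lo}); cannot normalize"
        )
    return replace(profile, intensities=(y - lo) / (hi - lo), raw=False)


def resample_to_grid(profiles: Sequence[AxialProfile], n_positions: int) -> SampleSet:
    """Linearly interpolate profiles onto a shared equally spaced grid.

    The grid spans the intersection of all axial ranges with ``n_positions``
    points.  Linear interpolation is exact on piecewise-linear data and avoids
    ringing on pulse edges.
    """
    profiles = list(profiles)
    if len(profiles) < 3:
        raise TooFewSamplesError("need at least 3 profiles")
    if n_positions < 4:
        raise InvalidGridError("n_positions must be >= 4")
    lo = max(float(p.positions[0]) for p in profiles)
    hi = min(float(p.positions[-1]) for p in profiles)
    if hi <= lo:
        raise NoOverlapError("profiles share no common axial interval")
    grid = np.linspace(lo, hi, n_positions)
    matrix = np.vstack([np.interp(grid, p.positions, p.intensities) for p in profiles])
    return SampleSet(matrix, tuple(p.sample_id for p in profiles), grid)
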