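"""Eye-camera image chain: raw frame → calibrated → filtered → pupil → gaze.

The chain turns one grayscale camera frame into a gaze angle:

1. *Calibration* removes head shift (integer-pixel registration against a
   reference frame by normalized cross-correlation) and uneven illumination
   (subtraction of an additive per-pixel background surface).
2. *Median filtering* suppresses impulse noise before segmentation.
3. *Eye detection* thresholds the dark pupil against the bright sclera,
   keeps the largest connected component, and takes a darkness-weighted
   centroid as the pupil centre.
4. A fitted affine *gaze calibration* maps pupil-centre pixel offsets to
   (azimuth, elevation) degrees.

A registration shift that hits the search boundary, or a pupil mask whose
area is implausible, marks the frame invalid — downstream these become
blink samples, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "EyeFrame",
    "FilterParams",
    "CalibrationModel",
    "GazeCalibration",
    "FrameInvalidError",
    "NoEyeError",
    "calibrate_frame",
    "median_filter",
    "detect_eye",
    "pupil_to_gaze",
    "fit_gaze_calibration",
    "read_frame",
    "write_frame",
]


class FrameInvalidError(ValueError):
    """Head movement exceeded the registration search range."""


class NoEyeError(ValueError):
    """No plausible pupil found (blink, eyelid closure, or no eye in frame)."""


@dataclass(frozen=True)
class EyeFrame:
    """One grayscale camera frame with intensities in [0, 1]."""

    pixels: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("frame must be a 2-D intensity grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame intensities must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class FilterParams:
    """Median-filter mask dimensions (rows × cols); both must be odd."""

    mask_rows: int = 3
    mask_cols: int = 3

    def __post_init__(self) -> None:
        for d in (self.mask_rows, self.mask_cols):
            if d < 1 or d % 2 == 0:
                raise ValueError("mask dimensions must be odd and >= 1")


@dataclass(frozen=True)
class CalibrationModel:
    """Reference frame + additive illumination surface + shift search radius."""

    reference_frame: EyeFrame
    illumination_surface: np.ndarray
    max_shift: int = 5

    def __post_init__(self) -> None:
        surf = np.asarray(self.illumination_surface, dtype=float)
        if surf.shape != self.reference_frame.pixels.shape:
            raise ValueError("illumination surface must match reference dimensions")
        object.__setattr__(self, "illumination_surface", surf)


@dataclass(frozen=True)
class GazeCalibration:
    """Affine pixel-offset → gaze-angle map: angle = A @ offset + b (degrees).

    Offsets are (col, row) pixel displacements of the pupil centre from the
    straight-ahead reference pixel; the reference offset (0, 0) maps to
    gaze (0, 0) up to the fitted intercept.
    """

    linear: np.ndarray  # 2x2
    offset: np.ndarray  # 2
    residual_deg: float

    def __post_init__(self) -> None:
        A = np.asarray(self.linear, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("gaze calibration must be invertible")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "offset", b)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_shift(
    frame: np.ndarray, reference: np.ndarray, max_shift: int
) -> tuple[int, int]:
    """Integer (row, col) translation of ``frame`` relative to ``reference``.

    Exhaustive normalized cross-correlation over the (2·max_shift+1)² shift
    grid, scored on the overlapping region only.  Ties break toward the
    smaller shift magnitude (scan order from the centre outward).
    """
    shifts = sorted(
        (
            (dr, dc)
            for dr in range(-max_shift, max_shift + 1)
            for dc in range(-max_shift, max_shift + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    best, best_score = (0, 0), -np.inf
    h, w = reference.shape
    for dr, dc in shifts:
        r0, r1 = max(0, dr), min(h, h + dr)
        c0, c1 = max(0, dc), min(w, w + dc)
        if r1 - r0 < 2 or c1 - c0 < 2:
            continue
        score = _ncc(frame[r0:r1, c0:c1], reference[r0 - dr:r1 - dr, c0 - dc:c1 - dc])
        if score > best_score + 1e-12:
            best, best_score = (dr, dc), score
    return best


def calibrate_frame(
    f: EyeFrame, m: CalibrationModel
) -> tuple[EyeFrame, tuple[int, int]]:
    """Return the calibrated frame L_C and the estimated head shift.

    The frame is registered to the reference (integer shift maximizing
    normalized cross-correlation within ±max_shift), shifted back, the
    illumination surface subtracted, and the result clipped to [0, 1].
    Raises :class:`FrameInvalidError` if the best shift sits on the search
    boundary — head movement too large for reliable registration.
    """
    if f.pixels.shape != m.reference_frame.pixels.shape:
        raise ValueError("frame and reference dimensions differ")
    dr, dc = estimate_shift(f.pixels, m.reference_frame.pixels, m.max_shift)
    if max(abs(dr), abs(dc)) >= m.max_shift:
        raise FrameInvalidError(
            f"estimated shift {(dr, dc)} at the ±{m.max_shift} px search boundary"
        )
    # undo the head shift, filling exposed borders by edge replication
    registered = ndimage.shift(f.pixels, (-dr, -dc), order=0, mode="nearest")
    out = np.clip(registered - m.illumination_surface, 0.0, 1.0)
    return EyeFrame(out, timestamp=f.timestamp), (dr, dc)


def build_calibration_model(
    reference_frames: list[EyeFrame], max_shift: int = 5
) -> CalibrationModel:
    """Calibration model from reference frames spanning several gaze angles.

    The illumination surface is the per-pixel median of the references
    minus its global median.  With the pupil at a different position in
    each reference the per-pixel median rejects it, leaving only the
    background (sclera + shading); subtracting the global median keeps the
    surface zero-mean so calibrated frames stay on the [0, 1] scale.  With
    a single reference frame the pupil leaks into the surface — supply at
    least three frames at distinct gaze angles.
    """
    stack = np.stack([f.pixels for f in reference_frames])
    background = np.median(stack, axis=0)
    surface = background - np.median(background)
    return CalibrationModel(reference_frames[0], surface, max_shift=max_shift)


def median_filter(f: EyeFrame, p: FilterParams = FilterParams()) -> EyeFrame:
    """Median-filter a frame with an M×N mask; borders by edge replication."""
    out = ndimage.median_filter(
        f.pixels, size=(p.mask_rows, p.mask_cols), mode="nearest"
    )
    return EyeFrame(out, timestamp=f.timestamp)


def detect_eye(
    f: EyeFrame,
    threshold: float = 0.5,
    min_area_frac: float = 1e-4,
    max_area_frac: float = 0.25,
) -> tuple[tuple[float, float], np.ndarray]:
    """Segment the dark pupil; return its (row, col) centre and the mask L_E.

    Pixels darker than ``threshold × frame mean`` form candidate eye pixels;
    only the largest connected component is kept.  The centre is the
    darkness-weighted centroid of that component.  A mask whose area falls
    outside the configured fraction bounds raises :class:`NoEyeError`
    (treated downstream as a blink).
    """
    px = f.pixels
    cut = threshold * px.mean()
    mask = px < cut
    if not mask.any():
        raise NoEyeError("no pixels below the pupil threshold")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(px), labels, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    area = mask.sum()
    if not min_area_frac * px.size <= area <= max_area_frac * px.size:
        raise NoEyeError(f"pupil candidate area {area} px outside plausible bounds")
    weights = np.where(mask, 1.0 - px, 0.0)
    total = weights.sum()
    rows, cols = np.indices(px.shape)
    centre = (
        float((weights * rows).sum() / total),
        float((weights * cols).sum() / total),
    )
    return centre, mask


def fit_gaze_calibration(
    pairs: list[tuple[tuple[float, float], tuple[float, float]]]
) -> GazeCalibration:
    """Least-squares affine fit from (pixel offset, known angle) pairs.

    Offsets are (col, row) pupil displacements from the reference pixel;
    angles are (azimuth, elevation) in degrees.  Needs ≥ 3 non-collinear
    offsets; the RMS angular residual of the fit is reported.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 calibration points")
    X = np.array([[p[0][0], p[0][1], 1.0] for p in pairs])
    Y = np.array([p[1] for p in pairs], dtype=float)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("calibration points are collinear or degenerate")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    A = coef[:2].T  # 2x2 linear part
    b = coef[2]
    pred = X @ coef
    residual = float(np.sqrt(np.mean(np.sum((pred - Y) ** 2, axis=1))))
    return GazeCalibration(linear=A, offset=b, residual_deg=residual)


def pupil_to_gaze(
    centre_offset: tuple[float, float], gc: GazeCalibration
) -> tuple[float, float]:
    """(azimuth, elevation) degrees for a pupil-centre (col, row) pixel offset."""
    v = gc.linear @ np.asarray(centre_offset, dtype=float) + gc.offset
    return float(v[0]), float(v[1])


def frame_to_gaze(
    f: EyeFrame,
    m: CalibrationModel,
    gc: GazeCalibration,
    reference_centre: tuple[float, float],
    params: FilterParams = FilterParams(),
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Full chain for one frame: calibrate → median filter → pupil → gaze.

    ``reference_centre`` is the (row, col) pupil centre of the calibrated
    straight-ahead frame.  Raises :class:`FrameInvalidError` or
    :class:`NoEyeError` when the frame cannot be used (treated as a blink
    sample at the trace level).
    """
    calibrated, _ = calibrate_frame(f, m)
    filtered = median_filter(calibrated, params)
    (row, col), _ = detect_eye(filtered, threshold=threshold)
    offset = (col - reference_centre[1], row - reference_centre[0])
    return pupil_to_gaze(offset, gc)


def read_frame(path, timestamp: float = 0.0) -> EyeFrame:
    """Read an 8-bit grayscale PGM/PNG frame, scaled to [0, 1]."""
    img = Image.open(path).convert("L")
    return EyeFrame(np.asarray(img, dtype=float) / 255.0, timestamp=timestamp)


def write_frame(f: EyeFrame, path) -> None:
    """Write a frame as 8-bit grayscale (format chosen by file extension)."""
    img = Image.fromarray(np.round(f.pixels * 255.0).astype(np.uint8), mode="L")
    img.save(path)
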