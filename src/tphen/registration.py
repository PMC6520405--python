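"""Serial-section co-registration.

Differently stained serial sections are first normalised to a common
single-channel representation (minimum intensity projection over RGB followed
by inversion, so stained tissue is bright on a dark background), then aligned
with a rigid transform (translation + optional rotation) found by exhaustive
search maximising the normalised cross-correlation (NCC). The fitted transform
is exposed through a regular grid of corresponding landmarks so the interface
stays compatible with richer, locally deforming registration schemes.

Only a single connected tissue piece is assumed; the multi-part correspondence
problem and deformable refinement are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi



class FlatImageError(ValueError):
    """Raised when an image is constant and NCC is undefined."""


def normalize_stain(rgb: np.ndarray) -> np.ndarray:
    """Stain-agnostic normalisation of an RGB image.

    Per pixel the result is ``255 - min(R, G, B)``: white background maps to
    0 and any chromogen (brown DAB, red Fast Red, haematoxylin blue) maps to
    a high value, making sections with different stains comparable.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {rgb.shape}")
    return (255 - rgb.astype(np.int16).min(axis=2)).astype(np.uint8)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalised cross-correlation of two equal-shaped images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have equal shape")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise FlatImageError("NCC undefined for a constant image")
    return float((a * b).sum() / denom)


@dataclass
class RigidSearch:
    """Search space for :func:`rigid_register`.

    ``max_shift`` bounds |dx| and |dy| in pixels (None = unbounded);
    ``rotations_deg`` is the grid of candidate rotations. ``downsample`` > 1
    runs the exhaustive search on decimated images first and refines the
    translation at full resolution within ±2·downsample pixels; whole-slide
    images typically use 16, small tiles 1.
    """

    max_shift: int | None = None
    rotations_deg: tuple[float, ...] = (0.0,)
    downsample: int = 1
    grid_spacing: int = 512


@dataclass
class TransformGrid:
    """Rigid transform plus a regular landmark grid.

    ``forward`` maps moving-image coordinates into the fixed image:
    ``q = R(p - c) + c + t`` with ``c`` the moving-image centre and ``t``
    = (dx, dy). Landmarks are forward images of a regular grid over the
    moving frame, so the rigid parameters reproduce them exactly.
    """

    dx: float = 0.0
    dy: float = 0.0
    rotation_deg: float = 0.0
    image_shape: tuple[int, int] = (0, 0)
    grid_spacing: int = 512
    ncc_value: float = float("nan")
    landmarks_src: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    landmarks_dst: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        if self.landmarks_src is None or len(np.atleast_2d(self.landmarks_src)) == 0:
            self._build_landmarks()

    @property
    def center(self) -> np.ndarray:
        h, w = self.image_shape
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    def _rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def _build_landmarks(self) -> None:
        h, w = self.image_shape
        if h == 0 or w == 0:
            self.landmarks_src = np.zeros((0, 2))
            self.landmarks_dst = np.zeros((0, 2))
            return
        xs = np.arange(0, w, self.grid_spacing, dtype=float)
        ys = np.arange(0, h, self.grid_spacing, dtype=float)
        gx, gy = np.meshgrid(xs, ys)
        src = np.column_stack([gx.ravel(), gy.ravel()])
        self.landmarks_src = src
        self.landmarks_dst = self.transform_points(src)

    def transform_points(self, points: np.ndarray, direction: str = "forward") -> np.ndarray:
        """Apply the rigid map to an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = self.center
        t = np.array([self.dx, self.dy])
        r = self._rotation_matrix()
        if direction == "forward":
            return (pts - c) @ r.T + c + t
        if direction == "inverse":
            return (pts - c - t) @ r + c
        raise ValueError("direction must be 'forward' or 'inverse'")

    def to_json(self) -> str:
        return json.dumps(
            {
                "dx": self.dx,
                "dy": self.dy,
                "rotation_deg": self.rotation_deg,
                "image_shape": list(self.image_shape),
                "grid_spacing": self.grid_spacing,
                "ncc_value": self.ncc_value,
                "landmarks_src": np.asarray(self.landmarks_src).tolist(),
                "landmarks_dst": np.asarray(self.landmarks_dst).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransformGrid":
        d = json.loads(text)
        return cls(
            dx=d["dx"],
            dy=d["dy"],
            rotation_deg=d["rotation_deg"],
            image_shape=tuple(d["image_shape"]),
            grid_spacing=d["grid_spacing"],
            ncc_value=d.get("ncc_value", float("nan")),
            landmarks_src=np.asarray(d["landmarks_src"], dtype=float),
            landmarks_dst=np.asarray(d["landmarks_dst"], dtype=float),
        )


def apply_transform(
    obj: np.ndarray,
    grid: TransformGrid,
    direction: str = "forward",
    *,
    points: bool | None = None,
    out_shape: tuple[int, int] | None = None,
):
    """Apply a :class:`TransformGrid` to points or a mask.

    Points: returns ``(transformed_points, inside)`` where ``inside`` flags
    points landing within ``grid.image_shape`` — out-of-frame points are
    flagged, never dropped. Masks are resampled with nearest-neighbour
    gathering (every output pixel looks up its pre-image), so rotations leave
    no holes.
    """
    arr = np.asarray(obj)
    if points is None:
        points = arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype != bool
    if points:
        pts = grid.transform_points(arr, direction)
        h, w = grid.image_shape
        inside = (
            (pts[:, 0] >= -0.5) & (pts[:, 0] < w - 0.5) & (pts[:, 1] >= -0.5) & (pts[:, 1] < h - 0.5)
        )
        return pts, inside
    # mask / label raster
    shape = out_shape or arr.shape
    yy, xx = np.indices(shape)
    out_pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    inv = "inverse" if direction == "forward" else "forward"
    src = grid.transform_points(out_pts, inv)
    xs = np.rint(src[:, 0]).astype(int)
    ys = np.rint(src[:, 1]).astype(int)
    valid = (xs >= 0) & (xs < arr.shape[1]) & (ys >= 0) & (ys < arr.shape[0])
    out = np.zeros(shape, dtype=arr.dtype)
    flat = out.ravel()
    flat[valid] = arr[ys[valid], xs[valid]]
    return flat.reshape(shape)


def _overlap_ncc(fixed: np.ndarray, moving: np.ndarray, dx: int, dy: int) -> float:
    """ZNCC of the region where ``moving`` shifted by (dx, dy) overlaps ``fixed``."""
    h, w = fixed.shape
    fy0, fy1 = max(0, dy), h + min(0, dy)
    fx0, fx1 = max(0, dx), w + min(0, dx)
    if fy1 - fy0 < 8 or fx1 - fx0 < 8:
        return -np.inf
    a = fixed[fy0:fy1, fx0:fx1]
    b = moving[fy0 - dy : fy1 - dy, fx0 - dx : fx1 - dx]
    try:
        return ncc(a, b)
    except FlatImageError:
        return -np.inf


def _best_shift(fixed: np.ndarray, moving: np.ndarray, max_shift: int | None):
    """Integer translation maximising overlap NCC.

    A global FFT phase-correlation pass (with real-space disambiguation)
    proposes the shift; the final answer is the exact overlap-NCC optimum
    within a small window around that proposal, so the reported score is the
    true normalised cross-correlation of the overlapping tissue.
    """
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        fixed.astype(float), moving.astype(float), disambiguate=True, normalization=None
    )
    dy0, dx0 = int(round(shift[0])), int(round(shift[1]))
    if max_shift is not None:
        dy0 = int(np.clip(dy0, -max_shift, max_shift))
        dx0 = int(np.clip(dx0, -max_shift, max_shift))
    best = None
    for dy in range(dy0 - 3, dy0 + 4):
        for dx in range(dx0 - 3, dx0 + 4):
            if max_shift is not None and (abs(dx) > max_shift or abs(dy) > max_shift):
                continue
            score = _overlap_ncc(fixed, moving, dx, dy)
            if best is None or score > best[2]:
                best = (dx, dy, score)
    if best is None or not np.isfinite(best[2]):
        best = (dx0, dy0, _overlap_ncc(fixed, moving, dx0, dy0))
    return best


def _rotate_about_center(img: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0:
        return np.asarray(img, dtype=float)
    return ndi.rotate(np.asarray(img, dtype=float), angle_deg, reshape=False, order=1, mode="constant")


def rigid_register(
    moving: np.ndarray, fixed: np.ndarray, search: RigidSearch | None = None
) -> TransformGrid:
    """Find the rigid transform aligning ``moving`` onto ``fixed``.

    Exhaustive search: for each candidate rotation the moving image is rotated
    about its centre and the best integer translation is found by normalised
    cross-correlation; the (rotation, translation) pair with the highest NCC
    wins. Images must be single-channel (use :func:`normalize_stain` first)
    and non-constant.
    """
    search = search or RigidSearch()
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.ndim != 2 or fix.ndim != 2:
        raise ValueError("rigid_register expects single-channel images")
    if mov.std() == 0 or fix.std() == 0:
        raise FlatImageError("cannot register a constant image")

    f = max(1, int(search.downsample))
    mov_c, fix_c = (mov[::f, ::f], fix[::f, ::f]) if f > 1 else (mov, fix)
    coarse_max = None if search.max_shift is None else max(1, search.max_shift // f)

    best = None  # (ncc, angle, dx, dy)
    for angle in search.rotations_deg:
        rot = _rotate_about_center(mov_c, angle)
        if rot.std() == 0:
            continue
        dx, dy, score = _best_shift(fix_c, rot, coarse_max)
        if best is None or score > best[0]:
            best = (score, angle, dx, dy)
    if best is None:
        raise FlatImageError("no usable rotation candidate")
    score, angle, dx, dy = best

    if f > 1:  # refine the translation at full resolution near the coarse optimum
        rot = _rotate_about_center(mov, angle)
        fdx, fdy, score = _best_shift(fix, rot, None)
        if abs(fdx - dx * f) <= 2 * f and abs(fdy - dy * f) <= 2 * f:
            dx, dy = fdx, fdy
        else:  # fall back to the scaled coarse solution
            dx, dy = dx * f, dy * f
            score = _overlap_ncc(fix, rot, dx, dy)

    return TransformGrid(
        dx=float(dx),
        dy=float(dy),
        rotation_deg=float(angle),
        image_shape=mov.shape,
        grid_spacing=search.grid_spacing,
        ncc_value=float(score),
    )
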