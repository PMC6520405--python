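"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the inputs of a serial-section IHC study of advanced
melanoma treated with ipilimumab: per case, co-registered CD3 and CD8 cell
maps on a shared tumor geometry, a clinical record (response category,
overall survival, censoring), and tumor annotations. The planted effect
mirrors the immune-contexture signal the analysis is built to find: the
intra-tumoral infiltration (ITI) to stroma density ratio of CD8+ cells is
higher for responders than for non-responders, and survival is coupled to
response through class-specific exponential medians.

Point patterns are inhomogeneous Poisson with constant intensity per
compartment (stroma, ITI band, tumor core); tumor geometry is one
simply-connected smooth radial blob per case so every eroded/dilated region
of interest is non-empty. None of this attempts histological realism — tiles
and maps are schematic, sufficient for mask logic and plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .registration import TransformGrid
from .types import CaseRecord, CellMap


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level knobs of the synthetic cohort.

    Densities are cells/mm²; the planted CD8 ITI/stroma ratio must be higher
    for responders than non-responders. Geometry defaults give a ~3.3 mm
    square field at 2 µm/px with an ~800 µm-radius tumor, large enough that
    the 338/676 µm morphological margins all exist.
    """

    n_cases: int = 31
    responder_fraction: float = 12 / 31
    density_stroma: float = 60.0
    iti_density_ratio_responder: float = 6.0
    iti_density_ratio_nonresponder: float = 1.5
    ratio_sigma: float = 0.2
    melanin_fraction: float = 0.1
    survival_median_responder_months: float = 40.0
    survival_median_nonresponder_months: float = 12.0
    censoring_rate: float = 0.3
    followup_min_months: float = 1.0
    followup_max_months: float = 59.5
    seed: int = 0
    # geometry
    image_px: int = 1664
    pixel_size_um: float = 2.0
    tumor_radius_um: float = 800.0
    radius_jitter: float = 0.08
    max_offset_px: int = 24
    # secondary intensities
    cd3_factor: float = 1.8
    cd3_iti_ratio: float = 2.0
    neg_density_factor: float = 2.0
    core_intensity_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.iti_density_ratio_responder <= self.iti_density_ratio_nonresponder:
            raise ValueError("responder ITI/stroma ratio must exceed the non-responder one")
        for name in ("density_stroma", "pixel_size_um", "tumor_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.melanin_fraction:
            raise ValueError("melanin_fraction must be non-negative")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass
class CaseAnnotations:
    """Per-case ground truth and annotations produced by the generator."""

    tumor_polygon: Polygon
    exclusion_polygons: list[Polygon]
    transform_cd8_to_cd3: TransformGrid
    true_iti_ratio: float


def simulate_survival(
    rng: np.random.Generator,
    n: int,
    median_months: float,
    censoring_rate: float,
    followup_min: float,
    followup_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with independent uniform censoring.

    Event times are exponential with the given median; with probability
    ``censoring_rate`` a case receives a uniform censoring time on the
    follow-up window, otherwise it is censored only at the end of follow-up.
    Returns (observed times, event flags).
    """
    t = rng.exponential(scale=median_months / math.log(2), size=n)
    cens = np.full(n, followup_max)
    draw = rng.random(n) < censoring_rate
    cens[draw] = rng.uniform(followup_min, followup_max, size=int(draw.sum()))
    events = t <= cens
    return np.minimum(t, cens), events


def _tumor_polygon(rng: np.random.Generator, cfg: SimulationConfig) -> Polygon:
    """Random smooth radial blob centred in the frame."""
    base_px = cfg.tumor_radius_um / cfg.pixel_size_um
    phis = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    r = np.ones_like(phis)
    for k in range(2, 6):
        amp = rng.normal(0, cfg.radius_jitter / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * phis + phase)
    r = np.clip(r, 1 - 2 * cfg.radius_jitter, 1 + 2 * cfg.radius_jitter) * base_px
    c = (cfg.image_px - 1) / 2.0
    xs = c + r * np.cos(phis)
    ys = c + r * np.sin(phis)
    return Polygon(np.column_stack([xs, ys]))


def rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of a polygon given in (x, y) pixel coordinates."""
    xy = np.asarray(poly.exterior.coords)
    return polygon2mask(shape, np.column_stack([xy[:, 1], xy[:, 0]]))


def _sample_points(rng: np.random.Generator, mask: np.ndarray, intensity_per_px: float) -> np.ndarray:
    """Homogeneous Poisson sample inside a mask; returns (N, 2) (x, y)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0 or intensity_per_px <= 0:
        return np.zeros((0, 2))
    n = rng.poisson(intensity_per_px * idx.size)
    if n == 0:
        return np.zeros((0, 2))
    pick = idx[rng.integers(0, idx.size, size=n)]
    ys, xs = np.unravel_index(pick, mask.shape)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    x = np.clip(xs + jitter[:, 0], 0, mask.shape[1] - 1)
    y = np.clip(ys + jitter[:, 1], 0, mask.shape[0] - 1)
    return np.column_stack([x, y])


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[CaseRecord], dict[str, dict[str, CellMap]], dict[str, CaseAnnotations]]:
    """Generate a full synthetic cohort.

    Returns ``(cases, cellmaps, annotations)`` where ``cellmaps`` maps
    case_id -> stain -> :class:`~tphen.types.CellMap`. CD3 and CD8 maps share
    the tumor geometry up to a known integer rigid offset recorded in the
    per-case :class:`~tphen.registration.TransformGrid` (CD8 -> CD3).
    Deterministic for a fixed ``config.seed``.
    """
    from scipy.ndimage import distance_transform_edt

    from .roi_features import RoiConfig

    master = np.random.SeedSequence(config.seed)
    rng_global = np.random.default_rng(master.spawn(1)[0])
    n_resp = int(round(config.n_cases * config.responder_fraction))
    n_resp = min(max(n_resp, 1), config.n_cases - 1)
    responder_flags = np.zeros(config.n_cases, dtype=bool)
    responder_flags[:n_resp] = True
    rng_global.shuffle(responder_flags)

    roi_cfg = RoiConfig(pixel_size_um=config.pixel_size_um)
    w_iti = roi_cfg.iti_px
    shape = (config.image_px, config.image_px)
    px_area_mm2 = (config.pixel_size_um / 1000.0) ** 2

    case_seeds = master.spawn(config.n_cases)
    cases: list[CaseRecord] = []
    cellmaps: dict[str, dict[str, CellMap]] = {}
    annotations: dict[str, CaseAnnotations] = {}

    for i in range(config.n_cases):
        rng = np.random.default_rng(case_seeds[i])
        case_id = f"case{i:03d}"
        responder = bool(responder_flags[i])

        if responder:
            category = "CR" if rng.random() < 11 / 12 else "PR"
            median = config.survival_median_responder_months
            group_ratio = config.iti_density_ratio_responder
        else:
            category = "PD" if rng.random() < 15 / 19 else "SD"
            median = config.survival_median_nonresponder_months
            group_ratio = config.iti_density_ratio_nonresponder
        os_t, ev = simulate_survival(
            rng, 1, median, config.censoring_rate, config.followup_min_months, config.followup_max_months
        )
        cases.append(CaseRecord(case_id, category, float(os_t[0]), bool(ev[0])))

        # per-case multiplicative jitter with unit mean
        jitter = math.exp(rng.normal(0, config.ratio_sigma) - config.ratio_sigma**2 / 2)
        ratio = group_ratio * jitter

        poly = _tumor_polygon(rng, config)
        tumor = rasterize_polygon(poly, shape)
        tissue = np.ones(shape, dtype=bool)
        dist_in = distance_transform_edt(tumor)
        iti = tumor & (dist_in <= w_iti)
        core = tumor & ~iti
        stroma = tissue & ~tumor

        lam_s = config.density_stroma * px_area_mm2  # per px²
        offsets = rng.integers(-config.max_offset_px, config.max_offset_px + 1, size=2)
        grid = TransformGrid(
            dx=float(offsets[0]), dy=float(offsets[1]), rotation_deg=0.0, image_shape=shape
        )

        per_stain: dict[str, CellMap] = {}
        for stain in ("CD3", "CD8"):
            if stain == "CD8":
                lam_stroma = lam_s
                lam_iti = lam_s * ratio
            else:
                lam_stroma = lam_s * config.cd3_factor
                lam_iti = lam_stroma * config.cd3_iti_ratio
            lam_core = lam_iti * config.core_intensity_factor
            pos = np.vstack(
                [
                    _sample_points(rng, stroma, lam_stroma),
                    _sample_points(rng, iti, lam_iti),
                    _sample_points(rng, core, lam_core),
                ]
            )
            neg = _sample_points(rng, tissue, lam_s * config.neg_density_factor)
            mel = _sample_points(rng, tissue, lam_s * config.melanin_fraction)
            cells = pd.DataFrame(
                {
                    "x_px": np.concatenate([pos[:, 0], neg[:, 0], mel[:, 0]]),
                    "y_px": np.concatenate([pos[:, 1], neg[:, 1], mel[:, 1]]),
                    "cls": ["ihc_pos"] * len(pos) + ["ihc_neg"] * len(neg) + ["melanin"] * len(mel),
                }
            )
            if stain == "CD8":
                # the CD8 section lives in its own frame: shift by the known offset
                cells = cells.assign(
                    x_px=cells.x_px - grid.dx, y_px=cells.y_px - grid.dy
                )
                h, w = shape
                keep = (
                    (cells.x_px >= 0) & (cells.x_px < w) & (cells.y_px >= 0) & (cells.y_px < h)
                )
                cells = cells[keep].reset_index(drop=True)
            per_stain[stain] = CellMap(
                stain=stain,
                cells=cells,
                image_shape=shape,
                pixel_size_um=config.pixel_size_um,
                tissue_mask=tissue.copy(),
            )
        cellmaps[case_id] = per_stain
        annotations[case_id] = CaseAnnotations(
            tumor_polygon=poly,
            exclusion_polygons=[],
            transform_cd8_to_cd3=grid,
            true_iti_ratio=ratio,
        )
    return cases, cellmaps, annotations


# ---------------------------------------------------------------------------
# Schematic patch image pairs for the patch factory
# ---------------------------------------------------------------------------

#: RGB colours used when rendering schematic tiles. Chosen so the normalised
#: stain intensity (255 - min RGB) is strong for specific stain and melanin
#: (215 and 200) and faint for non-specific stain (70).
_COLOURS = {
    "cd3_pos": (110, 70, 40),
    "melanin": (90, 70, 55),
    "nonspecific": (210, 195, 185),
}


@dataclass(frozen=True)
class LayoutDisk:
    """One disk of the schematic layout: centre, radius, class."""

    x: float
    y: float
    radius: float
    cls: str


@dataclass
class PatchImagePair:
    """Schematic CD3-like / FoxP3-like tile pair with exact ground truth."""

    cd3_rgb: np.ndarray
    foxp3_rgb: np.ndarray
    masks_cd3: dict[str, np.ndarray]
    masks_foxp3: dict[str, np.ndarray]
    layout: list[LayoutDisk]
    offset: tuple[int, int]

    def cell_maps(self, pixel_size_um: float = 0.22) -> tuple[CellMap, CellMap]:
        """Derive (CD3, FoxP3) cell maps from the layout bookkeeping.

        CD3-positive disks become ``ihc_pos`` cells on the CD3 map; melanin
        disks become ``melanin`` cells on both maps (shifted by the offset on
        the FoxP3 map).
        """
        shape = self.cd3_rgb.shape[:2]
        dx, dy = self.offset
        cd3_rows, fox_rows = [], []
        for d in self.layout:
            if d.cls == "cd3_pos":
                cd3_rows.append((d.x, d.y, "ihc_pos"))
            elif d.cls == "melanin":
                cd3_rows.append((d.x, d.y, "melanin"))
                fox_rows.append((d.x + dx, d.y + dy, "melanin"))
        def _mk(rows, stain):
            df = pd.DataFrame(rows, columns=["x_px", "y_px", "cls"])
            h, w = shape
            if len(df):
                df = df[(df.x_px >= 0) & (df.x_px < w) & (df.y_px >= 0) & (df.y_px < h)]
            return CellMap(stain=stain, cells=df.reset_index(drop=True), image_shape=shape,
                           pixel_size_um=pixel_size_um, tissue_mask=np.ones(shape, dtype=bool))
        return _mk(cd3_rows, "CD3"), _mk(fox_rows, "FoxP3")


def _paint_disk(rgb: np.ndarray, mask: np.ndarray, d: LayoutDisk, colour, dx=0.0, dy=0.0) -> None:
    h, w = mask.shape
    yy, xx = np.indices((h, w))
    disk = (xx - (d.x + dx)) ** 2 + (yy - (d.y + dy)) ** 2 <= d.radius**2
    mask |= disk
    rgb[disk] = colour


def generate_patch_image_pair(
    seed: int,
    class_layout: list[LayoutDisk | tuple],
    *,
    tile_px: int = 240,
    offset: tuple[int, int] = (0, 0),
) -> PatchImagePair:
    """Render a schematic (CD3-like, FoxP3-like) RGB tile pair.

    Specifically stained objects and faint non-specific blobs appear only in
    the CD3-like channel; melanin disks appear in both channels, shifted by
    the known rigid ``offset`` in the FoxP3-like channel. Ground-truth masks
    mark exactly which pixels belong to each class. Overlapping disks with
    different classes are rejected.
    """
    rng = np.random.default_rng(seed)
    layout = [d if isinstance(d, LayoutDisk) else LayoutDisk(*d) for d in class_layout]
    for d in layout:
        if d.cls not in _COLOURS:
            raise ValueError(f"unknown layout class {d.cls!r}")
    for i, a in enumerate(layout):
        for b in layout[i + 1 :]:
            if a.cls != b.cls and math.hypot(a.x - b.x, a.y - b.y) < a.radius + b.radius:
                raise ValueError("overlapping layout entries with contradictory classes")

    shape = (tile_px, tile_px)
    white = np.full(shape + (3,), 255, dtype=np.uint8)
    cd3 = white.copy()
    fox = white.copy()
    masks_cd3 = {k: np.zeros(shape, dtype=bool) for k in _COLOURS}
    masks_fox = {k: np.zeros(shape, dtype=bool) for k in _COLOURS}
    for d in layout:
        if d.cls in ("cd3_pos", "nonspecific"):
            _paint_disk(cd3, masks_cd3[d.cls], d, _COLOURS[d.cls])
        else:  # melanin: both channels, offset in the FoxP3 frame
            _paint_disk(cd3, masks_cd3[d.cls], d, _COLOURS[d.cls])
            _paint_disk(fox, masks_fox[d.cls], d, _COLOURS[d.cls], dx=offset[0], dy=offset[1])
    # mild background noise so NCC-based registration has texture to work with
    noise = rng.integers(-6, 7, size=shape + (1,))
    cd3 = np.clip(cd3.astype(int) + noise, 0, 255).astype(np.uint8)
    fox = np.clip(fox.astype(int) + noise, 0, 255).astype(np.uint8)
    return PatchImagePair(cd3, fox, masks_cd3, masks_fox, layout, offset)
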