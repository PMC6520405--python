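"""Regions of interest and the 114-feature immune-contexture extractor.

Six ROIs are derived from the pathologist's tumor annotation by isotropic
morphological operations (Euclidean-disk structuring elements realised with
distance transforms): *tumor*, *stroma* (all non-tumor tissue), *tumor plus
stroma*, the small and large tumor-microenvironment bands outside the tumor
border (widths 338 µm and 676 µm, inspired by the colorectal Immunoscore
invasive margin), and the intra-tumoral infiltration (ITI) band just inside
the border (width 676 µm). Exclusion annotations (necrosis, artifacts) are
removed from every mask, and for features that combine co-registered serial
sections only the intersection of the tissue masks is used.

Per case the extractor emits exactly 114 features:

* 12 densities — IHC-positive objects per ROI area for 2 stains x 6 ROIs,
  with areas measured in prediction-heatmap pixels (80 x 80 px patches) and
  melanin-flagged patches excluded from the positive counts;
* 66 ratios — one per unordered pair of the 12 densities, emitted in a fixed
  canonical order (direction is recovered downstream by the cut-point
  direction, since a/b > t iff b/a < 1/t);
* 36 cross-stain neighbour distances — mean distance (µm) to the k nearest
  cells of the other stain, k in {2, 4, 8}, both directions, per ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .registration import TransformGrid, apply_transform
from .synthetic import rasterize_polygon
from .types import CellMap

ROI_NAMES = ("tumor", "stroma", "tumor_stroma", "tme_small", "tme_large", "iti")
FEATURE_STAINS = ("CD3", "CD8")
KNN_KS = (2, 4, 8)


@dataclass(frozen=True)
class RoiConfig:
    """Widths of the morphological margins and the area unit.

    Margins are physical widths converted to pixels by rounding; densities
    use heatmap-patch units, i.e. areas are counted in blocks of
    ``heatmap_patch_px`` squared.
    """

    tme_small_um: float = 338.0
    tme_large_um: float = 676.0
    iti_um: float = 676.0
    pixel_size_um: float = 0.22
    heatmap_patch_px: int = 80

    def __post_init__(self) -> None:
        for name in ("tme_small_um", "tme_large_um", "iti_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def _px(self, um: float) -> int:
        return max(1, int(round(um / self.pixel_size_um)))

    @property
    def tme_small_px(self) -> int:
        return self._px(self.tme_small_um)

    @property
    def tme_large_px(self) -> int:
        return self._px(self.tme_large_um)

    @property
    def iti_px(self) -> int:
        return self._px(self.iti_um)


@dataclass
class RoiSet:
    """The six feature ROIs plus the tumor core and exclusion rasters."""

    masks: dict[str, np.ndarray]
    tumor_core: np.ndarray
    exclusions: np.ndarray
    tissue: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def build_rois(
    tumor_polygons: list[Polygon] | Polygon,
    exclusion_polygons: list[Polygon],
    tissue_masks: dict[str, np.ndarray],
    grid: TransformGrid | None,
    cfg: RoiConfig,
) -> RoiSet:
    """Rasterize annotations and derive the six ROI masks.

    ``tissue_masks`` maps stain -> tissue mask; masks for stains other than
    the reference (first key) are brought into the reference frame with
    ``grid`` (forward direction) and intersected, so across-section features
    are only measured where both sections have tissue.
    """
    if isinstance(tumor_polygons, Polygon):
        tumor_polygons = [tumor_polygons]
    stains = list(tissue_masks)
    shape = tissue_masks[stains[0]].shape
    tissue = tissue_masks[stains[0]].astype(bool).copy()
    for stain in stains[1:]:
        other = tissue_masks[stain].astype(bool)
        if grid is not None:
            other = apply_transform(other, grid, "forward", out_shape=shape)
        tissue &= other

    tumor = np.zeros(shape, dtype=bool)
    for poly in tumor_polygons:
        tumor |= rasterize_polygon(poly, shape)
    if not tumor.any():
        raise ValueError("tumor annotation rasterizes to an empty mask")
    excl = np.zeros(shape, dtype=bool)
    for poly in exclusion_polygons:
        excl |= rasterize_polygon(poly, shape)

    dist_out = distance_transform_edt(~tumor)
    dist_in = distance_transform_edt(tumor)
    band_small = (dist_out <= cfg.tme_small_px) & ~tumor
    band_large = (dist_out <= cfg.tme_large_px) & ~tumor
    iti = tumor & (dist_in <= cfg.iti_px)
    core = tumor & ~iti
    if not core.any():
        warnings.warn("tumor fully eroded away: ITI equals tumor, core empty", stacklevel=2)

    keep = tissue & ~excl
    masks = {
        "tumor": tumor & keep,
        "stroma": ~tumor & keep,
        "tumor_stroma": keep.copy(),
        "tme_small": band_small & keep,
        "tme_large": band_large & keep,
        "iti": iti & keep,
    }
    return RoiSet(masks=masks, tumor_core=core & keep, exclusions=excl, tissue=tissue)


def _cells_in_mask(coords: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Boolean selector of points whose (rounded) pixel lies in the mask."""
    if len(coords) == 0:
        return np.zeros(0, dtype=bool)
    xs = np.clip(np.rint(coords[:, 0]).astype(int), 0, mask.shape[1] - 1)
    ys = np.clip(np.rint(coords[:, 1]).astype(int), 0, mask.shape[0] - 1)
    return mask[ys, xs]


def roi_density(
    positives: np.ndarray,
    roi_mask: np.ndarray,
    cfg: RoiConfig,
    melanin_heatmap: np.ndarray | None = None,
) -> float:
    """Density of IHC-positive objects in a ROI, in heatmap-area units.

    ``positives`` is an (N, 2) array of positive-object coordinates already in
    the ROI's frame. Objects falling in patches the prediction heatmap flags
    as melanin are excluded from the count (whole-patch exclusion). A
    zero-area ROI yields NaN (missing), never 0.
    """
    area_units = roi_mask.sum() / float(cfg.heatmap_patch_px**2)
    if area_units == 0:
        return float("nan")
    sel = _cells_in_mask(positives, roi_mask)
    pts = positives[sel]
    if melanin_heatmap is not None and len(pts):
        from .patch_factory import HeatmapClass

        rows = np.minimum((np.rint(pts[:, 1]) // cfg.heatmap_patch_px).astype(int),
                          melanin_heatmap.shape[0] - 1)
        cols = np.minimum((np.rint(pts[:, 0]) // cfg.heatmap_patch_px).astype(int),
                          melanin_heatmap.shape[1] - 1)
        pts = pts[melanin_heatmap[rows, cols] != int(HeatmapClass.MELANIN)]
    return float(len(pts) / area_units)


def density_names() -> list[str]:
    return [f"density:{s}:{r}" for s in FEATURE_STAINS for r in ROI_NAMES]


def ratio_names() -> list[str]:
    names = density_names()
    return [f"ratio:{a.split(':', 1)[1]}/{b.split(':', 1)[1]}" for a, b in combinations(names, 2)]


def knn_names() -> list[str]:
    pairs = [("CD3", "CD8"), ("CD8", "CD3")]
    return [f"knn:{a}->{b}:{r}:k{k}" for a, b in pairs for k in KNN_KS for r in ROI_NAMES]


def feature_names() -> list[str]:
    """The canonical, stable ordering of all 114 feature columns."""
    return density_names() + ratio_names() + knn_names()


def density_ratios(densities: dict[str, float]) -> dict[str, float]:
    """All 66 unordered pairwise ratios of the 12 densities.

    Each unordered pair {a, b} is emitted once as a/b following the canonical
    column order; a zero denominator or a missing operand propagates NaN.
    """
    names = density_names()
    missing = set(names) - set(densities)
    if missing:
        raise KeyError(f"missing densities: {sorted(missing)}")
    out: dict[str, float] = {}
    for (na, nb), rname in zip(combinations(names, 2), ratio_names()):
        a, b = densities[na], densities[nb]
        out[rname] = float("nan") if (not np.isfinite(b) or b == 0 or not np.isfinite(a)) else a / b
    return out


def knn_cross_distance(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    k: int,
    roi_mask: np.ndarray | None,
    pixel_size_um: float,
) -> tuple[float, bool]:
    """Mean distance (µm) from ROI cells of one stain to their k nearest
    cells of the other stain.

    ``cells_a`` is restricted to the ROI; ``cells_b`` must already be in the
    same coordinate frame (co-registered). If fewer than ``k`` neighbours
    exist all are used and the result is flagged truncated. Empty sets yield
    (NaN, False).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    a = np.asarray(cells_a, dtype=float).reshape(-1, 2)
    b = np.asarray(cells_b, dtype=float).reshape(-1, 2)
    if roi_mask is not None and len(a):
        a = a[_cells_in_mask(a, roi_mask)]
    if len(a) == 0 or len(b) == 0:
        return float("nan"), False
    kk = min(k, len(b))
    tree = cKDTree(b)
    d, _ = tree.query(a, k=kk)
    d = np.atleast_2d(d.reshape(len(a), kk))
    return float(d.mean() * pixel_size_um), kk < k


def extract_features(
    cellmaps: dict[str, CellMap],
    roiset: RoiSet,
    cfg: RoiConfig,
    grid: TransformGrid | None = None,
    melanin_heatmaps: dict[str, np.ndarray] | None = None,
) -> pd.Series:
    """One case's 114-feature row.

    ``cellmaps`` must contain CD3 and CD8; CD8 coordinates are mapped into
    the CD3 (reference) frame with ``grid`` before any measurement. When no
    prediction heatmaps are supplied, melanin exclusion falls back to
    patch-level heatmaps built from each map's own melanin-class objects.
    """
    from .patch_factory import PatchSpec, melanin_heatmap_from_cells

    for stain in FEATURE_STAINS:
        if stain not in cellmaps:
            raise KeyError(f"missing {stain} cell map")
    cd3 = cellmaps["CD3"]
    spec = PatchSpec(patch_px=cfg.heatmap_patch_px, pixel_size_um=cfg.pixel_size_um)

    pos: dict[str, np.ndarray] = {}
    heat: dict[str, np.ndarray] = {}
    for stain in FEATURE_STAINS:
        cm = cellmaps[stain]
        p = cm.coords("ihc_pos")
        m = cm.coords("melanin")
        if stain != "CD3" and grid is not None:
            p, _ = apply_transform(p, grid, "forward", points=True)
            m, _ = apply_transform(m, grid, "forward", points=True)
        pos[stain] = p
        if melanin_heatmaps is not None and stain in melanin_heatmaps:
            heat[stain] = melanin_heatmaps[stain]
        else:
            heat[stain] = melanin_heatmap_from_cells(m, cd3.image_shape, spec)

    values: dict[str, float] = {}
    for stain in FEATURE_STAINS:
        for roi in ROI_NAMES:
            if len(pos[stain]) == 0:
                # an empty positive set means the section carries no signal at
                # all; its readouts are missing data, not true zeros
                values[f"density:{stain}:{roi}"] = float("nan")
            else:
                values[f"density:{stain}:{roi}"] = roi_density(
                    pos[stain], roiset[roi], cfg, melanin_heatmap=heat[stain]
                )
    values.update(density_ratios(values))
    # one k=8 neighbour query per (direction, ROI) serves all three k values
    for a, b in (("CD3", "CD8"), ("CD8", "CD3")):
        pb = pos[b]
        tree = cKDTree(pb) if len(pb) else None
        for roi in ROI_NAMES:
            pa = pos[a]
            pa = pa[_cells_in_mask(pa, roiset[roi])] if len(pa) else pa
            if tree is None or len(pa) == 0:
                for k in KNN_KS:
                    values[f"knn:{a}->{b}:{roi}:k{k}"] = float("nan")
                continue
            kk = min(max(KNN_KS), len(pb))
            d = np.atleast_2d(tree.query(pa, k=kk)[0].reshape(len(pa), kk))
            for k in KNN_KS:
                values[f"knn:{a}->{b}:{roi}:k{k}"] = float(
                    d[:, : min(k, kk)].mean() * cfg.pixel_size_um
                )
    return pd.Series(values).reindex(feature_names())


def extract_feature_table(cases, cellmaps, annotations, cfg: RoiConfig | None = None) -> pd.DataFrame:
    """Feature table (cases x 114) for a generated or loaded cohort."""
    cfg = cfg or RoiConfig(pixel_size_um=next(iter(cellmaps.values()))["CD3"].pixel_size_um)
    rows = {}
    for case in cases:
        ann = annotations[case.case_id]
        maps = cellmaps[case.case_id]
        grid = ann.transform_cd8_to_cd3
        roiset = build_rois(
            ann.tumor_polygon,
            ann.exclusion_polygons,
            {s: maps[s].tissue_mask for s in FEATURE_STAINS},
            grid,
            cfg,
        )
        rows[case.case_id] = extract_features(maps, roiset, cfg, grid=grid)
    return pd.DataFrame(rows).T.reindex(columns=feature_names())
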