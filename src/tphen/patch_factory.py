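"""Automatic training-data generation and patch-level prediction plumbing.

Brown chromogen (DAB) and melanin look alike, so IHC-positive T cells cannot
be told from melanin by colour alone. The factory exploits virtual
multiplexing across co-registered serial sections: on FoxP3-stained sections
the IHC chromogen is red, so every *brown* object there is melanin. Patches
of the CD3 section are labelled

* ``cd3_pos``     — IHC-positive objects present, no co-registered brown
                    FoxP3 objects;
* ``melanin``     — co-registered brown FoxP3 objects present, no
                    IHC-positive CD3 cells;
* ``nonspecific`` — brown image content present but faint (mean normalised
                    stain intensity of brown pixels below a threshold), and
                    neither of the above;

patches matching no rule are skipped. Labelled patches are augmented by the
group of four right-angle rotations crossed with four linear histogram
scalings (one of which is the identity), giving exactly 15 additional
variants, and under-represented classes are topped up by sampling without
replacement from their augmented pools.

The patch classifier itself is a plug-in contract (any callable mapping a
:class:`Patch` to a class name); the module ships a deterministic rule-based
reference classifier for end-to-end tests, and a prediction heatmap builder
that evaluates the classifier only on candidate patches overlapping
IHC-positive objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .registration import TransformGrid, apply_transform, normalize_stain
from .types import CellMap

PATCH_CLASSES = ("cd3_pos", "melanin", "nonspecific")


class HeatmapClass(IntEnum):
    UNPROCESSED = 0
    CD3_POS = 1
    MELANIN = 2
    NONSPECIFIC = 3


_HEATMAP_CODE = {
    "cd3_pos": HeatmapClass.CD3_POS,
    "melanin": HeatmapClass.MELANIN,
    "nonspecific": HeatmapClass.NONSPECIFIC,
}


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and labelling thresholds.

    80 px at 0.22 µm/px gives a 17.6 µm patch, typically holding one to three
    lymphocytes. ``faint_threshold`` operationalises "faint appearance" for
    non-specific stain: mean normalised-stain intensity of brown pixels below
    this value. ``intensity_gains`` are the four histogram scalings used for
    augmentation; the identity gain must be present so the rotation x gain
    grid contains the original exactly once.
    """

    patch_px: int = 80
    pixel_size_um: float = 0.22
    faint_threshold: float = 80.0
    brown_min: float = 40.0
    intensity_gains: tuple[float, ...] = (1.0, 0.8, 0.9, 1.2)

    def __post_init__(self) -> None:
        if self.patch_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("patch_px and pixel_size_um must be positive")
        if 1.0 not in self.intensity_gains:
            raise ValueError("intensity_gains must contain the identity gain 1.0")

    @property
    def patch_um(self) -> float:
        return self.patch_px * self.pixel_size_um


@dataclass
class LabeledPatch:
    """One labelled tile with provenance."""

    tile: np.ndarray | None
    label: str
    case_id: str = ""
    x0: int = 0
    y0: int = 0
    augmentation: str = "original"

    @property
    def patch_id(self) -> str:
        return f"{self.case_id}:{self.x0}:{self.y0}:{self.augmentation}"


def _patch_of(coords: np.ndarray, patch_px: int) -> tuple[np.ndarray, np.ndarray]:
    cols = (coords[:, 0] // patch_px).astype(int)
    rows = (coords[:, 1] // patch_px).astype(int)
    return rows, cols


def extract_training_patches(
    cd3_map: CellMap,
    foxp3_map: CellMap,
    grid: TransformGrid | None,
    spec: PatchSpec,
    cd3_image: np.ndarray | None = None,
    case_id: str = "",
) -> list[LabeledPatch]:
    """Label patches of the CD3 section by cross-channel mask logic.

    The patch grid is axis-aligned with stride ``patch_px``; boundary
    remainders are dropped. Object presence uses the centroid rule (a patch
    owns an object iff its centroid falls inside), which keeps the three
    label predicates pairwise disjoint. Brown FoxP3 objects (melanin) are
    transformed into CD3 coordinates with ``grid``; ``grid=None`` requires
    pre-aligned maps only when the maps share a frame, otherwise it is an
    error to omit it.
    """
    if grid is None and foxp3_map.image_shape != cd3_map.image_shape:
        raise ValueError("transform grid required for differently framed sections")
    h, w = cd3_map.image_shape
    p = spec.patch_px
    n_rows, n_cols = h // p, w // p

    cd3_pos = cd3_map.coords("ihc_pos")
    brown = foxp3_map.coords("melanin")
    if grid is not None and len(brown):
        brown, _ = apply_transform(brown, grid, "forward", points=True)

    def _sets(coords):
        if len(coords) == 0:
            return set()
        rows, cols = _patch_of(coords, p)
        ok = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
        return set(zip(rows[ok].tolist(), cols[ok].tolist()))

    pos_patches = _sets(cd3_pos)
    brown_patches = _sets(brown)

    norm = normalize_stain(cd3_image) if cd3_image is not None else None
    out: list[LabeledPatch] = []
    for r in range(n_rows):
        for c in range(n_cols):
            key = (r, c)
            has_pos = key in pos_patches
            has_brown = key in brown_patches
            tile = None
            if cd3_image is not None:
                tile = cd3_image[r * p : (r + 1) * p, c * p : (c + 1) * p]
            if has_pos and not has_brown:
                label = "cd3_pos"
            elif has_brown and not has_pos:
                label = "melanin"
            elif not has_pos and not has_brown and norm is not None:
                sub = norm[r * p : (r + 1) * p, c * p : (c + 1) * p]
                brown_px = sub[sub > spec.brown_min]
                if len(brown_px) == 0 or brown_px.mean() >= spec.faint_threshold:
                    continue
                label = "nonspecific"
            else:
                continue
            out.append(LabeledPatch(tile=tile, label=label, case_id=case_id, x0=c * p, y0=r * p))
    return out


def augment_patch(patch: LabeledPatch, spec: PatchSpec | None = None) -> list[LabeledPatch]:
    """Exactly 15 additional deterministic variants of a square patch.

    The variant grid is 4 rotations x 4 intensity gains = 16 combinations;
    the identity pair (0°, gain 1.0) duplicates the original and is dropped.
    Gains are linear histogram scalings clipped to [0, 255].
    """
    spec = spec or PatchSpec()
    tile = patch.tile
    if tile is None:
        raise ValueError("cannot augment a patch without image data")
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("augmentation requires a square patch")
    out: list[LabeledPatch] = []
    for rot in (0, 90, 180, 270):
        rotated = np.rot90(tile, k=rot // 90, axes=(0, 1))
        for gain in spec.intensity_gains:
            if rot == 0 and gain == 1.0:
                continue
            scaled = np.clip(np.rint(rotated.astype(float) * gain), 0, 255).astype(tile.dtype)
            out.append(
                replace(patch, tile=scaled, augmentation=f"rot{rot}_g{gain:g}")
            )
    return out


def balance_classes(
    patches_by_class: dict[str, list[LabeledPatch]],
    seed: int,
    spec: PatchSpec | None = None,
) -> dict[str, list[LabeledPatch]]:
    """Top up minority classes with augmented samples until balance.

    Each minority class draws without replacement from the pool of all
    augmented variants of its original patches until it reaches the majority
    count; if the pool runs dry a warning is issued and the class stays at
    originals + full pool. The majority class is untouched. Deterministic for
    a fixed seed.
    """
    if not patches_by_class or any(len(v) == 0 for v in patches_by_class.values()):
        raise ValueError("every class needs at least one original patch")
    rng = np.random.default_rng(seed)
    majority = max(len(v) for v in patches_by_class.values())
    out: dict[str, list[LabeledPatch]] = {}
    for cls in sorted(patches_by_class):
        originals = list(patches_by_class[cls])
        need = majority - len(originals)
        if need <= 0:
            out[cls] = originals
            continue
        pool: list[LabeledPatch] = []
        for p in originals:
            pool.extend(augment_patch(p, spec))
        if need >= len(pool):
            if need > len(pool):
                warnings.warn(
                    f"class {cls!r}: augmentation pool exhausted "
                    f"({len(pool)} < {need} needed)",
                    stacklevel=2,
                )
            picked = pool
        else:
            idx = rng.choice(len(pool), size=need, replace=False)
            picked = [pool[i] for i in sorted(idx)]
        out[cls] = originals + list(picked)
    return out


@dataclass
class Patch:
    """What a patch classifier receives: grid position, extent, content."""

    row: int
    col: int
    x0: int
    y0: int
    tile: np.ndarray | None
    cells: pd.DataFrame


def select_candidate_patches(cell_map: CellMap, spec: PatchSpec) -> set[tuple[int, int]]:
    """Grid patches (row, col) inside tissue overlapping IHC-positive objects.

    The grid is anchored at the image origin with stride ``patch_px`` and
    covers the whole image (ceil division, partial boundary patches
    included). Overlap means any intersection with the closed patch extent,
    so an object sitting exactly on a patch boundary selects every touching
    patch.
    """
    h, w = cell_map.image_shape
    p = spec.patch_px
    n_rows, n_cols = math.ceil(h / p), math.ceil(w / p)
    pos = cell_map.coords("ihc_pos")
    tissue = cell_map.tissue_mask
    out: set[tuple[int, int]] = set()
    for x, y in pos:
        rows = {int(y // p)}
        cols = {int(x // p)}
        if y % p == 0 and y > 0:
            rows.add(int(y // p) - 1)
        if x % p == 0 and x > 0:
            cols.add(int(x // p) - 1)
        for r in rows:
            for c in cols:
                if not (0 <= r < n_rows and 0 <= c < n_cols):
                    continue
                if tissue is not None:
                    sub = tissue[r * p : min((r + 1) * p, h), c * p : min((c + 1) * p, w)]
                    if not sub.any():
                        continue
                out.add((r, c))
    return out


class PatchClassifierError(RuntimeError):
    """Classifier failure, annotated with the offending patch."""


def predict_heatmap(
    cell_map: CellMap,
    classifier: Callable[[Patch], str],
    spec: PatchSpec,
    image: np.ndarray | None = None,
) -> np.ndarray:
    """Run the classifier over candidate patches and build the heatmap.

    The heatmap has shape ceil(image / patch) in both axes; non-candidate
    patches stay :attr:`HeatmapClass.UNPROCESSED`. Classifier exceptions are
    re-raised with patch provenance attached.
    """
    h, w = cell_map.image_shape
    p = spec.patch_px
    n_rows, n_cols = math.ceil(h / p), math.ceil(w / p)
    heat = np.full((n_rows, n_cols), int(HeatmapClass.UNPROCESSED), dtype=np.uint8)
    cells = cell_map.cells
    for r, c in sorted(select_candidate_patches(cell_map, spec)):
        x0, y0 = c * p, r * p
        tile = None if image is None else image[y0 : y0 + p, x0 : x0 + p]
        sub = cells[
            (cells.x_px >= x0) & (cells.x_px < x0 + p) & (cells.y_px >= y0) & (cells.y_px < y0 + p)
        ]
        try:
            label = classifier(Patch(row=r, col=c, x0=x0, y0=y0, tile=tile, cells=sub))
        except Exception as exc:  # attach provenance, keep the original chain
            raise PatchClassifierError(f"classifier failed on patch (row={r}, col={c})") from exc
        if label not in _HEATMAP_CODE:
            raise PatchClassifierError(f"classifier returned unknown class {label!r} at ({r}, {c})")
        heat[r, c] = int(_HEATMAP_CODE[label])
    return heat


def melanin_heatmap_from_cells(
    melanin_coords: np.ndarray, image_shape: tuple[int, int], spec: PatchSpec
) -> np.ndarray:
    """Heatmap flagging every patch that contains a melanin object centroid."""
    h, w = image_shape
    p = spec.patch_px
    heat = np.full((math.ceil(h / p), math.ceil(w / p)), int(HeatmapClass.UNPROCESSED), dtype=np.uint8)
    coords = np.asarray(melanin_coords, dtype=float).reshape(-1, 2)
    if len(coords):
        rows = np.clip((coords[:, 1] // p).astype(int), 0, heat.shape[0] - 1)
        cols = np.clip((coords[:, 0] // p).astype(int), 0, heat.shape[1] - 1)
        heat[rows, cols] = int(HeatmapClass.MELANIN)
    return heat


def rule_based_classifier(spec: PatchSpec | None = None) -> Callable[[Patch], str]:
    """Deterministic reference classifier on schematic tiles.

    Stands in for a trained network in end-to-end tests: strong stain with
    the specific-stain colour signature -> ``cd3_pos``; strong but darker,
    desaturated brown -> ``melanin``; anything faint -> ``nonspecific``.
    """
    spec = spec or PatchSpec()

    def classify(patch: Patch) -> str:
        if patch.tile is None:
            # cell-map mode: decide from object classes in the patch
            if (patch.cells.cls == "melanin").any():
                return "melanin"
            if (patch.cells.cls == "ihc_pos").any():
                return "cd3_pos"
            return "nonspecific"
        norm = normalize_stain(patch.tile).astype(float)
        brown = norm > spec.brown_min
        if not brown.any() or norm[brown].mean() < spec.faint_threshold:
            return "nonspecific"
        px = patch.tile[brown].astype(float)
        # melanin rendering is desaturated: small green-blue gap
        gb_gap = (px[:, 1] - px[:, 2]).mean()
        return "melanin" if gb_gap < 20 else "cd3_pos"

    return classify


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("label count must match matrix size")

    @classmethod
    def from_predictions(cls, truth: Sequence[str], pred: Sequence[str],
                         labels: Sequence[str] = PATCH_CLASSES) -> "ConfusionMatrix":
        idx = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(truth, pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, dict[str, float]]:
    """Overall accuracy (trace/total) and per-class accuracies (row-wise)."""
    counts = cm.counts.astype(float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        bad = [cm.labels[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"zero test count for classes {bad}: per-class accuracy undefined")
    overall = float(np.trace(counts) / counts.sum())
    per_class = {
        label: float(counts[i, i] / row_sums[i]) for i, label in enumerate(cm.labels)
    }
    return overall, per_class
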