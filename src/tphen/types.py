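"""Shared domain containers.

Coordinates are 0-based pixel coordinates with ``x`` = column and ``y`` = row.
Physical distances are micrometres, converted through ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Response categories; a responder is CR or PR.
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})

#: Cell classes found in a per-stain cell map.
CELL_CLASSES = ("ihc_pos", "ihc_neg", "melanin")

#: Stains handled by the pipeline. FoxP3 sections are used only to locate
#: melanin (brown objects on those sections are melanin, since the FoxP3
#: chromogen is red); FoxP3 readouts themselves are not analysed.
STAINS = ("CD3", "CD8", "FoxP3")


@dataclass(frozen=True)
class CaseRecord:
    """Clinical record for one patient."""

    case_id: str
    response_category: str
    os_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.response_category not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown response category {self.response_category!r}")
        if self.os_months < 0:
            raise ValueError("os_months must be non-negative")

    @property
    def responder(self) -> bool:
        return self.response_category in RESPONDER_CATEGORIES


@dataclass
class CellMap:
    """Cell centroids and classes for one stained section on a pixel grid.

    ``cells`` is a DataFrame with columns ``x_px``, ``y_px``, ``cls``
    (one of :data:`CELL_CLASSES`).
    """

    stain: str
    cells: pd.DataFrame
    image_shape: tuple[int, int]
    pixel_size_um: float = 0.22
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        c = self.cells
        for col in ("x_px", "y_px", "cls"):
            if col not in c.columns:
                raise ValueError(f"cells missing column {col!r}")
        h, w = self.image_shape
        if len(c):
            bad = ~((c.x_px >= 0) & (c.x_px < w) & (c.y_px >= 0) & (c.y_px < h))
            if bad.any():
                raise ValueError(f"{int(bad.sum())} cells outside image_shape")
            unknown = set(c.cls.unique()) - set(CELL_CLASSES)
            if unknown:
                raise ValueError(f"unknown cell classes {sorted(unknown)}")

    def coords(self, cls: str | None = None) -> np.ndarray:
        """(N, 2) array of (x, y) centroids, optionally filtered by class."""
        c = self.cells if cls is None else self.cells[self.cells.cls == cls]
        return c[["x_px", "y_px"]].to_numpy(dtype=float)


def clinical_frame(cases: list[CaseRecord]) -> pd.DataFrame:
    """Tidy clinical table for a list of cases, indexed by ``case_id``."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "response_category": [c.response_category for c in cases],
            "responder": [c.responder for c in cases],
            "os_months": [c.os_months for c in cases],
            "event": [c.event for c in cases],
        }
    ).set_index("case_id")
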