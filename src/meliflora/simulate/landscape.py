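"""Synthetic landscape grid: habitat raster plus crop field circles.

Stands in for a national land-cover raster and a crops map.  Coordinates
are a planar km grid; habitat labels fill the grid to target fractions via
an exact quota with seeded shuffling (spatially unstructured), and each
crop flags exactly the cells whose centers fall inside declared circular
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LandscapeGrid:
    """Complete rectangular grid of habitat cells.

    ``cells`` columns: x, y (cell-center km), habitat, plus one boolean
    ``crop_<name>`` column per simulated crop.
    """

    cells: pd.DataFrame
    resolution: float
    extent: float

    @property
    def habitats(self) -> list[str]:
        return sorted(self.cells["habitat"].unique())

    @property
    def crops(self) -> list[str]:
        return [c.removeprefix("crop_") for c in self.cells.columns if c.startswith("crop_")]

    def habitat_fractions(self) -> pd.Series:
        return self.cells["habitat"].value_counts(normalize=True).sort_index()

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution: float | None = None) -> "LandscapeGrid":
        cells = pd.read_csv(path)
        xs = np.sort(cells["x"].unique())
        res = float(xs[1] - xs[0]) if resolution is None else resolution
        extent = float(xs[-1] - xs[0] + res)
        return cls(cells=cells, resolution=res, extent=extent)


def simulate_landscape(
    extent: float,
    resolution: float,
    habitat_palette: dict[str, float],
    crop_fields: list[tuple[str, tuple[float, float], float]] | None = None,
    n_hives: int = 0,
    seed: int = 0,
) -> tuple[LandscapeGrid, pd.DataFrame]:
    """Build a grid with habitat fractions matching the palette targets.

    Cell quotas are exact (largest-remainder rounding), so realised
    fractions deviate from targets by at most one cell per habitat.
    ``crop_fields`` entries are (crop name, (cx, cy) km, radius km);
    overlapping habitat targets are resolved by palette order precedence
    (earlier labels claim their quota first).  Returns the grid and a
    hive coordinate table (sample_id, x, y).
    """
    n_side = extent / resolution
    if abs(n_side - round(n_side)) > 1e-9:
        raise ValueError("resolution must divide extent")
    n_side = int(round(n_side))
    if not habitat_palette:
        raise ValueError("empty habitat palette")
    total_frac = sum(habitat_palette.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError("habitat fractions must sum to 1")

    rng = np.random.default_rng(seed)
    centers = (np.arange(n_side) + 0.5) * resolution
    xx, yy = np.meshgrid(centers, centers, indexing="xy")
    x = xx.ravel()
    y = yy.ravel()
    n_cells = n_side * n_side

    # exact quota by largest remainder, precedence = palette order
    labels = list(habitat_palette)
    raw = np.array([habitat_palette[h] * n_cells for h in labels])
    quota = np.floor(raw).astype(int)
    remainder = raw - quota
    short = n_cells - quota.sum()
    for i in np.argsort(-remainder)[:short]:
        quota[i] += 1
    habitat = np.repeat(labels, quota)
    rng.shuffle(habitat)

    cells = pd.DataFrame({"x": x, "y": y, "habitat": habitat})
    for crop, (cx, cy), radius in crop_fields or []:
        col = f"crop_{crop}"
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
        if col in cells.columns:
            cells[col] = cells[col] | inside
        else:
            cells[col] = inside

    hives = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_hives)],
            "x": rng.uniform(0, extent, size=n_hives),
            "y": rng.uniform(0, extent, size=n_hives),
        }
    )
    return LandscapeGrid(cells=cells, resolution=resolution, extent=extent), hives
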