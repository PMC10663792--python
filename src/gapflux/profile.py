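"""Vertical biomass profiles at configurable vertical and horizontal resolution.

A tree's above-ground biomass is assumed uniformly distributed over its
height, so a tree of height ``H`` contributes to each height layer in
proportion to the layer's overlap with ``[0, H]``. Stand profiles aggregate
these per-tree vectors over all trees of a grid cell and normalize by cell
area, yielding biomass density per layer (t ha^-1). Cells tile each
simulated plot regularly; supported cell edges are multiples of the 20 m
patch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gap_model import SuccessionResult

__all__ = [
    "ProfileSpec",
    "tree_layer_biomass",
    "stand_profile",
    "tile_cells",
    "profile_table",
    "layer_columns",
]

#: canonical resolutions studied: vertical layer widths and cell edges (m)
LAYER_WIDTHS = (2.0, 10.0, 20.0, 100.0)
CELL_EDGES = (20.0, 100.0, 200.0)


@dataclass(frozen=True)
class ProfileSpec:
    """Discretization choice: layer width ``dh`` and cell edge (m)."""

    dh: float = 20.0
    cell_edge: float = 200.0
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if self.dh <= 0 or self.cell_edge <= 0:
            raise ValueError("dh and cell_edge must be positive")
        if round(self.ceiling / self.dh, 9) % 1:
            raise ValueError("ceiling must be divisible by dh")
        if round(self.cell_edge / 20.0, 9) % 1:
            raise ValueError("cell_edge must be a multiple of the 20 m patch")

    @property
    def n_layers(self) -> int:
        return int(round(self.ceiling / self.dh))

    @property
    def cell_area_ha(self) -> float:
        return self.cell_edge**2 / 10_000.0


def layer_columns(spec: ProfileSpec) -> list[str]:
    """Column names ``b_layer_00 ...`` for the layer vector of ``spec``."""
    return [f"b_layer_{i:02d}" for i in range(spec.n_layers)]


def tree_layer_biomass(height: float, biomass: float, dh: float,
                       ceiling: float = 100.0) -> np.ndarray:
    """Distribute one tree's biomass uniformly over height layers.

    Layer ``i`` spans the half-open interval ``[i*dh, (i+1)*dh)``; the tree
    contributes ``biomass * overlap(layer, [0, height]) / height``. The
    returned vector has ``ceiling/dh`` entries and sums to ``biomass``.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if height > ceiling:
        raise ValueError(f"height {height} exceeds ceiling {ceiling}")
    if biomass < 0:
        raise ValueError("biomass must be non-negative")
    n_layers = int(round(ceiling / dh))
    edges = np.arange(n_layers + 1) * dh
    overlap = np.clip(np.minimum(edges[1:], height) - edges[:-1], 0.0, None)
    return biomass * overlap / height


def stand_profile(trees: pd.DataFrame, spec: ProfileSpec) -> np.ndarray:
    """Layered biomass density (t ha^-1) of one cell from its tree list.

    ``trees`` needs columns ``height_m`` and ``biomass_t``; an empty table
    yields the zero vector.
    """
    out = np.zeros(spec.n_layers)
    if len(trees) == 0:
        return out
    h = trees["height_m"].to_numpy(float)
    b = trees["biomass_t"].to_numpy(float)
    if np.any(h <= 0):
        raise ValueError("tree heights must be positive")
    if np.any(h > spec.ceiling):
        raise ValueError("tree height exceeds the profile ceiling")
    edges = np.arange(spec.n_layers + 1) * spec.dh
    overlap = np.clip(np.minimum(edges[None, 1:], h[:, None]) - edges[None, :-1],
                      0.0, None)
    out = (b[:, None] * overlap / h[:, None]).sum(axis=0)
    return out / spec.cell_area_ha


def tile_cells(trees: pd.DataFrame, cell_edge: float,
               plot_edge: float = 200.0, patch_edge: float = 20.0) -> pd.DataFrame:
    """Assign each tree's patch to a cell of the regular ``cell_edge`` tiling.

    Expects ``patch_x`` / ``patch_y`` columns (patch grid indices within the
    plot). Returns a copy with integer ``cell_x`` / ``cell_y`` columns.
    """
    if round(plot_edge / cell_edge, 9) % 1:
        raise ValueError("cell_edge must divide plot_edge")
    per_cell = int(round(cell_edge / patch_edge))
    nside = int(round(plot_edge / patch_edge))
    out = trees.copy()
    px = out["patch_x"].to_numpy(int)
    py = out["patch_y"].to_numpy(int)
    if px.size and (px.min() < 0 or px.max() >= nside
                    or py.min() < 0 or py.max() >= nside):
        raise ValueError("patch coordinates outside plot bounds")
    out["cell_x"] = px // per_cell
    out["cell_y"] = py // per_cell
    return out


def _aggregate_layers(fine: np.ndarray, dh_fine: float, dh: float) -> np.ndarray:
    """Sum nested fine layers into coarse layers of width ``dh``."""
    factor = round(dh / dh_fine, 9)
    if factor % 1:
        raise ValueError(f"dh = {dh} is not a multiple of the recorded "
                         f"profile resolution {dh_fine}")
    factor = int(factor)
    n_coarse = fine.shape[-1] // factor
    return fine.reshape(fine.shape[:-1] + (n_coarse, factor)).sum(axis=-1)


def profile_table(result: SuccessionResult, spec: ProfileSpec,
                  drop_year_zero: bool = True) -> pd.DataFrame:
    """Cell-by-year biomass profiles from a simulation result.

    Aggregates the recorded patch-level profiles (at the simulation's native
    ``profile_dh``) into cells of ``spec.cell_edge`` and layers of
    ``spec.dh``; exact because layers and cells nest. Densities in t ha^-1.
    """
    cfg = result.config
    per_cell = int(round(spec.cell_edge / cfg.patch_edge))
    nside = cfg.patches_per_side
    cells_per_side = nside // per_cell
    n_rep, n_years, n_patch, _ = result.profile.shape

    prof = _aggregate_layers(result.profile.astype(float),
                             cfg.profile_dh, spec.dh)
    # patch -> cell index map
    px = np.arange(n_patch) % nside
    py = np.arange(n_patch) // nside
    cell = (py // per_cell) * cells_per_side + px // per_cell
    n_cells = cells_per_side**2
    # sum patch profiles per cell
    cell_prof = np.zeros((n_rep, n_years, n_cells, prof.shape[-1]))
    np.add.at(cell_prof, (slice(None), slice(None), cell), prof)
    cell_prof /= spec.cell_area_ha

    rep_ix, yr_ix, cell_ix = np.meshgrid(
        np.arange(n_rep), np.arange(n_years), np.arange(n_cells), indexing="ij")
    df = pd.DataFrame({
        "replicate": rep_ix.ravel(),
        "year": yr_ix.ravel(),
        "cell_x": (cell_ix % cells_per_side).ravel(),
        "cell_y": (cell_ix // cells_per_side).ravel(),
        "cell_edge_m": spec.cell_edge,
        "dh_m": spec.dh,
    })
    layers = cell_prof.reshape(-1, prof.shape[-1])
    for i, name in enumerate(layer_columns(spec)):
        df[name] = layers[:, i]
    if drop_year_zero:
        df = df[df["year"] > 0].reset_index(drop=True)
    return df
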