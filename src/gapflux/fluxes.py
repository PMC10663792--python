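"""Cell-level carbon stocks, fluxes and turnover time.

Aggregates per-tree (or per-patch) GPP/NPP and biomass to grid cells,
computes the carbon turnover time tau = AGB / GPP (years), and labels each
stand-year as disturbed (succession, year < 160) or mature (equilibrium,
year >= 160). The combined stand-year table — fluxes plus the layered
biomass profile — is the single input to the relationship statistics and
the boosted-tree analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gap_model import SuccessionResult
from .profile import ProfileSpec, profile_table, layer_columns

__all__ = [
    "EQUILIBRIUM_YEAR",
    "aggregate_fluxes",
    "turnover_time",
    "categorize_by_age",
    "stand_year_table",
]

#: first year counted as mature / in equilibrium
EQUILIBRIUM_YEAR = 160


def aggregate_fluxes(trees: pd.DataFrame, area_ha: float) -> tuple[float, float, float]:
    """Sum tree biomass and fluxes of one cell-year into per-ha densities.

    Returns ``(agb, gpp, npp)`` in t ha^-1 (yr^-1 for the fluxes); an empty
    table gives zeros.
    """
    if area_ha <= 0:
        raise ValueError("cell area must be positive")
    if len(trees) == 0:
        return 0.0, 0.0, 0.0
    return (float(trees["biomass_t"].sum() / area_ha),
            float(trees["gpp_t_yr"].sum() / area_ha),
            float(trees["npp_t_yr"].sum() / area_ha))


def turnover_time(agb, gpp):
    """Carbon turnover time tau = AGB / GPP (years).

    Zero biomass gives tau = 0; zero GPP with positive biomass is undefined
    and returned as NaN — such records are flagged and excluded from tau
    analyses rather than raising.
    """
    agb_arr = np.asarray(agb, dtype=float)
    gpp_arr = np.asarray(gpp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(gpp_arr > 0, agb_arr / np.where(gpp_arr > 0, gpp_arr, 1.0),
                       np.where(agb_arr == 0, 0.0, np.nan))
    if np.isscalar(agb) and np.isscalar(gpp):
        return float(tau)
    return tau


def categorize_by_age(year) -> np.ndarray | str:
    """Disturbed (succession) before year 160, mature from year 160 on.

    The boundary year itself counts as mature.
    """
    year_arr = np.asarray(year)
    cat = np.where(year_arr >= EQUILIBRIUM_YEAR, "mature", "disturbed")
    if np.isscalar(year):
        return str(cat)
    return cat


def stand_year_table(result: SuccessionResult, spec: ProfileSpec,
                     drop_year_zero: bool = True) -> pd.DataFrame:
    """Stand-year records at the resolution of ``spec``.

    One row per (replicate, year, cell) with columns ``agb``, ``gpp``,
    ``npp`` (t ha^-1 [yr^-1]), ``tau`` (yr, NaN where GPP = 0), ``category``
    and the layer densities ``b_layer_XX``. AGB equals the layer sum by
    construction.
    """
    cfg = result.config
    df = profile_table(result, spec, drop_year_zero=drop_year_zero)
    cols = layer_columns(spec)
    df.insert(6, "agb", df[cols].to_numpy().sum(axis=1))

    per_cell = int(round(spec.cell_edge / cfg.patch_edge))
    nside = cfg.patches_per_side
    cells_per_side = nside // per_cell
    n_cells = cells_per_side**2
    px = np.arange(cfg.n_patches) % nside
    py = np.arange(cfg.n_patches) // nside
    cell = (py // per_cell) * cells_per_side + px // per_cell

    n_rep, n_years, _ = result.gpp.shape
    gpp = np.zeros((n_rep, n_years, n_cells))
    npp = np.zeros((n_rep, n_years, n_cells))
    np.add.at(gpp, (slice(None), slice(None), cell), result.gpp)
    np.add.at(npp, (slice(None), slice(None), cell), result.npp)
    area = spec.cell_area_ha
    flat = np.ravel_multi_index(
        (df["replicate"].to_numpy(), df["year"].to_numpy(),
         (df["cell_y"].to_numpy() * cells_per_side + df["cell_x"].to_numpy())),
        (n_rep, n_years, n_cells))
    df.insert(7, "gpp", gpp.reshape(-1)[flat] / area)
    df.insert(8, "npp", npp.reshape(-1)[flat] / area)
    df.insert(9, "tau", turnover_time(df["agb"].to_numpy(), df["gpp"].to_numpy()))
    df.insert(10, "category", categorize_by_age(df["year"].to_numpy()))
    return df
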