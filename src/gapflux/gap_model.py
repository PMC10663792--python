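"""Individual-based forest gap model.

Simulates succession of a tropical forest from bare ground on a landscape of
20 x 20 m patches. Within a patch, trees compete for light: the vertical
leaf-area distribution of all crowns attenuates incoming radiation
(Lambert-Beer), each tree assimilates carbon according to a saturating light
response evaluated at its crown top, grows by allocating net production to
stem biomass, and dies through background, stress, crowding or treefall
mortality. Establishment from a constant seed rain closes the cycle and
produces the classic gap-dynamics mosaic in equilibrium.

The engine is array-based: one :class:`Landscape` holds all trees of one
replicate plot in flat numpy arrays. A thin object layer (:class:`Tree`,
:class:`Patch`) is provided for inspection and testing of single patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PFTParams, SimConfig, default_pfts

__all__ = [
    "Tree",
    "Patch",
    "Landscape",
    "SuccessionResult",
    "allometry",
    "dbh_from_biomass",
    "compute_light_profile",
    "tree_annual_fluxes",
    "annual_step",
    "run_succession",
]


# ---------------------------------------------------------------------------
# allometry


def allometry(pft: PFTParams, dbh):
    """Height, crown diameter, leaf area and above-ground biomass at ``dbh``.

    Accepts a scalar or array stem diameter (m). Biomass follows the
    geometric stem-volume form ``(pi/4) * D^2 * H * form * rho``.

    Raises
    ------
    ValueError
        if any diameter is non-positive or exceeds the PFT's ``d_max``.
    """
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be positive")
    if np.any(d > pft.d_max):
        raise ValueError(f"dbh exceeds d_max = {pft.d_max} m")
    height = pft.h0 * d**pft.h1
    crown_diameter = pft.c0 * d
    leaf_area = pft.la0 * d**pft.la1
    biomass = (math.pi / 4.0) * d**2 * height * pft.form * pft.rho
    if np.isscalar(dbh):
        return float(height), float(crown_diameter), float(leaf_area), float(biomass)
    return height, crown_diameter, leaf_area, biomass


def dbh_from_biomass(pft: PFTParams, biomass):
    """Invert the biomass allometry: ``B = (pi/4) h0 form rho D^(2+h1)``."""
    b = np.asarray(biomass, dtype=float)
    coef = (math.pi / 4.0) * pft.h0 * pft.form * pft.rho
    d = (b / coef) ** (1.0 / (2.0 + pft.h1))
    return float(d) if np.isscalar(biomass) else d


# ---------------------------------------------------------------------------
# object layer


@dataclass
class Tree:
    """One individual; height, crown and biomass derive from (pft, dbh)."""

    pft_id: int
    dbh: float
    height: float
    crown_diameter: float
    leaf_area: float
    biomass: float
    gpp_year: float = 0.0
    npp_year: float = 0.0
    patch_index: int = 0

    @classmethod
    def from_dbh(cls, pft: PFTParams, dbh: float, patch_index: int = 0) -> "Tree":
        h, cd, la, b = allometry(pft, dbh)
        return cls(pft.pft_id, dbh, h, cd, la, b, patch_index=patch_index)


@dataclass
class Patch:
    """A 20 x 20 m competition unit: its trees and vertical light profile."""

    index: int
    trees: list[Tree] = field(default_factory=list)
    edge: float = 20.0
    light_profile: np.ndarray | None = None


def _crown_layer_span(height, f_crown, layer_width, n_layers):
    """Inclusive (lo, hi) light-layer indices occupied by a crown."""
    height = np.asarray(height, dtype=float)
    top = np.ceil(height / layer_width).astype(np.int64) - 1
    top = np.clip(top, 0, n_layers - 1)
    base = np.floor(height * (1.0 - np.asarray(f_crown)) / layer_width).astype(np.int64)
    base = np.minimum(base, top)
    return base, top


def compute_light_profile(patch: Patch, k: float, pfts: list[PFTParams] | None = None,
                          layer_width: float = 0.5,
                          ceiling: float = 100.0) -> np.ndarray:
    """Relative light per vertical layer of one patch.

    Layer ``l`` spans ``[l*w, (l+1)*w)``; its light is attenuated by the
    summed leaf area of all crown segments in layers strictly above it:
    ``I(l) = exp(-k * LAI_above(l))``. Crowns occupy the top ``f_crown``
    fraction of tree height with uniform leaf-area density.
    """
    pfts = default_pfts() if pfts is None else pfts
    by_id = {p.pft_id: p for p in pfts}
    n_layers = int(round(ceiling / layer_width))
    la_layer = np.zeros(n_layers)
    area = patch.edge**2
    for t in patch.trees:
        p = by_id[t.pft_id]
        lo, hi = _crown_layer_span(t.height, p.f_crown, layer_width, n_layers)
        la_layer[lo:hi + 1] += t.leaf_area / (hi - lo + 1)
    # leaf area strictly above each layer, divided by patch ground area
    lai_above = np.concatenate([np.cumsum(la_layer[::-1])[::-1][1:], [0.0]]) / area
    return np.exp(-k * lai_above)


def tree_annual_fluxes(tree: Tree, pft: PFTParams, light: float) -> tuple[float, float]:
    """Annual GPP and NPP of one tree at relative light ``light`` at crown top.

    The leaf-level rate follows the saturating response
    ``p(I) = alpha*I*pmax / (alpha*I + pmax)``; GPP scales it by the tree's
    leaf area, and NPP subtracts maintenance respiration (proportional to
    biomass) and a fixed growth-respiration fraction. NPP may be negative
    (carbon stress); growth allocation floors it at zero.
    """
    if not 0.0 <= light <= 1.0:
        raise ValueError("relative light must lie in [0, 1]")
    denom = pft.alpha * light + pft.pmax
    p = pft.alpha * light * pft.pmax / denom if denom > 0 else 0.0
    gpp = p * tree.leaf_area
    npp = (1.0 - pft.r_growth) * (gpp - pft.r_main * tree.biomass)
    tree.gpp_year = gpp
    tree.npp_year = npp
    return gpp, npp


# ---------------------------------------------------------------------------
# array engine


class _PFTTable:
    """Struct-of-arrays view of the PFT list, indexed by dense pft index."""

    def __init__(self, pfts: list[PFTParams]):
        self.pfts = pfts
        self.id = np.array([p.pft_id for p in pfts])
        for name in ("h0", "h1", "c0", "f_crown", "la0", "la1", "rho", "form",
                     "alpha", "pmax", "r_main", "r_growth", "m_b", "d_max",
                     "i_seed", "i_min"):
            setattr(self, name, np.array([getattr(p, name) for p in pfts]))
        self.b_coef = (math.pi / 4.0) * self.h0 * self.form * self.rho


class Landscape:
    """All trees of one replicate plot, in flat arrays.

    Attributes are parallel arrays over the current tree population:
    ``pft`` (dense PFT index), ``dbh``, ``height``, ``crown_d``,
    ``leaf_area``, ``biomass``, ``patch``, ``stress`` (consecutive years of
    low diameter increment), ``gpp``, ``npp`` (current-year fluxes) and
    ``stem_inc`` (current-year stem biomass increment).
    """

    def __init__(self, config: SimConfig, pfts: list[PFTParams] | None = None):
        self.config = config
        self.pft_table = _PFTTable(default_pfts() if pfts is None else pfts)
        self.n_patches = config.n_patches
        self.pft = np.empty(0, dtype=np.int64)
        self.patch = np.empty(0, dtype=np.int64)
        self.stress = np.empty(0, dtype=np.int64)
        for name in ("dbh", "height", "crown_d", "leaf_area", "biomass",
                     "vigour", "gpp", "npp", "stem_inc"):
            setattr(self, name, np.empty(0))
        self.year = 0

    @property
    def n_trees(self) -> int:
        return self.pft.size

    def _derive(self, idx=slice(None)) -> None:
        """Recompute height/crown/leaf area from dbh for the given trees."""
        T = self.pft_table
        p = self.pft[idx]
        d = self.dbh[idx]
        self.height[idx] = T.h0[p] * d ** T.h1[p]
        self.crown_d[idx] = T.c0[p] * d
        self.leaf_area[idx] = T.la0[p] * d ** T.la1[p]

    def add_trees(self, pft_idx: np.ndarray, dbh: np.ndarray,
                  patch: np.ndarray, vigour: np.ndarray | None = None) -> None:
        T = self.pft_table
        n = pft_idx.size
        if vigour is None:
            vigour = np.ones(n)
        self.vigour = np.concatenate([self.vigour, vigour])
        self.pft = np.concatenate([self.pft, pft_idx])
        self.patch = np.concatenate([self.patch, patch])
        self.stress = np.concatenate([self.stress, np.zeros(n, dtype=np.int64)])
        self.dbh = np.concatenate([self.dbh, dbh])
        h = T.h0[pft_idx] * dbh ** T.h1[pft_idx]
        b = T.b_coef[pft_idx] * dbh ** (2.0 + T.h1[pft_idx])
        self.height = np.concatenate([self.height, h])
        self.crown_d = np.concatenate([self.crown_d, T.c0[pft_idx] * dbh])
        self.leaf_area = np.concatenate(
            [self.leaf_area, T.la0[pft_idx] * dbh ** T.la1[pft_idx]])
        self.biomass = np.concatenate([self.biomass, b])
        zeros = np.zeros(n)
        self.gpp = np.concatenate([self.gpp, zeros])
        self.npp = np.concatenate([self.npp, zeros.copy()])
        self.stem_inc = np.concatenate([self.stem_inc, zeros.copy()])

    def _keep(self, mask: np.ndarray) -> None:
        for name in ("pft", "patch", "stress", "dbh", "height", "crown_d",
                     "leaf_area", "biomass", "vigour", "gpp", "npp", "stem_inc"):
            setattr(self, name, getattr(self, name)[mask])

    # -- per-patch summaries -------------------------------------------------

    def patch_sums(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.patch, weights=values, minlength=self.n_patches)

    def patch_profile(self, dh: float) -> np.ndarray:
        """Per-patch vertical biomass profile (t per layer), biomass spread
        uniformly over each tree's height."""
        n_layers = int(round(self.config.ceiling / dh))
        prof = np.zeros((self.n_patches, n_layers + 1))
        if self.n_trees == 0:
            return prof[:, :n_layers]
        h = self.height
        b = self.biomass
        full = np.floor(h / dh).astype(np.int64)          # count of full layers
        dens = b / h                                       # t per metre of stem
        # full layers [0, full): difference-array trick, cumsum below
        diff = np.zeros((self.n_patches, n_layers + 2))
        np.add.at(diff, (self.patch, np.zeros_like(full)), dens * dh)
        np.add.at(diff, (self.patch, full), -dens * dh)
        prof_full = np.cumsum(diff, axis=1)[:, :n_layers + 1]
        # partial top layer
        frac = h - full * dh
        top = np.minimum(full, n_layers - 1)
        np.add.at(prof, (self.patch, top), dens * frac)
        prof += prof_full
        return prof[:, :n_layers]

    def tree_table(self, replicate: int, year: int) -> pd.DataFrame:
        T = self.pft_table
        nside = self.config.patches_per_side
        return pd.DataFrame({
            "replicate": replicate,
            "year": year,
            "patch_x": self.patch % nside,
            "patch_y": self.patch // nside,
            "pft": T.id[self.pft],
            "dbh_m": self.dbh,
            "height_m": self.height,
            "biomass_t": self.biomass,
            "gpp_t_yr": self.gpp,
            "npp_t_yr": self.npp,
        })


def _light_for_trees(land: Landscape):
    """Relative light at each tree's crown top plus per-patch floor light."""
    cfg = land.config
    T = land.pft_table
    w = cfg.light_layer_width
    n_layers = int(round(cfg.ceiling / w))
    area = cfg.patch_edge**2
    if land.n_trees == 0:
        return np.empty(0), np.ones(land.n_patches)
    lo, hi = _crown_layer_span(land.height, T.f_crown[land.pft], w, n_layers)
    per_layer = land.leaf_area / (hi - lo + 1)
    diff = np.zeros((land.n_patches, n_layers + 2))
    np.add.at(diff, (land.patch, lo), per_layer)
    np.add.at(diff, (land.patch, hi + 1), -per_layer)
    la_layer = np.cumsum(diff, axis=1)[:, :n_layers]
    # suffix[l] = leaf area in layers >= l; suffix has n_layers+1 entries
    suffix = np.zeros((land.n_patches, n_layers + 1))
    suffix[:, :n_layers] = np.cumsum(la_layer[:, ::-1], axis=1)[:, ::-1]
    light_tree = np.exp(-cfg.k_ext * suffix[land.patch, hi + 1] / area)
    floor_light = np.exp(-cfg.k_ext * suffix[:, 0] / area)
    return light_tree, floor_light


def _fluxes_and_growth(land: Landscape, light_tree: np.ndarray) -> None:
    T = land.pft_table
    p_idx = land.pft
    alpha = T.alpha[p_idx]
    pmax = T.pmax[p_idx]
    denom = alpha * light_tree + pmax
    rate = np.where(denom > 0, alpha * light_tree * pmax / denom, 0.0)
    # persistent per-tree vigour spreads growth rates within a PFT and
    # desynchronizes cohort senescence
    land.gpp = rate * land.leaf_area * land.vigour
    land.npp = (1.0 - T.r_growth[p_idx]) * (land.gpp - T.r_main[p_idx] * land.biomass)
    # stem allocation: positive NPP scaled by a size limiter vanishing at d_max
    limiter = np.clip(1.0 - (land.dbh / T.d_max[p_idx]) ** 2, 0.0, 1.0)
    land.stem_inc = limiter * np.maximum(land.npp, 0.0)
    new_biomass = land.biomass + land.stem_inc
    new_dbh = (new_biomass / T.b_coef[p_idx]) ** (1.0 / (2.0 + T.h1[p_idx]))
    rel_inc = (new_dbh - land.dbh) / land.dbh
    land.stress = np.where(rel_inc < land.config.stress_rel_increment,
                           land.stress + 1, 0)
    land.biomass = new_biomass
    land.dbh = new_dbh
    land._derive()


def _mortality(land: Landscape, rng: np.random.Generator) -> None:
    cfg = land.config
    T = land.pft_table
    area = cfg.patch_edge**2
    crown_area = (math.pi / 4.0) * land.crown_d**2
    cca = land.patch_sums(crown_area) / area
    m_crowd = np.maximum(
        0.0, 1.0 - cfg.cca_max / np.maximum(cca[land.patch], 1e-12))
    m_stress = np.where(land.stress >= cfg.stress_years, cfg.m_stress, 0.0)
    p_die = 1.0 - (1.0 - T.m_b[land.pft]) * (1.0 - m_stress) * (1.0 - m_crowd)
    die = rng.random(land.n_trees) < p_die

    # treefall: dying tall trees fall into a neighbouring patch and damage
    # smaller trees there with probability scaled by crown area
    fallers = np.flatnonzero(die & (land.height > cfg.treefall_height))
    if fallers.size:
        falls = fallers[rng.random(fallers.size) < cfg.p_treefall]
        nside = cfg.patches_per_side
        offsets = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])
        for i in falls:
            dx, dy = offsets[rng.integers(4)]
            px = land.patch[i] % nside + dx
            py = land.patch[i] // nside + dy
            if not (0 <= px < nside and 0 <= py < nside):
                continue  # falls out of the plot
            target = py * nside + px
            victims = np.flatnonzero(
                (land.patch == target) & (land.height < land.height[i]) & ~die)
            if victims.size:
                p_hit = cfg.p_damage * min(1.0, crown_area[i] / area)
                die[victims[rng.random(victims.size) < p_hit]] = True
    land._keep(~die)


def _establishment(land: Landscape, floor_light: np.ndarray,
                   rng: np.random.Generator) -> None:
    cfg = land.config
    T = land.pft_table
    expected = T.i_seed * cfg.patch_area_ha
    new_pft, new_patch = [], []
    for k in range(T.id.size):
        open_patches = np.flatnonzero(floor_light >= T.i_min[k])
        if open_patches.size == 0 or expected[k] == 0:
            continue
        counts = rng.poisson(expected[k], size=open_patches.size)
        tot = int(counts.sum())
        if tot:
            new_pft.append(np.full(tot, k, dtype=np.int64))
            new_patch.append(np.repeat(open_patches, counts))
    if new_pft:
        pfts = np.concatenate(new_pft)
        sig = cfg.sigma_vigour
        vig = np.exp(rng.normal(-0.5 * sig**2, sig, pfts.size))
        land.add_trees(pfts, np.full(pfts.size, cfg.d_start),
                       np.concatenate(new_patch), vig)


def annual_step(land: Landscape, rng: np.random.Generator) -> Landscape:
    """Advance the landscape by one year, in place.

    Order of processes: light competition, per-tree fluxes and growth,
    mortality (background + stress + crowding + treefall), establishment.
    Returns the landscape for chaining.
    """
    light_tree, floor_light = _light_for_trees(land)
    if land.n_trees:
        _fluxes_and_growth(land, light_tree)
        _mortality(land, rng)
        # canopy changed through mortality; recompute floor light for recruits
        _, floor_light = _light_for_trees(land)
    _establishment(land, floor_light, rng)
    land.year += 1
    return land


# ---------------------------------------------------------------------------
# succession runs


@dataclass
class SuccessionResult:
    """Output of :func:`run_succession`.

    Per-patch annual series are stored as arrays of shape
    ``(n_replicates, years + 1, n_patches)``; the biomass profile adds a
    trailing layer axis at the configured ``profile_dh``. Year 0 is the bare
    ground state (all zeros). Fluxes recorded for year ``t`` are the fluxes
    computed by all trees alive during step ``t`` (including trees that died
    that year); stocks are the post-step standing state.
    """

    config: SimConfig
    pfts: list[PFTParams]
    agb: np.ndarray          # t per patch
    gpp: np.ndarray          # t yr^-1 per patch
    npp: np.ndarray          # t yr^-1 per patch
    profile: np.ndarray      # t per patch per layer
    trees: pd.DataFrame | None = None

    @property
    def years(self) -> int:
        return self.config.years

    def plot_totals(self) -> pd.DataFrame:
        """Per-replicate plot-level AGB / GPP / NPP densities (per ha)."""
        area_ha = self.config.plot_edge**2 / 10_000.0
        n_rep, n_years, _ = self.agb.shape
        rep, year = np.meshgrid(np.arange(n_rep), np.arange(n_years), indexing="ij")
        return pd.DataFrame({
            "replicate": rep.ravel(),
            "year": year.ravel(),
            "agb": self.agb.sum(axis=2).ravel() / area_ha,
            "gpp": self.gpp.sum(axis=2).ravel() / area_ha,
            "npp": self.npp.sum(axis=2).ravel() / area_ha,
        })


def run_succession(config: SimConfig,
                   pfts: list[PFTParams] | None = None) -> SuccessionResult:
    """Simulate all replicate plots from bare ground.

    Each replicate draws its random stream from an independent child of the
    root seed, so results do not depend on replicate execution order and the
    whole run is reproducible bit-for-bit from ``config.rng_seed``.
    """
    pfts = default_pfts() if pfts is None else pfts
    n_rep, n_years = config.n_replicates, config.years
    n_layers = int(round(config.ceiling / config.profile_dh))
    shape = (n_rep, n_years + 1, config.n_patches)
    agb = np.zeros(shape)
    gpp = np.zeros(shape)
    npp = np.zeros(shape)
    profile = np.zeros(shape + (n_layers,), dtype=np.float32)
    tree_frames: list[pd.DataFrame] = []
    children = np.random.SeedSequence(config.rng_seed).spawn(n_rep)
    for rep in range(n_rep):
        rng = np.random.default_rng(children[rep])
        land = Landscape(config, pfts)
        for year in range(1, n_years + 1):
            light_tree, floor_light = _light_for_trees(land)
            if land.n_trees:
                _fluxes_and_growth(land, light_tree)
                gpp[rep, year] = land.patch_sums(land.gpp)
                npp[rep, year] = land.patch_sums(land.npp)
                _mortality(land, rng)
                _, floor_light = _light_for_trees(land)
            _establishment(land, floor_light, rng)
            land.year = year
            agb[rep, year] = land.patch_sums(land.biomass)
            profile[rep, year] = land.patch_profile(config.profile_dh)
            if config.record_trees and year % config.tree_record_every == 0:
                tree_frames.append(land.tree_table(rep, year))
    trees = pd.concat(tree_frames, ignore_index=True) if tree_frames else None
    return SuccessionResult(config, pfts, agb, gpp, npp, profile, trees)
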