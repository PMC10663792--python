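"""Parameter sets for the gap model: plant functional types and run configuration.

The simulator represents a species-rich tropical lowland forest with four
plant functional types (PFTs) spanning a pioneer -> shade-tolerant gradient:
pioneers have a steep light demand, fast potential growth and high turnover,
late-successional types tolerate deep shade, grow slowly and live long.
The default parameter set is calibrated so that the emergent stand-level
behaviour matches published field values for Barro Colorado Island (Panama):
equilibrium gross primary production of 52-58.8 t ODM ha^-1 yr^-1, net
primary production near 12 t ODM ha^-1 yr^-1, a productivity peak around
year 100 of succession and an equilibrium phase from about year 160 on.

All masses are tonnes of organic dry matter (t ODM), lengths are metres,
rates are per year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: vertical extent of the simulated canopy space (m); no tree may exceed it
PROFILE_CEILING = 100.0


@dataclass(frozen=True)
class PFTParams:
    """Physiological and allometric parameters of one plant functional type.

    Allometries (stem diameter ``D`` in m):

    * height            ``H  = h0 * D**h1``            (m)
    * crown diameter    ``CD = c0 * D``                (m)
    * leaf area         ``LA = la0 * D**la1``          (m^2)
    * above-ground mass ``B  = (pi/4) * D^2 * H * form * rho``  (t ODM)

    The leaf-level production rate saturates with relative light ``I``:
    ``p(I) = alpha*I*pmax / (alpha*I + pmax)`` (t ODM m^-2 yr^-1).
    """

    pft_id: int
    name: str
    h0: float          # height allometry scale (m at D = 1 m)
    h1: float          # height allometry exponent, 0 < h1 < 1
    c0: float          # crown diameter per stem diameter (dimensionless)
    f_crown: float     # crown length as fraction of tree height
    la0: float         # leaf area at D = 1 m (m^2)
    la1: float         # leaf area allometry exponent
    rho: float         # wood density surrogate (t ODM m^-3)
    form: float        # stem form factor (dimensionless)
    alpha: float       # initial slope of the light response (t ODM m^-2 yr^-1)
    pmax: float        # maximum leaf production rate (t ODM m^-2 yr^-1)
    r_main: float      # maintenance respiration per unit biomass (yr^-1)
    r_growth: float    # growth respiration fraction of assimilate (0-1)
    m_b: float         # background mortality probability (yr^-1)
    d_max: float       # maximum stem diameter (m)
    i_seed: float      # seed ingrowth rate (seedlings ha^-1 yr^-1)
    i_min: float       # minimum relative floor light for establishment (0-1)
    shade_tolerant: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.h1 < 1.0):
            raise ValueError(f"h1 must lie in (0, 1), got {self.h1}")
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if not (0.0 <= self.r_growth < 1.0):
            raise ValueError("r_growth must lie in [0, 1)")
        if not (0.0 < self.i_min <= 1.0):
            raise ValueError("i_min must lie in (0, 1]")
        for name in ("c0", "la0", "rho", "form", "alpha", "pmax", "d_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r_main", "m_b", "i_seed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.h0 * self.d_max**self.h1 > PROFILE_CEILING:
            raise ValueError(
                f"PFT {self.pft_id}: height at d_max exceeds the "
                f"{PROFILE_CEILING} m profile ceiling"
            )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one succession experiment.

    A run simulates ``n_replicates`` independent square plots of edge
    ``plot_edge`` (m) for ``years`` annual steps, starting from bare ground.
    Each plot is tiled into 20 x 20 m patches — the interaction unit for
    light competition, crowding and treefall.
    """

    plot_edge: float = 200.0
    n_replicates: int = 25
    years: int = 320
    rng_seed: int = 0
    k_ext: float = 0.7            # Lambert-Beer light extinction coefficient
    light_layer_width: float = 0.5  # internal light discretization (m)
    patch_edge: float = 20.0
    ceiling: float = PROFILE_CEILING
    d_start: float = 0.03         # stem diameter of new recruits (m)
    sigma_vigour: float = 0.35     # sd of log per-tree growth vigour multiplier
    profile_dh: float = 2.0       # layer width of the recorded biomass profile
    # mortality submodels
    stress_rel_increment: float = 0.003  # relative dbh increment threshold
    stress_years: int = 2                # consecutive years below threshold
    m_stress: float = 0.12                # added mortality when stressed
    cca_max: float = 1.6                 # crown-area sum per patch area above
                                         # which crowding mortality sets in
    treefall_height: float = 20.0        # dying trees taller than this fall
    p_treefall: float = 0.4              # probability that a dying tree falls
    p_damage: float = 0.25                # per-tree damage probability scale
    # output control
    record_trees: bool = False
    tree_record_every: int = 1

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.plot_edge % self.patch_edge:
            raise ValueError("plot_edge must be divisible by the patch edge")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ceiling % self.profile_dh:
            raise ValueError("ceiling must be divisible by profile_dh")

    @property
    def patches_per_side(self) -> int:
        return int(round(self.plot_edge / self.patch_edge))

    @property
    def n_patches(self) -> int:
        return self.patches_per_side**2

    @property
    def patch_area_ha(self) -> float:
        return self.patch_edge**2 / 10_000.0


def default_pfts() -> list[PFTParams]:
    """The calibrated four-PFT set for a typical tropical lowland forest.

    PFT 1 is a light-demanding pioneer with balsa-like wood: very high leaf
    area per unit biomass, a heavy respiration burden, and a small maximum
    diameter it reaches within decades, after which stress (senescence)
    mortality removes the cohort. PFTs 2 and 3 are mid-successional canopy
    types; PFT 4 is a shade-tolerant climax type. Along the gradient the
    establishment light threshold and respiration fall while the initial
    slope of the light response (shade-use efficiency) and maximum size
    rise. Values come from calibrating the emergent stand behaviour (see
    the package methods note), not from any single-species dataset.
    """
    return [
        PFTParams(
            pft_id=1, name="pioneer",
            h0=44.0, h1=0.60, c0=12.0, f_crown=0.35,
            la0=926.0, la1=2.0, rho=0.184, form=0.55,
            alpha=0.00691, pmax=0.000973, r_main=0.134, r_growth=0.837,
            m_b=0.019, d_max=0.837, i_seed=984.0, i_min=0.35,
            shade_tolerant=False,
        ),
        PFTParams(
            pft_id=2, name="mid-successional light",
            h0=46.0, h1=0.58, c0=12.0, f_crown=0.40,
            la0=550.0, la1=2.0, rho=0.459, form=0.55,
            alpha=0.0106, pmax=0.00149, r_main=0.0423, r_growth=0.816,
            m_b=0.0318, d_max=0.852, i_seed=513.0, i_min=0.05,
            shade_tolerant=False,
        ),
        PFTParams(
            pft_id=3, name="mid-successional shade",
            h0=47.0, h1=0.56, c0=12.0, f_crown=0.42,
            la0=555.0, la1=2.0, rho=0.662, form=0.55,
            alpha=0.0142, pmax=0.000983, r_main=0.0205, r_growth=0.714,
            m_b=0.034, d_max=1.24, i_seed=313.0, i_min=0.01,
            shade_tolerant=True,
        ),
        PFTParams(
            pft_id=4, name="climax",
            h0=48.0, h1=0.55, c0=11.0, f_crown=0.45,
            la0=571.0, la1=2.0, rho=0.568, form=0.55,
            alpha=0.0168, pmax=0.000874, r_main=0.0156, r_growth=0.731,
            m_b=0.0273, d_max=1.06, i_seed=258.0, i_min=0.003,
            shade_tolerant=True,
        ),
    ]


# ---------------------------------------------------------------------------
# configuration file round-trip


def save_config(path: str | Path, config: SimConfig,
                pfts: list[PFTParams] | None = None) -> None:
    """Write a YAML configuration with [simulation] and [pfts] sections."""
    pfts = default_pfts() if pfts is None else pfts
    doc = {
        "simulation": dataclasses.asdict(config),
        "pfts": [dataclasses.asdict(p) for p in pfts],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[SimConfig, list[PFTParams]]:
    """Read a YAML configuration written by :func:`save_config`.

    Missing sections fall back to the packaged defaults, so a file may
    override only the simulation block.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = doc.get("simulation", {})
    config = SimConfig(**sim)
    if "pfts" in doc:
        pfts = [PFTParams(**p) for p in doc["pfts"]]
    else:
        pfts = default_pfts()
    return config, pfts
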