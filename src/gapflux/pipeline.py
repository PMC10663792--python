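"""End-to-end orchestration: simulate, profile, relate, sweep, write.

``run_pipeline`` chains the full virtual experiment — gap-model succession,
stand-year tables at every resolution combination, biomass-flux
relationship statistics, and the BRT resolution sweep — and writes all
result tables plus a run manifest into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import brt as brt_mod
from .fluxes import stand_year_table
from .gap_model import SuccessionResult, run_succession
from .params import PFTParams, SimConfig, default_pfts
from .profile import CELL_EDGES, LAYER_WIDTHS, ProfileSpec
from .succession_stats import relationship_suite, results_frame

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_tables", "write_csv"]


def write_csv(df: pd.DataFrame, path: Path) -> None:
    """Write a result table with 6 significant digits."""
    df.to_csv(path, index=False, float_format="%.6g")


def build_tables(result: SuccessionResult,
                 cell_edges=CELL_EDGES,
                 dhs=LAYER_WIDTHS) -> dict[tuple[float, float], pd.DataFrame]:
    """Stand-year tables for every (cell_edge, dh) resolution combination."""
    return {(float(ce), float(dh)):
            stand_year_table(result, ProfileSpec(dh=float(dh), cell_edge=float(ce)))
            for ce in cell_edges for dh in dhs}


def run_pipeline(out_dir: str | Path,
                 config: SimConfig | None = None,
                 pfts: list[PFTParams] | None = None,
                 seed: int = 0,
                 quick: bool = False,
                 cell_edges=CELL_EDGES,
                 dhs=LAYER_WIDTHS,
                 categories: tuple[str, ...] = ("all", "disturbed", "mature"),
                 n_stages_max: int = 2000,
                 stage_selection: str = "holdout") -> dict:
    """Run the whole virtual experiment and write result tables.

    ``quick`` reduces the problem size (5 replicates, learning rates 0.05
    and 0.01 only) so the full chain finishes on a single CPU in minutes.
    Returns the manifest dictionary; every referenced file exists on disk.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimConfig(rng_seed=seed, n_replicates=5 if quick else 25)
    pfts = default_pfts() if pfts is None else pfts
    learning_rates = (0.05, 0.01) if quick else brt_mod.LEARNING_RATES

    stages = {}

    log.info("stage 1/4: simulating %d replicates x %d years",
             config.n_replicates, config.years)
    result = run_succession(config, pfts)
    totals = result.plot_totals()
    write_csv(totals, out / "plot_totals.csv")
    stages["simulate"] = {"plot_totals": "plot_totals.csv"}

    log.info("stage 2/4: stand-year tables at %d resolution combinations",
             len(cell_edges) * len(dhs))
    tables = build_tables(result, cell_edges, dhs)
    table_files = {}
    for (ce, dh), df in tables.items():
        name = f"stand_years_cell{int(ce)}_dh{int(dh)}.csv"
        write_csv(df, out / name)
        table_files[f"cell{int(ce)}_dh{int(dh)}"] = name
    stages["profile"] = table_files

    log.info("stage 3/4: biomass-flux relationships at the coarsest cell")
    rel_key = (max(ce for ce, _ in tables), 20.0)
    rel = relationship_suite(tables[rel_key]) if rel_key in tables else []
    write_csv(results_frame(rel), out / "relationships.csv")
    for r in rel:
        slug = f"{r.predictor}_{r.target}".replace(" ", "_").replace("-", "_")
        write_csv(r.scatter, out / f"scatter_{slug}.csv")
    stages["relationships"] = {"summary": "relationships.csv"}

    log.info("stage 4/4: BRT resolution sweep")
    sweep = brt_mod.resolution_sweep(tables, seed=seed,
                                     categories=categories,
                                     learning_rates=learning_rates,
                                     n_stages_max=n_stages_max,
                                     stage_selection=stage_selection)
    write_csv(sweep, out / "brt_sweep.csv")
    stages["brt"] = {"sweep": "brt_sweep.csv"}

    manifest = {
        "seed": seed,
        "quick": quick,
        "config": dataclasses.asdict(config),
        "pfts": [dataclasses.asdict(p) for p in pfts],
        "stages": stages,
        "runtime_s": round(time.time() - t0, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    missing = [f for st in stages.values() for f in st.values()
               if not (out / f).stat().st_size > 0]
    if missing:
        raise RuntimeError(f"manifest references empty outputs: {missing}")
    return manifest
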