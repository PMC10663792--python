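"""Shared fixtures: small simulation runs reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from gapflux import SimConfig, default_pfts, run_succession
from gapflux.params import PFTParams


@pytest.fixture(scope="session")
def small_run():
    """One 100 x 100 m replicate over 60 years — fast structural checks."""
    cfg = SimConfig(n_replicates=1, years=60, plot_edge=100.0, rng_seed=11)
    return run_succession(cfg)


@pytest.fixture(scope="session")
def calibrated_run():
    """Five replicate 200 x 200 m plots over the full 320-year succession.

    This is the study-scale run shared by the acceptance tests; building it
    once keeps the suite within a sensible runtime.
    """
    cfg = SimConfig(n_replicates=5, years=320, rng_seed=42)
    return run_succession(cfg)


def single_pft(**overrides) -> list[PFTParams]:
    """A one-PFT parameter set for isolated-process tests."""
    base = dict(
        pft_id=1, name="test", h0=40.0, h1=0.5, c0=10.0, f_crown=0.4,
        la0=400.0, la1=2.0, rho=0.4, form=0.5, alpha=0.01, pmax=0.002,
        r_main=0.02, r_growth=0.5, m_b=0.0, d_max=1.0, i_seed=0.0,
        i_min=0.05, shade_tolerant=False,
    )
    base.update(overrides)
    return [PFTParams(**base)]
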