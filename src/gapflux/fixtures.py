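"""Synthetic stand and regression fixtures with known statistical structure.

These generators stand in for simulator output where the profile and
regression stages need inputs whose ground truth is known analytically:
tree lists with prescribed height/biomass distributions, and feature-target
tables built from a known generating function plus optional noise, together
with the analytic ceiling on the achievable validation R^2,
``var(f) / (var(f) + var(noise))``.

Laplace noise is first-class here because the boosting loss is Laplace:
``Laplace(b)`` has variance ``2 b^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StandSpec", "RegressionSpec", "make_stand", "make_regression_fixture"]


@dataclass(frozen=True)
class StandSpec:
    """Recipe for one synthetic tree list.

    ``height_dist`` is ``("uniform", lo, hi)`` or ``("lognormal", mu, sigma)``
    (the latter truncated to (0, 100]); ``biomass_coupling`` maps height to
    expected biomass: ``("power", a, b)`` gives ``B = a * H**b`` with a
    lognormal multiplicative scatter of ``biomass_cv``.
    """

    n_trees: int = 100
    height_dist: tuple = ("uniform", 5.0, 45.0)
    biomass_coupling: tuple = ("power", 0.002, 2.0)
    biomass_cv: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be non-negative")
        if self.biomass_cv < 0:
            raise ValueError("biomass_cv must be non-negative")


def make_stand(spec: StandSpec) -> pd.DataFrame:
    """Reproducible tree table (columns as the simulator's tree output)."""
    rng = np.random.default_rng(spec.rng_seed)
    kind = spec.height_dist[0]
    if kind == "uniform":
        _, lo, hi = spec.height_dist
        if not (0 < lo <= hi <= 100.0):
            raise ValueError("uniform height bounds must lie in (0, 100]")
        h = rng.uniform(lo, hi, spec.n_trees)
    elif kind == "lognormal":
        _, mu, sigma = spec.height_dist
        h = rng.lognormal(mu, sigma, spec.n_trees)
        # truncate by resampling out-of-range draws
        bad = (h <= 0) | (h > 100.0)
        while bad.any():
            h[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
            bad = (h <= 0) | (h > 100.0)
    else:
        raise ValueError(f"unknown height distribution {kind!r}")
    _, a, b = spec.biomass_coupling
    scatter = (rng.lognormal(-0.5 * np.log(1 + spec.biomass_cv**2)**1,
                             np.sqrt(np.log(1 + spec.biomass_cv**2)),
                             spec.n_trees)
               if spec.biomass_cv > 0 else np.ones(spec.n_trees))
    biomass = a * h**b * scatter
    return pd.DataFrame({
        "replicate": 0,
        "year": 0,
        "patch_x": 0,
        "patch_y": 0,
        "pft": 0,
        "dbh_m": np.nan,
        "height_m": h,
        "biomass_t": biomass,
        "gpp_t_yr": 0.0,
        "npp_t_yr": 0.0,
    })


@dataclass(frozen=True)
class RegressionSpec:
    """Recipe for a feature-target table with a known generating function.

    ``function`` selects ``f``: "linear" (weighted feature sum),
    "saturating" (Michaelis-Menten in the first feature plus a linear rest)
    or "layered-sum" (sum of a feature subset — the idealized profile-to-
    flux map). ``noise`` is ("none",), ("gaussian", sd) or ("laplace", b).
    """

    n_rows: int = 2000
    n_features: int = 5
    function: str = "layered-sum"
    noise: tuple = ("none",)
    rng_seed: int = 0
    weights: tuple | None = None

    def noise_var(self) -> float:
        kind = self.noise[0]
        if kind == "none":
            return 0.0
        if kind == "gaussian":
            return float(self.noise[1])**2
        if kind == "laplace":
            return 2.0 * float(self.noise[1])**2
        raise ValueError(f"unknown noise family {kind!r}")


def _generating_function(spec: RegressionSpec, X: np.ndarray) -> np.ndarray:
    if spec.function == "linear":
        w = (np.asarray(spec.weights) if spec.weights is not None
             else np.linspace(1.0, 0.2, spec.n_features))
        return X @ w
    if spec.function == "saturating":
        return 5.0 * X[:, 0] / (1.0 + X[:, 0]) + 0.3 * X[:, 1:].sum(axis=1)
    if spec.function == "layered-sum":
        k = max(1, spec.n_features // 2)
        return X[:, :k].sum(axis=1)
    raise ValueError(f"unknown generating function {spec.function!r}")


def make_regression_fixture(spec: RegressionSpec,
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Features, noisy target and the analytic R^2 ceiling.

    Features are iid lognormal (heavy-tailed and non-negative, like layer
    biomass densities). The ceiling ``var(f) / (var(f) + var(noise))`` uses
    the empirical variance of the generated ``f`` values and the analytic
    noise variance, and bounds the validation R^2 of any regressor trained
    on these features.
    """
    rng = np.random.default_rng(spec.rng_seed)
    X = rng.lognormal(0.0, 0.6, size=(spec.n_rows, spec.n_features))
    f = _generating_function(spec, X)
    kind = spec.noise[0]
    if kind == "none":
        eps = np.zeros(spec.n_rows)
    elif kind == "gaussian":
        eps = rng.normal(0.0, spec.noise[1], spec.n_rows)
    elif kind == "laplace":
        eps = rng.laplace(0.0, spec.noise[1], spec.n_rows)
    else:
        raise ValueError(f"unknown noise family {kind!r}")
    var_f = float(np.var(f))
    denom = var_f + spec.noise_var()
    ceiling = 1.0 if denom == 0 else var_f / denom
    return X, f + eps, float(ceiling)
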