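"""Pairwise biomass-flux relationships over the full succession.

For 4-ha stand-years pooled over all replicates and years, quantifies how
linearly each flux (GPP, NPP, tau) relates to total above-ground biomass
and to the biomass of a single canopy layer (40-60 m by default), using the
squared Pearson correlation — identical to the R^2 of a simple
least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RelationshipResult", "linear_r2", "relationship_suite"]


def linear_r2(x, y) -> float:
    """Squared Pearson correlation of two vectors (= OLS R^2 for a line).

    Requires at least three points and non-constant ``x``; a constant ``y``
    gives 0 by convention. NaN pairs are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; R^2 undefined")
    if np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class RelationshipResult:
    """One predictor-target scatter and its linear R^2."""

    predictor: str
    target: str
    n: int
    r2: float
    scatter: pd.DataFrame = field(repr=False)


def relationship_suite(table: pd.DataFrame,
                       layer_name: str = "b_layer_02",
                       layer_label: str = "biomass 40-60 m",
                       ) -> list[RelationshipResult]:
    """All pairwise relationships for one stand-year table at dh = 20 m.

    Emits total-AGB versus GPP/NPP/tau, and the 40-60 m layer versus
    GPP/NPP/tau/AGB. tau rows with undefined values (GPP = 0) are excluded
    from the tau relationships.
    """
    if layer_name not in table.columns:
        raise ValueError(
            f"column {layer_name!r} missing: table must carry dh = 20 m layers")
    if "dh_m" in table.columns and not (table["dh_m"] == 20.0).all():
        raise ValueError("layer relationships are defined on dh = 20 m tables")
    results = []
    pairs = [("agb", "total AGB", ["gpp", "npp", "tau"]),
             (layer_name, layer_label, ["gpp", "npp", "tau", "agb"])]
    for xcol, xlabel, targets in pairs:
        for ycol in targets:
            sub = table[[xcol, ycol, "year"]].dropna()
            r2 = linear_r2(sub[xcol], sub[ycol])
            scatter = sub.rename(columns={xcol: "x", ycol: "y"})
            results.append(RelationshipResult(
                predictor=xlabel, target=ycol, n=len(sub), r2=r2,
                scatter=scatter))
    return results


def results_frame(results: list[RelationshipResult]) -> pd.DataFrame:
    """Compact (predictor, target, n, r2) table for saving."""
    return pd.DataFrame([{"predictor": r.predictor, "target": r.target,
                          "n": r.n, "r2": r.r2} for r in results])
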