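"""Occurrence thinning, predictor collinearity screening, and scenario clamping.

Three standard preparation steps for correlative distribution modelling:

* thinning presence records to one per species per grid cell, which dampens
  spatial sampling bias from opportunistic collections;
* stepwise elimination of multicollinear predictors by the variance inflation
  factor (VIF), removing the worst offender until all remaining VIFs fall
  below a threshold (default 10);
* clamping scenario predictor values to the training range so models never
  extrapolate into non-analogue conditions, with a per-layer novelty mask
  recording where clamping occurred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_landscape import EnvStack, GridSpec, OccurrenceSet

__all__ = [
    "VariableScreenResult",
    "ClampResult",
    "thin_to_grid",
    "check_min_records",
    "vif_stepwise",
    "training_ranges",
    "clamp_to_range",
]


@dataclass
class VariableScreenResult:
    steps: list[tuple[str, float]]  # (variable removed, VIF at removal)
    retained: list[str]
    threshold: float

    @property
    def eliminated(self) -> list[str]:
        return [name for name, _ in self.steps]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, v, vif) for i, (v, vif) in enumerate(self.steps)],
            columns=["step", "variable", "vif"],
        )


@dataclass
class ClampResult:
    clamped: EnvStack
    novelty_masks: dict[str, np.ndarray]
    ranges: dict[str, tuple[float, float]]

    def novelty_fractions(self) -> dict[str, float]:
        out = {}
        for name, m in self.novelty_masks.items():
            valid = ~self.clamped.mask
            out[name] = float(m[valid].mean()) if valid.any() else 0.0
        return out


def thin_to_grid(
    occ: OccurrenceSet,
    grid: GridSpec,
    land_mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Thin records to at most one per species per grid cell.

    Records outside the grid extent (or off-land when a land mask is given,
    True = land) are dropped with a logged count. The first record per cell
    in input order is kept.
    """
    if len(occ) == 0:
        return OccurrenceSet(occ.species, occ.lon, occ.lat, occ.provenance)
    inside = _inside(occ, grid, land_mask)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} record(s) outside extent/land mask")
    sp = occ.species[inside]
    lon = occ.lon[inside]
    lat = occ.lat[inside]
    row, col = grid.cell_of(lon, lat)
    keep = np.zeros(len(sp), dtype=bool)
    seen: set[tuple[str, int, int]] = set()
    for i in range(len(sp)):
        key = (sp[i], int(row[i]), int(col[i]))
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return OccurrenceSet(sp[keep], lon[keep], lat[keep], occ.provenance)


def _inside(occ: OccurrenceSet, grid: GridSpec, land_mask: np.ndarray | None) -> np.ndarray:
    inside = grid.contains(occ.lon, occ.lat)
    if land_mask is not None:
        row, col = grid.cell_of(occ.lon, occ.lat)
        on_land = land_mask[row, col]
        inside = inside & on_land
    return inside


def check_min_records(occ: OccurrenceSet, minimum: int = 200) -> pd.DataFrame:
    """Per-species record counts against the minimum-sample rule.

    Species failing the minimum are excluded from modelling unless explicitly
    overridden downstream.
    """
    species = occ.species_ids()
    counts = [int((occ.species == s).sum()) for s in species]
    return pd.DataFrame(
        {
            "species": species,
            "n_records": counts,
            "passed": [c >= minimum for c in counts],
        }
    )


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from regressing j on the other columns (+intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_stepwise(samples: pd.DataFrame, threshold: float = 10.0) -> VariableScreenResult:
    """Iteratively drop the highest-VIF predictor until all VIFs < threshold.

    Constant columns (undefined VIF) are removed first with a warning.
    Ties at infinite VIF (perfect collinearity) drop the later variable in
    input order, so the earlier-listed predictor survives.
    """
    cols = list(samples.columns)
    if len(cols) < 2:
        raise ValueError("need at least two predictors to screen")
    if len(samples) <= len(cols):
        raise ValueError("need more rows than predictors")

    steps: list[tuple[str, float]] = []
    active = list(cols)
    for c in list(active):
        if np.ptp(samples[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant column {c!r} has undefined VIF; removed")
            steps.append((c, np.inf))
            active.remove(c)

    while len(active) >= 2:
        X = samples[active].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(active))])
        vifs[vifs > 1e12] = np.inf  # numerically perfect collinearity
        worst = float(np.nanmax(vifs))
        if worst < threshold:
            break
        # among ties (e.g. a perfectly collinear pair, both effectively
        # infinite), remove the later variable in input order
        if np.isinf(worst):
            tied = np.flatnonzero(np.isinf(vifs))
        else:
            tied = np.flatnonzero(np.isclose(vifs, worst, rtol=1e-9))
        j = int(tied[-1])
        steps.append((active[j], worst))
        active.pop(j)

    return VariableScreenResult(steps=steps, retained=active, threshold=threshold)


def training_ranges(env: EnvStack, variables: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Per-layer min/max over the whole (unmasked) study region."""
    variables = variables or env.layer_names
    valid = ~env.mask
    out = {}
    for v in variables:
        vals = env.layers[v][valid]
        out[v] = (float(np.nanmin(vals)), float(np.nanmax(vals)))
    return out


def clamp_to_range(scenario: EnvStack, ranges: dict[str, tuple[float, float]]) -> ClampResult:
    """Clamp scenario layers to their training ranges; flag novel cells.

    Only layers with a stored range are clamped; asking for a layer without a
    range is an error (a model must never see unclamped projection values).
    """
    missing = [v for v in ranges if v not in scenario.layers]
    if missing:
        raise KeyError(f"scenario stack lacks layer(s): {missing}")
    out = scenario.copy()
    masks: dict[str, np.ndarray] = {}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range for {name!r} has min > max")
        x = out.layers[name]
        novel = (x < lo) | (x > hi)
        novel &= ~out.mask
        out.layers[name] = np.clip(x, lo, hi)
        masks[name] = novel
    return ClampResult(clamped=out, novelty_masks=masks, ranges=dict(ranges))
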