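"""Dominant functional type per cell, area statistics, and transition flows.

"Dominance" is purely about environmental suitability: per grid cell the
candidate PFTs are those passing the stacked presence criterion, and the
label is the candidate with the highest summed occurrence probability
(richness). Cells where no PFT qualifies are labelled "None". Comparing a
present-day and a scenario dominance map yields a square flow matrix of
class transitions (the chord-diagram machinery, without the drawing).

Cell areas use spherical geometry (cos-latitude weighting), since a
geographic grid's cells shrink towards the poles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacking import PFTResult
from .synthetic_landscape import GridSpec

__all__ = [
    "NONE_CLASS",
    "DominanceMap",
    "dominant_pft",
    "cell_areas",
    "area_fractions",
    "transition_flows",
]

NONE_CLASS = "None"
EARTH_RADIUS_KM = 6371.0


@dataclass
class DominanceMap:
    labels: np.ndarray  # object grid of PFT names / "None"; None (obj) where missing
    classes: list[str]  # canonical order incl. "None" last
    ties: np.ndarray  # boolean grid; True where argmax was tied

    @property
    def shape(self):
        return self.labels.shape


def dominant_pft(
    pft_results: list[PFTResult],
    order: list[str] | None = None,
    restrict_to_present: bool = True,
) -> DominanceMap:
    """Label each cell with the qualifying PFT of maximal richness.

    Candidates are PFTs whose presence mask is true in the cell (set
    ``restrict_to_present=False`` for an unrestricted argmax over all PFTs
    wherever at least one qualifies). No qualifying PFT -> "None". Exact
    richness ties are broken by the canonical order and flagged.
    """
    if not pft_results:
        raise ValueError("need at least one PFT result")
    names = [r.pft for r in pft_results]
    if order is None:
        order = list(names)
    if set(order) != set(names):
        raise ValueError("canonical order must name exactly the given PFTs")
    results = {r.pft: r for r in pft_results}
    shape = pft_results[0].richness.shape

    rich = np.stack([results[p].richness for p in order])  # (n_pft, R, C)
    pres = np.stack([results[p].presence for p in order])
    missing = np.isnan(rich).any(axis=0)
    any_present = pres.any(axis=0)

    if restrict_to_present:
        scored = np.where(pres, rich, -np.inf)
    else:
        scored = np.where(np.broadcast_to(any_present, rich.shape), rich, -np.inf)
    best = scored.max(axis=0)
    winner = scored.argmax(axis=0)  # first (canonical-order) among ties
    n_best = (scored == best).sum(axis=0)
    ties = any_present & (n_best > 1) & ~missing

    labels = np.empty(shape, dtype=object)
    labels[...] = NONE_CLASS
    for i, p in enumerate(order):
        labels[(winner == i) & any_present] = p
    labels[missing] = None
    ties[missing] = False
    return DominanceMap(labels=labels, classes=list(order) + [NONE_CLASS], ties=ties)


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell area in km^2 on a sphere (constant per row)."""
    lat_edges = grid.lat_max - np.arange(grid.n_rows + 1) * grid.cell_height
    phi = np.radians(lat_edges)
    band = np.abs(np.sin(phi[:-1]) - np.sin(phi[1:]))  # per row
    dlon = np.radians(grid.cell_width)
    row_area = EARTH_RADIUS_KM**2 * dlon * band
    return np.repeat(row_area[:, None], grid.n_cols, axis=1)


def area_fractions(dom: DominanceMap, cell_area: np.ndarray) -> pd.DataFrame:
    """Area and area fraction per dominance class, over non-missing cells."""
    if np.any(cell_area <= 0):
        raise ValueError("cell areas must be positive")
    rows = []
    valid = dom.labels != None  # noqa: E711 - elementwise object comparison
    total = float(cell_area[valid].sum())
    for cls in dom.classes:
        sel = dom.labels == cls
        a = float(cell_area[sel].sum())
        rows.append((cls, a, a / total if total > 0 else 0.0))
    return pd.DataFrame(rows, columns=["class", "area_km2", "fraction"])


def transition_flows(
    dom_present: DominanceMap,
    dom_future: DominanceMap,
    cell_area: np.ndarray | None = None,
) -> pd.DataFrame:
    """Square flow matrix: entry (i, j) = cells (or area) labelled i now, j then.

    Rows index the present-day class, columns the scenario class; the matrix
    total equals the number (or area) of jointly non-missing cells.
    """
    if dom_present.shape != dom_future.shape:
        raise ValueError("dominance maps are not co-registered")
    classes = dom_present.classes
    if dom_future.classes != classes:
        raise ValueError("dominance maps use different class tables")
    w = np.ones(dom_present.shape) if cell_area is None else cell_area
    valid = (dom_present.labels != None) & (dom_future.labels != None)  # noqa: E711
    mat = pd.DataFrame(0.0, index=classes, columns=classes)
    for i in classes:
        sel_i = valid & (dom_present.labels == i)
        for j in classes:
            mat.loc[i, j] = float(w[sel_i & (dom_future.labels == j)].sum())
    return mat
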