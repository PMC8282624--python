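"""Latitude-altitude structure of predicted presences and range-shift statistics.

Predicted presence cells are projected into (latitude, altitude) space. A
2-D Gaussian kernel density ("density cloud") visualizes suitability
centres; the lower range boundary is operationalized as a low altitude
quantile (default the 5th percentile) of presence cells, so upslope shifts
are simple quantile differences in meters; latitudinal divergence into
separate density centres is detected as multiple prominent modes of a 1-D
kernel density over latitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic_landscape import EnvStack, GridSpec, OccurrenceSet

__all__ = [
    "presence_lat_alt",
    "occurrence_lat_alt",
    "density_cloud",
    "boundary_shift",
    "latitudinal_modes",
]


def presence_lat_alt(
    presence: np.ndarray, elevation: np.ndarray, grid: GridSpec
) -> pd.DataFrame:
    """One row (cell-center latitude, elevation) per present cell."""
    if presence.shape != grid.shape or elevation.shape != grid.shape:
        raise ValueError("inputs are not co-registered with the grid")
    rows, cols = np.nonzero(presence)
    lats = grid.lat_centers()[rows]
    return pd.DataFrame({"lat": lats, "alt": elevation[rows, cols]})


def occurrence_lat_alt(occ: OccurrenceSet, env: EnvStack) -> pd.DataFrame:
    """Record latitudes with the elevation of the containing cell."""
    rows, cols = env.grid.cell_of(occ.lon, occ.lat)
    return pd.DataFrame({"lat": occ.lat, "alt": env.layers["elevation"][rows, cols]})


def density_cloud(
    points: pd.DataFrame,
    bandwidths: tuple[float, float],
    grid_size: tuple[int, int] = (100, 100),
    pad_bandwidths: float = 6.0,
):
    """Gaussian KDE of presences over a regular latitude x altitude grid.

    ``bandwidths`` = (degrees, meters) kernel standard deviations per axis.
    Returns (lat_axis, alt_axis, density) with density normalized so its sum
    times the cell area integrates to ~1 when the domain extends
    ``pad_bandwidths`` kernel widths beyond the data.
    """
    if len(points) < 1:
        raise ValueError("need at least one point")
    bw_lat, bw_alt = bandwidths
    if bw_lat <= 0 or bw_alt <= 0:
        raise ValueError("bandwidths must be positive")
    lat = points["lat"].to_numpy(dtype=float)
    alt = points["alt"].to_numpy(dtype=float)
    lat_axis = np.linspace(
        lat.min() - pad_bandwidths * bw_lat, lat.max() + pad_bandwidths * bw_lat, grid_size[0]
    )
    alt_axis = np.linspace(
        alt.min() - pad_bandwidths * bw_alt, alt.max() + pad_bandwidths * bw_alt, grid_size[1]
    )
    # separable Gaussian kernels, summed over points
    dl = (lat_axis[:, None] - lat[None, :]) / bw_lat
    da = (alt_axis[:, None] - alt[None, :]) / bw_alt
    kl = np.exp(-0.5 * dl**2) / (bw_lat * np.sqrt(2 * np.pi))  # (nl, n)
    ka = np.exp(-0.5 * da**2) / (bw_alt * np.sqrt(2 * np.pi))  # (na, n)
    density = (kl @ ka.T) / len(lat)  # (nl, na)
    return lat_axis, alt_axis, density


def boundary_shift(
    points_present: pd.DataFrame,
    points_scenario: pd.DataFrame,
    quantile: float = 0.05,
) -> float:
    """Upslope shift (m) of the lower range boundary: scenario minus present
    altitude quantile. Positive values mean the boundary moved upslope."""
    if len(points_present) == 0 or len(points_scenario) == 0:
        raise ValueError("both point sets must be non-empty")
    q_now = float(np.quantile(points_present["alt"].to_numpy(dtype=float), quantile))
    q_fut = float(np.quantile(points_scenario["alt"].to_numpy(dtype=float), quantile))
    return q_fut - q_now


def latitudinal_modes(
    points: pd.DataFrame,
    bandwidth: float,
    min_prominence: float = 0.1,
    n_eval: int = 512,
) -> tuple[int, np.ndarray]:
    """Count and locate modes of the latitudinal presence density.

    A mode is a local maximum of the 1-D Gaussian KDE whose peak prominence
    is at least ``min_prominence`` times the global maximum. Two or more
    modes indicate divergence of the suitable range into separate centres.
    """
    lat = points["lat"].to_numpy(dtype=float)
    if lat.size < 2:
        raise ValueError("need at least two points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    axis = np.linspace(lat.min() - 4 * bandwidth, lat.max() + 4 * bandwidth, n_eval)
    d = (axis[:, None] - lat[None, :]) / bandwidth
    dens = np.exp(-0.5 * d**2).sum(axis=1) / (lat.size * bandwidth * np.sqrt(2 * np.pi))
    peaks, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    return len(peaks), axis[peaks]
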