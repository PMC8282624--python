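"""Moving-window fragmentation classification of binary habitat maps.

Within a 3x3 window around each cell two statistics are computed from the
binary (present/absent) map of one functional type:

* ``Pf``  — the proportion of in-window, in-map cells that are present;
* ``Pff`` — the conditional probability that a neighbour of a present cell
  is present, estimated over unordered cardinally adjacent in-window cell
  pairs as 2*FF / (2*FF + FN), where FF counts both-present pairs and FN
  mixed pairs (the ordered-neighbour conditional frequency).

Cells where the type is present are then classified:

    interior      Pf = 1.0
    patch         Pf < 0.4
    transitional  0.4 <= Pf <= 0.6  (boundary values assigned here)
    perforated    Pf > 0.6 and Pf - Pff > 0
    edge          Pf > 0.6 and (Pf - Pff < 0 or Pf = Pff)

Cells absent now but present at a baseline are "area-loss"; absent in both
are "background". Map borders use truncated windows, so Pf stays a true
proportion of observed cells; adjacency is 4-neighbour with both endpoints
inside the window and the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "FragmentationMap",
    "pf_pff",
    "classify",
    "class_summary",
]

#: Class table; integer codes index into this list.
CLASS_NAMES = [
    "interior",
    "patch",
    "transitional",
    "perforated",
    "edge",
    "area-loss",
    "background",
]
CODE = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class FragmentationMap:
    codes: np.ndarray  # int grid over CLASS_NAMES codes; -1 = missing
    pft: str = ""
    scenario: str = ""

    def names(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype=object)
        out[...] = None
        for name, c in CODE.items():
            out[self.codes == c] = name
        return out


def _shifted(padded: np.ndarray, dr: int, dc: int, shape) -> np.ndarray:
    """View of the 1-padded array at offset (dr, dc) from each cell."""
    r0, c0 = 1 + dr, 1 + dc
    return padded[r0 : r0 + shape[0], c0 : c0 + shape[1]]


# the 12 unordered cardinal pairs inside a 3x3 window, as offset pairs
_PAIRS = [((r, c), (r, c + 1)) for r in (-1, 0, 1) for c in (-1, 0)] + [
    ((r, c), (r + 1, c)) for r in (-1, 0) for c in (-1, 0, 1)
]


def pf_pff(binary: np.ndarray, valid: np.ndarray | None = None):
    """Per-cell Pf and Pff over truncated 3x3 windows.

    ``binary`` must contain only 0/1 (NaN allowed for missing cells, which
    are treated as outside the map). Returns (pf, pff) float grids; Pff is
    NaN where no pair involves a present cell.
    """
    b = np.asarray(binary, dtype=float)
    if valid is None:
        valid = ~np.isnan(b)
    finite = b[valid]
    if not np.isin(finite, (0.0, 1.0)).all():
        raise ValueError("fragmentation input must be binary (0/1)")
    shape = b.shape
    bp = np.zeros((shape[0] + 2, shape[1] + 2))
    vp = np.zeros((shape[0] + 2, shape[1] + 2), dtype=bool)
    bp[1:-1, 1:-1] = np.where(valid, b, 0.0)
    vp[1:-1, 1:-1] = valid

    # Pf: window sums of values and of valid-cell counts
    val_sum = np.zeros(shape)
    cnt = np.zeros(shape)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            val_sum += _shifted(bp, dr, dc, shape)
            cnt += _shifted(vp, dr, dc, shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        pf = np.where(cnt > 0, val_sum / cnt, np.nan)

    # Pff: FF / FN tallies over in-window cardinal pairs
    ff = np.zeros(shape)
    fn = np.zeros(shape)
    for (o1, o2) in _PAIRS:
        a = _shifted(bp, *o1, shape)
        bb = _shifted(bp, *o2, shape)
        ok = _shifted(vp, *o1, shape) & _shifted(vp, *o2, shape)
        ff += np.where(ok, a * bb, 0.0)
        fn += np.where(ok, np.abs(a - bb), 0.0)
    denom = 2 * ff + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        pff = np.where(denom > 0, 2 * ff / denom, np.nan)
    pf[~valid] = np.nan
    pff[~valid] = np.nan
    return pf, pff


def classify(
    pf: np.ndarray,
    pff: np.ndarray,
    presence_now: np.ndarray,
    presence_baseline: np.ndarray | None = None,
    pft: str = "",
    scenario: str = "",
) -> FragmentationMap:
    """Apply the fragmentation rules at cells where the type is present.

    ``presence_baseline`` marks where the type occurred at the reference
    date; cells lost since then are labelled "area-loss".
    """
    finite_pf = pf[np.isfinite(pf)]
    if finite_pf.size and (finite_pf.min() < 0 or finite_pf.max() > 1):
        raise ValueError("Pf must lie in [0, 1]")
    shape = pf.shape
    if presence_baseline is None:
        presence_baseline = np.zeros(shape, dtype=bool)
    now = presence_now.astype(bool)
    base = presence_baseline.astype(bool)

    codes = np.full(shape, CODE["background"], dtype=int)
    codes[base & ~now] = CODE["area-loss"]

    diff = pf - pff
    interior = now & (pf == 1.0)
    patch = now & (pf < 0.4)
    transitional = now & (pf >= 0.4) & (pf <= 0.6)
    high = now & (pf > 0.6) & ~interior
    perforated = high & (diff > 0)
    edge = high & ~perforated  # Pf-Pff < 0, Pf = Pff, or Pff undefined
    codes[patch] = CODE["patch"]
    codes[transitional] = CODE["transitional"]
    codes[perforated] = CODE["perforated"]
    codes[edge] = CODE["edge"]
    codes[interior] = CODE["interior"]
    codes[np.isnan(pf) & ~base] = -1
    return FragmentationMap(codes=codes, pft=pft, scenario=scenario)


def class_summary(frag: FragmentationMap, cell_area: np.ndarray | None = None) -> pd.DataFrame:
    """Area and fraction per class over classified (non-background) cells."""
    w = np.ones(frag.codes.shape) if cell_area is None else cell_area
    rows = []
    classified = (frag.codes >= 0) & (frag.codes != CODE["background"])
    total = float(w[classified].sum())
    for name in CLASS_NAMES:
        if name == "background":
            continue
        sel = frag.codes == CODE[name]
        a = float(w[sel].sum())
        rows.append((name, a, a / total if total > 0 else 0.0))
    return pd.DataFrame(rows, columns=["class", "area", "fraction"])
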