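"""Discrimination and calibration metrics for distribution models.

Three metrics drive model selection:

* AUC — probability that a random presence outscores a random absence,
  with ties counted one half (the rank-sum formulation);
* Continuous Boyce Index (CBI) — Spearman correlation between the
  predicted-to-expected presence ratio (P/E) in moving suitability windows
  and the window position; +1 means the model ranks habitat monotonically;
* a calibration statistic in [0, 1]: one minus the occupancy-weighted L1
  distance between mean predicted probability and observed frequency over
  equal-width reliability bins (a scalar summary of the calibration plot).

Models are retained only if every applicable replicate-mean metric reaches a
threshold (default 0.7); the calibration statistic is waived for
presence-only learners, whose scores are relative and not probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationMetrics",
    "auc",
    "boyce_index",
    "calibration_statistic",
    "filter_models",
]


@dataclass(frozen=True)
class EvaluationMetrics:
    auc: float
    cbi: float
    calibration: float | None  # None for presence-only learners
    n_presences: int
    n_absences: int


def auc(scores, labels) -> float:
    """Rank-sum AUC; ties count 1/2. Errors if only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    rank_sum_pos = ranks[labels].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def boyce_index(
    suit_presence,
    suit_background,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce Index.

    Windows of width ``window_frac`` x (suitability range) are slid across the
    range at ``n_windows`` evenly spaced midpoints. Per window, P = fraction
    of presence values inside and E = fraction of background values inside;
    windows with E = 0 are dropped. The index is the Spearman rank
    correlation of P/E against the window midpoint.
    """
    pres = np.sort(np.asarray(suit_presence, dtype=float))
    back = np.sort(np.asarray(suit_background, dtype=float))
    if back.size == 0:
        raise ValueError("background suitabilities must be non-empty")
    if pres.size == 0:
        raise ValueError("presence suitabilities must be non-empty")
    lo = min(pres[0], back[0])
    hi = max(pres[-1], back[-1])
    if hi <= lo:
        raise ValueError("degenerate suitability range")
    width = window_frac * (hi - lo)
    mids = np.linspace(lo, hi, n_windows)

    def frac_in(sorted_vals, a, b):
        return (
            np.searchsorted(sorted_vals, b, side="right")
            - np.searchsorted(sorted_vals, a, side="left")
        ) / sorted_vals.size

    ratios, positions = [], []
    for m in mids:
        a, b = m - width / 2, m + width / 2
        e = frac_in(back, a, b)
        if e == 0:
            continue
        p = frac_in(pres, a, b)
        ratios.append(p / e)
        positions.append(m)
    if len(ratios) < 3:
        raise ValueError("fewer than 3 usable windows; CBI undefined")
    if np.ptp(ratios) == 0:
        return 0.0  # flat P/E profile: no monotone habitat signal
    rho = stats.spearmanr(positions, ratios).statistic
    return float(rho)


def calibration_statistic(probs, labels, n_bins: int = 10) -> float:
    """1 - occupancy-weighted mean |mean predicted - observed| over probability bins.

    Equal-width bins on [0, 1]; empty bins are skipped. Result lies in [0, 1];
    1.0 is perfect calibration.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(float)
    if probs.size == 0:
        raise ValueError("empty input")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    err = 0.0
    for b in range(n_bins):
        sel = idx == b
        n_b = int(sel.sum())
        if n_b == 0:
            continue
        w = n_b / probs.size
        err += w * abs(probs[sel].mean() - labels[sel].mean())
    return float(1.0 - err)


def filter_models(
    metrics: dict[str, EvaluationMetrics],
    threshold: float = 0.7,
    presence_only: set[str] = frozenset(),
) -> list[str]:
    """Learners whose replicate-mean metrics all reach the threshold.

    ``metrics`` maps learner name -> replicate-mean EvaluationMetrics. The
    calibration statistic is not applied to learners in ``presence_only``.
    An empty retained set triggers a warning but is returned as such.
    """
    import warnings

    retained = []
    for name, m in metrics.items():
        vals = [m.auc, m.cbi]
        if name not in presence_only and m.calibration is not None:
            vals.append(m.calibration)
        if all(v >= threshold for v in vals):
            retained.append(name)
    if not retained:
        warnings.warn("no learner passed the selection threshold")
    return retained
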