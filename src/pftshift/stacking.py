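"""Binarization and stacking of species ensembles into functional-type maps.

Species probability maps are binarized at the threshold maximizing
sensitivity + specificity (maxSSS) per learner; a species counts as present
in a cell only where at least ``min_agree`` learners (default 3) agree.
Member species of a plant functional type (PFT) are then stacked two ways:

* richness map — cellwise sum of member ensemble probabilities (range
  [0, n_members], a relative-suitability indicator);
* bS-SDM map — cellwise sum of binarized member presences; the PFT counts
  as present where bS-SDM >= ``presence_min`` (default 2), damping
  single-species outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PFTResult",
    "max_sss_threshold",
    "binarize_species",
    "stack_richness",
    "pft_presence",
    "build_pft_result",
]


@dataclass
class PFTResult:
    pft: str
    members: list[str]
    richness: np.ndarray  # [0, n_members]
    bssdm: np.ndarray  # integer counts 0..n_members (float grid, NaN = missing)
    presence: np.ndarray  # boolean
    presence_min: int = 2


def max_sss_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity (prediction: score >= tau).

    Candidates are the observed score values; exact ties in the objective are
    broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("maxSSS requires both classes")
    cand = np.unique(scores)
    # vectorized sens/spec over candidates via sorted positions
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    sens = 1.0 - np.searchsorted(pos_sorted, cand, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, cand, side="left") / n_neg
    obj = sens + spec
    best = np.flatnonzero(obj == obj.max())[0]  # smallest tau among ties
    return float(cand[best])


def binarize_species(
    learner_maps: list[np.ndarray],
    thresholds: list[float],
    min_agree: int = 3,
) -> np.ndarray:
    """Cell is a species presence iff >= min_agree learners clear their threshold.

    Comparison is >=: a cell exactly at a learner's threshold votes present.
    Missing cells (NaN in every map) propagate as NaN in a float grid.
    """
    if len(learner_maps) != len(thresholds):
        raise ValueError("one threshold per learner map required")
    if min_agree > len(learner_maps):
        raise ValueError("min_agree exceeds the number of learners")
    votes = np.zeros(learner_maps[0].shape)
    missing = np.zeros(learner_maps[0].shape, dtype=bool)
    for m, t in zip(learner_maps, thresholds):
        if m.shape != votes.shape:
            raise ValueError("maps are not co-registered")
        votes += (m >= t).astype(float)
        missing |= np.isnan(m)
    out = (votes >= min_agree).astype(float)
    out[missing] = np.nan
    return out


def stack_richness(member_maps: list[np.ndarray]) -> np.ndarray:
    """Cellwise sum of member ensemble probability maps."""
    if not member_maps:
        raise ValueError("need at least one member map")
    shape = member_maps[0].shape
    for m in member_maps:
        if m.shape != shape:
            raise ValueError("maps are not co-registered")
        finite = m[np.isfinite(m)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("member maps must be probabilities in [0, 1]")
    return np.sum(np.stack(member_maps), axis=0)


def pft_presence(
    member_binary_maps: list[np.ndarray], presence_min: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """bS-SDM count grid and the PFT presence mask (bS-SDM >= presence_min)."""
    if not member_binary_maps:
        raise ValueError("need at least one member map")
    for m in member_binary_maps:
        finite = m[np.isfinite(m)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("member maps must be binary (0/1, NaN for missing)")
    bssdm = np.sum(np.stack(member_binary_maps), axis=0)
    presence = np.where(np.isnan(bssdm), False, bssdm >= presence_min)
    return bssdm, presence


def build_pft_result(
    pft: str,
    members: list[str],
    member_prob_maps: list[np.ndarray],
    member_binary_maps: list[np.ndarray],
    presence_min: int = 2,
) -> PFTResult:
    bssdm, presence = pft_presence(member_binary_maps, presence_min)
    return PFTResult(
        pft=pft,
        members=list(members),
        richness=stack_richness(member_prob_maps),
        bssdm=bssdm,
        presence=presence,
        presence_min=presence_min,
    )
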