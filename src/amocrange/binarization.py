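"""Threshold criteria turning continuous suitability into presence/absence.

Four criteria are implemented:

- ``MTP``: minimum training presence — the smallest suitability observed at
  a training presence, giving zero training omission.
- ``P10TP``: the nearest-rank 10th percentile of training presence scores
  (the "10thTP" rule), tolerating ~10% training omission.
- ``ESS``: the threshold equalizing sensitivity and specificity.
- ``MSS``: the threshold maximizing sensitivity + specificity, equivalently
  maximizing TSS.

Presence is inclusive at the threshold (suitability >= t), so MTP omission
is exactly zero by construction.  ESS/MSS scan all unique observed scores
and break ties toward the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, MetricError, ParameterError

CRITERIA = ("MTP", "P10TP", "ESS", "MSS")


@dataclass(frozen=True)
class ThresholdSpec:
    criterion: str
    value: float


def _nearest_rank_percentile(sorted_scores: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: smallest value with >= pct of mass at or below."""
    n = len(sorted_scores)
    k = max(1, int(np.ceil(pct * n)))
    return float(sorted_scores[k - 1])


def compute_threshold(
    train_presence_scores: np.ndarray,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    criterion: str = "P10TP",
) -> ThresholdSpec:
    """Derive a binarization threshold from training scores.

    ``scores``/``labels`` (1 = presence, 0 = background) are required only
    for the ESS and MSS criteria, which scan every unique observed score as
    a candidate threshold with the inclusive (>=) presence rule.
    """
    if criterion not in CRITERIA:
        raise ParameterError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    sp = np.sort(np.asarray(train_presence_scores, dtype=float))
    if sp.size == 0:
        raise MetricError("no training presence scores")

    if criterion == "MTP":
        return ThresholdSpec("MTP", float(sp[0]))
    if criterion == "P10TP":
        return ThresholdSpec("P10TP", _nearest_rank_percentile(sp, 0.10))

    if scores is None or labels is None:
        raise MetricError(f"{criterion} requires labeled scores for both classes")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ParameterError("scores and labels must align")
    if not ((y == 1).any() and (y == 0).any()):
        raise MetricError(f"{criterion} requires both classes")

    candidates = np.unique(s)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    # sens(t) = P(score >= t | presence), spec(t) = P(score < t | background)
    sens = np.array([(s[y == 1] >= t).sum() for t in candidates]) / n_pos
    spec = np.array([(s[y == 0] < t).sum() for t in candidates]) / n_neg
    if criterion == "ESS":
        best = int(np.argmin(np.abs(sens - spec)))  # argmin takes the first=lowest tie
    else:  # MSS
        best = int(np.argmax(sens + spec))
    return ThresholdSpec(criterion, float(candidates[best]))


@dataclass
class BinaryRangeMap:
    """A thresholded presence/absence map restricted to a realm background."""

    species_id: str
    presence: np.ndarray  # bool, grid shape
    background: np.ndarray  # bool, grid shape; cells outside are always absent
    criterion: str = "P10TP"
    scenario: str = ""
    horizon: int | str = "current"
    algorithm: str = ""
    dispersal: str = ""

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if self.presence.shape != self.background.shape:
            raise AlignmentError("presence and background grids differ")
        # clip any presence leaking outside the background
        self.presence = self.presence & self.background

    @property
    def n_presence(self) -> int:
        return int(self.presence.sum())

    def cells(self) -> np.ndarray:
        """Sorted presence cell ids (row-major)."""
        return np.nonzero(self.presence.ravel())[0]


def apply_threshold(
    suitability_map: np.ndarray,
    t: ThresholdSpec,
    background: np.ndarray,
    **meta,
) -> BinaryRangeMap:
    """Binarize a suitability field: presence where suitability >= t.value.

    ``background`` is the species' realm mask; cells outside it are absent
    regardless of suitability.
    """
    suit = np.asarray(suitability_map, dtype=float)
    bg = np.asarray(background, dtype=bool)
    if suit.shape != bg.shape:
        raise AlignmentError(
            f"suitability {suit.shape} and background {bg.shape} grids differ"
        )
    return BinaryRangeMap(
        species_id=meta.pop("species_id", ""),
        presence=(suit >= t.value) & bg,
        background=bg,
        criterion=t.criterion,
        **meta,
    )
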