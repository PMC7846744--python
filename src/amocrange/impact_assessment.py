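"""Per-species range change and grouped contraction summaries.

The central statistic is the proportional range change

    q = (p1 - p2) / p1

where p1 counts cells predicted present under current climate and p2 under
a future scenario.  Positive q is contraction, negative q expansion; under
the no-dispersal assumption the future range is intersected with the
current one, so q >= 0.  Per-species estimates are averaged across the
retained algorithms into an ensemble value, and group summaries report the
median with a seeded percentile-bootstrap 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binarization import BinaryRangeMap
from .errors import AlignmentError, ParameterError, RangeUndefinedError

DISPERSAL_MODES = ("full", "none")
ENSEMBLE = "ENSEMBLE"

RECORD_COLUMNS = (
    "species_id",
    "realm",
    "family",
    "status",
    "scenario",
    "horizon",
    "dispersal",
    "algorithm",
    "p1",
    "p2",
    "q",
)


@dataclass(frozen=True)
class RangeChangeRecord:
    species_id: str
    scenario: str
    horizon: int
    dispersal: str
    algorithm: str
    p1: int
    p2: int
    q: float
    realm: str = ""
    family: str = ""
    status: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in RECORD_COLUMNS}


def range_change(
    current: BinaryRangeMap,
    future: BinaryRangeMap,
    dispersal: str,
) -> RangeChangeRecord:
    """q = (p1 - p2)/p1 between a current and a future binary map.

    Full dispersal counts every future presence cell in the realm
    background; no dispersal counts only future presences inside the
    current range.  An empty current range makes q undefined and raises.
    """
    if dispersal not in DISPERSAL_MODES:
        raise ParameterError(f"dispersal must be one of {DISPERSAL_MODES}")
    if current.presence.shape != future.presence.shape:
        raise AlignmentError("current and future maps on different grids")
    if current.species_id != future.species_id:
        raise ParameterError("maps belong to different species")
    p1 = current.n_presence
    if p1 == 0:
        raise RangeUndefinedError(
            f"{current.species_id}: empty current predicted range (p1 = 0)"
        )
    fut = future.presence & current.presence if dispersal == "none" else future.presence
    p2 = int(fut.sum())
    return RangeChangeRecord(
        species_id=current.species_id,
        scenario=future.scenario,
        horizon=int(future.horizon) if future.horizon != "current" else 0,
        dispersal=dispersal,
        algorithm=future.algorithm,
        p1=p1,
        p2=p2,
        q=(p1 - p2) / p1,
    )


def ensemble_range_change(
    records: Sequence[RangeChangeRecord],
) -> RangeChangeRecord:
    """Average q across the retained algorithms for one species/scenario cell.

    All records must share species, scenario, horizon and dispersal; the
    ensemble q is the arithmetic mean of the per-algorithm q values, and
    p1/p2 are carried as rounded means for bookkeeping.
    """
    if not records:
        raise ParameterError("no per-algorithm records to ensemble")
    keys = {(r.species_id, r.scenario, r.horizon, r.dispersal) for r in records}
    if len(keys) > 1:
        raise ParameterError(f"records mix analysis cells: {sorted(keys)}")
    q = float(np.mean([r.q for r in records]))
    return replace(
        records[0],
        algorithm=ENSEMBLE,
        p1=int(round(np.mean([r.p1 for r in records]))),
        p2=int(round(np.mean([r.p2 for r in records]))),
        q=q,
    )


def records_to_frame(records: Iterable[RangeChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records], columns=list(RECORD_COLUMNS))


def _bootstrap_median_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.quantile(medians, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def summarize_contractions(
    records: pd.DataFrame,
    grouping: Sequence[str],
    contracting_only: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median q per group with a percentile-bootstrap 95% CI of the median.

    With ``contracting_only`` the records are first restricted to q > 0
    (species contracting their ranges), applied within each analysis cell;
    groups emptied by the filter are omitted.  Deterministic given seed.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ParameterError("no records to summarize")
    if contracting_only:
        df = df[df["q"] > 0]
    rows = []
    for key, grp in df.groupby(list(grouping), sort=True):
        vals = grp["q"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        rng = np.random.default_rng(seed)
        lo, hi = _bootstrap_median_ci(vals, n_boot, rng)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(grouping, key))
            | {
                "n": int(vals.size),
                "median_q": float(np.median(vals)),
                "ci_lower": lo,
                "ci_upper": hi,
                "contracting_only": contracting_only,
            }
        )
    return pd.DataFrame(rows)
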