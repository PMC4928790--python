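"""MBT-based weighting of CRS-R subscale scores and the increment sweep.

A CRS-R subscale quoted exactly at its reflex level (auditory 1, visual 1,
motor 2, oromotor 1; communication 0 = "none") may understate consciousness
when subtle positive motor signs are present.  The weighting scheme raises
such a score by a sub-integer increment delta in (0, 1) whenever at least
one *mapped* positive MBT item is present, so the weighted score moves
toward — but never reaches — the next ordinal level, and the behavioural
diagnosis computed on integer levels is unchanged.

Item-to-subscale mapping: items 1, 3 and 5 raise all five subscales, item 2
raises the auditory and visual subscales, item 4 the motor and oromotor
subscales.  Negative (6-7) and reflex (8-10) items never enter weighting.

The increment sweep applies the weighting at each delta of a grid and runs
the outcome comparisons on the weighted first-assessment subscores.  Because
weighted values never cross an integer boundary, group ranks are identical
at every delta; the sweep therefore reports the same p-value along the grid
and the critical increment, when one exists, is the smallest grid point at
which the Holm-corrected p-value falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Comparison,
    MBTAssessment,
    PatientRecord,
    REFLEX_LEVEL,
    SUBSCALES,
    SubscaleProfile,
    enumerate_comparisons,
)
from .stats import DEFAULT_EXACT_LIMIT, holm_bonferroni, mann_whitney_u

__all__ = [
    "ITEM_SUBSCALE_MAP",
    "subscale_fires",
    "weight_profile",
    "WeightedProfile",
    "increment_sweep",
    "DEFAULT_DELTA_GRID",
]

#: MBT items (1-based) that raise each subscale when present.
ITEM_SUBSCALE_MAP: dict[str, frozenset[int]] = {
    "auditory": frozenset({1, 2, 3, 5}),
    "visual": frozenset({1, 2, 3, 5}),
    "motor": frozenset({1, 3, 4, 5}),
    "oromotor": frozenset({1, 3, 4, 5}),
    "communication": frozenset({1, 3, 5}),
}

DEFAULT_DELTA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


def subscale_fires(mbt: MBTAssessment, subscale: str) -> bool:
    """True when at least one MBT item mapped to ``subscale`` is present."""
    if subscale not in ITEM_SUBSCALE_MAP:
        raise ValueError(f"unknown subscale {subscale!r}")
    return any(mbt.item(i) == 1 for i in ITEM_SUBSCALE_MAP[subscale])


@dataclass(frozen=True)
class WeightedProfile:
    """Real-valued subscale scores after MBT weighting at one delta."""

    auditory: float
    visual: float
    motor: float
    oromotor: float
    communication: float
    delta: float
    applied: dict[str, bool]

    def scores(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in SUBSCALES)


def weight_profile(
    profile: SubscaleProfile,
    mbt: MBTAssessment,
    delta: float,
) -> WeightedProfile:
    """Apply the MBT increment to one CRS-R profile.

    A subscale receives ``score + delta`` exactly when its score sits at the
    reflex level and a mapped positive item fires; all other scores pass
    through unchanged.  ``delta`` of 0 is the identity; values outside
    [0, 1) are rejected because the increment must never reach the next
    ordinal level.
    """
    if not 0 <= delta < 1:
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    weighted = {}
    applied = {}
    for name in SUBSCALES:
        score = getattr(profile, name)
        fires = delta > 0 and score == REFLEX_LEVEL[name] and subscale_fires(mbt, name)
        weighted[name] = score + delta if fires else float(score)
        applied[name] = fires
    return WeightedProfile(**weighted, delta=delta, applied=applied)


def increment_sweep(
    patients: Sequence[PatientRecord],
    comparisons: Optional[Sequence[Comparison]] = None,
    deltas: Sequence[float] = DEFAULT_DELTA_GRID,
    alpha: float = 0.05,
    combine: str = "or",
    include_raw: bool = True,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> pd.DataFrame:
    """Sweep the weighting increment and test every outcome comparison.

    For each (comparison, delta) the five weighted first-assessment
    subscores are compared between groups with the Mann–Whitney U test and
    Holm-corrected across the five subscales; the family is the per-
    comparison row of five tests at one delta, the sweep across deltas being
    a search rather than a simultaneous inference.  ``include_raw`` adds
    delta = 0 rows (unweighted subscores).  The result is a long-format
    table with one row per (comparison, subscale, delta) carrying U, raw and
    corrected p-values and a ``critical`` flag marking, per (comparison,
    subscale), the smallest delta > 0 whose corrected p falls below alpha.
    Degenerate comparisons are flagged, not tested.
    """
    deltas = sorted(float(d) for d in deltas)
    if any(not 0 < d < 1 for d in deltas):
        raise ValueError("sweep deltas must lie strictly inside (0, 1)")
    if comparisons is None:
        comparisons = enumerate_comparisons(patients)
    by_id = {p.id: p for p in patients}
    grid = ([0.0] if include_raw else []) + deltas

    rows = []
    for comp in comparisons:
        if comp.degenerate:
            for delta in grid:
                for name in SUBSCALES:
                    rows.append(dict(comparison=comp.label, subscale=name, delta=delta,
                                     U=np.nan, p_raw=np.nan, p_holm=np.nan,
                                     critical=False, degenerate=True))
            continue
        critical_seen: set[str] = set()
        for delta in grid:
            scores = {}
            for side, ids in (("a", comp.group_a), ("b", comp.group_b)):
                vals = []
                for pid in ids:
                    patient = by_id[pid]
                    wp = weight_profile(
                        patient.first_assessment.profile,
                        patient.first_mbt(combine=combine),
                        delta,
                    )
                    vals.append(wp.scores())
                scores[side] = np.array(vals, dtype=float)
            praw, stats_u = [], []
            for j, name in enumerate(SUBSCALES):
                u, p = mann_whitney_u(scores["a"][:, j], scores["b"][:, j],
                                      exact_limit=exact_limit)
                stats_u.append(u)
                praw.append(p)
            pholm = holm_bonferroni(praw)
            for j, name in enumerate(SUBSCALES):
                crit = False
                if delta > 0 and pholm[j] < alpha and name not in critical_seen:
                    critical_seen.add(name)
                    crit = True
                rows.append(dict(comparison=comp.label, subscale=name, delta=delta,
                                 U=stats_u[j], p_raw=praw[j], p_holm=float(pholm[j]),
                                 critical=crit, degenerate=False))
    return pd.DataFrame(rows)


def critical_deltas(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per (comparison, subscale): the critical increment, or NaN if the
    weighted comparison never reaches significance along the grid."""
    rows = []
    for (comp, name), grp in sweep.groupby(["comparison", "subscale"], sort=False):
        hit = grp.loc[grp["critical"]]
        rows.append(dict(comparison=comp, subscale=name,
                         critical_delta=float(hit["delta"].iloc[0]) if len(hit) else np.nan))
    return pd.DataFrame(rows)
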