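"""Nonparametric prediction battery and descriptive group comparisons.

The outcome analyses rest on a small set of primitives: the Mann–Whitney U
test (exact by full enumeration for small samples, tie- and continuity-
corrected normal approximation otherwise), the Holm–Bonferroni step-down
adjustment for family-wise error control, and binary-predictor performance
metrics (sensitivity, specificity, Yule's Q) on 2x2 tables.

The exact Mann–Whitney path enumerates the permutation distribution of U
under the null of exchangeability, which is valid in the presence of ties —
the reason the test is implemented here rather than delegated to a library
routine whose exact method rejects tied data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    Comparison,
    MBT_NEGATIVE_ITEMS,
    MBT_POSITIVE_ITEMS,
    MBT_REFLEX_ITEMS,
    PatientRecord,
    PrimaryClass,
    SUBSCALES,
    classify_outcome,
)

__all__ = [
    "mann_whitney_u",
    "holm_bonferroni",
    "TwoByTwo",
    "binary_predictor_metrics",
    "mbt_prediction",
    "descriptive_comparison",
    "crsr_count_correlation",
]

DEFAULT_EXACT_LIMIT = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample ``x`` against ``y`` via midranks (ties get half credit)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` where U is the statistic of ``x`` versus ``y`` with
    midrank tie handling.  For ``n1 + n2 <= exact_limit`` the p-value is
    exact: every reassignment of the pooled values to the two groups is
    enumerated and the two-sided p is the probability of a U at least as far
    from its null mean ``n1*n2/2`` as observed.  Larger samples use the
    normal approximation with tie correction and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        const = n1 * (n1 + 1) / 2.0
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - const
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u_obs, min(p, 1.0)


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in input order.

    Adjusted values are clipped at 1 and made monotone along the sorted
    order, so rejection of ``p_adj < alpha`` reproduces the sequential
    step-down rule at every alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table for a binary predictor of a binary outcome.

    Rows: predictor present (``a``, ``b``) / absent (``c``, ``d``);
    columns: outcome positive (``a``, ``c``) / negative (``b``, ``d``).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) < 1:
            raise ValueError("2x2 table must contain at least one observation")


def binary_predictor_metrics(table: TwoByTwo) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Sensitivity, specificity and Yule's Q for a 2x2 table.

    ``sensitivity = a/(a+c)``, ``specificity = d/(b+d)``,
    ``Q = (ad - bc)/(ad + bc)``.  A zero denominator yields ``None`` for the
    affected metric (undefined rather than an arbitrary number).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    sens = a / (a + c) if (a + c) > 0 else None
    spec = d / (b + d) if (b + d) > 0 else None
    q_den = a * d + b * c
    q = (a * d - b * c) / q_den if q_den > 0 else None
    return sens, spec, q


#: For positive (1-5) and negative (6-7) MBT signs a present item predicts
#: emergence; for reflex signs (8-10) a present item predicts remaining in
#: DOC (reflex behaviour speaks for deeper consciousness impairment).
DEFAULT_ITEM_ORIENTATION = {i: "emerged" for i in MBT_POSITIVE_ITEMS + MBT_NEGATIVE_ITEMS}
DEFAULT_ITEM_ORIENTATION.update({i: "remaining" for i in MBT_REFLEX_ITEMS})


def _mbt_values(patients: dict[str, PatientRecord], ids: Iterable[str], item: int, combine: str) -> np.ndarray:
    return np.array([patients[pid].first_mbt(combine=combine).item(item) for pid in ids], dtype=float)


def mbt_prediction(
    patients: Sequence[PatientRecord],
    comparisons: Optional[Sequence[Comparison]] = None,
    alpha: float = 0.05,
    orientation: Optional[dict[int, str]] = None,
    combine: str = "or",
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> pd.DataFrame:
    """Outcome prediction from the ten binary MBT items.

    Per comparison and item: a Mann–Whitney test on the item values between
    the two outcome groups (for binaries this is a rank test on two
    Bernoulli samples), Holm-corrected across the ten items within the
    comparison.  Sensitivity, specificity and Yule's Q are reported only
    where the corrected p-value is below ``alpha``; group A of each
    comparison is the emerged side, and the predictor orientation per item
    follows ``orientation`` (default: items 1–7 present→emerged, reflex
    items 8–10 present→remaining).
    """
    from .cohort import enumerate_comparisons

    orientation = dict(DEFAULT_ITEM_ORIENTATION if orientation is None else orientation)
    by_id = {p.id: p for p in patients}
    if comparisons is None:
        comparisons = enumerate_comparisons(patients)
    rows = []
    for comp in comparisons:
        if comp.degenerate:
            for item in range(1, 11):
                rows.append(
                    dict(comparison=comp.label, item=item, n_a=len(comp.group_a),
                         n_b=len(comp.group_b), U=np.nan, p_raw=np.nan, p_holm=np.nan,
                         significant=False, sensitivity=np.nan, specificity=np.nan,
                         yules_q=np.nan, degenerate=True)
                )
            continue
        praw = []
        stats_u = []
        for item in range(1, 11):
            va = _mbt_values(by_id, comp.group_a, item, combine)
            vb = _mbt_values(by_id, comp.group_b, item, combine)
            u, p = mann_whitney_u(va, vb, exact_limit=exact_limit)
            stats_u.append(u)
            praw.append(p)
        pholm = holm_bonferroni(praw)
        for item in range(1, 11):
            va = _mbt_values(by_id, comp.group_a, item, combine)
            vb = _mbt_values(by_id, comp.group_b, item, combine)
            sig = bool(pholm[item - 1] < alpha)
            sens = spec = q = np.nan
            if sig:
                if orientation.get(item, "emerged") == "emerged":
                    pos, neg = va, vb
                else:
                    pos, neg = vb, va
                table = TwoByTwo(
                    a=int(pos.sum()), b=int(neg.sum()),
                    c=int(len(pos) - pos.sum()), d=int(len(neg) - neg.sum()),
                )
                s, sp, qq = binary_predictor_metrics(table)
                sens = np.nan if s is None else s
                spec = np.nan if sp is None else sp
                q = np.nan if qq is None else qq
            rows.append(
                dict(comparison=comp.label, item=item, n_a=len(comp.group_a),
                     n_b=len(comp.group_b), U=stats_u[item - 1],
                     p_raw=praw[item - 1], p_holm=float(pholm[item - 1]),
                     significant=sig, sensitivity=sens, specificity=spec,
                     yules_q=q, degenerate=False)
            )
    return pd.DataFrame(rows)


_CONTINUOUS_VARS = [
    ("age", "Age (years)"),
    ("n_crsr", "Number of CRS-R"),
    ("delay_first_crsr", "Delay insult-first CRS-R (days)"),
    ("delay_last_crsr", "Delay insult-last CRS-R (days)"),
    ("rehabilitation_duration", "Rehabilitation duration (days)"),
]


def descriptive_comparison(patients: Sequence[PatientRecord], alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Group descriptives contrasting emerged versus remaining patients.

    Returns tables keyed ``continuous`` (mean/SD per group, Mann–Whitney),
    ``lesions`` and ``aetiology`` (per-category counts with Fisher's exact
    test), ``subclasses`` (taxonomy counts) and ``endpoints`` (functional
    walking and return home, NA excluded pairwise, Fisher's exact).  All
    tested families are Holm-corrected within the table.
    """
    emerged = [p for p in patients if classify_outcome(p).primary_class is PrimaryClass.EMERGED]
    remaining = [p for p in patients if classify_outcome(p).primary_class is PrimaryClass.REMAINING]
    n_e, n_r = len(emerged), len(remaining)

    # continuous descriptives, Mann-Whitney tested
    rows = []
    praw = []
    for attr, label in _CONTINUOUS_VARS:
        ve = np.array([getattr(p, attr) for p in emerged], dtype=float)
        vr = np.array([getattr(p, attr) for p in remaining], dtype=float)
        if n_e and n_r:
            _, p = mann_whitney_u(ve, vr)
        else:
            p = np.nan
        praw.append(p)
        rows.append(
            dict(variable=label,
                 remaining_mean=vr.mean() if n_r else np.nan,
                 remaining_sd=vr.std(ddof=1) if n_r > 1 else np.nan,
                 emerged_mean=ve.mean() if n_e else np.nan,
                 emerged_sd=ve.std(ddof=1) if n_e > 1 else np.nan,
                 p_raw=p)
        )
    continuous = pd.DataFrame(rows)
    if n_e and n_r:
        continuous["p_holm"] = holm_bonferroni(praw)
    else:
        continuous["p_holm"] = np.nan

    # lesion-region tallies, Fisher tested per region
    from .io import lesion_regions
    from .io import REGION_GROUPS

    def _fisher_family(categories, members_e, members_r):
        recs, ps = [], []
        for cat in categories:
            ce = sum(1 for m in members_e if cat in m)
            cr = sum(1 for m in members_r if cat in m)
            if n_e and n_r:
                _, p = sps.fisher_exact([[cr, n_r - cr], [ce, n_e - ce]])
            else:
                p = np.nan
            ps.append(p)
            recs.append(dict(category=cat, remaining_n=cr,
                             remaining_pct=100.0 * cr / n_r if n_r else np.nan,
                             emerged_n=ce,
                             emerged_pct=100.0 * ce / n_e if n_e else np.nan,
                             p_raw=p))
        df = pd.DataFrame(recs)
        df["p_holm"] = holm_bonferroni(ps) if (n_e and n_r) else np.nan
        return df

    regions_e = [lesion_regions(p.lesion_sites) for p in emerged]
    regions_r = [lesion_regions(p.lesion_sites) for p in remaining]
    lesions = _fisher_family(list(REGION_GROUPS), regions_e, regions_r)

    aet_e = [{p.aetiology} for p in emerged]
    aet_r = [{p.aetiology} for p in remaining]
    aet_cats = sorted({p.aetiology for p in patients})
    aetiology = _fisher_family(aet_cats, aet_e, aet_r)

    # subclass taxonomy counts
    counts = {s: 0 for s in "abcdef"}
    for p in patients:
        counts[classify_outcome(p).subclass] += 1
    subclasses = pd.DataFrame(
        [dict(subclass=s, n=counts[s]) for s in "abcdef"]
        + [dict(subclass="class1", n=n_e), dict(subclass="class2", n=n_r)]
    )

    # secondary endpoints, NA excluded pairwise, Fisher tested
    ep_rows, ep_p = [], []
    for attr, label in (("walks", "Functional walking ability"), ("returned_home", "Return home")):
        ve = [getattr(p, attr) for p in emerged if getattr(p, attr) is not None]
        vr = [getattr(p, attr) for p in remaining if getattr(p, attr) is not None]
        ye, yr = sum(ve), sum(vr)
        if ve and vr:
            _, p = sps.fisher_exact([[yr, len(vr) - yr], [ye, len(ve) - ye]])
        else:
            p = np.nan
        ep_p.append(p)
        ep_rows.append(dict(endpoint=label, remaining_yes=yr, remaining_n=len(vr),
                            emerged_yes=ye, emerged_n=len(ve), p_raw=p))
    endpoints = pd.DataFrame(ep_rows)
    endpoints["p_holm"] = holm_bonferroni(ep_p) if (n_e and n_r) else np.nan

    return dict(continuous=continuous, lesions=lesions, aetiology=aetiology,
                subclasses=subclasses, endpoints=endpoints)


def crsr_count_correlation(
    cohort: pd.DataFrame,
    duration_column: str = "rehab_duration",
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between the number of CRS-R evaluations and a duration
    column of the cohort table (``pearson`` or ``spearman``)."""
    x = pd.to_numeric(cohort["n_crsr"], errors="coerce")
    y = pd.to_numeric(cohort[duration_column], errors="coerce")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)
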