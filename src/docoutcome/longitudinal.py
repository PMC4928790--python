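"""Longitudinal modelling of CRS-R subscale trajectories.

Each patient's per-subscale scores are regressed on an orthonormal
polynomial basis (degrees 0-3: constant, linear, quadratic, cubic) by
ordinary least squares.  Because assessments fall on irregular, patient-
specific days, the polynomials are orthonormalised once on a fixed uniform
reference grid over the analysis window and every patient's design matrix
evaluates those same canonical polynomials at the patient's days — this
keeps coefficients comparable across patients, which the group-level
coefficient tests require.

Regressor subsets are explored combinatorially (all non-empty subsets of
the four degrees); per subset the per-patient coefficients are checked for
normality (Lilliefors, Monte-Carlo null), tested against zero within each
group (one-sample t) and between groups (Welch t), with Holm correction
across the five subscales.  Group mean trajectories with standard-error
bands support two temporal read-outs: the discrimination time (earliest day
from which the two groups' mean±SEM bands stay disjoint) and the
cutoff-attainment time (earliest day the mean curve reaches the emergence
cutoff: motor 6 or communication 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Comparison, PatientRecord, SUBSCALE_MAX, SUBSCALES
from .stats import holm_bonferroni

__all__ = [
    "PolynomialBasis",
    "build_basis",
    "PatientFit",
    "fit_patient",
    "fit_cohort",
    "ALL_DEGREE_SUBSETS",
    "select_and_test",
    "lilliefors",
    "GroupCurve",
    "group_curves",
    "discrimination_time",
    "cutoff_attainment_time",
]

#: All 15 non-empty subsets of polynomial degrees {0, 1, 2, 3}.
ALL_DEGREE_SUBSETS: tuple[tuple[int, ...], ...] = tuple(
    subset
    for r in range(1, 5)
    for subset in itertools.combinations(range(4), r)
)

#: Emergence cutoffs on the mean curve.
CUTOFFS = {"motor": SUBSCALE_MAX["motor"], "communication": SUBSCALE_MAX["communication"]}


@dataclass(frozen=True)
class PolynomialBasis:
    """Orthonormal polynomial basis over a day window.

    ``coeffs[k, j]`` is the coefficient of the k-th monomial in the j-th
    basis polynomial, in the canonical variable u in [-1, 1] obtained by an
    affine map of the day window.  Columns are orthonormal with respect to
    the Euclidean inner product on the reference grid; ``orthonormality``
    certifies ``max |G^T G - I|`` there.
    """

    day_window: tuple[float, float]
    max_degree: int
    reference_grid_size: int
    coeffs: np.ndarray
    orthonormality: float

    def _canonical(self, days: np.ndarray) -> np.ndarray:
        lo, hi = self.day_window
        return 2.0 * (np.asarray(days, dtype=float) - lo) / (hi - lo) - 1.0

    def evaluate(self, days: Sequence[float], subset: Optional[Sequence[int]] = None) -> np.ndarray:
        """Design matrix of the basis polynomials at arbitrary days."""
        u = self._canonical(np.asarray(days, dtype=float))
        vand = np.vander(u, N=self.max_degree + 1, increasing=True)
        design = vand @ self.coeffs
        if subset is not None:
            design = design[:, list(subset)]
        return design


def build_basis(
    day_window: tuple[float, float] = (0.0, 100.0),
    max_degree: int = 3,
    reference_grid_size: int = 101,
) -> PolynomialBasis:
    """Gram–Schmidt orthonormalisation of monomials on a uniform grid.

    The monomials 1, u, u^2, ..., evaluated on a uniform reference grid over
    the canonical interval, are orthonormalised by QR decomposition; signs
    are fixed so the constant column is positive, making the construction
    deterministic.
    """
    lo, hi = day_window
    if not hi > lo:
        raise ValueError(f"degenerate day window {day_window}")
    if reference_grid_size < max_degree + 1:
        raise ValueError("reference grid must hold at least max_degree + 1 points")
    u = np.linspace(-1.0, 1.0, reference_grid_size)
    vand = np.vander(u, N=max_degree + 1, increasing=True)
    q, r = np.linalg.qr(vand)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    r = (r.T * signs).T
    coeffs = np.linalg.solve(r, np.eye(max_degree + 1))
    gram_err = float(np.abs(q.T @ q - np.eye(max_degree + 1)).max())
    return PolynomialBasis(
        day_window=(float(lo), float(hi)),
        max_degree=max_degree,
        reference_grid_size=reference_grid_size,
        coeffs=coeffs,
        orthonormality=gram_err,
    )


@dataclass
class PatientFit:
    """Least-squares coefficients of one patient's five subscale series."""

    patient_id: str
    subset: tuple[int, ...]
    coefficients: dict[str, np.ndarray]
    rss: dict[str, float]
    n_points: int
    rank_deficient: bool


def fit_patient(
    patient: PatientRecord,
    basis: PolynomialBasis,
    subset: Sequence[int] = (0, 1, 2, 3),
) -> PatientFit:
    """Project one patient's subscale scores onto the basis subset.

    Ordinary least squares at the patient's assessment days; when the design
    is rank-deficient (fewer assessments than regressors, or coincident
    canonical days) the minimum-norm solution is returned and flagged.
    """
    if not patient.assessments:
        raise ValueError(f"patient {patient.id} has no assessments to fit")
    subset = tuple(int(d) for d in subset)
    days = np.array([a.day for a in patient.assessments], dtype=float)
    design = basis.evaluate(days, subset=subset)
    coefficients: dict[str, np.ndarray] = {}
    rss: dict[str, float] = {}
    rank = 0
    for name in SUBSCALES:
        y = np.array([getattr(a.profile, name) for a in patient.assessments], dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        coefficients[name] = beta
        rss[name] = float(resid @ resid)
    return PatientFit(
        patient_id=patient.id,
        subset=subset,
        coefficients=coefficients,
        rss=rss,
        n_points=len(days),
        rank_deficient=bool(rank < len(subset)),
    )


def fit_cohort(
    patients: Sequence[PatientRecord],
    basis: PolynomialBasis,
    subset: Sequence[int] = (0, 1, 2, 3),
) -> dict[str, PatientFit]:
    return {p.id: fit_patient(p, basis, subset) for p in patients}


def lilliefors(
    sample: Sequence[float],
    n_reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Lilliefors normality test (KS distance to a fitted normal).

    The null distribution of the statistic — the Kolmogorov–Smirnov distance
    between the empirical CDF and the normal CDF with mean and SD estimated
    from the same sample — is simulated by ``n_reps`` seeded Monte-Carlo
    draws; the p-value is the (add-one) proportion of simulated distances at
    least as large as the observed one.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"Lilliefors test requires n >= 4, got {n}")

    def _stat(mat: np.ndarray) -> np.ndarray:
        # rows are samples; returns D per row
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((mat - mu) / sd, axis=1)
        cdf = sps.norm.cdf(z)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=1)
        d_minus = (cdf - (i - 1) / n).max(axis=1)
        return np.maximum(d_plus, d_minus)

    if np.ptp(x) == 0:
        return 1.0, 0.0  # degenerate sample: maximal distance, never normal
    d_obs = float(_stat(x[None, :])[0])
    rng = np.random.default_rng(seed)
    sims = _stat(rng.standard_normal(size=(n_reps, n)))
    p = (1.0 + np.sum(sims >= d_obs - 1e-12)) / (n_reps + 1.0)
    return d_obs, float(p)


def select_and_test(
    patients: Sequence[PatientRecord],
    comparison: Comparison,
    basis: PolynomialBasis,
    subsets: Sequence[Sequence[int]] = ALL_DEGREE_SUBSETS,
    alpha: float = 0.05,
    lilliefors_reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient tests for one outcome comparison over regressor subsets.

    Per (subset, subscale, degree): a Lilliefors normality check on the
    pooled coefficients of both groups, one-sample two-tailed t-tests of
    each group's coefficients against zero, and a two-sample Welch t-test
    between groups.  The between-group p-values are Holm-corrected across
    the five subscales within each (subset, degree) family.  Groups smaller
    than two, and subsets wider than some patient's assessment count, are
    flagged rather than silently dropped.
    """
    by_id = {p.id: p for p in patients}
    rows = []
    for subset in subsets:
        subset = tuple(int(d) for d in subset)
        fits_a = [fit_patient(by_id[pid], basis, subset) for pid in comparison.group_a]
        fits_b = [fit_patient(by_id[pid], basis, subset) for pid in comparison.group_b]
        flagged = any(f.rank_deficient for f in fits_a + fits_b)
        small = len(fits_a) < 2 or len(fits_b) < 2
        for pos, degree in enumerate(subset):
            welch_ps = []
            cells = []
            for name in SUBSCALES:
                ca = np.array([f.coefficients[name][pos] for f in fits_a])
                cb = np.array([f.coefficients[name][pos] for f in fits_b])
                pooled = np.concatenate([ca, cb])
                if small:
                    lil_stat = lil_p = p1a = p1b = welch = np.nan
                else:
                    lil_stat, lil_p = lilliefors(pooled, n_reps=lilliefors_reps, seed=seed)
                    p1a = float(sps.ttest_1samp(ca, 0.0).pvalue)
                    p1b = float(sps.ttest_1samp(cb, 0.0).pvalue)
                    welch = float(sps.ttest_ind(ca, cb, equal_var=False).pvalue)
                welch_ps.append(welch)
                cells.append(dict(subset="+".join(map(str, subset)), degree=degree,
                                  subscale=name, n_a=len(fits_a), n_b=len(fits_b),
                                  mean_a=float(ca.mean()) if len(ca) else np.nan,
                                  mean_b=float(cb.mean()) if len(cb) else np.nan,
                                  lilliefors_stat=lil_stat, lilliefors_p=lil_p,
                                  t1_p_group_a=p1a, t1_p_group_b=p1b,
                                  welch_p=welch, rank_flagged=flagged,
                                  degenerate=small))
            if small:
                adj = [np.nan] * len(cells)
            else:
                adj = holm_bonferroni(welch_ps)
            for cell, a in zip(cells, adj):
                cell["welch_p_holm"] = float(a) if a == a else np.nan
                rows.append(cell)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupCurve:
    """Mean trajectory with standard-error band for one group/subscale."""

    group: str
    subscale: str
    days: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("day grid must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError("SEM band must be non-negative")

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.sem

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.sem


def group_curves(
    patients: Sequence[PatientRecord],
    groups: Mapping[str, Sequence[str]],
    basis: PolynomialBasis,
    subset: Sequence[int] = (0, 1),
    grid: Optional[Sequence[float]] = None,
) -> list[GroupCurve]:
    """Group mean ± SEM trajectories from per-patient fitted curves.

    Each patient's fitted curve is evaluated on the day grid (default: one-
    day steps over the basis window); the group curve is the pointwise mean
    and the band the pointwise standard error of the per-patient curve
    values.  A single-patient group gets a zero-width band.
    """
    by_id = {p.id: p for p in patients}
    if grid is None:
        lo, hi = basis.day_window
        grid = np.arange(lo, hi + 1.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    design = basis.evaluate(grid, subset=subset)
    curves: list[GroupCurve] = []
    for label, ids in groups.items():
        fits = [fit_patient(by_id[pid], basis, subset) for pid in ids]
        for name in SUBSCALES:
            values = np.stack([design @ f.coefficients[name] for f in fits])
            mean = values.mean(axis=0)
            if len(fits) > 1:
                sem = values.std(axis=0, ddof=1) / np.sqrt(len(fits))
            else:
                sem = np.zeros_like(mean)
            curves.append(GroupCurve(group=label, subscale=name,
                                     days=grid, mean=mean, sem=sem))
    return curves


def discrimination_time(curve_a: GroupCurve, curve_b: GroupCurve) -> Optional[float]:
    """Earliest day from which the two mean±SEM bands stay disjoint.

    The persistence rule: the returned day d is the first grid day such
    that the bands are disjoint at every day >= d; ``None`` when the bands
    still overlap at the end of the grid.
    """
    if curve_a.days.shape != curve_b.days.shape or np.any(curve_a.days != curve_b.days):
        raise ValueError("curves must share the same day grid")
    disjoint = (curve_a.lower > curve_b.upper) | (curve_b.lower > curve_a.upper)
    if not disjoint[-1]:
        return None
    # last index where bands overlap; separation persists after it
    overlap_idx = np.nonzero(~disjoint)[0]
    first = 0 if overlap_idx.size == 0 else overlap_idx[-1] + 1
    return float(curve_a.days[first])


def cutoff_attainment_time(curve: GroupCurve, subscale: Optional[str] = None) -> Optional[float]:
    """Earliest grid day the mean curve reaches the emergence cutoff.

    Supported subscales: motor (cutoff 6, functional object use) and
    communication (cutoff 2, functional communication); ``None`` when the
    mean curve never attains the cutoff on the grid.
    """
    name = subscale or curve.subscale
    if name not in CUTOFFS:
        raise ValueError(f"no emergence cutoff defined for subscale {name!r}")
    hit = np.nonzero(curve.mean >= CUTOFFS[name])[0]
    if hit.size == 0:
        return None
    return float(curve.days[hit[0]])
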