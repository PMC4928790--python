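"""Seeded synthetic DOC cohorts with the structure the analyses assume.

No per-patient CRS-R trajectories are published for the study cohort, so
the generator emulates the *summary* statistics the analysis pipeline
needs: cohort composition (20 UWS / 13 MCS), emergence fractions (55% of
UWS, 77% of MCS), a weekly-jittered assessment schedule (first assessment
11.2 ± 6 days after insult, truncated to the 28-day inclusion window;
7.5 ± 2.9-day intervals), shared-latent logistic recovery trajectories
mapped to the ordinal subscales, and outcome-conditional Bernoulli MBT
items whose default rates are informed by the reported per-item
sensitivities and specificities.

Each patient carries one latent recovery process
``L(t) = 1 / (1 + exp(-(t - t50) / tau))`` shared across subscales; the
observed score on subscale k is ``round(L(t) * max_k)`` with ±1 ordinal
noise of probability epsilon, clipped to the subscale range.  The shared
latent produces the correlated subscale recovery the CRS-R exhibits while
keeping two parameters per patient.  Rejection sampling enforces the
structural constraints: the first assessment diagnoses the intended class,
emergers satisfy the emergence rule at the last assessment and
non-emergers never do.  Under ``enforce_outcome_constraints=False`` (the
"null" scenario) the outcome label is assigned independently of the
trajectory, so the two outcome groups are exchangeable — the configuration
used for type-I-error calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CRSRAssessment,
    Diagnosis,
    MBTAssessment,
    Outcome,
    PatientRecord,
    SUBSCALE_MAX,
    SUBSCALES,
    SubscaleProfile,
    diagnose,
)

__all__ = [
    "TrajectoryParams",
    "GeneratorConfig",
    "generate",
    "reference_scenarios",
    "cohort_table",
    "assessment_table",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent logistic recovery parameters for one (class, outcome) cell."""

    t50_mean: float
    t50_sd: float
    tau: float

    def latent(self, t, t50: Optional[float] = None) -> np.ndarray:
        t50 = self.t50_mean if t50 is None else t50
        return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t50) / self.tau))


#: Default latent dynamics per (initial class, emerger flag).  Emergers'
#: midpoints sit within the 6-week acute window so the emergence cutoffs are
#: reached before discharge; non-emergers' latents stay below the functional
#: range throughout follow-up (UWS: late flat midpoint; MCS: very shallow
#: slope keeping scores in the minimally-conscious band).
DEFAULT_TRAJECTORIES = {
    ("UWS", True): TrajectoryParams(38.0, 8.0, 5.0),
    ("UWS", False): TrajectoryParams(85.0, 15.0, 12.0),
    ("MCS", True): TrajectoryParams(24.0, 7.0, 7.0),
    ("MCS", False): TrajectoryParams(67.0, 10.0, 30.0),
}

#: Default outcome-conditional MBT item rates (items 1..10), informed by
#: the reported per-item sensitivity/specificity pattern: positive and
#: negative signs frequent in emergers, reflex signs frequent in
#: non-emergers.
DEFAULT_MBT_P_EMERGER = (0.86, 0.81, 0.90, 0.95, 0.90, 0.86, 0.76, 0.05, 0.05, 0.05)
DEFAULT_MBT_P_REMAINER = (0.33, 0.25, 0.33, 0.50, 0.42, 0.33, 0.42, 0.50, 0.25, 0.50)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator (units: days)."""

    n_uws: int = 20
    n_mcs: int = 13
    p_emerge_uws: float = 0.55
    p_emerge_mcs: float = 0.77
    trajectories: dict = field(default_factory=lambda: dict(DEFAULT_TRAJECTORIES))
    ordinal_noise: float = 0.12
    first_day_mean: float = 11.2
    first_day_sd: float = 6.0
    first_day_bounds: tuple[float, float] = (1.0, 28.0)
    interval_mean: float = 7.5
    interval_sd: float = 2.9
    interval_min: float = 2.0
    followup_mean: float = 52.0
    followup_sd: float = 15.0
    mbt_p_emerger: tuple[float, ...] = DEFAULT_MBT_P_EMERGER
    mbt_p_remainer: tuple[float, ...] = DEFAULT_MBT_P_REMAINER
    #: probability that each motor-band subscale (auditory, visual, motor,
    #: oromotor) shows a persistent reflex-level floor; drawn once per
    #: patient per subscale, identically in both outcome groups, so first
    #: assessments carry no outcome information beyond the latent.
    reflex_floor_p: float = 0.6
    #: SD of a per-patient vertical offset added to the latent (clipped to
    #: [0, 1]): persistent individual differences in behavioural level that
    #: are independent of outcome.
    latent_offset_sd: float = 0.12
    #: draw emerger labels per patient (False, Bernoulli) or fix the number
    #: of emergers per class to round(n * p) as in a cohort with known
    #: composition (True).
    stratify_outcomes: bool = False
    enforce_outcome_constraints: bool = True
    rejection_cap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_emerge_uws, self.p_emerge_mcs, *self.mbt_p_emerger, *self.mbt_p_remainer)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.mbt_p_emerger) != 10 or len(self.mbt_p_remainer) != 10:
            raise ValueError("MBT item probability vectors must have length 10")
        if min(self.first_day_sd, self.interval_sd, self.followup_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.ordinal_noise <= 0.5:
            raise ValueError("ordinal noise probability must lie in [0, 0.5]")

    # ------ analytic summaries used as simulation ground truth ------------

    def mean_latent(self, t, emerger: bool) -> np.ndarray:
        """Population mean latent trajectory of an outcome group (class mix
        weighted by cohort composition, at the mean midpoint)."""
        weights = {"UWS": self.n_uws, "MCS": self.n_mcs}
        total = sum(w for w in weights.values() if w)
        acc = np.zeros_like(np.asarray(t, dtype=float))
        for klass, w in weights.items():
            if w:
                acc = acc + w / total * self.trajectories[(klass, emerger)].latent(t)
        return acc

    def separation_day(
        self,
        subscale: str = "motor",
        gap: float = 0.5,
        horizon: float = 100.0,
    ) -> Optional[float]:
        """Earliest day the outcome groups' expected score trajectories
        differ by ``gap`` ordinal points on ``subscale`` (default: half a
        point, the resolution of the scale) — the generator's ground-truth
        separation day for trajectory-recovery checks.  Expectations are
        class-mixture weighted by cohort composition."""
        t = np.arange(0.0, horizon + 1.0)
        weights = {"UWS": self.n_uws, "MCS": self.n_mcs}
        total = sum(weights.values())
        e = sum(w / total * self.expected_score(t, subscale, k, True)
                for k, w in weights.items() if w)
        r = sum(w / total * self.expected_score(t, subscale, k, False)
                for k, w in weights.items() if w)
        hit = np.nonzero(np.abs(e - r) >= gap)[0]
        return float(t[hit[0]]) if hit.size else None

    def expected_score(self, t, subscale: str, klass: str, emerger: bool) -> np.ndarray:
        """Expected ordinal score at day t, marginal over the midpoint
        distribution, the reflex floor and the ±1 ordinal noise (with range
        clipping)."""
        from .cohort import REFLEX_LEVEL

        params = self.trajectories[(klass, emerger)]
        t = np.asarray(t, dtype=float)
        max_k = SUBSCALE_MAX[subscale]
        reflex = REFLEX_LEVEL[subscale]
        floor_p = self.reflex_floor_p if subscale != "communication" else 0.0
        # quadrature over the t50 distribution
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        t50s = params.t50_mean + params.t50_sd * nodes
        w = weights / weights.sum()
        acc = np.zeros_like(t)
        eps = self.ordinal_noise

        def _with_noise(s):
            return s + 0.5 * eps * ((s < max_k).astype(float) - (s > 0).astype(float))

        for t50, wk in zip(t50s, w):
            s = np.round(params.latent(t, t50) * max_k)
            floored = np.maximum(s, reflex)
            acc += wk * (floor_p * _with_noise(floored) + (1 - floor_p) * _with_noise(s))
        return acc

    def population_cutoff_crossing(
        self,
        subscale: str = "motor",
        klass: str = "UWS",
        basis=None,
        subset: Sequence[int] = (0, 1, 2, 3),
    ) -> Optional[float]:
        """Cutoff-attainment day of the population projection of the
        expected emerger trajectory — the estimand of the fitted group
        curve's crossing day.

        The group mean curve averages per-patient least-squares fits, each
        over that patient's own assessment days.  Because projection is
        linear in the scores and the visit schedule is independent of the
        trajectory, the mean coefficient vector equals the expectation,
        over the schedule distribution, of the projection of the expected
        score trajectory.  That expectation is computed by a seeded draw of
        schedules (designs only — no scores are simulated); the crossing is
        read off the averaged curve on a one-day grid over the mean
        observation window, where assessments exist.
        """
        from .longitudinal import build_basis, CUTOFFS

        if basis is None:
            basis = build_basis()
        rng = np.random.default_rng(2_000_000_001)
        betas = []
        for _ in range(500):
            days = np.asarray(_schedule(rng, self), dtype=float)
            design = basis.evaluate(days, subset=subset)
            target = self.expected_score(days, subscale, klass, True)
            beta, *_ = np.linalg.lstsq(design, target, rcond=None)
            betas.append(beta)
        mean_beta = np.mean(betas, axis=0)
        grid = np.arange(np.floor(self.first_day_mean), np.ceil(self.followup_mean) + 1.0)
        curve = basis.evaluate(grid, subset=subset) @ mean_beta
        hit = np.nonzero(curve >= CUTOFFS[subscale])[0]
        return float(grid[hit[0]]) if hit.size else None


class RejectionLimitError(RuntimeError):
    """Raised when a patient's structural constraints cannot be met."""


def _truncated_normal(rng: np.random.Generator, mean, sd, lo=-math.inf, hi=math.inf) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _schedule(rng: np.random.Generator, config: GeneratorConfig) -> list[int]:
    first = _truncated_normal(rng, config.first_day_mean, config.first_day_sd,
                              *config.first_day_bounds)
    followup = _truncated_normal(rng, config.followup_mean, config.followup_sd,
                                 lo=first + 2 * config.interval_min)
    days = [first]
    while days[-1] < followup:
        step = _truncated_normal(rng, config.interval_mean, config.interval_sd,
                                 lo=config.interval_min)
        days.append(days[-1] + step)
    days = [int(round(d)) for d in days]
    # integer rounding may merge close visits; enforce strict increase
    for i in range(1, len(days)):
        if days[i] <= days[i - 1]:
            days[i] = days[i - 1] + 1
    while len(days) < 3:
        days.append(days[-1] + int(round(config.interval_mean)))
    return days


def _emerged(profile: SubscaleProfile) -> bool:
    return profile.motor == SUBSCALE_MAX["motor"] or profile.communication == SUBSCALE_MAX["communication"]


def _draw_profile(
    rng: np.random.Generator,
    latent: float,
    eps: float,
    floor: Optional[dict[str, int]] = None,
) -> SubscaleProfile:
    scores = {}
    for name in SUBSCALES:
        max_k = SUBSCALE_MAX[name]
        s = int(round(latent * max_k))
        if floor is not None:
            s = max(s, floor.get(name, 0))
        r = rng.random()
        if r < eps / 2:
            s += 1
        elif r < eps:
            s -= 1
        scores[name] = int(min(max(s, 0), max_k))
    return SubscaleProfile(**scores)


def _generate_patient(
    rng: np.random.Generator,
    config: GeneratorConfig,
    pid: str,
    klass: str,
    emerger: bool,
) -> PatientRecord:
    params: TrajectoryParams = config.trajectories[(klass, emerger)]
    intended = Diagnosis(klass)
    from .cohort import REFLEX_LEVEL

    for _ in range(config.rejection_cap):
        days = _schedule(rng, config)
        t50 = rng.normal(params.t50_mean, params.t50_sd)
        offset = rng.normal(0.0, config.latent_offset_sd) if config.latent_offset_sd else 0.0
        floor = None
        if config.reflex_floor_p > 0:
            floor = {name: (REFLEX_LEVEL[name]
                            if name != "communication" and rng.random() < config.reflex_floor_p
                            else 0)
                     for name in SUBSCALES}
        profiles = [_draw_profile(rng, float(np.clip(params.latent(d, t50) + offset, 0.0, 1.0)),
                                  config.ordinal_noise, floor)
                    for d in days]
        if config.enforce_outcome_constraints:
            if diagnose(profiles[0]) is not intended:
                continue
            if emerger:
                if not _emerged(profiles[-1]):
                    continue
            elif any(_emerged(p) for p in profiles):
                continue
        break
    else:
        raise RejectionLimitError(
            f"patient {pid}: constraints for ({klass}, emerger={emerger}) not met "
            f"within {config.rejection_cap} attempts"
        )

    if emerger:
        outcome = Outcome.NON_DOC
    else:
        last = diagnose(profiles[-1])
        outcome = Outcome.MCS if last in (Diagnosis.MCS, Diagnosis.EMERGED) else Outcome.UWS

    item_p = np.asarray(config.mbt_p_emerger if emerger else config.mbt_p_remainer)
    items = tuple(int(v) for v in (rng.random(10) < item_p))
    assessments = tuple(CRSRAssessment(profile=p, day=d) for p, d in zip(profiles, days))
    age = _truncated_normal(rng, 49.0, 17.5, lo=18.0, hi=90.0)
    # endpoints loosely tied to outcome, matching the reported contrast
    walks = bool(rng.random() < (0.7 if emerger else 0.25))
    home = bool(rng.random() < (0.8 if emerger else 0.25))
    return PatientRecord(
        id=pid,
        initial_diagnosis=intended,
        discharge_outcome=outcome,
        age=round(age, 1),
        aetiology="TBI" if rng.random() < 0.5 else "IS",
        aetiology_raw="synthetic",
        assessments=assessments,
        mbt=(MBTAssessment(items=items, day=days[0]),),
        delay_first_crsr=float(days[0]),
        n_crsr=len(days),
        delay_last_crsr=float(days[-1]),
        rehabilitation_duration=float(days[-1] - days[0]),
        returned_home=home,
        walks=walks,
    )


def generate(config: GeneratorConfig, seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw a full cohort; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    patients: list[PatientRecord] = []
    spec_rows = [("UWS", config.n_uws, config.p_emerge_uws),
                 ("MCS", config.n_mcs, config.p_emerge_mcs)]
    idx = 0
    for klass, n, p_emerge in spec_rows:
        if config.stratify_outcomes:
            n_emerge = int(round(n * p_emerge))
            flags = rng.permutation([True] * n_emerge + [False] * (n - n_emerge))
        else:
            flags = rng.random(n) < p_emerge if n else []
        for emerger in flags:
            idx += 1
            patients.append(_generate_patient(rng, config, f"S{idx:03d}", klass, bool(emerger)))
    return patients


def reference_scenarios() -> dict[str, GeneratorConfig]:
    """Named generator configurations used across the test batteries.

    * ``paper-like`` — the defaults: cohort sizes 20/13, emergence
      probabilities 0.55/0.77, trajectory separation in the third week.
    * ``null`` — outcome label independent of everything: identical
      trajectory and MBT parameters for both outcome groups, structural
      constraints off; between-group tests should reject at the nominal
      rate.
    * ``strong-separation`` — an all-UWS cohort whose outcome groups share
      reflex-level first assessments (raw subscores uninformative) but have
      sharply different MBT profiles and recovery dynamics; used for power
      and trajectory-recovery checks.
    """
    flat = TrajectoryParams(85.0, 15.0, 12.0)
    shallow = TrajectoryParams(67.0, 10.0, 30.0)
    null = GeneratorConfig(
        trajectories={("UWS", True): flat, ("UWS", False): flat,
                      ("MCS", True): shallow, ("MCS", False): shallow},
        p_emerge_uws=0.5,
        p_emerge_mcs=0.5,
        mbt_p_emerger=(0.4,) * 10,
        mbt_p_remainer=(0.4,) * 10,
        enforce_outcome_constraints=False,
    )
    strong = GeneratorConfig(
        n_uws=24,
        n_mcs=0,
        p_emerge_uws=0.5,
        trajectories={("UWS", True): TrajectoryParams(28.0, 3.0, 4.0),
                      ("UWS", False): TrajectoryParams(150.0, 10.0, 30.0),
                      ("MCS", True): TrajectoryParams(14.0, 4.0, 5.0),
                      ("MCS", False): shallow},
        ordinal_noise=0.05,
        reflex_floor_p=0.85,
        latent_offset_sd=0.0,
        mbt_p_emerger=(0.9,) * 7 + (0.05,) * 3,
        mbt_p_remainer=(0.05,) * 7 + (0.6,) * 3,
    )
    return {"paper-like": GeneratorConfig(stratify_outcomes=True),
            "null": null, "strong-separation": strong}


def cohort_table(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Export patient scalars in the cohort-table schema."""
    rows = []
    for p in patients:
        rows.append(dict(
            patient_no=p.id, age=p.age, diagnosis=p.initial_diagnosis.value,
            lesions="", aetiology=p.aetiology, aetiology_raw=p.aetiology_raw,
            delay_first_crsr=p.delay_first_crsr, n_crsr=p.n_crsr,
            delay_last_crsr=p.delay_last_crsr,
            rehab_duration=p.rehabilitation_duration,
            outcome=p.discharge_outcome.value,
            return_home={True: "Yes", False: "No", None: "NA"}[p.returned_home],
            walk={True: "Yes", False: "No", None: "NA"}[p.walks],
        ))
    return pd.DataFrame(rows)


def assessment_table(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Export longitudinal assessments in the long-format schema."""
    rows = []
    for p in patients:
        mbt_by_day = {m.day: m for m in p.mbt}
        for a in p.assessments:
            row = dict(patient_no=p.id, day=a.day)
            for name in SUBSCALES:
                row[name] = getattr(a.profile, name)
            m = mbt_by_day.get(a.day)
            for i in range(1, 11):
                row[f"mbt_{i}"] = m.item(i) if m is not None else ""
            rows.append(row)
    return pd.DataFrame(rows)
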