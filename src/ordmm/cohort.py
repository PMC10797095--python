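"""Synthetic cohort generator.

Emulates a longitudinal soft-skill assessment study: three graduation
cohorts assessed at up to three stages (end of years 3, 4, 5), a catalog of
elective courses followed cumulatively during the last two years (at most 11
per student), ten skills scored on a 4-level ordinal rubric, a whole block
of missing baseline scores for the earliest cohort, and sporadic item-level
missingness.

Scores are drawn from the same multiple-membership cumulative-logit process
the inference model assumes: for skill ``i``, student ``s``, stage ``t``,

    logit P(Y <= k) = alpha_ik - eta,   eta = beta_i * N_st + sum_c u_ic w_cst + theta_is

with course effects ``u_ic ~ N(0, sigma_c)`` and student effects
``theta_is ~ N(0, sigma_s)``.  Keeping the generative process identical to
the model makes parameter-recovery testing meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data as dio
from .data import N_SKILLS, N_CATEGORIES, STAGES


@dataclass(frozen=True)
class CohortSpec:
    """One graduation cohort: its roster size and how many students have a
    dataset row at each stage (assessment coverage varies by cohort)."""

    label: str
    n_students: int
    rows_per_stage: Mapping[int, int]

    def __post_init__(self):
        if self.n_students <= 0:
            raise ValueError(f"cohort {self.label}: n_students must be positive")
        for t, n in self.rows_per_stage.items():
            if t not in STAGES:
                raise ValueError(f"cohort {self.label}: stage {t} outside {STAGES}")
            if not 0 < n <= self.n_students:
                raise ValueError(
                    f"cohort {self.label}: {n} rows at stage {t} exceeds roster"
                )


@dataclass(frozen=True)
class CohortDesign:
    """Cohort structure, course catalog, and per-stage enrollment increments."""

    cohorts: tuple[CohortSpec, ...]
    n_courses: int = 104
    max_courses: int = 11
    stage_increments: Mapping[int, int] = field(
        default_factory=lambda: {1: 6, 2: 5}
    )
    popularity_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.max_courses > self.n_courses:
            raise ValueError("max_courses exceeds catalog size")
        total = sum(self.stage_increments.values())
        if total > self.max_courses:
            raise ValueError(
                f"stage increments sum to {total} > max_courses={self.max_courses}"
            )
        if self.popularity_weights is not None and len(self.popularity_weights) != self.n_courses:
            raise ValueError("popularity_weights length must equal n_courses")

    @staticmethod
    def default() -> "CohortDesign":
        """The study-shaped design: three cohorts, 104 courses, <=11 per student.

        Row counts per stage mirror the published assessment coverage,
        including the absent baseline of the earliest cohort (those rows
        exist and are block-masked by the missingness plan) and the absent
        final stage of the latest cohort (no rows at all).
        """
        return CohortDesign(
            cohorts=(
                CohortSpec("2021", 250, {0: 250, 1: 250, 2: 141}),
                CohortSpec("2022", 245, {0: 194, 1: 245, 2: 141}),
                CohortSpec("2023", 366, {0: 339, 1: 366}),
            ),
            n_courses=104,
        )

    @staticmethod
    def small(n_students: int = 200, n_courses: int = 20) -> "CohortDesign":
        """A two-cohort desk-scale design with full stage coverage.

        Splitting the roster into two cohorts keeps block-missingness plans
        meaningful (a baseline block on cohort "A" leaves cohort "B" as the
        observed donor pool, as in the real study).  Enrollment increments
        shrink proportionally when the catalog cannot support the default
        6 + 5 schedule.
        """
        max_courses = min(11, n_courses)
        inc1 = min(6, max(1, max_courses * 6 // 11))
        inc2 = min(5, max_courses - inc1)
        n_a = n_students // 2
        n_b = n_students - n_a
        return CohortDesign(
            cohorts=(
                CohortSpec("A", n_a, {0: n_a, 1: n_a, 2: n_a}),
                CohortSpec("B", n_b, {0: n_b, 1: n_b, 2: n_b}),
            ),
            n_courses=n_courses,
            max_courses=max_courses,
            stage_increments={1: inc1, 2: inc2},
        )


@dataclass(frozen=True)
class EffectHyper:
    """Effect-size settings for drawing true parameters.

    Defaults sit at the magnitudes typical of postgraduate course effects on
    ordinal soft-skill scales: a mean per-course log-odds gain of ~0.2,
    course-effect SD ~0.15, student-effect SD ~0.35.  Default thresholds are
    chosen so the baseline (N=0) score distribution is right-skewed.
    ``shared_course_frac`` is the fraction of course-effect variance carried
    by a factor common to all skills; it induces positive cross-skill
    correlation of course effects.
    """

    beta: float = 0.2
    sigma_c: float = 0.15
    sigma_s: float = 0.35
    thresholds: tuple[float, ...] = (-0.5, 1.3, 3.0)
    shared_course_frac: float = 0.5
    assessment_halo: float = 0.65
    n_skills: int = N_SKILLS

    def __post_init__(self):
        if self.sigma_c < 0 or self.sigma_s < 0:
            raise ValueError("sigma hyper-values must be nonnegative")
        if not 0.0 <= self.shared_course_frac <= 1.0:
            raise ValueError("shared_course_frac must be in [0, 1]")
        if not 0.0 <= self.assessment_halo < 1.0:
            raise ValueError("assessment_halo must be in [0, 1)")
        d = np.diff(self.thresholds)
        if len(self.thresholds) != N_CATEGORIES - 1 or not (d > 0).all():
            raise ValueError("thresholds must be strictly increasing, length K-1")


@dataclass
class TrueParams:
    """Ground-truth parameters of one generated cohort (per skill)."""

    thresholds: np.ndarray   # (n_skills, K-1), strictly increasing rows
    beta: np.ndarray         # (n_skills,)
    sigma_c: np.ndarray      # (n_skills,)
    sigma_s: np.ndarray      # (n_skills,)
    u: np.ndarray            # (n_skills, n_courses)
    theta: np.ndarray        # (n_skills, n_students)
    student_ids: list = field(default_factory=list)

    def __post_init__(self):
        if (np.diff(self.thresholds, axis=1) <= 0).any():
            raise ValueError("thresholds must be strictly increasing within each skill")
        if (self.sigma_c < 0).any() or (self.sigma_s < 0).any():
            raise ValueError("sigma_c and sigma_s must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds.tolist(),
            "beta": self.beta.tolist(),
            "sigma_c": self.sigma_c.tolist(),
            "sigma_s": self.sigma_s.tolist(),
            "u": self.u.tolist(),
            "theta": self.theta.tolist(),
            "student_ids": list(self.student_ids),
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "TrueParams":
        d = json.loads(Path(path).read_text())
        return TrueParams(
            thresholds=np.asarray(d["thresholds"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            sigma_c=np.asarray(d["sigma_c"], dtype=float),
            sigma_s=np.asarray(d["sigma_s"], dtype=float),
            u=np.asarray(d["u"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            student_ids=d["student_ids"],
        )


@dataclass(frozen=True)
class MissingnessPlan:
    """Block rules (whole cohort x stage all-missing) plus MCAR item missingness."""

    blocks: tuple[tuple[str, int], ...] = ()
    item_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.item_rate <= 1.0:
            raise ValueError("item_rate must be in [0, 1]")

    @staticmethod
    def default() -> "MissingnessPlan":
        return MissingnessPlan(blocks=(("2021", 0),), item_rate=0.05)

    def check_against(self, design: CohortDesign) -> None:
        labels = {c.label for c in design.cohorts}
        for cohort, stage in self.blocks:
            if cohort not in labels:
                raise ValueError(f"block rule references unknown cohort {cohort!r}")
            if stage not in STAGES:
                raise ValueError(f"block rule references stage {stage} outside {STAGES}")


def _student_ids(design: CohortDesign) -> dict[str, list[str]]:
    ids: dict[str, list[str]] = {}
    counter = 1
    for spec in design.cohorts:
        ids[spec.label] = [str(counter + i) for i in range(spec.n_students)]
        counter += spec.n_students
    return ids


def draw_true_params(design: CohortDesign, hyper: EffectHyper, seed: int) -> TrueParams:
    """Draw per-skill true parameters; random effects are zero-mean normal.

    Course effects share a common factor across skills carrying
    ``shared_course_frac`` of their variance; student effects are
    independent across skills.
    """
    rng = np.random.default_rng(seed)
    n_students = sum(c.n_students for c in design.cohorts)
    I, C = hyper.n_skills, design.n_courses
    frac = hyper.shared_course_frac
    common = rng.standard_normal(C)
    specific = rng.standard_normal((I, C))
    u = hyper.sigma_c * (np.sqrt(frac) * common[None, :] + np.sqrt(1 - frac) * specific)
    theta = hyper.sigma_s * rng.standard_normal((I, n_students))
    ids = [sid for spec_ids in _student_ids(design).values() for sid in spec_ids]
    return TrueParams(
        thresholds=np.tile(np.asarray(hyper.thresholds, dtype=float), (I, 1)),
        beta=np.full(I, hyper.beta),
        sigma_c=np.full(I, hyper.sigma_c),
        sigma_s=np.full(I, hyper.sigma_s),
        u=u,
        theta=theta,
        student_ids=ids,
    )


def simulate_enrollment(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Draw cumulative course membership and emit the id/W/N part of the table.

    Every student starts with no courses at stage 0 and adds the per-stage
    increment of distinct courses (uniform over the catalog unless popularity
    weights are given).  Rows appear only for the (cohort, stage) coverage of
    the design; which students are assessed at an under-covered stage is a
    seeded random subset.
    """
    rng = np.random.default_rng(seed)
    ids = _student_ids(design)
    C = design.n_courses
    weights = None
    if design.popularity_weights is not None:
        weights = np.asarray(design.popularity_weights, dtype=float)
        weights = weights / weights.sum()

    records = []
    for spec in design.cohorts:
        n = spec.n_students
        # cumulative membership trajectory for every student in the roster
        member = np.zeros((n, C), dtype=np.int8)
        stage_snapshots = {0: member.copy()}
        for t in (1, 2):
            inc = design.stage_increments.get(t, 0)
            for s in range(n):
                available = np.flatnonzero(member[s] == 0)
                p = None
                if weights is not None:
                    p = weights[available] / weights[available].sum()
                chosen = rng.choice(available, size=inc, replace=False, p=p)
                member[s, chosen] = 1
            stage_snapshots[t] = member.copy()
        for t in sorted(spec.rows_per_stage):
            n_rows = spec.rows_per_stage[t]
            assessed = (np.arange(n) if n_rows == n
                        else np.sort(rng.choice(n, size=n_rows, replace=False)))
            snap = stage_snapshots[t]
            for s in assessed:
                records.append((ids[spec.label][s], spec.label, t, snap[s]))

    rows = pd.DataFrame(
        {
            "student_id": [r[0] for r in records],
            "cohort": [r[1] for r in records],
            "stage": [r[2] for r in records],
        }
    )
    W = np.stack([r[3] for r in records]).astype(int)
    wdf = pd.DataFrame(W, columns=[dio.course_col(c + 1) for c in range(C)])
    rows = pd.concat([rows, wdf], axis=1)
    rows["N"] = W.sum(axis=1)
    rows = rows.sort_values(["student_id", "stage"],
                            key=lambda s: s.astype(int) if s.name == "student_id" else s)
    return rows.reset_index(drop=True)


def category_probabilities(thresholds: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Cumulative-logit category probabilities, shape (..., K).

    ``P(Y <= k) = expit(alpha_k - eta)``; differences give the category
    masses.  Valid for any finite eta; rows sum to 1 exactly up to float
    rounding.
    """
    from scipy.special import expit

    thresholds = np.asarray(thresholds, dtype=float)
    if (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    eta = np.asarray(eta, dtype=float)
    cum = expit(thresholds - eta[..., None])          # (..., K-1)
    ones = np.ones_like(eta[..., None])
    zeros = np.zeros_like(eta[..., None])
    cum_full = np.concatenate([zeros, cum, ones], axis=-1)
    return np.diff(cum_full, axis=-1)


def simulate_scores(params: TrueParams, membership: pd.DataFrame, seed: int,
                    halo: float = 0.65) -> pd.DataFrame:
    """Draw ordinal scores for every row and skill from the generative model.

    ``halo`` is the Gaussian-copula correlation of the latent assessment
    noise across the ten skills within one student x stage row.  It
    emulates shared rater/occasion effects: each skill's marginal law is
    exactly the cumulative-logit model (so per-skill inference is
    untouched), but scores of different skills on the same assessment
    correlate, as rubric data do in practice.
    """
    from scipy.special import ndtr

    rng = np.random.default_rng(seed)
    n_courses = dio.n_courses_of(membership)
    if n_courses != params.u.shape[1]:
        raise ValueError("membership and params disagree on number of courses")
    sid_index = {s: i for i, s in enumerate(params.student_ids)}
    missing = [s for s in membership["student_id"] if s not in sid_index]
    if missing:
        raise ValueError(f"student {missing[0]!r} absent from TrueParams")
    w_cols = [dio.course_col(c) for c in range(1, n_courses + 1)]
    W = membership[w_cols].to_numpy(dtype=float)
    N = membership["N"].to_numpy(dtype=float)
    s_idx = np.array([sid_index[s] for s in membership["student_id"]])

    n_rows = len(membership)
    n_skills = params.beta.shape[0]
    # correlated uniforms via an equicorrelated Gaussian copula
    common = rng.standard_normal(n_rows)
    specific = rng.standard_normal((n_rows, n_skills))
    z = np.sqrt(halo) * common[:, None] + np.sqrt(1.0 - halo) * specific
    U = ndtr(z)

    out = membership.copy()
    cols = {}
    for i in range(n_skills):
        eta = params.beta[i] * N + W @ params.u[i] + params.theta[i, s_idx]
        probs = category_probabilities(params.thresholds[i], eta)
        cum = np.cumsum(probs, axis=1)
        draws = 1 + (U[:, i][:, None] > cum[:, :-1]).sum(axis=1)
        cols[dio.skill_col(i + 1)] = pd.array(draws, dtype="Int64")
    return pd.concat([out, pd.DataFrame(cols, index=out.index)], axis=1)


def apply_missingness(
    scores: pd.DataFrame, plan: MissingnessPlan, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask scores per the plan; returns (masked dataset, boolean mask frame).

    The mask frame has the score columns only, True where a value was
    removed, so tests can recover ground truth.
    """
    rng = np.random.default_rng(seed)
    out = scores.copy()
    score_cols = [dio.skill_col(i) for i in range(1, N_SKILLS + 1)]
    mask = pd.DataFrame(False, index=out.index, columns=score_cols)
    for cohort, stage in plan.blocks:
        rows = (out["cohort"] == cohort) & (out["stage"] == stage)
        mask.loc[rows, :] = True
    if plan.item_rate > 0:
        hits = rng.random((len(out), N_SKILLS)) < plan.item_rate
        mask |= pd.DataFrame(hits, index=out.index, columns=score_cols)
    for col in score_cols:
        out.loc[mask[col], col] = pd.NA
    return out, mask


@dataclass
class GeneratedCohort:
    dataset: pd.DataFrame
    true_params: TrueParams
    mask: pd.DataFrame


def generate(
    design: CohortDesign | None = None,
    hyper: EffectHyper | None = None,
    plan: MissingnessPlan | None = None,
    seed: int = 0,
) -> GeneratedCohort:
    """End-to-end generation: parameters, enrollment, scores, missingness.

    A single master seed streams into independent per-component seeds, so the
    output is byte-identical across re-runs with the same arguments.
    """
    design = design or CohortDesign.default()
    hyper = hyper or EffectHyper()
    plan = plan or MissingnessPlan.default()
    plan.check_against(design)
    ss = np.random.SeedSequence(seed)
    s_params, s_enroll, s_scores, s_miss = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    params = draw_true_params(design, hyper, s_params)
    membership = simulate_enrollment(design, s_enroll)
    full = simulate_scores(params, membership, s_scores, halo=hyper.assessment_halo)
    masked, mask = apply_missingness(full, plan, s_miss)
    return GeneratedCohort(dataset=masked, true_params=params, mask=mask)
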