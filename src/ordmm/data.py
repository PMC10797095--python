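"""Long-format dataset schema, validation, and conversion to model inputs.

The long table has one row per student x stage with the columns

    student_id, cohort, stage, W_1..W_C, N, sskill_1..sskill_10

where ``W_c`` are 0/1 course-membership dummies cumulative over stages,
``N`` is the row sum of the dummies (courses followed so far), and the ten
``sskill_i`` columns hold ordinal proficiency scores in {1, 2, 3, 4} with
missing entries left empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_SKILLS = 10
N_CATEGORIES = 4
STAGES = (0, 1, 2)

ID_COLS = ["student_id", "cohort", "stage"]


class SchemaError(ValueError):
    """Raised when a file or frame does not conform to the long-format schema."""


def skill_col(i: int) -> str:
    """Column name of skill ``i`` (1-based, as in the assessment rubric)."""
    if not 1 <= i <= N_SKILLS:
        raise IndexError(f"skill index must be in 1..{N_SKILLS}, got {i}")
    return f"sskill_{i}"


def course_col(c: int) -> str:
    return f"W_{c}"


def schema_columns(n_courses: int) -> list[str]:
    return (
        ID_COLS
        + [course_col(c) for c in range(1, n_courses + 1)]
        + ["N"]
        + [skill_col(i) for i in range(1, N_SKILLS + 1)]
    )


def n_courses_of(df: pd.DataFrame) -> int:
    return sum(1 for c in df.columns if c.startswith("W_"))


def write_long_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format dataset as UTF-8 CSV; missing scores become empty cells."""
    df.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read and type-check a long-format CSV.

    Raises :class:`SchemaError` naming the offending row and column on
    malformed headers or out-of-domain values.
    """
    raw = pd.read_csv(path, dtype={"student_id": str, "cohort": str})
    n_courses = n_courses_of(raw)
    expected = schema_columns(n_courses)
    if list(raw.columns) != expected:
        missing = [c for c in expected if c not in raw.columns]
        raise SchemaError(f"header mismatch; missing or misordered columns: {missing[:5]}")

    for col in ["stage", "N"] + [course_col(c) for c in range(1, n_courses + 1)]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-integer value in column {col!r} at row {r}")
        raw[col] = vals.astype(int)
    for i in range(1, N_SKILLS + 1):
        col = skill_col(i)
        vals = pd.to_numeric(raw[col], errors="coerce")
        filled = raw[col].notna()
        bad = filled & (vals.isna() | (vals != vals.round()))
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-integer score in column {col!r} at row {r}")
        out_of_scale = vals.notna() & ~vals.isin(range(1, N_CATEGORIES + 1))
        if out_of_scale.any():
            r = int(np.flatnonzero(out_of_scale.to_numpy())[0])
            raise SchemaError(
                f"score outside 1..{N_CATEGORIES} in column {col!r} at row {r}"
            )
        raw[col] = vals.astype("Int64")
    return raw


@dataclass
class Violation:
    kind: str
    student_id: str | None
    detail: str

    def to_dict(self) -> dict:
        return {"kind": self.kind, "student_id": self.student_id, "detail": self.detail}


def validate(df: pd.DataFrame) -> list[Violation]:
    """Check dataset invariants; returns an empty list iff all hold.

    Checked: stage domain, score domain, W dummies binary, N equal to the
    row sum of W, N = 0 at stage 0, and cumulative (nondecreasing) course
    membership within each student across stages.
    """
    out: list[Violation] = []
    n_courses = n_courses_of(df)
    w_cols = [course_col(c) for c in range(1, n_courses + 1)]
    W = df[w_cols].to_numpy()

    bad_stage = ~df["stage"].isin(STAGES)
    for r in np.flatnonzero(bad_stage.to_numpy()):
        out.append(Violation("stage domain", str(df["student_id"].iat[r]),
                             f"stage={df['stage'].iat[r]} not in {STAGES}"))

    if not np.isin(W, (0, 1)).all():
        r, c = np.argwhere(~np.isin(W, (0, 1)))[0]
        out.append(Violation("membership domain", str(df["student_id"].iat[r]),
                             f"{w_cols[c]} not 0/1"))

    mismatch = df["N"].to_numpy() != W.sum(axis=1)
    for r in np.flatnonzero(mismatch):
        out.append(Violation("count mismatch", str(df["student_id"].iat[r]),
                             f"N={df['N'].iat[r]} != row sum of W={int(W[r].sum())}"))

    stage0_n = (df["stage"] == 0) & (df["N"] != 0)
    for r in np.flatnonzero(stage0_n.to_numpy()):
        out.append(Violation("baseline count", str(df["student_id"].iat[r]),
                             "N != 0 at stage 0"))

    for i in range(1, N_SKILLS + 1):
        col = df[skill_col(i)]
        bad = col.notna() & ~col.isin(range(1, N_CATEGORIES + 1))
        for r in np.flatnonzero(bad.to_numpy()):
            out.append(Violation("score domain", str(df["student_id"].iat[r]),
                                 f"{skill_col(i)}={col.iat[r]} outside 1..4"))

    for sid, grp in df.sort_values("stage").groupby("student_id", sort=False):
        Wg = grp[w_cols].to_numpy()
        if (np.diff(Wg, axis=0) < 0).any():
            c = int(np.argwhere(np.diff(Wg, axis=0) < 0)[0][1])
            out.append(Violation("membership not cumulative", str(sid),
                                 f"{w_cols[c]} drops from 1 to 0 across stages"))
    return out


def write_violations(violations: list[Violation], path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        for v in violations:
            fh.write(json.dumps(v.to_dict()) + "\n")


@dataclass
class ModelData:
    """Per-skill arrays for the multiple-membership cumulative-logit model.

    Rows with a missing outcome for the skill are excluded: the likelihood
    runs over observed (or imputed) scores only.  The course dimension keeps
    the full catalog so that course labels are comparable across skills and
    imputations; students are re-indexed to those appearing in retained rows.
    """

    y: np.ndarray              # outcomes in 1..K, shape (n_rows,)
    counts: np.ndarray         # N_st per row
    membership: np.ndarray     # 0/1 matrix, shape (n_rows, n_courses)
    student_idx: np.ndarray    # 0-based index into `students` per row
    students: list             # retained student ids
    n_courses: int
    skill: int
    n_categories: int = N_CATEGORIES

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_students(self) -> int:
        return len(self.students)

    @property
    def members(self) -> list[np.ndarray]:
        """Course indices (0-based) followed by each row's student at that stage."""
        return [np.flatnonzero(row) for row in self.membership]


def to_model_inputs(df: pd.DataFrame, skill: int) -> ModelData:
    """Extract the per-skill model arrays from a validated long table."""
    col = skill_col(skill)
    obs = df[df[col].notna()]
    n_courses = n_courses_of(df)
    w_cols = [course_col(c) for c in range(1, n_courses + 1)]
    students = list(dict.fromkeys(obs["student_id"]))
    index = {s: i for i, s in enumerate(students)}
    return ModelData(
        y=obs[col].to_numpy(dtype=int),
        counts=obs["N"].to_numpy(dtype=int),
        membership=obs[w_cols].to_numpy(dtype=np.float64),
        student_idx=np.array([index[s] for s in obs["student_id"]], dtype=int),
        students=students,
        n_courses=n_courses,
        skill=skill,
    )


def wide_col(skill: int, stage: int) -> str:
    return f"sskill_{skill}_t{stage}"


def to_wide_scores(df: pd.DataFrame) -> pd.DataFrame:
    """One row per student; columns ``sskill_i_tT`` for every skill x stage, plus cohort.

    Cells are missing where the score is missing or the student has no row at
    that stage.  Raises on duplicate (student, stage) rows.
    """
    dup = df.duplicated(subset=["student_id", "stage"])
    if dup.any():
        sid = df.loc[dup, "student_id"].iloc[0]
        raise ValueError(f"duplicate (student, stage) rows for student {sid!r}")
    score_cols = [skill_col(i) for i in range(1, N_SKILLS + 1)]
    wide = df.pivot(index="student_id", columns="stage", values=score_cols)
    wide.columns = [wide_col(int(c[0].split("_")[1]), int(c[1])) for c in wide.columns]
    full = [wide_col(i, t) for t in STAGES for i in range(1, N_SKILLS + 1)
            if wide_col(i, t) in wide.columns]
    wide = wide[full].apply(lambda s: pd.to_numeric(s, errors="coerce"))
    wide = wide.astype("float64")
    cohorts = df.groupby("student_id", sort=False)["cohort"].first()
    wide.insert(0, "cohort", cohorts)
    # preserve first-appearance order of students
    order = list(dict.fromkeys(df["student_id"]))
    return wide.loc[order]


def fill_long_from_wide(wide: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    """Fill missing score cells of the long-format ``template`` from ``wide``.

    Observed cells are never modified; only cells that are missing in the
    template and present in the wide frame are written.
    """
    out = template.copy()
    for i in range(1, N_SKILLS + 1):
        for t in STAGES:
            col = wide_col(i, t)
            if col not in wide.columns:
                continue
            rows = (out["stage"] == t) & out[skill_col(i)].isna()
            if not rows.any():
                continue
            mapped = out.loc[rows, "student_id"].map(wide[col])
            arr = pd.to_numeric(mapped, errors="coerce").to_numpy(dtype=float,
                                                                  na_value=np.nan)
            vals = pd.Series(np.round(arr), index=mapped.index)
            out.loc[rows, skill_col(i)] = vals.astype("Int64")
    return out
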