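import numpy as np
import pandas as pd
import pytest

from ordmm import cohort as sc
from ordmm import data as dio


@pytest.fixture(scope="session")
def small_design():
    return sc.CohortDesign.small(60, 8)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """A fully generated small cohort with block and item missingness."""
    plan = sc.MissingnessPlan(blocks=(("A", 0),), item_rate=0.05)
    return sc.generate(small_design, sc.EffectHyper(), plan, seed=7)


@pytest.fixture(scope="session")
def complete_cohort(small_design):
    """Same design but no missingness at all."""
    return sc.generate(small_design, sc.EffectHyper(), sc.MissingnessPlan(), seed=7)


def build_toy_long(n_courses: int = 3) -> pd.DataFrame:
    """Two students x three stages with hand-set memberships and scores."""
    rows = []
    w = {
        ("s1", 0): [0, 0, 0], ("s1", 1): [1, 0, 0], ("s1", 2): [1, 1, 0],
        ("s2", 0): [0, 0, 0], ("s2", 1): [0, 1, 0], ("s2", 2): [0, 1, 1],
    }
    scores = {
        ("s1", 0): 1, ("s1", 1): 2, ("s1", 2): 3,
        ("s2", 0): 2, ("s2", 1): None, ("s2", 2): 4,
    }
    for (sid, stage), ws in w.items():
        row = {"student_id": sid, "cohort": "A", "stage": stage}
        for c, v in enumerate(ws, start=1):
            row[f"W_{c}"] = v
        row["N"] = sum(ws)
        for i in range(1, dio.N_SKILLS + 1):
            row[f"sskill_{i}"] = scores[(sid, stage)]
        rows.append(row)
    df = pd.DataFrame(rows)
    for i in range(1, dio.N_SKILLS + 1):
        df[f"sskill_{i}"] = df[f"sskill_{i}"].astype("Int64")
    return df


@pytest.fixture()
def toy_long():
    return build_toy_long()


@pytest.fixture(scope="session")
def small_fit(complete_cohort):
    """One short MCMC fit on the complete small cohort, shared across tests."""
    from ordmm import model as mdl

    data = dio.to_model_inputs(complete_cohort.dataset, 1)
    return mdl.fit(data, mcmc=mdl.McmcConfig(n_chains=2, n_iter=400,
                                             n_warmup=200), seed=4)
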