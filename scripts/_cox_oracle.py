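"""Brute-force Cox partial-likelihood oracle for the 6-subject toy."""

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from twinlate import TwinCohort

SPECS = [  # (score, event, duration)
    (1, 1, 2.0), (0, 1, 4.0), (1, 1, 6.0),
    (0, 0, 7.0), (1, 0, 9.0), (0, 1, 11.0),
]


def cox_toy_cohort():
    ind, obs = [], []
    for i, (score, event, dur) in enumerate(SPECS):
        pid = f"P{i}"
        ind.append((pid, f"F{i}", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0,
                    event, 70.0 + dur))
        obs.append((pid, 1, 70.0, score))
    individuals = pd.DataFrame(
        ind, columns=["person_id", "family_id", "zygosity", "study", "sex",
                      "birth_year", "education", "isei", "illness", "apoe_e4",
                      "dementia", "event_age"],
    ).astype({"apoe_e4": "Int64", "birth_year": "Int64", "education": "Int64"})
    observations = pd.DataFrame(
        obs, columns=["person_id", "wave", "age_at_wave", "score"]
    ).astype({"score": "Float64"})
    return TwinCohort(individuals, observations), SPECS


def _pl(beta, specs):
    x = np.array([s[0] for s in specs], dtype=float)
    event = np.array([s[1] for s in specs])
    dur = np.array([s[2] for s in specs], dtype=float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = dur >= dur[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_toy_grid_max(specs):
    grid = np.linspace(-4, 4, 2001)
    b0 = grid[int(np.argmax([_pl(b, specs) for b in grid]))]
    res = minimize_scalar(
        lambda b: -_pl(b, specs), bracket=(b0 - 0.01, b0, b0 + 0.01),
        method="golden", options={"xtol": 1e-10},
    )
    return float(res.x)
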