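"""Independent oracles shared by unit and acceptance tests.

These are deliberately naive implementations (grids, closed forms) kept
separate from the package so they can serve as a cross-check.
"""

import numpy as np
from scipy.optimize import minimize_scalar

from conftest import make_cohort


def cox_toy_cohort():
    """Six subjects, one binary covariate, distinct event times."""
    specs = [  # (score, event, duration)
        (1, 1, 2.0), (0, 1, 4.0), (1, 1, 6.0),
        (0, 0, 7.0), (1, 0, 9.0), (0, 1, 11.0),
    ]
    ind, obs = [], []
    for i, (score, event, dur) in enumerate(specs):
        pid = f"P{i}"
        ind.append((pid, f"F{i}", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0,
                    event, 70.0 + dur))
        obs.append((pid, 1, 70.0, score))
    return make_cohort(ind, obs), specs


def cox_partial_loglik(beta, specs):
    """Plain (no ties) Cox partial log-likelihood for the toy data."""
    x = np.array([s[0] for s in specs], dtype=float)
    event = np.array([s[1] for s in specs])
    dur = np.array([s[2] for s in specs], dtype=float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = dur >= dur[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_toy_grid_max(specs):
    """Brute-force maximiser: coarse grid then golden-section polish."""
    grid = np.linspace(-4, 4, 2001)
    lls = [cox_partial_loglik(b, specs) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, specs),
        bracket=(b0 - 0.01, b0, b0 + 0.01), method="golden",
        options={"xtol": 1e-10},
    )
    return float(res.x)
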