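"""Synthetic twin cohorts with known ACE structure on loneliness growth.

The generator emulates three Swedish longitudinal twin studies of aging
(SATSA, GENDER, OCTO-Twin): 5-6 measurement waves per study, intake ages
centred in the mid-70s, a single ordinal loneliness item on the 0-3 scale,
roughly a quarter of the sample developing dementia, and APOE genotypes at
the frequencies observed in the genotyped subsample.  Each person's latent
loneliness trajectory is quadratic in centred age,

    latent(age) = pi0 + pi1 * t + pi2 * t**2,    t = (age - 60) / 10,

and the per-person growth parameters (pi0, pi1, pi2) decompose into additive
genetic (A), shared environmental (C) and nonshared environmental (E)
component scores.  Monozygotic pairs share the genetic score entirely
(between-family weight 1, within-family genetic variance 0); dizygotic pairs
split the genetic variance equally between a shared between-family part and
an individual within-family part, so the DZ genetic correlation is 0.5 and
total genetic variance is the same in both zygosity groups.  Shared
environment is wholly between-family, nonshared environment wholly
within-family.  Realised component scores are retained (:class:`TrueParameters`)
so downstream estimators can be checked against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import TwinCohort
from .errors import ConfigError, DomainError

GENOTYPE_E4_COUNT = {"2/2": 0, "2/3": 0, "3/3": 0, "2/4": 1, "3/4": 1, "4/4": 2}

#: genotype frequencies in the genotyped subsample of the emulated registry
DEFAULT_APOE_FREQS = {
    "2/2": 0.0076,
    "2/3": 0.1393,
    "2/4": 0.0324,
    "3/3": 0.5691,
    "3/4": 0.2311,
    "4/4": 0.0205,
}

DEFAULT_WAVE_SCHEDULES = {
    # inter-wave gaps in years, matching the emulated studies' field periods
    "SATSA": [3.0, 3.0, 11.0, 3.0, 3.0],
    "GENDER": [3.0, 4.0, 4.0, 4.0],
    "OCTO": [2.0, 2.0, 2.0, 2.0],
}

STUDY_START_YEAR = {"SATSA": 1987, "GENDER": 1992, "OCTO": 1991}


@dataclass
class MissingSpec:
    """Missingness mechanism applied to loneliness scores."""

    mechanism: str = "MAR"  # MCAR | MAR | MNAR
    rate: float = 0.0
    delta: float = 0.0


@dataclass
class SimConfig:
    """Generating parameters of a synthetic twin cohort.

    Defaults emulate the pooled three-study sample: intake age 74.75 (SD
    8.66), ~25% dementia incidence with mean onset 82.67 (SD 6.29), baseline
    loneliness mean ~0.6 on the 0-3 scale, intercept variance split
    (A, C, E) ~ (0.08, 0.20, 0.72) and no between-family variance in the
    quadratic slope.
    """

    n_pairs_mz: int = 350
    n_pairs_dz: int = 500
    study_mix: dict = field(
        default_factory=lambda: {"SATSA": 0.446, "GENDER": 0.335, "OCTO": 0.219}
    )
    wave_schedules: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_SCHEDULES))
    age_intake_mean: float = 74.75
    age_intake_sd: float = 8.66
    fixed_effects: tuple = (0.2, 0.02, 0.015)  # (beta0, beta1, beta2) on t
    # per-growth-parameter component variances (intercept, linear, quadratic)
    var_a: tuple = (0.02, 0.015, 0.0)
    var_c: tuple = (0.05, 0.0, 0.0)
    var_e: tuple = (0.18, 0.025, 0.004)
    # intercept-slope covariance within each component (A, C, E)
    cov_is: tuple = (0.002, 0.0, 0.01)
    resid_sd: float = 0.6  # wave-level noise on the latent before ordinalization
    thresholds: tuple = (0.46, 1.28, 2.00)
    dementia_model: dict = field(
        default_factory=lambda: {
            "intercept": -1.58,
            "pi0": 0.35,
            "pi1": 0.0,
            "pi2": 0.0,
            "age": 0.5,  # per SD of intake age
            "apoe": 0.9,  # per e4 allele
            "education": -0.1,
            "illness": 0.15,
            "sex_f": 0.1,
            # weight on the genetic intercept score itself: > 0 makes the
            # loneliness-dementia association purely genetically confounded
            "a_intercept": 0.0,
        }
    )
    onset_mean: float = 82.67
    onset_sd: float = 6.29
    # biometric-regression generating effects: rows (intercept, linear,
    # quadratic), entries (areg, creg, ereg); all zero by default (the null
    # the emulated study reported)
    reg_effects: tuple = ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    risk_mu: float = 0.0
    # residual variance of the risk score: (within, between) per zygosity
    risk_resid_var: dict = field(
        default_factory=lambda: {"MZ": (1.0, 0.8), "DZ": (1.0, 0.76)}
    )
    apoe_freqs: dict = field(default_factory=lambda: dict(DEFAULT_APOE_FREQS))
    apoe_missing_rate: float = 0.626
    missing: MissingSpec = field(default_factory=MissingSpec)
    #: False records the noisy latent itself instead of the 0-3 category
    #: (used in estimator-validation studies; real instruments are ordinal)
    ordinal: bool = True
    seed: int = 0

    def component_cov(self, which: str) -> np.ndarray:
        """3x3 covariance of one component's (intercept, linear, quad) scores."""
        v = {"A": self.var_a, "C": self.var_c, "E": self.var_e}[which]
        c = self.cov_is[{"A": 0, "C": 1, "E": 2}[which]]
        m = np.array([[v[0], c, 0.0], [c, v[1], 0.0], [0.0, 0.0, v[2]]])
        return m

    def validate(self) -> None:
        if self.n_pairs_mz + self.n_pairs_dz <= 0:
            raise ConfigError("at least one twin pair is required")
        if any(v < 0 for v in (*self.var_a, *self.var_c, *self.var_e)):
            raise ConfigError("component variances must be nonnegative")
        if abs(sum(self.study_mix.values()) - 1.0) > 1e-8:
            raise ConfigError("study_mix proportions must sum to 1")
        th = self.thresholds
        if not (th[0] < th[1] < th[2]):
            raise ConfigError("thresholds must be strictly increasing")
        for which in "ACE":
            m = self.component_cov(which)[:2, :2]
            if np.linalg.det(m) < -1e-12:
                raise ConfigError(f"{which} intercept-slope covariance exceeds variances")
        if not 0 <= self.missing.rate < 1:
            raise ConfigError("missing rate must be in [0, 1)")
        if abs(sum(self.apoe_freqs.values()) - 1.0) > 1e-6:
            raise ConfigError("apoe_freqs must sum to 1")


@dataclass
class TrueParameters:
    """Realised latent quantities retained for estimator-recovery checks.

    ``params`` has one row per person: total growth parameters ``pi0..pi2``,
    component scores ``a_within/ a_between/ c_shared/ e_within`` for each of
    the three growth parameters, the total genetic score ``a_tot*``, and the
    dementia linear predictor.
    """

    params: pd.DataFrame

    def for_person(self, person_id) -> pd.Series:
        return self.params.set_index("person_id").loc[person_id]


def ordinalize_latent(latent, thresholds) -> np.ndarray:
    """Map a latent value onto the 0-3 ordinal scale.

    The category is the number of thresholds strictly below the latent value,
    so the map is monotone in the latent.
    """
    th = np.asarray(thresholds, dtype=float)
    if th.shape != (3,) or not (th[0] < th[1] < th[2]):
        raise ConfigError("thresholds must be three strictly increasing values")
    lat = np.asarray(latent, dtype=float)
    cat = (lat[..., None] > th).sum(axis=-1)
    if np.ndim(latent) == 0:
        return int(cat)
    return cat.astype(int)


def _draw_pair_components(rng, cov_a, cov_c, cov_e, zygosity, n_pairs):
    """Component scores for n_pairs pairs of one zygosity.

    Returns arrays of shape (n_pairs, 2, 3): a_within, a_between, c_shared,
    e_within.  a_between and c_shared are identical across the two twins of
    a pair by construction.
    """
    def mvn(cov, size):
        # eigen square root: components with zero variance yield exact zeros
        w, V = np.linalg.eigh(cov)
        root = V * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal(size=(*size, 3))
        return z @ root.T

    if zygosity == "MZ":
        ab = mvn(cov_a, (n_pairs,))  # shared genetic score, weight 1
        aw = np.zeros((n_pairs, 2, 3))  # within-family genetic effect is 0
    else:
        ab = mvn(0.5 * cov_a, (n_pairs,))
        aw = mvn(0.5 * cov_a, (n_pairs, 2))
    cshared = mvn(cov_c, (n_pairs,))
    ew = mvn(cov_e, (n_pairs, 2))
    ab2 = np.repeat(ab[:, None, :], 2, axis=1)
    cs2 = np.repeat(cshared[:, None, :], 2, axis=1)
    return aw, ab2, cs2, ew


def simulate_cohort(config: SimConfig) -> tuple[TwinCohort, TrueParameters]:
    """Generate a twin cohort and its generating truth.

    Identical configs (including seed) yield identical cohorts; all draws
    flow from one seeded generator in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    blocks = []
    for zyg, n_pairs in (("MZ", config.n_pairs_mz), ("DZ", config.n_pairs_dz)):
        if n_pairs == 0:
            continue
        aw, ab, cs, ew = _draw_pair_components(
            rng,
            config.component_cov("A"),
            config.component_cov("C"),
            config.component_cov("E"),
            zyg,
            n_pairs,
        )
        pi = np.asarray(config.fixed_effects) + aw + ab + cs + ew
        blocks.append((zyg, n_pairs, aw, ab, cs, ew, pi))

    studies = list(config.study_mix)
    probs = np.array([config.study_mix[s] for s in studies])

    ind_rows, obs_rows, truth_rows = [], [], []
    pid = 0
    fam = 0
    for zyg, n_pairs, aw, ab, cs, ew, pi in blocks:
        study_idx = rng.choice(len(studies), size=n_pairs, p=probs)
        intake = rng.normal(config.age_intake_mean, config.age_intake_sd, size=n_pairs)
        intake = np.clip(intake, 40.0, 95.0)
        for j in range(n_pairs):
            fam += 1
            study = studies[study_idx[j]]
            gaps = config.wave_schedules[study]
            ages = intake[j] + np.concatenate([[0.0], np.cumsum(gaps)])
            ages = np.round(ages[ages <= 101.0], 2)
            birth_year = int(round(STUDY_START_YEAR[study] - intake[j]))

            # pair-level APOE: MZ co-twins share a genotype draw
            genos = list(config.apoe_freqs)
            gp = np.array([config.apoe_freqs[g] for g in genos])
            g1 = genos[rng.choice(len(genos), p=gp)]
            g2 = g1 if zyg == "MZ" else genos[rng.choice(len(genos), p=gp)]

            if study == "GENDER" and zyg == "DZ":
                sexes = ["F", "M"] if rng.random() < 0.5 else ["M", "F"]
            else:
                sexes = [("F" if rng.random() < 0.5 else "M")] * 2

            for i in range(2):
                pid += 1
                person = f"P{pid:06d}"
                edu = int(rng.integers(1, 5))
                isei = float(np.round(rng.normal(45.0, 12.0), 1))
                illness = float(np.round(rng.gamma(2.0, 1.5), 2))
                geno = (g1, g2)[i]
                e4 = GENOTYPE_E4_COUNT[geno]
                apoe_obs = rng.random() >= config.apoe_missing_rate
                dm = config.dementia_model
                lp = (
                    dm["intercept"]
                    + dm["pi0"] * pi[j, i, 0]
                    + dm["pi1"] * pi[j, i, 1]
                    + dm["pi2"] * pi[j, i, 2]
                    + dm["age"] * (intake[j] - config.age_intake_mean) / config.age_intake_sd
                    + dm["apoe"] * e4
                    + dm["education"] * (edu - 2.5)
                    + dm["illness"] * (illness - 3.0)
                    + dm["sex_f"] * (sexes[i] == "F")
                    + dm.get("a_intercept", 0.0) * (aw[j, i, 0] + ab[j, i, 0])
                )
                dementia = int(rng.random() < expit(lp))
                if dementia:
                    onset = rng.normal(config.onset_mean, config.onset_sd)
                    event_age = float(np.clip(onset, intake[j] + 0.5, 101.0))
                else:
                    followup = np.clip(rng.normal(14.0, 6.0), 1.0, 30.0)
                    event_age = float(min(intake[j] + followup, 101.0))

                ind_rows.append(
                    (person, f"F{fam:05d}", zyg, study, sexes[i], birth_year,
                     edu, isei, illness, e4 if apoe_obs else pd.NA, dementia,
                     round(event_age, 2))
                )
                t = (ages - 60.0) / 10.0
                latent = (
                    pi[j, i, 0] + pi[j, i, 1] * t + pi[j, i, 2] * t**2
                    + rng.normal(0.0, config.resid_sd, size=len(ages))
                )
                if config.ordinal:
                    scores = ordinalize_latent(latent, config.thresholds)
                else:
                    scores = latent
                for w, (a, s) in enumerate(zip(ages, scores), start=1):
                    obs_rows.append((person, w, float(a), float(s)))

                truth_rows.append(
                    {
                        "person_id": person,
                        "family_id": f"F{fam:05d}",
                        "zygosity": zyg,
                        **{f"pi{k}": pi[j, i, k] for k in range(3)},
                        **{f"aw{k}": aw[j, i, k] for k in range(3)},
                        **{f"ab{k}": ab[j, i, k] for k in range(3)},
                        **{f"atot{k}": aw[j, i, k] + ab[j, i, k] for k in range(3)},
                        **{f"c{k}": cs[j, i, k] for k in range(3)},
                        **{f"ew{k}": ew[j, i, k] for k in range(3)},
                        "dementia_lp": lp,
                    }
                )

    individuals = pd.DataFrame(
        ind_rows,
        columns=["person_id", "family_id", "zygosity", "study", "sex",
                 "birth_year", "education", "isei", "illness", "apoe_e4",
                 "dementia", "event_age"],
    ).astype({"apoe_e4": "Int64", "birth_year": "Int64", "education": "Int64"})
    observations = pd.DataFrame(
        obs_rows, columns=["person_id", "wave", "age_at_wave", "score"]
    ).astype({"score": "Float64"})
    cohort = TwinCohort(individuals, observations, ordinal_scores=config.ordinal)
    truth = TrueParameters(pd.DataFrame(truth_rows))

    if config.missing.rate > 0:
        cohort = apply_missingness(
            cohort,
            config.missing.mechanism,
            config.missing.rate,
            config.missing.delta,
            rng,
        )
    return cohort, truth


def simulate_risk_scores(
    truth: TrueParameters, config: SimConfig, seed=None
) -> pd.DataFrame:
    """Continuous dementia-risk scores generated from the component scores.

    risk = mu + sum_k (areg_k * A_k + creg_k * C_k + ereg_k * Ew_k) + e,
    with the residual e split into a between-family part shared by co-twins
    and a within part, each with zygosity-specific variance.  Used to study
    the biometric regression under a known truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed + 1 if seed is None else seed
    )
    df = truth.params
    reg = np.asarray(config.reg_effects, dtype=float)  # rows: param; cols a,c,e
    systematic = config.risk_mu + sum(
        reg[k, 0] * df[f"atot{k}"] + reg[k, 1] * df[f"c{k}"] + reg[k, 2] * df[f"ew{k}"]
        for k in range(3)
    )
    fam_between = {}
    resid = np.empty(len(df))
    for idx, row in enumerate(df.itertuples()):
        w_var, b_var = config.risk_resid_var[row.zygosity]
        if row.family_id not in fam_between:
            fam_between[row.family_id] = rng.normal(0.0, np.sqrt(b_var))
        resid[idx] = fam_between[row.family_id] + rng.normal(0.0, np.sqrt(w_var))
    return pd.DataFrame(
        {"person_id": df["person_id"], "resid": np.asarray(systematic) + resid}
    )


# ---------------------------------------------------------------------------
# missingness


def _calibrated_bernoulli(rng, lp, rate):
    """Deletion indicators with mean ``rate`` given linear-predictor offsets."""
    lo, hi = -30.0, 30.0
    a = brentq(lambda a_: float(np.mean(expit(a_ + lp))) - rate, lo, hi)
    return rng.random(len(lp)) < expit(a + lp)


def apply_missingness(
    cohort: TwinCohort, mechanism: str, rate: float, delta: float = 0.0, seed=0
) -> TwinCohort:
    """Delete loneliness scores under MCAR, MAR or MNAR.

    MCAR deletes independently at ``rate``; MAR with probability depending on
    age and sex (observed covariates); MNAR with probability increasing in
    the value about to be deleted, shifted by ``delta``.  A person who would
    lose every score has one randomly chosen observation restored, so each
    person retains at least one score.
    """
    if not 0 <= rate < 1:
        raise DomainError("missingness rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR", "MNAR"):
        raise DomainError(f"unknown missingness mechanism {mechanism!r}")
    if rate == 0:
        return TwinCohort(cohort.individuals.copy(), cohort.observations.copy(),
                          ordinal_scores=cohort.ordinal_scores)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = cohort.observations.copy().reset_index(drop=True)
    present = obs["score"].notna().to_numpy()
    idx = np.flatnonzero(present)

    if mechanism == "MCAR":
        drop = rng.random(len(idx)) < rate
    elif mechanism == "MAR":
        merged = obs.merge(
            cohort.individuals[["person_id", "sex"]], on="person_id", how="left"
        )
        lp = (
            0.8 * (merged.loc[idx, "age_at_wave"].to_numpy() - 75.0) / 10.0
            - 0.3 * (merged.loc[idx, "sex"] == "F").to_numpy()
        )
        drop = _calibrated_bernoulli(rng, lp, rate)
    else:  # MNAR: depends on the (to-be-deleted) score, shifted by delta
        score = obs.loc[idx, "score"].to_numpy(dtype=float)
        lp = 0.7 * (score + delta)
        drop = _calibrated_bernoulli(rng, lp, rate)

    new_score = obs["score"].copy()
    new_score.iloc[idx[drop]] = pd.NA

    # guarantee >= 1 retained observation per person
    kept = new_score.notna()
    for person, grp in obs.groupby("person_id", sort=False):
        gi = grp.index
        if present[gi].any() and not kept.iloc[gi].any():
            candidates = gi[present[gi]]
            keep_one = candidates[rng.integers(len(candidates))]
            new_score.iloc[keep_one] = obs["score"].iloc[keep_one]

    obs["score"] = new_score
    return TwinCohort(cohort.individuals.copy(), obs,
                      ordinal_scores=cohort.ordinal_scores)


def perturb_config(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced (convenience)."""
    return replace(config, **overrides)
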