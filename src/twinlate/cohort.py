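"""Twin cohort data model, long-format CSV I/O and descriptive summaries.

A cohort couples a person-level table (one row per twin: zygosity, study,
dementia outcome, covariates) with a person-wave table of single-item
loneliness scores on the 0-3 scale (higher = lonelier).  The loneliness item
is administered with four response options (1 = nearly always lonely ...
4 = hardly ever/never); :func:`reverse_score_loneliness` maps the raw coding
onto the analysis scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, IntegrityError, SchemaError

#: person-level columns of the denormalised CSV layout
INDIVIDUAL_COLUMNS = [
    "person_id",
    "family_id",
    "zygosity",
    "study",
    "sex",
    "birth_year",
    "education",
    "isei",
    "illness",
    "apoe_e4",
    "dementia",
    "event_age",
]

#: person-wave columns
OBSERVATION_COLUMNS = ["person_id", "wave", "age_at_wave", "score"]

ZYGOSITIES = ("MZ", "DZ")
STUDIES = ("SATSA", "GENDER", "OCTO")


@dataclass
class TwinCohort:
    """A validated twin cohort.

    Parameters
    ----------
    individuals
        One row per person; columns :data:`INDIVIDUAL_COLUMNS`.
    observations
        One row per person-wave; columns :data:`OBSERVATION_COLUMNS`.
        ``score`` may be missing (NA); ``age_at_wave`` is in decimal years.
    rejected_lines
        1-based CSV line numbers of rows dropped at load time because the
        person id could not be parsed (empty for programmatically built
        cohorts).
    """

    individuals: pd.DataFrame
    observations: pd.DataFrame
    rejected_lines: list[int] = field(default_factory=list)
    #: False when scores are continuous latent readings (simulation studies
    #: of the estimators); the 0-3 category check then does not apply
    ordinal_scores: bool = True

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.observations = self.observations.reset_index(drop=True)
        _validate(self.individuals, self.observations, self.ordinal_scores)

    # -- structure -----------------------------------------------------
    @property
    def pairs(self) -> dict:
        """Mapping family_id -> tuple of person_ids (length 1 or 2)."""
        return {
            fam: tuple(g["person_id"])
            for fam, g in self.individuals.groupby("family_id", sort=False)
        }

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_pairs(self) -> int:
        """Number of complete twin pairs (families with both members)."""
        sizes = self.individuals.groupby("family_id").size()
        return int((sizes == 2).sum())

    def subset(self, person_ids) -> "TwinCohort":
        """Restrict the cohort to the given persons (families follow)."""
        keep = set(person_ids)
        ind = self.individuals[self.individuals["person_id"].isin(keep)]
        obs = self.observations[self.observations["person_id"].isin(keep)]
        return TwinCohort(ind.copy(), obs.copy(), ordinal_scores=self.ordinal_scores)

    def person_waves(self) -> pd.DataFrame:
        """Observations joined with person-level fields (analysis view)."""
        return self.observations.merge(self.individuals, on="person_id", how="left")

    def baseline_table(self) -> pd.DataFrame:
        """Per-person first/last non-missing score and intake age.

        Baseline is the first wave with a non-missing score for that person,
        not the first study wave; intake age is the age at that wave.
        """
        obs = self.observations.dropna(subset=["score"]).sort_values(
            ["person_id", "wave"]
        )
        if obs.empty:
            raise IntegrityError("cohort has no non-missing loneliness scores")
        first = obs.groupby("person_id", sort=False).first()
        last = obs.groupby("person_id", sort=False).last()
        n_obs = obs.groupby("person_id", sort=False).size()
        out = pd.DataFrame(
            {
                "baseline_score": first["score"].astype(float),
                "baseline_age": first["age_at_wave"].astype(float),
                "last_score": last["score"].astype(float),
                "last_age": last["age_at_wave"].astype(float),
                "n_scores": n_obs,
            }
        ).reset_index()
        return out.merge(self.individuals, on="person_id", how="left")


@dataclass
class CohortSummary:
    """Descriptive statistics of a cohort (baseline vs last loneliness)."""

    n_individuals: int
    n_pairs: int
    pct_dementia: float
    mean_baseline_loneliness: float
    sd_baseline: float
    mean_last_loneliness: float
    sd_last: float
    paired_t_statistic: float
    mean_intake_age: float
    t_degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------


def reverse_score_loneliness(raw):
    """Map the raw 1-4 loneliness item onto the 0-3 analysis scale.

    The raw response options run 1 = nearly always/always lonely ...
    4 = hardly ever/never.  Scores are reversed (``4 - raw``) so that higher
    values indicate higher loneliness, anchored at 0.
    """
    arr = np.asarray(raw)
    vals = arr[~pd.isna(arr)]
    if vals.size and (np.any(vals < 1) | np.any(vals > 4) | np.any(vals != np.round(vals))):
        raise DomainError(f"raw loneliness responses must be integers in 1..4, got {raw!r}")
    out = 4 - arr
    if np.isscalar(raw) or np.ndim(raw) == 0:
        return out.item() if not pd.isna(out) else out
    return out


def summarize_cohort(cohort: TwinCohort) -> CohortSummary:
    """Baseline/last loneliness descriptives and the paired-change t statistic.

    The paired t is computed on (last - baseline) over persons with at least
    two non-missing scores; with zero variance in the differences the
    statistic is reported as 0 with ``t_degenerate=True``.
    """
    if cohort.n_individuals == 0:
        raise IntegrityError("cannot summarise an empty cohort")
    base = cohort.baseline_table()
    d = base.loc[base["n_scores"] >= 2, "last_score"] - base.loc[
        base["n_scores"] >= 2, "baseline_score"
    ]
    degenerate = False
    if len(d) >= 2 and float(d.std(ddof=1)) > 0:
        t_stat = float(d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))
    else:
        t_stat, degenerate = 0.0, True
    return CohortSummary(
        n_individuals=cohort.n_individuals,
        n_pairs=cohort.n_pairs,
        pct_dementia=float(100.0 * cohort.individuals["dementia"].mean()),
        mean_baseline_loneliness=float(base["baseline_score"].mean()),
        sd_baseline=float(base["baseline_score"].std(ddof=1)),
        mean_last_loneliness=float(base["last_score"].mean()),
        sd_last=float(base["last_score"].std(ddof=1)),
        paired_t_statistic=t_stat,
        mean_intake_age=float(base["baseline_age"].mean()),
        t_degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def _read_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, dict):
        return dict(schema)
    with open(schema) as fh:  # YAML mapping canonical -> actual column name
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise SchemaError(f"schema file {schema!r} must contain a mapping")
    return loaded


def load_cohort(path, schema=None) -> TwinCohort:
    """Load a cohort from a denormalised long-format CSV.

    One row per person-wave; person-level fields are repeated across a
    person's rows.  ``schema`` optionally maps canonical column names to the
    file's actual column names (dict or YAML file path).  Rows whose person
    id is missing are rejected; their 1-based line numbers are recorded on
    the returned cohort.
    """
    mapping = _read_schema(schema)
    df = pd.read_csv(path, dtype={"person_id": str, "family_id": str})
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    df = df.rename(columns=rename)

    required = set(INDIVIDUAL_COLUMNS) | set(OBSERVATION_COLUMNS)
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    bad = df["person_id"].isna() | (df["person_id"].astype(str).str.strip() == "")
    rejected = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
    df = df[~bad]

    dup = df.duplicated(subset=["person_id", "wave"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["person_id", "wave"]].drop_duplicates()
        raise IntegrityError(
            "duplicate (person_id, wave) rows: "
            + ", ".join(f"({r.person_id}, {r.wave})" for r in pairs.itertuples())
        )

    individuals = (
        df[INDIVIDUAL_COLUMNS].groupby("person_id", as_index=False, sort=False).first()
    )
    individuals = individuals.astype(
        {"birth_year": "Int64", "apoe_e4": "Int64", "dementia": "int64",
         "education": "Int64", "event_age": "float64", "isei": "float64",
         "illness": "float64"}
    )
    observations = df[OBSERVATION_COLUMNS].copy()
    observations = observations.astype(
        {"wave": "int64", "age_at_wave": "float64", "score": "Float64"}
    )
    return TwinCohort(individuals, observations, rejected_lines=rejected)


def write_cohort(cohort: TwinCohort, path) -> None:
    """Write a cohort back to the denormalised long CSV layout."""
    wide = cohort.observations.merge(cohort.individuals, on="person_id", how="left")
    # canonical column order: person-wave first, then person-level
    wide = wide[OBSERVATION_COLUMNS + INDIVIDUAL_COLUMNS[1:]]
    wide.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def _validate(
    individuals: pd.DataFrame, observations: pd.DataFrame, ordinal_scores: bool = True
) -> None:
    for col in INDIVIDUAL_COLUMNS:
        if col not in individuals.columns:
            raise SchemaError(f"individuals table lacks column {col!r}")
    for col in OBSERVATION_COLUMNS:
        if col not in observations.columns:
            raise SchemaError(f"observations table lacks column {col!r}")

    if individuals["person_id"].duplicated().any():
        dups = individuals.loc[individuals["person_id"].duplicated(), "person_id"]
        raise IntegrityError(f"duplicate person_id(s): {sorted(set(dups))}")

    bad_zyg = ~individuals["zygosity"].isin(ZYGOSITIES)
    if bad_zyg.any():
        raise IntegrityError(
            f"zygosity must be one of {ZYGOSITIES}, got "
            f"{sorted(set(individuals.loc[bad_zyg, 'zygosity']))}"
        )

    apoe = individuals["apoe_e4"].dropna()
    if len(apoe) and not apoe.isin([0, 1, 2]).all():
        raise IntegrityError("apoe_e4 allele counts must be in {0, 1, 2} when present")

    if (individuals["event_age"] <= 0).any():
        raise IntegrityError("event_age must be positive")

    sizes = individuals.groupby("family_id").size()
    if (sizes > 2).any():
        raise IntegrityError(
            f"families with more than two members: {list(sizes.index[sizes > 2])}"
        )
    zyg_n = individuals.groupby("family_id")["zygosity"].nunique()
    if (zyg_n > 1).any():
        raise IntegrityError(
            f"pair members disagree on zygosity in families {list(zyg_n.index[zyg_n > 1])}"
        )

    if observations.duplicated(subset=["person_id", "wave"]).any():
        raise IntegrityError("duplicate (person_id, wave) in observations")

    known = set(individuals["person_id"])
    orphan = ~observations["person_id"].isin(known)
    if orphan.any():
        raise IntegrityError(
            f"observations reference unknown person_id(s): "
            f"{sorted(set(observations.loc[orphan, 'person_id']))[:5]}"
        )

    scores = pd.to_numeric(observations["score"], errors="coerce").dropna()
    if ordinal_scores and len(scores) and (~scores.isin([0, 1, 2, 3])).any():
        raise IntegrityError("loneliness scores must be in {0, 1, 2, 3} when present")

    ages = observations["age_at_wave"].dropna()
    if len(ages) and ((ages < 35) | (ages > 110)).any():
        raise IntegrityError("age_at_wave outside the plausible range [35, 110]")
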