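"""Synthetic populations for stratified multistage smoker-survey simulation.

A country is partitioned into geographic strata (region crossed with an
urbanization level).  Each stratum is a set of enumeration-area-sized
clusters; each cluster contains households; each household contains adults
(age 18+) with a sex, an age group, a smoker flag and fieldwork propensities
(contact and cooperation).  The generator is the ground truth against which
the sampling protocol and the weighting chain are validated: the true
smoker margins by stratum, sex and age group play the role that external
sociodemographic benchmarks (e.g. Eurobarometer-style prevalence tables)
play for a real survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "StratumConfig",
    "PropensitySpec",
    "PopulationConfig",
    "SyntheticPopulation",
    "BenchmarkTable",
    "generate_population",
    "true_margins",
]

Urbanization = Literal["urban", "semi_urban_rural", "rural"]

SEXES = ("male", "female")


class StratumConfig(BaseModel):
    """One geographic stratum of the sampling frame."""

    stratum_id: str
    region_id: str
    urbanization: Urbanization
    adult_population: int = Field(gt=0)
    n_clusters: int | None = Field(default=None, gt=0)


class PropensitySpec(BaseModel):
    """Distribution of a per-adult fieldwork propensity (contact or cooperation).

    ``constant`` assigns ``value`` to everyone (optionally sex-specific via
    ``by_sex``); ``beta`` draws independently from Beta(a, b).  The default is
    full response (1.0) so that design-based properties can be studied without
    nonresponse confounding.
    """

    kind: Literal["constant", "beta"] = "constant"
    value: float = Field(default=1.0, ge=0.0, le=1.0)
    by_sex: dict[str, float] | None = None
    a: float = Field(default=2.0, gt=0)
    b: float = Field(default=2.0, gt=0)

    @field_validator("by_sex")
    @classmethod
    def _check_by_sex(cls, v):
        if v is not None:
            for sex, p in v.items():
                if sex not in SEXES:
                    raise ValueError(f"unknown sex {sex!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError("propensity outside [0, 1]")
        return v

    def draw(self, rng: np.random.Generator, sex: np.ndarray) -> np.ndarray:
        n = len(sex)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.by_sex:
            out = np.full(n, self.value)
            for s, p in self.by_sex.items():
                out[sex == s] = p
            return out
        return np.full(n, self.value)


def _check_rate_table(table: dict[str, list[float]], n_ages: int, what: str) -> None:
    for sex in SEXES:
        if sex not in table:
            raise ValueError(f"{what}: missing rates for sex {sex!r}")
        rates = table[sex]
        if len(rates) != n_ages:
            raise ValueError(f"{what}: expected {n_ages} age-group rates for {sex}")
        for p in rates:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{what}: rate {p} outside [0, 1]")


class PopulationConfig(BaseModel):
    """Full recipe for one synthetic country.

    Smoking prevalence is a sex-by-age-group table (a smoker is an adult who
    smokes at least monthly and has smoked over 100 cigarettes); optional
    per-stratum multipliers induce geographic prevalence gradients.
    ``attributes`` are binary behavioural traits defined among smokers, again
    as sex-by-age tables — these are the estimands of the simulation studies.
    """

    strata: list[StratumConfig]
    age_groups: list[str] = ["18-24", "25-39", "40-54", "55+"]
    age_probs: list[float] = [0.11, 0.25, 0.28, 0.36]
    sex_male_prob: float = Field(default=0.49, gt=0.0, lt=1.0)
    household_size_probs: dict[int, float] = {1: 0.30, 2: 0.45, 3: 0.17, 4: 0.08}
    smoking_prevalence: dict[str, list[float]] = {
        "male": [0.30, 0.38, 0.36, 0.22],
        "female": [0.22, 0.28, 0.26, 0.14],
    }
    stratum_prevalence_scale: dict[str, float] = {}
    within_household_smoking_corr: float = Field(default=0.0, ge=0.0, le=1.0)
    contact: PropensitySpec = PropensitySpec()
    cooperation: PropensitySpec = PropensitySpec()
    screener_refusal_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    selection_refusal_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    attributes: dict[str, dict[str, list[float]]] = {
        "daily_smoker": {
            "male": [0.80, 0.85, 0.88, 0.90],
            "female": [0.65, 0.72, 0.78, 0.82],
        },
        "plans_to_quit": {
            "male": [0.45, 0.38, 0.30, 0.20],
            "female": [0.50, 0.42, 0.33, 0.22],
        },
    }
    frame_cluster_size: int = Field(default=250, gt=0)

    @model_validator(mode="after")
    def _validate(self):
        if not self.strata:
            raise ValueError("at least one stratum is required")
        ids = [s.stratum_id for s in self.strata]
        if len(set(ids)) != len(ids):
            raise ValueError("stratum_id values must be unique")
        keys = [(s.region_id, s.urbanization) for s in self.strata]
        if len(set(keys)) != len(keys):
            raise ValueError("(region_id, urbanization) must be unique per country")
        if len(self.age_probs) != len(self.age_groups):
            raise ValueError("age_probs must align with age_groups")
        if abs(sum(self.age_probs) - 1.0) > 1e-9:
            raise ValueError("age_probs must sum to 1")
        if abs(sum(self.household_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("household_size_probs must sum to 1")
        if any(k < 1 for k in self.household_size_probs):
            raise ValueError("household sizes must be >= 1 adult")
        n_ages = len(self.age_groups)
        _check_rate_table(self.smoking_prevalence, n_ages, "smoking_prevalence")
        for name, table in self.attributes.items():
            _check_rate_table(table, n_ages, f"attribute {name!r}")
        for sid, scale in self.stratum_prevalence_scale.items():
            if sid not in ids:
                raise ValueError(f"prevalence scale for unknown stratum {sid!r}")
            if scale < 0:
                raise ValueError("prevalence scale must be >= 0")
        return self


@dataclass
class BenchmarkTable:
    """Population-scale smoker counts per (stratum, sex, age group) cell.

    Stands in for an external calibration source such as a prevalence survey:
    the weighting chain rakes or post-stratifies the sample to the margins of
    this table.
    """

    cells: pd.DataFrame  # columns: stratum_id, sex, age_group, smokers
    source_label: str = "synthetic"

    def __post_init__(self) -> None:
        required = {"stratum_id", "sex", "age_group", "smokers"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"benchmark table missing columns {sorted(missing)}")
        if (self.cells["smokers"] < 0).any():
            raise ValueError("benchmark counts must be >= 0")

    def total(self) -> float:
        return float(self.cells["smokers"].sum())

    def margin(self, dim: str) -> pd.Series:
        """Benchmark totals collapsed onto one dimension."""
        if dim == "cells":
            return self.cells.set_index(["stratum_id", "sex", "age_group"])["smokers"]
        col = {"stratum": "stratum_id", "sex": "sex", "age_group": "age_group"}[dim]
        return self.cells.groupby(col, sort=True)["smokers"].sum()

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source_label: str = "file") -> "BenchmarkTable":
        return cls(pd.read_csv(path), source_label=source_label)


@dataclass
class SyntheticPopulation:
    """The generated frame: strata -> clusters -> households -> adults."""

    strata: pd.DataFrame
    clusters: pd.DataFrame
    households: pd.DataFrame
    adults: pd.DataFrame
    seed: int
    config: PopulationConfig = field(repr=False)

    def true_margins(self) -> BenchmarkTable:
        return true_margins(self)

    @property
    def n_adults(self) -> int:
        return len(self.adults)

    @property
    def n_smokers(self) -> int:
        return int(self.adults["is_smoker"].sum())

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.strata.to_csv(out / "strata.csv", index=False)
        self.households.to_csv(out / "households.csv", index=False)
        self.adults.to_csv(out / "adults.csv", index=False)


def _split_counts(total: int, parts: int) -> np.ndarray:
    """Split ``total`` into ``parts`` near-equal integers (largest remainder)."""
    base = total // parts
    out = np.full(parts, base, dtype=int)
    out[: total - base * parts] += 1
    return out


def generate_population(config: PopulationConfig, seed: int) -> SyntheticPopulation:
    """Generate a reproducible synthetic country from ``config``.

    Realized stratum adult counts match the configured populations exactly
    (household sizes are truncated at the cluster boundary); smoker status is
    Bernoulli per adult given the sex-by-age prevalence table, optionally with
    a within-household correlation.
    """
    if not isinstance(config, PopulationConfig):
        config = PopulationConfig.model_validate(config)
    rng = np.random.default_rng(seed)
    n_ages = len(config.age_groups)
    hh_sizes = np.array(sorted(config.household_size_probs), dtype=int)
    hh_probs = np.array([config.household_size_probs[k] for k in hh_sizes])
    mean_hh = float((hh_sizes * hh_probs).sum())

    prev = np.array([config.smoking_prevalence[s] for s in SEXES])  # (2, n_ages)
    attr_tables = {
        name: np.array([tab[s] for s in SEXES]) for name, tab in config.attributes.items()
    }

    strata_rows, cluster_rows = [], []
    adult_frames = []
    hh_counter = 0

    for s in config.strata:
        n_clusters = s.n_clusters or max(3, round(s.adult_population / config.frame_cluster_size))
        scale = config.stratum_prevalence_scale.get(s.stratum_id, 1.0)
        strata_rows.append(
            dict(
                stratum_id=s.stratum_id,
                region_id=s.region_id,
                urbanization=s.urbanization,
                adult_population=s.adult_population,
                n_clusters=n_clusters,
            )
        )
        targets = _split_counts(s.adult_population, n_clusters)
        for ci, target in enumerate(targets):
            cluster_id = f"{s.stratum_id}-c{ci:03d}"
            # draw household sizes until the cluster's adult target is covered
            est = int(target / mean_hh * 1.35) + 8
            sizes = rng.choice(hh_sizes, size=est, p=hh_probs)
            while sizes.sum() < target:
                sizes = np.concatenate([sizes, rng.choice(hh_sizes, size=est, p=hh_probs)])
            cut = int(np.searchsorted(np.cumsum(sizes), target)) + 1
            sizes = sizes[:cut].copy()
            sizes[-1] -= int(sizes.sum() - target)  # truncate last household
            n_hh = len(sizes)
            n = int(sizes.sum())

            hh_ids = np.arange(hh_counter, hh_counter + n_hh)
            hh_counter += n_hh
            hh_of_adult = np.repeat(hh_ids, sizes)

            sex = np.where(rng.random(n) < config.sex_male_prob, "male", "female")
            sex_code = (sex == "female").astype(int)
            age_code = rng.choice(n_ages, size=n, p=config.age_probs)
            p_smoke = np.clip(prev[sex_code, age_code] * scale, 0.0, 1.0)
            if config.within_household_smoking_corr > 0:
                hh_u = np.repeat(rng.random(n_hh), sizes)
                own_u = rng.random(n)
                shared = rng.random(n) < config.within_household_smoking_corr
                u = np.where(shared, hh_u, own_u)
            else:
                u = rng.random(n)
            is_smoker = u < p_smoke

            frame = pd.DataFrame(
                {
                    "household_id": hh_of_adult,
                    "cluster_id": cluster_id,
                    "stratum_id": s.stratum_id,
                    "sex": sex,
                    "age_group": pd.Categorical.from_codes(
                        age_code, categories=config.age_groups
                    ),
                    "is_smoker": is_smoker,
                    "contact_propensity": config.contact.draw(rng, sex),
                    "cooperation_propensity": config.cooperation.draw(rng, sex),
                }
            )
            for name, tab in attr_tables.items():
                frame[name] = is_smoker & (rng.random(n) < tab[sex_code, age_code])
            adult_frames.append(frame)
            cluster_rows.append(
                dict(
                    cluster_id=cluster_id,
                    stratum_id=s.stratum_id,
                    n_households=n_hh,
                    n_adults=n,
                )
            )

    adults = pd.concat(adult_frames, ignore_index=True)
    adults.insert(0, "person_id", np.arange(len(adults)))

    tmp = adults.assign(
        male_smoker=(adults["sex"] == "male") & adults["is_smoker"],
        female_smoker=(adults["sex"] == "female") & adults["is_smoker"],
    )
    by_hh = tmp.groupby("household_id", sort=True)
    households = pd.DataFrame(
        {
            "household_id": by_hh.size().index,
            "cluster_id": by_hh["cluster_id"].first().to_numpy(),
            "stratum_id": by_hh["stratum_id"].first().to_numpy(),
            "n_adults": by_hh.size().to_numpy(),
            "n_male_smokers": by_hh["male_smoker"].sum().to_numpy().astype(int),
            "n_female_smokers": by_hh["female_smoker"].sum().to_numpy().astype(int),
            "contact_propensity": by_hh["contact_propensity"].mean().to_numpy(),
        }
    )

    return SyntheticPopulation(
        strata=pd.DataFrame(strata_rows),
        clusters=pd.DataFrame(cluster_rows),
        households=households,
        adults=adults,
        seed=seed,
        config=config,
    )


def true_margins(pop: SyntheticPopulation) -> BenchmarkTable:
    """Exact smoker counts per (stratum, sex, age group) cell of the population.

    This is the ground-truth calibration benchmark: every cell of the full
    stratum x sex x age cross-classification is present, zero cells included.
    """
    smokers = pop.adults.loc[pop.adults["is_smoker"]].assign(
        age_group=lambda d: d["age_group"].astype(str)
    )
    idx = pd.MultiIndex.from_product(
        [
            pop.strata["stratum_id"].tolist(),
            list(SEXES),
            pop.config.age_groups,
        ],
        names=["stratum_id", "sex", "age_group"],
    )
    counts = (
        smokers.groupby(["stratum_id", "sex", "age_group"])
        .size()
        .reindex(idx, fill_value=0)
        .rename("smokers")
        .reset_index()
    )
    counts["smokers"] = counts["smokers"].astype(float)
    return BenchmarkTable(cells=counts, source_label=f"true margins (seed={pop.seed})")
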