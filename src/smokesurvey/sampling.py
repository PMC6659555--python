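"""Simulation of the face-to-face recruitment protocol.

The protocol mirrors a national multistage design for sampling adult
smokers: clusters are allocated to geographic strata proportionally to
adult population with a floor per stratum, dwellings inside a sampled
cluster are approached along a random systematic route (a stand-in for the
GPS-seeded random walk: a random permutation of the cluster's dwellings with
every k-th taken from a random start), households are screened for adult
smokers, and at most one smoker per sex is selected per household with a
uniform next-birthday rule.  A cluster's fieldwork stops once its quota of
completed interviews is reached.  Every fieldwork outcome is tallied into a
disposition record from which contact, cooperation and response rates are
derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .population import SyntheticPopulation, StratumConfig  # noqa: F401

__all__ = [
    "DesignSpec",
    "DispositionCounts",
    "FieldSample",
    "allocate_clusters",
    "select_in_household",
    "run_fieldwork",
    "FrameIndex",
]

logger = logging.getLogger(__name__)

# packaged disposition-table row positions for the nine raw counts
RAW_ROW_POSITIONS = {
    "addresses_attempted": 1,
    "addresses_contacted": 2,
    "eligibility_determined": 3,
    "no_eligible": 4,
    "with_eligible": 5,
    "households_with_selection": 6,
    "individuals_selected": 9,
    "individual_refusals": 10,
    "completed_interviews": 11,
}


class DesignSpec(BaseModel):
    """Tunable parameters of the recruitment design."""

    clusters_total: int = Field(default=100, ge=1)
    min_clusters_per_stratum: int = Field(default=2, ge=1)
    quota_per_cluster: int = Field(default=10, ge=1)
    walk_step: int = Field(default=5, ge=1)
    max_contact_attempts: int = Field(default=4, ge=1)
    select_one_per_sex: bool = True
    replace_unavailable: bool = False


@dataclass
class DispositionCounts:
    """Raw fieldwork accounting for one country (or one simulation run)."""

    addresses_attempted: int = 0
    addresses_contacted: int = 0
    eligibility_determined: int = 0
    no_eligible: int = 0
    with_eligible: int = 0
    households_with_selection: int = 0
    individuals_selected: int = 0
    individual_refusals: int = 0
    completed_interviews: int = 0

    def validate(self, select_one_per_sex: bool = True) -> None:
        """Raise ValueError on any internal inconsistency."""
        d = asdict(self)
        for k, v in d.items():
            if v < 0:
                raise ValueError(f"{k} is negative")
        checks = [
            (self.addresses_contacted <= self.addresses_attempted,
             "contacted exceeds attempted"),
            (self.eligibility_determined <= self.addresses_contacted,
             "eligibility determined exceeds contacted"),
            (self.no_eligible + self.with_eligible == self.eligibility_determined,
             "no_eligible + with_eligible != eligibility_determined"),
            (self.households_with_selection <= self.with_eligible,
             "selections exceed households with eligibles"),
            (self.households_with_selection <= self.individuals_selected,
             "fewer individuals than selecting households"),
            (self.completed_interviews + self.individual_refusals
             <= self.individuals_selected,
             "completions plus refusals exceed selections"),
        ]
        if select_one_per_sex:
            checks.append(
                (self.individuals_selected <= 2 * self.households_with_selection,
                 "more than two selections per household")
            )
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"inconsistent dispositions: {msg}")

    def as_series(self) -> pd.Series:
        return pd.Series(asdict(self), dtype=int)

    @classmethod
    def from_mapping(cls, data) -> "DispositionCounts":
        return cls(**{k: int(data[k]) for k in RAW_ROW_POSITIONS})


@dataclass
class FieldSample:
    """Result of one simulated fieldwork run on one country."""

    respondents: pd.DataFrame
    dispositions: DispositionCounts
    cluster_allocation: dict[str, int]
    sampled_clusters: dict[str, list[str]]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.respondents.to_csv(out / "respondents.csv", index=False)
        rows = pd.DataFrame(
            {
                "row": list(RAW_ROW_POSITIONS.values()),
                "key": list(RAW_ROW_POSITIONS.keys()),
                "count": [getattr(self.dispositions, k) for k in RAW_ROW_POSITIONS],
            }
        )
        rows.to_csv(out / "dispositions.csv", index=False)


def allocate_clusters(strata, design: DesignSpec) -> dict[str, int]:
    """Allocate the cluster budget to strata proportionally to adult population.

    Largest-remainder apportionment subject to a floor: strata whose
    proportional share falls below ``min_clusters_per_stratum`` are fixed at
    the floor and the remainder is re-apportioned among the rest.
    """
    if isinstance(strata, pd.DataFrame):
        ids = strata["stratum_id"].tolist()
        pops = strata["adult_population"].to_numpy(dtype=float)
    else:
        ids = [s.stratum_id for s in strata]
        pops = np.array([s.adult_population for s in strata], dtype=float)
    H = len(ids)
    floor = design.min_clusters_per_stratum
    total = design.clusters_total
    if total < floor * H:
        raise ValueError(
            f"{total} clusters cannot satisfy a floor of {floor} over {H} strata"
        )
    alloc = {}
    active = list(range(H))
    budget = total
    while True:
        share = budget * pops[active] / pops[active].sum()
        low = [i for i, s in zip(active, share) if s < floor]
        if not low:
            break
        for i in low:
            alloc[i] = floor
            budget -= floor
        active = [i for i in active if i not in alloc]
        if not active:
            break
    if active:
        share = budget * pops[active] / pops[active].sum()
        base = np.floor(share).astype(int)
        leftover = budget - int(base.sum())
        frac = share - base
        # ties broken toward larger populations, then frame order
        order = sorted(
            range(len(active)), key=lambda j: (-frac[j], -pops[active[j]], j)
        )
        for j in order[:leftover]:
            base[j] += 1
        for j, i in enumerate(active):
            alloc[i] = int(base[j])
    return {ids[i]: alloc[i] for i in range(H)}


def select_in_household(
    adult_smokers: pd.DataFrame | list,
    rng: np.random.Generator,
    select_one_per_sex: bool = True,
):
    """Select at most one smoker per sex from one household, uniformly at random.

    Models the next-birthday rule: birthdays are uniform over the year, so
    among the k eligible same-sex smokers each is picked with probability 1/k.
    A household with a single smoker of a given sex yields that person with
    certainty.  Returns the list of selected ``person_id`` values.
    """
    if isinstance(adult_smokers, list):
        if not adult_smokers:
            return []
        adult_smokers = pd.DataFrame(adult_smokers)
    if adult_smokers.empty:
        return []
    selected = []
    if select_one_per_sex:
        for sex in ("male", "female"):
            pool = adult_smokers.loc[adult_smokers["sex"] == sex, "person_id"]
            if len(pool):
                selected.append(pool.iloc[int(rng.integers(len(pool)))])
    else:
        pool = adult_smokers["person_id"]
        selected.append(pool.iloc[int(rng.integers(len(pool)))])
    return selected


class FrameIndex:
    """Flat numpy view of a population, built once so that repeated fieldwork
    simulations on the same frame avoid pandas overhead."""

    def __init__(self, pop: SyntheticPopulation):
        self.pop = pop
        hh = pop.households
        self.hh_contact = hh["contact_propensity"].to_numpy(dtype=float)
        self.hh_ids = hh["household_id"].to_numpy()
        self.n_male = hh["n_male_smokers"].to_numpy()
        self.n_female = hh["n_female_smokers"].to_numpy()

        # households grouped by cluster, as row positions into hh
        self.cluster_households: dict[str, np.ndarray] = {
            cid: np.asarray(idx)
            for cid, idx in hh.groupby("cluster_id", sort=False).indices.items()
        }
        self.clusters_by_stratum: dict[str, list[str]] = {
            sid: g["cluster_id"].tolist()
            for sid, g in pop.clusters.groupby("stratum_id", sort=False)
        }

        adults = pop.adults
        self.coop = adults["cooperation_propensity"].to_numpy(dtype=float)
        # CSR layout of smoker row-positions per household and sex
        n_hh = len(hh)
        self._sex_csr = {}
        hh_pos = pd.Series(np.arange(n_hh), index=hh["household_id"])
        for sex, counts in (("male", self.n_male), ("female", self.n_female)):
            mask = (adults["sex"] == sex) & adults["is_smoker"]
            rows = np.flatnonzero(mask.to_numpy())
            owner = hh_pos[adults.loc[mask, "household_id"]].to_numpy()
            order = np.argsort(owner, kind="stable")
            start = np.zeros(n_hh + 1, dtype=int)
            np.cumsum(counts, out=start[1:])
            self._sex_csr[sex] = (start, rows[order])

    def smokers_of(self, hh_row: int, sex: str) -> np.ndarray:
        start, rows = self._sex_csr[sex]
        return rows[start[hh_row]: start[hh_row + 1]]


def run_fieldwork(
    pop: SyntheticPopulation,
    design: DesignSpec,
    seed: int,
    frame: FrameIndex | None = None,
    screener_refusal_prob: float | None = None,
    selection_refusal_prob: float | None = None,
) -> FieldSample:
    """Simulate one full fieldwork run and tally dispositions.

    Within each sampled cluster the dwellings are randomly permuted and
    approached systematically (every ``walk_step``-th from a random start;
    skipped offsets are revisited in later passes, so the frame can be
    exhausted when smokers are scarce).  Contact succeeds if any of up to
    ``max_contact_attempts`` Bernoulli trials at the household's contact
    propensity succeeds; cooperating selected smokers are interviewed until
    the cluster quota of completed interviews is met.
    """
    if frame is None:
        frame = FrameIndex(pop)
    rng = np.random.default_rng(seed)
    cfg = pop.config
    scr_ref = cfg.screener_refusal_prob if screener_refusal_prob is None else screener_refusal_prob
    sel_ref = cfg.selection_refusal_prob if selection_refusal_prob is None else selection_refusal_prob

    alloc = allocate_clusters(pop.strata, design)
    sampled: dict[str, list[str]] = {}
    for sid, n_take in alloc.items():
        avail = frame.clusters_by_stratum.get(sid, [])
        if n_take > len(avail):
            raise ValueError(
                f"stratum {sid} has {len(avail)} frame clusters, {n_take} requested"
            )
        pick = rng.choice(len(avail), size=n_take, replace=False)
        sampled[sid] = [avail[int(i)] for i in pick]

    d = DispositionCounts()
    quota = design.quota_per_cluster
    k = design.walk_step
    resp_rows: list[int] = []
    resp_ks: list[int] = []
    warn_msgs: list[str] = []

    for sid, cluster_ids in sampled.items():
        for cid in cluster_ids:
            hh_rows = frame.cluster_households[cid]
            perm = rng.permutation(hh_rows)
            start = int(rng.integers(k))
            route = np.concatenate([perm[(start + j) % k:: k] for j in range(k)])
            completes = 0
            for hh in route:
                if completes >= quota:
                    break
                d.addresses_attempted += 1
                p = frame.hh_contact[hh]
                if p < 1.0 and not (rng.random(design.max_contact_attempts) < p).any():
                    continue
                d.addresses_contacted += 1
                if scr_ref > 0.0 and rng.random() < scr_ref:
                    continue  # informant refused the screener: eligibility unknown
                d.eligibility_determined += 1
                n_m = int(frame.n_male[hh])
                n_f = int(frame.n_female[hh])
                if n_m + n_f == 0:
                    d.no_eligible += 1
                    continue
                d.with_eligible += 1
                if sel_ref > 0.0 and rng.random() < sel_ref:
                    continue  # household declined the selection step
                d.households_with_selection += 1
                if design.select_one_per_sex:
                    picks = []
                    for sex, n_s in (("male", n_m), ("female", n_f)):
                        if n_s:
                            pool = frame.smokers_of(hh, sex)
                            picks.append((pool, int(rng.integers(n_s)), n_s))
                else:
                    pool = np.concatenate(
                        [frame.smokers_of(hh, "male"), frame.smokers_of(hh, "female")]
                    )
                    picks = [(pool, int(rng.integers(len(pool))), len(pool))]
                for pool, j, k_s in picks:
                    d.individuals_selected += 1
                    if completes >= quota:
                        continue  # quota filled mid-household: selection recorded only
                    person = int(pool[j])
                    coop = frame.coop[person]
                    if coop >= 1.0 or rng.random() < coop:
                        d.completed_interviews += 1
                        completes += 1
                        resp_rows.append(person)
                        resp_ks.append(k_s)
                    else:
                        d.individual_refusals += 1
                        if design.replace_unavailable and k_s > 1:
                            # in-household replacement of a respondent who was
                            # unavailable for the whole fieldwork period
                            rest = np.delete(pool, j)
                            j2 = int(rng.integers(len(rest)))
                            person2 = int(rest[j2])
                            d.individuals_selected += 1
                            coop2 = frame.coop[person2]
                            if coop2 >= 1.0 or rng.random() < coop2:
                                d.completed_interviews += 1
                                completes += 1
                                resp_rows.append(person2)
                                resp_ks.append(k_s)
                            else:
                                d.individual_refusals += 1
            if completes < quota:
                msg = f"cluster {cid}: quota shortfall ({completes}/{quota})"
                warn_msgs.append(msg)
                logger.debug(msg)

    cols = ["person_id", "household_id", "cluster_id", "stratum_id", "sex", "age_group"]
    extra = [c for c in pop.adults.columns if c not in cols + [
        "is_smoker", "contact_propensity", "cooperation_propensity"]]
    respondents = pop.adults.iloc[resp_rows][cols + extra].copy()
    respondents["age_group"] = respondents["age_group"].astype(str)
    respondents["same_sex_smokers_in_household"] = np.asarray(resp_ks, dtype=int)
    respondents["interview_complete"] = True
    respondents = respondents.reset_index(drop=True)

    d.validate(select_one_per_sex=design.select_one_per_sex)
    if warn_msgs:
        logger.warning("%d cluster(s) with quota shortfall", len(warn_msgs))
    return FieldSample(
        respondents=respondents,
        dispositions=d,
        cluster_allocation=alloc,
        sampled_clusters=sampled,
        seed=seed,
        warnings=warn_msgs,
    )
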