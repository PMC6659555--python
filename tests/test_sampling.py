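"""Fieldwork simulator: cluster allocation, household selection, dispositions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from smokesurvey.population import PropensitySpec, generate_population
from smokesurvey.sampling import (
    DesignSpec,
    DispositionCounts,
    FrameIndex,
    allocate_clusters,
    run_fieldwork,
    select_in_household,
)

from conftest import two_strata_config


def strata_frame(pops):
    return pd.DataFrame(
        {
            "stratum_id": [f"S{i}" for i in range(len(pops))],
            "region_id": "R",
            "urbanization": "urban",
            "adult_population": pops,
        }
    )


class TestAllocateClusters:
    def test_exact_proportionality(self):
        design = DesignSpec(clusters_total=100, min_clusters_per_stratum=2)
        alloc = allocate_clusters(strata_frame([50_000, 30_000, 20_000]), design)
        assert list(alloc.values()) == [50, 30, 20]

    def test_floor_binds_for_tiny_strata(self):
        """Oracle: brute force over all feasible allocations, minimising the
        maximum deviation from the proportional share."""
        pops = [97, 2, 1]
        total, floor = 10, 2
        shares = [total * p / sum(pops) for p in pops]
        best = min(
            (
                a
                for a in itertools.product(range(floor, total + 1), repeat=3)
                if sum(a) == total
            ),
            key=lambda a: max(abs(x - s) for x, s in zip(a, shares)),
        )
        assert best == (6, 2, 2)
        design = DesignSpec(clusters_total=total, min_clusters_per_stratum=floor)
        alloc = allocate_clusters(strata_frame(pops), design)
        assert tuple(alloc.values()) == best

    def test_single_stratum_gets_everything(self):
        design = DesignSpec(clusters_total=100)
        assert allocate_clusters(strata_frame([123]), design) == {"S0": 100}

    def test_totals_and_floor_respected(self):
        design = DesignSpec(clusters_total=17, min_clusters_per_stratum=3)
        alloc = allocate_clusters(strata_frame([5, 80, 10, 5]), design)
        assert sum(alloc.values()) == 17
        assert min(alloc.values()) >= 3

    def test_infeasible_floor_rejected(self):
        design = DesignSpec(clusters_total=5, min_clusters_per_stratum=2)
        with pytest.raises(ValueError, match="floor"):
            allocate_clusters(strata_frame([1, 1, 1]), design)


class TestSelectInHousehold:
    def hh(self, males=0, females=0):
        rows = [{"person_id": f"m{i}", "sex": "male"} for i in range(males)]
        rows += [{"person_id": f"f{i}", "sex": "female"} for i in range(females)]
        return pd.DataFrame(rows)

    def test_sole_smoker_of_a_sex_is_certain(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert select_in_household(self.hh(males=1), rng) == ["m0"]

    def test_empty_household_selects_nobody(self):
        assert select_in_household([], np.random.default_rng(0)) == []

    def test_one_per_sex_at_most(self):
        rng = np.random.default_rng(1)
        sel = select_in_household(self.hh(males=3, females=2), rng)
        assert len(sel) == 2
        assert len({s[0] for s in sel}) == 2  # one m, one f

    def test_uniform_among_same_sex_smokers(self):
        rng = np.random.default_rng(42)
        hh = self.hh(males=3)
        n = 10_000
        counts = pd.Series(
            [select_in_household(hh, rng)[0] for _ in range(n)]
        ).value_counts()
        # binomial oracle at p = 1/3 per candidate
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for pid in ("m0", "m1", "m2"):
            assert abs(counts[pid] / n - 1 / 3) < 3 * se
        chi2 = stats.chisquare(counts.to_numpy()).pvalue
        assert chi2 > 0.01


class TestRunFieldwork:
    def single_smoker_pop(self):
        cfg = two_strata_config(
            n_adults=80,
            household_size_probs={1: 1.0},
            smoking_prevalence={"male": [1.0] * 4, "female": [1.0] * 4},
        )
        cfg = cfg.model_copy(update={"strata": [
            cfg.strata[0].model_copy(update={"adult_population": 80, "n_clusters": 1})
        ]})
        return generate_population(cfg, seed=5)

    def test_full_response_single_smoker_households_fill_quota_exactly(self):
        pop = self.single_smoker_pop()
        design = DesignSpec(clusters_total=1, min_clusters_per_stratum=1,
                            quota_per_cluster=10, walk_step=5)
        sample = run_fieldwork(pop, design, seed=1)
        d = sample.dispositions
        assert d.completed_interviews == 10
        assert d.individual_refusals == 0
        assert d.addresses_attempted == d.addresses_contacted
        assert len(sample.respondents) == 10
        assert (sample.respondents["same_sex_smokers_in_household"] == 1).all()

    def test_zero_contact_propensity_yields_no_interviews(self):
        cfg = two_strata_config(
            n_adults=400, contact=PropensitySpec(kind="constant", value=0.0)
        )
        pop = generate_population(cfg, seed=6)
        design = DesignSpec(clusters_total=4, quota_per_cluster=5)
        sample = run_fieldwork(pop, design, seed=2)
        assert sample.dispositions.addresses_contacted == 0
        assert sample.dispositions.completed_interviews == 0
        assert sample.respondents.empty

    def test_dispositions_internally_consistent_under_full_response(
        self, small_pop, small_design, small_sample
    ):
        d = small_sample.dispositions
        d.validate()  # raises on violation
        assert d.no_eligible + d.with_eligible == d.eligibility_determined
        assert d.completed_interviews <= d.individuals_selected

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_dispositions_consistent_under_nonresponse(self, seed):
        cfg = two_strata_config(
            n_adults=1500,
            contact=PropensitySpec(kind="beta", a=4, b=1),
            cooperation=PropensitySpec(kind="beta", a=5, b=1),
            screener_refusal_prob=0.15,
            selection_refusal_prob=0.05,
        )
        pop = generate_population(cfg, seed=seed % 1000)
        design = DesignSpec(clusters_total=6, quota_per_cluster=8)
        sample = run_fieldwork(pop, design, seed=seed)
        sample.dispositions.validate(select_one_per_sex=True)
        per_cluster = sample.respondents.groupby("cluster_id").size()
        assert (per_cluster <= design.quota_per_cluster).all()

    def test_no_household_contributes_two_same_sex_respondents(self, small_sample):
        per = small_sample.respondents.groupby(["household_id", "sex"]).size()
        assert (per <= 1).all()

    def test_quota_cap_per_cluster(self, small_sample, small_design):
        per_cluster = small_sample.respondents.groupby("cluster_id").size()
        assert (per_cluster <= small_design.quota_per_cluster).all()

    def test_same_seed_reproduces_sample(self, small_pop, small_design):
        frame = FrameIndex(small_pop)
        a = run_fieldwork(small_pop, small_design, seed=99, frame=frame)
        b = run_fieldwork(small_pop, small_design, seed=99, frame=frame)
        assert a.respondents.equals(b.respondents)
        assert a.dispositions == b.dispositions

    def test_respondents_carry_screener_count(self, small_sample, small_pop):
        merged = small_sample.respondents.merge(
            small_pop.households, on="household_id", suffixes=("", "_hh")
        )
        males = merged[merged["sex"] == "male"]
        assert (males["same_sex_smokers_in_household"]
                == males["n_male_smokers"]).all()


def test_disposition_counts_validation_catches_additivity_violation():
    d = DispositionCounts(
        addresses_attempted=10, addresses_contacted=8, eligibility_determined=6,
        no_eligible=2, with_eligible=3, households_with_selection=3,
        individuals_selected=3, individual_refusals=0, completed_interviews=3,
    )
    with pytest.raises(ValueError, match="no_eligible"):
        d.validate()
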