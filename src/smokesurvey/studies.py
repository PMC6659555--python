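"""Monte-Carlo validation studies for the sampling-plus-weighting chain.

These are the package's own calibration experiments: repeated fieldwork
draws on a fixed synthetic country measure (a) whether the weighted
estimator recovers known population quantities, (b) whether calibration
repairs sex-differential nonresponse bias, and (c) whether the Rao-Wu
bootstrap variance and percentile intervals track the true Monte-Carlo
sampling variability.  The same entry points back the test suite and the
acceptance script.

The default study country is a desk-scale stand-in for a national frame:
about 40,000 adults in 8 strata (4 regions x 2 urbanization levels), 400
equal-sized frame clusters of which 40 are sampled, quota 10 completed
interviews per cluster — i.e. roughly 400 respondents per run, a 1:2.5
scale-down of a 1000-interview national survey that keeps every design
feature intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import (
    PopulationConfig,
    PropensitySpec,
    StratumConfig,
    SyntheticPopulation,
    generate_population,
)
from .sampling import DesignSpec, FrameIndex, run_fieldwork
from .weights import CalibrationSpec, calibrate, design_weights, initial_weights, rescale_mean_one
from .bootstrap import bootstrap_variance, rao_wu_replicates, replicate_estimates

__all__ = [
    "study_population_config",
    "study_design",
    "RecoveryStudy",
    "BootstrapStudy",
    "run_recovery_study",
    "run_bootstrap_study",
    "weights_for_sample",
]

URBAN_LEVELS = ("urban", "semi_urban_rural")


def study_population_config(
    n_adults: int = 40_000,
    n_regions: int = 4,
    clusters_per_stratum: int = 50,
    cooperation: PropensitySpec | None = None,
) -> PopulationConfig:
    """Eight-stratum study country with unequal stratum sizes and a mild
    urban/rural prevalence gradient."""
    n_strata = n_regions * len(URBAN_LEVELS)
    # unequal but fixed population shares so proportional allocation is exercised
    shares = np.array([3, 2] * n_regions, dtype=float)[:n_strata]
    shares = shares * np.linspace(1.0, 1.6, n_strata)
    shares /= shares.sum()
    pops = np.round(shares * n_adults).astype(int)
    pops[-1] += n_adults - pops.sum()
    strata = []
    scale = {}
    i = 0
    for r in range(n_regions):
        for u in URBAN_LEVELS:
            sid = f"R{r + 1}-{'U' if u == 'urban' else 'S'}"
            strata.append(
                StratumConfig(
                    stratum_id=sid,
                    region_id=f"R{r + 1}",
                    urbanization=u,
                    adult_population=int(pops[i]),
                    n_clusters=clusters_per_stratum,
                )
            )
            scale[sid] = 1.1 if u == "urban" else 0.9
            i += 1
    kwargs = {}
    if cooperation is not None:
        kwargs["cooperation"] = cooperation
    return PopulationConfig(strata=strata, stratum_prevalence_scale=scale, **kwargs)


def study_design(clusters_total: int = 40) -> DesignSpec:
    return DesignSpec(clusters_total=clusters_total, min_clusters_per_stratum=2,
                      quota_per_cluster=10)


def weights_for_sample(sample, pop, benchmark=None, do_calibrate=True,
                       spec: CalibrationSpec | None = None):
    """Run the four-step weighting chain on one fieldwork sample."""
    ws = initial_weights(sample)
    ws = design_weights(ws, pop.strata)
    if do_calibrate:
        ws = calibrate(ws, benchmark or pop.true_margins(), spec)
    return rescale_mean_one(ws)


def _truth(pop: SyntheticPopulation, attribute: str) -> float:
    """Population prevalence of a binary attribute among smokers."""
    smokers = pop.adults[pop.adults["is_smoker"]]
    return float(smokers[attribute].mean())


@dataclass
class RecoveryStudy:
    attribute: str
    truth: float
    estimates: np.ndarray  # calibrated-chain estimates, one per run
    estimates_design_only: np.ndarray  # chain without the calibration step
    R: int

    @property
    def mc_se(self) -> float:
        return float(self.estimates.std(ddof=1) / np.sqrt(self.R))

    @property
    def bias(self) -> float:
        return float(self.estimates.mean() - self.truth)

    @property
    def bias_design_only(self) -> float:
        return float(self.estimates_design_only.mean() - self.truth)


def run_recovery_study(
    pop: SyntheticPopulation,
    design: DesignSpec,
    attribute: str,
    R: int = 500,
    seed: int = 0,
) -> RecoveryStudy:
    """R independent fieldwork draws on a fixed population; for each, the
    weighted prevalence of ``attribute`` among smokers is estimated with the
    calibrated chain and with the design-only chain."""
    frame = FrameIndex(pop)
    bench = pop.true_margins()
    seeds = np.random.SeedSequence(seed).generate_state(R) % (2**31)
    truth = _truth(pop, attribute)
    est_cal = np.empty(R)
    est_des = np.empty(R)
    for r in range(R):
        sample = run_fieldwork(pop, design, int(seeds[r]), frame=frame)
        y = sample.respondents[attribute].to_numpy(dtype=float)
        ws_cal = weights_for_sample(sample, pop, bench, do_calibrate=True)
        est_cal[r] = float(ws_cal.column() @ y / ws_cal.column().sum())
        ws_des = weights_for_sample(sample, pop, bench, do_calibrate=False)
        est_des[r] = float(ws_des.column() @ y / ws_des.column().sum())
    return RecoveryStudy(attribute, truth, est_cal, est_des, R)


@dataclass
class BootstrapStudy:
    attribute: str
    truth: float
    estimates: np.ndarray  # (R,) point estimates
    boot_variances: np.ndarray  # (n_var_seeds,) bootstrap variances
    covered: np.ndarray  # (R,) bool, 95% percentile CI covers truth
    zero_freq_dev: float  # max |empirical - analytic| zero-weight probability
    R: int
    B: int

    @property
    def mc_variance(self) -> float:
        return float(self.estimates.var(ddof=1))

    @property
    def variance_ratio_median(self) -> float:
        return float(np.median(self.boot_variances / self.mc_variance))

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())


def run_bootstrap_study(
    pop: SyntheticPopulation,
    design: DesignSpec,
    attribute: str,
    R: int = 500,
    B: int = 500,
    n_var_seeds: int = 20,
    seed: int = 0,
) -> BootstrapStudy:
    """Bootstrap-validity experiment with fixed (non-recalibrated) weights.

    Each of R fieldwork draws gets its own four-step weights (without the
    calibration step, so the replicated estimator matches the bootstrap's
    fixed-weight assumption), a Rao-Wu replicate set of size B, a percentile
    CI, and — for the first ``n_var_seeds`` draws — the bootstrap variance
    used in the variance-ratio diagnostic.  The zero-weight frequency of each
    respondent is compared with the analytic (1 - 1/n_h)^(n_h - 1) on the
    first draw.
    """
    frame = FrameIndex(pop)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * R) % (2**31)
    truth = _truth(pop, attribute)
    est = np.empty(R)
    covered = np.zeros(R, dtype=bool)
    boot_vars = []
    zero_dev = 0.0
    for r in range(R):
        sample = run_fieldwork(pop, design, int(seeds[2 * r]), frame=frame)
        y = sample.respondents[attribute].to_numpy(dtype=float)
        ws = weights_for_sample(sample, pop, do_calibrate=False)
        w = ws.column("rescaled")
        est[r] = float(w @ y / w.sum())
        rw = rao_wu_replicates(
            ws, sample, B=B, seed=int(seeds[2 * r + 1]),
            recalibrate=False, strata=pop.strata,
        )
        reps = replicate_estimates(rw, y, estimator="proportion")
        ve = bootstrap_variance(est[r], reps)
        lo, hi = ve.percentile_ci
        covered[r] = lo <= truth <= hi
        if r < n_var_seeds:
            boot_vars.append(ve.variance)
        if r == 0:
            clus = sample.respondents["cluster_id"].to_numpy()
            n_h_of_resp = np.array(
                [rw.n_h[rw.stratum_of_cluster[c]] for c in clus], dtype=float
            )
            analytic = (1.0 - 1.0 / n_h_of_resp) ** (n_h_of_resp - 1.0)
            empirical = (rw.weights == 0.0).mean(axis=1)
            zero_dev = float(np.max(np.abs(empirical - analytic)))
    return BootstrapStudy(
        attribute=attribute,
        truth=truth,
        estimates=est,
        boot_variances=np.array(boot_vars),
        covered=covered,
        zero_freq_dev=zero_dev,
        R=R,
        B=B,
    )
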