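"""Rao-Wu rescaled bootstrap replicate weights and variance estimation.

For a stratified multistage design the first-stage clusters (PSUs) carry the
dominant sampling variability.  The rescaled bootstrap draws, independently
per stratum h and replicate b, ``n_h - 1`` of the stratum's n_h sampled
clusters *with replacement*; a respondent in cluster c receives replicate
weight

    w_i(b) = w_i * (n_h / (n_h - 1)) * m_c(b),

where m_c(b) is the number of times c was drawn.  Since E[m_c] =
(n_h - 1)/n_h the expected replicate weight equals the base weight, and the
empirical variance of a replicated estimator consistently estimates its
design variance under with-replacement PSU sampling.  (The technique is the
rescaled bootstrap of Rao & Wu, with the rescaling of Rao, Wu & Yue.)

Strata that end up with a single sampled cluster cannot be resampled and are
collapsed with the adjacent stratum of the same region before replication.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .weights import WeightSet, Raker, CalibrationSpec
from .population import BenchmarkTable
from .sampling import FieldSample

__all__ = [
    "ReplicateWeights",
    "VarianceEstimate",
    "rao_wu_replicates",
    "replicate_estimates",
    "bootstrap_variance",
]

logger = logging.getLogger(__name__)


@dataclass
class ReplicateWeights:
    """Respondent x B matrix of bootstrap weights plus design bookkeeping."""

    weights: np.ndarray  # shape (n_respondents, B)
    B: int
    base: str  # which WeightSet stage was replicated
    respondent_ids: np.ndarray
    stratum_of_cluster: dict[str, str]  # after any collapsing
    n_h: dict[str, int]
    seed: int
    recalibrated: bool = False
    collapsed_strata: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        width = len(str(self.B))
        cols = {f"w_rep_{b + 1:0{width}d}": self.weights[:, b] for b in range(self.B)}
        out = pd.DataFrame({"respondent_id": self.respondent_ids, **cols})
        out.to_csv(path, index=False)
        if sidecar is not None:
            meta = {
                "B": self.B,
                "seed": self.seed,
                "base": self.base,
                "recalibrated": self.recalibrated,
                "n_h": self.n_h,
                "collapsed_strata": self.collapsed_strata,
            }
            Path(sidecar).write_text(json.dumps(meta, indent=2))


def _collapse_singletons(
    strata_order: list[str],
    region_of: dict[str, str],
    clusters_by_stratum: dict[str, list[str]],
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Merge single-cluster strata into a neighbour (same region preferred)."""
    merged = {sid: list(cl) for sid, cl in clusters_by_stratum.items()}
    collapsed: list[tuple[str, str]] = []
    changed = True
    while changed:
        changed = False
        order = [s for s in strata_order if s in merged]
        for sid in order:
            if len(merged[sid]) >= 2 or len(merged) == 1:
                continue
            others = [o for o in order if o != sid]
            same_region = [o for o in others if region_of.get(o) == region_of.get(sid)]
            pool = same_region or others
            donor = min(pool, key=lambda o: abs(order.index(o) - order.index(sid)))
            merged[donor].extend(merged.pop(sid))
            collapsed.append((sid, donor))
            changed = True
            break
    for sid, cl in merged.items():
        if len(cl) < 2:
            raise ValueError(
                f"stratum {sid} has a single sampled cluster and no collapse partner"
            )
    return merged, collapsed


def rao_wu_replicates(
    ws: WeightSet,
    sample: FieldSample,
    B: int,
    seed: int,
    base: str | None = None,
    recalibrate: bool = True,
    benchmark: BenchmarkTable | None = None,
    calibration: CalibrationSpec | None = None,
    strata: pd.DataFrame | None = None,
) -> ReplicateWeights:
    """Generate B Rao-Wu rescaled bootstrap replicates of the base weights.

    With ``recalibrate`` (the default) every replicate is re-raked to the
    benchmark margins and re-scaled to mean 1, so the replicate variance also
    carries the calibration step's effect; disable it for speed or to study
    the pure design variance of fixed weights.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if recalibrate and benchmark is None:
        raise ValueError("recalibrate=True requires a benchmark table")
    resp = ws.respondents
    base = base or ws.latest_stage
    w0 = ws.column(base)
    rng = np.random.default_rng(seed)

    if strata is not None:
        strata_order = strata["stratum_id"].tolist()
        region_of = dict(zip(strata["stratum_id"], strata["region_id"]))
    else:
        strata_order = list(sample.sampled_clusters)
        region_of = {sid: sid for sid in strata_order}
    clusters_by_stratum, collapsed = _collapse_singletons(
        strata_order, region_of, {k: v for k, v in sample.sampled_clusters.items() if v}
    )
    if collapsed:
        msg = "; ".join(f"{a}->{b}" for a, b in collapsed)
        warnings.warn(f"singleton strata collapsed before replication: {msg}",
                      stacklevel=2)

    n = len(resp)
    cluster_col = resp["cluster_id"].to_numpy()
    W = np.empty((n, B), dtype=float)
    factors_by_cluster: dict[str, np.ndarray] = {}
    n_h_map: dict[str, int] = {}
    stratum_of_cluster: dict[str, str] = {}
    for sid, clusters in clusters_by_stratum.items():
        n_h = len(clusters)
        n_h_map[sid] = n_h
        m = rng.multinomial(n_h - 1, np.full(n_h, 1.0 / n_h), size=B)  # (B, n_h)
        fac = (n_h / (n_h - 1)) * m.astype(float)
        for j, cid in enumerate(clusters):
            factors_by_cluster[cid] = fac[:, j]
            stratum_of_cluster[cid] = sid
    for cid, fac in factors_by_cluster.items():
        rows = np.flatnonzero(cluster_col == cid)
        if rows.size:
            W[rows, :] = w0[rows, None] * fac[None, :]

    if recalibrate:
        spec = calibration or CalibrationSpec()
        raker = Raker(
            resp, benchmark, spec.margins,
            tolerance=spec.tolerance, max_iterations=spec.max_iterations,
        )
        for b in range(B):
            wb = raker.rake(W[:, b], allow_zero=True, raise_on_fail=False)
            s = wb.sum()
            if s > 0 and base == "rescaled":
                wb *= n / s
            W[:, b] = wb

    return ReplicateWeights(
        weights=W,
        B=B,
        base=base,
        respondent_ids=resp["person_id"].to_numpy(),
        stratum_of_cluster=stratum_of_cluster,
        n_h=n_h_map,
        seed=seed,
        recalibrated=recalibrate,
        collapsed_strata=collapsed,
    )


def replicate_estimates(
    rw: ReplicateWeights | np.ndarray,
    values: np.ndarray,
    estimator: str = "mean",
) -> np.ndarray:
    """Apply an estimator per replicate: Hajek weighted mean / proportion, or
    Horvitz-Thompson weighted total.

    Replicates whose weights sum to zero cannot support the Hajek form; they
    are returned as NaN with a warning so downstream variance code can drop
    them explicitly.
    """
    W = rw.weights if isinstance(rw, ReplicateWeights) else np.asarray(rw, dtype=float)
    y = np.asarray(values, dtype=float)
    if y.shape[0] != W.shape[0]:
        raise ValueError("values must be defined for every respondent")
    if np.isnan(y).any():
        raise ValueError("values contain NaN")
    num = y @ W
    if estimator == "total":
        return num
    if estimator not in ("mean", "proportion"):
        raise ValueError(f"unknown estimator {estimator!r}")
    den = W.sum(axis=0)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} replicate(s) with zero total weight excluded",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[bad] = np.nan
    return out


@dataclass
class VarianceEstimate:
    variance: float
    standard_error: float
    percentile_ci: tuple[float, float]
    normal_ci: tuple[float, float]
    B_used: int
    degenerate: bool = False


def bootstrap_variance(
    point: float, reps: np.ndarray, level: float = 0.95
) -> VarianceEstimate:
    """Bootstrap variance about the full-sample point estimate, with CIs.

    variance = (1/B) * sum_b (theta_b - theta_hat)^2 ; the percentile CI uses
    linearly interpolated (type-7) quantiles of the replicate distribution and
    the normal CI is theta_hat +/- z * SE.
    """
    reps = np.asarray(reps, dtype=float)
    reps = reps[~np.isnan(reps)]
    B = reps.size
    if B < 2:
        raise ValueError("need at least 2 usable replicates")
    var = float(np.mean((reps - point) ** 2))
    se = float(np.sqrt(var))
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    z = float(stats.norm.ppf(1 - alpha / 2))
    degenerate = bool(np.all(reps == reps[0]))
    if degenerate:
        logger.warning("all bootstrap replicates identical; degenerate CI")
    return VarianceEstimate(
        variance=var,
        standard_error=se,
        percentile_ci=(float(lo), float(hi)),
        normal_ci=(point - z * se, point + z * se),
        B_used=int(B),
        degenerate=degenerate,
    )
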