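"""Design-based point estimation and the calibration margin audit.

Estimates use the Hajek (ratio) form — weighted means and proportions are
invariant to rescaling all weights by a positive constant, which is the
right convention for calibrated weights rescaled to mean 1 (the population
scale has been deliberately discarded).  Uncertainty comes from the
bootstrap replicate weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import BenchmarkTable
from .weights import WeightSet, MARGIN_COLUMNS
from .bootstrap import ReplicateWeights, replicate_estimates, bootstrap_variance

__all__ = ["EstimateResult", "weighted_proportion", "margin_audit", "estimate_proportion"]


@dataclass
class EstimateResult:
    """A design-based estimate with its bootstrap uncertainty."""

    estimand_label: str
    point: float
    standard_error: float
    ci_low: float
    ci_high: float
    B_used: int
    method: str  # "percentile" | "normal"

    def summary(self) -> str:
        return (
            f"{self.estimand_label}: {self.point:.4f} "
            f"(SE {self.standard_error:.4f}, "
            f"{self.method} 95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}], "
            f"B={self.B_used})"
        )

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand_label,
            "point": self.point,
            "standard_error": self.standard_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "B": self.B_used,
            "method": self.method,
        }


def weighted_proportion(values, weights) -> float:
    """Hajek estimator: sum(w*y) / sum(w) for binary y and positive weights."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != w.shape:
        raise ValueError("values and weights must align")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("values must be binary")
    return float(w @ y / w.sum())


def margin_audit(
    ws: WeightSet,
    bench: BenchmarkTable,
    margins=("stratum", "sex", "age_group"),
    stage: str | None = None,
) -> pd.DataFrame:
    """Compare weighted sample margins against the benchmark, cell by cell.

    Returns a table (margin, category, weighted, benchmark, rel_error); the
    audit statistic is the maximum relative error.  Benchmark categories with
    no respondents are reported with NaN weighted counts, never silently
    dropped.  The audit runs on the calibrated column by default — the
    rescaled weights have deliberately lost the population scale.
    """
    if stage is None and "calibrated" in ws.table.columns:
        stage = "calibrated"
    w = ws.column(stage)
    resp = ws.respondents
    rows = []
    for dim in margins:
        col = MARGIN_COLUMNS[dim]
        bm = bench.margin(dim)
        bm.index = bm.index.astype(str)
        got = pd.Series(w).groupby(resp[col].astype(str).to_numpy()).sum()
        unmapped = set(got.index) - set(bm.index)
        if unmapped:
            raise ValueError(
                f"respondents in {dim} categories absent from benchmark: {sorted(unmapped)}"
            )
        for cat, target in bm.items():
            weighted = float(got.get(cat, np.nan))
            rel = abs(weighted - target) / target if target > 0 else np.nan
            rows.append(
                dict(margin=dim, category=cat, weighted=weighted,
                     benchmark=float(target), rel_error=rel)
            )
    return pd.DataFrame(rows)


def estimate_proportion(
    values,
    ws: WeightSet,
    replicates: ReplicateWeights | None = None,
    label: str = "proportion",
    method: str = "percentile",
    stage: str | None = None,
) -> EstimateResult:
    """Full-sample Hajek proportion with bootstrap SE and CI.

    Without replicate weights the SE and CI are reported as NaN (point
    estimate only).
    """
    point = weighted_proportion(values, ws.column(stage))
    if replicates is None:
        return EstimateResult(label, point, float("nan"), float("nan"),
                              float("nan"), 0, method)
    reps = replicate_estimates(replicates, np.asarray(values, dtype=float),
                               estimator="proportion")
    ve = bootstrap_variance(point, reps)
    lo, hi = ve.percentile_ci if method == "percentile" else ve.normal_ci
    return EstimateResult(label, point, ve.standard_error, float(lo), float(hi),
                          ve.B_used, method)
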