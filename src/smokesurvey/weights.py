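"""Four-step survey-weight construction.

1. *Initial weight*: the reciprocal of the respondent's within-household
   selection probability.  One smoker per sex is drawn uniformly among the
   k same-sex smokers, so the initial weight is k.
2. *Design weight*: household inclusion is treated as approximately equal
   within a stratum (the systematic-route inclusion probabilities are
   unknown but near-constant), so initial weights are scaled per stratum so
   that stratum weight totals are proportional to stratum adult population.
3. *Calibration*: post-stratification of the design weights to external
   benchmark smoker counts over stratum, sex and age group — either raking
   (iterative proportional fitting over the three margins, the default) or
   joint-cell post-stratification.
4. *Rescaling*: weights are rescaled to mean 1 within the country so that
   analyses across countries are on a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .population import BenchmarkTable
from .sampling import FieldSample

__all__ = [
    "WeightSet",
    "CalibrationSpec",
    "CalibrationError",
    "initial_weights",
    "design_weights",
    "calibrate",
    "rescale_mean_one",
    "Raker",
]

logger = logging.getLogger(__name__)

MARGIN_COLUMNS = {"stratum": "stratum_id", "sex": "sex", "age_group": "age_group"}


class CalibrationError(RuntimeError):
    """Raking failed to reach the margin tolerance; carries final errors."""

    def __init__(self, msg: str, margin_errors: dict[str, float] | None = None):
        super().__init__(msg)
        self.margin_errors = margin_errors or {}


class CalibrationSpec(BaseModel):
    mode: Literal["raking", "cell_poststratification"] = "raking"
    margins: list[str] = ["stratum", "sex", "age_group"]
    tolerance: float = Field(default=1e-8, gt=0)
    max_iterations: int = Field(default=200, ge=1)
    min_cell_count: int = Field(default=5, ge=1)


@dataclass
class WeightSet:
    """Respondent-level weights at the four construction stages.

    ``table`` is indexed like ``respondents`` and gains one column per stage
    (initial, design, calibrated, rescaled) as the chain progresses.
    """

    respondents: pd.DataFrame
    table: pd.DataFrame
    country: str = ""

    def column(self, stage: str | None = None) -> np.ndarray:
        """Weights of ``stage``, or of the most advanced stage computed."""
        if stage is None:
            stage = self.latest_stage
        return self.table[stage].to_numpy(dtype=float)

    @property
    def latest_stage(self) -> str:
        for stage in ("rescaled", "calibrated", "design", "initial"):
            if stage in self.table.columns:
                return stage
        raise ValueError("weight set has no weight columns")

    def with_column(self, stage: str, values: np.ndarray) -> "WeightSet":
        if np.any(values <= 0):
            raise ValueError(f"{stage} weights must be strictly positive")
        table = self.table.copy()
        table[stage] = values
        return replace(self, table=table)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "respondent_id", self.respondents["person_id"].to_numpy())
        out.to_csv(path, index=False)


def initial_weights(sample: FieldSample | pd.DataFrame, country: str = "") -> WeightSet:
    """Step 1: weight = number of same-sex smokers in the household (1/p)."""
    resp = sample.respondents if isinstance(sample, FieldSample) else sample
    if resp.empty:
        raise ValueError("no respondents")
    k = resp["same_sex_smokers_in_household"].to_numpy()
    if (k < 1).any():
        raise ValueError("same_sex_smokers_in_household must be >= 1")
    table = pd.DataFrame({"initial": k.astype(float)}, index=resp.index)
    return WeightSet(respondents=resp, table=table, country=country)


def design_weights(ws: WeightSet, strata: pd.DataFrame) -> WeightSet:
    """Step 2: scale initial weights so stratum totals track adult population.

    Within stratum h the household-inclusion constant cancels into a single
    scale factor N_h / (sum of initial weights in h).  A stratum with
    population but no respondents is merged into the preceding stratum of the
    same region (or the nearest stratum in frame order) with a warning.
    """
    resp = ws.respondents
    initial = ws.column("initial")
    strata = strata.reset_index(drop=True)
    pop = dict(zip(strata["stratum_id"], strata["adult_population"].astype(float)))
    unknown = set(resp["stratum_id"]) - set(pop)
    if unknown:
        raise ValueError(f"respondents in unknown strata: {sorted(unknown)}")

    present = set(resp["stratum_id"])
    target = dict(pop)
    order = strata["stratum_id"].tolist()
    region = dict(zip(strata["stratum_id"], strata["region_id"]))
    for sid in order:
        if sid in present or pop[sid] == 0:
            continue
        donors = [
            o for o in order
            if o in present and region[o] == region[sid]
        ] or [o for o in order if o in present]
        if not donors:
            raise ValueError("no stratum has respondents")
        donor = min(donors, key=lambda o: abs(order.index(o) - order.index(sid)))
        target[donor] += target.pop(sid)
        msg = f"stratum {sid} has no respondents; population merged into {donor}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)

    totals = pd.Series(initial).groupby(resp["stratum_id"].to_numpy()).sum()
    scale = resp["stratum_id"].map(
        {sid: target[sid] / totals[sid] for sid in totals.index}
    ).to_numpy(dtype=float)
    return ws.with_column("design", initial * scale)


class Raker:
    """Iterative proportional fitting of weights to fixed margin targets.

    Margin category codes are precomputed so that the same raker can be
    applied cheaply to many weight vectors (e.g. bootstrap replicates).
    """

    def __init__(
        self,
        respondents: pd.DataFrame,
        bench: BenchmarkTable,
        margins: Sequence[str] = ("stratum", "sex", "age_group"),
        tolerance: float = 1e-8,
        max_iterations: int = 200,
    ):
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.margins: list[str] = list(margins)
        self.codes: dict[str, np.ndarray] = {}
        self.targets: dict[str, np.ndarray] = {}
        self.categories: dict[str, list] = {}
        for dim in self.margins:
            col = MARGIN_COLUMNS[dim]
            bm = bench.margin(dim)
            values = resp_col = respondents[col].astype(str)
            unmatched = set(resp_col) - set(bm.index.astype(str))
            if unmatched:
                raise ValueError(
                    f"respondent {dim} categories missing from benchmark: {sorted(unmatched)}"
                )
            cats = [c for c in bm.index if str(c) in set(values)]
            dropped = bm.drop(index=cats)
            if float(dropped.sum()) > 0:
                warnings.warn(
                    f"{dim}: benchmark categories {list(dropped.index)} have no "
                    "respondents; their totals are excluded from the margin",
                    stacklevel=2,
                )
            code_of = {str(c): i for i, c in enumerate(cats)}
            self.codes[dim] = values.map(code_of).to_numpy(dtype=int)
            self.targets[dim] = bm.loc[cats].to_numpy(dtype=float)
            self.categories[dim] = cats
            if (self.targets[dim] <= 0).any():
                raise ValueError(f"{dim}: benchmark margin has non-positive cells")

    def margin_errors(self, w: np.ndarray) -> dict[str, float]:
        out = {}
        for dim in self.margins:
            cur = np.bincount(self.codes[dim], weights=w, minlength=len(self.targets[dim]))
            out[dim] = float(np.max(np.abs(cur - self.targets[dim]) / self.targets[dim]))
        return out

    def rake(
        self, w: np.ndarray, allow_zero: bool = False, raise_on_fail: bool = True
    ) -> np.ndarray:
        """Return raked weights; raises CalibrationError on non-convergence.

        ``allow_zero`` tolerates structurally zero weights (bootstrap
        replicates): a margin category whose current weighted count is zero
        keeps factor 1 and is excluded from the convergence check.  With
        ``raise_on_fail=False`` the best-effort weights after the final
        iteration are returned instead of raising (used for replicate
        re-calibration, where a degenerate replicate may converge slowly).
        """
        w = np.asarray(w, dtype=float).copy()
        for _ in range(self.max_iterations):
            for dim in self.margins:
                codes, tgt = self.codes[dim], self.targets[dim]
                cur = np.bincount(codes, weights=w, minlength=len(tgt))
                factor = np.ones_like(tgt)
                ok = cur > 0
                if not allow_zero and not ok.all():
                    raise CalibrationError(
                        f"{dim}: margin category with zero weighted count",
                        self.margin_errors(w),
                    )
                factor[ok] = tgt[ok] / cur[ok]
                w *= factor[codes]
            errs = []
            for dim in self.margins:
                cur = np.bincount(
                    self.codes[dim], weights=w, minlength=len(self.targets[dim])
                )
                ok = cur > 0 if allow_zero else np.ones_like(cur, dtype=bool)
                errs.append(
                    np.max(np.abs(cur[ok] - self.targets[dim][ok]) / self.targets[dim][ok])
                )
            if max(errs) < self.tolerance:
                return w
        if raise_on_fail:
            raise CalibrationError(
                f"raking did not converge in {self.max_iterations} iterations",
                self.margin_errors(w),
            )
        logger.warning("raking not fully converged (max rel error %.2e)", max(errs))
        return w


def _cell_poststratify(
    resp: pd.DataFrame, w: np.ndarray, bench: BenchmarkTable, spec: CalibrationSpec
) -> np.ndarray:
    """Joint-cell post-stratification with small-cell collapsing.

    Cells with fewer than ``min_cell_count`` respondents (or empty cells with
    positive benchmark) are merged with the adjacent age group within the same
    stratum and sex before the ratio adjustment.
    """
    cells = bench.cells.copy()
    ages = list(dict.fromkeys(cells["age_group"].astype(str)))
    key = ["stratum_id", "sex", "age_group"]

    def label(sid, sex, age):
        return f"{sid}|{sex}|{age}"

    resp_cell = [label(*t) for t in resp[key].astype(str).itertuples(index=False, name=None)]
    counts = pd.Series(resp_cell).value_counts()

    # scan age groups within each stratum x sex; open a new collapse group once
    # the running respondent count reaches min_cell_count
    group_of: dict[str, str] = {}
    n_collapsed = 0
    for (sid, sex), sub in cells.astype({"age_group": str}).groupby(
        ["stratum_id", "sex"], sort=False
    ):
        present = set(sub["age_group"])
        run: list[str] = []
        n_run = 0
        last_anchor: str | None = None
        for age in ages:
            if age not in present:
                continue
            cell = label(sid, sex, age)
            run.append(cell)
            n_run += int(counts.get(cell, 0))
            if n_run >= spec.min_cell_count:
                for c in run:
                    group_of[c] = run[0]
                last_anchor = run[0]
                n_collapsed += len(run) > 1
                run, n_run = [], 0
        if run:  # trailing short run merges backwards into the previous group
            anchor = last_anchor if last_anchor is not None else run[0]
            for c in run:
                group_of[c] = anchor
            n_collapsed += 1
    if n_collapsed:
        warnings.warn(
            f"{n_collapsed} benchmark cell group(s) collapsed below "
            f"min_cell_count={spec.min_cell_count}",
            stacklevel=3,
        )

    cell_labels = [label(*t) for t in cells[key].astype(str).itertuples(index=False, name=None)]
    tgt = cells.assign(group=[group_of[c] for c in cell_labels]).groupby("group")["smokers"].sum()
    missing = {c for c in resp_cell if c not in group_of}
    if missing:
        raise ValueError(f"respondent cells missing from benchmark: {sorted(missing)}")
    resp_group = np.array([group_of[c] for c in resp_cell])
    cur = pd.Series(w).groupby(resp_group).sum()
    factor = (tgt / cur).reindex(resp_group).to_numpy(dtype=float)
    if not np.isfinite(factor).all():
        raise CalibrationError("empty sample group with positive benchmark total")
    return w * factor


def calibrate(
    ws: WeightSet, bench: BenchmarkTable, spec: CalibrationSpec | None = None
) -> WeightSet:
    """Step 3: post-stratification calibration to benchmark smoker margins."""
    spec = spec or CalibrationSpec()
    w = ws.column("design") if "design" in ws.table.columns else ws.column()
    if spec.mode == "raking":
        raker = Raker(
            ws.respondents, bench, spec.margins,
            tolerance=spec.tolerance, max_iterations=spec.max_iterations,
        )
        w_cal = raker.rake(w)
    else:
        w_cal = _cell_poststratify(ws.respondents, w, bench, spec)
    return ws.with_column("calibrated", w_cal)


def rescale_mean_one(ws: WeightSet, stage: str | None = None) -> WeightSet:
    """Step 4: rescale to mean 1 within the country; relative weights unchanged."""
    w = ws.column(stage or ("calibrated" if "calibrated" in ws.table.columns else None))
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    return ws.with_column("rescaled", w * (len(w) / total))
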