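"""Fieldwork outcome rates derived from disposition counts.

From the nine raw counts (addresses attempted/contacted, eligibility
screening results, selections, refusals, completions) seven quantities are
derived: the household eligibility rate, the estimated number of eligible
households among all attempted addresses, and the household/individual
contact, cooperation and response rates.

All ratios are computed at full floating precision and only rounded at the
reporting layer (half-up, three decimals for rates, nearest integer for the
estimated eligible-household count).  The household response rate divides by
the *unrounded* estimated eligible-household count; chaining rounded values
does not reproduce the published accounting conventions this calculator
follows.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .sampling import DispositionCounts, RAW_ROW_POSITIONS

__all__ = ["OutcomeRates", "compute_rates", "rates_report", "read_report",
           "DERIVED_ROW_POSITIONS", "round_half_up"]

# positions of the derived rows in the 16-row disposition table
DERIVED_ROW_POSITIONS = {
    "eligibility_rate": 7,
    "estimated_eligible_households": 8,
    "household_contact_rate": 12,
    "household_cooperation_rate": 13,
    "household_response_rate": 14,
    "individual_cooperation_rate": 15,
    "individual_response_rate": 16,
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OutcomeRates:
    """The seven derived quantities, at full precision.

    A ``None`` field marks a rate whose denominator was zero — an explicit
    undefined-rate marker rather than a silent NaN.
    """

    eligibility_rate: float | None
    estimated_eligible_households: float | None
    household_contact_rate: float | None
    household_cooperation_rate: float | None
    household_response_rate: float | None
    individual_cooperation_rate: float | None
    individual_response_rate: float | None

    def rounded(self) -> dict[str, float | None]:
        """Reporting precision: 3 decimals for rates, integer for row 8."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                out[f.name] = None
            elif f.name == "estimated_eligible_households":
                out[f.name] = round_half_up(v, 0)
            else:
                out[f.name] = round_half_up(v, 3)
        return out


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_rates(d: DispositionCounts) -> OutcomeRates:
    """Derive the seven outcome quantities from raw disposition counts."""
    d.validate(select_one_per_sex=False)
    elig = _ratio(d.with_eligible, d.eligibility_determined)
    est_elig = None if elig is None else elig * d.addresses_attempted
    return OutcomeRates(
        eligibility_rate=elig,
        estimated_eligible_households=est_elig,
        household_contact_rate=_ratio(d.addresses_contacted, d.addresses_attempted),
        household_cooperation_rate=_ratio(d.households_with_selection, d.with_eligible),
        household_response_rate=(
            None if not est_elig else d.households_with_selection / est_elig
        ),
        individual_cooperation_rate=_ratio(
            d.completed_interviews, d.completed_interviews + d.individual_refusals
        ),
        individual_response_rate=_ratio(d.completed_interviews, d.individuals_selected),
    )


def rates_report(table: list[tuple[str, DispositionCounts]]) -> pd.DataFrame:
    """Render the full 16-row disposition-and-rates table, one column per country.

    Raw counts are echoed unchanged; derived rows carry the reporting
    rounding.  The frame round-trips losslessly through CSV.
    """
    if not table:
        raise ValueError("at least one country is required")
    names = [c for c, _ in table]
    if len(set(names)) != len(names):
        raise ValueError("duplicate country labels")
    keys = dict(sorted(
        {**RAW_ROW_POSITIONS, **DERIVED_ROW_POSITIONS}.items(), key=lambda kv: kv[1]
    ))
    out = pd.DataFrame({"row": list(keys.values()), "key": list(keys.keys())})
    for country, d in table:
        rates = compute_rates(d).rounded()
        col = []
        for key in keys:
            if key in RAW_ROW_POSITIONS:
                col.append(float(getattr(d, key)))
            else:
                v = rates[key]
                col.append(float("nan") if v is None else v)
        out[country] = col
    return out


def read_report(path_or_df: str | Path | pd.DataFrame) -> list[tuple[str, DispositionCounts]]:
    """Parse a report (CSV path or frame) back into raw disposition counts."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    df = df.set_index("key")
    countries = [c for c in df.columns if c != "row"]
    out = []
    for c in countries:
        d = DispositionCounts.from_mapping(df[c])
        d.validate(select_one_per_sex=False)
        out.append((c, d))
    return out
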