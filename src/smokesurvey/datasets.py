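"""Packaged reference data: Wave 1 (2016) fieldwork dispositions of the
six-country European face-to-face smoker survey.

The disposition table carries the nine raw accounting rows per country
(addresses approached, contacts, eligibility screening, selections,
refusals, completions); the published interview totals are also provided.
The completed-interview row of the disposition table lists 1003 for Romania
while the published per-country sample-size table lists 1001 — the package
takes each table as given and surfaces the discrepancy as a warning, not an
error.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .sampling import DispositionCounts

__all__ = [
    "load_wave1_dispositions",
    "wave1_sample_sizes",
    "cross_check_sample_sizes",
    "COUNTRIES",
]

COUNTRIES = ["Germany", "Greece", "Hungary", "Poland", "Romania", "Spain"]

# published number of completed interviews per country (overall 6011)
_SAMPLE_SIZES = {
    "Germany": 1003,
    "Greece": 1000,
    "Hungary": 1000,
    "Poland": 1006,
    "Romania": 1001,
    "Spain": 1001,
}


def _fixture_frame() -> pd.DataFrame:
    with (resources.files("smokesurvey") / "data" / "wave1_dispositions.csv").open() as fh:
        return pd.read_csv(fh)


def load_wave1_dispositions() -> dict[str, DispositionCounts]:
    """The six countries' raw disposition counts, validated on load."""
    df = _fixture_frame().set_index("key")
    out = {}
    for country in COUNTRIES:
        d = DispositionCounts.from_mapping(df[country])
        d.validate(select_one_per_sex=False)
        out[country] = d
    return out


def wave1_sample_sizes() -> dict[str, int]:
    """Published per-country completed-interview totals (sum 6011)."""
    return dict(_SAMPLE_SIZES)


def cross_check_sample_sizes() -> dict[str, tuple[int, int]]:
    """Compare disposition completions against published sample sizes.

    Returns the mismatching countries as {country: (dispositions, published)}
    and warns — the tables genuinely disagree for Romania.
    """
    disp = load_wave1_dispositions()
    sizes = wave1_sample_sizes()
    mismatch = {
        c: (disp[c].completed_interviews, sizes[c])
        for c in COUNTRIES
        if disp[c].completed_interviews != sizes[c]
    }
    if mismatch:
        warnings.warn(
            f"completed-interview counts disagree across source tables: {mismatch}",
            stacklevel=2,
        )
    return mismatch
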