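"""Reference summary tables for active UGS wells in six U.S. states.

Small published state-level summaries of population-at-risk estimates
around active underground natural gas storage wells (2010 census basis,
200 m radius and state setback distances).  They let the reporting and
aggregation routines be exercised against realistic state-level magnitudes
without shipping any well, address, or census microdata: re-aggregating the
state rows must reproduce the reference totals, and any column whose rows
do not sum to its stated total is flagged rather than reproduced.

Each loader returns the per-state rows; totals rows (labelled
``TOTAL_PRINTED``) are returned separately.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "state_summary_200m",
    "top_wells_200m",
    "setback_summary",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("abode.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def state_summary_200m() -> tuple[pd.DataFrame, dict]:
    """State rows and stated totals for the 200 m well-area summary.

    Columns: wells, wells with at least one RHU (count and stated percent),
    uncapped RHU count, and the three PAR estimates (PPA, capped ABODE,
    uncapped ABODE), plus the well-level Wilcoxon z.
    """
    df = _load("ugs_200m_state_summary.csv")
    totals = df[df["state"] == "TOTAL_PRINTED"].iloc[0].to_dict()
    rows = df[df["state"] != "TOTAL_PRINTED"].reset_index(drop=True)
    return rows, totals


def top_wells_200m() -> pd.DataFrame:
    """Top ten wells by capped-ABODE PAR within 200 m.

    The PAR difference column is not stored; it is recomputed as
    capped ABODE minus PPA by the table builder.
    """
    return _load("ugs_200m_top_wells.csv")


def setback_summary() -> tuple[pd.DataFrame, dict]:
    """State rows and stated totals for the setback-conflict summary."""
    df = _load("ugs_setback_summary.csv")
    totals = df[df["state"] == "TOTAL_PRINTED"].iloc[0].to_dict()
    rows = df[df["state"] != "TOTAL_PRINTED"].reset_index(drop=True)
    return rows, totals
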