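"""Report tables: state summaries, top-ranked wells, setback conflicts.

Every table closes with a TOTAL row re-derived by summing the state rows
inside the writer; where an externally supplied total disagrees with the
column sum, the discrepancy is flagged rather than silently reproduced.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationResult, SetbackRecord
from .metrics import wilcoxon_signed_rank

__all__ = [
    "add_total_row",
    "check_total_row",
    "summarize_by_state",
    "top_wells_table",
    "setback_table",
]

log = logging.getLogger(__name__)


def add_total_row(
    df: pd.DataFrame,
    sum_columns: Sequence[str],
    label_column: str = "state",
    label: str = "TOTAL",
) -> pd.DataFrame:
    """Append a total row holding the column sums of the given columns."""
    total = {c: "" for c in df.columns}
    total[label_column] = label
    for c in sum_columns:
        total[c] = df[c].sum()
    out = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return out


def check_total_row(
    df: pd.DataFrame,
    printed_totals: Mapping[str, float],
    sum_columns: Sequence[str],
) -> dict[str, tuple[float, float]]:
    """Compare column sums against externally printed totals.

    Returns {column: (column_sum, printed_total)} for every column whose sum
    disagrees with the supplied total, logging each mismatch.
    """
    mismatches: dict[str, tuple[float, float]] = {}
    for c in sum_columns:
        if c not in printed_totals:
            continue
        s = float(df[c].sum())
        p = float(printed_totals[c])
        if not np.isclose(s, p, rtol=0, atol=0.5):
            mismatches[c] = (s, p)
            log.warning(
                "column %r: state rows sum to %s but supplied total is %s", c, s, p
            )
    return mismatches


def summarize_by_state(
    per_well: pd.DataFrame,
    wells_by_state: Mapping[str, int],
    universe_by_state: Mapping[str, Mapping[str, AllocationResult]] | None = None,
) -> pd.DataFrame:
    """Per-state summary of the 200 m (or other radius) results.

    ``per_well`` needs columns well_id, state, rhu_count, abode_capped,
    abode_uncapped, ppa.  Population columns come from the dissolved-union
    (universe) results when supplied, so overlapping buffers are not double
    counted; otherwise they are per-well sums.  The closing TOTAL row
    aggregates across all states (union-based when available), with the
    well-level Wilcoxon signed-rank z of capped ABODE vs PPA alongside.
    """
    rows = []
    for state in sorted(per_well["state"].dropna().unique()):
        sub = per_well[per_well["state"] == state]
        n_wells = int(wells_by_state.get(state, len(sub)))
        with_rhu = int((sub["rhu_count"] > 0).sum())
        if universe_by_state and state in universe_by_state:
            uni = universe_by_state[state]
            ppa = uni["ppa"].population
            cap = uni["abode_capped"].population
            unc = uni["abode_uncapped"].population
            rhus = uni["abode_uncapped"].rhu_count
        else:
            ppa = float(sub["ppa"].sum())
            cap = float(sub["abode_capped"].sum())
            unc = float(sub["abode_uncapped"].sum())
            rhus = int(sub["rhu_count"].sum())
        w = wilcoxon_signed_rank(sub["abode_capped"].to_numpy(), sub["ppa"].to_numpy())
        rows.append(
            {
                "state": state,
                "wells": n_wells,
                "wells_with_rhu": with_rhu,
                "pct_with_rhu": int(round(100.0 * with_rhu / n_wells)) if n_wells else 0,
                "uncapped_rhus": rhus,
                "par_ppa": ppa,
                "par_abode_capped": cap,
                "par_abode_uncapped": unc,
                "wilcoxon_z": w.z,
                "wilcoxon_p": w.p,
            }
        )
    df = pd.DataFrame(rows)
    sum_cols = [
        "wells",
        "wells_with_rhu",
        "uncapped_rhus",
        "par_ppa",
        "par_abode_capped",
        "par_abode_uncapped",
    ]
    df = add_total_row(df, sum_cols)
    total = df.index[-1]
    n_wells_total = int(df.loc[total, "wells"]) or 1
    df.loc[total, "pct_with_rhu"] = int(
        round(100.0 * df.loc[total, "wells_with_rhu"] / n_wells_total)
    )
    w = wilcoxon_signed_rank(per_well["abode_capped"].to_numpy(), per_well["ppa"].to_numpy())
    df.loc[total, "wilcoxon_z"] = w.z
    df.loc[total, "wilcoxon_p"] = w.p
    return df


def top_wells_table(per_well: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k wells ranked by capped-ABODE population at risk.

    Ties break deterministically by well_id.  ``par_diff`` is capped ABODE
    minus PPA; ``ppa_rank`` is the well's competition rank among all wells
    ordered by PPA descending.
    """
    if k > len(per_well):
        log.warning("top_wells_table: k=%d exceeds %d wells; returning all", k, len(per_well))
        k = len(per_well)
    df = per_well.copy()
    df["par_diff"] = df["abode_capped"] - df["ppa"]
    order = (-df["ppa"]).rank(method="min").astype(int)
    df["ppa_rank"] = order
    df = df.sort_values(
        ["abode_capped", "well_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    df.insert(0, "rank", range(1, len(df) + 1))
    cols = ["rank", "well_id"]
    for opt in ("facility_id", "state"):
        if opt in df.columns:
            cols.append(opt)
    cols += ["rhu_count", "abode_capped", "ppa", "par_diff", "ppa_rank"]
    return df[cols].reset_index(drop=True)


def setback_table(records: Sequence[SetbackRecord]) -> pd.DataFrame:
    """Per-state setback-conflict summary with a TOTAL row.

    Counts facilities and wells with at least one dwelling inside the
    regulated setback, the conflicting RHUs, and the two PAR estimates for
    the setback circles (ABODE column uses the capped estimate).
    """
    rows = []
    states = sorted({r.state for r in records})
    for state in states:
        sub = [r for r in records if r.state == state]
        conflict = [r for r in sub if r.n_conflict_rhus > 0]
        rows.append(
            {
                "state": state,
                "setback_ft": sub[0].setback_ft,
                "facilities_with_conflict": len(
                    {r.facility_id for r in conflict if r.facility_id is not None}
                ),
                "wells_with_conflict": len(conflict),
                "rhus_in_setback": int(sum(r.n_conflict_rhus for r in conflict)),
                "par_ppa": float(sum(r.ppa for r in conflict)),
                "par_abode": float(sum(r.abode_capped for r in conflict)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "state",
            "setback_ft",
            "facilities_with_conflict",
            "wells_with_conflict",
            "rhus_in_setback",
            "par_ppa",
            "par_abode",
        ],
    )
    if len(df):
        df = add_total_row(
            df,
            [
                "facilities_with_conflict",
                "wells_with_conflict",
                "rhus_in_setback",
                "par_ppa",
                "par_abode",
            ],
        )
    return df
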