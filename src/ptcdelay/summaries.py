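"""Cohort-level descriptive summaries of node counts and delays.

Two summary shapes are produced from the tidy cohort delay table:

* a *global* summary — encounter counts split by side (demand/supply) and
  caregiver category (community/clinical), with per-participant medians,
  plus sums/medians/IQRs of the global delay measures and the demand/supply
  share of total delay-days;
* a *per-node-type* summary — encounter frequency, participant reach and
  per-side marginal-delay distribution for every node type observed.

Quantiles use linear interpolation; rendered tables round to one decimal
but the underlying frames keep full precision so rounding never feeds a
downstream computation. The marginal-delay mass of an interval that
straddles the antipsychotic date is counted in the side delay *sums* (via
the global measures) but excluded from any single encounter's delay
statistics, since it belongs to no one side in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delays import DEMAND, SUPPLY


def _quantiles(x) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return med, q1, q3


@dataclass
class GlobalSummary:
    n_participants: int
    node_counts: pd.DataFrame   # index (side, category) -> sum, pct, median...
    delays: pd.DataFrame        # index measure -> sum, pct, median, q1, q3


def summarize_global(table: pd.DataFrame) -> GlobalSummary:
    """Cohort-wide node-count and delay summary.

    Node-count medians/IQRs are per participant and include participants
    with zero encounters in a stratum; delay statistics are over
    participants' global measures. Percentages are within-stratum for the
    community/clinical split and relative to total delay-days for the
    demand/supply delay split.
    """
    if table.empty:
        raise ValueError("empty delay table")
    enc = table[table.row_kind == "encounter"]
    glob = table[table.row_kind == "global"]
    pids = glob.participant_id.unique()
    n = len(pids)

    rows = []
    for side in ("all", DEMAND, SUPPLY):
        sub = enc if side == "all" else enc[enc.side == side]
        side_total = len(sub)
        for cat in ("total", "community", "clinical"):
            csub = sub if cat == "total" else sub[sub.category == cat]
            per_pid = (csub.groupby("participant_id").size()
                       .reindex(pids, fill_value=0))
            med, q1, q3 = _quantiles(per_pid.to_numpy())
            rows.append({
                "side": side, "category": cat, "sum": len(csub),
                "pct": 100.0 * len(csub) / side_total if side_total else np.nan,
                "median": med, "q1": q1, "q3": q3,
            })
    node_counts = pd.DataFrame(rows).set_index(["side", "category"])

    total_days = glob.dup_total.sum()
    drows = []
    for measure in ("dup_total", "dup_demand", "dup_supply", "onset_delay"):
        vals = glob[measure].dropna()
        med, q1, q3 = _quantiles(vals.to_numpy())
        drows.append({
            "measure": measure, "sum": vals.sum(),
            "pct": 100.0 * vals.sum() / total_days if total_days else np.nan,
            "median": med, "q1": q1, "q3": q3,
        })
    delays = pd.DataFrame(drows).set_index("measure")
    return GlobalSummary(n_participants=n, node_counts=node_counts,
                         delays=delays)


def summarize_node_types(table: pd.DataFrame) -> pd.DataFrame:
    """Per-node-type encounter frequency and marginal-delay contribution.

    One row per node type actually observed; per-side delay medians, IQRs
    and ranges are over that type's encounter rows on that side (straddling
    rows excluded). Strata with no encounters are reported as NaN, not zero.
    """
    if table.empty:
        raise ValueError("empty delay table")
    enc = table[table.row_kind == "encounter"]
    glob = table[table.row_kind == "global"]
    n_cohort = glob.participant_id.nunique()
    n_enc = len(enc)

    rows = []
    for (cat, node), sub in enc.groupby(["category", "node_type"], sort=True):
        row = {
            "category": cat,
            "node_type": node,
            "total_encounters": len(sub),
            "pct_of_encounters": 100.0 * len(sub) / n_enc,
            "unique_participants": sub.participant_id.nunique(),
            "pct_of_cohort": 100.0 * sub.participant_id.nunique() / n_cohort,
        }
        for side in (DEMAND, SUPPLY):
            ssub = sub[sub.side == side]
            row[f"{side}_encounters"] = len(ssub)
            stat = ssub[~ssub.straddles.astype(bool)].marginal_delay
            med, q1, q3 = _quantiles(stat.to_numpy())
            row.update({
                f"{side}_delay_median": med,
                f"{side}_delay_q1": q1,
                f"{side}_delay_q3": q3,
                f"{side}_delay_min": stat.min() if len(stat) else np.nan,
                f"{side}_delay_max": stat.max() if len(stat) else np.nan,
            })
        rows.append(row)
    out = pd.DataFrame(rows)
    # community block first, then clinical, each by descending frequency
    out["_cat_order"] = (out.category != "community").astype(int)
    out = (out.sort_values(["_cat_order", "total_encounters"],
                           ascending=[True, False])
           .drop(columns="_cat_order").reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# rendering


def frame_to_markdown(df: pd.DataFrame, ndec: int = 1) -> str:
    """Minimal pipe-table rendering with numeric rounding."""
    d = df.reset_index() if df.index.name or isinstance(
        df.index, pd.MultiIndex) else df
    d = d.copy()
    for col in d.columns:
        if pd.api.types.is_float_dtype(d[col]):
            d[col] = d[col].round(ndec)
    header = "| " + " | ".join(str(c) for c in d.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in d.columns) + "|"
    body = [
        "| " + " | ".join("" if pd.isna(v) else str(v) for v in rec) + " |"
        for rec in d.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body]) + "\n"


def render_global_summary(s: GlobalSummary, fmt: str = "md") -> str:
    if fmt == "md":
        return (
            f"Cohort of {s.n_participants} participants\n\n"
            "## Node counts\n\n" + frame_to_markdown(s.node_counts)
            + "\n## Delay measures (days)\n\n" + frame_to_markdown(s.delays)
        )
    if fmt == "csv":
        return (s.node_counts.reset_index().to_csv(index=False)
                + "\n" + s.delays.reset_index().to_csv(index=False))
    raise ValueError(f"unknown format {fmt!r}")
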