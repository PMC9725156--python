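"""Decomposition of the Duration of Untreated Psychosis into marginal delays.

Three global measures are defined on each pathway, all in whole days:

* ``dup_total``   — onset of psychosis to service enrollment;
* ``dup_demand``  — onset to first antipsychotic prescribed for psychosis
  (the help-seeking phase, before the healthcare system has recognised
  psychosis);
* ``dup_supply``  — first antipsychotic to enrollment (delay inside the
  system). Antipsychotic-naive participants have dup_supply = 0 by
  definition: their entire delay is demand-side.

The node-level measure is the *marginal delay* of each encounter: the days
from the start of that encounter to the start of the next one (or to
enrollment, for the last encounter). Together with the *onset delay* (onset
to first encounter) the marginal delays tile the whole interval, so the
decomposition obeys exact conservation identities:

    onset_delay + sum(marginal delays) = dup_total
    dup_demand + dup_supply = dup_total

Side attribution: an encounter is demand-side iff it is dated strictly
before the antipsychotic date; the prescribing encounter itself is
supply-side, since its marginal delay elapses entirely after prescription.
When the antipsychotic date falls strictly inside an interval (a phone
prescription between visits, say), that interval's delay is split at the
antipsychotic date so that both conservation identities still hold exactly;
the split is recorded in ``boundary_split``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import ParticipantCovariates, Pathway, validate_pathway

DEMAND = "demand"
SUPPLY = "supply"

#: covariate columns attached to delay-table rows when covariates are supplied
COVARIATE_COLUMNS = [
    "sex", "race_ethnicity", "age_at_onset", "household_income", "insurance",
    "living_situation", "max_education", "in_school", "employed",
    "gaf_e", "gaf_12", "gaf_delta", "gf_r", "gf_s",
]


@dataclass(frozen=True)
class MarginalDelay:
    """Delay attributable to a single encounter."""

    seq_index: int
    node_type: str
    category: str
    side: str            # demand | supply
    delay: int           # days until the next node (or enrollment)
    straddles: bool = False  # antipsychotic date falls inside this interval


@dataclass(frozen=True)
class BoundarySplit:
    """Demand/supply partition of the one interval containing the
    antipsychotic date; ``after_seq`` is the seq_index of the encounter the
    interval starts at (0 when the onset-delay interval itself straddles)."""

    after_seq: int
    demand_days: int
    supply_days: int


@dataclass(frozen=True)
class DelayDecomposition:
    participant_id: str
    onset_delay: Optional[int]          # None on a zero-encounter pathway
    marginal_delays: tuple[MarginalDelay, ...]
    dup_total: int
    dup_demand: int
    dup_supply: int
    naive_flag: bool
    boundary_split: Optional[BoundarySplit] = None
    degenerate: bool = False            # pathway had no encounters


def decompose_delays(p: Pathway) -> DelayDecomposition:
    """Decompose one validated pathway into its global and marginal delays."""
    res = validate_pathway(p)
    if not res.ok:
        raise ValueError(
            f"pathway {p.participant_id} failed validation: "
            + "; ".join(res.violations)
        )

    dup_total = p.enrollment_date - p.onset_date
    ap = p.antipsychotic_date
    if p.naive_flag:
        dup_demand, dup_supply = dup_total, 0
    else:
        dup_demand = ap - p.onset_date
        dup_supply = p.enrollment_date - ap

    encs = p.encounters
    if not encs:
        split = None
        if ap is not None and p.onset_date < ap < p.enrollment_date:
            split = BoundarySplit(0, ap - p.onset_date, p.enrollment_date - ap)
        return DelayDecomposition(
            participant_id=p.participant_id,
            onset_delay=None,
            marginal_delays=(),
            dup_total=dup_total,
            dup_demand=dup_demand,
            dup_supply=dup_supply,
            naive_flag=p.naive_flag,
            boundary_split=split,
            degenerate=True,
        )

    onset_delay = encs[0].date - p.onset_date
    split: Optional[BoundarySplit] = None
    if ap is not None and p.onset_date < ap < encs[0].date:
        split = BoundarySplit(0, ap - p.onset_date, encs[0].date - ap)

    margins: list[MarginalDelay] = []
    for i, e in enumerate(encs):
        nxt = encs[i + 1].date if i + 1 < len(encs) else p.enrollment_date
        delay = nxt - e.date
        side = DEMAND if (ap is None or e.date < ap) else SUPPLY
        straddles = ap is not None and e.date < ap < nxt
        if straddles:
            split = BoundarySplit(e.seq_index, ap - e.date, nxt - ap)
        margins.append(MarginalDelay(
            seq_index=e.seq_index,
            node_type=e.node_type,
            category=e.category.value,
            side=side,
            delay=delay,
            straddles=straddles,
        ))
    return DelayDecomposition(
        participant_id=p.participant_id,
        onset_delay=onset_delay,
        marginal_delays=tuple(margins),
        dup_total=dup_total,
        dup_demand=dup_demand,
        dup_supply=dup_supply,
        naive_flag=p.naive_flag,
        boundary_split=split,
    )


def side_delay_sums(d: DelayDecomposition) -> tuple[int, int]:
    """Demand/supply delay mass reassembled from the node-level pieces.

    Returns (demand_days, supply_days): onset delay plus demand-side
    marginal delays on one side, supply-side marginal delays on the other,
    with a straddling interval's mass divided at the antipsychotic date.
    Equals (dup_demand, dup_supply) on every valid pathway — the
    conservation identity the decomposition is built around.
    """
    if d.degenerate:
        if d.boundary_split is not None:
            return d.boundary_split.demand_days, d.boundary_split.supply_days
        return (d.dup_total, 0) if d.dup_supply == 0 else (0, d.dup_total)
    # demand share of the onset interval: the interval is clipped at the
    # antipsychotic date, so its demand part can never exceed dup_demand
    demand = min(d.onset_delay, d.dup_demand)
    supply = d.onset_delay - demand
    split = d.boundary_split
    for m in d.marginal_delays:
        if m.straddles and split is not None and split.after_seq == m.seq_index:
            demand += split.demand_days
            supply += split.supply_days
        elif m.side == DEMAND:
            demand += m.delay
        else:
            supply += m.delay
    return demand, supply


def aggregate_decompositions(
    ds: Iterable[DelayDecomposition],
    covariates: Optional[Mapping[str, ParticipantCovariates]] = None,
) -> pd.DataFrame:
    """Stack decompositions into one tidy long-format cohort delay table.

    One ``row_kind == "encounter"`` row per marginal delay and one
    ``row_kind == "global"`` row per participant carrying the global
    measures; when a covariate mapping is supplied its columns are joined
    onto every row so the table feeds the mixed model directly.
    """
    ds = list(ds)
    if not ds:
        raise ValueError("empty decomposition collection")
    rows = []
    for d in ds:
        for m in d.marginal_delays:
            rows.append({
                "row_kind": "encounter",
                "participant_id": d.participant_id,
                "seq_index": m.seq_index,
                "node_type": m.node_type,
                "category": m.category,
                "side": m.side,
                "marginal_delay": m.delay,
                "straddles": m.straddles,
            })
        rows.append({
            "row_kind": "global",
            "participant_id": d.participant_id,
            "onset_delay": d.onset_delay,
            "dup_total": d.dup_total,
            "dup_demand": d.dup_demand,
            "dup_supply": d.dup_supply,
            "naive_flag": d.naive_flag,
            "degenerate": d.degenerate,
        })
    table = pd.DataFrame(rows)
    if covariates is not None:
        cov_rows = [{
            "participant_id": c.participant_id,
            **{k: getattr(c, k) for k in COVARIATE_COLUMNS},
        } for c in covariates.values()]
        table = table.merge(pd.DataFrame(cov_rows), on="participant_id",
                            how="left")
    return table
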