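"""A fully dated single-participant worked example.

A nine-day illustrative pathway used throughout the documentation and
tests: psychosis onset on day 0; a family member notices symptoms on day 2
and brings the patient to an urgent-care evaluation the same day; the
patient self-refers on day 3 to an urgent-care psychiatric service seen on
day 4, where the first antipsychotic is prescribed; an outpatient
psychiatrist follows on day 7; on day 8 a family member and then a
community counsellor escalate to the emergency department, which refers to
the first-episode service; enrollment is on day 9.

The decomposition of this pathway is exact and known by hand: DUP-total 9,
DUP-demand 4, DUP-supply 5, onset delay 2, marginal delays
(0, 1, 1, 3, 1, 0, 0, 1) with three demand-side and five supply-side
encounters.
"""

from __future__ import annotations

from .model import Cohort, Encounter, ParticipantCovariates, Pathway

DEMO_ID = "demo-01"


def demo_pathway() -> Pathway:
    """The worked-example pathway (onset day 0, enrollment day 9)."""
    mk = lambda seq, node, day, rx=False: Encounter(  # noqa: E731
        participant_id=DEMO_ID, seq_index=seq, node_type=node, date=day,
        prescribing_flag=rx)
    return Pathway(
        participant_id=DEMO_ID,
        onset_date=0,
        enrollment_date=9,
        antipsychotic_date=4,
        naive_flag=False,
        encounters=(
            mk(1, "Family", 2),
            mk(2, "Acute", 2),
            mk(3, "Self", 3),
            mk(4, "Acute", 4, rx=True),
            mk(5, "Outpt", 7),
            mk(6, "Family", 8),
            mk(7, "OtherCommunity", 8),
            mk(8, "ED", 8),
        ),
    )


def demo_cohort() -> Cohort:
    """The worked example wrapped as a one-participant cohort.

    The covariates are plausible placeholders (the narrative does not give
    any); they only exist so cohort-level operations run end to end.
    """
    cv = ParticipantCovariates(
        participant_id=DEMO_ID, sex="male", race_ethnicity="Other",
        age_at_onset=19.0, household_income="<$40k", insurance="Public",
        living_situation="With family", max_education="High school",
        in_school=True, employed=False,
        gaf_e=35.0, gaf_12=60.0, gf_r=5.0, gf_s=5.0,
    )
    return Cohort(
        pathways={DEMO_ID: demo_pathway()},
        covariates={DEMO_ID: cv},
        metadata={"date_axis": "day", "provenance": "worked-example"},
    )
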