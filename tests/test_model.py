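import datetime

import pandas as pd
import pytest

from ptcdelay import (Encounter, Pathway, impute_partial_date, read_cohort,
                      validate_pathway, write_cohort)
from ptcdelay.model import ENCOUNTER_COLUMNS


def _enc(seq, node, day, pid="p1", rx=False):
    return Encounter(participant_id=pid, seq_index=seq, node_type=node,
                     date=day, prescribing_flag=rx)


def _pathway(**kw):
    base = dict(
        participant_id="p1", onset_date=0, enrollment_date=9,
        antipsychotic_date=4, naive_flag=False,
        encounters=(_enc(1, "Family", 2), _enc(2, "ED", 4, rx=True)),
    )
    base.update(kw)
    return Pathway(**base)


def test_demo_pathway_valid(demo):
    assert validate_pathway(demo).ok


@pytest.mark.parametrize("mutation, fragment", [
    (dict(encounters=(_enc(1, "Family", -1),)), "precedes onset"),
    (dict(encounters=(_enc(1, "Family", 2), _enc(2, "ED", 4, rx=True)),
          antipsychotic_date=6), "prescribing date mismatch"),
    (dict(encounters=(_enc(1, "ED", 5), _enc(2, "Family", 3))),
     "dates decrease"),
    (dict(encounters=(_enc(1, "Family", 11),)), "after enrollment"),
    (dict(naive_flag=True), "naive pathway carries"),
    (dict(antipsychotic_date=None), "missing antipsychotic date"),
    (dict(antipsychotic_date=12), "after enrollment"),
    (dict(encounters=(_enc(1, "ED", 4, rx=True), _enc(2, "ED", 4, rx=True))),
     "more than one prescribing"),
    (dict(encounters=(_enc(1, "Family", 2), _enc(1, "ED", 4, rx=True))),
     "seq_index"),
], ids=["before-onset", "rx-date-mismatch", "date-inversion",
        "after-enrollment", "naive-with-apdate", "missing-apdate",
        "apdate-after-enrollment", "two-prescribers", "dup-seq-index"])
def test_invariant_violations_reported(mutation, fragment):
    res = validate_pathway(_pathway(**mutation))
    assert not res.ok
    assert any(fragment in v for v in res.violations), res.violations


def test_validation_reports_all_violations_not_just_first():
    p = _pathway(encounters=(_enc(1, "Family", -2), _enc(2, "ED", 99)),
                 antipsychotic_date=None)
    res = validate_pathway(p)
    assert len(res.violations) >= 3


@pytest.mark.parametrize("ymd, policy, expected", [
    ((2017, 3, 12), "mid", (datetime.date(2017, 3, 12), "exact")),
    ((2017, 3, None), "mid", (datetime.date(2017, 3, 15), "imputed_mid")),
    ((2017, 2, None), "first", (datetime.date(2017, 2, 1), "imputed_first")),
    ((2017, 12, None), "mid", (datetime.date(2017, 12, 15), "imputed_mid")),
])
def test_partial_date_imputation(ymd, policy, expected):
    y, m, d = ymd
    assert impute_partial_date(y, m, d, policy) == expected


def test_partial_date_rejects_bad_input():
    with pytest.raises(ValueError):
        impute_partial_date(2017, 2, 30, "mid")
    with pytest.raises(ValueError):
        impute_partial_date(2017, 2, None, "nearest")


def test_cohort_roundtrip_identity(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    back = read_cohort(paths["participants"], paths["encounters"])
    assert back.pathways == small_cohort.pathways
    assert back.covariates == small_cohort.covariates
    assert back.exclusions == []


def test_write_is_deterministic(demo_coh, tmp_path):
    a = write_cohort(demo_coh, tmp_path / "a")
    b = write_cohort(demo_coh, tmp_path / "b")
    for key in ("participants", "encounters"):
        assert a[key].read_bytes() == b[key].read_bytes()


def test_precision_flags_survive_roundtrip(demo_coh, tmp_path):
    pid = next(iter(demo_coh.pathways))
    p = demo_coh.pathways[pid]
    encs = list(p.encounters)
    encs[0] = Encounter(participant_id=pid, seq_index=1,
                        node_type=encs[0].node_type, date=encs[0].date,
                        date_precision="imputed_first")
    demo_coh.pathways[pid] = Pathway(
        participant_id=pid, onset_date=p.onset_date,
        enrollment_date=p.enrollment_date,
        antipsychotic_date=p.antipsychotic_date, naive_flag=p.naive_flag,
        encounters=tuple(encs))
    paths = write_cohort(demo_coh, tmp_path)
    back = read_cohort(paths["participants"], paths["encounters"])
    assert back.pathways[pid].encounters[0].date_precision == "imputed_first"


def test_invalid_pathway_excluded_with_reason(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    parts = pd.read_csv(paths["participants"])
    # invert one participant's onset/enrollment dates
    victim = parts.loc[0, "participant_id"]
    parts.loc[0, ["onset_date", "enrollment_date"]] = (
        parts.loc[0, ["enrollment_date", "onset_date"]].to_numpy())
    parts.to_csv(paths["participants"], index=False)
    back = read_cohort(paths["participants"], paths["encounters"])
    assert back.n == small_cohort.n - 1
    assert [pid for pid, _ in back.exclusions] == [victim]
    assert back.n + len(back.exclusions) == len(parts)


def test_covariate_bounds_exclude_participant(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    parts = pd.read_csv(paths["participants"])
    victim = parts.loc[1, "participant_id"]
    parts.loc[1, "gaf_e"] = 250
    parts.to_csv(paths["participants"], index=False)
    back = read_cohort(paths["participants"], paths["encounters"])
    assert any(pid == victim and "gaf_e" in reason
               for pid, reason in back.exclusions)


def test_empty_encounters_file_rejected(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    pd.DataFrame(columns=ENCOUNTER_COLUMNS).to_csv(
        paths["encounters"], index=False)
    with pytest.raises(ValueError, match="no encounters"):
        read_cohort(paths["participants"], paths["encounters"])


def test_unknown_node_type_is_an_error(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    encs = pd.read_csv(paths["encounters"])
    encs.loc[0, "node_type"] = "Shaman"
    encs.to_csv(paths["encounters"], index=False)
    with pytest.raises(ValueError, match="Shaman"):
        read_cohort(paths["participants"], paths["encounters"])


def test_missing_column_is_an_error(small_cohort, tmp_path):
    paths = write_cohort(small_cohort, tmp_path)
    parts = pd.read_csv(paths["participants"]).drop(columns=["gaf_12"])
    parts.to_csv(paths["participants"], index=False)
    with pytest.raises(ValueError, match="gaf_12"):
        read_cohort(paths["participants"], paths["encounters"])


def test_iso_calendar_dates_convert_to_day_axis(demo_coh, tmp_path):
    """Calendar-dated input lands on the onset = day 0 axis."""
    paths = write_cohort(demo_coh, tmp_path)
    base = datetime.date(2017, 5, 1)
    for name, datecols in (("participants",
                            ["onset_date", "enrollment_date",
                             "antipsychotic_date"]),
                           ("encounters", ["date"])):
        df = pd.read_csv(paths[name])
        for col in datecols:
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v)
                else (base + datetime.timedelta(days=int(v))).isoformat())
        df.to_csv(paths[name], index=False)
    back = read_cohort(paths["participants"], paths["encounters"])
    assert back.pathways == demo_coh.pathways


def test_gaf_delta_recomputed_not_trusted(demo_coh):
    cv = next(iter(demo_coh.covariates.values()))
    assert cv.gaf_delta == cv.gaf_e - cv.gaf_12
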