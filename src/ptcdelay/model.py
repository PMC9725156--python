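"""Domain types, validation, and CSV I/O for pathway-to-care (PTC) cohorts.

A pathway to care is the ordered, dated sequence of help-seeking encounters
("nodes") a patient traverses between psychosis onset and enrollment in a
specialty first-episode service. All delay arithmetic in this package runs
on a participant-local integer day axis with onset = day 0; calendar dates
in input files are converted on load. Two CSV tables describe a cohort:

``participants.csv``
    participant_id, onset_date, enrollment_date, antipsychotic_date (empty
    when the participant was antipsychotic-naive at enrollment), naive_flag,
    and the covariate columns (sex, race_ethnicity, age_at_onset,
    household_income, insurance, living_situation, max_education, in_school,
    employed, gaf_e, gaf_12, gf_r, gf_s).

``encounters.csv``
    participant_id, seq_index, node_type, date, date_precision,
    prescribing_flag.

Dates may be ISO-8601 calendar dates or bare integer day numbers; the
convention is declared in a ``metadata.json`` sidecar (or autodetected).
Pathways that fail validation are excluded from the cohort and reported,
mirroring how discrepant, irreconcilable interview data are handled in
practice rather than aborting an analysis run.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .nodes import NODE_TYPES, Category, category_of

DATE_PRECISIONS = ("exact", "imputed_mid", "imputed_first")

PARTICIPANT_COLUMNS = [
    "participant_id", "onset_date", "enrollment_date", "antipsychotic_date",
    "naive_flag", "sex", "race_ethnicity", "age_at_onset", "household_income",
    "insurance", "living_situation", "max_education", "in_school", "employed",
    "gaf_e", "gaf_12", "gf_r", "gf_s",
]
ENCOUNTER_COLUMNS = [
    "participant_id", "seq_index", "node_type", "date", "date_precision",
    "prescribing_flag",
]


@dataclass(frozen=True)
class Encounter:
    """One dated interaction with a caregiver node on a participant's pathway."""

    participant_id: str
    seq_index: int
    node_type: str
    date: int
    date_precision: str = "exact"
    prescribing_flag: bool = False

    @property
    def category(self) -> Category:
        return category_of(self.node_type)


@dataclass(frozen=True)
class Pathway:
    """A participant's full journey from psychosis onset to service enrollment.

    ``antipsychotic_date`` is the day the first antipsychotic for psychosis
    was prescribed; it is absent exactly when ``naive_flag`` is set (the
    participant reached enrollment antipsychotic-naive).
    """

    participant_id: str
    onset_date: int
    enrollment_date: int
    antipsychotic_date: Optional[int]
    naive_flag: bool
    encounters: tuple[Encounter, ...]

    def shifted(self, k: int) -> "Pathway":
        """The same pathway with every date translated by ``k`` days."""
        return replace(
            self,
            onset_date=self.onset_date + k,
            enrollment_date=self.enrollment_date + k,
            antipsychotic_date=None if self.antipsychotic_date is None
            else self.antipsychotic_date + k,
            encounters=tuple(replace(e, date=e.date + k) for e in self.encounters),
        )


@dataclass(frozen=True)
class ParticipantCovariates:
    """Baseline characteristics used in the association analyses.

    GAF scores (Global Assessment of Functioning, 1-100) are rated at
    enrollment (``gaf_e``) and retrospectively for 12 months prior
    (``gaf_12``); ``gaf_delta`` is always recomputed as gaf_e - gaf_12 and
    never trusted from file. Global Functioning Role/Social scores run 1-10.
    """

    participant_id: str
    sex: str
    race_ethnicity: str
    age_at_onset: float
    household_income: str
    insurance: str
    living_situation: str
    max_education: str
    in_school: bool
    employed: bool
    gaf_e: float
    gaf_12: float
    gf_r: float
    gf_s: float

    @property
    def gaf_delta(self) -> float:
        return self.gaf_e - self.gaf_12

    def violations(self) -> list[str]:
        out = []
        for name, lo, hi in (
            ("gaf_e", 1, 100), ("gaf_12", 1, 100),
            ("gf_r", 1, 10), ("gf_s", 1, 10),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                out.append(f"{name} {v} outside scale bounds [{lo}, {hi}]")
        return out


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    violations: tuple[str, ...] = ()


@dataclass
class Cohort:
    """Validated pathways plus covariates, keyed by participant id."""

    pathways: dict[str, Pathway]
    covariates: dict[str, ParticipantCovariates]
    metadata: dict = field(default_factory=dict)
    #: (participant_id, reason) for every participant dropped at validation
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if set(self.pathways) != set(self.covariates):
            raise ValueError("pathway and covariate key sets differ")

    @property
    def n(self) -> int:
        return len(self.pathways)

    @property
    def exclusion_fraction(self) -> float:
        total = self.n + len(self.exclusions)
        return len(self.exclusions) / total if total else 0.0


def validate_pathway(p: Pathway) -> ValidationResult:
    """Check every pathway invariant; violations are data, not exceptions.

    Returns all violated rules: date ordering along the sequence, the
    onset/enrollment envelope, the naive-flag / antipsychotic-date
    exclusivity, and prescribing-encounter consistency.
    """
    v: list[str] = []
    if p.enrollment_date < p.onset_date:
        v.append("enrollment precedes onset")
    if p.naive_flag and p.antipsychotic_date is not None:
        v.append("naive pathway carries an antipsychotic date")
    if not p.naive_flag and p.antipsychotic_date is None:
        v.append("non-naive pathway missing antipsychotic date")
    if p.antipsychotic_date is not None:
        if p.antipsychotic_date < p.onset_date:
            v.append("antipsychotic date precedes onset")
        if p.antipsychotic_date > p.enrollment_date:
            v.append("antipsychotic date after enrollment")

    prev_date = None
    prev_seq = 0
    prescribers = []
    for e in p.encounters:
        try:
            e.category
        except KeyError:
            v.append(f"unknown node_type {e.node_type!r} at seq {e.seq_index}")
        if e.seq_index <= prev_seq:
            v.append(f"seq_index not strictly increasing at {e.seq_index}")
        prev_seq = max(prev_seq, e.seq_index)
        if e.date < p.onset_date:
            v.append(f"encounter precedes onset (seq {e.seq_index})")
        if e.date > p.enrollment_date:
            v.append(f"encounter after enrollment (seq {e.seq_index})")
        if prev_date is not None and e.date < prev_date:
            v.append(f"dates decrease at seq {e.seq_index}")
        prev_date = e.date
        if e.date_precision not in DATE_PRECISIONS:
            v.append(f"bad date_precision {e.date_precision!r} (seq {e.seq_index})")
        if e.prescribing_flag:
            prescribers.append(e)
    if len(prescribers) > 1:
        v.append("more than one prescribing encounter")
    for e in prescribers:
        if p.antipsychotic_date is None:
            v.append("prescribing encounter on pathway without antipsychotic date")
        elif e.date != p.antipsychotic_date:
            v.append(
                f"prescribing date mismatch (encounter day {e.date} vs "
                f"antipsychotic day {p.antipsychotic_date})"
            )
    return ValidationResult(ok=not v, violations=tuple(v))


def impute_partial_date(
    year: int, month: int, day: Optional[int] = None, policy: str = "mid"
) -> tuple[_dt.date, str]:
    """Resolve a possibly day-less calendar date.

    When interview participants recall only the month of an encounter, the
    day is approximated to the 15th (policy ``mid``, the default) or the 1st
    (policy ``first``) of that month, and flagged so downstream tables can
    distinguish imputed from exact dates.
    """
    if policy not in ("mid", "first"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    if day is not None:
        return _dt.date(year, month, day), "exact"
    if policy == "mid":
        return _dt.date(year, month, 15), "imputed_mid"
    return _dt.date(year, month, 1), "imputed_first"


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValueError(f"unparseable boolean {x!r}")


def _detect_axis(values: Iterable) -> str:
    for x in values:
        s = str(x).strip()
        if s in ("", "nan"):
            continue
        try:
            float(s)
            return "day"
        except ValueError:
            return "iso"
    return "day"


def _parse_date(x, axis: str):
    s = str(x).strip()
    if s in ("", "nan"):
        return None
    if axis == "day":
        try:
            v = float(s)
        except ValueError:
            raise ValueError(f"unparseable day number {x!r}") from None
        if not v.is_integer():
            raise ValueError(f"day number {x!r} is not a whole day")
        return int(v)
    try:
        return _dt.date.fromisoformat(s)
    except ValueError:
        raise ValueError(f"unparseable date {x!r}") from None


def read_cohort(
    participants_csv, encounters_csv, date_axis: Optional[str] = None
) -> Cohort:
    """Load and validate a cohort from the two-table CSV schema.

    Calendar dates are converted to participant-local day numbers with
    onset = day 0. Participants whose pathway or covariates fail validation
    are excluded (with reasons) rather than raising, so one irreconcilable
    record never aborts a cohort analysis; the exclusion list and rate are
    available on the returned :class:`Cohort`.
    """
    parts = pd.read_csv(participants_csv, dtype=str, keep_default_na=False)
    encs = pd.read_csv(encounters_csv, dtype=str, keep_default_na=False)
    missing = set(PARTICIPANT_COLUMNS) - set(parts.columns)
    if missing:
        raise ValueError(f"participants file missing columns: {sorted(missing)}")
    missing = set(ENCOUNTER_COLUMNS) - set(encs.columns)
    if missing:
        raise ValueError(f"encounters file missing columns: {sorted(missing)}")
    if len(encs) == 0:
        raise ValueError("no encounters")

    if date_axis is None:
        date_axis = _detect_axis(parts["onset_date"])
    if date_axis not in ("day", "iso"):
        raise ValueError(f"unknown date axis {date_axis!r}")

    unknown = sorted(set(encs["node_type"]) - set(NODE_TYPES))
    if unknown:
        raise ValueError(f"unknown node_type labels: {unknown}")

    enc_by_pid: dict[str, list] = {}
    for row in encs.itertuples(index=False):
        enc_by_pid.setdefault(row.participant_id, []).append(row)

    pathways: dict[str, Pathway] = {}
    covars: dict[str, ParticipantCovariates] = {}
    exclusions: list[tuple[str, str]] = []

    for row in parts.itertuples(index=False):
        pid = row.participant_id
        try:
            onset = _parse_date(row.onset_date, date_axis)
            enroll = _parse_date(row.enrollment_date, date_axis)
            ap = _parse_date(row.antipsychotic_date, date_axis)
            if onset is None or enroll is None:
                raise ValueError("missing onset or enrollment date")
            naive = _parse_bool(row.naive_flag)

            def to_day(d):
                if d is None:
                    return None
                if date_axis == "day":
                    return d
                return (d - onset).days

            raw = sorted(
                enc_by_pid.get(pid, []),
                key=lambda r: (_parse_date(r.date, date_axis), int(r.seq_index)),
            )
            encounters = tuple(
                Encounter(
                    participant_id=pid,
                    seq_index=int(r.seq_index),
                    node_type=r.node_type,
                    date=to_day(_parse_date(r.date, date_axis)),
                    date_precision=r.date_precision or "exact",
                    prescribing_flag=_parse_bool(r.prescribing_flag),
                )
                for r in raw
            )
            pw = Pathway(
                participant_id=pid,
                onset_date=to_day(onset) if date_axis == "day" else 0,
                enrollment_date=to_day(enroll),
                antipsychotic_date=to_day(ap),
                naive_flag=naive,
                encounters=encounters,
            )
            cv = ParticipantCovariates(
                participant_id=pid,
                sex=row.sex,
                race_ethnicity=row.race_ethnicity,
                age_at_onset=float(row.age_at_onset),
                household_income=row.household_income,
                insurance=row.insurance,
                living_situation=row.living_situation,
                max_education=row.max_education,
                in_school=_parse_bool(row.in_school),
                employed=_parse_bool(row.employed),
                gaf_e=float(row.gaf_e),
                gaf_12=float(row.gaf_12),
                gf_r=float(row.gf_r),
                gf_s=float(row.gf_s),
            )
        except ValueError as err:
            exclusions.append((pid, str(err)))
            continue
        res = validate_pathway(pw)
        cov_bad = cv.violations()
        if not res.ok or cov_bad:
            exclusions.append((pid, "; ".join([*res.violations, *cov_bad])))
            continue
        pathways[pid] = pw
        covars[pid] = cv

    meta = {"date_axis": "day", "source_axis": date_axis,
            "n_input": len(parts), "n_excluded": len(exclusions)}
    return Cohort(pathways=pathways, covariates=covars,
                  metadata=meta, exclusions=exclusions)


def write_cohort(c: Cohort, out_dir) -> dict[str, Path]:
    """Write a cohort back to the two-table schema plus a metadata sidecar.

    Output is on the internal day-number axis and deterministically ordered,
    so reading it back reproduces the cohort field-for-field and repeated
    writes are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prows, erows = [], []
    for pid in sorted(c.pathways):
        p, cv = c.pathways[pid], c.covariates[pid]
        prows.append({
            "participant_id": pid,
            "onset_date": p.onset_date,
            "enrollment_date": p.enrollment_date,
            "antipsychotic_date": "" if p.antipsychotic_date is None
            else p.antipsychotic_date,
            "naive_flag": p.naive_flag,
            "sex": cv.sex,
            "race_ethnicity": cv.race_ethnicity,
            "age_at_onset": cv.age_at_onset,
            "household_income": cv.household_income,
            "insurance": cv.insurance,
            "living_situation": cv.living_situation,
            "max_education": cv.max_education,
            "in_school": cv.in_school,
            "employed": cv.employed,
            "gaf_e": cv.gaf_e,
            "gaf_12": cv.gaf_12,
            "gf_r": cv.gf_r,
            "gf_s": cv.gf_s,
        })
        for e in p.encounters:
            erows.append({
                "participant_id": pid,
                "seq_index": e.seq_index,
                "node_type": e.node_type,
                "date": e.date,
                "date_precision": e.date_precision,
                "prescribing_flag": e.prescribing_flag,
            })
    paths = {
        "participants": out / "participants.csv",
        "encounters": out / "encounters.csv",
        "metadata": out / "metadata.json",
    }
    pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS).to_csv(
        paths["participants"], index=False)
    pd.DataFrame(erows, columns=ENCOUNTER_COLUMNS).to_csv(
        paths["encounters"], index=False)
    meta = dict(c.metadata)
    meta["date_axis"] = "day"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
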