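"""Semi-Markov synthetic cohort generator.

Real pathway-to-care datasets redact service dates for confidentiality, so
every stage of this package is exercised against synthetic cohorts that
reproduce the statistical structure the analysis assumes: a skewed onset
delay, a community-heavy help-seeking (demand) phase that switches to a
clinical-heavy supply phase at the first antipsychotic prescription, node-
type-specific right-skewed inter-node delays, a small antipsychotic-naive
minority, and baseline covariates with realistic marginals. Covariates act
multiplicatively on all delay draws through a log-linear predictor, which
injects a known ground truth for parameter-recovery tests of the screen
and the mixed model.

Each participant's walk draws node types from a demand-phase transition
matrix until a clinical encounter prescribes (with configured probability),
then from a supply-phase matrix until absorption at the STEP terminal;
inter-node delays are log-normal with node-type- and phase-specific
medians. Delays are whole days. One root seed determines everything; each
participant gets an independently spawned substream so cohorts are
reproducible under partial regeneration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .model import Cohort, Encounter, ParticipantCovariates, Pathway
from .nodes import NODE_TYPES, STEP, Category

_COMMUNITY = [t for t, c in NODE_TYPES.items() if c is Category.COMMUNITY]
_CLINICAL = [t for t, c in NODE_TYPES.items() if c is Category.CLINICAL]


def _norm(weights: dict[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive mass")
    return {k: v / total for k, v in weights.items()}


def _phase_matrix(community_row: dict, clinical_row: dict) -> dict:
    """One transition row per node type, community/clinical prototypes."""
    return {t: _norm(dict(community_row if t in _COMMUNITY else clinical_row))
            for t in NODE_TYPES}


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults are anchored to a published first-episode-psychosis cohort of
    156 participants: 72.4% male, age at onset 21.6 (SD 3.8), GAF 31.1
    (10.9) at enrollment and 53.7 (17.5) a year earlier, onset-delay median
    about 21.5 days, ~7.7% antipsychotic-naive, outpatient mental health the
    slowest node and community nodes near-instant. Where the anchor tables
    give no value (log-scale spreads, transition weights) a single realistic
    choice is documented in the methods note.
    """

    n_participants: int = 156
    seed: int = 0

    # onset delay: log-normal, whole days
    onset_delay_median: float = 21.5
    onset_delay_sigma: float = 1.8

    # routing
    initial_node_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "Family": 0.38, "Self": 0.17, "Police": 0.10, "Education": 0.03,
        "OtherCommunity": 0.05, "ED": 0.13, "Acute": 0.04, "PCP": 0.05,
        "Outpt": 0.03, "Inpt": 0.01, "Mobile": 0.005, "OtherMH": 0.003,
        "OtherMed": 0.002,
    }))
    demand_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: _phase_matrix(
            community_row={
                "Family": 0.06, "Self": 0.04, "Police": 0.03,
                "Education": 0.01, "OtherCommunity": 0.02,
                "ED": 0.30, "Acute": 0.07, "PCP": 0.08, "Outpt": 0.18,
                "Inpt": 0.08, "IOP": 0.02, "Mobile": 0.02, "OtherMH": 0.03,
                "OtherMed": 0.02, STEP: 0.04,
            },
            clinical_row={
                "Family": 0.14, "Self": 0.10, "Police": 0.05,
                "Education": 0.01, "OtherCommunity": 0.04,
                "ED": 0.12, "Acute": 0.03, "PCP": 0.05, "Outpt": 0.20,
                "Inpt": 0.12, "IOP": 0.03, "Mobile": 0.01, "OtherMH": 0.03,
                "OtherMed": 0.02, STEP: 0.05,
            },
        ))
    supply_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: _phase_matrix(
            community_row={
                "Family": 0.08, "Self": 0.12, "Police": 0.03,
                "Education": 0.005, "OtherCommunity": 0.02,
                "ED": 0.15, "Acute": 0.03, "PCP": 0.02, "Outpt": 0.15,
                "Inpt": 0.15, "IOP": 0.05, "Mobile": 0.005, "OtherMH": 0.02,
                "OtherMed": 0.01, STEP: 0.16,
            },
            clinical_row={
                "Family": 0.05, "Self": 0.08, "Police": 0.02,
                "Education": 0.005, "OtherCommunity": 0.01,
                "ED": 0.08, "Acute": 0.02, "PCP": 0.02, "Outpt": 0.18,
                "Inpt": 0.12, "IOP": 0.06, "Mobile": 0.005, "OtherMH": 0.02,
                "OtherMed": 0.01, STEP: 0.30,
            },
        ))

    # per-node-type log-normal delay medians (days), by phase
    delay_median_demand: dict[str, float] = field(default_factory=lambda: {
        "Family": 0.6, "Self": 0.6, "Police": 0.6, "Education": 0.6,
        "OtherCommunity": 0.6, "ED": 0.8, "Inpt": 12.0, "Outpt": 36.5,
        "IOP": 19.5, "Acute": 5.5, "PCP": 2.0, "Mobile": 0.6,
        "OtherMH": 0.6, "OtherMed": 40.0,
    })
    delay_median_supply: dict[str, float] = field(default_factory=lambda: {
        "Family": 0.6, "Self": 0.6, "Police": 0.6, "Education": 8.5,
        "OtherCommunity": 0.6, "ED": 0.8, "Inpt": 13.0, "Outpt": 56.0,
        "IOP": 29.0, "Acute": 5.5, "PCP": 1.5, "Mobile": 0.6,
        "OtherMH": 60.0, "OtherMed": 41.0,
    })
    delay_sigma: dict[str, float] = field(default_factory=lambda: {
        t: (1.5 if c is Category.COMMUNITY else 1.2)
        for t, c in NODE_TYPES.items()
    })

    #: probability that a clinical encounter in the demand phase prescribes
    #: the first antipsychotic; calibrated so the naive fraction lands near
    #: the anchor cohort's 12/156 = 7.7%
    prescribing_prob: float = 0.57
    max_path_length: int = 80

    # covariate marginals
    male_fraction: float = 0.724
    age_mean: float = 21.6
    age_sd: float = 3.8
    gaf_e_mean: float = 31.1
    gaf_e_sd: float = 10.9
    gaf_12_mean: float = 53.7
    gaf_12_sd: float = 17.5
    gf_r_mean: float = 4.4
    gf_r_sd: float = 2.2
    gf_s_mean: float = 5.1
    gf_s_sd: float = 1.5
    in_school_fraction: float = 0.16
    employed_fraction: float = 0.25
    race_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "Black, non-Hispanic": 0.43, "White, non-Hispanic": 0.26,
        "Hispanic": 0.19, "Multi-racial, non-Hispanic": 0.10, "Other": 0.02,
    }))
    income_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "<$40k": 0.40, "$40-60k": 0.16, "$60-100k": 0.15, ">=$100k": 0.17,
        "Unknown": 0.11,
    }))
    insurance_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "Public": 0.54, "Private": 0.37, "Uninsured": 0.04, "Other": 0.01,
    }))
    living_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "With family": 0.88, "Alone": 0.04, "With spouse/partner": 0.01,
        "Other": 0.04,
    }))
    education_probs: dict[str, float] = field(default_factory=lambda: _norm({
        "Less than high school": 0.20, "High school": 0.65,
        "College or technical": 0.15,
    }))

    #: covariate -> (beta per unit on log-delay scale, centering value);
    #: the injected ground truth for parameter-recovery tests. The default
    #: GAF-12 effect of -0.03 per point induces a Spearman correlation of
    #: about -0.35 between GAF-12 and DUP-total at the default noise
    #: levels, the magnitude reported for that association in first-episode
    #: cohorts of this size
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"gaf_12": (-0.03, 53.7)})
    #: SD of a participant-level normal intercept on the log-delay scale
    #: (multiplicative frailty): between-participant delay propensity beyond
    #: what covariates explain — the variance component the mixed model's
    #: random intercept estimates
    participant_frailty_sd: float = 0.35

    def validate(self) -> None:
        for name, mat in (("demand", self.demand_matrix),
                          ("supply", self.supply_matrix)):
            for node, row in mat.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{name} matrix row {node} does not sum to 1")
                if any(v < 0 for v in row.values()):
                    raise ValueError(f"{name} matrix row {node} has negative mass")
        if abs(sum(self.initial_node_probs.values()) - 1.0) > 1e-9:
            raise ValueError("initial node probabilities do not sum to 1")
        if not 0 <= self.prescribing_prob <= 1:
            raise ValueError("prescribing_prob must be a probability")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "covariate_effects" in d:
            d["covariate_effects"] = {
                k: tuple(v) for k, v in d["covariate_effects"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0, n_participants: int = 156) -> CohortConfig:
    """The documented default generator settings (156 participants)."""
    return CohortConfig(seed=seed, n_participants=n_participants)


def _draw_covariates(pid: str, rng: np.random.Generator,
                     cfg: CohortConfig) -> ParticipantCovariates:
    def cat(probs):
        labels = list(probs)
        return labels[rng.choice(len(labels), p=list(probs.values()))]

    def clipped(mean, sd, lo, hi):
        return float(np.clip(round(rng.normal(mean, sd), 1), lo, hi))

    return ParticipantCovariates(
        participant_id=pid,
        sex="male" if rng.random() < cfg.male_fraction else "female",
        race_ethnicity=cat(cfg.race_probs),
        age_at_onset=clipped(cfg.age_mean, cfg.age_sd, 12.0, 45.0),
        household_income=cat(cfg.income_probs),
        insurance=cat(cfg.insurance_probs),
        living_situation=cat(cfg.living_probs),
        max_education=cat(cfg.education_probs),
        in_school=bool(rng.random() < cfg.in_school_fraction),
        employed=bool(rng.random() < cfg.employed_fraction),
        gaf_e=clipped(cfg.gaf_e_mean, cfg.gaf_e_sd, 1.0, 100.0),
        gaf_12=clipped(cfg.gaf_12_mean, cfg.gaf_12_sd, 1.0, 100.0),
        gf_r=clipped(cfg.gf_r_mean, cfg.gf_r_sd, 1.0, 10.0),
        gf_s=clipped(cfg.gf_s_mean, cfg.gf_s_sd, 1.0, 10.0),
    )


def _delay_multiplier(cv: ParticipantCovariates, cfg: CohortConfig) -> float:
    lp = 0.0
    for cov, (beta, center) in cfg.covariate_effects.items():
        lp += beta * (float(getattr(cv, cov)) - center)
    return float(np.exp(lp))


def _lognormal_days(rng, median: float, sigma: float, mult: float) -> int:
    return int(np.floor(mult * rng.lognormal(np.log(median), sigma)))


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate one fully validated synthetic cohort from a config.

    Raises if the routing configuration is non-absorbing (more than 1% of
    walks hit ``max_path_length`` before reaching STEP).
    """
    cfg.validate()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    width = len(str(cfg.n_participants))
    pathways: dict[str, Pathway] = {}
    covars: dict[str, ParticipantCovariates] = {}
    truncated = 0

    init_labels = list(cfg.initial_node_probs)
    init_p = list(cfg.initial_node_probs.values())
    matrices = {}
    for phase, mat in (("demand", cfg.demand_matrix),
                       ("supply", cfg.supply_matrix)):
        matrices[phase] = {node: (list(row), list(row.values()))
                          for node, row in mat.items()}

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"sim-{i:0{width}d}"
        cv = _draw_covariates(pid, rng, cfg)
        mult = _delay_multiplier(cv, cfg)
        if cfg.participant_frailty_sd > 0:
            mult *= float(np.exp(rng.normal(0.0, cfg.participant_frailty_sd)))

        t = _lognormal_days(rng, cfg.onset_delay_median,
                            cfg.onset_delay_sigma, mult)
        node = init_labels[rng.choice(len(init_labels), p=init_p)]
        phase = "demand"
        ap_date: Optional[int] = None
        encounters: list[Encounter] = []
        enrollment = None
        while True:
            prescribes = (
                phase == "demand"
                and NODE_TYPES[node] is Category.CLINICAL
                and rng.random() < cfg.prescribing_prob
            )
            if prescribes:
                ap_date = t
                phase = "supply"
            medians = (cfg.delay_median_demand if phase == "demand"
                       else cfg.delay_median_supply)
            delay = _lognormal_days(rng, medians[node],
                                    cfg.delay_sigma[node], mult)
            encounters.append(Encounter(
                participant_id=pid, seq_index=len(encounters) + 1,
                node_type=node, date=t, prescribing_flag=prescribes,
            ))
            labels, probs = matrices[phase][node]
            nxt = labels[rng.choice(len(labels), p=probs)]
            if nxt == STEP:
                enrollment = t + delay
                break
            if len(encounters) >= cfg.max_path_length:
                truncated += 1
                enrollment = t + delay
                break
            t += delay
            node = nxt
        pathways[pid] = Pathway(
            participant_id=pid, onset_date=0, enrollment_date=enrollment,
            antipsychotic_date=ap_date, naive_flag=ap_date is None,
            encounters=tuple(encounters),
        )
        covars[pid] = cv

    if truncated > 0.01 * cfg.n_participants:
        raise ValueError(
            f"non-absorbing routing: {truncated}/{cfg.n_participants} walks "
            "exceeded max_path_length; check the demand/supply transition "
            "matrices' STEP mass"
        )
    meta = {
        "date_axis": "day",
        "provenance": "synthetic",
        "generator": {"seed": cfg.seed, "n_participants": cfg.n_participants},
    }
    return Cohort(pathways=pathways, covariates=covars, metadata=meta)
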