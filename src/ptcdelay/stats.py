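"""Association screen and mixed-effects model for pathway delays.

Two layers of analysis connect participant characteristics to delay:

* a rank-based bivariate screen of each covariate against the three global
  delay measures — Spearman correlation for continuous covariates,
  Kruskal-Wallis for categorical ones, with the eta-squared effect size
  computed from the H statistic as (H - k + 1) / (n - k) and a Bonferroni
  correction whose family is, by default, all covariates screened against
  one outcome;
* a linear mixed model of per-encounter marginal delay (log1p-transformed
  by default — marginal delays are heavily right-skewed) with fixed effects
  for node type plus one covariate (unadjusted) or all covariates
  (adjusted), and a random intercept per participant to absorb
  between-participant delay propensity across their repeated encounters.

Non-convergence and boundary (singular) fits are reported in the result
object, never papered over with a silent fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .delays import COVARIATE_COLUMNS, DelayDecomposition
from .model import Cohort

#: covariate -> "continuous" | "categorical"; mirrors the screen's default
DEFAULT_COVARIATE_SPEC: dict[str, str] = {
    "sex": "categorical",
    "age_at_onset": "continuous",
    "race_ethnicity": "categorical",
    "household_income": "categorical",
    "insurance": "categorical",
    "living_situation": "categorical",
    "max_education": "categorical",
    "in_school": "categorical",
    "employed": "categorical",
    "gaf_e": "continuous",
    "gaf_12": "continuous",
    "gaf_delta": "continuous",
    "gf_r": "continuous",
    "gf_s": "continuous",
}

OUTCOMES = ("dup_total", "dup_demand", "dup_supply")


def spearman_assoc(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p.

    A constant vector leaves the correlation undefined; that case returns
    (nan, nan) rather than raising, so a degenerate covariate produces an
    NA row in the screen instead of aborting it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_eta2(groups: Iterable) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected), chi-square p, and eta-squared.

    The effect size is derived from the H statistic as
    eta2 = (H - k + 1) / (n - k); the formula can dip below zero for
    near-null data, and is clamped at exactly 0 there.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    n = sum(g.size for g in groups)
    if n < 5:
        raise ValueError("need total n >= 5")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # scipy raises on all-identical data; H is 0 by definition
        return 0.0, 1.0, 0.0
    H, p = sps.kruskal(*groups)
    eta2 = max(0.0, (H - k + 1) / (n - k))
    return float(H), float(p), float(eta2)


@dataclass(frozen=True)
class BivariateResult:
    covariate: str
    outcome: str
    test: str              # spearman | kruskal
    statistic: float       # rho or H
    p_raw: float
    p_bonferroni: float
    effect_size: float     # rho, or eta2 from H
    n: int
    bonferroni_m: int


def bivariate_screen(
    c: Cohort,
    decomps: Iterable[DelayDecomposition],
    covariate_spec: Optional[Mapping[str, str]] = None,
    bonferroni_family: str | int = "per_outcome",
) -> pd.DataFrame:
    """Screen every covariate against every global delay measure.

    Returns one row per (covariate, outcome) pair. Missing covariate values
    are dropped pairwise and the n actually used is reported per cell. The
    Bonferroni multiplier m (printed in every row) is the number of
    covariates in the family per outcome by default; pass an integer to
    override, or ``"all"`` to correct across the full grid.
    """
    spec = dict(covariate_spec or DEFAULT_COVARIATE_SPEC)
    unknown = set(spec) - set(COVARIATE_COLUMNS)
    if unknown:
        raise ValueError(f"covariates absent from cohort: {sorted(unknown)}")
    for kind in spec.values():
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"covariate kind must be continuous/categorical,"
                             f" got {kind!r}")

    out_by_pid = {d.participant_id: d for d in decomps}
    pids = [pid for pid in sorted(c.covariates) if pid in out_by_pid]
    cov_frame = pd.DataFrame([
        {"participant_id": pid,
         **{k: getattr(c.covariates[pid], k) for k in spec}}
        for pid in pids
    ])
    if isinstance(bonferroni_family, int):
        m = bonferroni_family
    elif bonferroni_family == "per_outcome":
        m = len(spec)
    elif bonferroni_family == "all":
        m = len(spec) * len(OUTCOMES)
    else:
        raise ValueError(f"unknown Bonferroni family {bonferroni_family!r}")

    rows = []
    for outcome in OUTCOMES:
        y_all = np.array([getattr(out_by_pid[pid], outcome) for pid in pids],
                         dtype=float)
        for cov, kind in spec.items():
            x_raw = cov_frame[cov]
            keep = x_raw.notna().to_numpy() & ~np.isnan(y_all)
            y = y_all[keep]
            x = x_raw[keep]
            n_used = int(keep.sum())
            if kind == "continuous":
                test = "spearman"
                xv = x.astype(float).to_numpy()
                if n_used < 3 or np.ptp(xv) == 0:
                    stat = p = eff = math.nan
                else:
                    stat, p = spearman_assoc(xv, y)
                    eff = stat
            else:
                test = "kruskal"
                levels = x.astype(str)
                groups = [y[(levels == lv).to_numpy()]
                          for lv in sorted(levels.unique())]
                if len(groups) < 2 or n_used < 5:
                    stat = p = eff = math.nan
                else:
                    stat, p, eff = kruskal_eta2(groups)
            p_bonf = min(1.0, m * p) if not math.isnan(p) else math.nan
            rows.append(BivariateResult(
                covariate=cov, outcome=outcome, test=test,
                statistic=stat, p_raw=p, p_bonferroni=p_bonf,
                effect_size=eff, n=n_used, bonferroni_m=m,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class MixedModelResult:
    """Fit summary of the marginal-delay mixed model."""

    flavour: str                 # unadjusted | adjusted
    transform: str               # log1p | raw
    covariate: Optional[str]
    fixed_effects: pd.DataFrame  # estimate, se, p per term
    random_intercept_var: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    warnings: list[str] = field(default_factory=list)

    def term_estimate(self, name_fragment: str) -> pd.Series:
        """First fixed-effect row whose term name contains the fragment."""
        hits = self.fixed_effects[
            self.fixed_effects.index.str.contains(name_fragment, regex=False)]
        if hits.empty:
            raise KeyError(f"no fixed effect matching {name_fragment!r}")
        return hits.iloc[0]


def fit_marginal_delay_mixed_model(
    table: pd.DataFrame,
    covariate: Optional[str] = None,
    flavour: str = "unadjusted",
    transform: str = "log1p",
) -> MixedModelResult:
    """Random-intercept linear mixed model of per-encounter marginal delay.

    The table must be the covariate-joined cohort delay table. Fixed
    effects are node type plus the named covariate (``unadjusted``) or node
    type plus every covariate (``adjusted``); the grouping structure is one
    random intercept per participant. Zero-delay encounters are included —
    they carry most of the community-node information. Inference on fixed
    effects is Wald. Convergence failure or a boundary (zero) random-effect
    variance is reported on the result, not raised.
    """
    if flavour not in ("unadjusted", "adjusted"):
        raise ValueError(f"unknown flavour {flavour!r}")
    if transform not in ("log1p", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    if flavour == "unadjusted" and covariate is None:
        raise ValueError("unadjusted flavour needs a covariate name")

    data = table[table.row_kind == "encounter"].copy()
    if data.empty:
        raise ValueError("no encounter rows in table")
    terms = list(DEFAULT_COVARIATE_SPEC) if flavour == "adjusted" \
        else [covariate]
    for t in terms:
        if t not in data.columns:
            raise ValueError(f"covariate {t!r} not joined onto the table")
    data = data.dropna(subset=["marginal_delay", *terms])
    data["outcome"] = (np.log1p(data.marginal_delay) if transform == "log1p"
                       else data.marginal_delay.astype(float))

    rhs = ["C(node_type)"]
    for t in terms:
        kind = DEFAULT_COVARIATE_SPEC.get(t, "continuous")
        rhs.append(f"C({t})" if kind == "categorical" else t)
    formula = "outcome ~ " + " + ".join(rhs)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=data, groups=data["participant_id"])
        try:
            # Powell: derivative-free, robust near the variance boundary
            # where quasi-Newton steps can hit a singular Hessian
            res = model.fit(reml=True, method="powell")
            converged = bool(getattr(res, "converged", False))
        except (np.linalg.LinAlgError, ValueError) as err:
            caught.append(str(err))
            res, converged = None, False
        caught.extend(str(w.message) for w in wlist
                      if issubclass(w.category, (ConvergenceWarning,
                                                 RuntimeWarning,
                                                 UserWarning)))
    if res is None:
        return MixedModelResult(
            flavour=flavour, transform=transform, covariate=covariate,
            fixed_effects=pd.DataFrame(columns=["estimate", "se", "p"]),
            random_intercept_var=math.nan, converged=False, singular=True,
            n_obs=len(data), n_groups=data.participant_id.nunique(),
            warnings=caught,
        )
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    fe_names = [t for t in res.fe_params.index]
    fixed = pd.DataFrame({
        "estimate": res.fe_params,
        "se": res.bse.loc[fe_names],
        "p": res.pvalues.loc[fe_names],
    })
    # boundary / unidentifiable variance: zero estimate, a non-PD Hessian,
    # or an explicit singularity warning from the optimizer
    singular = (
        (not converged)
        or re_var < 1e-8
        or any("singular" in w.lower() or "positive definite" in w.lower()
               for w in caught)
    )
    return MixedModelResult(
        flavour=flavour, transform=transform, covariate=covariate,
        fixed_effects=fixed, random_intercept_var=re_var,
        converged=converged, singular=singular,
        n_obs=int(res.nobs), n_groups=data.participant_id.nunique(),
        warnings=caught,
    )
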