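import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptcdelay import (aggregate_decompositions, bivariate_screen,
                      decompose_delays, default_config,
                      fit_marginal_delay_mixed_model, kruskal_eta2,
                      simulate_cohort, spearman_assoc)
from ptcdelay.stats import DEFAULT_COVARIATE_SPEC


# -- independent rank oracles ------------------------------------------------

def _midranks(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[order[j]] == v[order[i]]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # average of 1-based positions
        i = j
    return ranks


def _spearman_oracle(x, y):
    return np.corrcoef(_midranks(x), _midranks(y))[0, 1]


def _kruskal_oracle(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / tie


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_assoc([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_gives_na_not_crash(self):
        rho, p = spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_matches_midrank_oracle_with_ties(self):
        rho, _ = spearman_assoc([1, 2, 2, 4], [7, 5, 9, 11])
        assert rho == pytest.approx(_spearman_oracle([1, 2, 2, 4],
                                                     [7, 5, 9, 11]))

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.integers(0, 9), min_size=3, max_size=20))
    def test_matches_oracle_on_generated_vectors(self, x):
        rng = np.random.default_rng(sum(x) + len(x))
        y = rng.integers(0, 9, size=len(x))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, _ = spearman_assoc(x, y)
        assert rho == pytest.approx(_spearman_oracle(x, y), abs=1e-12)

    def test_self_correlation_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert spearman_assoc(x, x)[0] == pytest.approx(1.0)
        y = rng.normal(size=30)
        assert spearman_assoc(x, y)[0] == pytest.approx(
            -spearman_assoc(x, -y)[0])


class TestKruskal:
    def test_identical_groups_clamp_to_zero(self):
        h, p, eta2 = kruskal_eta2([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert eta2 == 0.0

    def test_matches_hand_ranked_oracle(self):
        groups = [[1, 2, 3], [10, 11, 12]]
        h, p, eta2 = kruskal_eta2(groups)
        h_exp = _kruskal_oracle([np.asarray(g, float) for g in groups])
        assert h == pytest.approx(h_exp)
        n, k = 6, 2
        assert eta2 == pytest.approx(max(0.0, (h_exp - k + 1) / (n - k)))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [rng.integers(0, 6, size=int(rng.integers(3, 8)))
                  for _ in range(k)]
        if np.ptp(np.concatenate(groups)) == 0:
            return
        h, _, eta2 = kruskal_eta2(groups)
        assert h == pytest.approx(_kruskal_oracle(groups), abs=1e-10)
        assert 0.0 <= eta2 <= 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc=m, size=12) for m in (0, 0.5, 1.0)]
        h1, _, e1 = kruskal_eta2(groups)
        h2, _, e2 = kruskal_eta2([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)
        assert e1 == pytest.approx(e2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kruskal_eta2([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_eta2([[1, 2], []])
        with pytest.raises(ValueError):
            kruskal_eta2([[1], [2]])


@pytest.fixture(scope="module")
def screened():
    c = simulate_cohort(default_config(seed=99, n_participants=80))
    ds = [decompose_delays(p) for p in c.pathways.values()]
    return c, ds, bivariate_screen(c, ds)


class TestScreen:
    def test_full_grid_with_bonferroni(self, screened):
        _, _, res = screened
        assert len(res) == len(DEFAULT_COVARIATE_SPEC) * 3
        m = len(DEFAULT_COVARIATE_SPEC)
        assert (res.bonferroni_m == m).all()
        ok = res.dropna(subset=["p_raw"])
        assert np.allclose(ok.p_bonferroni,
                           np.minimum(1.0, m * ok.p_raw))
        assert (ok.p_bonferroni >= ok.p_raw).all()
        spear = ok[ok.test == "spearman"]
        assert spear.statistic.between(-1, 1).all()
        krus = ok[ok.test == "kruskal"]
        assert krus.effect_size.between(0, 1).all()

    def test_constant_covariate_yields_na_row(self):
        c = simulate_cohort(default_config(seed=3, n_participants=30))
        for pid, cv in c.covariates.items():
            c.covariates[pid] = dataclasses.replace(cv, gf_s=5.0)
        ds = [decompose_delays(p) for p in c.pathways.values()]
        res = bivariate_screen(c, ds)
        rows = res[res.covariate == "gf_s"]
        assert rows.statistic.isna().all()

    def test_unknown_covariate_rejected(self, screened):
        c, ds, _ = screened
        with pytest.raises(ValueError, match="absent"):
            bivariate_screen(c, ds, covariate_spec={"shoe_size": "continuous"})


class TestMixedModel:
    def test_recovers_injected_negative_effect(self, small_cohort,
                                               small_table):
        res = fit_marginal_delay_mixed_model(small_table, "gaf_12")
        assert res.converged
        assert res.term_estimate("gaf_12").estimate < 0
        assert res.random_intercept_var > 0

    def test_adjusted_flavour_includes_all_covariates(self, small_table):
        res = fit_marginal_delay_mixed_model(small_table, flavour="adjusted")
        terms = res.fixed_effects.index
        assert any("gaf_12" in t for t in terms)
        assert any("sex" in t for t in terms)
        assert any("node_type" in t for t in terms)

    def test_single_encounter_per_participant_flags_singular(self):
        c = simulate_cohort(default_config(seed=8, n_participants=60))
        ds = [decompose_delays(p) for p in c.pathways.values()]
        ds = [dataclasses.replace(d, marginal_delays=d.marginal_delays[:1])
              for d in ds if d.marginal_delays]
        table = aggregate_decompositions(ds, c.covariates)
        res = fit_marginal_delay_mixed_model(table, "gaf_12")
        assert res.singular

    def test_raw_transform_available(self, small_table):
        res = fit_marginal_delay_mixed_model(small_table, "gaf_12",
                                             transform="raw")
        assert res.transform == "raw"
        assert len(res.fixed_effects)

    def test_bad_arguments_rejected(self, small_table):
        with pytest.raises(ValueError):
            fit_marginal_delay_mixed_model(small_table, "gaf_12",
                                           flavour="bayes")
        with pytest.raises(ValueError):
            fit_marginal_delay_mixed_model(small_table, None)
        with pytest.raises(ValueError, match="not joined"):
            fit_marginal_delay_mixed_model(
                small_table.drop(columns=["gaf_12"]), "gaf_12")

    def test_null_effect_rejection_rate_nominal(self):
        """Type-I error of the covariate Wald test under a null generator."""
        rejections = 0
        runs = 50
        for s in range(runs):
            cfg = default_config(seed=7000 + s, n_participants=60)
            cfg.covariate_effects = {}
            c = simulate_cohort(cfg)
            ds = [decompose_delays(p) for p in c.pathways.values()]
            table = aggregate_decompositions(ds, c.covariates)
            res = fit_marginal_delay_mixed_model(table, "gaf_12")
            p = res.term_estimate("gaf_12").p
            rejections += p < 0.05
        rate = rejections / runs
        band = 2.576 * math.sqrt(0.05 * 0.95 / runs)
        assert rate <= 0.05 + band
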