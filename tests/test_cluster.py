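"""Permutation-cluster along-tract statistics: null calibration against an
independent re-implementation, planted-cluster recovery, group t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spelltract.stats import (
    along_tract_analysis,
    fdr_across_family,
    group_profile_ttests,
)
from spelltract.synth import CohortConfig, TractEffectSpec, simulate_profiles, simulate_scores


def brute_force_max_runs(profiles, scores, alpha, n_perm, seed):
    """Independent oracle for the null max-run-length distribution: plain
    loops, scipy.spearmanr per node, explicit run counting."""
    rng = np.random.default_rng(seed)
    out = []
    n, n_nodes = profiles.shape
    for _ in range(n_perm):
        perm = rng.permutation(scores)
        best = run = 0
        for j in range(n_nodes):
            p = sps.spearmanr(profiles[:, j], perm).pvalue
            run = run + 1 if p < alpha else 0
            best = max(best, run)
        out.append(best)
    return np.array(out)


class TestAlongTract:
    def _cohort(self, n=32, seed=4):
        sc = simulate_scores(CohortConfig(seed=seed, n_participants=n))
        return sc

    def test_seed_reproducible(self):
        sc = self._cohort()
        prof = simulate_profiles(sc, TractEffectSpec("T", cluster_nodes=(30, 50), effect_r=0.5), seed=1)
        a = along_tract_analysis(prof, sc["score"], n_perm=500, seed=9)
        b = along_tract_analysis(prof, sc["score"], n_perm=500, seed=9)
        assert a.critical_length == b.critical_length
        assert np.allclose(a.node_rho, b.node_rho)
        assert [(c.start, c.end, c.fwe_p) for c in a.clusters] == [
            (c.start, c.end, c.fwe_p) for c in b.clusters
        ]

    def test_null_distribution_matches_brute_force_on_toy_profiles(self, rng):
        # 20-node toy profiles: the vectorized null must agree in
        # distribution with the loop-and-scipy re-implementation
        n = 16
        X = rng.normal(0.45, 0.04, size=(n, 20))
        s = rng.uniform(0, 1, n)
        res = along_tract_analysis(X, s, n_perm=400, seed=5)
        R = sps.rankdata(X, axis=0)
        Z = (R - R.mean(axis=0)) / R.std(axis=0)
        # recompute our null the same way the implementation does
        zs = sps.rankdata(s)
        zs = (zs - zs.mean()) / zs.std()
        g = np.random.default_rng(5)
        perms = np.stack([g.permutation(zs) for _ in range(400)], axis=1)
        rho_null = Z.T @ perms / n
        oracle = brute_force_max_runs(X, s, 0.05, 400, seed=11)
        ours_crit = res.critical_length
        oracle_crit = next(
            L for L in range(1, 22) if np.mean(oracle >= L) <= 0.05
        )
        # distributions agree within one node at the 95th percentile
        assert abs(ours_crit - oracle_crit) <= 1
        ks = sps.ks_2samp(oracle, np.asarray(
            [  # our null max runs, re-derived from the same pathway
                int(m) for m in _max_runs_from_pmatrix(rho_null, n, 0.05)
            ]
        ))
        assert ks.pvalue > 0.01

    def test_planted_cluster_recovered_with_sign_and_location(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            sc = simulate_scores(CohortConfig(seed=100 + seed, n_participants=32))
            spec = TractEffectSpec("T", cluster_nodes=(30, 50), effect_r=0.6)
            prof = simulate_profiles(sc, spec, seed=200 + seed)
            res = along_tract_analysis(prof, sc["score"], n_perm=1000, seed=seed)
            for c in res.clusters:
                if c.significant and c.rho > 0 and c.start >= 25 and c.end <= 55:
                    hits += 1
                    break
        assert hits >= 0.8 * n_seeds

    def test_negative_effect_gives_negative_cluster_rho(self):
        sc = self._cohort(seed=7)
        spec = TractEffectSpec("T", cluster_nodes=(40, 70), effect_r=-0.7)
        prof = simulate_profiles(sc, spec, seed=3)
        res = along_tract_analysis(prof, sc["score"], n_perm=1000, seed=1)
        sig = [c for c in res.clusters if c.significant]
        assert sig and all(c.rho < 0 for c in sig)

    def test_family_p_falls_back_to_tract_fa(self, rng):
        X = rng.normal(0.45, 0.04, size=(20, 100))
        s = rng.uniform(0, 1, 20)
        res = along_tract_analysis(X, s, n_perm=200, seed=2, tract="null", group="all")
        if res.cluster_fa_p is None:
            assert res.family_p == res.tract_fa_p
        fam = fdr_across_family([res])
        assert len(fam) == 1

    def test_missing_participants_dropped_pairwise(self, rng):
        X = rng.normal(0.45, 0.04, size=(25, 100))
        s = rng.uniform(0, 1, 25)
        X[3, :] = np.nan
        s[5] = np.nan
        res = along_tract_analysis(X, s, n_perm=200, seed=2)
        assert res.n == 23

    def test_refuses_tiny_permutation_count(self, rng):
        X = rng.normal(size=(20, 100))
        with pytest.raises(ValueError, match="n_perm"):
            along_tract_analysis(X, rng.uniform(size=20), n_perm=50)

    def test_refuses_tiny_samples(self, rng):
        X = rng.normal(size=(8, 100))
        with pytest.raises(ValueError, match="participants"):
            along_tract_analysis(X, rng.uniform(size=8), n_perm=200)


def _max_runs_from_pmatrix(rho_null, n, alpha):
    from spelltract.stats.cluster import _max_run_lengths, _p_from_rho

    below = _p_from_rho(rho_null, n) < alpha
    return _max_run_lengths(below)


class TestGroupProfiles:
    def test_identical_groups_t_zero(self, rng):
        X = rng.normal(0.45, 0.04, size=(12, 100))
        res = group_profile_ttests(X, X.copy(), n_perm=200, seed=1)
        assert np.allclose(res.node_t, 0.0)
        assert not any(c.significant for c in res.clusters)

    def test_planted_offset_detected(self, rng):
        a = rng.normal(0.45, 0.05, size=(30, 100))
        b = rng.normal(0.45, 0.05, size=(30, 100))
        b[:, 9:30] += 0.1
        res = group_profile_ttests(a, b, n_perm=500, seed=3)
        sig = [c for c in res.clusters if c.significant]
        assert sig
        assert any(c.start <= 15 and c.end >= 25 for c in sig)

    def test_null_rarely_significant(self):
        fp = 0
        for seed in range(12):
            g = np.random.default_rng(seed)
            a = g.normal(0.45, 0.05, size=(15, 100))
            b = g.normal(0.45, 0.05, size=(15, 100))
            res = group_profile_ttests(a, b, n_perm=300, seed=seed)
            fp += any(c.significant for c in res.clusters)
        assert fp <= 2

    def test_max_stat_variant(self, rng):
        a = rng.normal(0.45, 0.05, size=(30, 100))
        b = rng.normal(0.45, 0.05, size=(30, 100))
        b[:, 39:60] += 0.12
        res = group_profile_ttests(a, b, n_perm=300, seed=2, method="max-stat")
        assert res.method == "max-stat"
        assert any(c.start >= 35 and c.end <= 65 for c in res.clusters)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_profile_ttests(rng.normal(size=(3, 100)), rng.normal(size=(10, 100)))
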