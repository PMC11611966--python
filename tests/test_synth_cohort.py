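"""Cohort generator: mixture structure, responses, profiles, laterality."""

import numpy as np
import pandas as pd
import pytest

from spelltract.spelling import score_table, participant_summaries
from spelltract.synth import (
    CohortConfig,
    DEFAULT_LI_TARGETS,
    ErrorModel,
    MixtureSpec,
    TractEffectSpec,
    simulate_laterality,
    simulate_profiles,
    simulate_responses,
    simulate_scores,
)


class TestScores:
    def test_sample_mean_matches_analytic_mixture_mean(self):
        cfg = CohortConfig(
            seed=11,
            n_participants=1000,
            quantize=False,
            mixture=MixtureSpec(w1=0.56, mu1=0.22, var1=0.008, mu2=0.55, var2=0.041),
        )
        df = simulate_scores(cfg)
        m = cfg.mixture
        analytic = m.mean
        # mixture SD ~ 0.23 -> 3 SE at n=1000
        se = 0.23 / np.sqrt(1000)
        assert abs(df["score"].mean() - analytic) < 3 * se

    def test_same_seed_identical_tables(self):
        cfg = CohortConfig(seed=7, n_participants=50)
        pd.testing.assert_frame_equal(simulate_scores(cfg), simulate_scores(cfg))

    def test_quantization_to_items(self):
        df = simulate_scores(CohortConfig(seed=1, n_participants=200, n_items=40))
        assert np.allclose(df["score"] * 40, np.round(df["score"] * 40))

    def test_scores_within_unit_interval(self):
        df = simulate_scores(CohortConfig(seed=2, n_participants=500, quantize=False))
        assert df["score"].between(0, 1).all()

    def test_degenerate_mixture_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(w1=0.5, mu1=0.4, var1=0.01, mu2=0.4, var2=0.01)
        with pytest.raises(ValueError):
            MixtureSpec(w1=1.0)
        with pytest.raises(ValueError):
            MixtureSpec(var1=0.0)

    def test_covariate_loadings_have_planted_sign(self):
        cfg = CohortConfig(seed=3, n_participants=2000, quantize=False)
        df = simulate_scores(cfg)
        r_vocab = np.corrcoef(df["score"], df["vocabulary"])[0, 1]
        r_ran = np.corrcoef(df["score"], df["ran"])[0, 1]
        assert r_vocab > 0.4
        assert r_ran < 0

    def test_config_recorded_in_output(self):
        df = simulate_scores(CohortConfig(seed=9, n_participants=20))
        assert df.attrs["config"]["seed"] == 9


class TestResponses:
    def test_perfect_speller_all_correct(self, lexicon):
        scores = pd.DataFrame(
            {"participant_id": ["P1"], "score": [1.0], "component": [2]}
        )
        resp = simulate_responses(scores, lexicon, n_items=20, seed=1)
        scored = score_table(resp)
        assert scored["correct"].all()

    def test_realized_accuracy_equals_score(self, lexicon):
        scores = pd.DataFrame(
            {
                "participant_id": ["P1", "P2", "P3"],
                "score": [0.40, 0.75, 0.10],
                "component": [1, 2, 1],
            }
        )
        resp = simulate_responses(scores, lexicon, n_items=40, seed=5)
        acc = participant_summaries(score_table(resp)).set_index("participant_id")
        assert acc.loc["P1", "accuracy"] == pytest.approx(0.40)
        assert acc.loc["P2", "accuracy"] == pytest.approx(0.75)

    def test_errors_carry_both_distance_types(self, lexicon):
        scores = pd.DataFrame(
            {"participant_id": ["P1"], "score": [0.0], "component": [1]}
        )
        resp = simulate_responses(scores, lexicon, n_items=39, seed=3)
        scored = score_table(resp)
        errs = scored[~scored["correct"]]
        assert (errs["orth_dist"] > 0).all()
        # plausible errors exist (phon 0) and implausible ones too (phon > 0)
        assert (errs["phon_dist"] == 0).any()
        assert (errs["phon_dist"] > 0).any()

    def test_low_group_orthographically_heavier(self, lexicon):
        scores = pd.DataFrame(
            {
                "participant_id": [f"L{i}" for i in range(15)] + [f"H{i}" for i in range(15)],
                "score": [0.2] * 15 + [0.6] * 15,
                "component": [1] * 15 + [2] * 15,
            }
        )
        resp = simulate_responses(scores, lexicon, n_items=40, seed=8)
        scored = score_table(resp)
        errs = scored[~scored["correct"]].copy()
        errs["grp"] = errs["participant_id"].str[0]
        gap = errs.groupby("grp")[["orth_dist", "phon_dist"]].mean()
        orth_gap = gap.loc["L", "orth_dist"] - gap.loc["H", "orth_dist"]
        phon_gap = gap.loc["L", "phon_dist"] - gap.loc["H", "phon_dist"]
        assert orth_gap > phon_gap > 0

    def test_empty_lexicon_rejected(self):
        from spelltract.spelling import LexiconG2P

        scores = pd.DataFrame({"participant_id": ["P1"], "score": [0.5], "component": [1]})
        with pytest.raises(ValueError, match="empty lexicon"):
            simulate_responses(scores, LexiconG2P({}), seed=1)


class TestProfiles:
    def _scores(self, n=32, seed=4):
        return simulate_scores(CohortConfig(seed=seed, n_participants=n))

    def test_zero_noise_gives_perfect_in_cluster_correlation(self):
        sc = self._scores()
        spec = TractEffectSpec("T", noise_sd=0.0, cluster_nodes=(30, 50), effect_r=0.6)
        prof = simulate_profiles(sc, spec, seed=1)
        r = np.corrcoef(prof["node040"], sc["score"])[0, 1]
        assert r == pytest.approx(1.0)
        spec_neg = TractEffectSpec("T", noise_sd=0.0, cluster_nodes=(30, 50), effect_r=-0.6)
        prof = simulate_profiles(sc, spec_neg, seed=1)
        assert np.corrcoef(prof["node040"], sc["score"])[0, 1] == pytest.approx(-1.0)

    def test_null_effect_profiles_uncorrelated_on_average(self):
        sc = self._scores(n=200, seed=6)
        spec = TractEffectSpec("T")
        prof = simulate_profiles(sc, spec, seed=2)
        rs = [
            np.corrcoef(prof.iloc[:, j], sc["score"])[0, 1] for j in range(0, 100, 10)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_planted_correlation_magnitude(self):
        sc = self._scores(n=4000, seed=8)
        spec = TractEffectSpec("T", cluster_nodes=(40, 60), effect_r=0.6)
        prof = simulate_profiles(sc, spec, seed=3)
        r_in = np.corrcoef(prof["node050"], sc["score"])[0, 1]
        r_out = np.corrcoef(prof["node010"], sc["score"])[0, 1]
        assert r_in == pytest.approx(0.6, abs=0.05)
        assert abs(r_out) < 0.05

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TractEffectSpec("T", cluster_nodes=(0, 50))
        with pytest.raises(ValueError):
            TractEffectSpec("T", effect_r=1.0)
        with pytest.raises(ValueError):
            TractEffectSpec("T", baseline_profile=np.full(100, 1.5))

    def test_clipping_warns(self):
        sc = self._scores()
        spec = TractEffectSpec("T", noise_sd=0.4)
        with pytest.warns(UserWarning, match="clipping"):
            prof = simulate_profiles(sc, spec, seed=4)
        assert (prof.to_numpy() > 0).all() and (prof.to_numpy() < 1).all()


class TestLaterality:
    def test_defaults_reproduce_target_means(self):
        li = simulate_laterality([f"P{i}" for i in range(4000)], seed=2)
        for tract, (mu, sd) in DEFAULT_LI_TARGETS.items():
            # 4 SE: five simultaneous checks share one fixed seed
            assert li[tract].mean() == pytest.approx(mu, abs=4 * sd / np.sqrt(4000))
        assert li.to_numpy().min() >= -1 and li.to_numpy().max() <= 1

    def test_score_loading_induces_correlation(self, rng):
        scores = rng.uniform(0, 1, 500)
        li = simulate_laterality(
            [f"P{i}" for i in range(500)],
            seed=3,
            score_loading={"SLF-III": 0.4},
            scores=scores,
        )
        assert np.corrcoef(li["SLF-III"], scores)[0, 1] > 0.2
        assert abs(np.corrcoef(li["ILF"], scores)[0, 1]) < 0.15
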