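"""Config-driven orchestration of the full analysis.

Stages: behavioral scoring -> cognitive correlation matrix (FDR) ->
tract-FA stepwise selection -> Shapiro-Wilk + GMM bimodality split ->
group-wise along-tract permutation-cluster analyses (with the tracts x
groups FDR family) -> specificity regressions -> lateralization battery ->
error-type LME.  Every stage records its outputs into an AnalysisReport
(JSON-serializable) stamped with the config hash and seed; any stage
failure is recorded and the remaining stages continue where their inputs
allow.  On a synthetic run all inputs are generated by the cohort
generator under the config's seed, so a rerun with the same config is
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spelling import LexiconG2P, participant_summaries, score_table
from .stats import (
    along_tract_analysis,
    behavioral_correlation_matrix,
    compare_gmm_aic,
    error_type_lme,
    fdr_across_family,
    group_profile_ttests,
    li_tests,
    specificity_regression,
    split_groups,
    stepwise_regression,
    normality_test,
)
from .synth import (
    CohortConfig,
    ErrorModel,
    MixtureSpec,
    TractEffectSpec,
    simulate_laterality,
    simulate_profiles,
    simulate_responses,
    simulate_scores,
)

__all__ = ["PipelineConfig", "AnalysisReport", "run_full", "default_tract_effects"]

TRACTS = [
    f"{name}_{h}" for name in ("SLF-I", "SLF-II", "SLF-III", "Arcuate", "ILF") for h in ("L", "R")
]


def default_tract_effects() -> dict[str, dict]:
    """The planted association structure of a default synthetic cohort:

    a positive spelling-FA cluster in the ventral left ILF among high
    performers, and a negative cluster in the dorsal-stream right SLF-III
    among low performers; the remaining eight tracts carry no effect.
    """
    return {
        "ILF_L": {
            "cluster_nodes": (55, 79),
            "effect_r": 0.65,
            "group_restriction": "high",
            "full_sample_r": 0.35,
        },
        "SLF-III_R": {
            "cluster_nodes": (28, 52),
            "effect_r": -0.65,
            "group_restriction": "low",
            "full_sample_r": -0.35,
        },
    }


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_participants: int = 73
    n_items: int = 40
    alpha: float = 0.05
    q: float = 0.05
    n_perm: int = 2000
    p_enter: float = 0.05
    p_remove: float = 0.10
    mixture: dict = field(default_factory=dict)  # MixtureSpec overrides
    tract_effects: dict = field(default_factory=default_tract_effects)
    noise_sd: float = 0.04
    behavioral_table: str | None = None  # CSV path; generated if None
    profiles_table: str | None = None  # TSV path; generated if None
    li_table: str | None = None  # CSV path; generated if None
    out_dir: str | None = None

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_json(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


class AnalysisReport(dict):
    """Nested stage results; ``save`` writes canonical JSON."""

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(dict(self)), fh, indent=1)


def _simulate_inputs(config: PipelineConfig, rng: np.random.Generator):
    mixture = MixtureSpec(**config.mixture) if config.mixture else MixtureSpec()
    cohort_cfg = CohortConfig(
        seed=int(rng.integers(2**31 - 1)),
        n_participants=config.n_participants,
        n_items=config.n_items,
        mixture=mixture,
    )
    cohort = simulate_scores(cohort_cfg)
    lexicon = LexiconG2P.british_english_reference()
    responses = simulate_responses(
        cohort, lexicon, ErrorModel(), n_items=config.n_items,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth_groups = pd.Series(
        np.where(cohort["component"] == 1, "low", "high"), index=cohort.index
    )
    profiles: dict[str, pd.DataFrame] = {}
    for tract in TRACTS:
        eff = config.tract_effects.get(tract, {})
        spec = TractEffectSpec(
            tract_name=tract,
            noise_sd=config.noise_sd,
            cluster_nodes=tuple(eff["cluster_nodes"]) if eff.get("cluster_nodes") else None,
            effect_r=float(eff.get("effect_r", 0.0)),
            group_restriction=eff.get("group_restriction", "all"),
            full_sample_r=float(eff.get("full_sample_r", 0.0)),
        )
        profiles[tract] = simulate_profiles(
            cohort, spec, seed=int(rng.integers(2**31 - 1)), groups=truth_groups
        )
    li = simulate_laterality(
        cohort["participant_id"],
        seed=int(rng.integers(2**31 - 1)),
        score_loading={"SLF-III": 0.25},
        scores=cohort["score"],
    )
    return cohort, responses, profiles, li


def _load_profiles(path: str) -> dict[str, pd.DataFrame]:
    """Profiles TSV: participant_id, tract, node001..node100."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    node_cols = [c for c in df.columns if c.startswith("node")]
    for tract, grp in df.groupby("tract"):
        out[tract] = grp.set_index("participant_id")[node_cols]
    return out


def run_full(config: PipelineConfig, out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the full analysis chain and return the report."""
    rng = np.random.default_rng(config.seed)
    report = AnalysisReport(
        config=config.to_json(),
        config_hash=config.config_hash,
        seed=config.seed,
        stages={},
        warnings=[],
        errors={},
    )
    caught: list[str] = []

    def _stage(name):
        def deco(fn):
            try:
                with warnings.catch_warnings(record=True) as ws:
                    warnings.simplefilter("always")
                    out = fn()
                for w in ws:
                    caught.append(f"{name}: {w.message}")
                report["stages"][name] = out
                return out
            except Exception as exc:  # record and continue
                report["errors"][name] = f"{type(exc).__name__}: {exc}"
                return None
        return deco

    # ---- inputs ---------------------------------------------------------
    synthetic = config.behavioral_table is None
    if synthetic:
        cohort, responses, profiles, li = _simulate_inputs(config, rng)
        scored = score_table(responses)
    else:
        scored_in = pd.read_csv(config.behavioral_table)
        g2p = None
        if "target_ipa" not in scored_in.columns:
            try:
                g2p = LexiconG2P.british_english_reference()
            except Exception:
                g2p = None
        scored = score_table(scored_in, g2p=g2p)
        cohort = None
        profiles = _load_profiles(config.profiles_table) if config.profiles_table else {}
        li = pd.read_csv(config.li_table, index_col=0) if config.li_table else None

    # ---- stage: scoring -------------------------------------------------
    @_stage("scoring")
    def scoring():
        summaries = participant_summaries(scored)
        if scored["phon_dist"].isna().all():
            warnings.warn("no IPA available: phonological distances skipped")
        return {"participants": summaries, "n_records": len(scored)}

    summaries = report["stages"]["scoring"]["participants"]
    accuracy = summaries.set_index("participant_id")["accuracy"]
    if cohort is not None:
        cohort = cohort.set_index("participant_id")
        cohort["score"] = accuracy  # realized accuracy over items
        cohort = cohort.reset_index()
    else:
        cohort = summaries.rename(columns={"accuracy": "score"})

    # ---- stage: behavioral correlations ---------------------------------
    @_stage("behavioral_correlations")
    def behav():
        measures = [
            c for c in ("score", "vocabulary", "spoonerisms", "towre_swe",
                        "towre_pde", "nonword_rep", "ran")
            if c in cohort.columns
        ]
        if len(measures) < 2:
            warnings.warn("no covariates: correlation matrix skipped")
            return None
        rho, p, rej = behavioral_correlation_matrix(cohort, measures, q=config.q)
        return {"rho": rho, "p": p, "significant": rej}

    # ---- stage: stepwise tract selection --------------------------------
    tract_fa = pd.DataFrame(
        {t: profiles[t].mean(axis=1) for t in profiles}
    ) if profiles else pd.DataFrame()

    @_stage("stepwise_selection")
    def stepwise():
        if tract_fa.empty:
            warnings.warn("no profiles: tract selection skipped")
            return None
        merged = tract_fa.join(cohort.set_index("participant_id")["score"], how="inner").dropna()
        res = stepwise_regression(
            merged[tract_fa.columns], merged["score"].to_numpy(),
            p_enter=config.p_enter, p_remove=config.p_remove,
        )
        return {
            "selected": list(res.selected),
            "history": list(res.history),
            "report": res.report.summary() if res.report else None,
        }

    selected = (report["stages"].get("stepwise_selection") or {}).get("selected", [])

    # ---- stage: bimodality and split ------------------------------------
    @_stage("bimodality")
    def bimodality():
        s = cohort["score"].to_numpy(dtype=float)
        W, p_norm = normality_test(s)
        fit1, fit2 = compare_gmm_aic(s, seed=int(rng.integers(2**31 - 1)))
        criterion = fit2.local_min
        out = {
            "shapiro_w": W,
            "shapiro_p": p_norm,
            "aic_k1": fit1.aic,
            "aic_k2": fit2.aic,
            "prefers_two_components": fit2.aic < fit1.aic,
            "means_k2": fit2.means,
            "variances_k2": fit2.variances,
            "weights_k2": fit2.weights,
            "criterion": criterion,
        }
        if criterion is not None:
            labels, counts = split_groups(cohort, criterion)
            out["group_counts"] = counts
            cohort["group"] = labels.to_numpy()
        return out

    groups = cohort["group"] if "group" in cohort.columns else None

    # ---- stage: along-tract group analyses ------------------------------
    @_stage("along_tract")
    def along_tract():
        if not selected or groups is None:
            warnings.warn("no selected tracts or no group split: along-tract skipped")
            return None
        results = []
        indexed = cohort.set_index("participant_id")
        for tract in selected:
            prof = profiles[tract]
            for grp in ("high", "low"):
                members = indexed.index[indexed["group"] == grp]
                sub = prof.loc[prof.index.intersection(members)]
                sc = indexed.loc[sub.index, "score"].to_numpy(dtype=float)
                results.append(
                    along_tract_analysis(
                        sub, sc, alpha=config.alpha, n_perm=config.n_perm,
                        seed=int(rng.integers(2**31 - 1)), tract=tract, group=grp,
                    )
                )
        family = fdr_across_family(results, q=config.q)
        return {"results": results, "family_fdr": family}

    # ---- stage: specificity regressions ---------------------------------
    @_stage("specificity")
    def specificity():
        at = report["stages"].get("along_tract")
        if not at:
            return None
        indexed = cohort.set_index("participant_id")
        out = {}
        for res in at["results"]:
            sig = [c for c in res.clusters if c.significant]
            if not sig:
                continue
            best = max(sig, key=lambda c: c.length)
            members = indexed.index[indexed["group"] == res.group]
            prof = profiles[res.tract].loc[profiles[res.tract].index.intersection(members)]
            cfa = prof.iloc[:, best.start - 1 : best.end].mean(axis=1)
            sub = indexed.loc[cfa.index]
            if not {"vocabulary", "spoonerisms", "towre_swe"}.issubset(sub.columns):
                warnings.warn("covariates missing: specificity regression skipped")
                continue
            rep = specificity_regression(
                cfa.to_numpy(), sub["score"], sub["vocabulary"],
                sub["spoonerisms"], sub["towre_swe"],
            )
            out[f"{res.tract}|{res.group}"] = {
                "cluster": [best.start, best.end],
                "summary": rep.summary(),
                "r2": rep.r2,
                "f_stat": rep.f_stat,
            }
        return out

    # ---- stage: group profile comparison --------------------------------
    @_stage("group_profiles")
    def group_profiles():
        if not selected or groups is None:
            return None
        indexed = cohort.set_index("participant_id")
        out = {}
        for tract in selected:
            prof = profiles[tract]
            hi = prof.loc[prof.index.intersection(indexed.index[indexed["group"] == "high"])]
            lo = prof.loc[prof.index.intersection(indexed.index[indexed["group"] == "low"])]
            res = group_profile_ttests(
                hi, lo, alpha=config.alpha,
                n_perm=min(config.n_perm, 1000), seed=int(rng.integers(2**31 - 1)),
            )
            out[tract] = {
                "significant_clusters": [
                    [c.start, c.end] for c in res.clusters if c.significant
                ],
                "critical_length": res.critical_length,
            }
        return out

    # ---- stage: lateralization ------------------------------------------
    @_stage("lateralization")
    def lateralization():
        if li is None or li.empty:
            warnings.warn("no LI table: lateralization skipped")
            return None
        indexed = cohort.set_index("participant_id")
        common = li.index.intersection(indexed.index)
        rep = li_tests(
            li.loc[common],
            scores=indexed.loc[common, "score"].to_numpy(dtype=float),
            groups=indexed.loc[common, "group"].to_numpy() if "group" in indexed else None,
            alpha=config.alpha, q=config.q,
        )
        return {
            "one_sample": rep.one_sample,
            "score_correlation": rep.score_correlation,
            "group_comparison": rep.group_comparison,
            "bonferroni_alpha": rep.bonferroni_alpha,
        }

    # ---- stage: error-type LME ------------------------------------------
    @_stage("error_lme")
    def error_lme():
        if groups is None:
            return None
        if scored["phon_dist"].isna().all():
            warnings.warn("no phonological distances: error-type LME skipped")
            return None
        errs = scored[~scored["correct"]].copy()
        gmap = cohort.set_index("participant_id")["group"]
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "distance": errs[col].to_numpy(dtype=float),
                        "error_type": etype,
                        "subject": errs["participant_id"].to_numpy(),
                        "item": errs["item_id"].to_numpy(),
                    }
                )
                for col, etype in (("orth_dist", "orthographic"), ("phon_dist", "phonological"))
            ],
            ignore_index=True,
        )
        long["group"] = long["subject"].map(gmap)
        long = long.dropna(subset=["distance", "group"])
        res = error_type_lme(long)
        return {
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p,
            "n_excluded_subjects": res.n_excluded_subjects,
            "fixed_effects": res.fixed_effects,
            "simple_effects": res.simple_effects,
        }

    report["warnings"] = caught
    if out_dir or config.out_dir:
        out = Path(out_dir or config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "analysis_report.json")
        scored.to_csv(out / "scored_responses.csv", index=False)
        if profiles:
            frames = []
            for tract, prof in profiles.items():
                f = prof.reset_index()
                f.insert(1, "tract", tract)
                frames.append(f)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "tract_profiles.tsv", sep="\t", index=False
            )
    return report
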