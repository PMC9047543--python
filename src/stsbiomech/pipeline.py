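"""Seeded, logged orchestration of the full analysis.

``run_pipeline`` executes the stages in order — simulate cohort and
trials, inverse kinematics, inverse dynamics, L5S1 loads, feature
extraction, optimal-scaling PCA, permutation/bootstrap validation, cohort
statistics — serializing every intermediate as plain CSV/JSON and writing
a manifest with the config hash, the seeds, and a checksum per artifact,
so a rerun with the same config reproduces identical files.

``analyze_cohort`` runs the same computation in memory (no file I/O) and
is what the tests and the reproduction script call.

All numeric defaults are the study conditions: cohort sizes 26/43/42,
30 Hz sampling, 1.8 cm landmark noise, 5 Hz second-order Butterworth,
degree-2 splines with 3 quartile knots, 1,000 permutations, 300 balanced
bootstraps, |loading| >= 0.5 salience.  Every random stage has an explicit
seed; nothing falls back to wall-clock entropy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import body, features, kinematics, nlpca, spine, stats, synthetic, validation
from .errors import InvalidConfigError

log = logging.getLogger("stsbiomech")


@dataclass(frozen=True)
class Seeds:
    cohort: int = 10
    trials: int = 20
    permutation: int = 30
    bootstrap: int = 40


@dataclass(frozen=True)
class ValidationSettings:
    n_perm: int = 1000
    n_boot: int = 300
    alpha: float = 0.05
    loading_threshold: float = 0.5
    n_stability_components: int = 3


@dataclass(frozen=True)
class FilterSettings:
    cutoff: float = 5.0
    order: int = 2


@dataclass(frozen=True)
class RunConfig:
    seeds: Seeds = field(default_factory=Seeds)
    n_control: int = 26
    n_nslbp: int = 43
    n_sdlbp: int = 42
    strategies: dict[str, synthetic.StrategyParams] = field(
        default_factory=lambda: {g: synthetic.default_strategy_for_group(g)
                                 for g in synthetic.GROUPS})
    noise_sd: float = synthetic.DEFAULT_NOISE_SD
    strategy_jitter: float = 0.05
    strategy_variability: synthetic.StrategyVariability = field(
        default_factory=synthetic.StrategyVariability)
    sample_rate: float = synthetic.DEFAULT_SAMPLE_RATE
    filter: FilterSettings = field(default_factory=FilterSettings)
    ukf: kinematics.UKFConfig = field(default_factory=kinematics.UKFConfig)
    events: kinematics.EventConfig = field(default_factory=kinematics.EventConfig)
    spine_params: spine.SpineModelParams = field(default_factory=spine.SpineModelParams)
    nlpca: nlpca.NLPCAConfig = field(default_factory=lambda: nlpca.NLPCAConfig(n_components=7))
    validation: ValidationSettings = field(default_factory=ValidationSettings)


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    try:
        kwargs = {}
        nested = {"seeds": Seeds, "filter": FilterSettings, "ukf": kinematics.UKFConfig,
                  "events": kinematics.EventConfig, "spine_params": spine.SpineModelParams,
                  "nlpca": nlpca.NLPCAConfig, "validation": ValidationSettings,
                  "strategy_variability": synthetic.StrategyVariability}
        for key, val in raw.items():
            if key == "strategies":
                kwargs[key] = {g: synthetic.StrategyParams(**v) for g, v in val.items()}
            elif key in nested:
                kwargs[key] = nested[key](**val)
            else:
                kwargs[key] = val
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise InvalidConfigError(f"bad run config: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# In-memory analysis
# --------------------------------------------------------------------------

def process_trial(
    traj: synthetic.JointTrajectory,
    linkage: body.LinkageModel,
    profile: synthetic.SubjectProfile,
    config: RunConfig,
    dictionary: features.DataDictionary,
) -> np.ndarray:
    """Run one trial through IK, dynamics, spine loads, and summarization."""
    kin = kinematics.ukf_inverse_kinematics(traj, linkage, config.ukf)
    kin = kinematics.filter_and_differentiate(kin, cutoff=config.filter.cutoff,
                                              order=config.filter.order)
    kin = kinematics.segment_and_kinematics(kin, linkage)
    events = kinematics.detect_events(kin, linkage, config.events)
    dyn = dynamics_for_trial(kin, linkage, profile)
    loads = spine.l5s1_loads(dyn, kin, config.spine_params)
    loads = spine.normalize_spine_loads(loads, profile)
    return features.extract_trial_features(kin, dyn, loads, dictionary, events)


def dynamics_for_trial(kin, linkage, profile):
    from . import dynamics as dyn_mod
    dyn = dyn_mod.inverse_dynamics(kin, linkage)
    dyn = dyn_mod.joint_powers(dyn, kin)
    return dyn_mod.normalize_dynamics(dyn, profile)


def build_cohort_features(
    config: RunConfig,
    dictionary: features.DataDictionary | None = None,
    cohort: list[synthetic.SubjectProfile] | None = None,
) -> features.FeatureTable:
    """Simulate (or take) a cohort and produce the subjects x 118 table."""
    dictionary = dictionary or features.load_dictionary()
    if cohort is None:
        cohort = synthetic.generate_cohort(config.n_control, config.n_nslbp,
                                           config.n_sdlbp, seed=config.seeds.cohort)
    per_subject: dict[str, np.ndarray] = {}
    for idx, profile in enumerate(cohort):
        linkage = body.scale_segments(profile.sex, profile.height, profile.mass)
        subj_seed = int(np.random.SeedSequence(
            [config.seeds.trials, idx]).generate_state(1)[0] % (2**31))
        strategy = synthetic.sample_subject_strategy(
            config.strategies[profile.group], config.strategy_variability,
            rng=np.random.default_rng(np.random.SeedSequence([subj_seed, 7])))
        trials = synthetic.simulate_subject_trials(
            profile, linkage, strategy,
            noise_sd=config.noise_sd, jitter=config.strategy_jitter, seed=subj_seed)
        vecs = [process_trial(t, linkage, profile, config, dictionary) for t in trials]
        per_subject[profile.subject_id] = features.average_subject_features(vecs)
        if (idx + 1) % 25 == 0:
            log.info("processed %d/%d subjects", idx + 1, len(cohort))
    return features.build_feature_table(cohort, per_subject, dictionary,
                                        config_hash=config_hash(config))


@dataclass
class PipelineResult:
    cohort: list[synthetic.SubjectProfile]
    table: features.FeatureTable
    solution: nlpca.NLPCASolution
    retention: validation.RetentionReport | None
    stability: validation.StabilityReport | None
    n_selected: int | None
    score_anovas: dict[str, stats.AnovaResult]
    regressions: dict[str, stats.RegressionResult]


def analyze_cohort(config: RunConfig | None = None,
                   table: features.FeatureTable | None = None) -> PipelineResult:
    """Full in-memory analysis; ``table`` may inject precomputed features."""
    config = config or RunConfig()
    if table is None:
        table = build_cohort_features(config)
    cohort = [synthetic.SubjectProfile(
        subject_id=str(sid), group=str(r.group), sex=int(r.sex), age=float(r.age),
        height=float(r.height), mass=float(r.mass), bmi=float(r.bmi),
        vas=None if pd.isna(r.vas) else float(r.vas),
        odi=None if pd.isna(r.odi) else float(r.odi),
    ) for sid, r in table.data.iterrows()]

    solution = nlpca.fit_nlpca(table, config.nlpca)
    retention = stability = n_selected = None
    if config.validation.n_perm > 0:
        retention = validation.permutation_retention(
            table, config.nlpca, n_perm=config.validation.n_perm,
            alpha=config.validation.alpha, seed=config.seeds.permutation,
            solution=solution, loading_threshold=config.validation.loading_threshold)
        n_selected = validation.select_components(retention)
        stability = validation.bootstrap_stability(
            solution=solution, n_boot=config.validation.n_boot,
            n_components=config.validation.n_stability_components,
            seed=config.seeds.bootstrap)

    groups = table.data["group"].to_numpy()
    n_report = min(3, solution.n_components if n_selected is None
                   else max(n_selected, 1))
    score_anovas = {}
    for k in range(n_report):
        score_anovas[f"PC{k + 1}"] = stats.anova_tukey(solution.scores[:, k], groups)

    regressions = {}
    score_df = pd.DataFrame(
        solution.scores[:, :min(3, solution.n_components)],
        columns=[f"PC{k + 1}" for k in range(min(3, solution.n_components))],
        index=table.data.index)
    covars = table.data[["age", "bmi"]]
    for outcome in ("vas", "odi"):
        series = table.data[outcome]
        if series.notna().sum() >= score_df.shape[1] + 4:
            regressions[outcome] = stats.regress_outcomes(
                score_df, series, covars, outcome_name=outcome)

    return PipelineResult(cohort=cohort, table=table, solution=solution,
                         retention=retention, stability=stability,
                         n_selected=n_selected, score_anovas=score_anovas,
                         regressions=regressions)


# --------------------------------------------------------------------------
# File-backed run
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and persist every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    log.info("pipeline start: config=%s seeds=%s", chash, asdict(config.seeds))
    (out / "config.yaml").write_text(config_to_yaml(config))

    result = analyze_cohort(config)
    artifacts: dict[str, Path] = {}

    synthetic.write_cohort_csv(result.cohort, out / "cohort.csv")
    artifacts["cohort"] = out / "cohort.csv"
    features.write_feature_table(result.table, out / "features.csv",
                                 out / "channel_dictionary.json")
    artifacts["features"] = out / "features.csv"
    artifacts["dictionary"] = out / "channel_dictionary.json"
    nlpca.solution_to_json(result.solution, out / "nlpca_solution.json")
    nlpca.scores_to_csv(result.solution, out / "scores.csv", index=result.table.data.index)
    artifacts["nlpca"] = out / "nlpca_solution.json"
    artifacts["scores"] = out / "scores.csv"

    notes = []
    if result.retention is not None:
        (out / "retention.json").write_text(json.dumps({
            "observed_vaf": result.retention.observed_vaf.tolist(),
            "null_mean": result.retention.null_mean.tolist(),
            "null_upper": result.retention.null_upper.tolist(),
            "significant": result.retention.significant.tolist(),
            "kaiser_eigenvalues": result.retention.kaiser_eigenvalues.tolist(),
            "n_salient_loadings": result.retention.n_salient_loadings.tolist(),
            "n_permutations": result.retention.n_permutations,
            "n_selected": result.n_selected,
        }, indent=1))
        artifacts["retention"] = out / "retention.json"
        (out / "stability.json").write_text(json.dumps({
            "n_boot": result.stability.n_boot,
            "n_skipped": result.stability.n_skipped,
            "rms_difference": [asdict(c) for c in result.stability.rms_difference],
            "congruence": [asdict(c) for c in result.stability.congruence],
            "pearson": [asdict(c) for c in result.stability.pearson],
        }, indent=1))
        artifacts["stability"] = out / "stability.json"
    else:
        notes.append("validation stage skipped (n_perm=0)")

    stats_payload = {
        "score_anovas": {
            name: {"F": a.f_statistic, "df": [a.df_between, a.df_within],
                   "p": a.p_value, "group_means": a.group_means,
                   "tukey": [asdict(t) for t in a.tukey]}
            for name, a in result.score_anovas.items()},
        "regressions": {name: asdict(r) for name, r in result.regressions.items()},
    }
    (out / "statistics.json").write_text(json.dumps(stats_payload, indent=1))
    artifacts["statistics"] = out / "statistics.json"

    manifest = {
        "config_hash": chash,
        "seeds": asdict(config.seeds),
        "notes": notes,
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline done: %d artifacts in %s", len(artifacts), out)
    return out
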