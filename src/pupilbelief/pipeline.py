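"""Pipeline orchestration: configuration, reward mapping, end-to-end runs.

Ties the stages together into the two headline analyses:

* the Accuracy x Difficulty interaction pattern of pre- and post-feedback
  pupil responses (positive before, negative after feedback under the
  Belief State model), and
* model-pupil correlations comparing Belief State against Stimulus State
  predictions (four-condition cell means; equal-count evidence bins and
  single-trial variants on error trials).

A single global seed deterministically spawns per-stage substreams, and a
manifest records every stage's parameters for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import epochs as ep
from . import preprocess as pp
from . import sdt, stats, synthetic
from .io import write_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reward mapping


@dataclass
class RewardMapping:
    """Linear accuracy-to-Euros mapping, clamped at the chance floor.

    50% correct earns the floor (0 Euros), 100% the ceiling (10 Euros);
    rewards scale linearly in between and never go below the floor.
    """

    accuracy_floor: float = 50.0
    accuracy_ceiling: float = 100.0
    reward_floor: float = 0.0
    reward_ceiling: float = 10.0

    def __post_init__(self) -> None:
        if not self.accuracy_floor < self.accuracy_ceiling:
            raise ValueError("accuracy floor must be below ceiling")
        if not self.reward_floor < self.reward_ceiling:
            raise ValueError("reward mapping must be monotone increasing")


def compute_reward(block_accuracies, mapping: RewardMapping | None = None) -> float:
    """Session reward in Euros from per-block percent-correct values."""
    mapping = mapping or RewardMapping()
    acc = np.atleast_1d(np.asarray(block_accuracies, dtype=float))
    if np.any((acc < 0) | (acc > 100)):
        raise ValueError("accuracies must be percentages in [0, 100]")
    mean_acc = float(acc.mean())
    frac = (mean_acc - mapping.accuracy_floor) / (
        mapping.accuracy_ceiling - mapping.accuracy_floor
    )
    frac = min(max(frac, 0.0), 1.0)
    return mapping.reward_floor + frac * (mapping.reward_ceiling - mapping.reward_floor)


# ---------------------------------------------------------------------------
# configuration


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PreprocessConfig:
    pad_s: float = 0.1
    low_hz: float = 0.01
    high_hz: float = 6.0
    order: int = 3
    nuisance_window_s: float = 6.0
    nuisance_resolution_s: float = 0.25
    analysis_rate_hz: float = 50.0


@dataclass
class EpochConfig:
    span_s: tuple = (-1.0, 6.0)
    baseline_window_s: float = 0.5
    min_delay_s: float = 7.5
    sustained: tuple = (3.0, 6.0)
    pre_feedback: tuple = (-0.5, 0.0)


@dataclass
class StatsConfig:
    alpha_cluster: float = 0.05
    n_perm: int = 1000
    n_bins: int = 6
    min_trials_per_class: int = 10


@dataclass
class RunConfig:
    """Complete run configuration; every stage's parameters serialize round-trip."""

    design: synthetic.TaskDesign = field(default_factory=synthetic.TaskDesign)
    sdt: dict = field(default_factory=lambda: {"sigma": sdt.DEFAULT_SIGMA, "model": "belief"})
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.sdt) - {"sigma", "model", "c"}
        if unknown:
            raise ValueError(f"unknown keys in sdt config: {sorted(unknown)}")
        self.design = dataclasses.replace(self.design, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {"design", "sdt", "preprocess", "epochs", "stats", "seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        if "design" in data:
            d = dict(data["design"])
            for key in ("delay_levels_s", "iti_levels_s", "baseline_range_s"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = _from_dict(synthetic.TaskDesign, d)
        if "sdt" in data:
            kwargs["sdt"] = dict(data["sdt"])
        if "preprocess" in data:
            kwargs["preprocess"] = _from_dict(PreprocessConfig, data["preprocess"])
        if "epochs" in data:
            e = dict(data["epochs"])
            for key in ("span_s", "sustained", "pre_feedback"):
                if key in e:
                    e[key] = tuple(e[key])
            kwargs["epochs"] = _from_dict(EpochConfig, e)
        if "stats" in data:
            kwargs["stats"] = _from_dict(StatsConfig, data["stats"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "design": asdict(self.design),
            "sdt": dict(self.sdt),
            "preprocess": asdict(self.preprocess),
            "epochs": asdict(self.epochs),
            "stats": asdict(self.stats),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# stage runners


def simulate_stage(config: RunConfig):
    """Generate behavior and per-block pupil recordings."""
    return synthetic.generate_experiment(
        config.design,
        sigma=config.sdt.get("sigma", sdt.DEFAULT_SIGMA),
        model=config.sdt.get("model", "belief"),
    )


def preprocess_stage(recordings: dict, config: RunConfig) -> dict:
    """Clean every block recording to percent signal change at analysis rate."""
    pc = config.preprocess
    return {
        key: pp.preprocess_block(rec, **asdict(pc)) for key, rec in sorted(recordings.items())
    }


def epoch_stage(clean: dict, behavior: pd.DataFrame, config: RunConfig):
    """Choice- and feedback-locked epochs pooled across blocks."""
    ec = config.epochs
    parts_choice, parts_fb = [], []
    for (s, b), series in sorted(clean.items()):
        blk = behavior[(behavior["subject"] == s) & (behavior["block"] == b)]
        parts_choice.append(
            ep.extract_epochs(
                series, blk, "choice", span_s=ec.span_s, baseline_window_s=ec.baseline_window_s
            )
        )
        parts_fb.append(
            ep.extract_epochs(
                series, blk, "feedback", span_s=ec.span_s, baseline_window_s=ec.baseline_window_s
            )
        )
    return ep.Epochs.concat(parts_choice), ep.Epochs.concat(parts_fb)


def _scalar_table(epochs_obj: ep.Epochs, window: ep.WindowSpec) -> pd.DataFrame:
    vals = ep.window_mean(epochs_obj, window)
    cols = [
        c
        for c in (
            "subject",
            "block",
            "trial",
            "difficulty",
            "correct",
            "rt_s",
            "delay_feedback_s",
            "iti_s",
            "motion_energy",
            "coherence",
            "mu",
            "uncertainty",
            "prediction_error",
        )
        if c in epochs_obj.meta.columns
    ]
    out = epochs_obj.meta[cols].copy()
    out["value"] = vals
    return out


def _summaries_to_long(summaries: list) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for cell, mean in s.cell_means.items():
            diff, acc = cell.split("-")
            rows.append(
                {
                    "subject": s.subject_id,
                    "difficulty": diff.lower(),
                    "accuracy": acc.lower(),
                    "value": mean,
                }
            )
    return pd.DataFrame(rows)


def interaction_analysis(
    epochs_choice: ep.Epochs, epochs_feedback: ep.Epochs, config: RunConfig, seed: int
) -> dict:
    """The interaction-pattern analysis for both trial intervals.

    Pre-feedback: feedback-locked responses with a pre-stimulus baseline,
    averaged -0.5-0 s before feedback, long choice->feedback delays only.
    Post-feedback: feedback-locked responses with a pre-feedback baseline,
    averaged over the 3-6 s sustained window, long ITIs only.  Each scalar
    enters a 2x2 RM-ANOVA plus a sign-flip permutation test on the
    per-subject interaction; interaction time courses (choice-locked and
    feedback-locked) enter the cluster-based permutation test.
    """
    ec, sc = config.epochs, config.stats
    results = {}

    pre = ep.baseline_correct(epochs_feedback, "stimulus")
    pre = ep.filter_long_delays(pre, "delay_feedback_s", ec.min_delay_s)
    pre_scalars = _scalar_table(pre, ep.WindowSpec("pre_feedback", *ec.pre_feedback))

    post = ep.baseline_correct(epochs_feedback, "feedback")
    post = ep.filter_long_delays(post, "iti_s", ec.min_delay_s)
    post_scalars = _scalar_table(post, ep.WindowSpec("sustained", *ec.sustained))

    for name, scalars, sub_seed in (
        ("pre_feedback", pre_scalars, seed),
        ("post_feedback", post_scalars, seed + 1),
    ):
        summaries = ep.condition_average(scalars, "value")
        interactions = np.array([s.interaction for s in summaries])
        aov = stats.rm_anova_2x2(_summaries_to_long(summaries))
        perm = stats.permutation_test_paired(interactions, n_perm=sc.n_perm, seed=sub_seed)
        results[name] = {
            "n_subjects": len(summaries),
            "cell_means": {
                cell: float(np.mean([s.cell_means[cell] for s in summaries]))
                for cell in sdt.CELL_NAMES
            },
            "mean_interaction": float(interactions.mean()),
            "anova": asdict(aov),
            "interaction_p": perm.p_value,
        }

    # interaction time courses for the cluster test
    choice_tc = ep.baseline_correct(epochs_choice, "stimulus")
    choice_tc = ep.filter_long_delays(choice_tc, "delay_feedback_s", ec.min_delay_s)
    fb_tc = ep.baseline_correct(epochs_feedback, "feedback")
    fb_tc = ep.filter_long_delays(fb_tc, "iti_s", ec.min_delay_s)
    for name, tc_epochs, sub_seed in (
        ("choice_locked", choice_tc, seed + 2),
        ("feedback_locked", fb_tc, seed + 3),
    ):
        inter, subjects, times = ep.condition_time_courses(tc_epochs)
        cres = stats.cluster_permutation(
            inter, times, alpha_cluster=sc.alpha_cluster, n_perm=sc.n_perm, seed=sub_seed
        )
        results[f"clusters_{name}"] = [
            {"start_s": c.start_s, "end_s": c.end_s, "mass": c.mass, "p": c.p_value}
            for c in cres.clusters
        ]
    results["_scalars"] = {"pre_feedback": pre_scalars, "post_feedback": post_scalars}
    return results


def _model_predictions(trials: pd.DataFrame, sigma: float) -> pd.DataFrame:
    """Attach per-trial Belief/Stimulus model predictions from nominal evidence."""
    out = trials.copy()
    for model in sdt.MODELS:
        preds = sdt.predict_from_evidence(
            trials["mu"].to_numpy(), trials["correct"].to_numpy(), sigma=sigma, model=model
        )
        out[f"pred_uncertainty_{model}"] = preds["uncertainty"].to_numpy()
        out[f"pred_cpe_{model}"] = preds["complement_prediction_error"].to_numpy()
    return out


def correlation_analysis(
    interaction_results: dict, config: RunConfig, seed: int
) -> dict:
    """Model-pupil correlations, Belief State vs Stimulus State.

    Four-condition scheme on all retained trials; six-bin and single-trial
    schemes on error trials with predictions driven by the calibrated
    motion-energy evidence.  Pre-feedback pupil scalars pair with predicted
    uncertainty, post-feedback scalars with the predicted complement of the
    prediction error.
    """
    sc = config.stats
    sigma = config.sdt.get("sigma", sdt.DEFAULT_SIGMA)
    results: dict = {}
    for interval, pred_col in (
        ("pre_feedback", "pred_uncertainty"),
        ("post_feedback", "pred_cpe"),
    ):
        scalars = interaction_results["_scalars"][interval]
        trials = _model_predictions(scalars, sigma)
        interval_res: dict = {}
        # four-condition cell-mean correlation, all trials
        per_model = {}
        for model in sdt.MODELS:
            per_model[model] = stats.model_pupil_correlation(
                trials,
                f"{pred_col}_{model}",
                "value",
                scheme="four_condition",
                n_perm=sc.n_perm,
                seed=seed,
            )
        comp = stats.compare_model_correlations(
            per_model["belief"], per_model["stimulus"], n_perm=sc.n_perm, seed=seed + 1
        )
        interval_res["four_condition"] = {
            "belief_mean_r": per_model["belief"]["mean_r"],
            "stimulus_mean_r": per_model["stimulus"]["mean_r"],
            "belief_p": per_model["belief"]["group_p"],
            "stimulus_p": per_model["stimulus"]["group_p"],
            "belief_vs_stimulus_p": comp.p_value,
        }
        # motion-energy driven schemes, error trials only
        errors = trials[trials["correct"] == 0].copy()
        slope, intercept = sdt.calibrate_evidence(
            errors["motion_energy"].to_numpy(), errors["mu"].to_numpy()
        )
        ev_mu = sdt.apply_calibration(errors["motion_energy"].to_numpy(), slope, intercept)
        for model in sdt.MODELS:
            preds = sdt.predict_from_evidence(
                ev_mu, errors["correct"].to_numpy(), sigma=sigma, model=model
            )
            errors[f"me_{pred_col}_{model}"] = preds[
                "uncertainty" if pred_col == "pred_uncertainty" else "complement_prediction_error"
            ].to_numpy()
        for scheme in ("six_bin", "single_trial"):
            per_model = {}
            enough = errors.groupby("subject").size().min() >= max(sc.n_bins, 5)
            if not enough:
                logger.warning("too few error trials for scheme %s; skipped", scheme)
                continue
            for model in sdt.MODELS:
                per_model[model] = stats.model_pupil_correlation(
                    errors,
                    f"me_{pred_col}_{model}",
                    "value",
                    scheme=scheme,
                    n_bins=sc.n_bins,
                    n_perm=sc.n_perm,
                    seed=seed + 2,
                )
            comp = stats.compare_model_correlations(
                per_model["belief"], per_model["stimulus"], n_perm=sc.n_perm, seed=seed + 3
            )
            interval_res[scheme] = {
                "belief_mean_r": per_model["belief"]["mean_r"],
                "stimulus_mean_r": per_model["stimulus"]["mean_r"],
                "belief_p": per_model["belief"]["group_p"],
                "stimulus_p": per_model["stimulus"]["group_p"],
                "belief_vs_stimulus_p": comp.p_value,
            }
        results[interval] = interval_res
    return results


def run_all(config: RunConfig, outdir=None) -> dict:
    """Execute simulate -> preprocess -> epoch -> analyze; optionally write files.

    Returns a result bundle (nested dict) including reward totals, the
    interaction analysis, the model-correlation analysis and a manifest.
    Deterministic given the config seed.
    """
    behavior, recordings = simulate_stage(config)
    clean = preprocess_stage(recordings, config)
    epochs_choice, epochs_feedback = epoch_stage(clean, behavior, config)
    seed = config.seed + 10_000
    interaction = interaction_analysis(epochs_choice, epochs_feedback, config, seed)
    correlation = correlation_analysis(interaction, config, seed + 100)

    block_acc = (
        behavior.groupby(["subject", "block"])["correct"].mean().mul(100.0)
    )
    rewards = {
        int(s): compute_reward(acc.to_numpy())
        for s, acc in block_acc.groupby(level="subject")
    }

    scalars = interaction.pop("_scalars")
    results = {
        "config": config.to_dict(),
        "n_trials": int(len(behavior)),
        "rewards_eur": rewards,
        "interaction": interaction,
        "correlation": correlation,
    }
    results["manifest"] = _manifest(config, behavior)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(behavior, outdir / "behavior.tsv")
        for name, df in scalars.items():
            write_table(df, outdir / f"scalars_{name}.tsv")
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=_jsonable)
    results["_scalars"] = scalars
    return results


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _manifest(config: RunConfig, behavior: pd.DataFrame) -> dict:
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(behavior.drop(columns=["gen_model"]), index=False)
        .to_numpy()
        .tobytes()
    ).hexdigest()
    return {
        "seed": config.seed,
        "behavior_sha256": digest,
        "stages": ["simulate", "preprocess", "epoch", "analyze"],
        "config": config.to_dict(),
    }
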