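"""Synthetic experiment generator with known ground truth.

Emulates a two-alternative forced-choice random-dot motion task with delayed
reward feedback: 25-trial blocks, a Hard coherence (2/3 of trials, targeting
70% correct) and an Easy coherence (1/3 of trials, targeting 85% correct),
choice-to-feedback delays and inter-trial intervals uniform over five levels
from 3.5 to 11.5 s in 2-s steps.  Behavior (choice, accuracy, RT) follows the
signal-detection observer of :mod:`pupilbelief.sdt`; continuous pupil traces
are synthesized as a baseline plus IRF-convolved transients at cue, choice
and feedback, plus sustained boxcar components whose amplitudes encode the
generating model's decision uncertainty (choice -> feedback) and complement
of the reward prediction error (feedback -> trial end).  Blink dropouts are
inserted at a Poisson rate, so every downstream stage can be exercised
against known ground truth without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import sdt
from .preprocess import PupilRecording

DELAY_LEVELS_S = (3.5, 5.5, 7.5, 9.5, 11.5)


@dataclass
class TaskDesign:
    """Experiment design parameters (defaults follow the task layout above)."""

    n_subjects: int = 15
    blocks_per_subject: int = 24
    trials_per_block: int = 25
    hard_coherence: float = 0.0697  # ~70% correct at sigma = 0.133
    easy_coherence: float = 0.1378  # ~85% correct at sigma = 0.133
    p_hard: float = 2.0 / 3.0
    delay_levels_s: tuple = DELAY_LEVELS_S
    iti_levels_s: tuple = DELAY_LEVELS_S
    baseline_range_s: tuple = (0.5, 7.0)
    stimulus_duration_s: float = 0.75
    response_deadline_s: float = 2.25
    block_padding_s: float = 12.0
    sample_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_subjects < 1:
            errors.append("n_subjects must be >= 1")
        if self.blocks_per_subject < 1:
            errors.append("blocks_per_subject must be >= 1")
        if self.trials_per_block < 1:
            errors.append("trials_per_block must be >= 1")
        for name in ("hard_coherence", "easy_coherence"):
            v = getattr(self, name)
            if not 0 < v <= 0.5:
                errors.append(f"{name} must lie in (0, 0.5]")
        if not 0 < self.p_hard < 1:
            errors.append("p_hard must lie in (0, 1)")
        for name in ("delay_levels_s", "iti_levels_s"):
            lv = np.asarray(getattr(self, name), dtype=float)
            if lv.size < 1 or np.any(lv <= 0):
                errors.append(f"{name} must be positive")
            elif lv.size > 2 and not np.allclose(np.diff(lv), np.diff(lv)[0]):
                errors.append(f"{name} must be uniformly spaced")
        if self.sample_rate_hz <= 0:
            errors.append("sample_rate_hz must be positive")
        if errors:
            raise ValueError("invalid TaskDesign: " + "; ".join(errors))

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.blocks_per_subject * self.trials_per_block


@dataclass
class RTParams:
    """Generative reaction-time model: RT = base + slope * uncertainty + noise.

    RT scales with the generating model's decision uncertainty, reproducing
    the slower responses on Hard and on error trials.  Values are truncated
    to (rt_min_s, response deadline].
    """

    base_s: float = 0.9
    slope_s: float = 0.6
    noise_sd_s: float = 0.15
    rt_min_s: float = 0.15


@dataclass
class PupilGenParams:
    """Forward model of the continuous pupil signal (arbitrary units).

    The IRF kernel is the classic Erlang-type pupil response
    h(t) proportional to t^n * exp(-n*t/t_max) with shape n and peak time
    t_max.  Transients use a peak-normalized kernel (gain = peak amplitude);
    sustained boxcars are convolved with an area-normalized kernel (gain =
    plateau amplitude), scaled per trial by the generating model's
    uncertainty (pre-feedback) and 1 - prediction error (post-feedback).
    """

    irf_shape_n: float = 10.1
    irf_tmax_s: float = 0.93
    baseline_au: float = 1000.0
    transient_gains: dict = field(
        default_factory=lambda: {"cue": 5.0, "choice": 5.0, "feedback": 10.0}
    )
    sustained_gain_pre: float = 30.0
    sustained_gain_post: float = 15.0
    noise_sd: float = 5.0
    blink_rate_hz: float = 0.2
    blink_duration_s: float = 0.15
    blink_gain: float = -10.0

    def __post_init__(self) -> None:
        if self.irf_tmax_s <= 0 or self.irf_shape_n <= 0:
            raise ValueError("IRF shape and peak time must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for k, v in self.transient_gains.items():
            if not np.isfinite(v):
                raise ValueError(f"transient gain for '{k}' must be finite")
        if not np.isfinite(self.sustained_gain_pre) or not np.isfinite(self.sustained_gain_post):
            raise ValueError("sustained gains must be finite")


def irf_kernel(
    shape_n: float,
    tmax_s: float,
    rate_hz: float,
    duration_s: float = 6.0,
    normalize: str = "peak",
) -> np.ndarray:
    """Sampled pupil IRF h(t) ~ t^n * exp(-n*t/t_max), peak- or area-normalized."""
    t = np.arange(0, duration_s, 1.0 / rate_hz)
    with np.errstate(over="ignore"):
        h = (t / tmax_s) ** shape_n * np.exp(shape_n * (1.0 - t / tmax_s))
    if normalize == "peak":
        h = h / h.max()
    elif normalize == "area":
        h = h / (h.sum() / rate_hz)
    else:
        raise ValueError("normalize must be 'peak' or 'area'")
    return h


def generate_design(design: TaskDesign) -> pd.DataFrame:
    """Per-trial design table: coherences, identities, delays, baselines.

    Hard trials occur with probability ``p_hard`` (binomially), delays and
    ITIs are drawn uniformly over the five levels, stimulus identity is an
    equiprobable coin flip.  Reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    rows = []
    for s in range(design.n_subjects):
        for b in range(design.blocks_per_subject):
            n = design.trials_per_block
            hard = rng.random(n) < design.p_hard
            rows.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "block": b,
                        "trial": np.arange(n),
                        "difficulty": np.where(hard, "hard", "easy"),
                        "coherence": np.where(
                            hard, design.hard_coherence, design.easy_coherence
                        ),
                        "stimulus_identity": rng.choice([-1, 1], size=n),
                        "baseline_s": rng.uniform(*design.baseline_range_s, size=n),
                        "delay_feedback_s": rng.choice(design.delay_levels_s, size=n),
                        "iti_s": rng.choice(design.iti_levels_s, size=n),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_behavior(
    design_table: pd.DataFrame,
    design: TaskDesign,
    sigma: float = sdt.DEFAULT_SIGMA,
    rt_params: RTParams | None = None,
    model: str = "belief",
    motion_energy_jitter: float = 0.25,
) -> pd.DataFrame:
    """Simulate choices, RTs and ground-truth model variables per trial.

    ``model`` selects the generating model whose uncertainty / prediction
    error drive RT and (downstream) the sustained pupil components; both
    models' confidences are stored.  ``motion_energy`` is the signed nominal
    evidence plus Gaussian jitter (sd = ``motion_energy_jitter`` * coherence),
    standing in for a per-trial motion-energy readout of the dot stimulus.
    """
    if model not in sdt.MODELS:
        raise ValueError(f"model must be one of {sdt.MODELS}")
    rt_params = rt_params or RTParams()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    df = design_table.copy()
    mu = df["stimulus_identity"].to_numpy() * df["coherence"].to_numpy()
    dv = rng.normal(mu, sigma)
    choice = sdt.sign(dv)
    correct = (choice == sdt.sign(mu)).astype(int)
    conf_belief = sdt.prob_correct(np.abs(dv), sigma)
    conf_stim = sdt.prob_correct(np.abs(mu), sigma)
    conf_gen = conf_belief if model == "belief" else conf_stim
    unc_gen = 1.0 - conf_gen
    pe_gen = correct - conf_gen
    rt = rt_params.base_s + rt_params.slope_s * unc_gen + rng.normal(
        0, rt_params.noise_sd_s, size=len(df)
    )
    rt = np.clip(rt, rt_params.rt_min_s + 1e-3, design.response_deadline_s)
    me = mu + rng.normal(0, motion_energy_jitter * df["coherence"].to_numpy())
    df = df.assign(
        mu=mu,
        dv=dv,
        choice=choice,
        correct=correct,
        feedback=correct,
        rt_s=rt,
        motion_energy=me,
        confidence_belief=conf_belief,
        confidence_stimulus=conf_stim,
        gen_model=model,
        uncertainty=unc_gen,
        prediction_error=pe_gen,
    )
    return df


def _event_times(block_behavior: pd.DataFrame, design: TaskDesign) -> pd.DataFrame:
    """Lay the trial phases out on the block timeline; returns timing columns."""
    t = design.block_padding_s
    cue, choice, feedback, trial_end = [], [], [], []
    for row in block_behavior.itertuples():
        t_cue = t + row.baseline_s
        t_choice = t_cue + row.rt_s
        t_fb = t_choice + row.delay_feedback_s
        t_end = t_fb + row.iti_s
        cue.append(t_cue)
        choice.append(t_choice)
        feedback.append(t_fb)
        trial_end.append(t_end)
        t = t_end
    out = block_behavior.copy()
    out["t_cue"], out["t_choice"], out["t_feedback"], out["t_end"] = (
        cue,
        choice,
        feedback,
        trial_end,
    )
    return out


def synthesize_pupil(
    block_behavior: pd.DataFrame,
    design: TaskDesign,
    params: PupilGenParams | None = None,
    seed: int | None = None,
) -> tuple[PupilRecording, pd.DataFrame]:
    """Forward-model a continuous pupil trace for one block of trials.

    Returns the recording (baseline + transients + sustained components +
    noise + blink dropouts, arbitrary units) and the block behavior table
    augmented with event times (the stored ground truth).
    """
    params = params or PupilGenParams()
    if block_behavior.empty:
        raise ValueError("block behavior table is empty")
    if block_behavior[["subject", "block"]].drop_duplicates().shape[0] != 1:
        raise ValueError("synthesize_pupil expects exactly one (subject, block)")
    timed = _event_times(block_behavior, design)
    if not timed["t_cue"].is_monotonic_increasing:
        raise ValueError("overlapping trial boundaries in block layout")
    rate = design.sample_rate_hz
    n = int(round((timed["t_end"].iloc[-1] + design.block_padding_s) * rate))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [design.seed, 2, int(timed["subject"].iloc[0]), int(timed["block"].iloc[0])]
            if seed is None
            else [seed]
        )
    )

    impulses = np.zeros(n)
    sustained = np.zeros(n)
    events = []
    for row in timed.itertuples():
        for ev, t_ev in (("cue", row.t_cue), ("choice", row.t_choice), ("feedback", row.t_feedback)):
            i = int(round(t_ev * rate))
            if i < n:
                impulses[i] += params.transient_gains.get(ev, 0.0)
            events.append({"onset_s": t_ev, "duration_s": 0.0, "type": ev, "trial": row.trial})
        i0, i1 = int(round(row.t_choice * rate)), int(round(row.t_feedback * rate))
        sustained[i0:i1] += params.sustained_gain_pre * row.uncertainty
        i2 = int(round(row.t_end * rate))
        sustained[i1:i2] += params.sustained_gain_post * (1.0 - row.prediction_error)

    h_peak = irf_kernel(params.irf_shape_n, params.irf_tmax_s, rate, normalize="peak")
    h_area = irf_kernel(params.irf_shape_n, params.irf_tmax_s, rate, normalize="area")
    trace = np.convolve(impulses, h_peak)[:n]
    trace += np.convolve(sustained, h_area)[:n] / rate
    trace += params.baseline_au
    if params.noise_sd > 0:
        trace += rng.normal(0, params.noise_sd, size=n)

    # Blink dropouts: Poisson train; a short transient artifact precedes the
    # gap so nuisance deconvolution has something real to remove.
    n_blinks = rng.poisson(params.blink_rate_hz * n / rate)
    blink_onsets = np.sort(rng.uniform(1.0, n / rate - 7.0, size=n_blinks))
    # eyes can't blink mid-blink: enforce a refractory gap between onsets
    kept = []
    for t_b in blink_onsets:
        if not kept or t_b - kept[-1] > params.blink_duration_s + 0.05:
            kept.append(t_b)
    blink_onsets = np.asarray(kept)
    if params.blink_gain != 0 and n_blinks:
        blink_impulses = np.zeros(n)
        for t_b in blink_onsets:
            blink_impulses[int(round(t_b * rate))] += params.blink_gain
        trace += np.convolve(blink_impulses, h_peak)[:n]
    for t_b in blink_onsets:
        i0 = int(round(t_b * rate))
        i1 = min(i0 + int(round(params.blink_duration_s * rate)), n)
        trace[i0:i1] = 0.0  # tracker signal loss
        events.append(
            {"onset_s": t_b, "duration_s": params.blink_duration_s, "type": "blink", "trial": -1}
        )

    rec = PupilRecording(
        samples=trace,
        rate=rate,
        events=pd.DataFrame(events).sort_values("onset_s", ignore_index=True),
        block_id=(int(timed["subject"].iloc[0]), int(timed["block"].iloc[0])),
    )
    return rec, timed


def generate_irf_session(
    params: PupilGenParams | None = None,
    n_trials: int = 25,
    rate_hz: float = 1000.0,
    interval_range_s: tuple = (2.0, 6.0),
    seed: int = 0,
) -> PupilRecording:
    """Auditory-cue control session: transient responses only, overlapping.

    Cues occur at uniform random intervals of 2-6 s (25 per block, as in the
    IRF control task), which makes adjacent responses overlap — the condition
    deconvolution is meant to handle.
    """
    params = params or PupilGenParams()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    gaps = rng.uniform(*interval_range_s, size=n_trials)
    onsets = 5.0 + np.cumsum(gaps)
    n = int(round((onsets[-1] + 10.0) * rate_hz))
    impulses = np.zeros(n)
    for t_c in onsets:
        impulses[int(round(t_c * rate_hz))] += params.transient_gains["cue"]
    h = irf_kernel(params.irf_shape_n, params.irf_tmax_s, rate_hz, normalize="peak")
    trace = np.convolve(impulses, h)[:n] + params.baseline_au
    if params.noise_sd > 0:
        trace += rng.normal(0, params.noise_sd, size=n)
    events = pd.DataFrame(
        {"onset_s": onsets, "duration_s": 0.0, "type": "cue", "trial": np.arange(n_trials)}
    )
    return PupilRecording(samples=trace, rate=rate_hz, events=events, block_id="irf")


def generate_experiment(
    design: TaskDesign,
    sigma: float = sdt.DEFAULT_SIGMA,
    rt_params: RTParams | None = None,
    pupil_params: PupilGenParams | None = None,
    model: str = "belief",
):
    """Full synthetic experiment: behavior plus one recording per block.

    Returns ``(behavior, recordings)`` where ``behavior`` carries event times
    and ground-truth model variables and ``recordings`` maps
    ``(subject, block)`` to a :class:`PupilRecording`.
    """
    table = generate_design(design)
    behavior = simulate_behavior(table, design, sigma=sigma, rt_params=rt_params, model=model)
    recordings = {}
    timed_blocks = []
    for (s, b), blk in behavior.groupby(["subject", "block"], sort=True):
        rec, timed = synthesize_pupil(blk, design, params=pupil_params)
        recordings[(s, b)] = rec
        timed_blocks.append(timed)
    return pd.concat(timed_blocks, ignore_index=True), recordings


def accuracy_for_coherence(coherence: float, sigma: float = sdt.DEFAULT_SIGMA) -> float:
    """Expected accuracy of the unbiased observer at a given |mu|."""
    return float(ndtr(coherence / sigma))
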