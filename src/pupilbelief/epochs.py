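"""Event-locked epoch extraction, baseline correction and window summaries.

Clean percent-signal-change series are cut into choice-locked and
feedback-locked epochs (default span -1 to 6 s).  Baselines are the mean of
the 0.5 s preceding a reference event taken from the continuous series:
pre-stimulus (cue) baseline for choice-locked responses, pre-feedback
baseline for feedback-locked responses — the latter isolates the
feedback-evoked response from the level already reached while anticipating
it.  Scalar summaries use half-open windows: the sustained window 3-6 s
after the locking event and the -0.5-0 s window immediately before
feedback.  The long-delay trial filter keeps only trials whose relevant
delay (choice->feedback for pre-feedback analyses, the inter-trial interval
for post-feedback analyses) is at least 7.5 s, i.e. the three longest of
the five delay levels (3/5 of trials).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CleanPupilSeries
from .sdt import ConditionSummary

logger = logging.getLogger(__name__)

LOCK_EVENTS = ("choice", "feedback")

#: Event whose preceding 0.5 s serves as baseline, per reference name.
BASELINE_EVENT = {"stimulus": "cue", "feedback": "feedback"}


@dataclass
class WindowSpec:
    """Named half-open scalar window [start_s, end_s) on the epoch time axis."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"window '{self.name}': start must precede end")


SUSTAINED = WindowSpec("sustained", 3.0, 6.0)
PRE_FEEDBACK = WindowSpec("pre_feedback", -0.5, 0.0)


@dataclass
class Epochs:
    """Event-locked pupil segments with aligned trial metadata.

    ``data`` is (n_trials, n_times) percent signal change; ``meta`` carries
    one row per epoch (subject, block, trial, difficulty, accuracy, RT,
    delays, motion energy, and per-reference baseline values).
    """

    lock: str
    times: np.ndarray
    data: np.ndarray
    meta: pd.DataFrame
    baselined: bool = False
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.meta), self.times.size):
            raise ValueError("data shape must be (n_epochs, n_times)")
        if not (self.times[0] <= 0 <= self.times[-1]):
            raise ValueError("epoch time axis must include 0 (the locking event)")

    def __len__(self) -> int:
        return self.data.shape[0]

    @staticmethod
    def concat(parts: list) -> "Epochs":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.lock != first.lock or not np.allclose(p.times, first.times):
                raise ValueError("epochs must share lock event and time axis")
            if p.baselined != first.baselined:
                raise ValueError("cannot mix baselined and raw epochs")
        return Epochs(
            lock=first.lock,
            times=first.times,
            data=np.vstack([p.data for p in parts]),
            meta=pd.concat([p.meta for p in parts], ignore_index=True),
            baselined=first.baselined,
            n_skipped=sum(p.n_skipped for p in parts),
        )

    def select(self, mask) -> "Epochs":
        mask = np.asarray(mask, dtype=bool)
        return Epochs(
            lock=self.lock,
            times=self.times,
            data=self.data[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            baselined=self.baselined,
            n_skipped=self.n_skipped,
        )


def extract_epochs(
    series: CleanPupilSeries,
    behavior: pd.DataFrame,
    lock: str,
    span_s: tuple = (-1.0, 6.0),
    baseline_window_s: float = 0.5,
) -> Epochs:
    """Cut one epoch per trial around the locking event of a block series.

    ``behavior`` must be the timed block table (with ``t_cue``, ``t_choice``,
    ``t_feedback`` columns from the generator or event join).  Trials whose
    lock event is missing (e.g. no response) or whose span falls outside the
    recording are skipped and counted.  Baseline values (mean of the
    ``baseline_window_s`` preceding the cue and the feedback) are computed
    from the continuous series and stored in ``meta`` as ``baseline_stimulus``
    and ``baseline_feedback``.
    """
    if lock not in LOCK_EVENTS:
        raise ValueError(f"lock must be one of {LOCK_EVENTS}")
    t_lo, t_hi = span_s
    if not t_lo < 0 < t_hi:
        raise ValueError("span must bracket the locking event")
    rate = series.rate
    n = series.samples.size
    i_lo, i_hi = int(round(t_lo * rate)), int(round(t_hi * rate))
    times = np.arange(i_lo, i_hi + 1) / rate
    n_base = int(round(baseline_window_s * rate))
    lock_col = {"choice": "t_choice", "feedback": "t_feedback"}[lock]

    rows, segs, skipped = [], [], 0
    for row in behavior.itertuples():
        t_ev = getattr(row, lock_col)
        if not np.isfinite(t_ev):
            skipped += 1
            logger.info("trial %s lacks a %s event; skipped", row.trial, lock)
            continue
        i_ev = series.index_of(t_ev)
        if i_ev + i_lo < 0 or i_ev + i_hi >= n:
            skipped += 1
            logger.info("trial %s epoch outside recording span; dropped", row.trial)
            continue
        baselines = {}
        ok = True
        for ref, ev in BASELINE_EVENT.items():
            t_ref = getattr(row, f"t_{ev}")
            i_ref = series.index_of(t_ref)
            if not np.isfinite(t_ref) or i_ref - n_base < 0:
                ok = False
                break
            baselines[f"baseline_{ref}"] = float(series.samples[i_ref - n_base : i_ref].mean())
        if not ok:
            skipped += 1
            logger.info("trial %s lacks pre-event baseline samples; dropped", row.trial)
            continue
        segs.append(series.samples[i_ev + i_lo : i_ev + i_hi + 1])
        rows.append({**row._asdict(), **baselines})

    meta = pd.DataFrame(rows).drop(columns=["Index"], errors="ignore")
    data = np.vstack(segs) if segs else np.empty((0, times.size))
    return Epochs(lock=lock, times=times, data=data, meta=meta, n_skipped=skipped)


def baseline_correct(epochs: Epochs, reference: str = "stimulus") -> Epochs:
    """Subtract the per-trial baseline for the given reference event.

    ``reference='stimulus'`` uses the 0.5 s before motion-stimulus onset
    (choice-locked analyses); ``reference='feedback'`` uses the 0.5 s before
    feedback (feedback-evoked responses).  Idempotent: once corrected, the
    stored baselines are zeroed so a second application subtracts nothing.
    """
    if reference not in BASELINE_EVENT:
        raise ValueError(f"reference must be one of {tuple(BASELINE_EVENT)}")
    col = f"baseline_{reference}"
    if col not in epochs.meta.columns:
        raise ValueError(f"epochs lack stored baseline column '{col}'")
    base = epochs.meta[col].to_numpy()
    meta = epochs.meta.copy()
    for c in [c for c in meta.columns if c.startswith("baseline_")]:
        meta[c] = meta[c] - base
    return Epochs(
        lock=epochs.lock,
        times=epochs.times,
        data=epochs.data - base[:, None],
        meta=meta,
        baselined=True,
        n_skipped=epochs.n_skipped,
    )


def window_mean(epochs: Epochs, spec: WindowSpec) -> np.ndarray:
    """Per-epoch mean over the half-open window [start_s, end_s)."""
    mask = (epochs.times >= spec.start_s) & (epochs.times < spec.end_s)
    if not mask.any():
        raise ValueError(f"window '{spec.name}' selects no samples")
    return epochs.data[:, mask].mean(axis=1)


def filter_long_delays(obj, delay_field: str, min_delay_s: float = 7.5):
    """Keep trials whose relevant delay is at least ``min_delay_s``.

    ``delay_field`` is ``delay_feedback_s`` for pre-feedback analyses and
    ``iti_s`` for post-feedback analyses.  Works on an Epochs object or a
    plain trial DataFrame.
    """
    meta = obj.meta if isinstance(obj, Epochs) else obj
    mask = meta[delay_field].to_numpy() >= min_delay_s
    if not mask.any():
        warnings.warn(
            f"no trials with {delay_field} >= {min_delay_s}; result is empty",
            RuntimeWarning,
            stacklevel=2,
        )
    if isinstance(obj, Epochs):
        return obj.select(mask)
    return obj.loc[mask].reset_index(drop=True)


def condition_average(
    scalars: pd.DataFrame,
    value_col: str = "value",
    variable_name: str = "pupil_scalar",
) -> list:
    """Per-subject 2x2 Difficulty x Accuracy cell means and interactions.

    ``scalars`` needs columns ``subject``, ``difficulty`` (easy/hard),
    ``correct`` (0/1) and ``value_col``.  Subjects with an empty cell are
    excluded from the contrast with a log entry.  Returns a list of
    :class:`~pupilbelief.sdt.ConditionSummary`.
    """
    out = []
    for subj, df in scalars.groupby("subject", sort=True):
        means, ns = {}, {}
        complete = True
        for cell, (diff, corr) in {
            "Easy-Correct": ("easy", 1),
            "Easy-Error": ("easy", 0),
            "Hard-Correct": ("hard", 1),
            "Hard-Error": ("hard", 0),
        }.items():
            sel = df[(df["difficulty"] == diff) & (df["correct"] == corr)][value_col]
            if sel.empty:
                logger.warning("subject %s: empty cell %s; excluded from contrast", subj, cell)
                complete = False
                break
            means[cell] = float(sel.mean())
            ns[cell] = int(sel.size)
        if complete:
            out.append(
                ConditionSummary(
                    subject_id=subj, variable_name=variable_name, cell_means=means, cell_ns=ns
                )
            )
    return out


def condition_time_courses(epochs: Epochs) -> tuple[np.ndarray, list, np.ndarray]:
    """Per-subject interaction time courses from condition-mean epochs.

    Returns ``(interactions, subjects, times)`` where ``interactions`` is
    (n_subjects, n_times): (Easy Error - Easy Correct) - (Hard Error -
    Hard Correct) per subject.  Subjects missing a cell are dropped with a
    log entry.
    """
    inter, subjects = [], []
    for subj, idx in epochs.meta.groupby("subject", sort=True).groups.items():
        meta = epochs.meta.loc[idx]
        cells = {}
        for cell, (diff, corr) in {
            "Easy-Correct": ("easy", 1),
            "Easy-Error": ("easy", 0),
            "Hard-Correct": ("hard", 1),
            "Hard-Error": ("hard", 0),
        }.items():
            rows = meta[(meta["difficulty"] == diff) & (meta["correct"] == corr)].index
            if len(rows) == 0:
                break
            cells[cell] = epochs.data[epochs.meta.index.get_indexer(rows)].mean(axis=0)
        if len(cells) < 4:
            logger.warning("subject %s: incomplete 2x2 for time courses; dropped", subj)
            continue
        inter.append(
            (cells["Easy-Error"] - cells["Easy-Correct"])
            - (cells["Hard-Error"] - cells["Hard-Correct"])
        )
        subjects.append(subj)
    return np.array(inter), subjects, epochs.times
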