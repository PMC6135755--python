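"""Signal-detection models of confidence, uncertainty and reward prediction error.

Two observer models share a common front end: on each trial a decision
variable ``dv`` is drawn from N(mu, sigma), where ``mu`` is the signed
sensory evidence (stimulus direction times motion coherence, in proportion
coherence units) and ``sigma`` is the observer's internal noise.  The binary
choice is the sign of ``dv`` relative to the decision bound ``c`` (0 for an
unbiased observer).

The models differ only in the quantity entering the confidence transform

    f(x) = 0.5 * [1 + erf(x / (sigma * sqrt(2)))]

which maps a distance-from-bound onto the probability of a correct choice:

* Belief State model:    confidence = f(|dv - c|)  (internal, noisy)
* Stimulus State model:  confidence = f(|mu - c|)  (external, noise-free)

Decision uncertainty is ``1 - confidence``; the reward prediction error is
``feedback - confidence`` with binary feedback, and its complement
``1 - prediction_error`` is the predicted driver of post-feedback arousal.

The diagnostic contrast throughout is the Accuracy x Difficulty interaction
(Easy Error - Easy Correct) - (Hard Error - Hard Correct): positive for
uncertainty and negative for 1 - prediction error under the Belief State
model, and identically zero under the Stimulus State model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf, ndtr, ndtri
from scipy.stats import multivariate_normal
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Group-level internal noise (1 / probit slope of the pooled psychometric fit).
DEFAULT_SIGMA = 1.0 / 7.5

CELL_NAMES = ("Easy-Correct", "Easy-Error", "Hard-Correct", "Hard-Error")

MODELS = ("belief", "stimulus")
VARIABLES = ("uncertainty", "complement_prediction_error")


class FitError(RuntimeError):
    """Raised when a psychometric fit cannot be estimated."""


@dataclass
class SDTParams:
    """Parameters of a signal-detection simulation.

    sigma : internal noise (std of the dv distribution, coherence units)
    c : decision bound (coherence units); 0 means no choice bias
    mu_grid : signed evidence strengths in [-0.5, 0.5]
    n_per_mu : simulated trials per grid point
    seed : RNG seed for reproducibility
    """

    sigma: float = DEFAULT_SIGMA
    c: float = 0.0
    mu_grid: tuple = field(default_factory=lambda: tuple(np.round(np.arange(-0.5, 0.501, 0.01), 4)))
    n_per_mu: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite number, got {self.sigma}")
        if not np.isfinite(self.c):
            raise ValueError("decision bound c must be finite")
        grid = np.asarray(self.mu_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("mu_grid must not be empty")
        if np.any(np.abs(grid) > 0.5):
            raise ValueError("mu_grid values must lie in [-0.5, 0.5] (proportion coherence)")
        if self.n_per_mu < 1:
            raise ValueError("n_per_mu must be >= 1")


@dataclass
class PsychometricFit:
    """Probit psychometric fit: P(choice = +1) = Phi(beta * mu + bias)."""

    beta: float
    bias: float

    @property
    def sigma_hat(self) -> float:
        """Internal-noise estimate, the reciprocal of the probit slope."""
        return 1.0 / self.beta


@dataclass
class ConditionSummary:
    """Per-subject 2x2 (Difficulty x Accuracy) cell means plus the interaction.

    The interaction term is
    (Easy Error - Easy Correct) - (Hard Error - Hard Correct).
    """

    subject_id: object
    variable_name: str
    cell_means: dict
    cell_ns: dict

    @property
    def interaction(self) -> float:
        m = self.cell_means
        return (m["Easy-Error"] - m["Easy-Correct"]) - (m["Hard-Error"] - m["Hard-Correct"])


def sign(x):
    """Sign with the tie broken upward: sign(0) = +1 (deterministic choice rule)."""
    return np.where(np.asarray(x, dtype=float) >= 0, 1, -1)


def prob_correct(x, sigma):
    """Probability of a correct choice given distance ``x`` from the bound.

    f(x) = 0.5 * [1 + erf(x / (sigma * sqrt(2)))], i.e. the standard normal
    CDF evaluated at x / sigma.  Strictly increasing, in [0.5, 1) for x >= 0.
    """
    if sigma <= 0 or not np.isfinite(sigma):
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance x must be non-negative")
    return 0.5 * (1.0 + erf(x / (sigma * np.sqrt(2.0))))


def uncertainty(confidence):
    """Decision uncertainty: the complement of confidence."""
    confidence = np.asarray(confidence, dtype=float)
    if np.any((confidence < 0) | (confidence > 1)):
        raise ValueError("confidence must lie in [0, 1]")
    return 1.0 - confidence


def prediction_error(feedback, confidence):
    """Reward prediction error: feedback (0/1) minus confidence.

    The predicted post-feedback pupil quantity is its complement,
    ``1 - prediction_error``.
    """
    feedback = np.asarray(feedback)
    if not np.all(np.isin(feedback, (0, 1))):
        raise ValueError("feedback must be binary (0 or 1)")
    confidence = np.asarray(confidence, dtype=float)
    if np.any((confidence < 0) | (confidence > 1)):
        raise ValueError("confidence must lie in [0, 1]")
    return feedback.astype(float) - confidence


def simulate_trials(params: SDTParams) -> pd.DataFrame:
    """Simulate the signal-detection observer over the evidence grid.

    For each mu in ``params.mu_grid``, draws ``n_per_mu`` decision variables
    dv ~ N(mu, sigma).  Choice is the sign of dv - c; a choice is correct when
    it matches the sign of mu.  Both confidence variants are computed per
    trial; ``uncertainty`` and ``prediction_error`` columns refer to the
    Belief State model (the Stimulus State counterparts follow from
    ``confidence_stimulus``).

    Returns a tidy DataFrame with one row per simulated trial.
    """
    rng = np.random.default_rng(params.seed)
    grid = np.asarray(params.mu_grid, dtype=float)
    mu = np.repeat(grid, params.n_per_mu)
    dv = rng.normal(loc=mu, scale=params.sigma)
    choice = sign(dv - params.c)
    correct = (choice == sign(mu)).astype(int)
    feedback = correct  # feedback is veridical
    conf_belief = prob_correct(np.abs(dv - params.c), params.sigma)
    conf_stim = prob_correct(np.abs(mu - params.c), params.sigma)
    return pd.DataFrame(
        {
            "mu": mu,
            "dv": dv,
            "choice": choice,
            "correct": correct,
            "feedback": feedback,
            "confidence_belief": conf_belief,
            "confidence_stimulus": conf_stim,
            "uncertainty": 1.0 - conf_belief,
            "prediction_error": feedback - conf_belief,
        }
    )


def _variable_values(trials: pd.DataFrame, model: str, variable: str) -> np.ndarray:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}, got {variable!r}")
    conf = trials["confidence_belief" if model == "belief" else "confidence_stimulus"].to_numpy()
    if variable == "uncertainty":
        return 1.0 - conf
    pe = trials["feedback"].to_numpy() - conf
    return 1.0 - pe


def summarize_conditions(
    trials: pd.DataFrame,
    model: str = "belief",
    variable: str = "uncertainty",
    easy_mus: set | None = None,
    hard_mus: set | None = None,
    subject_id=None,
) -> ConditionSummary:
    """Average a model variable within the 2x2 Difficulty x Accuracy design.

    Coherence levels are collapsed across the sign of mu (up/down symmetric);
    ``easy_mus`` and ``hard_mus`` are sets of absolute evidence strengths.
    Raises if any cell is empty (Easy-Error is the rarest — simulate enough
    trials) or if a trial's |mu| belongs to neither or both difficulty sets.
    """
    easy = {round(abs(m), 6) for m in (easy_mus or set())}
    hard = {round(abs(m), 6) for m in (hard_mus or set())}
    if not easy or not hard:
        raise ValueError("easy_mus and hard_mus must both be non-empty")
    if easy & hard:
        raise ValueError(f"difficulty sets overlap: {sorted(easy & hard)}")
    abs_mu = np.round(np.abs(trials["mu"].to_numpy()), 6)
    observed = set(np.unique(abs_mu))
    unassigned = observed - easy - hard
    if unassigned:
        raise ValueError(f"|mu| levels not assigned to a difficulty: {sorted(unassigned)}")

    values = _variable_values(trials, model, variable)
    is_easy = np.isin(abs_mu, sorted(easy))
    correct = trials["correct"].to_numpy().astype(bool)
    cell_means, cell_ns = {}, {}
    for name, mask in (
        ("Easy-Correct", is_easy & correct),
        ("Easy-Error", is_easy & ~correct),
        ("Hard-Correct", ~is_easy & correct),
        ("Hard-Error", ~is_easy & ~correct),
    ):
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty design cell: {name}")
        cell_means[name] = float(values[mask].mean())
        cell_ns[name] = n
    return ConditionSummary(
        subject_id=subject_id,
        variable_name=variable,
        cell_means=cell_means,
        cell_ns=cell_ns,
    )


def fit_internal_noise(signed_mu, choice) -> PsychometricFit:
    """Estimate internal noise from choices via a probit psychometric fit.

    Fits P(choice = +1) = Phi(beta * mu + bias) by maximum likelihood with a
    free intercept; only the slope enters sigma_hat = 1 / beta.
    """
    mu = np.asarray(signed_mu, dtype=float)
    ch = np.asarray(choice)
    if mu.shape != ch.shape:
        raise ValueError("signed_mu and choice must have equal length")
    if not np.all(np.isin(ch, (-1, 1))):
        raise ValueError("choices must be coded +1 / -1")
    if np.unique(np.abs(mu[mu != 0])).size < 2:
        raise ValueError("need at least two distinct |mu| levels")
    y = (ch == 1).astype(float)
    if y.min() == y.max():
        raise FitError("all choices identical; probit slope is not identified")
    if mu[y == 1].min() > mu[y == 0].max() or mu[y == 1].max() < mu[y == 0].min():
        raise FitError("choices perfectly separable by mu; probit slope diverges")
    X = sm.add_constant(mu)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(y, X).fit(disp=False, maxiter=200)
        bias, beta = res.params
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise FitError(f"probit fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or abs(beta) > 1e4:
        raise FitError("probit fit diverged (data may be perfectly separable)")
    if beta <= 0:
        raise FitError(f"non-positive psychometric slope ({beta:.3g})")
    return PsychometricFit(beta=float(beta), bias=float(bias))


def _expected_confidence_given_accuracy(mu_abs: float, sigma: float, correct: bool) -> float:
    """E[f(|dv|)] for dv ~ N(mu_abs, sigma), conditioned on choice accuracy.

    Uses the identity E[Phi(dv/sigma); dv > 0] = P(dv > 0, dv - sigma*Z > 0)
    with Z an independent standard normal, i.e. a bivariate-normal orthant
    probability — deterministic, no re-simulation.
    """
    if mu_abs == 0:
        # Symmetric case: |dv| has the same distribution on both sides.
        mu_abs = 0.0
    var = sigma**2
    cov = np.array([[var, var], [var, 2 * var]])
    # P(dv > 0, dv - sigma Z > 0)
    orthant = float(
        multivariate_normal(mean=[-mu_abs, -mu_abs], cov=cov, allow_singular=True).cdf([0.0, 0.0])
    )
    p_pos = float(ndtr(mu_abs / sigma))
    e_phi = float(ndtr(mu_abs / (sigma * np.sqrt(2.0))))  # unconditional E[Phi(dv/sigma)]
    if correct:
        # correct (for mu >= 0): dv > 0, confidence = Phi(dv/sigma)
        if p_pos == 0:
            return 0.5
        return orthant / p_pos
    # error: dv < 0, confidence = Phi(-dv/sigma) = 1 - Phi(dv/sigma)
    p_neg = 1.0 - p_pos
    if p_neg == 0:
        return 0.5
    return 1.0 - (e_phi - orthant) / p_neg


def predict_from_evidence(
    evidence,
    accuracy,
    sigma: float = DEFAULT_SIGMA,
    model: str = "belief",
) -> pd.DataFrame:
    """Per-trial model predictions from single-trial sensory evidence.

    ``evidence`` is a signed motion-energy scalar already calibrated to mu
    units (see :func:`calibrate_evidence`); values outside [-0.5, 0.5] are
    clipped with a warning.  For the Belief State model the expected
    confidence is the analytic conditional mean over the dv distribution
    truncated to the correct (or error) region; for the Stimulus State model
    confidence follows from |evidence| directly and does not depend on the
    trial's accuracy.

    Returns a DataFrame with per-trial ``uncertainty`` (pre-feedback
    prediction) and ``complement_prediction_error`` (post-feedback
    prediction), conditioned on the observed accuracy.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    ev = np.asarray(evidence, dtype=float)
    acc = np.asarray(accuracy).astype(int)
    if ev.shape != acc.shape:
        raise ValueError("evidence and accuracy must have equal length")
    if not np.all(np.isin(acc, (0, 1))):
        raise ValueError("accuracy must be binary")
    n_out = int(np.sum(np.abs(ev) > 0.5))
    if n_out:
        warnings.warn(
            f"{n_out} evidence values outside the calibrated range [-0.5, 0.5]; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("clipped %d out-of-range evidence values", n_out)
        ev = np.clip(ev, -0.5, 0.5)
    mu_abs = np.abs(ev)
    if model == "stimulus":
        conf = prob_correct(mu_abs, sigma)
    else:
        conf = np.empty_like(mu_abs)
        cache: dict = {}
        for i, (m, a) in enumerate(zip(np.round(mu_abs, 10), acc)):
            key = (m, a)
            if key not in cache:
                cache[key] = _expected_confidence_given_accuracy(m, sigma, bool(a))
            conf[i] = cache[key]
    pe = acc - conf
    return pd.DataFrame(
        {
            "evidence_mu": ev,
            "correct": acc,
            "confidence": conf,
            "uncertainty": 1.0 - conf,
            "complement_prediction_error": 1.0 - pe,
        }
    )


def calibrate_evidence(motion_energy, nominal_mu):
    """Affine map from motion-energy units to mu units.

    Regresses |nominal mu| on |motion energy| (least squares, within
    subject); returns (slope, intercept) such that
    ``mu_units = slope * motion_energy + sign(motion_energy) * intercept``
    preserves the sign of the evidence.
    """
    me = np.abs(np.asarray(motion_energy, dtype=float))
    mu = np.abs(np.asarray(nominal_mu, dtype=float))
    if me.size != mu.size or me.size < 2:
        raise ValueError("need >= 2 paired samples for calibration")
    A = np.column_stack([me, np.ones_like(me)])
    (slope, intercept), *_ = np.linalg.lstsq(A, mu, rcond=None)
    return float(slope), float(intercept)


def apply_calibration(motion_energy, slope: float, intercept: float):
    """Apply an affine evidence calibration, preserving sign."""
    me = np.asarray(motion_energy, dtype=float)
    return np.sign(me) * (slope * np.abs(me) + intercept)


def coherence_for_accuracy(accuracy: float, sigma: float = DEFAULT_SIGMA) -> float:
    """Evidence strength |mu| at which the unbiased observer attains ``accuracy``."""
    if not 0.5 <= accuracy < 1:
        raise ValueError("accuracy must lie in [0.5, 1)")
    return float(ndtri(accuracy) * sigma)
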