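"""Group-level inference for condition contrasts and time courses.

Implements the study's inferential toolkit: a 2x2 repeated-measures ANOVA
(Difficulty x Accuracy) on scalar window summaries, cluster-based sign-flip
permutation tests on per-subject contrast time courses (family-wise error
controlled by maximum cluster mass), non-parametric paired permutation
tests for post-hocs, within-subject RT residualization of pupil scalars,
per-subject regressions of pupil on evidence strength split by accuracy
(interaction = beta_error - beta_correct), and model-pupil correlation
schemes (four-condition cell means, equal-count evidence bins, and
single-trial), compared between the Belief State and Stimulus State models
via Fisher-z permutation tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    """Clusters of contiguous supra-threshold time points with permutation p."""

    clusters: list
    threshold: float
    n_permutations: int
    seed: int | None
    t_obs: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value < alpha]


@dataclass
class AnovaResult:
    """2x2 repeated-measures ANOVA F statistics (df = 1, n_subjects - 1)."""

    F_difficulty: float
    F_accuracy: float
    F_interaction: float
    p_difficulty: float
    p_accuracy: float
    p_interaction: float
    df1: int
    df2: int


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool


@dataclass
class RegressionInteraction:
    """Per-subject evidence-strength slopes split by accuracy."""

    subjects: list
    beta_error: np.ndarray
    beta_correct: np.ndarray
    group_p: float

    @property
    def interaction(self) -> np.ndarray:
        return self.beta_error - self.beta_correct

    @property
    def group_mean(self) -> float:
        return float(self.interaction.mean())

    @property
    def group_sd(self) -> float:
        return float(self.interaction.std(ddof=1))


# ---------------------------------------------------------------------------
# cluster-based permutation test


def _find_clusters(t: np.ndarray, threshold: float) -> list:
    """Runs of same-sign supra-threshold samples; returns (start, stop) slices."""
    supra = np.abs(t) > threshold
    clusters = []
    i = 0
    n = t.size
    while i < n:
        if supra[i]:
            j = i
            s = np.sign(t[i])
            while j + 1 < n and supra[j + 1] and np.sign(t[j + 1]) == s:
                j += 1
            clusters.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return clusters


def _paired_t(data: np.ndarray) -> np.ndarray:
    """One-sample t across subjects (rows) at each time point (columns)."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def cluster_permutation(
    contrasts: np.ndarray,
    times: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of per-subject contrasts vs 0.

    A paired t statistic is computed at each time point; contiguous
    same-sign samples exceeding the two-tailed ``alpha_cluster`` t threshold
    form clusters scored by summed t (cluster mass).  The null distribution
    of the maximum |mass| is built by randomly sign-flipping whole-subject
    contrast time courses; each cluster's p is the add-one-corrected
    fraction of null maxima at least as large as its |mass|.
    """
    contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))
    n_subj, n_times = contrasts.shape
    if n_subj < 5:
        raise ValueError("need at least 5 subjects for the cluster permutation test")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    times = np.asarray(times, dtype=float)
    if times.size != n_times:
        raise ValueError("times length must match the contrast time axis")
    threshold = float(sps.t.ppf(1.0 - alpha_cluster / 2.0, n_subj - 1))

    t_obs = _paired_t(contrasts)
    obs_clusters = _find_clusters(t_obs, threshold)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        t_null = _paired_t(signs[p][:, None] * contrasts)
        masses = [abs(t_null[a:b].sum()) for a, b in _find_clusters(t_null, threshold)]
        null_max[p] = max(masses) if masses else 0.0

    clusters = []
    dt = times[1] - times[0] if n_times > 1 else 0.0
    for a, b in obs_clusters:
        mass = float(t_obs[a:b].sum())
        p_val = float((1 + np.sum(null_max >= abs(mass))) / (n_perm + 1))
        clusters.append(
            Cluster(start_s=float(times[a]), end_s=float(times[b - 1] + dt), mass=mass, p_value=p_val)
        )
    return ClusterResult(
        clusters=clusters, threshold=threshold, n_permutations=n_perm, seed=seed, t_obs=t_obs
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_2x2(cell_means: pd.DataFrame) -> AnovaResult:
    """Two-way repeated-measures ANOVA with factors difficulty and accuracy.

    ``cell_means`` is long format with columns ``subject``, ``difficulty``
    (easy/hard), ``accuracy`` (correct/error) and ``value`` — one cell mean
    per subject per condition.  With two-level factors each effect has
    df = (1, n-1) and the interaction F equals the squared paired t of the
    per-subject interaction contrast.
    """
    required = {"subject", "difficulty", "accuracy", "value"}
    if not required.issubset(cell_means.columns):
        raise ValueError(f"cell_means must have columns {sorted(required)}")
    counts = cell_means.groupby("subject").size()
    bad = counts[counts != 4]
    if len(bad):
        raise ValueError(f"incomplete 2x2 cells for subjects: {list(bad.index)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=cell_means,
            dv="value",
            within=["difficulty", "accuracy"],
            subject="subject",
            detailed=True,
        )
    aov = aov.set_index("Source")
    inter = [s for s in aov.index if "*" in s][0]
    n = cell_means["subject"].nunique()
    return AnovaResult(
        F_difficulty=float(aov.loc["difficulty", "F"]),
        F_accuracy=float(aov.loc["accuracy", "F"]),
        F_interaction=float(aov.loc[inter, "F"]),
        p_difficulty=float(aov.loc["difficulty", "p_unc"]),
        p_accuracy=float(aov.loc["accuracy", "p_unc"]),
        p_interaction=float(aov.loc[inter, "p_unc"]),
        df1=1,
        df2=n - 1,
    )


# ---------------------------------------------------------------------------
# paired permutation test


def permutation_test_paired(
    x,
    y=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-tailed sign-flip permutation test on paired differences.

    Tests the mean of ``x - y`` (or of ``x`` against 0 when ``y`` is None).
    When all ``2**n`` sign assignments fit within ``n_perm`` the null is
    enumerated exhaustively (exact p); otherwise random sign flips with the
    add-one correction are used.
    """
    x = np.asarray(x, dtype=float)
    d = x - (np.zeros_like(x) if y is None else np.asarray(y, dtype=float))
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    obs = d.mean()
    if np.allclose(d, 0):
        warnings.warn("zero-variance differences; p = 1", RuntimeWarning, stacklevel=2)
        return PermutationResult(statistic=float(obs), p_value=1.0, n_permutations=0, exact=True)
    tol = 1e-12 * max(1.0, abs(obs))
    if 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n) & 1  # all sign patterns
        signs = 2.0 * bits - 1.0
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(obs) - tol))
        return PermutationResult(
            statistic=float(obs), p_value=p, n_permutations=2**n, exact=True
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = signs @ d / n
    p = float((1 + np.sum(np.abs(null) >= abs(obs) - tol)) / (n_perm + 1))
    return PermutationResult(statistic=float(obs), p_value=p, n_permutations=n_perm, exact=False)


# ---------------------------------------------------------------------------
# RT residualization and evidence regressions


def residualize_rt(values: np.ndarray, rt: np.ndarray) -> np.ndarray:
    """Remove the linear influence of RT from pupil values, within subject.

    ``values`` is (n_trials,) or (n_trials, n_times).  The least-squares fit
    on RT is subtracted and the mean re-added so units stay interpretable.
    Constant RT leaves the input unchanged (with a warning).
    """
    v = np.asarray(values, dtype=float)
    rt = np.asarray(rt, dtype=float)
    one_d = v.ndim == 1
    V = v[:, None] if one_d else v
    if rt.size != V.shape[0]:
        raise ValueError("rt must have one entry per trial")
    if np.ptp(rt) == 0:
        warnings.warn("constant RT; residualization is the identity", RuntimeWarning, stacklevel=2)
        return v.copy()
    X = np.column_stack([np.ones_like(rt), rt])
    beta, *_ = np.linalg.lstsq(X, V, rcond=None)
    resid = V - X @ beta + V.mean(axis=0, keepdims=True)
    return resid[:, 0] if one_d else resid


def regress_on_evidence(
    trials: pd.DataFrame,
    value_col: str = "value",
    evidence_col: str = "abs_evidence",
    min_trials: int = 10,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> RegressionInteraction:
    """Per-subject pupil ~ evidence-strength slopes, split by accuracy.

    ``trials`` needs columns ``subject``, ``correct`` (0/1), ``evidence_col``
    (absolute evidence) and ``value_col`` (RT-corrected pupil scalar).  The
    interaction is beta_error - beta_correct per subject; its group mean is
    tested against 0 with a sign-flip permutation test.  Subjects with fewer
    than ``min_trials`` in either accuracy class are excluded and logged.
    """
    subjects, b_err, b_cor = [], [], []
    for subj, df in trials.groupby("subject", sort=True):
        err = df[df["correct"] == 0]
        cor = df[df["correct"] == 1]
        if len(err) < min_trials or len(cor) < min_trials:
            logger.warning(
                "subject %s excluded from evidence regression: %d error / %d correct trials",
                subj,
                len(err),
                len(cor),
            )
            continue
        slopes = []
        for part in (err, cor):
            x = part[evidence_col].to_numpy()
            y = part[value_col].to_numpy()
            slopes.append(np.polyfit(x, y, 1)[0])
        subjects.append(subj)
        b_err.append(slopes[0])
        b_cor.append(slopes[1])
    b_err, b_cor = np.asarray(b_err), np.asarray(b_cor)
    if len(subjects) < 5:
        raise ValueError("fewer than 5 subjects retained for the evidence regression")
    group = permutation_test_paired(b_err, b_cor, n_perm=n_perm, seed=seed)
    return RegressionInteraction(
        subjects=subjects, beta_error=b_err, beta_correct=b_cor, group_p=group.p_value
    )


# ---------------------------------------------------------------------------
# model-pupil correlation


def equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign trials to equal-count bins by rank; counts differ by <= 1.

    Ties are broken by stable trial order (stable argsort).
    """
    values = np.asarray(values)
    if values.size < n_bins:
        raise ValueError(f"fewer trials ({values.size}) than bins ({n_bins})")
    order = np.argsort(values, kind="stable")
    bins = np.empty(values.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def model_pupil_correlation(
    trials: pd.DataFrame,
    model_col: str,
    pupil_col: str,
    scheme: str = "four_condition",
    n_bins: int = 6,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Per-subject Pearson correlation between model predictions and pupil.

    Schemes: ``four_condition`` correlates the 2x2 Difficulty x Accuracy
    cell means (requires ``difficulty`` and ``correct`` columns);
    ``six_bin`` bins trials within subject into ``n_bins`` equal-count bins
    of the model prediction and correlates bin means; ``single_trial``
    correlates trial-wise values.  Returns per-subject r, the group
    permutation test of Fisher-z(r) against 0, plus the z values for model
    comparisons.
    """
    rs, subjects = [], []
    for subj, df in trials.groupby("subject", sort=True):
        if scheme == "four_condition":
            cells = df.groupby(["difficulty", "correct"])[[model_col, pupil_col]].mean()
            if len(cells) < 4:
                logger.warning("subject %s: incomplete 2x2; skipped in correlation", subj)
                continue
            r = _pearson(cells[model_col].to_numpy(), cells[pupil_col].to_numpy())
        elif scheme == "six_bin":
            bins = equal_count_bins(df[model_col].to_numpy(), n_bins)
            g = df.assign(_bin=bins).groupby("_bin")[[model_col, pupil_col]].mean()
            r = _pearson(g[model_col].to_numpy(), g[pupil_col].to_numpy())
        elif scheme == "single_trial":
            r = _pearson(df[model_col].to_numpy(), df[pupil_col].to_numpy())
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        rs.append(r)
        subjects.append(subj)
    rs = np.asarray(rs)
    z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
    group = permutation_test_paired(z, n_perm=n_perm, seed=seed)
    return {
        "subjects": subjects,
        "r": rs,
        "mean_r": float(rs.mean()),
        "fisher_z": z,
        "group_p": group.p_value,
        "scheme": scheme,
    }


def compare_model_correlations(
    result_a: dict, result_b: dict, n_perm: int = 10_000, seed: int | None = None
) -> PermutationResult:
    """Paired permutation test of Fisher-z correlations, model A vs model B."""
    if result_a["subjects"] != result_b["subjects"]:
        raise ValueError("correlation results must cover the same subjects")
    return permutation_test_paired(
        result_a["fisher_z"], result_b["fisher_z"], n_perm=n_perm, seed=seed
    )
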