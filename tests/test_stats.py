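"""Inference layer: cluster permutation, RM-ANOVA, permutation tests, regressions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupilbelief import stats


class TestClusterPermutation:
    def test_all_zero_contrasts_no_clusters(self):
        res = stats.cluster_permutation(np.zeros((8, 50)), np.arange(50) / 50, n_perm=200, seed=0)
        assert res.clusters == []

    def test_constant_offset_single_spanning_cluster_at_floor(self):
        rng = np.random.default_rng(1)
        data = 10.0 + 0.01 * rng.normal(size=(10, 60))
        res = stats.cluster_permutation(data, np.arange(60) / 50, n_perm=500, seed=2)
        sig = res.significant()
        assert len(sig) == 1
        assert sig[0].start_s == 0.0
        assert sig[0].end_s == pytest.approx(60 / 50)
        assert sig[0].p_value == pytest.approx(1 / 501)

    def test_agrees_with_mne_reference(self):
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (12, 80))
        data[:, 30:50] += 1.2
        times = np.arange(80) / 50
        ours = stats.cluster_permutation(data, times, n_perm=2000, seed=4)
        t_thresh = ours.threshold
        _, clusters, p_vals, _ = mne_stats.permutation_cluster_1samp_test(
            data, threshold=t_thresh, n_permutations=2000, tail=0, seed=5, verbose=False
        )
        def bounds(c):
            c = c[0] if isinstance(c, tuple) else c
            if isinstance(c, slice):
                return c.start, c.stop
            c = np.asarray(c)
            idx = np.flatnonzero(c) if c.dtype == bool else c
            return int(idx.min()), int(idx.max()) + 1

        ref = sorted(bounds(c) for c, p in zip(clusters, p_vals) if p < 0.05)
        ours_sig = sorted(
            (int(round(c.start_s * 50)), int(round(c.end_s * 50))) for c in ours.significant()
        )
        assert ours_sig == ref

    def test_too_few_subjects_or_perms_rejected(self):
        with pytest.raises(ValueError):
            stats.cluster_permutation(np.zeros((3, 10)), np.arange(10), n_perm=200)
        with pytest.raises(ValueError):
            stats.cluster_permutation(np.zeros((8, 10)), np.arange(10), n_perm=50)


class TestRmAnova:
    @staticmethod
    def _long(cells, noise_sd, n_subj=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            base = rng.normal(0, 1)
            for (d, a), mu in cells.items():
                rows.append(
                    {
                        "subject": s,
                        "difficulty": d,
                        "accuracy": a,
                        "value": base + mu + rng.normal(0, noise_sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_additive_cells_give_null_interaction(self):
        cells = {("easy", "correct"): 0.0, ("easy", "error"): 1.0,
                 ("hard", "correct"): 0.5, ("hard", "error"): 1.5}
        aov = stats.rm_anova_2x2(self._long(cells, noise_sd=0.05))
        assert aov.p_interaction > 0.1
        assert aov.F_accuracy > 100

    def test_interaction_f_equals_squared_paired_t(self):
        from scipy import stats as sps

        cells = {("easy", "correct"): 0.0, ("easy", "error"): 1.5,
                 ("hard", "correct"): 0.4, ("hard", "error"): 1.0}
        df = self._long(cells, noise_sd=0.3, seed=5)
        aov = stats.rm_anova_2x2(df)
        wide = df.pivot_table(index="subject", columns=["difficulty", "accuracy"], values="value")
        inter = (wide[("easy", "error")] - wide[("easy", "correct")]) - (
            wide[("hard", "error")] - wide[("hard", "correct")]
        )
        t = sps.ttest_1samp(inter, 0).statistic
        assert aov.F_interaction == pytest.approx(t**2, rel=1e-9)
        assert (aov.df1, aov.df2) == (1, 11)

    def test_missing_cells_error_lists_subjects(self):
        df = self._long(
            {("easy", "correct"): 0, ("easy", "error"): 0,
             ("hard", "correct"): 0, ("hard", "error"): 0},
            noise_sd=0.1,
        )
        df = df.drop(df[(df.subject == 3) & (df.accuracy == "error") & (df.difficulty == "hard")].index)
        with pytest.raises(ValueError, match="3"):
            stats.rm_anova_2x2(df)


class TestPairedPermutation:
    def test_identical_vectors_p_one(self):
        x = np.arange(8.0)
        with pytest.warns(RuntimeWarning):
            res = stats.permutation_test_paired(x, x)
        assert res.p_value == 1.0

    def test_large_separated_effect_hits_floor(self):
        rng = np.random.default_rng(0)
        x = 10 + rng.normal(0, 0.1, 20)
        res = stats.permutation_test_paired(x, np.zeros(20), n_perm=10_000, seed=1)
        assert not res.exact
        assert res.p_value == pytest.approx(1 / 10_001)

    def test_matches_exhaustive_enumeration_at_n10(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.4, 1.0, 10)
        res = stats.permutation_test_paired(d, n_perm=10_000, seed=2)
        assert res.exact and res.n_permutations == 1024
        # independent brute-force oracle over all sign assignments
        obs = abs(d.mean())
        count = sum(
            abs(np.mean(np.array(signs) * d)) >= obs - 1e-12
            for signs in itertools.product([-1, 1], repeat=10)
        )
        assert res.p_value == pytest.approx(count / 1024)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20)
    def test_p_value_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        res = stats.permutation_test_paired(rng.normal(0, 1, 12), n_perm=500, seed=0)
        assert 0 < res.p_value <= 1


class TestResidualizeRT:
    def test_pupil_linear_in_rt_residual_variance_zero(self):
        rng = np.random.default_rng(0)
        rt = rng.uniform(0.5, 2.0, 100)
        pupil = 3.0 * rt - 1.0
        out = stats.residualize_rt(pupil, rt)
        assert out.var() < 1e-20
        assert out.mean() == pytest.approx(pupil.mean())

    def test_orthogonal_pupil_unchanged(self):
        rt = np.tile([1.0, 2.0], 50)
        pupil = np.tile([1.0, 1.0, -1.0, -1.0], 25)  # orthogonal to rt
        out = stats.residualize_rt(pupil, rt)
        assert np.allclose(out, pupil, atol=1e-12)

    def test_matches_hat_matrix_closed_form(self):
        rng = np.random.default_rng(1)
        rt = rng.uniform(0.5, 2.0, 60)
        v = rng.normal(size=(60, 5))
        out = stats.residualize_rt(v, rt)
        X = np.column_stack([np.ones_like(rt), rt])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        closed = (np.eye(60) - H) @ v + v.mean(axis=0, keepdims=True)
        assert np.allclose(out, closed, atol=1e-10)

    def test_constant_rt_identity_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = stats.residualize_rt(np.arange(10.0), np.ones(10))
        assert np.array_equal(out, np.arange(10.0))


class TestRegressOnEvidence:
    @staticmethod
    def _trials(slope_err, slope_cor, n_subj=6, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            ev = rng.uniform(0.0, 0.3, n)
            correct = np.tile([0, 1], n // 2)
            val = np.where(correct == 0, slope_err, slope_cor) * ev + rng.normal(0, 0.01, n)
            rows.append(
                pd.DataFrame({"subject": s, "correct": correct, "abs_evidence": ev, "value": val})
            )
        return pd.concat(rows, ignore_index=True)

    def test_recovers_constructed_interaction(self):
        res = stats.regress_on_evidence(self._trials(+1.0, -1.0), n_perm=2000, seed=0)
        assert res.group_mean == pytest.approx(2.0, abs=0.05)
        assert res.group_p < 0.05

    def test_independent_pupil_null_interaction(self):
        res = stats.regress_on_evidence(self._trials(0.0, 0.0), n_perm=2000, seed=1)
        assert abs(res.group_mean) < 0.05
        assert res.group_p > 0.05

    def test_sparse_subjects_excluded(self):
        df = self._trials(1.0, -1.0)
        # subject 0 loses nearly all error trials
        drop = df[(df.subject == 0) & (df.correct == 0)].index[:-2]
        res = stats.regress_on_evidence(df.drop(drop), n_perm=500, seed=2)
        assert 0 not in res.subjects


class TestModelPupilCorrelation:
    @staticmethod
    def _trials(sign=1.0, n_subj=6, n=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            pred = rng.uniform(0, 1, n)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "difficulty": rng.choice(["easy", "hard"], n),
                        "correct": rng.integers(0, 2, n),
                        "pred": pred,
                        "pupil": sign * pred,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @pytest.mark.parametrize("scheme", ["four_condition", "six_bin", "single_trial"])
    def test_perfect_correlation(self, scheme):
        res = stats.model_pupil_correlation(
            self._trials(+1.0), "pred", "pupil", scheme=scheme, n_perm=1000, seed=0
        )
        assert np.allclose(res["r"], 1.0)
        assert res["group_p"] < 0.05

    def test_anticorrelation(self):
        res = stats.model_pupil_correlation(
            self._trials(-1.0), "pred", "pupil", scheme="single_trial", n_perm=1000, seed=0
        )
        assert np.allclose(res["r"], -1.0)

    def test_fewer_trials_than_bins_rejected(self):
        df = self._trials().groupby("subject").head(3)
        with pytest.raises(ValueError):
            stats.model_pupil_correlation(df, "pred", "pupil", scheme="six_bin")

    @given(st.integers(8, 200), st.integers(2, 8))
    @settings(derandomize=True, max_examples=30)
    def test_equal_count_bins_balanced(self, n, k):
        rng = np.random.default_rng(0)
        bins = stats.equal_count_bins(rng.normal(size=n), k)
        counts = np.bincount(bins, minlength=k)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == n
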