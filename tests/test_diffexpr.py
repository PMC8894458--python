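"""Log-CPM transform, precision weights, moderated fit, BH, washout, profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pseudoex.io import GenomicInterval
from pseudoex.quantify import CountMatrix, ExonBin
from pseudoex.diffexpr import (
    DEParams,
    DEResult,
    adjust_results,
    bh_adjust,
    build_design,
    call_events,
    classify_washout,
    exon_profile,
    logcpm_transform,
    mean_variance_weights,
    weighted_moderated_fit,
)


def _count_matrix(mat, lib=None):
    df = pd.DataFrame(
        np.asarray(mat),
        index=[f"f{i}" for i in range(len(mat))],
        columns=[f"s{j}" for j in range(len(mat[0]))],
    )
    lib = lib or {c: 1_000_000 for c in df.columns}
    return CountMatrix(df, pd.Series(lib))


DESIGN_3V3 = build_design(["a", "a", "a", "b", "b", "b"], reference="a")


class TestLogCpm:
    def test_zero_count_plug_in(self):
        cm = _count_matrix([[0]], lib={"s0": 999_999})
        val = logcpm_transform(cm).iloc[0, 0]
        assert val == pytest.approx(np.log2(0.5), abs=1e-12)

    def test_doubling_count_plus_half_adds_one(self):
        cm1 = _count_matrix([[10]])
        cm2 = _count_matrix([[20.5]])  # (count + 0.5) exactly doubled
        a = logcpm_transform(cm1).iloc[0, 0]
        b = logcpm_transform(cm2).iloc[0, 0]
        assert b - a == pytest.approx(1.0)

    def test_matrix_matches_scalar_loop(self):
        rng = np.random.default_rng(6)
        mat = rng.integers(0, 300, size=(10, 4))
        lib = {f"s{j}": int(v) for j, v in enumerate(rng.integers(10_000, 50_000, 4))}
        got = logcpm_transform(_count_matrix(mat, lib))
        for i in range(10):
            for j in range(4):
                want = np.log2((mat[i, j] + 0.5) / (lib[f"s{j}"] + 1) * 1e6)
                assert got.iloc[i, j] == pytest.approx(want)


class TestWeights:
    def test_homoscedastic_weights_nearly_flat(self):
        rng = np.random.default_rng(12)
        y = pd.DataFrame(rng.normal(8.0, 1.0, size=(200, 6)))
        w = mean_variance_weights(y, DESIGN_3V3)
        assert w.to_numpy().max() / w.to_numpy().min() < 10

    def test_trend_decreasing_for_nb_counts(self):
        rng = np.random.default_rng(13)
        mus = np.exp(rng.uniform(np.log(2), np.log(500), size=400))
        counts = rng.negative_binomial(10, 10 / (10 + mus[:, None]), size=(400, 6))
        cm = _count_matrix(counts, {f"s{j}": 50_000 for j in range(6)})
        y = logcpm_transform(cm)
        w = mean_variance_weights(y, DESIGN_3V3)
        mean_lc = y.mean(axis=1).to_numpy()
        lo = w.to_numpy()[mean_lc < np.quantile(mean_lc, 0.2)].mean()
        hi = w.to_numpy()[mean_lc > np.quantile(mean_lc, 0.8)].mean()
        assert hi > lo  # high-count features are more precise

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        y = pd.DataFrame(rng.normal(5, 1, size=(50, 6)), index=[f"f{i}" for i in range(50)])
        w = mean_variance_weights(y, DESIGN_3V3)
        perm = rng.permutation(50)
        w_perm = mean_variance_weights(y.iloc[perm], DESIGN_3V3)
        pd.testing.assert_frame_equal(w.iloc[perm], w_perm)

    def test_single_sample_group_rejected(self):
        y = pd.DataFrame(np.zeros((5, 3)))
        design = build_design(["a", "a", "b"], reference="a")
        with pytest.raises(ValueError, match="2 samples"):
            mean_variance_weights(y, design)


class TestModeratedFit:
    def test_identical_groups_give_zero_fc_p_one(self):
        y = pd.DataFrame(np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (5, 1)))
        y += np.arange(5)[:, None]  # distinct features, same group pattern
        w = pd.DataFrame(np.ones_like(y))
        res = weighted_moderated_fit(y, w, DESIGN_3V3)
        for r in res:
            assert r.log2fc == pytest.approx(0.0, abs=1e-12)
            assert r.p == pytest.approx(1.0)

    def test_prior_df_zero_equals_ordinary_weighted_t(self):
        rng = np.random.default_rng(15)
        y = pd.DataFrame(rng.normal(size=(20, 6)))
        w = pd.DataFrame(rng.uniform(0.5, 2.0, size=(20, 6)))
        res = weighted_moderated_fit(y, w, DESIGN_3V3, prior_df=0)
        X = DESIGN_3V3
        for i, r in enumerate(res):
            # independent weighted least squares
            W = np.diag(w.iloc[i].to_numpy())
            XtWX = X.T @ W @ X
            b = np.linalg.solve(XtWX, X.T @ W @ y.iloc[i].to_numpy())
            resid = y.iloc[i].to_numpy() - X @ b
            s2 = resid @ W @ resid / (6 - 2)
            se = np.sqrt(s2 * np.linalg.inv(XtWX)[1, 1])
            assert r.t == pytest.approx(b[1] / se)

    def test_toy_matrix_matches_formula_oracle(self):
        """Five-feature fit vs a step-by-step recomputation including the
        empirical-Bayes moderation formulas."""
        rng = np.random.default_rng(16)
        y = pd.DataFrame(rng.normal(5, 1, size=(5, 6)))
        w = pd.DataFrame(rng.uniform(0.2, 3.0, size=(5, 6)))
        res = weighted_moderated_fit(y, w, DESIGN_3V3, prior_df=4.0)
        from scipy import special as sp, stats as ss

        X = DESIGN_3V3
        s2_list, b_list, se_list = [], [], []
        for i in range(5):
            W = np.diag(w.iloc[i].to_numpy())
            XtWXinv = np.linalg.inv(X.T @ W @ X)
            b = XtWXinv @ (X.T @ W @ y.iloc[i].to_numpy())
            resid = y.iloc[i].to_numpy() - X @ b
            s2_list.append(float(resid @ W @ resid) / 4)
            b_list.append(b[1])
            se_list.append(np.sqrt(XtWXinv[1, 1]))
        d0 = 4.0
        # method-of-moments prior variance on the log scale (df = 4)
        e = np.log(s2_list) - sp.digamma(2.0) + np.log(2.0)
        s02 = float(np.exp(e.mean() + sp.digamma(d0 / 2) - np.log(d0 / 2)))
        for i, r in enumerate(res):
            post = (d0 * s02 + 4 * s2_list[i]) / (d0 + 4)
            t = b_list[i] / (np.sqrt(post) * se_list[i])
            assert r.t == pytest.approx(t)
            assert r.p == pytest.approx(2 * ss.t.sf(abs(t), d0 + 4))

    def test_monotone_shift_moves_log2fc_exactly(self):
        rng = np.random.default_rng(18)
        y = pd.DataFrame(rng.normal(size=(10, 6)))
        w = pd.DataFrame(rng.uniform(0.5, 2.0, size=(10, 6)))
        base = weighted_moderated_fit(y, w, DESIGN_3V3)
        y2 = y.copy()
        y2.iloc[0, 3:] += 1.7  # add constant to treated group of feature 0
        shifted = weighted_moderated_fit(y2, w, DESIGN_3V3)
        assert shifted[0].log2fc - base[0].log2fc == pytest.approx(1.7)

    def test_non_finite_input_rejected(self):
        y = pd.DataFrame(np.ones((3, 6)))
        y.iloc[1, 2] = np.nan
        w = pd.DataFrame(np.ones((3, 6)))
        with pytest.raises(ValueError, match="non-finite"):
            weighted_moderated_fit(y, w, DESIGN_3V3)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_three_value_example(self):
        got = bh_adjust([0.01, 0.04, 0.03])
        # definition: sort (0.01,0.03,0.04), multiply by n/rank
        # (0.03,0.045,0.04), cumulative min from the right (0.03,0.04,0.04)
        np.testing.assert_allclose(got, [0.03, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False), min_size=1, max_size=8
        )
    )
    def test_matches_definition_oracle_exhaustively(self, ps):
        got = bh_adjust(ps)
        n = len(ps)
        order = sorted(range(n), key=lambda i: ps[i])
        for rank_pos, i in enumerate(order):
            # step-up definition: min over j with rank >= this one of n*p_(j)/j
            want = min(
                ps[order[k]] * n / (k + 1) for k in range(rank_pos, n)
            )
            assert got[i] == pytest.approx(min(want, 1.0))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCallEvents:
    def _result(self, fc, adj):
        r = DEResult("f", 0.0, fc, 0.0, adj, adj_p=adj)
        return r

    def test_boundaries_are_strict(self):
        params = DEParams(lfc_threshold=1.0, alpha=0.01)
        assert call_events([self._result(2.0, 0.01)], params) == set()
        assert call_events([self._result(1.0, 0.001)], params) == set()
        assert call_events([self._result(1.01, 0.009)], params) == {"f"}

    def test_direction_any_uses_absolute_fc(self):
        params = DEParams(lfc_threshold=1.0, alpha=0.01)
        down = self._result(-2.0, 0.001)
        assert call_events([down], params, direction="up") == set()
        down.significant = False
        assert call_events([down], params, direction="any") == {"f"}

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(20)
        results = [
            DEResult(f"f{i}", 0.0, float(fc), 0.0, float(p), adj_p=float(p))
            for i, (fc, p) in enumerate(
                zip(rng.normal(0, 2, 100), rng.uniform(size=100))
            )
        ]
        params = DEParams(lfc_threshold=1.0, alpha=0.05)
        got = call_events(results, params)
        want = {
            r.feature_id for r in results if r.adj_p < 0.05 and r.log2fc > 1.0
        }
        assert got == want


class TestWashout:
    def _results(self, flags):
        out = []
        for i, sig in enumerate(flags):
            adj = 0.001 if sig else 0.5
            out.append(DEResult(f"f{i}", 0.0, 3.0, 5.0, adj, adj_p=adj))
        return out

    @pytest.mark.parametrize(
        "pre,post,expected",
        [(True, True, "persistent"), (True, False, "reversible"), (False, False, "absent"), (False, True, "absent")],
    )
    def test_pure_function_of_flags(self, pre, post, expected):
        labels = classify_washout(self._results([pre]), self._results([post]))
        assert labels["f0"] == expected

    def test_id_mismatch_rejected(self):
        pre = self._results([True])
        post = self._results([True, False])
        with pytest.raises(ValueError, match="share feature ids"):
            classify_washout(pre, post)


class TestExonProfile:
    def _bins(self, n):
        return [
            ExonBin("G", GenomicInterval("chr1", 100 * k, 100 * k + 50, "+"), k)
            for k in range(1, n + 1)
        ]

    def _counts(self, mat):
        df = pd.DataFrame(
            mat,
            index=[f"G:bin{k}" for k in range(1, len(mat) + 1)],
            columns=[f"s{j}" for j in range(len(mat[0]))],
        )
        return CountMatrix(df, pd.Series({c: 1_000_000 for c in df.columns}))

    def test_identical_conditions_flat_profile(self):
        cm = self._counts([[10, 10, 10, 10]] * 3)
        sf = pd.Series(1.0, index=cm.counts.columns)
        df, med = exon_profile(
            self._bins(3), cm, sf, ["c", "c", "t", "t"], "t", "c"
        )
        assert (df["log2fc"] == 0).all() and med == 0

    def test_planted_bin_stands_out_against_downregulation(self):
        # all bins halved in treatment except bin 2 raised 4x
        cm = self._counts(
            [[40, 40, 20, 20], [10, 10, 40, 40], [40, 40, 20, 20], [40, 40, 20, 20]]
        )
        sf = pd.Series(1.0, index=cm.counts.columns)
        df, med = exon_profile(
            self._bins(4), cm, sf, ["c", "c", "t", "t"], "t", "c"
        )
        planted = df.loc[df["rank"] == 2, "log2fc"].iloc[0]
        assert planted > 0 and med < 0
        assert planted == pytest.approx(np.log2(40.5 / 10.5))

    def test_output_ordered_by_rank(self):
        cm = self._counts([[5, 6, 7, 8]] * 4)
        sf = pd.Series(1.0, index=cm.counts.columns)
        df, _ = exon_profile(self._bins(4), cm, sf, ["c", "c", "t", "t"], "t", "c")
        assert list(df["rank"]) == [1, 2, 3, 4]

    def test_no_bins_rejected(self):
        cm = self._counts([[1, 1]])
        with pytest.raises(ValueError, match="no exon bins"):
            exon_profile([], cm, pd.Series(1.0, index=cm.counts.columns), ["c", "t"], "t", "c")
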