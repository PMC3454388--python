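import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsnet.netbuild import CorrelationMatrix
from nirsnet.repro import (
    SplitDesign,
    contrast_anova,
    matrix_similarity,
    nodal_profile_correlation,
    split,
    split_by_subject,
    split_by_time,
)

import oracles


def _corr(n, seed):
    x = np.random.default_rng(seed).normal(size=(n, 3 * n))
    return CorrelationMatrix(values=np.corrcoef(x), channel_ids=[f"ch{i+1}" for i in range(n)])


class TestSplit:
    def test_fifteen_subjects_split_seven_eight(self):
        g1, g2 = split_by_subject(list(range(15)), seed=0)
        assert (len(g1), len(g2)) == (7, 8)
        assert sorted(g1 + g2) == list(range(15))

    def test_split_is_deterministic_given_seed(self):
        a = split_by_subject(list(range(15)), seed=3)
        b = split_by_subject(list(range(15)), seed=3)
        assert a == b

    def test_time_split_halves_are_contiguous_and_exhaustive(self):
        x = np.arange(12000.0).reshape(1, -1)
        h1, h2 = split_by_time(x)
        assert h1.shape[-1] == h2.shape[-1] == 6000
        assert np.array_equal(np.concatenate([h1, h2], axis=-1), x)

    def test_odd_sample_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            split_by_time(np.zeros(101))

    def test_dispatch_on_design(self):
        g1, g2 = split(list(range(10)), SplitDesign(mode="by_subject", seed=1))
        assert len(g1) + len(g2) == 10
        h1, h2 = split([np.zeros((2, 8))], SplitDesign(mode="by_time"))
        assert h1[0].shape == (2, 4)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            SplitDesign(mode="odd_even")


class TestMatrixSimilarity:
    def test_self_similarity_is_one(self):
        m = _corr(6, 0)
        assert matrix_similarity(m, m) == pytest.approx(1.0)

    def test_negated_offdiagonals_give_minus_one(self):
        m = _corr(6, 1)
        v = m.values.copy()
        iu = np.triu_indices(6, 1)
        v[iu] *= -1
        v.T[iu] *= -1
        neg = CorrelationMatrix(values=v, channel_ids=m.channel_ids)
        assert matrix_similarity(m, neg) == pytest.approx(-1.0)

    def test_matches_flatten_and_correlate_oracle(self):
        a, b = _corr(8, 2), _corr(8, 3)
        iu = np.triu_indices(8, 1)
        assert matrix_similarity(a, b) == pytest.approx(
            oracles.pearson(a.values[iu], b.values[iu]), abs=1e-12
        )

    def test_symmetry_and_relabel_invariance(self):
        a, b = _corr(7, 4), _corr(7, 5)
        assert matrix_similarity(a, b) == pytest.approx(matrix_similarity(b, a))
        perm = np.random.default_rng(6).permutation(7)
        ap = CorrelationMatrix(values=a.values[np.ix_(perm, perm)],
                               channel_ids=[a.channel_ids[i] for i in perm])
        bp = CorrelationMatrix(values=b.values[np.ix_(perm, perm)],
                               channel_ids=[b.channel_ids[i] for i in perm])
        assert matrix_similarity(ap, bp) == pytest.approx(matrix_similarity(a, b))

    def test_channel_order_mismatch_rejected(self):
        a = _corr(5, 7)
        b = CorrelationMatrix(values=_corr(5, 8).values, channel_ids=list("vwxyz"))
        with pytest.raises(ValueError):
            matrix_similarity(a, b)


class TestNodalProfileCorrelation:
    def test_identical_halves_give_unit_correlation(self):
        v = np.random.default_rng(0).normal(size=(20, 10))
        rs, mean, sd = nodal_profile_correlation(v, v)
        assert np.allclose(rs, 1.0)
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_independent_profiles_average_near_zero(self):
        rng = np.random.default_rng(1)
        rs, mean, _ = nodal_profile_correlation(
            rng.normal(size=(200, 30)), rng.normal(size=(200, 30))
        )
        assert abs(mean) < 0.1

    def test_constant_levels_excluded_as_nan(self):
        v1 = np.random.default_rng(2).normal(size=(5, 8))
        v2 = v1.copy()
        v1[2] = 1.0  # constant across nodes: r undefined at this level
        rs, _, _ = nodal_profile_correlation(v1, v2)
        assert np.isnan(rs[2]) and np.isfinite(rs[[0, 1, 3, 4]]).all()


class TestContrastAnova:
    def _table(self, seed, n=10):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 1))
        return pd.DataFrame(
            base + rng.normal(scale=0.3, size=(n, 3)),
            columns=["oxy", "deoxy", "total"],
        )

    def test_identical_contrasts_give_zero_f(self):
        v = np.random.default_rng(3).normal(size=10)
        tab = pd.DataFrame({"oxy": v, "deoxy": v, "total": v})
        out = contrast_anova(tab)
        assert out.f_stat == pytest.approx(0.0)

    def test_alternating_differences_give_zero_t(self):
        oxy = np.array([1.0, 2.0, 3.0, 4.0])
        deoxy = oxy - np.array([1.0, -1.0, 1.0, -1.0])
        tab = pd.DataFrame({"oxy": oxy, "deoxy": deoxy, "total": oxy})
        out = contrast_anova(tab)
        row = out.pairwise.set_index("pair").loc["oxy-deoxy"]
        assert row["t"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_f_statistic_matches_longhand_sums_of_squares(self, seed):
        tab = self._table(seed)
        out = contrast_anova(tab)
        f_ref, (df1, df2) = oracles.rm_anova_longhand(tab.to_numpy())
        assert out.f_stat == pytest.approx(f_ref, abs=1e-9)
        assert out.df == (df1, df2)
        assert out.p_value == pytest.approx(stats.f.sf(f_ref, df1, df2), abs=1e-12)

    def test_f_statistic_matches_statsmodels(self):
        # independent route through the installed rm-ANOVA implementation
        from statsmodels.stats.anova import AnovaRM

        tab = self._table(11)
        long = tab.reset_index().melt(
            id_vars="index", var_name="contrast", value_name="auc"
        )
        sm = AnovaRM(long, "auc", "index", within=["contrast"]).fit()
        out = contrast_anova(tab)
        assert out.f_stat == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), rel=1e-9
        )

    def test_pairwise_t_matches_scipy(self):
        tab = self._table(12)
        out = contrast_anova(tab)
        t_ref, p_ref = stats.ttest_rel(tab["oxy"], tab["total"])
        row = out.pairwise.set_index("pair").loc["oxy-total"]
        assert row["t"] == pytest.approx(float(t_ref))
        assert row["p"] == pytest.approx(float(p_ref))

    def test_missing_cells_rejected(self):
        tab = self._table(13)
        tab.loc[0, "deoxy"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            contrast_anova(tab)

    def test_fdr_and_bonferroni_are_monotone_in_raw_p(self):
        tab = self._table(14)
        out = contrast_anova(tab)
        pw = out.pairwise.sort_values("p")
        assert (pw["p_bonferroni"] >= pw["p"] - 1e-15).all()
        assert pw["p_fdr"].is_monotonic_increasing
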