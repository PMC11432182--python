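import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cystfem.runner import packaged_table1
from cystfem.stats import (
    describe,
    round_half_up,
    friedman,
    stats_report,
    wilcoxon_pairs,
    wilcoxon_signed_rank,
)

# printed summary row of the published table: mean +/- population SD per scenario
PUBLISHED_MEANS = {"S1": 1.24, "S2": 1.81, "S3": 1.26, "S4": 1.92,
                   "S5": 1.32, "S6": 1.48, "S7": 1.70}
PUBLISHED_SDS = {"S1": 0.35, "S2": 0.52, "S3": 0.36, "S4": 0.55,
                 "S5": 0.42, "S6": 0.42, "S7": 0.49}


@pytest.fixture(scope="module")
def table1():
    return packaged_table1()


class TestDescribe:
    def test_published_means_and_population_sds(self, table1):
        desc = describe(table1)
        for s in table1.columns:
            assert round_half_up(desc.loc[s, "mean"]) == PUBLISHED_MEANS[s]
            assert round_half_up(desc.loc[s, "sd"]) == PUBLISHED_SDS[s]

    def test_population_form_is_required_for_published_sds(self, table1):
        # the sample (n-1) SD of the control column rounds to 0.39, not 0.35:
        # only the population form reproduces the printed row
        pop = describe(table1, population_sd=True)
        samp = describe(table1, population_sd=False)
        assert round_half_up(pop.loc["S1", "sd"]) == 0.35
        assert round_half_up(samp.loc["S1", "sd"]) == 0.39

    def test_per_kg_slopes_round_to_published_partition(self, table1):
        desc = describe(table1)
        for s in ("S1", "S3", "S5", "S6", "S7"):
            assert desc.loc[s, "slope_rounded"] == pytest.approx(0.01)
        for s in ("S2", "S4"):
            assert desc.loc[s, "slope_rounded"] == pytest.approx(0.02)

    def test_stress_weight_correlation_near_perfect(self, table1):
        desc = describe(table1)
        assert (desc["r"].drop("S5") > 0.999).all()
        # the 130 kg dip in S5 is preserved as printed; r stays high but < 1
        assert 0.9 < desc.loc["S5", "r"] < 0.999

    def test_constant_column_degenerates_gracefully(self):
        tbl = pd.DataFrame({"A": [2.0] * 4, "B": [1, 2, 3, 4.0]},
                           index=pd.Index([70, 90, 110, 130.0], name="weight"))
        with pytest.warns(UserWarning, match="constant"):
            desc = describe(tbl)
        assert desc.loc["A", "mean"] == 2.0
        assert desc.loc["A", "sd"] == 0.0
        assert desc.loc["A", "slope"] == 0.0
        assert np.isnan(desc.loc["A", "r"])

    def test_single_row_rejected(self):
        tbl = pd.DataFrame({"A": [1.0]}, index=pd.Index([70.0], name="weight"))
        with pytest.raises(ValueError):
            describe(tbl)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5),
           c=st.floats(0.1, 10), d=st.floats(-5, 5))
    def test_pearson_r_affine_invariant(self, table1, a, b, c, d):
        scaled = table1 * c + d
        scaled.index = table1.index * a + b
        r0 = describe(table1)["r"]
        r1 = describe(scaled)["r"]
        assert np.allclose(r0, r1, atol=1e-9)


class TestFriedman:
    def test_published_table_is_highly_significant(self, table1):
        res = friedman(table1)
        assert res.df == 6
        assert res.p < 1e-4

    def test_identical_columns_give_zero_statistic(self):
        col = [1.0, 2.0, 3.0, 4.0]
        tbl = pd.DataFrame({"A": col, "B": col, "C": col})
        res = friedman(tbl)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_dominant_column_two_treatments(self):
        # 6 blocks, one column always larger: ranks are (1, 2) in every
        # block, so R = (6, 12) and chi2 = 12/(6*2*3)*(36+144) - 3*6*3 = 6
        tbl = pd.DataFrame({"A": np.arange(6.0), "B": np.arange(6.0) + 1.0})
        assert friedman(tbl).chi2 == pytest.approx(6.0)

    def test_matches_scipy_on_tie_free_table(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(8, 4))
        tbl = pd.DataFrame(data, columns=list("ABCD"))
        ours = friedman(tbl)
        ref_chi2, ref_p = sps.friedmanchisquare(*[data[:, j] for j in range(4)])
        assert ours.chi2 == pytest.approx(ref_chi2, rel=1e-12)
        assert ours.p == pytest.approx(ref_p, rel=1e-12)

    def test_statistic_against_enumerated_rank_null(self):
        # enumerate every within-block rank assignment of a 4x4 grid; at
        # each one, compare our statistic with an independently derived
        # form, 12/(n k (k+1)) * sum_j (R_j - n(k+1)/2)^2, and locate the
        # observed table's statistic inside the exact permutation null
        import itertools

        rng = np.random.default_rng(3)
        k, n = 4, 4
        data = rng.normal(size=(n, k))
        tbl = pd.DataFrame(data, columns=list("ABCD"))
        observed = friedman(tbl).chi2

        def oracle_stat(rank_rows):
            R = rank_rows.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * ((R - n * (k + 1) / 2.0) ** 2).sum()

        perms = [np.array(p, dtype=float) for p in itertools.permutations(range(1, k + 1))]
        combos = list(itertools.product(range(len(perms)), repeat=n))
        null = np.array([oracle_stat(np.stack([perms[i] for i in c])) for c in combos])
        # spot-check our statistic against the oracle on a seeded subsample
        for idx in rng.choice(len(combos), size=200, replace=False):
            ranks = np.stack([perms[i] for i in combos[idx]])
            ours = friedman(pd.DataFrame(ranks, columns=list("ABCD"))).chi2
            assert ours == pytest.approx(oracle_stat(ranks), abs=1e-9)
        p_exact = float((null >= observed - 1e-12).mean())
        # observed statistic must be a member of the exact null support
        assert np.isclose(null, observed).any()
        # the chi-square tail is an approximation at this size; it must at
        # least agree with enumeration on which side of 0.5 the p falls
        assert (p_exact - 0.5) * (friedman(tbl).p - 0.5) >= 0 or abs(p_exact - 0.5) < 0.2

    def test_incomplete_grid_rejected(self):
        tbl = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, 3.0]})
        with pytest.raises(ValueError, match="incomplete"):
            friedman(tbl)


class TestWilcoxon:
    def test_identical_pair_is_one_with_warning(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_exact_minimum_two_sided_p_at_n6(self, table1):
        # all six differences share one sign, the strongest possible
        # evidence at n = 6: the exact two-sided p is 2/2^6 = 0.03125
        p = wilcoxon_signed_rank(
            table1["S1"].to_numpy(), table1["S2"].to_numpy(), mode="exact"
        )
        assert p == pytest.approx(2.0 / 64.0)

    def test_approx_mode_reaches_below_0_03(self, table1):
        # the normal approximation (no continuity correction) is the only
        # route to p < 0.03 with six pairs
        p = wilcoxon_signed_rank(
            table1["S1"].to_numpy(), table1["S3"].to_numpy(), mode="approx"
        )
        assert p <= 0.05
        assert p < 0.03

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ours = wilcoxon_signed_rank(x, y, mode="exact")
            ref = sps.wilcoxon(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_approx_tracks_exact_at_moderate_n(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 1.0, size=18)
        y = rng.normal(0.0, 1.0, size=18)
        exact = wilcoxon_signed_rank(x, y, mode="exact")
        approx = wilcoxon_signed_rank(x, y, mode="approx")
        assert approx == pytest.approx(exact, abs=0.03)

    def test_pair_matrix_symmetric_unit_diagonal(self, table1):
        P = wilcoxon_pairs(table1, mode="exact")
        assert np.allclose(P.values, P.values.T)
        assert np.allclose(np.diag(P.values), 1.0)
        off = P.values[~np.eye(7, dtype=bool)]
        assert (off >= 2.0 / 64.0).all()  # n=6 exact floor


class TestReport:
    def test_modes_disagree_on_the_0_03_bound(self, table1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exact = stats_report(table1, mode="exact")
            approx = stats_report(table1, mode="approx")
        assert not exact.all_pairs_below_003  # floor is 0.03125
        # under the normal approximation every pair moves below 0.03 except
        # the one contrast whose differences change sign (S3 vs S5 region)
        off = approx.pairwise_p.values[~np.eye(7, dtype=bool)]
        assert (off < 0.03).sum() >= 2 * 19  # at least 19 of 21 pairs

    def test_multiplicity_correction_only_raises_p(self, table1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = stats_report(table1, mode="exact")
            adj = stats_report(table1, mode="exact", correction="holm")
        assert (adj.pairwise_p.values >= raw.pairwise_p.values - 1e-15).all()

    def test_report_serializes(self, table1, tmp_path):
        import json

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stats_report(table1)
        path = tmp_path / "report.json"
        rep.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["friedman"]["df"] == 6
        assert round_half_up(doc["descriptives"]["S4"]["mean"]) == 1.92
        assert "S1" in rep.to_text()
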