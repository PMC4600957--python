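from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poroarch import (GroupData, UndefinedResultError, build_table,
                      conover_inman_pairwise, kruskal_wallis, mann_whitney_u,
                      percent_change)


class TestKruskalWallis:
    def test_identical_groups_null(self):
        h, p = kruskal_wallis(GroupData(["a", "b"],
                                        [[1, 2, 3], [1, 2, 3]]))
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_hand_ranks(self):
        # ranks 1..6; rank sums 3, 7, 11 -> H = 12/42 * 89.5 - 21 = 32/7
        h, p = kruskal_wallis(GroupData(["a", "b", "c"],
                                        [[1, 2], [3, 4], [5, 6]]))
        assert h == pytest.approx(32 / 7)

    def test_matches_permutation_oracle_statistic(self, rng):
        groups = [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]]
        h, _ = kruskal_wallis(GroupData(["a", "b", "c"], groups))
        # independent rank arithmetic (no ties): H = 12/(N(N+1)) ΣR²/n − 3(N+1)
        pooled = np.concatenate(groups)
        ranks = pooled.argsort().argsort() + 1
        rs = [ranks[i * 3:(i + 1) * 3].sum() for i in range(3)]
        expected = 12 / (9 * 10) * sum(r**2 / 3 for r in rs) - 3 * 10
        assert h == pytest.approx(expected)

    def test_degenerate_data_raises(self):
        with pytest.raises(UndefinedResultError):
            kruskal_wallis(GroupData(["a", "b"], [[5, 5], [5, 5]]))


class TestConoverInman:
    def test_identical_groups_all_p_one(self):
        p = conover_inman_pairwise(GroupData(["a", "b", "c"],
                                             [[1, 2, 3]] * 3))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(p.to_numpy()[off], 1.0)

    def test_most_separated_pair_smallest_p(self):
        p = conover_inman_pairwise(GroupData(
            ["lo", "mid", "hi"], [[1, 2, 3], [4, 5, 6], [7, 8, 9]]))
        assert p.loc["lo", "hi"] < p.loc["lo", "mid"]
        assert p.loc["lo", "hi"] < p.loc["mid", "hi"]

    def test_hand_computed_reference(self):
        # 3 tie-free groups of 4: ranks are exact integers
        data = GroupData(["a", "b", "c"],
                         [[1, 5, 9, 10], [2, 6, 11, 12], [3, 7, 13, 14]])
        got = conover_inman_pairwise(data)
        pooled = np.concatenate(data.values)
        ranks = stats.rankdata(pooled)
        rbar = [ranks[i * 4:(i + 1) * 4].mean() for i in range(3)]
        h, _ = stats.kruskal(*data.values)
        N, k = 12, 3
        s2 = ranks.var(ddof=1)
        scale2 = s2 * (N - 1 - h) / (N - k)
        for i, j in combinations(range(3), 2):
            t = (rbar[i] - rbar[j]) / np.sqrt(scale2 * (1 / 4 + 1 / 4))
            p = 2 * stats.t.sf(abs(t), N - k)
            assert got.iloc[i, j] == pytest.approx(p)

    def test_symmetry_and_diagonal(self):
        p = conover_inman_pairwise(GroupData(
            ["a", "b"], [[1, 2, 5], [3, 4, 6]]))
        assert np.isnan(p.iloc[0, 0]) and np.isnan(p.iloc[1, 1])
        assert p.iloc[0, 1] == p.iloc[1, 0]


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        # two-sided exact p = 2 × 1/C(6,3) = 2/20
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_symmetric_u(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)    # n1 n2 / 2

    def test_exact_p_equals_enumeration(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 5)
        u, p = mann_whitney_u(a, b)
        # enumerate all C(10,5) assignments of the pooled ranks
        from itertools import combinations as combs
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        def ustat(idx):
            ra = ranks[list(idx)]
            return ra.sum() - 5 * 6 / 2
        u_obs = ustat(range(5))
        null = np.array([ustat(c) for c in combs(range(10), 5)])
        lo = np.mean(null <= min(u_obs, 25 - u_obs))
        expected = min(1.0, 2 * lo)
        assert p == pytest.approx(expected)

    def test_degenerate_raises(self):
        with pytest.raises(UndefinedResultError):
            mann_whitney_u([3, 3], [3, 3])

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.random(6) + 0.1
        b = rng.random(6) + 0.5
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.log(a), np.log(b))
        assert u1 == u2 and p1 == pytest.approx(p2)


class TestPercentChange:
    def test_table_worked_examples(self):
        assert percent_change(58.9, 75.3) == pytest.approx(27.84, abs=0.01)
        assert percent_change(4.98, 5.56) == pytest.approx(11.65, abs=0.01)

    def test_equal_means_zero(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedResultError):
            percent_change(0.0, 1.0)


class TestBuildTable:
    @staticmethod
    def _long(groups, params=("Po",), rng=None):
        rows = []
        for param in params:
            for g, vals in groups.items():
                for i, v in enumerate(vals):
                    rows.append({"sample_id": f"{g}{i}", "group": g,
                                 "parameter": param, "value": v})
        return pd.DataFrame(rows)

    def test_row_per_parameter(self, rng):
        groups = {g: rng.random(3) for g in "ABCD"}
        rep = build_table(self._long(groups, params=("Po", "BS_TV", "Df")))
        assert len(rep.table) == 3
        assert rep.table["A_n"].tolist() == [3, 3, 3]

    def test_identical_groups_not_flagged(self):
        rep = build_table(self._long({"A": [1, 2, 3], "B": [1, 2, 3]}))
        assert not rep.significant("Po").any().any()

    def test_separated_phantom_groups_flagged(self, rng):
        hd = 69.1 + rng.normal(0, 0.3, 5)
        ld = 88.8 + rng.normal(0, 0.3, 5)
        rep = build_table(self._long({"HD": hd, "LD": ld}))
        assert rep.pairwise["Po"].loc["HD", "LD"] < 0.05

    def test_small_group_excluded_with_warning(self):
        df = self._long({"A": [1.0, 2.0, 3.0], "B": [9.0]})
        rep = build_table(df)
        assert any("n < 2" in w for w in rep.warnings)
        assert np.isnan(rep.table.loc[0, "B_sd"])
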