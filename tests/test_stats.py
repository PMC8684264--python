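"""Paired-core tests (Wilcoxon + permutation), ANOVA/Tukey, immune densities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mxifhet.stats import (
    AnovaResult,
    chi2_contingency_test,
    compare_groups_anova,
    compare_paired_cores,
    immune_density,
    permutation_mean_test,
    permutation_mean_test_bruteforce,
    run_paired_core_screen,
)

from conftest import make_cells


class TestComparePairedCores:
    def test_identical_vectors_not_significant(self):
        a = np.tile([1, 1, 2, 2, 9, 13], 30)
        res = compare_paired_cores(a, a.copy(), seed=0, n_perm=2000)
        assert res.permutation_p == 1.0
        assert not res.significant

    def test_disjoint_distributions_significant(self):
        res = compare_paired_cores([1] * 200, [9] * 200, seed=0, n_perm=2000)
        assert res.wilcoxon_p < 0.01 and res.permutation_p < 0.01
        assert res.significant

    def test_constant_pooled_vector_gives_p_one(self):
        res = compare_paired_cores([5] * 50, [5] * 80, seed=0, n_perm=500)
        assert res.wilcoxon_p == 1.0 and res.permutation_p == 1.0

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError):
            compare_paired_cores([], [1, 2], seed=0)

    def test_permutation_reproducible_bit_for_bit(self, rng):
        a = rng.integers(1, 17, 300)
        b = rng.integers(1, 17, 280)
        r1 = compare_paired_cores(a, b, seed=99, n_perm=3000)
        r2 = compare_paired_cores(a, b, seed=99, n_perm=3000)
        assert r1.permutation_p == r2.permutation_p
        assert r1.wilcoxon_p == r2.wilcoxon_p

    def test_significance_is_conjunction(self):
        res = compare_paired_cores([1] * 200, [9] * 200, seed=0, n_perm=50)
        # with only 50 permutations the permutation p cannot go below 1/51 > 0.01
        assert res.wilcoxon_p < 0.01
        assert res.permutation_p >= 1 / 51
        assert not res.significant


class TestPermutationImplementation:
    def test_matches_bruteforce_shuffles(self, rng):
        a = rng.integers(1, 17, 60).astype(float)
        b = rng.integers(1, 17, 50).astype(float) + rng.integers(0, 2, 50)
        p_fast = permutation_mean_test(a, b, n_perm=4000, rng=np.random.default_rng(1))
        p_slow = permutation_mean_test_bruteforce(a, b, n_perm=4000, rng=np.random.default_rng(2))
        # both are MC estimates of the same permutation p-value
        se = np.sqrt(max(p_slow * (1 - p_slow), 0.01) / 4000)
        assert abs(p_fast - p_slow) < 5 * se + 1e-3

    def test_matches_exact_enumeration_tiny_n(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([9.0, 9.0, 16.0])
        t_obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            sel = np.zeros(6, dtype=bool)
            sel[list(idx)] = True
            t = abs(pooled[sel].mean() - pooled[~sel].mean())
            hits += t >= t_obs - 1e-12
            total += 1
        exact = hits / total
        p = permutation_mean_test(a, b, n_perm=20000, rng=np.random.default_rng(3))
        assert p == pytest.approx(exact, abs=0.02)

    def test_label_exchangeability(self, rng):
        a = rng.integers(1, 17, 120).astype(float)
        b = rng.integers(1, 17, 80).astype(float)
        ps_ab = [permutation_mean_test(a, b, 1000, np.random.default_rng(s)) for s in range(30)]
        ps_ba = [permutation_mean_test(b, a, 1000, np.random.default_rng(s)) for s in range(30, 60)]
        assert abs(np.mean(ps_ab) - np.mean(ps_ba)) < 0.05

    def test_chi2_alternative_sane(self):
        assert chi2_contingency_test(np.array([1] * 100), np.array([9] * 100)) < 1e-6
        assert chi2_contingency_test(np.array([1, 9] * 50), np.array([1, 9] * 50)) > 0.9


class TestPairedScreen:
    @staticmethod
    def screen_inputs(vectors: dict, subtypes: dict):
        cells = []
        for core, vec in vectors.items():
            df = make_cells([{} for _ in vec])
            df["core_id"] = core
            df["eph_ki67_class"] = vec
            cells.append(df)
        cells = pd.concat(cells, ignore_index=True)
        cells["cell_id"] = [f"c{i}" for i in range(len(cells))]
        meta = pd.DataFrame(
            [
                {"core_id": core, "case_id": f"case_{core[:-1]}", "subtype": subtypes[core]}
                for core in vectors
            ]
        )
        return cells, meta

    def test_one_null_one_disjoint_pair(self):
        vectors = {
            "p1a": [1, 2] * 100, "p1b": [1, 2] * 100,
            "p2a": [1] * 200, "p2b": [9] * 200,
        }
        subtypes = dict.fromkeys(vectors, "LumA")
        cells, meta = self.screen_inputs(vectors, subtypes)
        screen = run_paired_core_screen(cells, meta, n_perm=2000, seed=5)
        assert len(screen.results) == 2
        flags = {r.case_id: r.significant for r in screen.results}
        assert flags == {"case_p1": False, "case_p2": True}
        tally = screen.subtype_tally(meta)
        assert tally.loc[tally["subtype"] == "LumA", "n_cases"].iloc[0] == 2
        assert tally.loc[tally["subtype"] == "LumA", "n_significant"].iloc[0] == 1

    def test_discordant_subtype_case_tallied_under_both(self):
        vectors = {"d1a": [1] * 150, "d1b": [13] * 150}
        subtypes = {"d1a": "LumA", "d1b": "LumB"}
        cells, meta = self.screen_inputs(vectors, subtypes)
        screen = run_paired_core_screen(cells, meta, n_perm=2000, seed=5)
        tally = screen.subtype_tally(meta)
        assert set(tally["subtype"]) == {"LumA", "LumB"}
        assert (tally["n_cases"] == 1).all()

    def test_unpaired_cases_skipped(self):
        vectors = {"u1a": [1] * 50, "u1b": [1] * 50, "solo": [2] * 50}
        subtypes = dict.fromkeys(vectors, "TNBC")
        cells, meta = self.screen_inputs(vectors, subtypes)
        meta.loc[meta["core_id"] == "solo", "case_id"] = "case_solo"
        screen = run_paired_core_screen(cells, meta, n_perm=500, seed=1)
        assert len(screen.results) == 1


class TestAnova:
    def test_identical_groups(self):
        res = compare_groups_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        res = compare_groups_anova({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, abs=1e-9)

    def test_outlier_group_flagged_by_tukey(self, rng):
        groups = {
            "g1": rng.normal(0, 0.01, 20),
            "g2": rng.normal(0, 0.01, 20),
            "g3": rng.normal(10, 0.01, 20),
        }
        res = compare_groups_anova(groups)
        tk = res.tukey
        involving3 = tk[(tk["group1"] == "g3") | (tk["group2"] == "g3")]
        assert (involving3["p-adj"].astype(float) < 0.01).all()
        other = tk[(tk["group1"] != "g3") & (tk["group2"] != "g3")]
        assert (other["p-adj"].astype(float) > 0.01).all()

    def test_f_statistic_against_hand_formula(self):
        # 3 groups x 4 observations, computed with the textbook decomposition
        groups = {
            "a": np.array([4.0, 5.0, 6.0, 5.0]),
            "b": np.array([7.0, 8.0, 9.0, 8.0]),
            "c": np.array([4.0, 4.0, 5.0, 3.0]),
        }
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 9)
        res = compare_groups_anova(groups)
        assert res.f_statistic == pytest.approx(f_hand, abs=1e-9)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            compare_groups_anova({"only": [1.0, 2.0]})


class TestImmuneDensity:
    @staticmethod
    def cells_with_positivity(n, n_cd8, n_cd20, core_id="core1"):
        df = make_cells([{} for _ in range(n)])
        df["core_id"] = core_id
        df["pos_cd8"] = [True] * n_cd8 + [False] * (n - n_cd8)
        df["pos_cd20"] = [False] * (n - n_cd20) + [True] * n_cd20
        return df

    def test_ten_percent(self):
        out = immune_density(self.cells_with_positivity(100, 10, 0))
        assert out["cd8_density_pct"].iloc[0] == pytest.approx(10.0)
        assert out["cd20_density_pct"].iloc[0] == pytest.approx(0.0)

    def test_qc_failures_excluded_from_denominator(self):
        df = self.cells_with_positivity(100, 10, 5)
        df.loc[df.index[:20], "qc_pass"] = False  # 10 of the CD8+ are in here
        out = immune_density(df)
        assert out["n_cells"].iloc[0] == 80
        assert out["cd8_density_pct"].iloc[0] == pytest.approx(0.0)
        assert out["cd20_density_pct"].iloc[0] == pytest.approx(100 * 5 / 80)

    def test_binomial_recovery(self, rng):
        n = 2000
        df = make_cells([{} for _ in range(n)])
        df["pos_cd8"] = rng.random(n) < 0.05
        df["pos_cd20"] = False
        out = immune_density(df)
        assert out["cd8_density_pct"].iloc[0] == pytest.approx(5.0, abs=1.5)
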