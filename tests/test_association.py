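"""Chi-square and rank-sum layer, including the published-table reproduction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cnvland.array_io import ValidationError
from cnvland.association import (
    burden_by_group,
    cnv_phenotype_scan,
    pearson_chi2,
    wilcoxon_rank_sum,
)
from cnvland.pipeline import fixtures_tables
from cnvland.tables import CONTINGENCY_TABLES


class TestPearsonChi2:
    def test_hand_computed_2x2(self):
        chi2, df, p = pearson_chi2([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20 / 3)
        assert df == 1
        assert p == pytest.approx(9.82e-3, rel=1e-3)

    def test_proportional_rows_give_zero(self):
        chi2, df, p = pearson_chi2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_high_grade_loss_example(self):
        _, _, p = pearson_chi2([[15, 8, 4], [316, 38, 2]])
        assert p == pytest.approx(4.05e-10, rel=5e-3)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            pearson_chi2([[1.5, 2], [3, 4]])

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            pearson_chi2([[5, 5], [0, 0]])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_direct_formula_oracle(self, seed):
        """Agrees with an independent cell-by-cell computation (and scipy)
        to 1e-12 on random tables."""
        rng = np.random.default_rng(seed)
        r, c = rng.integers(2, 5, size=2)
        O = rng.integers(1, 60, size=(r, c)).astype(float)
        chi2, df, p = pearson_chi2(O)
        # brute-force oracle: expected counts cell by cell
        total = O.sum()
        brute = 0.0
        for i in range(r):
            for j in range(c):
                e = O[i].sum() * O[:, j].sum() / total
                brute += (O[i, j] - e) ** 2 / e
        assert abs(chi2 - brute) < 1e-12
        s_chi2, s_p, s_df, _ = sps.chi2_contingency(O, correction=False)
        assert abs(chi2 - s_chi2) < 1e-9 and abs(p - s_p) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_row_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        O = rng.integers(1, 40, size=(3, 3)).astype(float)
        chi2, _, _ = pearson_chi2(O)
        perm = O[rng.permutation(3)][:, rng.permutation(3)]
        chi2_p, _, _ = pearson_chi2(perm)
        assert chi2 == pytest.approx(chi2_p, abs=1e-10)


class TestPublishedTableReproduction:
    @pytest.mark.parametrize(
        "fixture", CONTINGENCY_TABLES,
        ids=[f"{f.region}-{f.phenotype}" for f in CONTINGENCY_TABLES],
    )
    def test_published_p_value_recovered(self, fixture):
        """No-continuity-correction chi-square on the published counts
        reproduces each published p-value at its printing precision."""
        _, _, p = pearson_chi2(np.array(fixture.counts))
        assert p == pytest.approx(fixture.published_p, rel=fixture.rel_tol)

    def test_fixture_runner_all_pass(self):
        df = fixtures_tables()
        assert df["pass"].all(), df[~df["pass"]]


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_full_enumeration(self):
        """DP-based exact null distribution equals brute-force enumeration of
        every rank assignment."""
        x = [0.1, 2.3, 3.1, 5.0]
        y = [1.2, 2.9, 4.4]
        w, p = wilcoxon_rank_sum(x, y)
        n, m = len(x), len(y)
        all_ranks = range(1, n + m + 1)
        mu = n * (n + m + 1) / 2
        dev = abs(w - mu)
        count = sum(
            1 for subset in itertools.combinations(all_ranks, n)
            if abs(sum(subset) - mu) >= dev - 1e-9
        )
        from math import comb
        assert p == count / comb(n + m, n)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 12, size=2)
        x = rng.normal(size=n)
        y = rng.normal(0.5, size=m)
        _, p = wilcoxon_rank_sum(x, y)
        sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(sp, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(20, 100).astype(float)
        y = rng.poisson(26, 120).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        sp = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(sp, rel=1e-9)

    def test_planted_shift_power(self):
        """Poisson(20) vs Poisson(40), n=100/group: p <= 0.01 in >= 95% of
        seeded replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            x = rng.poisson(20, 100).astype(float)
            y = rng.poisson(40, 100).astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            hits += p <= 0.01
        assert hits >= 0.95 * n_rep


def _carrier_frame(statuses, regions=("r1:loss",)):
    return pd.DataFrame({r: statuses for r in regions},
                        index=[f"P{i}" for i in range(len(statuses))])


def _clin_frame(values, column):
    idx = [f"P{i}" for i in range(len(values))]
    base = pd.DataFrame(index=pd.Index(idx, name="patient_id"))
    base[column] = values
    return base


class TestPhenotypeScan:
    def test_two_by_two_scan(self):
        statuses = ["loss"] * 12 + ["none"] * 48
        gender = (["male"] * 8 + ["female"] * 4) + (["male"] * 12 + ["female"] * 36)
        cm = _carrier_frame(statuses)
        clin = _clin_frame(gender, "gender")
        results = cnv_phenotype_scan(cm, clin, "gender")
        assert len(results) == 1
        r = results[0]
        assert r.table.loc["loss", "male"] == 8
        expected = pearson_chi2([[4, 8], [36, 12]])[2]
        assert r.p == pytest.approx(expected)

    def test_single_status_region_skipped(self):
        cm = _carrier_frame(["none"] * 20)
        clin = _clin_frame(["male"] * 10 + ["female"] * 10, "gender")
        assert cnv_phenotype_scan(cm, clin, "gender") == []

    def test_missing_phenotype_level_rejected(self):
        cm = _carrier_frame(["loss"] * 5 + ["none"] * 5)
        clin = _clin_frame(["female"] * 10, "gender")
        with pytest.raises(ValidationError, match="no patients"):
            cnv_phenotype_scan(cm, clin, "gender")


class TestBurdenByGroup:
    def _burden(self, counts):
        idx = [f"P{i}" for i in range(len(counts))]
        df = pd.DataFrame({"n_cnvs": counts}, index=pd.Index(idx, name="sample_id"))
        for b in ("<500 kb", "500-1,000 kb", "1-5 Mb", ">5 Mb"):
            df[f"n_{b}"] = 0
        return df

    def test_identical_burdens_p_one(self):
        burden = self._burden([5, 5, 7, 7, 9, 9])
        clin = _clin_frame(["female", "male"] * 3, "gender")
        res = burden_by_group(burden, clin, "gender")
        assert res.p == 1.0

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(11)
        counts = np.concatenate([rng.poisson(20, 80), rng.poisson(45, 80)])
        burden = self._burden(counts)
        # a token grade III patient so every level is observed
        burden.loc["P160"] = 0
        clin = _clin_frame(["I"] * 80 + ["II"] * 80 + ["III"], "who_grade")
        res = burden_by_group(burden, clin, "who_grade")
        assert res.p <= 0.01
        assert ("I", "II") in res.pairwise

    def test_empty_size_bin_reported_not_applicable(self):
        burden = self._burden([3, 4, 5, 6])
        clin = _clin_frame(["no", "no", "yes", "yes"], "edema")
        res = burden_by_group(burden, clin, "edema")
        assert res.size_bin_results[">5 Mb"] is None
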