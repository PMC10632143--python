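"""Genotyping thresholds, germline/overdispersion filters, DBS merging."""

import numpy as np
import pytest
from scipy.stats import betabinom, binom, fisher_exact

from microclone.core import MutationCall
from microclone.filtering import (
    RHO_GRID,
    binom_test_two_sided,
    estimate_sensitivity,
    filter_calls,
    genotype_mutations,
    germline_filter,
    merge_dbs,
    rho_filter,
)
from tests.conftest import make_matrix


def germline_oracle(alt, depth, p0=0.5):
    """Brute-force two-sided exact binomial on pooled counts."""
    x, n = int(sum(alt)), int(sum(depth))
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return pmf[pmf <= pmf[x] * (1 + 1e-7)].sum()


def rho_oracle(alt, depth):
    """Direct beta-binomial grid search via scipy's betabinom.

    The mean is profiled over the same two candidates as the
    implementation (pooled VAF; mean VAF of alt-bearing samples), but the
    likelihood itself is evaluated independently through scipy.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    pooled = sum(alt) / sum(depth)
    carriers = alt > 0
    if carriers.any():
        carrier_mean = np.mean(alt[carriers] / depth[carriers])
    else:
        carrier_mean = pooled
    best, best_ll = None, -np.inf
    for mu in (np.clip(pooled, 1e-3, 1 - 1e-3),
               np.clip(carrier_mean, 1e-3, 1 - 1e-3)):
        for rho in RHO_GRID:
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            ll = sum(
                betabinom.logpmf(x, n, a, b)
                for x, n in zip(alt, depth) if n > 0
            )
            if ll > best_ll:
                best_ll, best = ll, rho
    return best


class TestGenotyping:
    @pytest.mark.parametrize(
        "alt, depth, kept",
        [
            ([[3]], [[4]], True),        # threshold boundary: 3 alt at depth 4
            ([[2, 2, 2]], [[50, 50, 50]], False),
            ([[0, 0, 0]], [[60, 60, 60]], False),
            ([[3]], [[3]], False),       # depth below 4
        ],
    )
    def test_support_threshold(self, alt, depth, kept):
        m = make_matrix(alt, depth)
        assert genotype_mutations(m)[0] == kept


class TestGermlineFilter:
    def test_exact_vaf_half_is_germline(self):
        m = make_matrix([[25, 26, 24]], [[50, 50, 50]])
        res = germline_filter(m)
        assert res["germline_q"].iloc[0] > 0.5
        assert bool(res["germline"].iloc[0])

    def test_clonal_mutation_rejected(self):
        m = make_matrix([[20, 0, 0]], [[40, 50, 60]])
        res = germline_filter(m)
        assert res["germline_q"].iloc[0] < 1e-3
        assert not bool(res["germline"].iloc[0])
        assert res["germline_p"].iloc[0] == pytest.approx(
            germline_oracle([20, 0, 0], [40, 50, 60])
        )

    def test_male_sex_chromosome_uses_p95(self):
        m = make_matrix([[48]], [[50]], chrom="chrX")
        assert bool(germline_filter(m, sex="male")["germline"].iloc[0])
        # the same counts on an autosome are far from VAF 0.5
        m2 = make_matrix([[48]], [[50]], chrom="chr1")
        assert not bool(germline_filter(m2, sex="male")["germline"].iloc[0])

    def test_zero_pooled_depth_is_low_support(self):
        m = make_matrix([[0, 0]], [[0, 0]])
        res = germline_filter(m)
        assert bool(res["low_support"].iloc[0])

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = rng.integers(1, 21)
            depth = rng.integers(0, 11, size=s)  # pooled depth ≤ 200
            alt = rng.binomial(depth, rng.uniform(0, 1))
            if depth.sum() == 0:
                continue
            m = make_matrix([alt], [depth])
            mine = germline_filter(m)["germline_p"].iloc[0]
            assert mine == pytest.approx(germline_oracle(alt, depth), abs=1e-12)

    def test_bh_q_monotone_in_p(self):
        rows = [[i, 0, 0] for i in range(0, 25, 2)]
        deps = [[50, 50, 50]] * len(rows)
        res = germline_filter(make_matrix(rows, deps))
        order = res.sort_values("germline_p")
        assert order["germline_q"].is_monotonic_increasing


class TestRhoFilter:
    def test_even_low_vaf_spread_is_artifact(self):
        m = make_matrix([[2] * 20], [[50] * 20])
        res = rho_filter(m)
        assert res["rho_hat"].iloc[0] == pytest.approx(RHO_GRID[0])
        assert bool(res["artifact"].iloc[0])

    def test_present_absent_pattern_is_somatic(self):
        m = make_matrix([[20] + [0] * 19], [[50] * 20])
        res = rho_filter(m)
        assert res["rho_hat"].iloc[0] > 0.1
        assert not bool(res["artifact"].iloc[0])

    def test_rho_never_leaves_grid(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(1, 100, size=(30, 8))
        alt = rng.binomial(depth, rng.uniform(0, 0.6, size=(30, 1)))
        res = rho_filter(make_matrix(alt, depth))
        assert res["rho_hat"].between(1e-6, 10 ** -0.05).all()

    def test_matches_grid_ml_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            s = rng.integers(2, 12)
            depth = rng.integers(0, 60, size=s)
            if depth.sum() == 0:
                continue
            alt = rng.binomial(depth, rng.uniform(0, 0.5))
            mine = rho_filter(make_matrix([alt], [depth]))["rho_hat"].iloc[0]
            assert mine == pytest.approx(rho_oracle(alt, depth))


class TestVerdictPartition:
    def test_every_mutation_gets_exactly_one_verdict(self):
        rng = np.random.default_rng(3)
        depth = rng.integers(0, 80, size=(50, 10))
        alt = rng.binomial(depth, rng.uniform(0, 0.6, size=(50, 1)))
        res = filter_calls(make_matrix(alt, depth))
        assert res["verdict"].isin(
            ["somatic", "germline", "artifact", "low_support"]
        ).all()
        assert len(res) == 50


class TestMergeDbs:
    def _setup(self, alt2, dep2):
        calls = [
            MutationCall("chr1", 100, "C", "T"),
            MutationCall("chr1", 101, "C", "T"),
        ]
        m = make_matrix([[20], [alt2]], [[50], [dep2]])
        m.mutations = calls
        return calls, m

    def test_similar_counts_merge(self):
        calls, m = self._setup(22, 51)
        assert fisher_exact([[20, 30], [22, 29]])[1] >= 0.05
        merged = merge_dbs(calls, m)
        assert len(merged) == 1 and merged[0].mut_class == "DBS"
        assert merged[0].ref == "CC" and merged[0].alt == "TT"

    def test_dissimilar_counts_do_not_merge(self):
        calls, m = self._setup(2, 50)
        assert fisher_exact([[20, 30], [2, 48]])[1] < 0.05
        assert len(merge_dbs(calls, m)) == 2

    def test_non_adjacent_never_merge(self):
        calls = [
            MutationCall("chr1", 100, "C", "T"),
            MutationCall("chr1", 102, "C", "T"),
        ]
        m = make_matrix([[20], [20]], [[50], [50]])
        m.mutations = calls
        assert len(merge_dbs(calls, m)) == 2

    def test_triple_merges_greedily_left_to_right(self):
        calls = [MutationCall("chr1", 100 + i, "C", "T") for i in range(3)]
        m = make_matrix([[20]] * 3, [[50]] * 3)
        m.mutations = calls
        merged = merge_dbs(calls, m)
        assert [c.mut_class for c in merged] == ["DBS", "SBS"]
        assert merged[0].pos == 100 and merged[1].pos == 102


class TestSensitivity:
    def test_identical_and_disjoint_sets(self):
        assert estimate_sensitivity([({"a", "b"}, {"a", "b"})])["median"] == 1.0
        assert estimate_sensitivity([({"a"}, {"b"})])["median"] == 0.0

    def test_empty_member_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty member"):
            res = estimate_sensitivity([(set(), {"a"}), ({"a"}, {"a"})])
        assert res["per_pair"] == [1.0]
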