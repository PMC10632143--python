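"""The synthetic cohort generator: determinism, conservation, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microclone.synthetic import (
    PROCESSES,
    SimulationConfig,
    emit_reads,
    simulate_clone_burdens,
    simulate_cohort,
    simulate_genic_mutations,
    simulate_replicate_pairs,
    spike_contaminants,
    make_toy_annotation,
)


SMALL = dict(n_patients=4, rng_seed=7)


class TestSimulateCohort:
    def test_same_seed_gives_identical_cohorts(self):
        _, t1 = simulate_cohort(SimulationConfig(**SMALL))
        _, t2 = simulate_cohort(SimulationConfig(**SMALL))
        pd.testing.assert_frame_equal(t1.mutations, t2.mutations)
        pd.testing.assert_frame_equal(t1.cf, t2.cf)

    def test_every_mutation_has_one_truth_record(self):
        _, truth = simulate_cohort(SimulationConfig(**SMALL))
        assert truth.mutations["mut_id"].is_unique
        assert truth.mutations["clone_id"].isin(truth.clones.index).all()
        # conservation: mutation rows match the clone burden table
        per_clone = truth.mutations.groupby("clone_id").size()
        assert (
            per_clone.reindex(truth.clones.index, fill_value=0)
            == truth.clones["total"]
        ).all()

    def test_clone_fractions_feasible(self):
        _, truth = simulate_cohort(SimulationConfig(**SMALL))
        top = truth.clones[truth.clones["parent"].isna()].index
        occupancy = truth.cf.loc[top].fillna(0.0)
        by_sample = occupancy.groupby(
            truth.clones.loc[top, "biopsy_id"].values
        ).sum()
        assert (by_sample.to_numpy() <= 1.0 + 1e-9).all()

    def test_nested_child_cf_below_parent(self):
        _, truth = simulate_cohort(SimulationConfig(**SMALL))
        nested = truth.clones[truth.clones["parent"].notna()]
        for cid, row in nested.iterrows():
            child = truth.cf.loc[cid].fillna(0)
            parent = truth.cf.loc[row["parent"]].fillna(0)
            assert (child <= parent + 1e-9).all()

    def test_single_full_clone_gives_vaf_half(self):
        cfg = SimulationConfig(
            n_patients=1, biopsies_per_patient=1, microbiopsies_per_biopsy=1,
            mean_clones_per_microbiopsy=1.0, base_cf_alpha=1e6, base_cf_beta=1.0,
            nest_prob=0.0, rng_seed=1,
        )
        cohort, truth = simulate_cohort(cfg)
        m = emit_reads(truth, 1000, cohort, "P001", np.random.default_rng(0))
        vaf = np.nanmean(m.vaf())
        assert vaf == pytest.approx(0.5, abs=0.02)

    def test_median_microbiopsy_vaf_in_oligoclonal_range(self):
        cfg = SimulationConfig(n_patients=6, rng_seed=2)
        cohort, truth = simulate_cohort(cfg)
        rng = np.random.default_rng(3)
        medians = []
        for pat in cohort.patients:
            m = emit_reads(truth, cfg.mean_depth, cohort, pat.patient_id, rng)
            v = m.vaf()
            det = (m.alt >= 3) & (m.depth >= 4)
            for j in range(m.shape[1]):
                if det[:, j].any():
                    medians.append(np.median(v[det[:, j], j]))
        assert 0.1 <= np.median(medians) <= 0.5

    def test_mean_clone_burden_tracks_age_effect(self):
        # law of large numbers on the generator's linear burden model
        cfg = SimulationConfig(
            n_patients=60, age_range=(50.0, 50.0), duration_max=0.0,
            puva_band_probs=(1.0, 0, 0, 0), nonpuva_psoralen_rate=0.0,
            apobec_clone_rate=0.0, rng_seed=5,
        )
        bd = simulate_clone_burdens(cfg)
        expected = cfg.burden_intercept + cfg.clock_intercept + cfg.age_effect * 50.0
        se = bd["total"].std() / np.sqrt(len(bd))
        assert abs(bd["total"].mean() - expected) < 3 * se + 1.0


class TestEmitReads:
    def test_absent_mutation_has_zero_alt(self):
        cfg = SimulationConfig(**SMALL)
        cohort, truth = simulate_cohort(cfg)
        pat = cohort.patients[0].patient_id
        m = emit_reads(truth, 56, cohort, pat, np.random.default_rng(0))
        cf = truth.cf.reindex(
            truth.mutations.loc[truth.mutations.patient_id == pat, "clone_id"]
        )[m.samples].to_numpy()
        absent = np.nan_to_num(cf, nan=0.0) == 0.0
        assert (m.alt[absent] == 0).all()

    def test_vaf_distribution_matches_binomial(self):
        # KS check of alt counts against Binomial(depth, CF/2) at fixed depth
        from microclone.core import CountMatrix, MutationCall
        from microclone.synthetic import CloneTruthSet, Cohort
        from microclone.core import Microbiopsy, Patient

        n = 10_000
        cohort = Cohort(
            patients=[Patient("P001", 50.0)],
            microbiopsies=[Microbiopsy("P001_b1_m1", "P001", "P001_b1")],
        )
        muts = pd.DataFrame(
            {
                "mut_id": range(n), "clone_id": "c1", "patient_id": "P001",
                "process": "SBS7b-like", "class96": 0, "chrom": "chr1",
                "pos": np.arange(1, n + 1), "ref": "C", "alt": "A",
                "flag": "somatic",
            }
        )
        cf = pd.DataFrame({"P001_b1_m1": [0.6]}, index=pd.Index(["c1"]))
        truth = CloneTruthSet(clones=pd.DataFrame(index=["c1"]), cf=cf, mutations=muts)
        m = emit_reads(truth, 100, cohort, "P001", np.random.default_rng(9))
        fixed = m.depth[:, 0] == 100
        obs = m.alt[fixed, 0]
        # chi-square goodness of fit against Binomial(100, 0.3), pooled tails
        lo, hi = 18, 43  # ±~4 SD around the mean
        edges = np.arange(lo, hi + 1)
        expected = stats.binom.pmf(edges, 100, 0.3)
        expected = np.concatenate(
            [[stats.binom.cdf(lo - 1, 100, 0.3)], expected,
             [stats.binom.sf(hi, 100, 0.3)]]
        ) * len(obs)
        counts = np.concatenate(
            [[np.sum(obs < lo)],
             [np.sum(obs == k) for k in edges],
             [np.sum(obs > hi)]]
        )
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.01


class TestSpikes:
    def test_zero_rates_leave_matrix_unchanged(self, mk_matrix):
        m = mk_matrix([[5, 6]], [[20, 20]])
        m2, flags = spike_contaminants(m, 0.0, 0.0)
        assert m2 is m and list(flags) == ["somatic"]

    def test_germline_spike_near_half_in_all_samples(self, mk_matrix):
        m = mk_matrix([[0] * 20] * 40, [[50] * 20] * 40)
        m2, flags = spike_contaminants(m, 0.5, 0.0, rng=np.random.default_rng(0))
        germ = np.flatnonzero(flags == "germline")
        vafs = m2.vaf()[germ]
        assert np.nanmean(vafs) == pytest.approx(0.5, abs=0.02)

    def test_artifact_spike_has_low_vaf_everywhere(self, mk_matrix):
        m = mk_matrix([[0] * 20] * 40, [[60] * 20] * 40)
        m2, flags = spike_contaminants(m, 0.0, 0.5, rng=np.random.default_rng(1))
        art = np.flatnonzero(flags == "artifact")
        vafs = m2.vaf()[art]
        assert np.nanmax(vafs) < 0.3

    def test_row_conservation(self, mk_matrix):
        m = mk_matrix([[1, 2]] * 10, [[9, 9]] * 10)
        m2, flags = spike_contaminants(m, 0.2, 0.1, rng=np.random.default_rng(2))
        assert m2.shape[0] == 10 + 2 + 1 == len(flags)


class TestReplicatePairs:
    def test_sensitivity_one_gives_identical_pairs(self):
        pairs = simulate_replicate_pairs(5, 1.0, rng=np.random.default_rng(0))
        assert all(a == b for a, b in pairs)

    def test_shared_fraction_matches_sensitivity(self):
        pairs = simulate_replicate_pairs(
            200, 0.89, n_mutations=400, rng=np.random.default_rng(1)
        )
        fracs = [len(a & b) / len(a) for a, b in pairs]
        assert np.mean(fracs) == pytest.approx(0.89, abs=0.01)

    def test_zero_pairs_empty(self):
        assert simulate_replicate_pairs(0, 0.9) == []


class TestGenicMutations:
    def test_symmetric_generator_has_equal_strand_counts(self, toy_annotation):
        muts = simulate_genic_mutations(
            toy_annotation, 4000, strand_asymmetry_tpa=1.0,
            leading_lagging_ratio=1.0, rng=np.random.default_rng(0),
        )
        genic = muts[muts.region == "genic"]
        on_untx = (genic.t_strand == genic.gene_strand).sum()
        p = stats.binomtest(on_untx, len(genic), 0.5).pvalue
        assert p > 0.01

    def test_asymmetry_recovered(self, toy_annotation):
        muts = simulate_genic_mutations(
            toy_annotation, 30_000, strand_asymmetry_tpa=2.0,
            leading_lagging_ratio=1.0, rng=np.random.default_rng(1),
        )
        genic = muts[muts.region == "genic"]
        untx = (genic.t_strand == genic.gene_strand).sum()
        assert untx / (len(genic) - untx) == pytest.approx(2.0, rel=0.05)

    def test_zero_expression_effect_is_flat(self, toy_annotation):
        from microclone.strand import expression_decile_rates

        muts = simulate_genic_mutations(
            toy_annotation, 20_000, expression_effect=0.0,
            strand_asymmetry_tpa=1.0, leading_lagging_ratio=1.0,
            timing_effect=1.0, rng=np.random.default_rng(2),
        )
        rates = expression_decile_rates(muts, toy_annotation)["relative_rate"]
        assert rates.max() / rates.min() < 1.25

    def test_nonpositive_n_gives_empty(self, toy_annotation):
        assert len(simulate_genic_mutations(toy_annotation, 0)) == 0
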