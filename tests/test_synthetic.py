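"""The synthetic cohort generator: determinism, conservation, ground truth."""

import numpy as np
import pytest

from sigspec.catalog import MutationRecord, build_catalog
from sigspec.motifs import MOTIF_ORDER, parse_motif_label, motif_index
from sigspec.synthetic import (
    CancerProfile,
    emit_maf,
    make_benchmark_scenario,
    make_reference_signatures,
    simulate_cohort,
)


class TestReferenceSignatures:
    def test_single_signature_valid(self):
        sig = make_reference_signatures(1, seed=0)
        assert sig.profiles.shape == (96, 1)
        assert sig.profiles[:, 0].sum() == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        a = make_reference_signatures(6, seed=5)
        b = make_reference_signatures(6, seed=5)
        np.testing.assert_array_equal(a.profiles, b.profiles)

    @pytest.mark.parametrize("seed", range(20))
    def test_pairwise_cosines_below_cap(self, seed):
        sig = make_reference_signatures(10, sparsity_concentration=0.1, seed=seed)
        U = sig.profiles / np.linalg.norm(sig.profiles, axis=0)
        gram = U.T @ U
        off = gram[~np.eye(10, dtype=bool)]
        assert off.max() < 0.9

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            make_reference_signatures(0)


class TestSimulateCohort:
    def test_column_sums_equal_drawn_burdens(self, small_signatures):
        prof = CancerProfile("AAA", np.full(5, 0.5), n_mut_mean=300)
        cat, truth = simulate_cohort([prof], small_signatures, 15, seed=1)
        np.testing.assert_allclose(
            cat.counts.sum(axis=0), truth.exposures.values.sum(axis=0), rtol=1e-9
        )
        assert (cat.counts.sum(axis=0) >= 50).all()  # minimum burden

    def test_deterministic_under_seed(self, small_signatures):
        prof = CancerProfile("AAA", np.full(5, 0.5), n_mut_mean=300)
        a = simulate_cohort([prof], small_signatures, 10, seed=2)
        b = simulate_cohort([prof], small_signatures, 10, seed=2)
        np.testing.assert_array_equal(a[0].counts, b[0].counts)
        np.testing.assert_array_equal(a[1].exposures.values, b[1].exposures.values)

    def test_single_always_active_signature_lln(self, small_signatures):
        # with one signature at activity 1, catalog columns converge to its profile
        prof = CancerProfile(
            "AAA", np.array([1.0, 0, 0, 0, 0]), n_mut_mean=100_000, n_mut_dispersion=50
        )
        cat, truth = simulate_cohort([prof], small_signatures, 3, seed=3)
        profile = small_signatures.profiles[:, 0]
        for j in range(3):
            col = cat.counts[:, j] / cat.counts[:, j].sum()
            cos = col @ profile / (np.linalg.norm(col) * np.linalg.norm(profile))
            assert cos > 0.99
        assert (truth.exposures.values[1:, :] == 0).all()

    def test_empty_active_set_forced_to_top_signature(self, small_signatures):
        prof = CancerProfile("AAA", np.array([0.0, 1e-12, 0, 0, 0]), n_mut_mean=100)
        cat, truth = simulate_cohort([prof], small_signatures, 5, seed=4)
        assert (truth.exposures.values.sum(axis=0) > 0).all()
        # only the forced signature can be active
        assert (truth.exposures.values[[0, 2, 3, 4], :] == 0).all()

    def test_labels_align_with_samples(self, small_cohort):
        cat, truth = small_cohort
        assert truth.labels.sample_ids == cat.sample_ids
        assert set(truth.labels.table["cancer_type"]) == {"AAA", "BBB"}


class TestEmitMaf:
    def test_round_trip_reproduces_catalog(self, small_cohort):
        cat, _ = small_cohort
        df = emit_maf(cat, seed=5)
        records = [
            MutationRecord(r.sample, r.chromosome, int(r.position), r.ref, r.alt, r.context)
            for r in df.itertuples()
        ]
        rebuilt, skipped = build_catalog(records)
        assert skipped == 0
        assert rebuilt.sample_ids == cat.sample_ids
        np.testing.assert_array_equal(rebuilt.counts, cat.counts)

    def test_purine_rows_have_consistent_context_and_both_strands_used(self, small_cohort):
        cat, _ = small_cohort
        df = emit_maf(cat, seed=6)
        purine = df[df.ref.isin(["A", "G"])]
        assert 0.3 < len(purine) / len(df) < 0.7  # roughly half strand-flipped
        assert (purine.context.str[1] == purine.ref).all()

    def test_motif_census_equals_catalog(self, small_cohort):
        cat, _ = small_cohort
        df = emit_maf(cat, seed=7)
        census = np.zeros((96, cat.n_samples), dtype=int)
        pos = {s: j for j, s in enumerate(cat.sample_ids)}
        from sigspec.catalog import classify_mutation

        for r in df.itertuples():
            m = classify_mutation(
                MutationRecord(r.sample, r.chromosome, int(r.position), r.ref, r.alt, r.context)
            )
            census[motif_index(m), pos[r.sample]] += 1
        np.testing.assert_array_equal(census, cat.counts)


class TestScenarios:
    def test_same_seed_identical_bundles(self):
        a = make_benchmark_scenario("null_identical_types", seed=8, n_per_type=5, n_mut_mean=200)
        b = make_benchmark_scenario("null_identical_types", seed=8, n_per_type=5, n_mut_mean=200)
        np.testing.assert_array_equal(a.train_catalog.counts, b.train_catalog.counts)
        np.testing.assert_array_equal(a.test_catalog.counts, b.test_catalog.counts)
        np.testing.assert_array_equal(a.signatures.profiles, b.signatures.profiles)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_benchmark_scenario("nope", seed=0)

    def test_skcm_analogue_structure(self):
        bundle = make_benchmark_scenario("specific_skcm_analogue", seed=9, n_per_type=5,
                                          n_mut_mean=200)
        skcm = next(p for p in bundle.profiles if p.cancer_type == "SKCM")
        others = [p for p in bundle.profiles if p.cancer_type != "SKCM"]
        assert skcm.activity_prob[0] == pytest.approx(0.95)
        assert all(p.activity_prob[0] == 0 for p in others)
        # train is US-only, test regions differ
        assert set(bundle.train_truth.labels.table["region"]) == {"US"}
        assert "US" not in set(bundle.test_truth.labels.table["region"])

    def test_null_scenario_profiles_identical(self):
        bundle = make_benchmark_scenario("null_identical_types", seed=10, n_per_type=5,
                                          n_mut_mean=200)
        probs = [p.activity_prob for p in bundle.profiles]
        for p in probs[1:]:
            np.testing.assert_array_equal(p, probs[0])

    def test_config_echo_regenerates(self, small_signatures):
        prof = CancerProfile("AAA", np.full(5, 0.5), n_mut_mean=300)
        cat, truth = simulate_cohort([prof], small_signatures, 6, seed=11)
        echo = truth.config["profiles"][0]
        prof2 = CancerProfile(
            echo["cancer_type"],
            np.array(echo["activity_prob"]),
            exposure_shape=echo["exposure_shape"],
            exposure_scale=np.array(echo["exposure_scale"]),
            n_mut_mean=echo["n_mut_mean"],
            n_mut_dispersion=echo["n_mut_dispersion"],
        )
        cat2, _ = simulate_cohort([prof2], small_signatures, truth.config["n_per_type"],
                                  seed=truth.seed)
        np.testing.assert_array_equal(cat.counts, cat2.counts)
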