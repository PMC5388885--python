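"""Reference-database model: CRB indexing, sampling, classification,
identification, threshold scans, curve fits and worked arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodekit.errors import CRBBuildError
from barcodekit.refmodel import (
    IRBSample,
    build_crb,
    classify_barcodes,
    coverage_projection,
    default_threshold_grid,
    filter_by_length,
    fit_decay_curve,
    identify,
    percent_identity,
    relabel_by_genus,
    run_irb_size_experiment,
    sample_ess,
    sample_irb,
    scan_thresholds,
    shared_overlap,
)
from barcodekit.seqio import BarcodeRecord
from barcodekit.synth import SynthConfig, random_sequence, simulate_crb


def _rec(species, specimen, locus, seq):
    return BarcodeRecord(species, specimen, locus, seq)


class TestBuildCrb:
    def test_combined_locus_materialized(self):
        records = []
        for i in range(3):
            records.append(_rec(f"Sp a{i}", f"s{i}", "rbcL", "ACGT" * 5))
            records.append(_rec(f"Sp a{i}", f"s{i}", "matK", "TTGG" * 5))
        crb = build_crb(records)
        assert "rbcL+matK" in crb.loci
        assert len(crb.barcode_index["rbcL+matK"]) == 1
        combined = crb.record_for("s0", "rbcL+matK")
        assert combined.sequence == "ACGT" * 5 + "TTGG" * 5

    def test_specimen_missing_matk_excluded_from_combined(self):
        records = [
            _rec("Sp a", "s0", "rbcL", "ACGT"),
            _rec("Sp a", "s0", "matK", "TTGG"),
            _rec("Sp b", "s1", "rbcL", "ACGA"),
        ]
        crb = build_crb(records)
        assert crb.record_for("s1", "rbcL+matK") is None
        assert crb.record_for("s0", "rbcL+matK") is not None
        assert crb.record_for("s1", "rbcL") is not None

    def test_shared_sequence_indexed_to_both_species(self, tiny_crb):
        assert tiny_crb.barcode_index["rbcL"]["ACGTACGTAC"] == {
            "Aster alpha",
            "Aster beta",
        }

    def test_duplicate_specimen_locus_raises(self):
        records = [
            _rec("Sp a", "s0", "rbcL", "ACGT"),
            _rec("Sp b", "s0", "rbcL", "ACGA"),
        ]
        with pytest.raises(CRBBuildError):
            build_crb(records)


class TestSampling:
    def test_irb_with_all_species(self, tiny_crb):
        rng = np.random.default_rng(0)
        irb = sample_irb(tiny_crb, 3, rng)
        assert irb.species() == set(tiny_crb.species)

    def test_irb_single_species(self, tiny_crb):
        irb = sample_irb(tiny_crb, 1, np.random.default_rng(0))
        assert len(irb.species()) == 1

    def test_irb_deterministic_under_seed(self, tiny_crb):
        a = sample_irb(tiny_crb, 2, np.random.default_rng(42))
        b = sample_irb(tiny_crb, 2, np.random.default_rng(42))
        assert a.records == b.records

    def test_irb_too_many_species_raises(self, tiny_crb):
        with pytest.raises(ValueError):
            sample_irb(tiny_crb, 4, np.random.default_rng(0))

    def test_ess_retains_duplicates_and_labels(self, tiny_crb):
        ess = sample_ess(tiny_crb, 3, np.random.default_rng(1))
        assert len(ess.samples) >= 3
        specimens = {s for s, _ in ess.samples}
        assert specimens <= set(tiny_crb.specimens)
        ess1 = sample_ess(tiny_crb, 1, np.random.default_rng(5))
        assert len({sp for _, sp in ess1.samples}) == 1

    def test_ess_deterministic_under_seed(self, tiny_crb):
        a = sample_ess(tiny_crb, 2, np.random.default_rng(7))
        b = sample_ess(tiny_crb, 2, np.random.default_rng(7))
        assert a.samples == b.samples


def brute_force_classification(irb_records, crb_records, locus):
    """Nested-loop reference implementation grouping sequences by species sets."""
    irb = [r for r in irb_records if r.locus == locus]
    crb = [r for r in crb_records if r.locus == locus]
    seqs = []
    for r in irb:
        if r.sequence not in seqs:
            seqs.append(r.sequence)
    n_perc = n_amb = n_false = 0
    for seq in seqs:
        irb_species = []
        for r in irb:
            if r.sequence == seq and r.species not in irb_species:
                irb_species.append(r.species)
        crb_species = []
        for r in crb:
            if r.sequence == seq and r.species not in crb_species:
                crb_species.append(r.species)
        if len(irb_species) == 1:
            n_perc += 1
            if len(crb_species) > 1:
                n_false += 1
        else:
            n_amb += 1
    n = len(seqs)
    return 100.0 * n_perc / n, 100.0 * n_amb / n, 100.0 * n_false / n


class TestClassifyBarcodes:
    def test_hand_enumerated_shared_barcode(self, tiny_crb):
        irb = IRBSample(
            n_species=2,
            records=[
                tiny_crb.record_for("A1", "rbcL"),
                tiny_crb.record_for("C1", "rbcL"),
            ],
        )
        s = classify_barcodes(irb, tiny_crb, "rbcL")
        assert s.n_barcodes == 2
        assert s.pct_perceived == 100.0
        assert s.pct_ambiguous == 0.0
        assert s.pct_false == 50.0  # X is shared with Aster beta in the CRB

    def test_full_irb_has_no_false_uniques(self, tiny_crb):
        irb = IRBSample(n_species=3, records=list(tiny_crb.records))
        s = classify_barcodes(irb, tiny_crb, "rbcL")
        assert s.pct_false == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        cfg = SynthConfig(
            n_species=8,
            variants_per_species=1,
            loci={"rbcL": 40},
            d_inter=0.05,
            p_share=0.3,
            rng_seed=seed,
        )
        crb, _ = simulate_crb(cfg)
        rng = np.random.default_rng(seed + 100)
        irb = sample_irb(crb, 4, rng)
        s = classify_barcodes(irb, crb, "rbcL")
        expected = brute_force_classification(irb.records, crb.records, "rbcL")
        assert (s.pct_perceived, s.pct_ambiguous, s.pct_false) == pytest.approx(
            expected
        )

    def test_partition_and_false_subset(self):
        cfg = SynthConfig(n_species=20, loci={"rbcL": 60}, p_share=0.2, rng_seed=3)
        crb, _ = simulate_crb(cfg)
        irb = sample_irb(crb, 10, np.random.default_rng(0))
        s = classify_barcodes(irb, crb, "rbcL")
        assert s.pct_perceived + s.pct_ambiguous == pytest.approx(100.0)
        assert s.pct_false <= s.pct_perceived


class TestIdentify:
    def test_shared_barcode_query_is_perceived_but_false(self, tiny_crb):
        irb = IRBSample(
            n_species=2,
            records=[
                tiny_crb.record_for("A1", "rbcL"),
                tiny_crb.record_for("C1", "rbcL"),
            ],
        )
        from barcodekit.refmodel import ESSQuerySet

        ess = ESSQuerySet(samples=[("A1", "Aster alpha")], n_species=1)
        s = identify(ess, irb, tiny_crb, "rbcL")
        assert s.pct_perceived == 100.0 and s.pct_false == 100.0

    def test_absent_sequence_is_unknown(self, tiny_crb):
        irb = IRBSample(n_species=1, records=[tiny_crb.record_for("A1", "rbcL")])
        from barcodekit.refmodel import ESSQuerySet

        ess = ESSQuerySet(samples=[("C1", "Carex gamma")], n_species=1)
        s = identify(ess, irb, tiny_crb, "rbcL")
        assert s.pct_unknown == 100.0

    def test_complete_irb_has_no_unknowns_or_false(self):
        cfg = SynthConfig(
            n_species=15, variants_per_species=1, loci={"rbcL": 80}, rng_seed=2
        )
        crb, _ = simulate_crb(cfg)
        irb = IRBSample(n_species=15, records=list(crb.records))
        ess = sample_ess(crb, 10, np.random.default_rng(4))
        s = identify(ess, irb, crb, "rbcL")
        assert s.pct_unknown == 0.0
        assert s.pct_false == 0.0

    def test_identification_partition(self):
        cfg = SynthConfig(n_species=20, loci={"rbcL": 80}, p_share=0.2, rng_seed=6)
        crb, _ = simulate_crb(cfg)
        rng = np.random.default_rng(1)
        irb = sample_irb(crb, 8, rng)
        ess = sample_ess(crb, 12, rng)
        for mode, t in (("exact", None), ("threshold", 99.0)):
            s = identify(ess, irb, crb, "rbcL", mode=mode, threshold=t)
            assert s.pct_perceived + s.pct_ambiguous + s.pct_unknown == pytest.approx(
                100.0
            )
            assert s.pct_true + s.pct_false == pytest.approx(s.pct_perceived)

    def test_threshold_identity_arithmetic(self):
        # a 1,000-base query one substitution away: identity 99.9
        base = random_sequence(1000, np.random.default_rng(0))
        variant = ("A" if base[0] != "A" else "C") + base[1:]
        crb = build_crb(
            [
                _rec("Sp a", "s0", "rbcL", base),
                _rec("Sp b", "s1", "rbcL", random_sequence(1000, np.random.default_rng(9))),
            ],
            combine=None,
        )
        irb = IRBSample(n_species=1, records=[crb.record_for("s0", "rbcL")])
        from barcodekit.refmodel import ESSQuerySet

        # inject the variant as a CRB-external query via its own database
        crb2 = build_crb(
            [
                _rec("Sp a", "s0", "rbcL", base),
                _rec("Sp a", "s2", "rbcL", variant),
            ],
            combine=None,
        )
        ess = ESSQuerySet(samples=[("s2", "Sp a")], n_species=1)
        matched = identify(ess, irb, crb2, "rbcL", mode="threshold", threshold=99.9)
        assert matched.pct_perceived == 100.0
        missed = identify(ess, irb, crb2, "rbcL", mode="threshold", threshold=99.95)
        assert missed.pct_unknown == 100.0

    def test_threshold_100_equals_exact_on_equal_lengths(self):
        cfg = SynthConfig(
            n_species=12, loci={"rbcL": 60}, p_share=0.25, d_intra=0.02, rng_seed=8
        )
        crb, _ = simulate_crb(cfg)
        rng = np.random.default_rng(2)
        irb = sample_irb(crb, 6, rng)
        ess = sample_ess(crb, 8, rng)
        exact = identify(ess, irb, crb, "rbcL", mode="exact")
        t100 = identify(ess, irb, crb, "rbcL", mode="threshold", threshold=100.0)
        for fld in ("pct_perceived", "pct_ambiguous", "pct_unknown", "pct_true", "pct_false"):
            assert getattr(exact, fld) == getattr(t100, fld)


class TestScanThresholds:
    def test_ot_in_grid_and_separating_construction(self):
        # intraspecific divergence 0.1%, interspecific 2%: the optimum lies
        # between the two identity distributions
        cfg = SynthConfig(
            n_species=25,
            variants_per_species=2,
            loci={"rbcL": 1000},
            d_inter=0.02,
            d_intra=0.001,
            rng_seed=5,
        )
        crb, _ = simulate_crb(cfg)
        rng = np.random.default_rng(3)
        irb = sample_irb(crb, 12, rng)
        ess = sample_ess(crb, 15, rng)
        scan = scan_thresholds(ess, irb, crb, "rbcL")
        assert scan.o_t in scan.grid
        assert 98.0 < scan.o_t <= 99.9
        brute_best = max(
            scan.summaries, key=lambda s: (s.pct_true, s.threshold)
        ).threshold
        assert scan.o_t == brute_best

    def test_grid_of_100_degenerates_to_exact(self, tiny_crb):
        rng = np.random.default_rng(0)
        irb = sample_irb(tiny_crb, 2, rng)
        ess = sample_ess(tiny_crb, 2, rng)
        scan = scan_thresholds(ess, irb, tiny_crb, "rbcL", grid=[100.0])
        exact = identify(ess, irb, tiny_crb, "rbcL", mode="exact")
        assert scan.o_t == 100.0
        assert scan.summaries[0].pct_true == exact.pct_true


class TestIrbSizeExperiment:
    def test_zero_shared_barcodes_always_perceived(self):
        cfg = SynthConfig(
            n_species=12, variants_per_species=1, loci={"rbcL": 200}, p_share=0.0, rng_seed=4
        )
        crb, shared = simulate_crb(cfg)
        assert shared == []
        table = run_irb_size_experiment(crb, "rbcL", [3, 6, 12], replicates=20)
        assert (table["pct_perceived_mean"] == 100.0).all()
        assert (table["pct_false_mean"] == 0.0).all()

    def test_false_vanishes_at_full_species_coverage_without_variants(self):
        cfg = SynthConfig(
            n_species=12, variants_per_species=1, loci={"rbcL": 120}, p_share=0.3, rng_seed=4
        )
        crb, shared = simulate_crb(cfg)
        assert shared  # construction injected shared barcodes
        table = run_irb_size_experiment(crb, "rbcL", [12], replicates=30)
        assert table["pct_false_mean"].iloc[0] == 0.0

    def test_genus_level_improves_resolution(self):
        # congeneric species sharing a barcode stop being ambiguous once
        # records are relabelled to the genus
        records = [
            _rec("Poa alpha", "p1", "rbcL", "ACGT" * 10),
            _rec("Poa beta", "p2", "rbcL", "ACGT" * 10),
            _rec("Carex gamma", "c1", "rbcL", "TTGG" * 10),
        ]
        crb = build_crb(records, combine=None)
        genus_crb = relabel_by_genus(crb)
        irb = IRBSample(n_species=3, records=list(crb.records))
        g_irb = IRBSample(n_species=2, records=list(genus_crb.records))
        species_level = classify_barcodes(irb, crb, "rbcL")
        genus_level = classify_barcodes(g_irb, genus_crb, "rbcL")
        assert species_level.pct_ambiguous == 50.0
        assert genus_level.pct_ambiguous == 0.0


class TestFitDecayCurve:
    def test_power_recovery_on_exact_data(self):
        xs = np.arange(70, 736, 35, dtype=float)
        fit = fit_decay_curve(xs, 104.37 * xs**-0.12, "power")
        assert fit.a == pytest.approx(104.37, abs=1e-9)
        assert fit.b == pytest.approx(-0.12, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exponential_recovery_on_exact_data(self):
        xs = np.arange(70, 736, 35, dtype=float)
        fit = fit_decay_curve(xs, 99.188 * np.exp(-0.003 * xs), "exponential")
        assert fit.a == pytest.approx(99.188, abs=1e-9)
        assert fit.b == pytest.approx(-0.003, abs=1e-9)

    def test_constant_data_gives_zero_exponent(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_decay_curve(xs, np.full(4, 7.5), "power")
        assert fit.a == pytest.approx(7.5)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_data_rejected(self):
        with pytest.raises(ValueError):
            fit_decay_curve([1, 2, 3], [5, 0, 5], "power")


class TestSharedOverlap:
    def test_examples(self):
        assert shared_overlap([(0, 600), (100, 700)]) == 500
        assert shared_overlap([(0, 100), (200, 300)]) == 0

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            shared_overlap([])

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 500)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_position_by_position_count(self, intervals):
        count = sum(
            1
            for pos in range(0, 1001)
            if all(s <= pos < e for s, e in intervals)
        )
        assert shared_overlap(intervals) == count


class TestWorkedArithmetic:
    def test_length_filter(self):
        records = [
            _rec("Sp a", f"s{i}", "rbcL", "A" * (200 if i < 2 else 400))
            for i in range(10)
        ]
        kept, pct = filter_by_length(records, 300)
        assert len(kept) == 8 and pct == pytest.approx(20.0)
        assert filter_by_length(records, 0)[0] == records
        assert filter_by_length(records, 1000) == ([], 100.0)

    def test_database_completion_projection(self):
        proj = coverage_projection(51410, 350699, 11)
        assert proj == {
            "coverage_pct": 15,
            "rate_per_annum": 4674,
            "years_remaining": 64,
        }

    def test_projection_degenerate_cases(self):
        assert coverage_projection(1000, 1000, 10)["coverage_pct"] == 100
        assert coverage_projection(1000, 1000, 10)["years_remaining"] == 0
        with pytest.raises(ValueError):
            coverage_projection(0, 1000, 10)


class TestPercentIdentity:
    def test_equal_length_excludes_n_columns(self):
        assert percent_identity("ACGT", "ACGA") == 75.0
        assert percent_identity("ACGN", "ACGT") == 100.0  # N column dropped
        assert percent_identity("NNNN", "ACGT") == 0.0

    def test_unequal_length_uses_alignment(self):
        # one internal deletion in 10 aligned columns
        assert percent_identity("ACGTACGTAC", "ACGTCGTAC") == pytest.approx(90.0)


def test_default_threshold_grid_spans_97_to_999():
    grid = default_threshold_grid()
    assert grid[0] == 97.0 and grid[-1] == 99.9 and len(grid) == 30
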