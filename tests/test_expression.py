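"""TPM normalization, distributions, saturation, correlation."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tagdge.expression import (
    DEFAULT_BINS,
    InvalidBinsError,
    ZeroLibraryTotalError,
    ZeroVarianceError,
    abundance_distribution,
    library_correlation,
    quantify,
    saturation,
    to_tpm,
)
from tagdge.filtering import TagLibrary, filter_tags
from tagdge.reference import build_reference


def _clean(counts):
    return TagLibrary(sample_id="s", counts=counts, filter_log={})


class TestToTpm:
    def test_simple_scaling(self):
        table = to_tpm({"g": 5}, 20)
        assert table.tpm["g"] == 250_000.0

    def test_absent_gene_gets_zero(self):
        table = to_tpm({"g1": 5}, 20, gene_ids=["g1", "g2"])
        assert table.tpm["g2"] == 0.0
        assert table.counts["g2"] == 0

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroLibraryTotalError):
            to_tpm({"g": 1}, 0)

    def test_sum_is_exactly_one_million_under_full_mapping(self):
        """When every clean tag maps unambiguously the per-gene TPM is an
        exact partition of 1e6 (rational identity)."""
        counts = {"g1": 3, "g2": 7, "g3": 90}
        total = sum(counts.values())
        exact = sum(Fraction(c) * 10**6 / Fraction(total) for c in counts.values())
        assert exact == 10**6
        table = to_tpm(counts, total)
        assert np.isclose(table.tpm.sum(), 1e6, rtol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=30))
    def test_scale_invariance(self, counts):
        """Doubling every count (and the total) leaves TPM unchanged."""
        total = sum(counts) or 1
        named = {f"g{i}": c for i, c in enumerate(counts)}
        a = to_tpm(named, total).tpm
        b = to_tpm({g: 2 * c for g, c in named.items()}, 2 * total).tpm
        assert np.allclose(a, b, rtol=1e-12)


class TestAbundanceDistribution:
    def test_binning_example(self):
        counts = {f"t{i}": c for i, c in enumerate([2, 3, 5, 7, 150])}
        bins = ((1, 1), (2, 5), (6, 10), (11, 100), (101, None))
        dist = abundance_distribution(counts, bins)
        assert dist.n_distinct.tolist() == [0, 3, 1, 0, 1]
        assert dist.n_total.sum() == sum(counts.values())

    def test_partition_conserved(self, small_experiment):
        cfg = small_experiment.truth.config
        lib = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        dist = abundance_distribution(lib.counts, DEFAULT_BINS)
        assert dist.n_distinct.sum() == lib.n_clean_distinct
        assert dist.n_total.sum() == lib.n_clean_total

    def test_invalid_bins_rejected(self):
        with pytest.raises(InvalidBinsError):
            abundance_distribution({"t": 2}, ((1, 5), (4, 10), (11, None)))
        with pytest.raises(InvalidBinsError):
            abundance_distribution({"t": 2}, ((1, 5), (6, 10)))  # not open-ended

    def test_total_vs_distinct_contrast_on_lognormal_library(self, small_experiment):
        """Occurrences concentrate in high-copy bins while distinct tags
        concentrate in low-copy bins (the standard deep-library contrast)."""
        cfg = small_experiment.truth.config
        lib = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        dist = abundance_distribution(lib.counts, DEFAULT_BINS).set_index("bin")
        high = dist.loc[["[101,500]", "[501,1000]", ">1000"]]
        # occurrences concentrate above 100 copies; distinct tags do not
        # (singletons are already filtered, so the low-copy side starts at 2)
        assert high.n_total.sum() > 0.5 * dist.n_total.sum()
        assert high.n_distinct.sum() < 0.2 * dist.n_distinct.sum()
        assert dist.loc[["[2,5]", "[6,10]", "[11,20]"]].n_distinct.sum() > (
            0.5 * dist.n_distinct.sum()
        )


class TestSaturation:
    def test_single_full_point_when_step_exceeds_library(self, toy_reference):
        lib = _clean({"CATG" + "A" * 17: 5})
        curve = saturation(lib, toy_reference, step=1000, seed=0)
        assert len(curve) == 1
        assert curve.n_subsampled_tags.iloc[0] == 5

    def test_monotone_and_reproducible(self, small_experiment):
        cfg = small_experiment.truth.config
        ref = build_reference(small_experiment.transcripts)
        lib = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        c1 = saturation(lib, ref, step=5000, seed=42)
        c2 = saturation(lib, ref, step=5000, seed=42)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.n_detected_genes.diff().dropna() >= 0).all()

    def test_final_point_equals_full_detection(self, small_experiment):
        cfg = small_experiment.truth.config
        ref = build_reference(small_experiment.transcripts)
        lib = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        table, _ = quantify(lib, ref)
        full = int((table.counts > 0).sum())
        curve = saturation(lib, ref, step=7000, seed=1)
        assert curve.n_detected_genes.iloc[-1] == full


class TestLibraryCorrelation:
    def test_self_correlation_is_one(self, small_experiment):
        cfg = small_experiment.truth.config
        lib = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        assert library_correlation(lib, lib) == pytest.approx(1.0)

    def test_disjoint_libraries_anticorrelated(self):
        a = _clean({"CATG" + "A" * 10 + "C" * 7: 5, "CATG" + "G" * 9 + "T" * 8: 9})
        b = _clean({"CATG" + "T" * 9 + "A" * 8: 4, "CATG" + "C" * 10 + "G" * 7: 2})
        assert library_correlation(a, b) < 0

    def test_zero_variance_rejected(self):
        a = _clean({"CATG" + "A" * 10 + "C" * 7: 5})
        with pytest.raises(ZeroVarianceError):
            library_correlation(a, a)  # single shared tag -> constant vectors

    def test_replicates_correlate_raw_scale(self):
        """Independent replicate draws of one expression state: Pearson on
        raw tag counts is near 1 (abundance-dominated, as in parallel
        sequencing libraries)."""
        from tagdge.simulate import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_genes=400, library_size=150_000,
                               de_fraction=0.0, seed=11)
        exp = simulate_experiment(cfg, ("r1", "r2"))
        l1 = filter_tags(exp.libraries["r1"], cfg.adaptor_seq)
        l2 = filter_tags(exp.libraries["r2"], cfg.adaptor_seq)
        assert library_correlation(l1, l2, log_transform=False) >= 0.95

    def test_error_free_replicates_correlate_log_scale(self):
        from tagdge.simulate import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_genes=400, library_size=150_000,
                               de_fraction=0.0, per_base_error_rate=0.0, seed=11)
        exp = simulate_experiment(cfg, ("r1", "r2"))
        l1 = filter_tags(exp.libraries["r1"], cfg.adaptor_seq)
        l2 = filter_tags(exp.libraries["r2"], cfg.adaptor_seq)
        assert library_correlation(l1, l2) >= 0.95
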