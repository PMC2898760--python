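"""Audic-Claverie exact test, BH-FDR, and differential-expression calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ac_pvalue_exact, bh_stepup
from tagdge.diffexpr import (
    ac_log_pmf,
    InvalidCountsError,
    MismatchedTablesError,
    ac_pvalue,
    bh_fdr,
    call_de,
    log2_ratio,
)
from tagdge.expression import to_tpm


class TestAcPvalue:
    def test_observation_at_mode_is_not_significant(self):
        assert ac_pvalue(0, 0, 100, 100) == 1.0
        assert ac_pvalue(0, 0, 50_000, 50_000) == 1.0

    def test_frozen_exact_value_20_vs_0(self):
        """x=20, y=0, equal totals: lower tail is the single term
        P(0|20) = 2^-21, so p = 2^-20 exactly (exact-rational oracle)."""
        assert ac_pvalue_exact(20, 0, 100_000, 100_000) == 2.0**-20
        assert ac_pvalue(20, 0, 100_000, 100_000) == pytest.approx(2.0**-20, rel=1e-10)

    @pytest.mark.parametrize(
        "x,y,n1,n2",
        [(0, 5, 1000, 1000), (5, 25, 1000, 1000), (17, 3, 2000, 1000),
         (40, 80, 10_000, 20_000), (120, 100, 50_000, 50_000)],
    )
    def test_matches_exact_rational_oracle(self, x, y, n1, n2):
        assert ac_pvalue(x, y, n1, n2) == pytest.approx(
            ac_pvalue_exact(x, y, n1, n2), rel=1e-10
        )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.integers(0, 150), st.integers(0, 150),
        st.sampled_from([(1000, 1000), (1000, 2000), (3000, 1500)]),
    )
    def test_model_exchange_symmetry(self, x, y, totals):
        """The conditional model's exact symmetry:
        N2 * P(y|x; N1,N2) == N1 * P(x|y; N2,N1).  The tail-sum p-value
        inherits it only up to tail discreteness, so the p-values are
        required to agree within the discreteness bound (factor ~ (N1+N2)/N1
        on the tail ratio) while the pmf identity is exact."""
        n1, n2 = totals
        lhs = math.log(n2) + ac_log_pmf(x, y, n1, n2)
        rhs = math.log(n1) + ac_log_pmf(y, x, n2, n1)
        assert lhs == pytest.approx(rhs, abs=1e-9)
        pa = ac_pvalue(x, y, n1, n2)
        pb = ac_pvalue(y, x, n2, n1)
        bound = max((n1 + n2) / n1, (n1 + n2) / n2) * (1 + 1e-9)
        assert pa / bound <= pb <= pa * bound

    def test_one_sided_tails_sum_consistently(self):
        x, y, n1, n2 = 8, 20, 1000, 1000
        lo = ac_pvalue(x, y, n1, n2, alternative="less")
        hi = ac_pvalue(x, y, n1, n2, alternative="greater")
        # tails overlap exactly in the observed point
        assert lo + hi == pytest.approx(1 + math.exp(
            y * math.log(n2 / n1)
            + math.lgamma(x + y + 1) - math.lgamma(x + 1) - math.lgamma(y + 1)
            - (x + y + 1) * math.log1p(n2 / n1)
        ), rel=1e-9)

    def test_zero_totals_rejected(self):
        with pytest.raises(InvalidCountsError):
            ac_pvalue(1, 1, 0, 100)
        with pytest.raises(InvalidCountsError):
            ac_pvalue(-1, 1, 100, 100)

    def test_more_extreme_disparity_gives_smaller_p(self):
        ps = [ac_pvalue(10, y, 10_000, 10_000) for y in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.042])[0] == pytest.approx(0.042)

    def test_hand_computed_stepup(self):
        # 3*0.01/1 = 0.03; 3*0.02/2 = 0.03; 3*0.03/3 = 0.03
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_stepup_oracle_and_is_monotone(self, rng):
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert np.allclose(q, bh_stepup(p), atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestLog2Ratio:
    def test_plain_ratio(self):
        assert log2_ratio(10.0, 40.0) == 2.0

    def test_zero_uses_pseudo_tpm(self):
        assert log2_ratio(0.0, 1.0) == pytest.approx(math.log2(1 / 0.001))


class TestCallDe:
    def _tables(self, c1, c2, n1=1000, n2=1000):
        genes = sorted(set(c1) | set(c2))
        return (
            to_tpm(c1, n1, sample_id="a", gene_ids=genes),
            to_tpm(c2, n2, sample_id="b", gene_ids=genes),
        )

    def test_zero_both_excluded_and_one_sample_flagged(self):
        t1, t2 = self._tables({"g1": 0, "g2": 50}, {"g1": 0, "g2": 5, "g3": 30})
        table, summary = call_de(t1, t2)
        assert set(table.gene_id) == {"g2", "g3"}
        assert table.set_index("gene_id").loc["g3", "one_sample_only"]

    def test_calls_respect_both_thresholds(self):
        # strong count change but tiny fold change must stay ns
        t1, t2 = self._tables({"g": 400}, {"g": 600}, 10_000, 10_000)
        table, _ = call_de(t1, t2, alpha=0.5, min_abs_log2=1.0)
        assert table.call.iloc[0] == "ns"  # |log2 1.5| < 1
        t1, t2 = self._tables({"g": 100}, {"g": 800}, 10_000, 10_000)
        table, _ = call_de(t1, t2, alpha=0.001, min_abs_log2=1.0)
        assert table.call.iloc[0] == "up"

    def test_summary_tallies_match_calls(self):
        rng = np.random.default_rng(0)
        c1 = {f"g{i}": int(x) for i, x in enumerate(rng.poisson(40, 100))}
        c2 = dict(c1)
        for g in list(c2)[:10]:
            c2[g] *= 8
        t1, t2 = self._tables(c1, c2, 10_000, 10_000)
        table, summary = call_de(t1, t2, alpha=0.01)
        assert summary.n_up == (table.call == "up").sum()
        assert summary.n_down == (table.call == "down").sum()
        assert summary.n_tested == len(table)

    def test_mismatched_tables_rejected(self):
        t1 = to_tpm({"g1": 1}, 100, gene_ids=["g1"])
        t2 = to_tpm({"g2": 1}, 100, gene_ids=["g2"])
        with pytest.raises(MismatchedTablesError):
            call_de(t1, t2)

    def test_gene_order_invariance(self):
        c1 = {"g3": 30, "g1": 300, "g2": 3}
        c2 = {"g1": 30, "g2": 33, "g3": 290}
        t1, t2 = self._tables(c1, c2, 5000, 5000)
        a, _ = call_de(t1, t2)
        genes_rev = sorted(set(c1), reverse=True)
        t1r = to_tpm(c1, 5000, gene_ids=genes_rev)
        t2r = to_tpm(c2, 5000, gene_ids=genes_rev)
        b, _ = call_de(t1r, t2r)
        pd.testing.assert_frame_equal(a, b)


class TestTagLevelMode:
    def test_tag_calls_collapse_to_genes_with_direction_consistency(
        self, small_experiment
    ):
        """Tag-entity testing collapses to gene calls that broadly agree
        with gene-level testing on strongly changed genes."""
        from tagdge.filtering import filter_tags
        from tagdge.reference import build_reference
        from tagdge.diffexpr import call_de_tag_level
        from tagdge.expression import quantify

        cfg = small_experiment.truth.config
        ref = build_reference(small_experiment.transcripts)
        l1 = filter_tags(small_experiment.libraries["cond1"], cfg.adaptor_seq)
        l2 = filter_tags(small_experiment.libraries["cond2"], cfg.adaptor_seq)
        tags, genes = call_de_tag_level(l1, l2, ref)
        # per-gene calls derive exactly from the per-tag calls
        for _, row in genes.iterrows():
            tag_calls = set(
                tags.loc[tags.gene_id == row.gene_id, "call"]
            ) - {"ns"}
            if row.call == "ns":
                assert not tag_calls
            elif row.call == "discordant":
                assert tag_calls == {"up", "down"}
            else:
                assert tag_calls == {row.call}
        # gene-level route finds mostly the same up/down genes
        gene_ids = [t.gene_id for t in ref.transcripts]
        t1, _ = quantify(l1, ref, gene_ids=gene_ids)
        t2, _ = quantify(l2, ref, gene_ids=gene_ids)
        gene_table, _ = call_de(t1, t2)
        strong = set(
            gene_table.loc[gene_table.call != "ns", "gene_id"]
        )
        tag_called = set(genes.loc[genes.call.isin(["up", "down"]), "gene_id"])
        assert len(strong & tag_called) >= 0.6 * len(strong)


class TestPowerMonotonicity:
    def test_detection_rate_increases_with_fold_change_and_depth(self):
        """Empirical detection of a planted change is non-decreasing in the
        fold change and in library depth (count-level simulation)."""
        rng = np.random.default_rng(123)

        def rate(fc, depth):
            base = rng.poisson(20 * depth, 300)
            alt = rng.poisson(20 * depth * fc, 300)
            n = int(3e4 * depth)
            ps = [ac_pvalue(int(x), int(y), n, n) for x, y in zip(base, alt)]
            return np.mean(bh_fdr(ps) < 0.001)

        assert rate(1.5, 1) <= rate(2.5, 1) <= rate(4.0, 1)
        assert rate(2.0, 0.25) <= rate(2.0, 1) <= rate(2.0, 4)
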