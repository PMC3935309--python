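"""Background estimation, Poisson testing, BH adjustment, merging, flanks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from novotx.coverage import ReadPlacement
from novotx.hcp import (
    BackgroundModel,
    EmptyBackgroundError,
    bh_adjust,
    call_windows,
    estimate_background,
    estimate_lambda,
    merge_significant,
    poisson_upper_tail,
    scan_flanks,
)
from novotx.intervals import GenomicInterval
from novotx.regions import CompartmentSet, Window, make_windows

from conftest import bh_step_up_oracle, build_annotation, poisson_sf_oracle


def _starts(values, chrom="chrT"):
    return {chrom: np.sort(np.asarray(values, dtype=np.int64))}


class TestEstimateLambda:
    def test_rate_is_reads_per_bp(self):
        rng = np.random.default_rng(0)
        starts = _starts(rng.integers(0, 100_000, size=500))
        rate, n_reads, n_bp = estimate_lambda(
            starts, [GenomicInterval("chrT", 0, 100_000)]
        )
        assert n_bp == 100_000 and n_reads == 500
        assert rate == pytest.approx(0.005)

    def test_zero_reads_gives_zero_rate(self):
        rate, n_reads, _ = estimate_lambda(
            _starts([]), [GenomicInterval("chrT", 0, 1000)]
        )
        assert rate == 0.0 and n_reads == 0

    def test_empty_background_raises(self):
        with pytest.raises(EmptyBackgroundError):
            estimate_lambda(_starts([10]), [])

    def test_poisson_sampled_rate_within_three_standard_errors(self):
        rng = np.random.default_rng(1234)
        true_rate, length = 0.01, 1_000_000
        n = rng.poisson(true_rate * length)
        starts = _starts(rng.integers(0, length, size=n))
        rate, _, _ = estimate_lambda(starts, [GenomicInterval("chrT", 0, length)])
        se = math.sqrt(true_rate / length)
        assert abs(rate - true_rate) <= 3 * se

    def test_only_reads_inside_background_counted(self):
        starts = _starts([10, 50, 150, 250])
        rate, n_reads, n_bp = estimate_lambda(
            starts, [GenomicInterval("chrT", 0, 100)]
        )
        assert n_reads == 2 and n_bp == 100


class TestPoissonUpperTail:
    def test_zero_count_has_pvalue_one(self):
        assert poisson_upper_tail(0, 1.0) == 1.0

    def test_known_values_from_pmf_summation(self):
        assert poisson_upper_tail(3, 1.0) == pytest.approx(
            1 - math.exp(-1) * (1 + 1 + 0.5), abs=1e-12
        )
        assert poisson_upper_tail(10, 1.0) == pytest.approx(1.1142e-7, rel=1e-3)

    def test_matches_direct_summation_on_grid(self):
        for mu in (0.1, 0.5, 1.0, 5.0, 20.0, 50.0):
            for k in (0, 1, 2, 5, 10, 50, 100, 200):
                assert poisson_upper_tail(k, mu) == pytest.approx(
                    poisson_sf_oracle(k, mu), abs=1e-10
                )

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(3, 0.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(3, -1.0)

    def test_monotone_decreasing_in_k_and_increasing_in_mu(self):
        ps = [poisson_upper_tail(k, 2.0) for k in range(0, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        qs = [poisson_upper_tail(5, mu) for mu in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )
        assert bh_adjust([0.04, 0.5, 1.0]).tolist() == pytest.approx(
            [0.12, 0.75, 1.0]
        )

    def test_empty_input_empty_output(self):
        assert bh_adjust([]).size == 0

    def test_rejects_out_of_range_pvalues(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 1000))
        p = rng.uniform(1e-12, 1.0, size=n)
        np.testing.assert_allclose(
            bh_adjust(p), bh_step_up_oracle(p.tolist()), rtol=0, atol=1e-12
        )

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(1e-9, 1.0, size=300)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        ),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance(self, pvalues, rnd):
        q = bh_adjust(pvalues)
        perm = list(range(len(pvalues)))
        rnd.shuffle(perm)
        q_perm = bh_adjust([pvalues[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-15)


class TestCallAndMerge:
    def _model(self, lam=0.005):
        return BackgroundModel(lambda_intronic=lam, lambda_intergenic=lam)

    def test_all_zero_counts_never_significant(self):
        windows = make_windows([GenomicInterval("chrT", 0, 10_000)], 200, "intronic")
        call_windows(windows, self._model(), fdr=0.5)
        assert not any(w.significant for w in windows)
        assert all(w.p == 1.0 for w in windows)

    def test_single_strong_window_survives_bh(self):
        windows = make_windows(
            [GenomicInterval("chrT", 0, 1_000 * 200)], 200, "intronic"
        )
        for w in windows:
            w.count = 1  # roughly the expectation at lambda=0.005
        windows[500].count = 50
        call_windows(windows, self._model(), fdr=0.05)
        assert windows[500].significant
        assert windows[500].q < 1e-40

    def test_mu_scales_with_true_width_of_partial_window(self):
        windows = make_windows([GenomicInterval("chrT", 0, 450)], 200, "intronic")
        call_windows(windows, self._model(0.01))
        assert windows[-1].mu == pytest.approx(0.01 * 50)
        assert windows[0].mu == pytest.approx(0.01 * 200)

    def test_bh_families_are_per_compartment_by_default(self):
        intronic = make_windows([GenomicInterval("chrT", 0, 2000)], 200, "intronic")
        intergenic = make_windows(
            [GenomicInterval("chrT", 10_000, 12_000)], 500, "intergenic"
        )
        windows = intronic + intergenic
        for w in windows:
            w.count = 3
        call_windows(windows, self._model(0.001))
        # within a family all p equal, hence all q equal; families differ
        q_intronic = {round(w.q, 12) for w in intronic}
        q_intergenic = {round(w.q, 12) for w in intergenic}
        assert len(q_intronic) == 1 and len(q_intergenic) == 1
        assert q_intronic != q_intergenic

    def _sig_windows(self, spans, width=200, compartment="intronic"):
        out = []
        for s, e in spans:
            w = Window("chrT", s, e, compartment=compartment, nominal_width=width)
            w.count, w.q, w.significant = 10, 1e-6, True
            out.append(w)
        return out

    def test_adjacent_significant_windows_merge(self):
        hcps = merge_significant(self._sig_windows([(0, 200), (200, 400)]))
        assert [(h.start, h.end) for h in hcps] == [(0, 400)]
        assert hcps[0].n_windows == 2 and hcps[0].total_reads == 20

    def test_gap_equal_to_window_width_merges(self):
        hcps = merge_significant(self._sig_windows([(0, 200), (400, 600)]))
        assert [(h.start, h.end) for h in hcps] == [(0, 600)]

    def test_gap_larger_than_window_width_splits(self):
        hcps = merge_significant(self._sig_windows([(0, 200), (500, 700)]))
        assert [(h.start, h.end) for h in hcps] == [(0, 200), (500, 700)]

    def test_compartments_never_merge_together(self):
        windows = self._sig_windows([(0, 200)]) + self._sig_windows(
            [(200, 400)], compartment="intergenic"
        )
        hcps = merge_significant(windows)
        assert len(hcps) == 2

    def test_hcp_min_q_is_minimum_over_members(self):
        windows = self._sig_windows([(0, 200), (200, 400)])
        windows[1].q = 1e-9
        hcps = merge_significant(windows)
        assert hcps[0].min_q == 1e-9


class TestEstimateBackground:
    def _comp(self):
        return CompartmentSet(
            intronic=[GenomicInterval("chrT", 0, 10_000)],
            intergenic=[GenomicInterval("chrT", 20_000, 40_000)],
            genic=[GenomicInterval("chrT", 10_000, 20_000)],
        )

    def test_fallback_to_whole_compartment_on_small_genomes(self):
        rng = np.random.default_rng(3)
        starts = _starts(rng.integers(0, 40_000, size=400))
        model = estimate_background(starts, self._comp())
        assert model.summary["intronic"]["fallback"]
        assert model.summary["intergenic"]["fallback"]
        assert model.lambda_intronic > 0 and model.lambda_intergenic > 0

    def test_fallback_disabled_raises(self):
        with pytest.raises(EmptyBackgroundError):
            estimate_background(
                _starts([100]), self._comp(), allow_fallback=False
            )

    def test_zero_read_compartment_gets_pseudocount(self):
        starts = _starts([25_000, 26_000])  # intergenic only
        model = estimate_background(starts, self._comp())
        assert model.summary["intronic"]["pseudocount"]
        assert model.lambda_intronic > 0

    def test_custom_thresholds_select_real_background(self):
        starts = _starts(list(range(0, 40_000, 100)))
        model = estimate_background(
            starts,
            self._comp(),
            intronic_min_len=5_000,
            intronic_trim=500,
            intergenic_min_len=5_000,
            intergenic_trim=500,
        )
        assert not model.summary["intronic"]["fallback"]
        assert model.summary["intronic"]["bp"] == 9_000
        assert model.lambda_intronic == pytest.approx(0.01, rel=0.05)


class TestScanFlanks:
    def _ann(self):
        return build_annotation(
            {
                "GP": ("+", {"TP": [(10_000, 10_200), (11_000, 11_200)]}),
                "GM": ("-", {"TM": [(19_000, 19_200), (19_800, 20_000)]}),
            },
            {"chrT": 30_000},
        )

    def test_strand_aware_window_placement(self):
        model = BackgroundModel(0.001, 0.001)
        report = scan_flanks(self._ann(), _starts([]), model, widths=[200])
        rows = {
            (r.transcript_id, r.side): (r.start, r.end)
            for r in report.itertuples()
        }
        assert rows[("TP", "upstream")] == (9_800, 10_000)
        assert rows[("TP", "downstream")] == (11_200, 11_400)
        # minus strand: upstream extends to larger coordinates
        assert rows[("TM", "upstream")] == (20_000, 20_200)
        assert rows[("TM", "downstream")] == (18_800, 19_000)

    def test_zero_reads_gives_pvalue_one_everywhere(self):
        model = BackgroundModel(0.001, 0.001)
        report = scan_flanks(self._ann(), _starts([]), model)
        assert (report["p"] == 1.0).all()
        assert (report["count"] == 0).all()

    def test_window_truncated_at_chromosome_edge_is_flagged(self):
        ann = build_annotation(
            {"G": ("+", {"T": [(100, 200)]})}, {"chrT": 350}
        )
        model = BackgroundModel(0.001, 0.001)
        report = scan_flanks(ann, _starts([]), model, widths=[200])
        up = report[report["side"] == "upstream"].iloc[0]
        down = report[report["side"] == "downstream"].iloc[0]
        assert up.truncated and (up.start, up.end) == (0, 100)
        assert down.truncated and (down.start, down.end) == (200, 350)

    def test_exon_overlap_flagged(self):
        ann = build_annotation(
            {
                "G": ("+", {"T": [(10_000, 10_200)]}),
                "G2": ("+", {"T2": [(9_900, 9_950)]}),
            },
            {"chrT": 30_000},
        )
        model = BackgroundModel(0.001, 0.001)
        report = scan_flanks(ann, _starts([]), model, widths=[200])
        up = report[
            (report["transcript_id"] == "T") & (report["side"] == "upstream")
        ].iloc[0]
        assert up.exon_overlap
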