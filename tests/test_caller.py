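"""Window means, classification, segmentation, copy number, exon spans."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panelcnv as pc
from panelcnv.caller import footprint_blocks

from conftest import flat_ratio_matrix, uniform_coverage


def set_segment(rm: pc.RatioMatrix, start: int, length: int, value: float, sample=0):
    rm.ratios[sample, start:start + length] = value
    return rm


def brute_force_window_means(values: np.ndarray, w: int) -> list[float]:
    """Oracle: independent per-window recomputation, mask rule included."""
    out = []
    for s in range(len(values) - w + 1):
        win = values[s:s + w]
        masked = np.isnan(win)
        if masked.sum() * 2 > w:
            out.append(np.nan)
        else:
            out.append(float(np.mean(win[~masked])))
    return out


class TestWindowMeans:
    def test_constant_block_gives_constant_means(self):
        rm = flat_ratio_matrix(length=10, value=0.5)
        track = pc.window_means(rm)
        assert len(track.windows) == 1
        assert track.windows["mean_ratio"].iloc[0] == pytest.approx(0.5)

    def test_mixed_window_mean(self):
        rm = flat_ratio_matrix(length=10, value=1.0)
        rm.ratios[0, 5:] = 0.5
        track = pc.window_means(rm)
        assert track.windows["mean_ratio"].iloc[0] == pytest.approx(0.75)

    def test_all_masked_window_is_masked(self):
        rm = flat_ratio_matrix(length=10, value=1.0)
        rm.mask[:] = True
        rm.ratios[:] = np.nan
        track = pc.window_means(rm)
        assert (track.windows["state"] == "masked").all()

    def test_windows_never_span_target_gaps(self, small_panel):
        cov = uniform_coverage(small_panel, n_samples=4, depth=200)
        rm = pc.normalize_batch(cov)
        track = pc.window_means(rm)
        blocks = footprint_blocks(rm.positions)
        # every window fits inside one block
        for _, win in track.windows.iterrows():
            assert any(s <= win.start_col and win.end_col <= e for _, s, e in blocks)
        # 16 blocks (4 genes x 4 flank-extended exons), each 160 bp -> 151
        # sliding windows per block per sample
        assert len(track.windows) == 16 * 151 * 4

    def test_short_block_gets_single_shortened_window(self, caplog):
        rm = flat_ratio_matrix(length=6, value=0.4)
        with caplog.at_level("WARNING", logger="panelcnv"):
            track = pc.window_means(rm)
        assert len(track.windows) == 1
        assert track.windows["end_col"].iloc[0] - track.windows["start_col"].iloc[0] == 6

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=2**16),
        length=st.integers(min_value=10, max_value=60),
        n_masked=st.integers(min_value=0, max_value=12),
    )
    def test_oracle_equivalence_on_random_tracks(self, seed, length, n_masked):
        rng = np.random.default_rng(seed)
        rm = flat_ratio_matrix(length=length, value=1.0)
        rm.ratios[0] = rng.uniform(0.2, 2.0, size=length)
        masked = rng.choice(length, size=min(n_masked, length), replace=False)
        rm.mask[masked] = True
        rm.ratios[0, masked] = np.nan
        track = pc.window_means(rm)
        expected = brute_force_window_means(rm.ratios[0], 10)
        got = track.windows["mean_ratio"].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestClassifyWindow:
    @pytest.mark.parametrize(
        "mean,state",
        [
            (0.65, "del"),     # inclusive deletion boundary
            (0.66, "normal"),
            (1.34, "normal"),
            (1.35, "dup"),     # inclusive duplication boundary
            (1.0, "normal"),
            (float("nan"), "masked"),
        ],
    )
    def test_cutoff_semantics(self, mean, state):
        assert pc.classify_window(mean, pc.CallerConfig()) == state


class TestSegmentation:
    def test_forty_bp_deletion_run_is_one_call(self):
        rm = set_segment(flat_ratio_matrix(length=400), 100, 40, 0.5)
        calls = pc.segment_calls(pc.window_means(rm))
        assert len(calls) == 1
        call = calls[0]
        assert call.type == "del"
        assert call.span == 40
        assert call.start == rm.positions["pos"].iloc[100]
        assert call.mean_ratio == pytest.approx(0.5)

    def test_twenty_bp_run_suppressed_by_min_span(self):
        rm = set_segment(flat_ratio_matrix(length=400), 100, 20, 0.5)
        assert pc.segment_calls(pc.window_means(rm)) == []

    def test_single_masked_dropout_is_bridged(self):
        rm = set_segment(flat_ratio_matrix(length=400), 100, 60, 0.5)
        # mask a 10 bp dropout inside the event: wide enough to mask a window,
        # tiled stride keeps it to a single masked window
        rm.mask[120:130] = True
        rm.ratios[0, 120:130] = np.nan
        cfg = pc.CallerConfig(stride_bp=10)
        calls = pc.segment_calls(pc.window_means(rm, cfg))
        assert len(calls) == 1
        assert calls[0].type == "del"
        assert calls[0].span == 60

    def test_duplication_run_called(self):
        rm = set_segment(flat_ratio_matrix(length=400), 50, 120, 1.5)
        calls = pc.segment_calls(pc.window_means(rm))
        assert [c.type for c in calls] == ["dup"]
        assert calls[0].span == 120
        assert calls[0].copy_number == 3

    def test_calls_disjoint_and_windows_qualify(self):
        rm = flat_ratio_matrix(length=600)
        set_segment(rm, 50, 60, 0.5)
        set_segment(rm, 200, 80, 1.6)
        set_segment(rm, 400, 45, 0.4)
        track = pc.window_means(rm)
        calls = pc.segment_calls(track)
        assert len(calls) == 3
        intervals = sorted((c.start, c.end) for c in calls)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2
        # every window inside a call's interval carries that call's state
        cfg = track.cfg
        pos0 = rm.positions["pos"].iloc[0]
        for c in calls:
            inside = track.windows[
                (track.windows["start_col"] >= c.start - pos0)
                & (track.windows["end_col"] <= c.end - pos0)
            ]
            assert (inside["state"] == c.type).all()
            if c.type == "del":
                assert (inside["mean_ratio"] <= cfg.del_cutoff + 1e-9).all()
            else:
                assert (inside["mean_ratio"] >= cfg.dup_cutoff - 1e-9).all()

    def test_loosening_del_cutoff_never_drops_covered_region(self):
        """Any deletion called at a strict cutoff is still covered by a
        deletion call when the cutoff is loosened."""
        rng = np.random.default_rng(5)
        rm = flat_ratio_matrix(length=500)
        rm.ratios[0] = rng.uniform(0.4, 1.2, size=500)
        strict = pc.segment_calls(
            pc.window_means(rm, pc.CallerConfig(del_cutoff=0.55))
        )
        loose = pc.segment_calls(
            pc.window_means(rm, pc.CallerConfig(del_cutoff=0.65))
        )
        for call in (c for c in strict if c.type == "del"):
            assert any(
                l.type == "del" and l.start <= call.start and call.end <= l.end
                for l in loose
            )

    def test_raising_dup_cutoff_never_adds_calls(self):
        rng = np.random.default_rng(6)
        rm = flat_ratio_matrix(length=500)
        rm.ratios[0] = rng.uniform(0.8, 1.8, size=500)
        lo = pc.segment_calls(pc.window_means(rm, pc.CallerConfig(dup_cutoff=1.35)))
        hi = pc.segment_calls(pc.window_means(rm, pc.CallerConfig(dup_cutoff=1.45)))
        lo_dups = [c for c in lo if c.type == "dup"]
        hi_dups = [c for c in hi if c.type == "dup"]
        assert len(hi_dups) <= len(lo_dups)
        for call in hi_dups:
            assert any(
                l.start <= call.start and call.end <= l.end for l in lo_dups
            )

    @pytest.mark.parametrize("span", [10, 20, 25, 29])
    def test_detection_floor_short_spans_never_called(self, span):
        rm = set_segment(flat_ratio_matrix(length=400), 150, span, 0.5)
        assert pc.segment_calls(pc.window_means(rm)) == []

    @pytest.mark.parametrize("span", [40, 55, 80, 120])
    def test_detection_floor_long_spans_always_called(self, span):
        rm = set_segment(flat_ratio_matrix(length=400), 150, span, 0.5)
        calls = pc.segment_calls(pc.window_means(rm))
        assert len(calls) == 1
        assert calls[0].span == span
        assert calls[0].start == rm.positions["pos"].iloc[150]


class TestCopyNumber:
    @pytest.mark.parametrize(
        "ratio,baseline,expected",
        [
            (0.5, 2, 1),    # one copy at a unique locus
            (1.0, 2, 2),    # diploid baseline
            (1.5, 2, 3),
            (2.0, 2, 4),    # the four-copy unique-locus convention
            (0.75, 4, 3),   # homology scale
            (1.25, 4, 5),
            (1.25, 2, 3),   # half rounds up
        ],
    )
    def test_rounding(self, ratio, baseline, expected):
        call = pc.CNVCall(
            sample="S", gene="G", type="dup" if ratio > 1 else "del",
            chrom="chr1", start=0, end=100, mean_ratio=ratio,
            copy_number=0, n_windows=10, baseline_copies=baseline,
        )
        assert pc.estimate_copy_number(call) == expected


class TestAnnotateExons:
    def _call(self, panel, start, end, gene="GENE1"):
        region = panel.exon_regions(gene)[0]
        return pc.CNVCall(
            sample="S", gene=gene, type="del", chrom=region.chrom,
            start=start, end=end, mean_ratio=0.5, copy_number=1, n_windows=30,
        )

    def test_full_exons_span_without_subexon_flag(self, small_panel):
        regs = small_panel.exon_regions("GENE1")
        call = self._call(small_panel, regs[2].start, regs[3].end)
        out = pc.annotate_exons(call, small_panel)
        assert (out.first_exon, out.last_exon) == (3, 4)
        assert not out.sub_exon

    def test_half_exon_sets_subexon_flag(self, small_panel):
        r = small_panel.exon_regions("GENE1")[2]
        call = self._call(small_panel, r.start + 60, r.end)
        out = pc.annotate_exons(call, small_panel)
        assert (out.first_exon, out.last_exon) == (3, 3)
        assert out.sub_exon

    def test_whole_gene_call_spans_all_exons(self, small_panel):
        regs = small_panel.exon_regions("GENE1")
        call = self._call(
            small_panel, regs[0].start - small_panel.flank_bp,
            regs[-1].end + small_panel.flank_bp,
        )
        out = pc.annotate_exons(call, small_panel)
        assert (out.first_exon, out.last_exon) == (1, 4)
        assert not out.sub_exon

    def test_pure_flank_call_kept_with_empty_span(self, small_panel):
        r = small_panel.exon_regions("GENE1")[0]
        call = self._call(small_panel, r.start - 20, r.start - 2)
        out = pc.annotate_exons(call, small_panel)
        assert out.first_exon is None and out.last_exon is None
        assert out.flank_only


class TestConfigValidation:
    def test_min_span_must_cover_window(self):
        with pytest.raises(ValueError):
            pc.CallerConfig(window_bp=10, min_span_bp=5)

    def test_cutoffs_must_bracket_one(self):
        with pytest.raises(ValueError):
            pc.CallerConfig(del_cutoff=1.4)
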