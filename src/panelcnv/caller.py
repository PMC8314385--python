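"""Sliding-window CNV calling on normalized ratio tracks.

A fixed 10 bp window slides base-by-base over each contiguous footprint block;
window mean ratios are classified against fixed cutoffs (deletion <= 0.65,
duplication >= 1.35 at unique loci; 0.8 / 1.2 on the merged four-allele
scale), maximal runs of qualifying windows are segmented into calls, call
boundaries are refined to the qualifying positions, events shorter than
30 bp are suppressed, and an integer copy number is estimated from the mean
ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .four_allele import (
    FourAlleleConfig,
    four_allele_ratios,
    merge_homologous_coverage,
)
from .normalize import (
    DEFAULT_MIN_REF_DEPTH,
    RatioMatrix,
    normalization_factors,
    normalize_batch,
)
from .panel_io import CoverageMatrix, HomologyGroup, PanelDesign

logger = logging.getLogger("panelcnv")


@dataclass
class CallerConfig:
    """Window geometry and ratio cutoffs for segmentation.

    Defaults implement the unique-locus assay: 10 bp windows sliding 1 bp at
    a time, deletion at ratio <= 0.65, duplication at >= 1.35, and events
    shorter than 30 bp suppressed.  ``stride_bp = window_bp`` gives a tiled
    mode instead of a sliding one.
    """

    window_bp: int = 10
    stride_bp: int = 1
    del_cutoff: float = 0.65
    dup_cutoff: float = 1.35
    min_span_bp: int = 30
    max_bridged_windows: int = 1  # masked windows tolerated inside one run

    def __post_init__(self) -> None:
        if not (0 < self.del_cutoff < 1 < self.dup_cutoff):
            raise ValueError("need 0 < del_cutoff < 1 < dup_cutoff")
        if self.window_bp < 1 or self.stride_bp < 1:
            raise ValueError("window_bp and stride_bp must be >= 1")
        if self.min_span_bp < self.window_bp:
            raise ValueError("min_span_bp must be >= window_bp")

    @classmethod
    def four_allele(
        cls, four_cfg: FourAlleleConfig | None = None, **kwargs
    ) -> "CallerConfig":
        """Same window machinery with the merged-scale cutoffs."""
        four_cfg = four_cfg or FourAlleleConfig()
        return cls(
            del_cutoff=four_cfg.del_cutoff, dup_cutoff=four_cfg.dup_cutoff, **kwargs
        )


@dataclass
class WindowTrack:
    """Classified window means for every sample over every footprint block."""

    ratios: RatioMatrix
    windows: pd.DataFrame  # sample, gene, chrom, block_id, start_col, end_col, mean_ratio, state
    cfg: CallerConfig


@dataclass
class CNVCall:
    """One contiguous deletion/duplication event in one sample."""

    sample: str
    gene: str
    type: str                     # 'del' | 'dup'
    chrom: str
    start: int                    # 0-based inclusive
    end: int                      # 0-based exclusive
    mean_ratio: float
    copy_number: int
    n_windows: int
    group_scope: str = "unique"   # 'unique' | 'homology'
    baseline_copies: int = 2
    first_exon: int | None = None
    last_exon: int | None = None
    sub_exon: bool = False
    flank_only: bool = False
    hgvs: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def footprint_blocks(positions: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive positions of one gene: (gene, start_col, end_col)."""
    chrom = positions["chrom"].to_numpy()
    pos = positions["pos"].to_numpy()
    gene = positions["gene"].to_numpy()
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(
        (chrom[1:] != chrom[:-1]) | (pos[1:] != pos[:-1] + 1) | (gene[1:] != gene[:-1])
    )
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks + 1, len(positions)]
    return [(gene[s], int(s), int(e)) for s, e in zip(starts, ends)]


# Inclusive cutoff comparisons are padded by a tiny absolute tolerance so a
# window mean that equals the cutoff analytically is not pushed off it by
# floating-point summation order.
_CUTOFF_EPS = 1e-9


def classify_window(mean_ratio: float, cfg: CallerConfig) -> str:
    """del if mean <= del_cutoff, dup if mean >= dup_cutoff, else normal.

    Both comparisons are inclusive; a NaN mean marks a masked window.
    """
    if np.isnan(mean_ratio):
        return "masked"
    if mean_ratio <= cfg.del_cutoff + _CUTOFF_EPS:
        return "del"
    if mean_ratio >= cfg.dup_cutoff - _CUTOFF_EPS:
        return "dup"
    return "normal"


def window_means(ratios: RatioMatrix, cfg: CallerConfig | None = None) -> WindowTrack:
    """Window mean ratios per contiguous footprint block, per sample.

    No window spans a gap between targets or a gene boundary.  A window is
    masked when more than half of its positions are masked; otherwise its mean
    is the arithmetic mean of the unmasked ratios it covers.  A block shorter
    than the window yields a single shortened window (with a warning).
    """
    cfg = cfg or CallerConfig()
    w, stride = cfg.window_bp, cfg.stride_bp
    rows = []
    for block_id, (gene, s, e) in enumerate(footprint_blocks(ratios.positions)):
        length = e - s
        if length < w:
            logger.warning(
                "block %s (%d bp) shorter than window (%d bp): using one shortened window",
                gene, length, w,
            )
            starts = np.array([0])
            width = length
        else:
            starts = np.arange(0, length - w + 1, stride)
            width = w
        chrom = ratios.positions["chrom"].iloc[s]
        for si, sample in enumerate(ratios.samples):
            vals = ratios.ratios[si, s:e]
            windows = np.lib.stride_tricks.sliding_window_view(vals, width)[starts]
            valid = ~np.isnan(windows)
            n_valid = valid.sum(axis=1)
            sums = np.where(valid, windows, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
            n_masked = width - n_valid
            means = np.where(n_masked * 2 > width, np.nan, means)
            for k, st in enumerate(starts):
                mean = float(means[k])
                rows.append(
                    (
                        sample, gene, chrom, block_id,
                        s + int(st), s + int(st) + width,
                        mean, classify_window(mean, cfg),
                    )
                )
    windows = pd.DataFrame(
        rows,
        columns=[
            "sample", "gene", "chrom", "block_id",
            "start_col", "end_col", "mean_ratio", "state",
        ],
    )
    return WindowTrack(ratios=ratios, windows=windows, cfg=cfg)


def _position_qualifies(ratio: float, state: str, cfg: CallerConfig) -> bool:
    if np.isnan(ratio):
        return False
    if state == "del":
        return ratio <= cfg.del_cutoff + _CUTOFF_EPS
    return ratio >= cfg.dup_cutoff - _CUTOFF_EPS


def _emit_call(
    run: list,
    state: str,
    track: WindowTrack,
    group_scope: str,
) -> CNVCall | None:
    """Turn one run of qualifying windows into a call, or suppress it.

    The interval is the union of the member windows, then trimmed inward so
    both terminal positions individually satisfy the state's cutoff; partially
    overlapping windows otherwise pad a noiseless event by up to
    window_bp - 1 flanking bases.
    """
    cfg = track.cfg
    ratios = track.ratios
    first = run[0]
    si = ratios.samples.index(first.sample)
    lo = min(r.start_col for r in run)
    hi = max(r.end_col for r in run)
    row = ratios.ratios[si]
    while lo < hi and not _position_qualifies(row[lo], state, cfg):
        lo += 1
    while hi > lo and not _position_qualifies(row[hi - 1], state, cfg):
        hi -= 1
    if hi - lo < cfg.min_span_bp:
        return None
    mean_ratio = float(np.nanmean(row[lo:hi]))
    baseline = ratios.baseline_copies
    return CNVCall(
        sample=first.sample,
        gene=first.gene,
        type=state,
        chrom=first.chrom,
        start=int(ratios.positions["pos"].iloc[lo]),
        end=int(ratios.positions["pos"].iloc[hi - 1]) + 1,
        mean_ratio=mean_ratio,
        copy_number=_round_half_up(baseline * mean_ratio),
        n_windows=len(run),
        group_scope=group_scope,
        baseline_copies=baseline,
    )


def segment_calls(track: WindowTrack, group_scope: str = "unique") -> list[CNVCall]:
    """Merge maximal runs of same-state qualifying windows into CNV calls.

    Up to ``max_bridged_windows`` intervening masked windows are bridged so a
    single capture dropout does not split one event; a normal window always
    ends the run.  Segments whose refined span is below ``min_span_bp`` are
    suppressed.
    """
    cfg = track.cfg
    calls: list[CNVCall] = []
    grouped = track.windows.groupby(
        ["sample", "block_id"], sort=False, group_keys=False
    )
    for _, block in grouped:
        run: list = []
        run_state: str | None = None
        gap = 0

        def close() -> None:
            nonlocal run, run_state, gap
            if run:
                call = _emit_call(run, run_state, track, group_scope)
                if call is not None:
                    calls.append(call)
            run, run_state, gap = [], None, 0

        for win in block.itertuples(index=False):
            state = win.state
            if state in ("del", "dup"):
                if run_state == state:
                    run.append(win)
                    gap = 0
                else:
                    close()
                    run = [win]
                    run_state = state
            elif state == "masked" and run_state is not None:
                gap += 1
                if gap > cfg.max_bridged_windows:
                    close()
            else:  # normal, or masked outside a run
                close()
        close()
    calls.sort(key=lambda c: (c.sample, c.chrom, c.start))
    return calls


def estimate_copy_number(call: CNVCall) -> int:
    """Integer copies from the mean ratio: round(baseline * ratio), half away
    from zero upward (0.5 -> 1 copy, 1.5 -> 3 copies at unique loci)."""
    return _round_half_up(call.baseline_copies * call.mean_ratio)


def annotate_exons(call: CNVCall, panel: PanelDesign) -> CNVCall:
    """Fill the exon span of a call from the panel's target regions.

    ``sub_exon`` is set when a call boundary falls strictly inside an exon;
    a call confined to intronic flank keeps an empty span with a flag.
    Homology-group calls are annotated by coordinate overlap with whichever
    gene's exons they fall in.
    """
    candidates = [
        r
        for r in panel.regions
        if r.chrom == call.chrom and r.start < call.end and call.start < r.end
    ]
    if not candidates:
        return replace(call, first_exon=None, last_exon=None, flank_only=True)
    genes = {r.gene for r in candidates}
    if len(genes) > 1:
        logger.warning("call %s:%d-%d overlaps multiple genes %s",
                       call.chrom, call.start + 1, call.end, sorted(genes))
    regions = sorted(candidates, key=lambda r: r.exon_index)
    first, last = regions[0], regions[-1]
    sub_exon = call.start > first.start or call.end < last.end
    gene = call.gene if call.group_scope == "homology" else first.gene
    return replace(
        call,
        gene=gene,
        first_exon=first.exon_index,
        last_exon=last.exon_index,
        sub_exon=sub_exon,
        flank_only=False,
    )


# ---------------------------------------------------------------------------
# Batch pipeline
# ---------------------------------------------------------------------------

def call_batch(
    cov: CoverageMatrix,
    panel: PanelDesign,
    homology_groups: list[HomologyGroup] | None = None,
    cfg: CallerConfig | None = None,
    four_cfg: FourAlleleConfig | None = None,
    norm_mode: str = "factor",
    min_ref_depth: float = DEFAULT_MIN_REF_DEPTH,
    exclude_self: bool = False,
) -> list[CNVCall]:
    """Run normalization and calling over a whole batch.

    Unique loci go through factor (or quantile) normalization and the
    0.65/1.35 cutoffs; homology-group member positions are excluded from that
    path and instead merged, normalized, and called on the four-allele scale
    with the 0.8/1.2 cutoffs.  Calls are exon-annotated; HGVS strings are
    added by the reporting layer.
    """
    cfg = cfg or CallerConfig()
    four_cfg = four_cfg or FourAlleleConfig()
    homology_groups = homology_groups or []
    ratios = normalize_batch(
        cov, mode=norm_mode, min_ref_depth=min_ref_depth, exclude_self=exclude_self
    )
    # exclude homologous positions from the two-allele path: their ratios are
    # not interpretable locus-by-locus and the group path reports them
    if homology_groups:
        key = pd.MultiIndex.from_frame(ratios.positions[["chrom", "pos"]])
        for group in homology_groups:
            for member in group.members:
                idx = key.get_indexer(
                    pd.MultiIndex.from_frame(
                        group.position_map[member][["chrom", "pos"]]
                    )
                )
                idx = idx[idx >= 0]
                ratios.mask[idx] = True
                ratios.ratios[:, idx] = np.nan
    calls = segment_calls(window_means(ratios, cfg), group_scope="unique")
    if homology_groups:
        f = normalization_factors(cov)
        group_caller_cfg = CallerConfig(
            window_bp=cfg.window_bp,
            stride_bp=cfg.stride_bp,
            del_cutoff=four_cfg.del_cutoff,
            dup_cutoff=four_cfg.dup_cutoff,
            min_span_bp=cfg.min_span_bp,
            max_bridged_windows=cfg.max_bridged_windows,
        )
        for group in homology_groups:
            merged = merge_homologous_coverage(cov, group)
            group_ratios = four_allele_ratios(merged, f, min_ref_depth=min_ref_depth)
            calls.extend(
                segment_calls(
                    window_means(group_ratios, group_caller_cfg),
                    group_scope="homology",
                )
            )
    calls = [annotate_exons(c, panel) for c in calls]
    calls.sort(key=lambda c: (c.sample, c.chrom, c.start))
    return calls
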