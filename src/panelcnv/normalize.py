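"""Batch normalization of per-base depth into per-nucleotide copy ratios.

Two-stage scheme: a per-sample normalization factor derived from total
footprint coverage equalizes library size, then each position is divided by a
per-position batch reference (the median of normalized depths across samples).
A ratio of 1.0 corresponds to the diploid two copies at unique loci; 0.5 is
one copy, 1.5 three copies.  An alternative quantile-normalization mode
replaces each sample's depth distribution by the batch-mean distribution
before the per-position reference is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CoverageMatrix

logger = logging.getLogger("panelcnv")

#: Positions whose normalized batch reference falls below this depth carry too
#: little evidence for a stable ratio and are masked from calling.
DEFAULT_MIN_REF_DEPTH = 50.0

#: Fewer samples than this makes the per-position median reference fragile.
MIN_REFERENCE_SAMPLES = 4


@dataclass
class NormalizationFactors:
    """Per-sample scalar f_s = mean(batch totals) / total_s."""

    factors: pd.Series  # index: sample IDs

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("normalization factors must be finite and positive")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])

    def as_column(self) -> np.ndarray:
        return self.factors.to_numpy(float)[:, None]


@dataclass
class RatioMatrix:
    """Per-nucleotide normalized copy ratios with a low-evidence mask.

    ``ratios`` is NaN at masked positions; ``reference`` holds the per-position
    normalized baseline r_i.  ``baseline_copies`` records what a ratio of 1.0
    means (2 at unique loci; the total allele count for merged homology
    groups).
    """

    samples: list[str]
    positions: pd.DataFrame          # chrom, pos, gene
    ratios: np.ndarray               # (n_samples, n_positions), NaN where masked
    mask: np.ndarray                 # (n_positions,) bool, True = masked out
    reference: np.ndarray            # (n_positions,) float
    baseline_copies: int = 2

    def __post_init__(self) -> None:
        n_s, n_p = len(self.samples), len(self.positions)
        if self.ratios.shape != (n_s, n_p):
            raise ValueError("ratio matrix shape mismatch")
        unmasked = ~self.mask
        if np.any(self.reference[unmasked] <= 0):
            raise ValueError("unmasked reference values must be positive")
        if np.any(self.ratios[:, unmasked] < 0):
            raise ValueError("ratios must be non-negative")
        if not np.all(np.isnan(self.ratios[:, self.mask])):
            raise ValueError("masked positions must carry no ratio")

    def sample_row(self, sample: str) -> np.ndarray:
        return self.ratios[self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (sample, chrom, pos, ratio) for plotting."""
        frames = []
        for si, s in enumerate(self.samples):
            df = self.positions[["chrom", "pos"]].copy()
            df.insert(0, "sample", s)
            df["ratio"] = self.ratios[si]
            frames.append(df[~self.mask])
        return pd.concat(frames, ignore_index=True)


def normalization_factors(cov: CoverageMatrix) -> NormalizationFactors:
    """Library-size factors from total footprint coverage.

    f_s = mean(totals) / total_s, so that f_s * total_s equals the batch mean
    total for every sample and normalized depths stay on the raw-depth scale.
    """
    totals = cov.totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total coverage: {list(zero.index)}")
    f = totals.mean() / totals
    return NormalizationFactors(factors=f.rename("factor"))


def quantile_normalize(cov: CoverageMatrix) -> CoverageMatrix:
    """Replace each sample's depth distribution by the batch-mean distribution.

    Standard quantile normalization: position ranks are kept within each
    sample, values are taken from the rank-wise mean of the per-sample sorted
    depth vectors, and tied input values receive the mean of the target values
    over their tied rank span.
    """
    if len(cov.samples) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    depth = cov.depth.astype(float)
    n_pos = depth.shape[1]
    target = np.sort(depth, axis=1).mean(axis=0)  # rank-wise mean distribution
    out = np.empty_like(depth)
    for si in range(depth.shape[0]):
        order = np.argsort(depth[si], kind="mergesort")
        assigned = np.empty(n_pos)
        assigned[order] = target
        # ties: average the target values across each tied block
        sorted_vals = depth[si][order]
        block_starts = np.flatnonzero(np.r_[True, np.diff(sorted_vals) != 0])
        block_ends = np.r_[block_starts[1:], n_pos]
        for b0, b1 in zip(block_starts, block_ends):
            if b1 - b0 > 1:
                assigned[order[b0:b1]] = target[b0:b1].mean()
        out[si] = assigned
    return CoverageMatrix(
        samples=list(cov.samples),
        positions=cov.positions.copy(),
        depth=np.rint(out).astype(np.int64),
    )


def position_reference(
    cov: CoverageMatrix,
    f: NormalizationFactors,
    min_ref_depth: float = DEFAULT_MIN_REF_DEPTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position batch reference r_i and low-evidence mask.

    r_i is the median across samples of factor-normalized depth; positions
    with r_i below ``min_ref_depth`` are masked.  The median keeps r_i robust
    to a single-sample CNV in typical batch sizes.
    """
    if len(cov.samples) < MIN_REFERENCE_SAMPLES:
        logger.warning(
            "only %d samples: per-position median reference may be unstable",
            len(cov.samples),
        )
    normalized = cov.depth * f.as_column()
    r = np.median(normalized, axis=0)
    mask = r < min_ref_depth
    return r, mask


def ratio_matrix(
    cov: CoverageMatrix,
    f: NormalizationFactors,
    reference: np.ndarray,
    mask: np.ndarray,
    baseline_copies: int = 2,
) -> RatioMatrix:
    """R_{s,i} = depth_{s,i} * f_s / r_i at unmasked positions (NaN elsewhere)."""
    normalized = cov.depth * f.as_column()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = normalized / reference[None, :]
    ratios[:, mask] = np.nan
    return RatioMatrix(
        samples=list(cov.samples),
        positions=cov.positions.copy(),
        ratios=ratios,
        mask=mask.copy(),
        reference=reference.copy(),
        baseline_copies=baseline_copies,
    )


def normalize_batch(
    cov: CoverageMatrix,
    mode: str = "factor",
    min_ref_depth: float = DEFAULT_MIN_REF_DEPTH,
    exclude_self: bool = False,
) -> RatioMatrix:
    """Full normalization pipeline: factors -> reference -> ratio matrix.

    ``mode`` selects library-size factor normalization (default) or quantile
    normalization of the depth distributions before the per-position
    reference.  With ``exclude_self`` the reference at each position is
    recomputed per sample from the other samples only (leave-one-out), at the
    cost of one median pass per sample.
    """
    if mode == "quantile":
        cov = quantile_normalize(cov)
    elif mode != "factor":
        raise ValueError(f"unknown normalization mode {mode!r}")
    f = normalization_factors(cov)
    reference, mask = position_reference(cov, f, min_ref_depth=min_ref_depth)
    if not exclude_self:
        return ratio_matrix(cov, f, reference, mask)
    normalized = cov.depth * f.as_column()
    n_s = len(cov.samples)
    ratios = np.full_like(normalized, np.nan, dtype=float)
    mask_any = np.zeros(normalized.shape[1], dtype=bool)
    for si in range(n_s):
        others = np.delete(normalized, si, axis=0)
        r_i = np.median(others, axis=0)
        m = r_i < min_ref_depth
        mask_any |= m
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[si] = normalized[si] / r_i
        ratios[si, m] = np.nan
    ratios[:, mask_any] = np.where(
        np.isnan(ratios[:, mask_any]), np.nan, ratios[:, mask_any]
    )
    # a position masked for any sample is masked batch-wide to keep the
    # RatioMatrix mask a single vector
    ratios[:, mask_any] = np.nan
    return RatioMatrix(
        samples=list(cov.samples),
        positions=cov.positions.copy(),
        ratios=ratios,
        mask=mask_any,
        reference=reference,
    )
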