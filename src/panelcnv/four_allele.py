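"""Four-allele normalization for gene/pseudogene homology groups.

Reads from a gene and a highly similar pseudogene (PMS2/PMS2CL being the
classic pair) map ambiguously between the two, so per-locus ratios are
unreliable.  Instead, coverage of all homologous positions is summed per
aligned column before normalization: the diploid baseline then counts
2k alleles for a k-member group (four for a pair), a single-allele loss gives
a merged ratio of 3/4 = 0.75 and a single-allele gain 5/4 = 1.25, and the
calling cutoffs move to 0.8 / 1.2 accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import (
    DEFAULT_MIN_REF_DEPTH,
    NormalizationFactors,
    RatioMatrix,
    position_reference,
    ratio_matrix,
)
from .panel_io import CoverageMatrix, HomologyGroup


@dataclass
class FourAlleleConfig:
    """Calling cutoffs on the merged ratio scale (1.0 = all baseline alleles)."""

    del_cutoff: float = 0.8   # 3 of 4 alleles
    dup_cutoff: float = 1.2   # 5 of 4 alleles

    def __post_init__(self) -> None:
        if not (0 < self.del_cutoff < 1 < self.dup_cutoff):
            raise ValueError("need 0 < del_cutoff < 1 < dup_cutoff")


@dataclass
class MergedCoverage:
    """Summed depth over all group members, per sample per aligned column."""

    samples: list[str]
    group: HomologyGroup
    depth: np.ndarray  # (n_samples, aligned_length)

    def __post_init__(self) -> None:
        if self.depth.shape != (len(self.samples), self.group.aligned_length):
            raise ValueError("merged coverage shape mismatch")

    @property
    def totals(self) -> pd.Series:
        return pd.Series(self.depth.sum(axis=1), index=self.samples, name="total")


def merge_homologous_coverage(
    cov: CoverageMatrix, group: HomologyGroup
) -> MergedCoverage:
    """Sum member depths column-wise: merged_c = sum over members of depth at
    the member position mapped to aligned column c.  Reads are conserved
    exactly (total merged = sum of member totals)."""
    key = pd.MultiIndex.from_frame(cov.positions[["chrom", "pos"]])
    merged = np.zeros((len(cov.samples), group.aligned_length), dtype=np.int64)
    for member in group.members:
        pm = group.position_map[member]
        idx = key.get_indexer(pd.MultiIndex.from_frame(pm[["chrom", "pos"]]))
        if (idx < 0).any():
            missing = pm[idx < 0].iloc[0]
            raise ValueError(
                f"homology group {group.name} member {member}: position "
                f"{missing.chrom}:{int(missing.pos) + 1} outside panel footprint"
            )
        merged += cov.depth[:, idx]
    return MergedCoverage(samples=list(cov.samples), group=group, depth=merged)


def four_allele_ratios(
    merged: MergedCoverage,
    f: NormalizationFactors,
    min_ref_depth: float = DEFAULT_MIN_REF_DEPTH,
) -> RatioMatrix:
    """Normalize merged columns with the batch factors and median reference.

    The same factor/median pipeline as unique loci, applied to the summed
    track; a merged ratio of 1.0 corresponds to ``baseline_alleles`` copies.
    Positions are reported on the first member's coordinates, tagged with the
    group name so downstream calls carry ``group_scope``.
    """
    group = merged.group
    lead = group.position_map[group.members[0]]
    positions = pd.DataFrame(
        {"chrom": lead["chrom"], "pos": lead["pos"], "gene": group.name}
    )
    as_cov = CoverageMatrix(
        samples=list(merged.samples), positions=positions, depth=merged.depth
    )
    reference, mask = position_reference(as_cov, f, min_ref_depth=min_ref_depth)
    return ratio_matrix(
        as_cov, f, reference, mask, baseline_copies=group.baseline_alleles
    )


def classify_four_allele(
    mean_ratio: float, cfg: FourAlleleConfig | None = None
) -> str:
    """Classify a merged mean ratio: deletion <= 0.8, duplication >= 1.2 (inclusive)."""
    cfg = cfg or FourAlleleConfig()
    if mean_ratio < 0:
        raise ValueError("mean ratio must be non-negative")
    if mean_ratio <= cfg.del_cutoff:
        return "deletion"
    if mean_ratio >= cfg.dup_cutoff:
        return "duplication"
    return "normal"
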