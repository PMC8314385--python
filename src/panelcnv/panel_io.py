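"""Panel definitions, transcript models, homology maps and per-base depth I/O.

The panel data model mirrors a targeted capture design: every coding exon is a
target region, and the capture extends ``flank_bp`` intronic bases past each
exon boundary (20 bp in the default design).  All internal coordinates are
0-based half-open; file formats keep their native conventions (BED 0-based
half-open, depth TSV 1-based).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("panelcnv")

# QC defaults: the assay targets deep coverage (>200x) and a batch reference
# needs at least a handful of samples to be robust.
DEFAULT_MIN_MEDIAN_DEPTH = 200
MIN_BATCH_SAMPLES = 4

_CDNA_TOKEN_RE = re.compile(r"^(-\d+|\*\d+|\d+)$")


def _cdna_key(token: str) -> tuple[int, int]:
    """Sort key for HGVS c. coordinate tokens: 5'UTR (-N) < CDS (N) < 3'UTR (*N)."""
    if not _CDNA_TOKEN_RE.match(token):
        raise ValueError(f"malformed cDNA coordinate token: {token!r}")
    if token.startswith("-"):
        return (0, int(token))
    if token.startswith("*"):
        return (2, int(token[1:]))
    return (1, int(token))


@dataclass(frozen=True)
class TargetRegion:
    """One panel exon: genomic interval plus its place in the transcript."""

    gene: str
    exon_index: int
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"
    cdna_first: str | None = None
    cdna_last: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene} exon {self.exon_index}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TranscriptModel:
    """cDNA boundaries of every panel exon of one gene, in transcript order.

    Coordinates are HGVS c. tokens kept as strings ("-25" = 5'UTR, "80" = CDS,
    "*103" = 3'UTR) so that boundary rendering never re-derives UTR arithmetic.
    """

    gene: str
    exons: dict[int, tuple[str, str]]  # exon_index -> (cdna_first, cdna_last)

    def __post_init__(self) -> None:
        indices = sorted(self.exons)
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(f"{self.gene}: exon indices must be 1..n, got {indices}")
        flat = [tok for i in indices for tok in self.exons[i]]
        keys = [_cdna_key(t) for t in flat]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(f"{self.gene}: cDNA boundaries not strictly increasing")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def junction(self, exon_index: int) -> tuple[str, str]:
        """cDNA tokens flanking the intron after ``exon_index`` (last, next-first)."""
        if exon_index not in self.exons or exon_index + 1 not in self.exons:
            raise KeyError(f"{self.gene}: no junction after exon {exon_index}")
        return self.exons[exon_index][1], self.exons[exon_index + 1][0]


@dataclass
class PanelDesign:
    """Ordered target regions plus the materialized capture footprint."""

    regions: list[TargetRegion]
    flank_bp: int = 20
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        self._check_gene_overlaps()
        self._footprint = self._build_footprint()
        if len(self._footprint) == 0:
            raise ValueError("panel footprint is empty")

    def _check_gene_overlaps(self) -> None:
        for gene, regs in self.genes.items():
            ordered = sorted(regs, key=lambda r: (r.chrom, r.start))
            for a, b in zip(ordered, ordered[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"overlapping exons within gene {gene}")

    @property
    def genes(self) -> dict[str, list[TargetRegion]]:
        out: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            out.setdefault(r.gene, []).append(r)
        return out

    def _build_footprint(self) -> pd.DataFrame:
        frames = []
        for r in self.regions:
            lo = max(0, r.start - self.flank_bp)
            hi = r.end + self.flank_bp
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": r.chrom,
                        "pos": np.arange(lo, hi, dtype=np.int64),
                        "gene": r.gene,
                    }
                )
            )
        fp = pd.concat(frames, ignore_index=True)
        fp = fp.drop_duplicates(subset=["chrom", "pos"], keep="first")
        fp = fp.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return fp

    @property
    def footprint(self) -> pd.DataFrame:
        """Per-position table (chrom, pos, gene) covering the capture, sorted."""
        return self._footprint

    def exon_regions(self, gene: str) -> list[TargetRegion]:
        return sorted(self.genes[gene], key=lambda r: r.exon_index)


@dataclass
class HomologyGroup:
    """Position-aligned gene/pseudogene members sharing ambiguously mapped reads.

    ``position_map`` gives, per member, the genomic position of every aligned
    column (a bijection column <-> position within each member).  The diploid
    baseline is two alleles per member: four for the classic gene+pseudogene
    pair such as PMS2/PMS2CL.
    """

    name: str
    members: list[str]
    position_map: dict[str, pd.DataFrame]  # member -> (chrom, pos) indexed 0..L-1

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"homology group {self.name}: needs >= 2 members")
        lengths = {m: len(self.position_map[m]) for m in self.members}
        if len(set(lengths.values())) != 1:
            raise ValueError(
                f"homology group {self.name}: members have unequal aligned lengths {lengths}"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.position_map[self.members[0]])

    @property
    def baseline_alleles(self) -> int:
        return 2 * len(self.members)

    def member_rows(self) -> pd.DataFrame:
        """Enumerate (group, member_id, chrom, pos, aligned_column) rows."""
        frames = []
        for m in self.members:
            df = self.position_map[m].copy()
            df.insert(0, "member_id", m)
            df.insert(0, "group", self.name)
            df["aligned_column"] = np.arange(len(df), dtype=np.int64)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class CoverageMatrix:
    """Per-nucleotide read depth for a batch over the panel footprint."""

    samples: list[str]
    positions: pd.DataFrame  # chrom, pos, gene — one row per footprint base
    depth: np.ndarray        # (n_samples, n_positions) non-negative ints

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("coverage matrix needs at least one sample")
        if self.depth.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"depth shape {self.depth.shape} != "
                f"({len(self.samples)}, {len(self.positions)})"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def totals(self) -> pd.Series:
        """Total footprint coverage per sample."""
        return pd.Series(self.depth.sum(axis=1), index=self.samples, name="total")

    def sample_row(self, sample: str) -> np.ndarray:
        return self.depth[self.samples.index(sample)]


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_transcript_table(path: str | Path) -> dict[str, TranscriptModel]:
    """Read a TSV (gene, exon_index, cdna_first, cdna_last) into transcript models."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "exon_index", "cdna_first", "cdna_last"}
    if not required.issubset(df.columns):
        raise ValueError(f"transcript table missing columns {required - set(df.columns)}")
    models: dict[str, TranscriptModel] = {}
    for gene, sub in df.groupby("gene", sort=False):
        exons = {
            int(row.exon_index): (row.cdna_first, row.cdna_last)
            for row in sub.itertuples()
        }
        models[gene] = TranscriptModel(gene=gene, exons=exons)
    return models


def load_panel(
    bed_path: str | Path,
    transcript_table_path: str | Path,
    flank_bp: int = 20,
) -> PanelDesign:
    """Load a 4+ column BED (name = "GENE|EXONINDEX") plus transcript table.

    The optional 6th BED column carries strand.  Every gene in the BED must
    have a transcript model covering each of its exons.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#", dtype=str
    )
    if bed.shape[1] < 4:
        raise ValueError("BED must have >= 4 columns (chrom, start, end, name)")
    transcripts = load_transcript_table(transcript_table_path)
    regions = []
    for row in bed.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5] if bed.shape[1] >= 6 and row[5] in {"+", "-"} else "+"
        try:
            gene, exon_str = name.split("|")
            exon_index = int(exon_str)
        except ValueError as exc:
            raise ValueError(f"BED name field not 'GENE|EXONINDEX': {name!r}") from exc
        if gene not in transcripts:
            raise ValueError(f"gene {gene} in BED has no transcript table entry")
        if exon_index not in transcripts[gene].exons:
            raise ValueError(
                f"exon {exon_index} of {gene} in BED missing from transcript table"
            )
        cdna_first, cdna_last = transcripts[gene].exons[exon_index]
        regions.append(
            TargetRegion(
                gene=gene,
                exon_index=exon_index,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                cdna_first=cdna_first,
                cdna_last=cdna_last,
            )
        )
    return PanelDesign(regions=regions, flank_bp=flank_bp, transcripts=transcripts)


def load_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Parse one samtools-depth style TSV (chrom, 1-based pos, depth)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str},
            comment="#",
        )
        df["pos"] = pd.to_numeric(df["pos"], errors="raise")
        df["depth"] = pd.to_numeric(df["depth"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed depth file {path}: {exc}") from exc
    if df["depth"].isna().any() or df["pos"].isna().any():
        bad = int(df.index[df[["pos", "depth"]].isna().any(axis=1)][0]) + 1
        raise ValueError(f"malformed depth file {path}: non-numeric value at line {bad}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate position {first.chrom}:{int(first.pos)} in depth file {path}"
        )
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    df["depth"] = df["depth"].astype(np.int64)
    return df


def load_coverage(
    depth_paths: Mapping[str, str | Path], panel: PanelDesign
) -> CoverageMatrix:
    """Assemble the batch coverage matrix over the panel footprint.

    Footprint positions absent from a sample's file get depth 0 (capture
    dropout, not an error); positions outside the footprint are ignored;
    unknown chromosomes are skipped with a warning.
    """
    fp = panel.footprint
    known_chroms = set(fp["chrom"])
    key = pd.MultiIndex.from_frame(fp[["chrom", "pos"]])
    samples = list(depth_paths)
    depth = np.zeros((len(samples), len(fp)), dtype=np.int64)
    for si, sample in enumerate(samples):
        df = load_depth_tsv(depth_paths[sample])
        unknown = ~df["chrom"].isin(known_chroms)
        if unknown.any():
            logger.warning(
                "sample %s: skipping %d positions on unknown chromosomes %s",
                sample, int(unknown.sum()), sorted(set(df.loc[unknown, "chrom"])),
            )
            df = df[~unknown]
        idx = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        inside = idx >= 0
        depth[si, idx[inside]] = df["depth"].to_numpy()[inside]
        n_missing = len(fp) - int(inside.sum())
        if n_missing:
            logger.warning(
                "sample %s: %d footprint positions missing from depth file (set to 0)",
                sample, n_missing,
            )
    return CoverageMatrix(samples=samples, positions=fp.copy(), depth=depth)


def write_coverage(cov: CoverageMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write one depth TSV per sample (1-based positions); inverse of load_coverage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for si, sample in enumerate(cov.samples):
        df = pd.DataFrame(
            {
                "chrom": cov.positions["chrom"],
                "pos": cov.positions["pos"] + 1,
                "depth": cov.depth[si],
            }
        )
        path = out_dir / f"{sample}.depth.tsv"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[sample] = path
    return paths


def load_homology_map(map_path: str | Path) -> list[HomologyGroup]:
    """Read a TSV (group, member_id, chrom, pos, aligned_column) into groups.

    ``pos`` is 1-based in the file, matching the depth TSV dialect.  Each
    member must cover every aligned column of its group exactly once.
    """
    df = pd.read_csv(
        map_path,
        sep="\t",
        dtype={"group": str, "member_id": str, "chrom": str},
        comment="#",
    )
    required = {"group", "member_id", "chrom", "pos", "aligned_column"}
    if not required.issubset(df.columns):
        raise ValueError(f"homology map missing columns {required - set(df.columns)}")
    groups = []
    for name, sub in df.groupby("group", sort=False):
        columns_by_member = {}
        for member, rows in sub.groupby("member_id", sort=False):
            if rows["aligned_column"].duplicated().any():
                raise ValueError(
                    f"group {name} member {member}: duplicate aligned_column"
                )
            columns_by_member[member] = rows
        col_sets = {m: frozenset(r["aligned_column"]) for m, r in columns_by_member.items()}
        if len(set(col_sets.values())) != 1:
            raise ValueError(
                f"group {name}: aligned columns differ between members"
            )
        position_map = {}
        for member, rows in columns_by_member.items():
            rows = rows.sort_values("aligned_column")
            expected = np.arange(len(rows), dtype=np.int64)
            if not np.array_equal(rows["aligned_column"].to_numpy(), expected):
                raise ValueError(
                    f"group {name} member {member}: aligned columns not contiguous from 0"
                )
            position_map[member] = pd.DataFrame(
                {"chrom": rows["chrom"].to_numpy(), "pos": rows["pos"].to_numpy(np.int64) - 1}
            )
        groups.append(
            HomologyGroup(
                name=name, members=list(position_map), position_map=position_map
            )
        )
    return groups


def write_homology_map(groups: Sequence[HomologyGroup], path: str | Path) -> Path:
    """Write groups back to the TSV dialect read by :func:`load_homology_map`."""
    frames = []
    for g in groups:
        df = g.member_rows()
        df["pos"] = df["pos"] + 1  # back to 1-based
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Batch QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    per_sample: pd.DataFrame  # sample, total, median_depth, qc_pass
    batch_pass: bool
    min_median_depth: float

    def to_tsv(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            fh.write(f"# min_median_depth={self.min_median_depth}\n")
            fh.write(f"# batch_pass={self.batch_pass}\n")
            self.per_sample.to_csv(fh, sep="\t", index=False)
        return Path(path)


def validate_batch(
    cov: CoverageMatrix, min_median_depth: float = DEFAULT_MIN_MEDIAN_DEPTH
) -> QCReport:
    """Per-sample depth QC plus a batch-size check.

    A sample fails when its median per-base depth is below ``min_median_depth``
    (the assay expects deep, >200x coverage); the batch is flagged when fewer
    than four samples are available to form a reference.
    """
    medians = np.median(cov.depth, axis=1)
    per_sample = pd.DataFrame(
        {
            "sample": cov.samples,
            "total": cov.totals.to_numpy(),
            "median_depth": medians,
            "qc_pass": medians >= min_median_depth,
        }
    )
    batch_pass = len(cov.samples) >= MIN_BATCH_SAMPLES
    if not batch_pass:
        logger.warning(
            "batch has %d samples (< %d): reference will be thin",
            len(cov.samples), MIN_BATCH_SAMPLES,
        )
    return QCReport(
        per_sample=per_sample, batch_pass=batch_pass, min_median_depth=min_median_depth
    )
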