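"""Synthetic targeted-capture coverage batches with known spiked CNVs.

The generator reproduces the batch structure that per-position reference
normalization exploits: every sample shares the same per-position capture
efficiency profile (lognormal across positions), library sizes vary between
samples (lognormal), and depth is either the exact expectation (``noise
"none"``) or a Poisson draw around it.  Expected depth at position i of
sample s is

    mean_depth * L_s * E_i * copies_{s,i} / 2

with diploid copies 2 everywhere except inside spiked events.  Defaults match
the assay the caller targets: 200x mean coverage and batches of clinical
size.  A truth set of the spiked events supports parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CNVCall
from .panel_io import (
    CoverageMatrix,
    HomologyGroup,
    PanelDesign,
    TargetRegion,
    TranscriptModel,
)

DEFAULT_MEAN_DEPTH = 200.0


@dataclass(frozen=True)
class SpikeEvent:
    """One spiked CNV: ``copies`` of the segment instead of the diploid two.

    For homology groups the event is spiked into one member's segment; the
    truth record carries ``baseline`` (total alleles, 4 for a pair) and the
    group-scale expected type so recovery scoring matches merged calls.
    """

    sample: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    copies: int
    baseline: int = 2

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must be < end")
        if self.copies < 0:
            raise ValueError("copies must be non-negative")
        if self.copies == self.baseline:
            raise ValueError("event copies equal the baseline: not an event")

    @property
    def type(self) -> str:
        return "del" if self.copies < self.baseline else "dup"

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    events: list[SpikeEvent]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [e.sample for e in self.events],
                "chrom": [e.chrom for e in self.events],
                "start": [e.start + 1 for e in self.events],  # 1-based out
                "end": [e.end for e in self.events],
                "copies": [e.copies for e in self.events],
                "baseline": [e.baseline for e in self.events],
                "type": [e.type for e in self.events],
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, sep="\t", index=False)
        return Path(path)


def load_truth(path: str | Path) -> TruthSet:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    events = [
        SpikeEvent(
            sample=r.sample, chrom=r.chrom, start=int(r.start) - 1, end=int(r.end),
            copies=int(r.copies), baseline=int(getattr(r, "baseline", 2)),
        )
        for r in df.itertuples()
    ]
    return TruthSet(events=events)


@dataclass
class SimConfig:
    panel: PanelDesign
    n_samples: int
    mean_depth: float = DEFAULT_MEAN_DEPTH
    library_size_cv: float = 0.0
    capture_effect_sd: float = 0.0
    noise: str = "none"  # 'none' | 'poisson'
    events: list[SpikeEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.noise not in {"none", "poisson"}:
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.library_size_cv < 0 or self.capture_effect_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")


def simulate_batch(cfg: SimConfig) -> tuple[CoverageMatrix, TruthSet]:
    """Draw one batch; identical (config, seed) gives bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    fp = cfg.panel.footprint
    n_s, n_p = cfg.n_samples, len(fp)
    samples = [f"S{si + 1:02d}" for si in range(n_s)]
    lib = (
        rng.lognormal(0.0, cfg.library_size_cv, size=n_s)
        if cfg.library_size_cv > 0
        else np.ones(n_s)
    )
    eff = (
        rng.lognormal(0.0, cfg.capture_effect_sd, size=n_p)
        if cfg.capture_effect_sd > 0
        else np.ones(n_p)
    )
    copies = np.full((n_s, n_p), 2.0)
    key = pd.MultiIndex.from_frame(fp[["chrom", "pos"]])
    for event in cfg.events:
        if event.sample not in samples:
            raise ValueError(f"event sample {event.sample} not in batch")
        si = samples.index(event.sample)
        want = pd.MultiIndex.from_arrays(
            [
                np.repeat(event.chrom, event.span),
                np.arange(event.start, event.end, dtype=np.int64),
            ]
        )
        idx = key.get_indexer(want)
        if (idx < 0).any():
            raise ValueError(
                f"event {event.chrom}:{event.start + 1}-{event.end} "
                "extends outside the panel footprint"
            )
        # homology events state total alleles over the whole group; the spiked
        # member segment carries the gain/loss, its partners stay diploid
        copies[si, idx] = 2.0 + (event.copies - event.baseline)
    expected = cfg.mean_depth * lib[:, None] * eff[None, :] * copies / 2.0
    if cfg.noise == "poisson":
        depth = rng.poisson(expected).astype(np.int64)
    else:
        depth = np.rint(expected).astype(np.int64)
    return (
        CoverageMatrix(samples=samples, positions=fp.copy(), depth=depth),
        TruthSet(events=list(cfg.events)),
    )


# ---------------------------------------------------------------------------
# Toy panel construction (programmatic fixtures and CLI demo)
# ---------------------------------------------------------------------------

def toy_panel(
    n_genes: int = 4,
    exons_per_gene: int = 4,
    exon_bp: int = 120,
    intron_bp: int = 400,
    gene_gap_bp: int = 5000,
    flank_bp: int = 20,
    chrom: str = "chr1",
    origin: int = 10_000,
    gene_prefix: str = "GENE",
) -> PanelDesign:
    """A regular synthetic panel: ``n_genes`` genes of equal exon structure.

    cDNA coordinates are fully coding (exon k spans
    c.[(k-1)*exon_bp + 1 .. k*exon_bp]), which is all the HGVS layer needs.
    """
    regions: list[TargetRegion] = []
    transcripts: dict[str, TranscriptModel] = {}
    cursor = origin
    for gi in range(n_genes):
        gene = f"{gene_prefix}{gi + 1}"
        exons = {}
        for k in range(1, exons_per_gene + 1):
            start = cursor
            end = start + exon_bp
            first = (k - 1) * exon_bp + 1
            last = k * exon_bp
            exons[k] = (str(first), str(last))
            regions.append(
                TargetRegion(
                    gene=gene, exon_index=k, chrom=chrom, start=start, end=end,
                    strand="+", cdna_first=str(first), cdna_last=str(last),
                )
            )
            cursor = end + intron_bp
        transcripts[gene] = TranscriptModel(gene=gene, exons=exons)
        cursor += gene_gap_bp
    return PanelDesign(regions=regions, flank_bp=flank_bp, transcripts=transcripts)


def toy_homology_group(
    panel: PanelDesign, gene: str, pseudogene: str, name: str = "HOM1"
) -> HomologyGroup:
    """Pair two equally structured panel genes into an aligned homology group.

    Aligned columns enumerate the exon-body positions of each member in
    order; both members must have identical exon counts and lengths.
    """
    maps = {}
    for member in (gene, pseudogene):
        regs = panel.exon_regions(member)
        chroms = np.concatenate([np.repeat(r.chrom, r.end - r.start) for r in regs])
        pos = np.concatenate([np.arange(r.start, r.end) for r in regs])
        maps[member] = pd.DataFrame({"chrom": chroms, "pos": pos.astype(np.int64)})
    return HomologyGroup(name=name, members=[gene, pseudogene], position_map=maps)


def write_panel_files(panel: PanelDesign, out_dir: str | Path) -> dict[str, Path]:
    """Write the BED + transcript table that :func:`panel_io.load_panel` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_path = out_dir / "panel.bed"
    with open(bed_path, "w") as fh:
        for r in panel.regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}|{r.exon_index}\t0\t{r.strand}\n"
            )
    tx_path = out_dir / "transcripts.tsv"
    rows = []
    for gene, tm in panel.transcripts.items():
        for k in sorted(tm.exons):
            first, last = tm.exons[k]
            rows.append((gene, k, first, last))
    pd.DataFrame(
        rows, columns=["gene", "exon_index", "cdna_first", "cdna_last"]
    ).to_csv(tx_path, sep="\t", index=False)
    return {"bed": bed_path, "transcripts": tx_path}


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    sensitivity: float
    precision: float
    per_event: pd.DataFrame  # one row per truth event with recovery status
    n_truth: int
    n_calls: int


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def evaluate(
    calls: Sequence[CNVCall], truth: TruthSet, min_overlap: float = 0.5
) -> EvalResult:
    """Score calls against spiked truth by reciprocal overlap.

    A truth event is recovered when a same-sample, same-type call reciprocally
    overlaps it by at least ``min_overlap``; precision counts calls matched to
    some truth event.  With no calls at all precision is reported as 1.0
    (nothing asserted, nothing wrong).
    """
    matched_calls: set[int] = set()
    rows = []
    for event in truth.events:
        hit = None
        for ci, call in enumerate(calls):
            if call.sample != event.sample or call.type != event.type:
                continue
            if call.chrom != event.chrom:
                continue
            if _reciprocal_overlap(call.start, call.end, event.start, event.end) >= min_overlap:
                hit = ci
                matched_calls.add(ci)
                break
        rows.append(
            {
                "sample": event.sample,
                "chrom": event.chrom,
                "start": event.start + 1,
                "end": event.end,
                "type": event.type,
                "copies": event.copies,
                "recovered": hit is not None,
            }
        )
    n_truth = len(truth.events)
    n_calls = len(calls)
    sensitivity = (
        sum(r["recovered"] for r in rows) / n_truth if n_truth else 1.0
    )
    precision = len(matched_calls) / n_calls if n_calls else 1.0
    return EvalResult(
        sensitivity=sensitivity,
        precision=precision,
        per_event=pd.DataFrame(rows),
        n_truth=n_truth,
        n_calls=n_calls,
    )
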