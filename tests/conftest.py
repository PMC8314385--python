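"""Shared fixtures: toy panels, uniform batches, synthetic ratio tracks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import panelcnv as pc

DATA_DIR = Path(__file__).parent / "data"

# Synthetic stand-in transcript structures for the golden-corpus genes: the
# exon-junction cDNA coordinates are the ones the corpus nomenclature
# strings encode; exon counts and terminal-exon lengths are invented.
CORPUS_JUNCTIONS: dict[str, list[int]] = {
    "MSH2": [366, 1076],
    "MSH6": [260],
    "MLH1": [116, 545],
    "PMS2": [537, 903, 2006],
    "BRCA2": [67, 8487, 8632],
    "ATM": [662, 8850, 9171],
    "PALB2": [2586, 2748],
    "BRCA1": [80, 4185, 4357, 4484, 4986, 5074, 5277, 5332, 5406],
    "RAD51C": [571, 837, 965],
    "CHEK2": [319, 592, 908, 1095, 1461],
    "BARD1": [300],
    "RAD51D": [200],
}


def transcript_from_junctions(gene: str, junctions: list[int]) -> pc.TranscriptModel:
    """Build a transcript model whose exon boundaries sit at the given
    coding-cDNA junction positions (last exon extended arbitrarily)."""
    bounds = [0] + list(junctions) + [junctions[-1] + 500]
    exons = {
        k: (str(bounds[k - 1] + 1), str(bounds[k]))
        for k in range(1, len(bounds))
    }
    return pc.TranscriptModel(gene=gene, exons=exons)


@pytest.fixture(scope="session")
def corpus_transcripts() -> dict[str, pc.TranscriptModel]:
    return {
        gene: transcript_from_junctions(gene, junctions)
        for gene, junctions in CORPUS_JUNCTIONS.items()
    }


@pytest.fixture(scope="session")
def hgvs_corpus() -> list[str]:
    lines = (DATA_DIR / "hgvs_corpus.txt").read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


@pytest.fixture
def small_panel() -> pc.PanelDesign:
    """4 genes x 4 exons of 120 bp, 20 bp flanks, well-separated targets."""
    return pc.toy_panel(n_genes=4, exons_per_gene=4, exon_bp=120)


@pytest.fixture
def homology_panel() -> tuple[pc.PanelDesign, pc.HomologyGroup]:
    panel = pc.toy_panel(n_genes=6, exons_per_gene=4, exon_bp=120)
    group = pc.toy_homology_group(panel, "GENE5", "GENE6")
    return panel, group


def uniform_coverage(
    panel: pc.PanelDesign, n_samples: int = 8, depth: int = 200
) -> pc.CoverageMatrix:
    fp = panel.footprint
    return pc.CoverageMatrix(
        samples=[f"S{si + 1:02d}" for si in range(n_samples)],
        positions=fp.copy(),
        depth=np.full((n_samples, len(fp)), depth, dtype=np.int64),
    )


def flat_ratio_matrix(
    length: int = 1000,
    n_samples: int = 1,
    value: float = 1.0,
    gene: str = "GENE1",
    chrom: str = "chr1",
    origin: int = 1000,
    baseline_copies: int = 2,
) -> pc.RatioMatrix:
    """A single contiguous ratio block at a constant value (direct caller input)."""
    positions = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(origin, origin + length, dtype=np.int64),
            "gene": gene,
        }
    )
    return pc.RatioMatrix(
        samples=[f"S{si + 1:02d}" for si in range(n_samples)],
        positions=positions,
        ratios=np.full((n_samples, length), value, dtype=float),
        mask=np.zeros(length, dtype=bool),
        reference=np.full(length, 200.0),
        baseline_copies=baseline_copies,
    )
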