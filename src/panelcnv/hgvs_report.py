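"""HGVS-style CNV nomenclature and report writing.

Calls are rendered as uncertainty-interval strings of the form
``GENE:c.(L1_L2)_(R1_R2)del|dup``: each breakpoint is known only to lie in
the uncaptured intron between two exons, so the boundary tokens span from the
first uncaptured base past one exon to the first uncaptured base before the
next.  With a 20 bp captured flank that first uncaptured base is the 21st
intronic base, giving the characteristic ``+21``/``-21`` offsets; transcript
ends are open (``?``), with ``-21`` before the first exon and ``*21`` past
the stop codon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .caller import CNVCall
from .panel_io import PanelDesign, TranscriptModel

logger = logging.getLogger("panelcnv")


@dataclass(frozen=True)
class HgvsCnvString:
    """Parsed/renderable CNV nomenclature with two uncertainty boundaries."""

    gene: str
    left: tuple[str, str]
    right: tuple[str, str]
    suffix: str  # 'del' | 'dup'

    def render(self) -> str:
        l1, l2 = self.left
        r1, r2 = self.right
        return f"{self.gene}:c.({l1}_{l2})_({r1}_{r2}){self.suffix}"


def boundary_token(
    tm: TranscriptModel, exon_index: int, side: str, flank_bp: int = 20
) -> str:
    """Uncertainty token for the boundary on ``side`` ('left'/'right') of an
    exon span.

    For a junction after cDNA position N the token is ``N+F_{N+1}-F`` with
    F = flank_bp + 1 (the first intronic base the capture does not cover);
    the transcript start yields ``?_-F`` and the transcript end ``*F_?``.
    """
    offset = flank_bp + 1
    if side == "left":
        if exon_index == 1:
            return f"?_-{offset}"
        last, nxt = tm.junction(exon_index - 1)
        return f"{last}+{offset}_{nxt}-{offset}"
    if side == "right":
        if exon_index == tm.n_exons:
            return f"*{offset}_?"
        last, nxt = tm.junction(exon_index)
        return f"{last}+{offset}_{nxt}-{offset}"
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def hgvs_string(call: CNVCall, tm: TranscriptModel, flank_bp: int = 20) -> HgvsCnvString:
    """Render a call's exon span as an uncertainty-interval CNV string.

    The span is expressed in transcript (cDNA) order, which the exon indices
    already follow on either strand.  Sub-exon calls fall back to the
    exon-level span: read-depth windows do not resolve breakpoints past the
    flanking-intron uncertainty convention.
    """
    if call.first_exon is None or call.last_exon is None:
        raise ValueError("call has no exon span; annotate_exons first")
    if tm.gene != call.gene:
        raise ValueError(f"transcript model {tm.gene} does not match call gene {call.gene}")
    if call.sub_exon:
        logger.warning(
            "%s %s call exons %d-%d has sub-exon boundaries; HGVS reported at exon level",
            call.gene, call.type, call.first_exon, call.last_exon,
        )
    left = boundary_token(tm, call.first_exon, "left", flank_bp)
    right = boundary_token(tm, call.last_exon, "right", flank_bp)
    return HgvsCnvString(
        gene=call.gene,
        left=tuple(left.split("_", 1)),
        right=tuple(right.split("_", 1)),
        suffix=call.type,
    )


_CDNA_POS = r"[-*]?\d+(?:[+-]\d+)?"
_BOUND = rf"(?:\?|{_CDNA_POS})"
_UNCERTAIN_RE = re.compile(
    rf"^(?P<gene>[A-Za-z0-9][A-Za-z0-9_.-]*):c\."
    rf"\((?P<l1>{_BOUND})_(?P<l2>{_BOUND})\)"
    rf"_\((?P<r1>{_BOUND})_(?P<r2>{_BOUND})\)"
    rf"(?P<suffix>del|dup)$"
)
_EXACT_RE = re.compile(
    rf"^(?P<gene>[A-Za-z0-9][A-Za-z0-9_.-]*):c\."
    rf"(?P<a>{_CDNA_POS})_(?P<b>{_CDNA_POS})(?P<suffix>del|dup)$"
)


def parse_hgvs_cnv(text: str) -> HgvsCnvString:
    """Parse a CNV nomenclature string back into its components.

    Accepts the uncertainty-interval dialect produced by :func:`hgvs_string`
    (whitespace tolerated inside tokens, as clinical reports often print) and
    base-resolved two-coordinate strings such as breakpoint-sequenced events,
    which are returned with degenerate single-coordinate boundaries.
    """
    normalized = re.sub(r"\s+", "", text)
    m = _UNCERTAIN_RE.match(normalized)
    if m:
        return HgvsCnvString(
            gene=m["gene"],
            left=(m["l1"], m["l2"]),
            right=(m["r1"], m["r2"]),
            suffix=m["suffix"],
        )
    m = _EXACT_RE.match(normalized)
    if m:
        return HgvsCnvString(
            gene=m["gene"], left=(m["a"], m["a"]), right=(m["b"], m["b"]),
            suffix=m["suffix"],
        )
    # locate the first offending character for the error message
    prefix = re.match(r"[A-Za-z0-9_.-]*:c\.", normalized)
    at = prefix.end() if prefix else 0
    raise ValueError(f"malformed CNV nomenclature at position {at}: {text!r}")


def annotate_hgvs(
    calls: Sequence[CNVCall], panel: PanelDesign
) -> list[CNVCall]:
    """Fill the ``hgvs`` field of every call that has a transcript model."""
    out = []
    for call in calls:
        tm = panel.transcripts.get(call.gene)
        if tm is None or call.first_exon is None:
            if call.group_scope != "homology":
                logger.warning("no transcript model for %s: HGVS omitted", call.gene)
            out.append(call)
            continue
        out.append(
            replace(call, hgvs=hgvs_string(call, tm, panel.flank_bp).render())
        )
    return out


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample", "gene", "type", "chrom", "start", "end", "mean_ratio",
    "copy_number", "exon_span", "sub_exon", "group_scope", "hgvs",
]


def write_report(
    calls: Sequence[CNVCall],
    dest: str | Path,
    config_header: dict | None = None,
    vcf_path: str | Path | None = None,
) -> Path:
    """Write the calls TSV (1-based inclusive coordinates) and optional VCF.

    The header records the run configuration (cutoffs, window, flank,
    normalization mode, simulation seed) as ``# key=value`` lines; rows are
    sorted by sample then coordinate.
    """
    dest = Path(dest)
    ordered = sorted(calls, key=lambda c: (c.sample, c.chrom, c.start))
    with open(dest, "w") as fh:
        for key, value in (config_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for c in ordered:
            span = (
                f"{c.first_exon}-{c.last_exon}" if c.first_exon is not None else ""
            )
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.sample, c.gene, c.type, c.chrom, c.start + 1, c.end,
                        f"{c.mean_ratio:.4f}", c.copy_number, span,
                        str(c.sub_exon).lower(), c.group_scope, c.hgvs or "",
                    )
                )
                + "\n"
            )
    if vcf_path is not None:
        write_vcf(ordered, vcf_path)
    return dest


def write_vcf(calls: Sequence[CNVCall], path: str | Path) -> Path:
    """Write calls as a VCFv4.2 with symbolic <DEL>/<DUP> alleles.

    One record per distinct event locus; per-sample integer copy number in
    FORMAT/CN, with END, SVLEN and SVTYPE in INFO.
    """
    path = Path(path)
    samples = sorted({c.sample for c in calls})
    loci: dict[tuple, dict[str, CNVCall]] = {}
    for c in calls:
        loci.setdefault((c.chrom, c.start, c.end, c.type), {})[c.sample] = c
    contigs = sorted({c.chrom for c in calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelcnv\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (chrom, start, end, typ), by_sample in sorted(loci.items()):
            svtype = "DEL" if typ == "del" else "DUP"
            svlen = end - start
            if typ == "del":
                svlen = -svlen
            cn_fields = [
                str(by_sample[s].copy_number) if s in by_sample else "."
                for s in samples
            ]
            # SV convention: POS is the padding base before the event, END the
            # last event base (both 1-based), so END - POS == |SVLEN|
            fh.write(
                f"{chrom}\t{start}\t.\tN\t<{svtype}>\t.\tPASS\t"
                f"END={end};SVLEN={svlen};SVTYPE={svtype}\tCN\t"
                + "\t".join(cn_fields)
                + "\n"
            )
    return path
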