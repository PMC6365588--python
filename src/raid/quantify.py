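"""Paired FASTQ → matched mRNA and ARC UMI count tables.

Every read pair is processed in three steps:

1. **Cell demultiplexing** — exact whitelist match on the cell-barcode
   substring of read 2; the pair is rejected when any base of the
   barcode+UMI region falls below the quality threshold (default Q10).
2. **ARC detection** — anchor-start positions inside the stagger-derived
   window of read 1 are scanned in ascending order; the first position
   whose 12-mer is within the mismatch budget (default 1) of the anchor
   wins.  The 10-nt antibody barcode and 15-nt ARC UMI immediately
   upstream are then extracted and the barcode matched against the panel.
3. **Transcript assignment** — reads without an ARC hit are truncated to
   ``cut_length`` (default 50) and assigned by unanimous unique-k-mer
   vote against the transcript index.

Counting is UMI-collapsed by exact identity: each distinct
``(cell, antibody, ARC UMI)`` or ``(cell, gene, read-2 UMI)`` tuple
contributes one count.  ARC classification takes precedence over
transcript assignment, so the read-fate tallies partition the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Set, Tuple

import pysam

from .arc_model import (
    AntibodyPanel,
    ArcLayout,
    CellBarcodeIndex,
    TranscriptIndex,
    hamming_at_most,
)
from .matrix import CountMatrix


@dataclass
class ReadPair:
    """One sequenced molecule: 63-nt read 1 and 14-nt read 2 with qualities."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class ArcHit:
    antibody_name: str
    arc_umi: str
    anchor_position: int
    anchor_mismatches: int


@dataclass
class DemuxResult:
    status: str  # "ok" | "quality_fail" | "unassigned"
    cell_name: Optional[str] = None
    read2_umi: Optional[str] = None


@dataclass
class QuantifySettings:
    """Pipeline settings; defaults are the published ones."""

    min_bc_quality: int = 10
    cut_length: int = 50
    barcode_mismatches: int = 0  # tolerance for the 10-nt antibody barcode
    swap_reads: bool = False     # accept libraries stored with read roles swapped


def read_pairs(
    r1_path: str | Path, r2_path: str | Path, swap_reads: bool = False
) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    if swap_reads:
        r1_path, r2_path = r2_path, r1_path
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            if e1.name != e2.name:
                raise ValueError(f"unpaired reads: {e1.name} vs {e2.name}")
            yield ReadPair(
                e1.name,
                e1.sequence.upper(),
                e1.quality or "",
                e2.sequence.upper(),
                e2.quality or "",
            )


def demultiplex_cell(
    pair: ReadPair, index: CellBarcodeIndex, min_bc_quality: int = 10
) -> DemuxResult:
    """Assign a read pair to a whitelist cell from read 2.

    The quality gate applies to the whole barcode+UMI region; the
    whitelist match on the cell barcode is exact.  Rejections are
    reported as statuses, never raised.
    """
    region_len = index.read2_len
    if len(pair.seq2) < region_len:
        return DemuxResult("unassigned")
    qual = pair.qual2[:region_len]
    if qual and min(ord(c) - 33 for c in qual) < min_bc_quality:
        return DemuxResult("quality_fail")
    barcode, umi = index.split_read2(pair.seq2)
    cell = index.lookup(barcode)
    if cell is None:
        return DemuxResult("unassigned")
    return DemuxResult("ok", cell, umi)


def detect_arc(
    seq1: str,
    layout: ArcLayout,
    panel: AntibodyPanel,
    barcode_mismatches: int = 0,
    full_scan: bool = False,
) -> Optional[ArcHit]:
    """Locate the ARC anchor on read 1 and extract antibody barcode + UMI.

    Scans candidate anchor starts in the stagger-derived window in
    ascending order; the first position within the anchor mismatch budget
    wins (a later exact match never preempts an earlier 1-mismatch
    match).  Returns ``None`` when no window position qualifies or the
    extracted barcode is not in the panel.  ``full_scan=True`` widens the
    window to the whole read (diagnostic use).
    """
    anchor = layout.anchor
    alen = layout.anchor_len
    if full_scan:
        lo = layout.umi_len + layout.ab_barcode_len
        hi = len(seq1) - alen
    else:
        lo, hi = layout.anchor_window
        hi = min(hi, len(seq1) - alen)
    for pos in range(lo, hi + 1):
        mm = hamming_at_most(seq1[pos : pos + alen], anchor, layout.max_anchor_mismatches)
        if mm is None:
            continue
        barcode = seq1[pos - layout.ab_barcode_len : pos]
        umi = seq1[pos - layout.ab_barcode_len - layout.umi_len : pos - layout.ab_barcode_len]
        antibody = panel.match(barcode, barcode_mismatches)
        if antibody is None:
            return None
        return ArcHit(antibody, umi, pos, mm)
    return None


def assign_transcript(
    seq1: str, index: TranscriptIndex, cut_length: int = 50
) -> Optional[str]:
    """Assign a read to a gene by unanimous vote of its unique k-mers.

    The read is truncated to ``cut_length`` first.  Returns ``None`` on
    zero or conflicting votes.
    """
    if cut_length < index.kmer_len:
        raise ValueError("cut_length must be >= kmer_len")
    seq = seq1[:cut_length]
    kmer_map = index.kmer_map
    k = index.kmer_len
    winner: Optional[str] = None
    for i in range(len(seq) - k + 1):
        gene = kmer_map.get(seq[i : i + k])
        if gene is None:
            continue
        if winner is None:
            winner = gene
        elif gene != winner:
            return None  # conflicting votes
    return winner


def tally_counts(
    pairs: Iterable[ReadPair],
    layout: ArcLayout,
    panel: AntibodyPanel,
    cell_index: CellBarcodeIndex,
    transcript_index: TranscriptIndex,
    settings: QuantifySettings | None = None,
) -> Tuple[CountMatrix, CountMatrix, Dict[str, int]]:
    """Stream read pairs into matched mRNA and ARC count matrices.

    Both matrices span the identical, complete whitelist cell list
    (zero-count cells included) so the two modalities can be combined
    per cell downstream.  The returned report counts reads by fate;
    the fates partition the input:
    ``quality_fail + unassigned_cell + arc + mrna + neither == total``.
    """
    settings = settings or QuantifySettings()
    arc_tallies: Set[Tuple[str, str, str]] = set()
    mrna_tallies: Set[Tuple[str, str, str]] = set()
    report = {
        "total": 0,
        "quality_fail": 0,
        "unassigned_cell": 0,
        "arc": 0,
        "mrna": 0,
        "neither": 0,
    }
    for pair in pairs:
        report["total"] += 1
        demux = demultiplex_cell(pair, cell_index, settings.min_bc_quality)
        if demux.status == "quality_fail":
            report["quality_fail"] += 1
            continue
        if demux.status == "unassigned":
            report["unassigned_cell"] += 1
            continue
        hit = detect_arc(pair.seq1, layout, panel, settings.barcode_mismatches)
        if hit is not None:
            arc_tallies.add((demux.cell_name, hit.antibody_name, hit.arc_umi))
            report["arc"] += 1
            continue
        gene = assign_transcript(pair.seq1, transcript_index, settings.cut_length)
        if gene is not None:
            mrna_tallies.add((demux.cell_name, gene, demux.read2_umi))
            report["mrna"] += 1
        else:
            report["neither"] += 1

    cells = cell_index.cell_names
    mrna = CountMatrix.from_tallies("mRNA", mrna_tallies, cells, transcript_index.genes)
    arc = CountMatrix.from_tallies("ARC", arc_tallies, cells, panel.names)
    return mrna, arc, report


def quantify_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    layout: ArcLayout,
    panel: AntibodyPanel,
    cell_index: CellBarcodeIndex,
    transcript_index: TranscriptIndex,
    settings: QuantifySettings | None = None,
) -> Tuple[CountMatrix, CountMatrix, Dict[str, int]]:
    """Convenience wrapper: FASTQ pair on disk → count matrices + report."""
    settings = settings or QuantifySettings()
    pairs = read_pairs(r1_path, r2_path, settings.swap_reads)
    return tally_counts(pairs, layout, panel, cell_index, transcript_index, settings)


def write_tables(
    mrna: CountMatrix,
    arc: CountMatrix,
    out_dir: str | Path,
    report: Optional[Dict[str, int]] = None,
) -> Dict[str, Path]:
    """Write count tables (features as rows, cells as columns) and the run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": mrna.to_tsv(out_dir / "counts_mrna.tsv"),
        "arc": arc.to_tsv(out_dir / "counts_arc.tsv"),
    }
    if report is not None:
        report_path = out_dir / "run_report.json"
        report_path.write_text(json.dumps(report, indent=2))
        paths["report"] = report_path
    return paths
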