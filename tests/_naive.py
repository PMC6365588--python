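"""Brute-force oracle: an independent re-implementation of read tallying.

Deliberately naive — per-read dictionary bookkeeping, full scans, no
early exits — so it shares no code path with the streaming
implementation it cross-checks.
"""

from collections import defaultdict

import pandas as pd


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def naive_tally(pairs, layout, panel, cell_index, transcript_index,
                min_bc_quality=10, cut_length=50):
    """Return (mrna DataFrame, arc DataFrame, fate dict), features x cells."""
    barcode_to_cell = dict((b, n) for n, b in cell_index.entries)
    barcode_to_ab = dict((b, n) for n, b in panel.entries)
    lo, hi = layout.anchor_window
    arc_seen = defaultdict(set)   # (cell, antibody) -> set of ARC UMIs
    mrna_seen = defaultdict(set)  # (cell, gene) -> set of read-2 UMIs
    fates = {"total": 0, "quality_fail": 0, "unassigned_cell": 0,
             "arc": 0, "mrna": 0, "neither": 0}
    for pair in pairs:
        fates["total"] += 1
        region = pair.qual2[: cell_index.read2_len]
        if any(ord(c) - 33 < min_bc_quality for c in region):
            fates["quality_fail"] += 1
            continue
        if cell_index.read2_order == "umi_first":
            r2_umi = pair.seq2[: cell_index.read2_umi_len]
            cb = pair.seq2[cell_index.read2_umi_len : cell_index.read2_len]
        else:
            cb = pair.seq2[: cell_index.cb_len]
            r2_umi = pair.seq2[cell_index.cb_len : cell_index.read2_len]
        cell = barcode_to_cell.get(cb)
        if cell is None:
            fates["unassigned_cell"] += 1
            continue
        # full scan of every window anchor position, collect all qualifiers
        qualifying = []
        for p in range(lo, hi + 1):
            if p + layout.anchor_len > len(pair.seq1):
                continue
            mm = _hamming(pair.seq1[p : p + layout.anchor_len], layout.anchor)
            if mm <= layout.max_anchor_mismatches:
                qualifying.append(p)
        is_arc = False
        if qualifying:
            p = min(qualifying)
            bc = pair.seq1[p - layout.ab_barcode_len : p]
            umi = pair.seq1[p - layout.ab_barcode_len - layout.umi_len : p - layout.ab_barcode_len]
            ab = barcode_to_ab.get(bc)
            if ab is not None:
                arc_seen[(cell, ab)].add(umi)
                fates["arc"] += 1
                is_arc = True
        if is_arc:
            continue
        # transcript: vote over all k-mers of the truncated read
        seq = pair.seq1[:cut_length]
        votes = set()
        for i in range(len(seq) - transcript_index.kmer_len + 1):
            g = transcript_index.kmer_map.get(seq[i : i + transcript_index.kmer_len])
            if g is not None:
                votes.add(g)
        if len(votes) == 1:
            mrna_seen[(cell, votes.pop())].add(r2_umi)
            fates["mrna"] += 1
        else:
            fates["neither"] += 1

    cells = cell_index.cell_names
    mrna = pd.DataFrame(0, index=list(transcript_index.genes), columns=cells)
    for (cell, gene), umis in mrna_seen.items():
        mrna.loc[gene, cell] = len(umis)
    arc = pd.DataFrame(0, index=list(panel.names), columns=cells)
    for (cell, ab), umis in arc_seen.items():
        arc.loc[ab, cell] = len(umis)
    return mrna, arc, fates
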