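"""ARC read architecture, antibody panels, cell whitelists, transcript index.

An Antibody RNA-barcode Conjugate (ARC) is an antibody carrying an in
vitro transcribed RNA tag.  On read 1 the tag reads, 5'→3':

    stagger (1–8 nt) · UMI (15 nt) · antibody barcode (10 nt) · anchor (12 nt) · tail

The fixed 12-nt anchor (``ATCAGTCAACAG``) classifies a read as ARC and
locates the barcode/UMI fields; together with the 10-nt antibody barcode
it forms a 22-nt antibody-identification span.  Because the stagger
length varies over a known range, the anchor start is confined to a
derived window on read 1, ``[stagger_min + umi_len + ab_barcode_len,
stagger_max + umi_len + ab_barcode_len]`` (0-based, inclusive; [26, 33]
with defaults).  Coordinates are 0-based half-open throughout and only
the forward strand of read 1 is ever searched: the library is
strand-specific by construction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

#: Fixed identification sequence inside every ARC barcode.
DEFAULT_ANCHOR = "ATCAGTCAACAG"

#: Illumina read-primer motif that immediately precedes the stagger in the
#: ARC DNA template.
READ_PRIMER_MOTIF = "CTCTTCCGATCT"


class MalformedTemplateError(ValueError):
    """Template lacks a required motif (read primer or anchor)."""


class TemplateParseError(ValueError):
    """Template contains characters outside the expected alphabet."""


class PanelValidationError(ValueError):
    """Antibody panel fails its separation or uniqueness requirements."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def hamming_at_most(a: str, b: str, limit: int) -> Optional[int]:
    """Hamming distance if ≤ ``limit``, else ``None`` (early exit)."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return None
    return mismatches


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


# ---------------------------------------------------------------------------
# ArcLayout
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ArcLayout:
    """Geometry of the ARC portion of read 1.

    Defaults encode the published architecture: a 12-nt anchor, 15-nt UMI,
    10-nt antibody barcode and a 1–8-nt stagger, tolerating one mismatch
    in the anchor.
    """

    anchor: str = DEFAULT_ANCHOR
    umi_len: int = 15
    ab_barcode_len: int = 10
    stagger_min: int = 1
    stagger_max: int = 8
    max_anchor_mismatches: int = 1

    def __post_init__(self) -> None:
        _check_dna(self.anchor, "anchor")
        if self.umi_len <= 0 or self.ab_barcode_len <= 0:
            raise ValueError("umi_len and ab_barcode_len must be positive")
        if self.stagger_min < 1:
            raise ValueError("stagger_min must be >= 1")
        if self.stagger_max < self.stagger_min:
            raise ValueError("stagger_max must be >= stagger_min")
        if self.max_anchor_mismatches < 0:
            raise ValueError("max_anchor_mismatches must be >= 0")

    @property
    def anchor_len(self) -> int:
        return len(self.anchor)

    @property
    def identification_span(self) -> int:
        """Nucleotides used for antibody identification (barcode + anchor)."""
        return self.ab_barcode_len + self.anchor_len

    @property
    def anchor_window(self) -> Tuple[int, int]:
        """Inclusive 0-based range of admissible anchor start positions."""
        offset = self.umi_len + self.ab_barcode_len
        return (self.stagger_min + offset, self.stagger_max + offset)

    def anchor_start(self, stagger_len: int) -> int:
        """Anchor start position on a read rendered with ``stagger_len``."""
        if not self.stagger_min <= stagger_len <= self.stagger_max:
            raise ValueError(
                f"stagger length {stagger_len} outside [{self.stagger_min}, {self.stagger_max}]"
            )
        return stagger_len + self.umi_len + self.ab_barcode_len


# ---------------------------------------------------------------------------
# Template parsing
# ---------------------------------------------------------------------------
def _clean_template(template: str) -> str:
    """Strip layout artifacts (whitespace, hyphens, emphasis) and upcase."""
    return re.sub(r"[\s\-*_']", "", template).upper()


_PLACEHOLDER_RE = re.compile(r"\[(\d+)[A-Z0-9]*\]")


def parse_template_spec(template: str, anchor: str = DEFAULT_ANCHOR) -> ArcLayout:
    """Derive an :class:`ArcLayout` from an ARC DNA template string.

    The template is expected to contain the Illumina read-primer motif
    ``CTCTTCCGATCT`` followed by a rendered stagger, a run of ``N``
    placeholders for the UMI, an antibody-barcode placeholder (either a
    bracketed ``[10 nt antibody barcode]`` annotation or a run of ``B``),
    and one exact occurrence of the anchor.  The rendered stagger is taken
    as the longest stagger variant, so ``stagger_max`` equals its length
    while ``stagger_min`` keeps the default of 1.

    Raises
    ------
    TemplateParseError
        If non-IUPAC characters remain after removing placeholders.
    MalformedTemplateError
        If the read-primer motif or the anchor is missing, or the
        stagger/UMI/barcode structure cannot be located.
    """
    _check_dna(anchor, "anchor")
    cleaned = _clean_template(template)
    residue = _PLACEHOLDER_RE.sub("", cleaned)
    bad = set(residue) - (DNA_ALPHABET | {"N", "B"})
    if bad:
        raise TemplateParseError(f"template contains unexpected characters: {sorted(bad)}")
    if anchor not in cleaned:
        raise MalformedTemplateError("anchor sequence not found in template")
    motif_at = cleaned.find(READ_PRIMER_MOTIF)
    if motif_at < 0:
        raise MalformedTemplateError("read-primer motif CTCTTCCGATCT not found in template")
    tail = cleaned[motif_at + len(READ_PRIMER_MOTIF):]
    structure = re.match(
        r"(?P<stagger>[ACGT]*?)(?P<umi>N+)(?:\[(?P<bclen>\d+)[A-Z0-9]*\]|(?P<brun>B+))"
        + re.escape(anchor),
        tail,
    )
    if structure is None:
        raise MalformedTemplateError(
            "could not locate stagger/UMI/antibody-barcode placeholders before the anchor"
        )
    umi_len = len(structure.group("umi"))
    if structure.group("bclen") is not None:
        ab_barcode_len = int(structure.group("bclen"))
    else:
        ab_barcode_len = len(structure.group("brun"))
    stagger = structure.group("stagger")
    stagger_max = len(stagger) if stagger else 8
    return ArcLayout(
        anchor=anchor,
        umi_len=umi_len,
        ab_barcode_len=ab_barcode_len,
        stagger_min=1,
        stagger_max=stagger_max,
    )


# ---------------------------------------------------------------------------
# Antibody panel
# ---------------------------------------------------------------------------
@dataclass
class AntibodyPanel:
    """Whitelist of (antibody name, barcode) pairs."""

    entries: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise PanelValidationError("antibody panel is empty")
        names = [n for n, _ in self.entries]
        barcodes = [b.upper() for _, b in self.entries]
        if len(set(names)) != len(names):
            raise PanelValidationError("duplicate antibody names")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise PanelValidationError("antibody barcodes have differing lengths")
        for b in barcodes:
            _check_dna(b, "antibody barcode")
        self.entries = list(zip(names, barcodes))
        self._by_barcode: Dict[str, str] = {b: n for n, b in self.entries}
        self._by_name: Dict[str, str] = dict(self.entries)

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.entries]

    @property
    def barcode_len(self) -> int:
        return len(self.entries[0][1])

    def barcode_of(self, name: str) -> str:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown antibody {name!r}") from None

    def match(self, barcode: str, max_mismatches: int = 0) -> Optional[str]:
        """Antibody name for an observed barcode, or ``None``.

        Exact dictionary lookup when ``max_mismatches`` is 0; otherwise the
        unique whitelist entry within the tolerance (panel separation must
        have been validated so at most one can qualify).
        """
        name = self._by_barcode.get(barcode)
        if name is not None or max_mismatches == 0:
            return name
        hits = [
            n
            for n, b in self.entries
            if hamming_at_most(barcode, b, max_mismatches) is not None
        ]
        if len(hits) == 1:
            return hits[0]
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AntibodyPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(list(zip(df["antibody_name"], df["barcode"])))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.entries, columns=["antibody_name", "barcode"]).to_csv(
            path, sep="\t", index=False
        )
        return path


@dataclass
class PanelReport:
    ok: bool
    min_pairwise_hamming: Optional[int]
    required_distance: int
    messages: List[str] = field(default_factory=list)


def validate_panel(panel: AntibodyPanel, tolerated_mismatches: int = 0) -> PanelReport:
    """Check that barcode separation supports the matching tolerance.

    Matching with up to ``m`` mismatches is unambiguous iff the minimum
    pairwise Hamming distance among whitelist barcodes is at least
    ``2 m + 1``.  The report is invariant to entry order.
    """
    if tolerated_mismatches < 0:
        raise ValueError("tolerated_mismatches must be >= 0")
    required = 2 * tolerated_mismatches + 1
    messages: List[str] = []
    if len(panel.entries) == 1:
        return PanelReport(True, None, required, ["single-entry panel"])
    min_d = min(
        hamming(a, b) for (_, a), (_, b) in itertools.combinations(panel.entries, 2)
    )
    ok = min_d >= required
    if min_d == 0:
        messages.append("duplicate barcodes in panel")
    elif not ok:
        messages.append(
            f"minimum pairwise Hamming distance {min_d} < {required} required for "
            f"{tolerated_mismatches}-mismatch matching"
        )
    return PanelReport(ok, min_d, required, messages)


# ---------------------------------------------------------------------------
# Cell barcode whitelist
# ---------------------------------------------------------------------------
@dataclass
class CellBarcodeIndex:
    """Plate-sorted cell whitelist and the read-2 layout that carries it.

    Read 2 is ``read2_umi_len`` + ``cb_len`` bases (14 by default, CEL-Seq2
    convention: 6-nt UMI first, then the 8-nt cell barcode).
    """

    entries: List[Tuple[str, str]]
    cb_len: int = 8
    read2_umi_len: int = 6
    read2_order: str = "umi_first"

    def __post_init__(self) -> None:
        if self.read2_order not in ("umi_first", "barcode_first"):
            raise ValueError("read2_order must be 'umi_first' or 'barcode_first'")
        names = [n for n, _ in self.entries]
        barcodes = [b.upper() for _, b in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell names")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate cell barcodes")
        for b in barcodes:
            _check_dna(b, "cell barcode")
            if len(b) != self.cb_len:
                raise ValueError(f"cell barcode {b} is not {self.cb_len} nt")
        self.entries = list(zip(names, barcodes))
        self._by_barcode: Dict[str, str] = {b: n for n, b in self.entries}
        self._by_cell: Dict[str, str] = dict(self.entries)

    @property
    def read2_len(self) -> int:
        return self.cb_len + self.read2_umi_len

    @property
    def cell_names(self) -> List[str]:
        return [n for n, _ in self.entries]

    def barcode_of(self, cell: str) -> str:
        try:
            return self._by_cell[cell]
        except KeyError:
            raise KeyError(f"unknown cell {cell!r}") from None

    def lookup(self, barcode: str) -> Optional[str]:
        return self._by_barcode.get(barcode)

    def split_read2(self, seq2: str) -> Tuple[str, str]:
        """Return ``(cell_barcode, read2_umi)`` from a read-2 sequence."""
        if self.read2_order == "umi_first":
            return seq2[self.read2_umi_len:self.read2_len], seq2[: self.read2_umi_len]
        return seq2[: self.cb_len], seq2[self.cb_len:self.read2_len]

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "CellBarcodeIndex":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(list(zip(df["cell_name"], df["barcode"])), **kwargs)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.entries, columns=["cell_name", "barcode"]).to_csv(
            path, sep="\t", index=False
        )
        return path


# ---------------------------------------------------------------------------
# Transcript index
# ---------------------------------------------------------------------------
@dataclass
class TranscriptIndex:
    """Unique-k-mer transcript assigner.

    Stores only k-mers that occur in exactly one gene of the reference;
    reads voting for more than one gene (or none) stay unassigned.  This
    deterministic index stands in for a full aligner and is adequate for
    transcript references at desk scale.
    """

    genes: List[str]
    kmer_len: int
    kmer_map: Dict[str, str]
    n_distinct_kmers: int
    n_discarded_kmers: int

    @property
    def fraction_discarded(self) -> float:
        if self.n_distinct_kmers == 0:
            return 0.0
        return self.n_discarded_kmers / self.n_distinct_kmers


def read_reference_fasta(path: str | Path) -> Dict[str, str]:
    """Load a transcript reference; record ID is the gene name."""
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate gene name in reference: {record.id}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def build_transcript_index(
    reference: str | Path | Mapping[str, str], kmer_len: int = 21
) -> TranscriptIndex:
    """Index every k-mer that is unique to one gene of the reference.

    ``reference`` may be a FASTA path or a gene→sequence mapping.  K-mers
    are taken from the forward strand only.
    """
    if kmer_len <= 0:
        raise ValueError("kmer_len must be positive")
    if not isinstance(reference, Mapping):
        reference = read_reference_fasta(reference)
    if not reference:
        raise ValueError("empty transcript reference")
    owners: Dict[str, Optional[str]] = {}
    for gene, seq in reference.items():
        seq = seq.upper()
        if len(seq) < kmer_len:
            raise ValueError(f"sequence for {gene} shorter than kmer_len={kmer_len}")
        seen_here = set()
        for i in range(len(seq) - kmer_len + 1):
            kmer = seq[i : i + kmer_len]
            if kmer in seen_here:
                continue
            seen_here.add(kmer)
            if kmer not in owners:
                owners[kmer] = gene
            elif owners[kmer] != gene:
                owners[kmer] = None  # shared between genes -> discard
    kmer_map = {k: g for k, g in owners.items() if g is not None}
    n_distinct = len(owners)
    return TranscriptIndex(
        genes=list(reference.keys()),
        kmer_len=kmer_len,
        kmer_map=kmer_map,
        n_distinct_kmers=n_distinct,
        n_discarded_kmers=n_distinct - len(kmer_map),
    )
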