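"""Synthetic RAID libraries with known ground truth.

The simulator emulates a two-condition keratinocyte experiment: an
untreated population and a population treated with an EGFR inhibitor to
induce differentiation.  Per-cell molecule counts for genes and for a
six-antibody ARC panel are drawn from a negative-binomial model with
multiplicative group effects:

* stem-signature genes are down-regulated in the treated group,
* differentiation-signature genes are up-regulated,
* phospho-pathway ARCs (pFAK, pRPS6) drop while differentiation-marker
  ARCs (NOTCH1, TGM1, KLK6) rise and JAG1 falls slightly,
* a configurable fraction of treated cells ("retainers") keep pFAK and
  their stem-gene expression at untreated-like levels, producing the
  bimodal treated pFAK distribution and the pFAK-high / stem-score
  association the analysis stage is meant to recover.

Molecules can then be rendered into a paired-FASTQ library with the RAID
read architecture (63-nt read 1, 14-nt read 2) so the quantification
stage has a known answer.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .arc_model import (
    READ_PRIMER_MOTIF,
    AntibodyPanel,
    ArcLayout,
    CellBarcodeIndex,
    hamming_at_most,
)
from .matrix import CountMatrix

_BASES = np.array(list("ACGT"))

#: T7 leader of the ARC DNA template, up to and including the read-primer motif.
TEMPLATE_LEADER = "GGATCCTAATACGACTCACTATAGGGAGACCGACGAAACTGTTAACGTCGCACGACGCTCTTCCGATCT"

#: Sequence downstream of the anchor on the ARC (template tail + poly-A).
ARC_DOWNSTREAM = (
    "ATAAGCGTGAGATAGGGCATTACCGAGGCCTGGAGCATTGCCGATACCGAGAGTATTAGCTACGTTGCAGAGGATGCGACGGATGC"
    + "A" * 28
)

#: Longest stagger variant; shorter staggers are its prefixes.
STAGGER_BASE = "GTCAGTCA"

DEFAULT_ANTIBODIES = ("pFAK", "pRPS6", "NOTCH1", "JAG1", "KLK6", "TGM1")


def _stagger_seq(stagger_len: int) -> str:
    reps = -(-stagger_len // len(STAGGER_BASE))
    return (STAGGER_BASE * reps)[:stagger_len]


def build_template_spec(layout: ArcLayout) -> str:
    """Render an ARC DNA template string for a layout.

    The rendered stagger is the longest variant (``stagger_max`` bases),
    the UMI is a run of ``N`` and the antibody barcode a bracketed
    placeholder — the same conventions :func:`~raid.arc_model.parse_template_spec`
    understands, so parse(build(layout)) round-trips for layouts with
    ``stagger_min == 1``.
    """
    return (
        TEMPLATE_LEADER
        + _stagger_seq(layout.stagger_max)
        + "N" * layout.umi_len
        + f"[{layout.ab_barcode_len} nt antibody barcode]"
        + layout.anchor
        + ARC_DOWNSTREAM
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _unique_random_dna(rng: np.random.Generator, length: int, n: int) -> List[str]:
    """Draw ``n`` distinct random sequences of the given length."""
    if n > 4 ** length:
        raise ValueError("sequence space too small for distinct draws")
    out: set[str] = set()
    while len(out) < n:
        out.add(random_dna(rng, length))
    return sorted(out)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------
@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Count model: gene (and antibody) counts are negative binomial with a
    per-feature mean and a shared dispersion (shape) parameter; group
    effects act multiplicatively on the mean.  Defaults mirror the
    emulated experiment: 530 stem and 226 differentiation genes, treated
    stem genes at 0.25×, treated differentiation genes at 4×, and a
    bimodal treated pFAK response with a 0.3 retainer fraction.
    """

    n_cells_per_group: int = 200
    n_genes: int = 2000
    n_stem_genes: int = 530
    n_diff_genes: int = 226
    n_integrin_substrates: int = 4
    antibodies: Tuple[str, ...] = DEFAULT_ANTIBODIES
    pfak_antibody: str = "pFAK"

    # negative-binomial count model
    mrna_mean: float = 4.0          # mean molecules per gene per cell
    mrna_dispersion: float = 2.0    # NB shape; smaller = more overdispersed
    gene_mean_sigma: float = 0.6    # lognormal spread of per-gene baseline means
    arc_mean: float = 120.0         # mean molecules per antibody per cell
    arc_dispersion: float = 10.0

    # treated-group effects (multiplicative on the mean)
    stem_fold_treated: float = 0.25
    diff_fold_treated: float = 4.0
    retainer_fraction: float = 0.3
    retainer_stem_fold: float = 1.0   # stem-gene fold in pFAK-retaining treated cells
    pfak_retainer_fold: float = 1.0
    pfak_loser_fold: float = 0.15
    arc_folds_treated: Dict[str, float] = field(
        default_factory=lambda: {
            "pRPS6": 0.25,
            "NOTCH1": 3.0,
            "JAG1": 0.8,
            "KLK6": 3.0,
            "TGM1": 3.0,
        }
    )

    # sequencing channel
    error_rate: float = 0.001       # per-base substitution probability
    low_quality_fraction: float = 0.0  # fraction of read pairs with a planted Q9 base in read 2
    read1_len: int = 63
    read2_len: int = 14
    reference_len: int = 240        # synthetic transcript length
    unique_umis: bool = True        # draw UMIs without replacement per (cell, feature)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_group <= 0 or self.n_genes <= 0:
            raise ValueError("need at least one cell and one gene")
        if self.n_stem_genes + self.n_diff_genes > self.n_genes:
            raise ValueError("signature genes exceed n_genes")
        if self.n_integrin_substrates > self.n_stem_genes:
            raise ValueError("integrin substrates must be a subset of stem genes")
        if not 0.0 <= self.retainer_fraction <= 1.0:
            raise ValueError("retainer_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        for fold in (
            self.stem_fold_treated,
            self.diff_fold_treated,
            self.retainer_stem_fold,
            self.pfak_retainer_fold,
            self.pfak_loser_fold,
            *self.arc_folds_treated.values(),
        ):
            if fold <= 0:
                raise ValueError("fold effects must be positive")
        if self.pfak_antibody not in self.antibodies:
            raise ValueError("pfak_antibody must be in the antibody list")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "antibodies" in raw:
            raw["antibodies"] = tuple(raw["antibodies"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = asdict(self)
        raw["antibodies"] = list(raw["antibodies"])
        path.write_text(yaml.safe_dump(raw))
        return path


@dataclass
class GroundTruth:
    """True molecule counts per cell with group labels and gene roles."""

    cells: pd.DataFrame            # index = cell name; columns: group, pfak_retainer
    gene_counts: pd.DataFrame      # cells x genes, int
    arc_counts: pd.DataFrame       # cells x antibodies, int
    signature_assignment: Dict[str, str]   # gene -> stem | differentiation | neither
    integrin_substrates: List[str]

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate cell names")
        if self.cells.empty:
            raise ValueError("no cells")
        if set(self.cells["group"]) != {"untreated", "treated"} and len(
            set(self.cells["group"])
        ) < 1:
            raise ValueError("groups must be non-empty")
        if (self.gene_counts.to_numpy() < 0).any() or (self.arc_counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> List[str]:
        return list(self.gene_counts.columns)

    @property
    def antibodies(self) -> List[str]:
        return list(self.arc_counts.columns)

    def cells_in_group(self, group: str) -> List[str]:
        return list(self.cells.index[self.cells["group"] == group])

    def signature_genes(self, role: str) -> List[str]:
        return [g for g, r in self.signature_assignment.items() if r == role]

    def total_molecules(self) -> int:
        return int(self.gene_counts.to_numpy().sum() + self.arc_counts.to_numpy().sum())


def simulate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw per-cell true molecule counts under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    stem = genes[: config.n_stem_genes]
    diff = genes[config.n_stem_genes : config.n_stem_genes + config.n_diff_genes]
    assignment = {g: "neither" for g in genes}
    assignment.update({g: "stem" for g in stem})
    assignment.update({g: "differentiation" for g in diff})
    substrates = stem[: config.n_integrin_substrates]

    n = config.n_cells_per_group
    cell_names = [f"U{i:04d}" for i in range(n)] + [f"T{i:04d}" for i in range(n)]
    groups = ["untreated"] * n + ["treated"] * n
    retainer = np.zeros(2 * n, dtype=bool)
    retainer[n:] = rng.random(n) < config.retainer_fraction
    cells = pd.DataFrame(
        {"group": groups, "pfak_retainer": retainer}, index=pd.Index(cell_names, name="cell")
    )

    # per-gene baseline means, lognormal spread, normalized to mrna_mean
    base = rng.lognormal(mean=0.0, sigma=config.gene_mean_sigma, size=config.n_genes)
    base *= config.mrna_mean / base.mean()

    mu = np.tile(base, (2 * n, 1))
    treated_rows = np.arange(n, 2 * n)
    stem_idx = np.arange(config.n_stem_genes)
    diff_idx = np.arange(config.n_stem_genes, config.n_stem_genes + config.n_diff_genes)
    stem_fold = np.where(retainer[treated_rows], config.retainer_stem_fold, config.stem_fold_treated)
    mu[np.ix_(treated_rows, stem_idx)] *= stem_fold[:, None]
    mu[np.ix_(treated_rows, diff_idx)] *= config.diff_fold_treated

    theta = config.mrna_dispersion
    gene_counts = rng.negative_binomial(theta, theta / (theta + mu))
    gene_df = pd.DataFrame(gene_counts, index=cells.index, columns=genes)

    arc_mu = np.full((2 * n, len(config.antibodies)), config.arc_mean, dtype=float)
    for j, ab in enumerate(config.antibodies):
        if ab == config.pfak_antibody:
            fold = np.where(
                retainer[treated_rows], config.pfak_retainer_fold, config.pfak_loser_fold
            )
            arc_mu[treated_rows, j] *= fold
        else:
            arc_mu[treated_rows, j] *= config.arc_folds_treated.get(ab, 1.0)
    theta_a = config.arc_dispersion
    arc_counts = rng.negative_binomial(theta_a, theta_a / (theta_a + arc_mu))
    arc_df = pd.DataFrame(arc_counts, index=cells.index, columns=list(config.antibodies))

    return GroundTruth(cells, gene_df, arc_df, assignment, substrates)


def truth_to_matrices(truth: GroundTruth) -> Tuple[CountMatrix, CountMatrix]:
    """Ground-truth counts as the pair of count matrices quantify would emit."""
    return (
        CountMatrix("mRNA", truth.gene_counts.T.copy()),
        CountMatrix("ARC", truth.arc_counts.T.copy()),
    )


# ---------------------------------------------------------------------------
# Read rendering
# ---------------------------------------------------------------------------
def render_arc_read(
    antibody: str,
    layout: ArcLayout,
    panel: AntibodyPanel,
    arc_umi: str,
    stagger_len: int,
    read_len: int = 63,
) -> str:
    """Render the 63-nt read-1 sequence of one ARC molecule.

    Layout: stagger · UMI · antibody barcode · anchor · downstream filler,
    truncated (or A-padded) to ``read_len``.  The anchor therefore starts
    at ``stagger_len + umi_len + ab_barcode_len``.
    """
    if len(arc_umi) != layout.umi_len:
        raise ValueError(f"ARC UMI must be {layout.umi_len} nt")
    start = layout.anchor_start(stagger_len)  # validates stagger bounds
    barcode = panel.barcode_of(antibody)
    read = _stagger_seq(stagger_len) + arc_umi + barcode + layout.anchor + ARC_DOWNSTREAM
    read = (read + "A" * read_len)[:read_len]
    assert read[start : start + layout.anchor_len] == layout.anchor[: max(0, read_len - start)]
    return read


def simulate_reference(
    genes: Sequence[str], length: int = 240, seed: int = 0
) -> Dict[str, str]:
    """Random transcript sequences, one per gene."""
    rng = np.random.default_rng([seed, 17])
    return {g: random_dna(rng, length) for g in genes}


def generate_cell_index(
    cell_names: Sequence[str], cb_len: int = 8, read2_umi_len: int = 6, seed: int = 0
) -> CellBarcodeIndex:
    """Assign distinct random cell barcodes to the given cells."""
    rng = np.random.default_rng([seed, 23])
    barcodes = _unique_random_dna(rng, cb_len, len(cell_names))
    rng.shuffle(barcodes)
    return CellBarcodeIndex(
        list(zip(cell_names, barcodes)), cb_len=cb_len, read2_umi_len=read2_umi_len
    )


def generate_panel(antibodies: Sequence[str], barcode_len: int = 10, seed: int = 0) -> AntibodyPanel:
    """Assign distinct random antibody barcodes (min pairwise Hamming ≥ 3)."""
    rng = np.random.default_rng([seed, 29])
    from .arc_model import hamming  # local import to avoid cycle noise

    chosen: List[str] = []
    while len(chosen) < len(antibodies):
        cand = random_dna(rng, barcode_len)
        if all(hamming(cand, b) >= 3 for b in chosen):
            chosen.append(cand)
    return AntibodyPanel(list(zip(antibodies, chosen)))


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def _spurious_anchor(read1: str, layout: ArcLayout, true_start: int) -> bool:
    """True when a window position before the real anchor would qualify.

    The detector takes the first window position within the mismatch
    budget, so a chance anchor-like 12-mer inside the random UMI/barcode
    bases would shift the extracted fields.  The simulator redraws UMIs
    that would render such a read, keeping the error-free channel
    lossless.
    """
    lo, hi = layout.anchor_window
    alen = layout.anchor_len
    for p in range(lo, min(true_start, hi + 1)):
        if hamming_at_most(
            read1[p : p + alen], layout.anchor, layout.max_anchor_mismatches
        ) is not None:
            return True
    return False


@dataclass
class SimulationOutput:
    r1_path: Path
    r2_path: Path
    truth_genes_path: Path
    truth_arcs_path: Path
    provenance_path: Path
    n_read_pairs: int


def write_fastq_pair(
    truth: GroundTruth,
    layout: ArcLayout,
    panel: AntibodyPanel,
    cell_index: CellBarcodeIndex,
    reference: Mapping[str, str],
    config: SimConfig,
    out_dir: str | Path,
) -> SimulationOutput:
    """Render one read pair per ground-truth molecule into gzipped FASTQ.

    Read 1 carries either a 63-nt transcript fragment or the rendered ARC
    sequence; read 2 carries the 6-nt UMI followed by the 8-nt cell
    barcode.  Base qualities are constant Q30 except for planted
    sub-threshold bases (``low_quality_fraction``).  A provenance table
    mapping every read to its true (cell, feature, UMI) is written
    alongside for oracle tests.
    """
    missing = [g for g in truth.genes if g not in reference]
    if missing:
        raise ValueError(f"genes missing from reference: {missing[:5]}")
    missing_cells = [c for c in truth.cells.index if c not in set(cell_index.cell_names)]
    if missing_cells:
        raise ValueError(f"cells without whitelist barcode: {missing_cells[:5]}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 101])
    q30 = chr(33 + 30)
    q9 = chr(33 + 9)
    stagger_of = {
        ab: layout.stagger_min + (i % (layout.stagger_max - layout.stagger_min + 1))
        for i, ab in enumerate(panel.names)
    }

    r1_path = out_dir / "R1.fastq.gz"
    r2_path = out_dir / "R2.fastq.gz"
    prov_rows: List[Tuple[str, str, str, str, str]] = []
    serial = 0

    def _read2(cell: str, read2_umi: str) -> str:
        barcode = cell_index.barcode_of(cell)
        if cell_index.read2_order == "umi_first":
            return read2_umi + barcode
        return barcode + read2_umi

    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:

        def _emit(read1: str, read2: str, cell: str, kind: str, feature: str, umi: str) -> None:
            nonlocal serial
            read1 = _mutate(read1, rng, config.error_rate)
            read2 = _mutate(read2, rng, config.error_rate)
            qual1 = q30 * len(read1)
            qual2 = q30 * len(read2)
            if config.low_quality_fraction > 0 and rng.random() < config.low_quality_fraction:
                pos = int(rng.integers(0, cell_index.read2_len))
                qual2 = qual2[:pos] + q9 + qual2[pos + 1 :]
            name = f"RAID:{serial}"
            f1.write(f"@{name}\n{read1}\n+\n{qual1}\n")
            f2.write(f"@{name}\n{read2}\n+\n{qual2}\n")
            prov_rows.append((name, cell, kind, feature, umi))
            serial += 1

        for cell in truth.cells.index:
            # transcript molecules
            row = truth.gene_counts.loc[cell]
            for gene, count in row[row > 0].items():
                count = int(count)
                seq = reference[gene]
                if config.unique_umis:
                    umis = _unique_random_dna(rng, cell_index.read2_umi_len, count)
                else:
                    umis = [random_dna(rng, cell_index.read2_umi_len) for _ in range(count)]
                max_off = len(seq) - config.read1_len
                offsets = rng.integers(0, max_off + 1, size=count)
                for umi, off in zip(umis, offsets):
                    read1 = seq[off : off + config.read1_len]
                    _emit(read1, _read2(cell, umi), cell, "mRNA", gene, umi)
            # ARC molecules
            arow = truth.arc_counts.loc[cell]
            for ab, count in arow[arow > 0].items():
                count = int(count)
                true_start = layout.anchor_start(stagger_of[ab])
                used: set[str] = set()
                for _ in range(count):
                    while True:
                        arc_umi = random_dna(rng, layout.umi_len)
                        if config.unique_umis and arc_umi in used:
                            continue
                        read1 = render_arc_read(
                            ab, layout, panel, arc_umi, stagger_of[ab], config.read1_len
                        )
                        if not _spurious_anchor(read1, layout, true_start):
                            break
                    used.add(arc_umi)
                    read2_umi = random_dna(rng, cell_index.read2_umi_len)
                    _emit(read1, _read2(cell, read2_umi), cell, "ARC", ab, arc_umi)

    truth_genes_path = out_dir / "truth_genes.tsv"
    truth_arcs_path = out_dir / "truth_arcs.tsv"
    truth.gene_counts.T.to_csv(truth_genes_path, sep="\t", index_label="feature")
    truth.arc_counts.T.to_csv(truth_arcs_path, sep="\t", index_label="feature")
    provenance_path = out_dir / "provenance.tsv"
    pd.DataFrame(
        prov_rows, columns=["read_id", "cell", "kind", "feature", "umi"]
    ).to_csv(provenance_path, sep="\t", index=False)
    return SimulationOutput(
        r1_path, r2_path, truth_genes_path, truth_arcs_path, provenance_path, serial
    )
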