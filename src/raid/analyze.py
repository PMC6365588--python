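"""Downstream multimodal analysis of matched mRNA + ARC count tables.

Implements the standard post-normalization workflow: log normalization,
mean/dispersion variable-gene selection, PCA + t-SNE embedding, per-cell
ARC ratios with display clipping, gene-signature scores, extreme-cell
selection on an antibody channel, group resampling of per-gene sums,
differential expression with a log fold-change gate, and two-sample
KS / Welch tests.

Conventions follow the Seurat lineage this workflow derives from:
log normalization is ``ln(1 + count * scale / cell_total)``; the DE log
fold-change is the difference of ``ln(mean(expm1(x)) + 1)`` between
groups (natural log, configurable to log2); multiple testing uses
Bonferroni over the tested genes, with an unadjusted restricted-universe
mode for signature-limited comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .dataset import MultimodalDataset
from .matrix import CountMatrix

#: Number of cells selected on each extreme of an antibody channel.
DEFAULT_EXTREME_N = 50

#: Principal components fed to t-SNE (1-based, inclusive).
DEFAULT_PCS = range(1, 9)

ArrayLike = Union[np.ndarray, pd.Series, Sequence[float]]


def _as_frame(data: Union[CountMatrix, pd.DataFrame]) -> pd.DataFrame:
    return data.data if isinstance(data, CountMatrix) else data


@dataclass
class GeneSignature:
    """Named gene list scored by per-cell UMI aggregation."""

    name: str
    genes: List[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    @classmethod
    def from_tsv(cls, path, name: Optional[str] = None) -> "GeneSignature":
        genes = pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()
        return cls(name or str(path), genes)


# ---------------------------------------------------------------------------
# Normalization / feature selection / embedding
# ---------------------------------------------------------------------------
def log_normalize(
    mrna: Union[CountMatrix, pd.DataFrame], scale: float = 10_000.0
) -> pd.DataFrame:
    """Per-cell log normalization: ``ln(1 + count * scale / cell_total)``.

    After depth subsampling all cell totals are equal, so this preserves
    rank order within every gene.  A zero-total cell is an error.
    """
    data = _as_frame(mrna)
    totals = data.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise ValueError(f"zero-total cells cannot be log normalized: {bad}")
    return np.log1p(data * (scale / totals))


def select_variable_genes(
    lognorm: pd.DataFrame,
    n_bins: int = 20,
    dispersion_z_min: float = 1.0,
    mean_low: float = 0.1,
    mean_high: float = 8.0,
) -> List[str]:
    """Mean/dispersion-binned variable-gene selection.

    Works on the exponentiated scale: per gene, ``m = mean(expm1(x))``
    and ``d = var(expm1(x)) / m``.  Genes are binned (equal-width on
    ``log1p(m)``, 20 bins) and the dispersion z-scored within each bin;
    a gene is variable when its z-score is at least ``dispersion_z_min``
    and ``m`` lies within ``[mean_low, mean_high]``.  Deterministic and
    invariant to cell order.
    """
    if lognorm.shape[1] < 2:
        raise ValueError("variable-gene selection needs at least 2 cells")
    ex = np.expm1(lognorm.to_numpy())
    m = ex.mean(axis=1)
    v = ex.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(m > 0, v / m, 0.0)
    x = np.log1p(m)
    bins = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(x, bins) - 1, 0, n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mu = disp[mask].mean()
        sd = disp[mask].std(ddof=1) if mask.sum() > 1 else 0.0
        z[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0
    keep = (z >= dispersion_z_min) & (m >= mean_low) & (m <= mean_high) & (v > 0)
    return [g for g, k in zip(lognorm.index, keep) if k]


def embed(
    lognorm: pd.DataFrame,
    variable_genes: Sequence[str],
    pcs: range = DEFAULT_PCS,
    seed: int = 0,
    perplexity: float = 30.0,
) -> Tuple[pd.DataFrame, Dict]:
    """PCA on centered/scaled variable genes, then t-SNE on the chosen PCs.

    ``pcs`` is a 1-based inclusive range (default 1–8).  Returns the
    cells × 2 embedding and a metadata dict recording seed and
    hyperparameters.  Errors when there are fewer cells than the largest
    requested PC.
    """
    n_cells = lognorm.shape[1]
    max_pc = max(pcs)
    if n_cells <= max_pc:
        raise ValueError(f"need more than {max_pc} cells for PCs {list(pcs)}")
    missing = [g for g in variable_genes if g not in lognorm.index]
    if missing:
        raise KeyError(f"variable genes absent from matrix: {missing[:5]}")
    X = lognorm.loc[list(variable_genes)].to_numpy().T  # cells x genes
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = X / sd
    n_components = min(max_pc, X.shape[1])
    if n_components < max_pc:
        warnings.warn(
            f"only {X.shape[1]} variable genes; using PCs 1-{n_components}",
            stacklevel=2,
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    pcs_all = pca.fit_transform(X)
    used_pcs = [p for p in pcs if p <= n_components]
    use = pcs_all[:, [p - 1 for p in used_pcs]]
    eff_perplexity = min(perplexity, max(2.0, (n_cells - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(use)
    embedding = pd.DataFrame(coords, index=lognorm.columns, columns=["tsne1", "tsne2"])
    meta = {
        "pcs_used": used_pcs,
        "seed": seed,
        "perplexity": eff_perplexity,
        "n_variable_genes": len(list(variable_genes)),
    }
    return embedding, meta


# ---------------------------------------------------------------------------
# ARC-level summaries
# ---------------------------------------------------------------------------
def arc_ratio(
    arc: Union[CountMatrix, pd.DataFrame],
    numerator: str,
    denominator: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-cell ``(numerator + pc) / (denominator + pc)`` antibody ratio."""
    data = _as_frame(arc)
    for ab in (numerator, denominator):
        if ab not in data.index:
            raise KeyError(f"unknown antibody {ab!r}")
    num = data.loc[numerator].astype(float) + pseudocount
    den = data.loc[denominator].astype(float) + pseudocount
    out = num / den
    out.name = f"{numerator}/{denominator}"
    return out


def clip_for_display(values: ArrayLike, lo_pct: float = 5.0, hi_pct: float = 95.0):
    """Winsorize at the given percentiles (default 5% / 95%) for plotting.

    Percentile bounds are order statistics (``lower``/``higher``
    interpolation), which makes the operation idempotent: clipping an
    already-clipped vector changes nothing.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to clip")
    lo = np.percentile(arr, lo_pct, method="lower")
    hi = np.percentile(arr, hi_pct, method="higher")
    clipped = np.clip(arr, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name)
    return clipped


def signature_score(
    mrna: Union[CountMatrix, pd.DataFrame], signature: GeneSignature
) -> pd.Series:
    """Per-cell score: sum of (subsampled) UMI counts over signature genes.

    Signature genes missing from the matrix are ignored with a warning;
    zero overlap is an error.  Scores are computed on raw subsampled
    counts, not log values.
    """
    data = _as_frame(mrna)
    present = [g for g in signature.genes if g in data.index]
    missing = [g for g in signature.genes if g not in data.index]
    if not present:
        raise ValueError(f"signature {signature.name!r} shares no genes with the matrix")
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} genes absent from matrix: "
            f"{missing[:10]}",
            stacklevel=2,
        )
    score = data.loc[present].sum(axis=0)
    score.name = signature.name
    return score


def select_extremes(
    arc: Union[CountMatrix, pd.DataFrame],
    antibody: str,
    cells: Sequence[str],
    n: int = DEFAULT_EXTREME_N,
) -> Tuple[List[str], List[str]]:
    """Top-``n`` and bottom-``n`` cells of a group by one antibody's counts.

    Ties are broken by cell-name lexicographic order, so the result is
    deterministic and independent of input order.  Returns
    ``(high_cells, low_cells)``, disjoint and each of size exactly ``n``.
    """
    data = _as_frame(arc)
    if antibody not in data.index:
        raise KeyError(f"unknown antibody {antibody!r}")
    cells = list(cells)
    if len(cells) < 2 * n:
        raise ValueError(f"group of {len(cells)} cells cannot supply 2 x {n} extremes")
    counts = data.loc[antibody, cells]
    ordered = sorted(cells, key=lambda c: (counts[c], c))
    low = ordered[:n]
    high = ordered[-n:][::-1]  # highest first
    return high, low


def resample_group_sums(
    mrna: Union[CountMatrix, pd.DataFrame],
    cells: Sequence[str],
    gene: str,
    group_size: int = 10,
    reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Distribution of a gene's summed counts over random cell subsets.

    Each of ``reps`` draws samples ``group_size`` cells without
    replacement (within a draw) from ``cells`` and sums the gene's
    counts; the expectation is ``group_size ×`` the mean count.
    """
    data = _as_frame(mrna)
    if gene not in data.index:
        raise KeyError(f"unknown gene {gene!r}")
    cells = list(cells)
    if len(cells) < group_size:
        raise ValueError("fewer cells than group_size")
    counts = data.loc[gene, cells].to_numpy()
    rng = np.random.default_rng(seed)
    sums = np.empty(reps, dtype=float)
    for r in range(reps):
        idx = rng.choice(len(cells), size=group_size, replace=False)
        sums[r] = counts[idx].sum()
    return sums


# ---------------------------------------------------------------------------
# Differential expression and tests
# ---------------------------------------------------------------------------
def _seurat_logfc(a: np.ndarray, b: np.ndarray, base: str) -> np.ndarray:
    """Log fold-change between groups on log-normalized data.

    Seurat convention: ``log(mean(expm1(x)) + 1)`` per group, differenced;
    natural log by default, ``base='log2'`` for the log2 variant.
    """
    mean_a = np.log1p(np.expm1(a).mean(axis=1))
    mean_b = np.log1p(np.expm1(b).mean(axis=1))
    fc = mean_a - mean_b
    if base == "log2":
        fc = fc / np.log(2.0)
    return fc


def differential_expression(
    lognorm: pd.DataFrame,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    universe: Optional[Sequence[str]] = None,
    adjust: str = "bonferroni",
    fc_base: str = "ln",
) -> pd.DataFrame:
    """Welch-t differential expression with a log fold-change gate.

    Only genes whose |log fold-change| reaches ``logfc_threshold`` are
    tested (two-sided Welch t-test on the log-normalized values), then
    Bonferroni-adjusted over the tested genes.  ``universe`` restricts
    the comparison to a gene subset (e.g. a signature); ``adjust='none'``
    reproduces unadjusted per-gene testing on such a restricted universe.

    Returns a DataFrame indexed by tested gene with columns ``mean_a``,
    ``mean_b``, ``logfc``, ``t_stat``, ``pval``, ``padj``,
    ``significant``.
    """
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    frame = lognorm if universe is None else lognorm.loc[[g for g in universe]]
    a = frame[list(cells_a)].to_numpy()
    b = frame[list(cells_b)].to_numpy()
    logfc = _seurat_logfc(a, b, fc_base)
    gate = np.abs(logfc) >= logfc_threshold
    genes = frame.index[gate]
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["mean_a", "mean_b", "logfc", "t_stat", "pval", "padj", "significant"]
        )
    a_g, b_g = a[gate], b[gate]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, pval = stats.ttest_ind(a_g, b_g, axis=1, equal_var=False)
    # Welch fallback for degenerate (zero-variance) genes
    mean_a, mean_b = a_g.mean(axis=1), b_g.mean(axis=1)
    nan = np.isnan(pval)
    pval = np.where(nan, np.where(mean_a == mean_b, 1.0, 0.0), pval)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    n_tested = len(genes)
    padj = np.minimum(pval * n_tested, 1.0) if adjust == "bonferroni" else pval.copy()
    result = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "logfc": logfc[gate],
            "t_stat": t_stat,
            "pval": pval,
            "padj": padj,
            "significant": padj < alpha,
        },
        index=genes,
    )
    return result.sort_values("pval")


def two_sample_tests(a: ArrayLike, b: ArrayLike) -> Dict[str, float]:
    """Two-sample Kolmogorov–Smirnov and Welch t-test results.

    The t-test is omitted (flagged ``t_valid=False``) when either sample
    has fewer than 2 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    out: Dict[str, float] = {
        "ks_stat": float(ks.statistic),
        "ks_pval": float(ks.pvalue),
        "t_valid": a.size >= 2 and b.size >= 2,
        "t_stat": float("nan"),
        "t_pval": float("nan"),
    }
    if out["t_valid"]:
        t = stats.ttest_ind(a, b, equal_var=False)
        out["t_stat"] = float(t.statistic)
        out["t_pval"] = float(t.pvalue)
    return out


def qc_gene_stats(counts: Union[CountMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene mean expression, detection rate and coefficient of variation.

    Detection rate is the fraction of cells with a nonzero count; CV is
    SD/mean on counts, undefined (NaN, flagged) for zero-mean genes.
    """
    data = _as_frame(counts)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    values = data.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    detection = (values > 0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {
            "mean_expression": mean,
            "detection_rate": detection,
            "cv": cv,
            "cv_defined": mean > 0,
        },
        index=data.index,
    )
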