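# Methods

## Read architecture and ARC detection

An ARC (antibody RNA-barcode conjugate) tag on read 1 consists of a
1–8-nt stagger, a 15-nt UMI, a 10-nt antibody barcode and the fixed 12-nt
anchor `ATCAGTCAACAG`, followed by template tail and poly-A. The anchor plus
barcode form the 22-nt antibody-identification span. All coordinates in the
package are 0-based, half-open, and only the forward strand of read 1 is
searched: the library is strand-specific by construction.

Because the stagger length is bounded, the anchor start can only fall in
`[stagger_min + umi_len + ab_barcode_len, stagger_max + umi_len + ab_barcode_len]`
— `[26, 33]` with defaults. The detector scans this window in ascending
position order and takes the **first** position within the anchor mismatch
budget (default 1). This first-qualifying-position rule is deterministic and
means a later exact match never preempts an earlier one-mismatch match.
Restricting the scan to the window (rather than the whole read) keeps chance
anchor hits inside transcript reads negligible; a full-read scan remains
available for diagnostics. If the extracted 10-nt barcode is not in the
panel, the read is treated as a non-ARC read and passed to transcript
assignment.

Antibody-barcode matching is exact by default. Hamming-tolerant matching
(up to `m` mismatches) is supported but gated by a whitelist-separation
check: it is only unambiguous when the minimum pairwise Hamming distance in
the panel is at least `2m + 1`, which `validate_panel` verifies.

`parse_template_spec` recovers the layout from an ARC DNA template string
(read-primer motif, rendered stagger, `N`-run UMI, bracketed or `B`-run
barcode placeholder, anchor). A single rendered template cannot encode the
stagger *minimum*, so the parser interprets the rendered stagger as the
longest variant (`stagger_max` = its length) and leaves `stagger_min` at 1;
round-tripping with the template builder is exact for layouts with
`stagger_min = 1`.

## Cell demultiplexing and transcript assignment

Read 2 is a 6-nt UMI followed by an 8-nt cell barcode (CEL-Seq2 convention;
both order and lengths are configurable). Cells are defined by a whitelist
(sorted plates), so no knee-point cell calling exists. A read pair is
rejected when any base of the read-2 barcode+UMI region is below the quality
threshold (default Q10) — the published setting's exact scope is not stated,
so the gate conservatively covers both fields. Whitelist matching is exact.

Transcript assignment uses a unique-k-mer index (k = 21, ≤ the 50-nt read
truncation length): only k-mers occurring in exactly one reference gene are
stored, and a read is assigned iff all of its indexed k-mers vote for the
same gene. This deterministic assigner keeps the package self-contained and
is adequate for transcript-level references at desk scale; it is not a
splice-aware genome aligner and is not meant to be one.

UMI collapse is exact identity: each distinct `(cell, gene, read-2 UMI)` or
`(cell, antibody, ARC UMI)` tuple counts once. No directional network
correction is applied, since plain UMI counting is the documented behaviour
of the upstream pipelines this follows. ARC classification takes precedence
over transcript assignment, so the per-read fates (quality-fail,
unassigned-cell, ARC, mRNA, neither) partition the input — an invariant the
tests assert.

## Depth normalization

Cells are depth-normalized by drawing a fixed number of UMIs per cell
**without replacement** from the cell's UMI-expanded pool (multivariate
hypergeometric), discarding cells below the target. Sampling without
replacement follows from drawing from a finite pool of observed molecules
and guarantees the subsampled count never exceeds the raw count; the
per-feature marginals are hypergeometric, which a goodness-of-fit test
verifies against `scipy.stats.hypergeom`. For multimodal data the mRNA and
ARC thresholds are applied jointly: a cell is kept only if it passes both,
keeping the matrices matched cell-for-cell. Preset depths: 10,000 / 40,000 /
4,500 mRNA UMIs and 2,750 / 400 ARC UMIs; the intracellular (fixed-cell)
configuration is 4,500 + 400.

Randomness is reproducible and order-independent: each cell's draw uses a
stream keyed by `(seed, modality, crc32(cell name))`, so permuting the cell
order cannot change any cell's result.

## Downstream analysis

- **Log normalization**: `ln(1 + count · scale / cell_total)`, scale 10,000.
  Totals are equal after subsampling, so per-gene rank order is preserved.
- **Variable genes**: per gene, the mean and dispersion (variance/mean) of
  `expm1`-transformed values; genes are binned into 20 equal-width bins of
  `log1p(mean)` and dispersions z-scored within bins; selection requires
  z ≥ 1 and mean within [0.1, 8]. Singleton bins get z = 0 (no within-bin
  spread to standardize against) and zero-variance genes are never selected.
- **Embedding**: PCA on centered, unit-variance variable genes; t-SNE
  (perplexity 30, capped at (n−1)/3 for small n; fixed seed; PCA
  initialization) on PCs 1–8. If fewer variable genes than requested PCs
  exist, the PC range is truncated with a warning and recorded in the run
  metadata.
- **ARC ratios**: `(a + 1)/(b + 1)` per cell, pseudocount configurable.
- **Display clipping**: winsorization at the 5th/95th percentiles using
  order-statistic (lower/higher) percentile bounds, which makes clipping
  idempotent.
- **Signature scores**: per-cell sums of *subsampled raw* UMI counts over a
  gene set (not log values) — equal depths make the sums comparable.
  Missing genes are ignored with a warning; zero overlap is an error.
- **Extreme cells**: top/bottom n (default 50) cells of a group by one
  antibody's subsampled counts; ties break by cell name, so the selection
  is deterministic and order-independent.
- **Group resampling**: `reps` (default 1,000) draws of `group_size`
  (default 10) cells without replacement within a draw; each draw's value
  is the summed count of one gene.
- **Differential expression**: genes are gated on |log fold-change| ≥ 0.25,
  where the fold change follows the Seurat convention
  `ln(mean(expm1(x)) + 1)` differenced between groups (natural log,
  configurable to log2); gated genes get a two-sided Welch t-test and
  Bonferroni adjustment over the tested genes. A restricted-universe mode
  (`universe=`, `adjust="none"`) supports signature-limited comparisons with
  unadjusted per-gene tests. Degenerate zero-variance genes fall back to
  p = 1 when the group means are equal and p = 0 otherwise.
- **Two-sample tests**: `scipy.stats.ks_2samp` and Welch `ttest_ind`; the
  t-test is flagged invalid below 2 values per sample.

## The simulator

The synthetic experiment emulates two keratinocyte populations — untreated
and EGFR-inhibitor treated — with negative-binomial molecule counts
(the standard overdispersed scRNA-seq model; no distribution is prescribed
by the protocol itself). Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_cells_per_group` | 200 | cells per condition |
| `n_genes` | 2,000 | transcriptome size |
| `n_stem_genes` / `n_diff_genes` | 530 / 226 | signature sizes |
| `mrna_mean`, `mrna_dispersion` | 4.0, 2.0 | NB mean/shape per gene |
| `arc_mean`, `arc_dispersion` | 120, 10 | NB mean/shape per antibody |
| `stem_fold_treated` | 0.25 | treated-group stem-gene fold |
| `diff_fold_treated` | 4.0 | treated-group differentiation fold |
| `retainer_fraction` | 0.3 | treated cells keeping pFAK high |
| `pfak_retainer_fold` / `pfak_loser_fold` | 1.0 / 0.15 | bimodal pFAK response |
| `error_rate` | 0.001 | per-base substitution probability |

Treated "retainer" cells keep both their pFAK signal and their stem-gene
expression at untreated-like levels while expressing differentiation genes
like the rest of the treated group — the coupling that makes pFAK-high cells
stem-score-enriched at equal differentiation score, which the analysis stage
must recover. A small named subset of stem genes ("integrin substrates",
default 4) marks the genes whose resampling distributions are compared
between extremes. ARC group effects default to pRPS6 ×0.25, NOTCH1/TGM1/KLK6
×3, JAG1 ×0.8 in the treated group, matching the expected direction of each
marker under differentiation.

FASTQ rendering emits one read pair per molecule: constant Q30 qualities
(optionally planting sub-threshold Q9 bases in the read-2 barcode region),
substitution errors at the configured rate, per-antibody stagger lengths
cycling over 1–8, and UMIs drawn without replacement per (cell, feature)
when `unique_umis` is set. The renderer also redraws any ARC UMI whose
rendered read would contain a chance anchor-qualifying 12-mer *before* the
true anchor position, because the first-position detector would otherwise
mis-extract the fields: with error rate 0 and unique UMIs the
FASTQ→quantify channel is then exactly lossless, which the tests assert at
the 200-cell scale. A provenance table maps every read to its true
(cell, feature, UMI) for oracle tests.

What the simulator does **not** model: PCR duplicates, indels, quality-score
variation, ambient RNA, doublets, batch structure, gene-length or GC bias,
and gene-gene correlation beyond the planted group effects. Passing tests
therefore demonstrate correctness of the counting and analysis machinery
under a clean generative model, not robustness to every artifact of real
libraries.

## Numerical and scale choices

Tests and the acceptance script run at desk scale: lossless recovery uses
200 cells × 300 genes × 6 antibodies (~210k read pairs), planted-effect
recovery uses 20 seeded runs at the default 400-cell configuration operating
on ground-truth count matrices (FASTQ losslessness is established
separately, so re-rendering reads for every run would only re-test the same
channel). Resampling equivalence is checked against full enumeration of all
C(20,10) subsets on a 20-cell fixture. Seeds are fixed everywhere;
`numpy.random.Generator` streams are derived from `(seed, salt, name-hash)`
tuples so results are independent of iteration order.
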