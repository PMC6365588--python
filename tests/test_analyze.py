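import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raid import (
    CountMatrix,
    DepthSpec,
    GeneSignature,
    SimConfig,
    arc_ratio,
    clip_for_display,
    differential_expression,
    embed,
    log_normalize,
    normalize_dataset,
    qc_gene_stats,
    resample_group_sums,
    select_extremes,
    select_variable_genes,
    signature_score,
    simulate_ground_truth,
    truth_to_matrices,
    two_sample_tests,
)


def normalized_dataset(seed=3, **overrides):
    """Small simulated dataset pushed through joint depth normalization."""
    kwargs = dict(
        n_cells_per_group=50, n_genes=600, n_stem_genes=120, n_diff_genes=60,
        n_integrin_substrates=3, mrna_mean=4.0, arc_mean=120.0, seed=seed,
    )
    kwargs.update(overrides)
    cfg = SimConfig(**kwargs)
    truth = simulate_ground_truth(cfg)
    mrna, arc = truth_to_matrices(truth)
    ds = normalize_dataset(mrna, arc, DepthSpec(1500, 400, seed=seed), cell_meta=truth.cells)
    return cfg, truth, ds


class TestLogNormalize:
    def test_closed_form(self):
        data = pd.DataFrame({"c1": [45, 4455], "c2": [0, 4500]}, index=["g1", "g2"])
        ln = log_normalize(CountMatrix("mRNA", data), scale=10_000)
        assert ln.at["g1", "c1"] == pytest.approx(np.log(101), rel=1e-12)
        assert ln.at["g1", "c2"] == 0.0

    def test_zero_total_cell_is_error(self):
        data = pd.DataFrame({"c1": [1], "c2": [0]}, index=["g"])
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(CountMatrix("mRNA", data))

    def test_scale_shifts_nonzero_values_monotonically(self):
        data = pd.DataFrame({"c1": [3, 7, 0]}, index=["a", "b", "c"])
        lo = log_normalize(data, scale=10_000)
        hi = log_normalize(data, scale=20_000)
        nz = data["c1"] > 0
        assert (hi["c1"][nz] > lo["c1"][nz]).all()
        assert hi.at["c", "c1"] == lo.at["c", "c1"] == 0.0


class TestVariableGenes:
    def test_constant_gene_excluded_and_order_invariant(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.poisson(5, size=(30, 40)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"c{i}" for i in range(40)],
        )
        data.loc["g0"] = 5  # constant across cells
        ln = log_normalize(CountMatrix("mRNA", data + 1))
        genes = select_variable_genes(ln)
        assert "g0" not in genes
        permuted = ln[list(ln.columns[::-1])]
        assert select_variable_genes(permuted) == genes

    def test_planted_high_dispersion_gene_found(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5, size=(50, 60))
        data = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                            columns=[f"c{i}" for i in range(60)])
        # bimodal marker: huge dispersion at a mean inside the other genes'
        # range (so it shares a dispersion bin); scale keeps per-gene means
        # inside the selector's [0.1, 8] mean window
        data.loc["g10"] = np.where(rng.random(60) < 0.5, 0, 10)
        ln = log_normalize(CountMatrix("mRNA", data + 1), scale=300)
        assert "g10" in select_variable_genes(ln)


class TestEmbedding:
    def test_groups_separate_and_seeded_runs_match(self):
        from sklearn.metrics import silhouette_score

        _, truth, ds = normalized_dataset(seed=1, retainer_fraction=0.0)
        ln = log_normalize(ds.mrna)
        genes = select_variable_genes(ln)
        emb, meta = embed(ln, genes, seed=0)
        labels = (ds.cells["group"] == "treated").to_numpy()
        assert silhouette_score(emb.to_numpy(), labels) > 0
        centroids = emb.groupby(ds.cells["group"]).mean()
        between = np.linalg.norm(centroids.iloc[0] - centroids.iloc[1])
        within = np.mean([
            np.linalg.norm(emb.loc[c] - centroids.loc[ds.cells.at[c, "group"]])
            for c in emb.index
        ])
        assert between > within
        emb2, _ = embed(ln, genes, seed=0)
        assert np.allclose(emb.to_numpy(), emb2.to_numpy())
        assert meta["pcs_used"] == list(range(1, 9))

    def test_too_few_cells_is_error(self):
        rng = np.random.default_rng(2)
        ln = pd.DataFrame(rng.random((20, 5)), index=[f"g{i}" for i in range(20)],
                          columns=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="cells"):
            embed(ln, list(ln.index)[:10])


class TestArcSummaries:
    def test_ratio_arithmetic(self):
        arc = CountMatrix("ARC", pd.DataFrame(
            {"c1": [99, 49], "c2": [7, 7]}, index=["EGFR", "ITGA6"]))
        r = arc_ratio(arc, "EGFR", "ITGA6", pseudocount=1)
        assert r["c1"] == pytest.approx(2.0)
        assert r["c2"] == pytest.approx(1.0)
        with pytest.raises(KeyError):
            arc_ratio(arc, "EGFR", "nope")

    def test_planted_receptor_knockdown_lowers_treated_ratio(self):
        cfg, truth, ds = normalized_dataset(
            seed=5,
            antibodies=("EGFR", "ITGA6", "pFAK"),
            arc_folds_treated={"EGFR": 0.3, "ITGA6": 1.2},
            arc_mean=300.0,  # keep treated cells above the 400-count ARC gate
        )
        ratios = arc_ratio(ds.arc, "EGFR", "ITGA6")
        treated = ds.cells_in_group("treated")
        untreated = ds.cells_in_group("untreated")
        assert ratios[treated].median() < ratios[untreated].median()

    def test_clip_bounds_and_idempotence(self):
        values = np.arange(1, 101, dtype=float)
        clipped = clip_for_display(values)
        lo = np.percentile(values, 5, method="lower")
        hi = np.percentile(values, 95, method="higher")
        assert clipped.min() == pytest.approx(lo)
        assert clipped.max() == pytest.approx(hi)
        assert np.array_equal(clip_for_display(clipped), clipped)
        const = np.full(10, 3.3)
        assert np.array_equal(clip_for_display(const), const)


class TestSignatureScores:
    @pytest.fixture()
    def counts(self):
        return CountMatrix("mRNA", pd.DataFrame(
            {"c1": [3, 5, 2], "c2": [1, 0, 9]}, index=["g1", "g2", "g3"]))

    def test_single_gene_signature(self, counts):
        s = signature_score(counts, GeneSignature("one", ["g2"]))
        assert s["c1"] == 5 and s["c2"] == 0

    def test_full_signature_equals_depth(self, counts):
        s = signature_score(counts, GeneSignature("all", ["g1", "g2", "g3"]))
        assert s["c1"] == 10 and s["c2"] == 10

    def test_missing_genes_warn_and_no_overlap_errors(self, counts):
        with pytest.warns(UserWarning, match="absent"):
            s = signature_score(counts, GeneSignature("partial", ["g1", "gX"]))
        assert s["c1"] == 3
        with pytest.raises(ValueError, match="no genes"):
            signature_score(counts, GeneSignature("none", ["gX", "gY"]))

    def test_treated_group_scores_move_as_planted(self):
        _, truth, ds = normalized_dataset(seed=6)
        stem = GeneSignature("stem", truth.signature_genes("stem"))
        diff = GeneSignature("diff", truth.signature_genes("differentiation"))
        stem_s = signature_score(ds.mrna, stem)
        diff_s = signature_score(ds.mrna, diff)
        treated = ds.cells_in_group("treated")
        untreated = ds.cells_in_group("untreated")
        t_stem = two_sample_tests(stem_s[untreated], stem_s[treated])
        t_diff = two_sample_tests(diff_s[treated], diff_s[untreated])
        assert stem_s[untreated].mean() > stem_s[treated].mean() and t_stem["t_pval"] < 0.01
        assert diff_s[treated].mean() > diff_s[untreated].mean() and t_diff["t_pval"] < 0.01


class TestSelectExtremes:
    def test_partition_of_even_group(self):
        counts = pd.DataFrame(
            {f"c{i:03d}": [i] for i in range(100)}, index=["pFAK"])
        high, low = select_extremes(counts, "pFAK", list(counts.columns), n=50)
        assert len(high) == len(low) == 50
        assert set(high) | set(low) == set(counts.columns)
        assert set(high).isdisjoint(low)
        assert high[0] == "c099" and low[0] == "c000"

    def test_ties_broken_by_name_deterministically(self):
        cells = [f"c{i:02d}" for i in range(10)]
        counts = pd.DataFrame({c: [7] for c in cells}, index=["pFAK"])
        h1, l1 = select_extremes(counts, "pFAK", cells, n=5)
        h2, l2 = select_extremes(counts, "pFAK", cells[::-1], n=5)
        assert (h1, l1) == (h2, l2)
        assert len(set(h1) & set(l1)) == 0 and len(h1) == len(l1) == 5

    def test_small_group_is_error(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["pFAK"])
        with pytest.raises(ValueError):
            select_extremes(counts, "pFAK", ["a", "b"], n=2)


class TestResampling:
    def test_constant_counts_sum_exactly(self):
        cells = [f"c{i}" for i in range(20)]
        counts = pd.DataFrame({c: [1] for c in cells}, index=["g"])
        sums = resample_group_sums(counts, cells, "g", group_size=10, reps=50, seed=0)
        assert len(sums) == 50
        assert (sums == 10).all()

    def test_mean_matches_linearity_of_expectation(self):
        rng = np.random.default_rng(4)
        cells = [f"c{i}" for i in range(20)]
        values = rng.integers(0, 30, size=20)
        counts = pd.DataFrame({c: [v] for c, v in zip(cells, values)}, index=["g"])
        sums = resample_group_sums(counts, cells, "g", group_size=10, reps=1000, seed=1)
        expected = 10 * values.mean()
        se = sums.std(ddof=1) / np.sqrt(len(sums))
        assert abs(sums.mean() - expected) < 3 * se

    def test_unknown_gene_is_error(self):
        counts = pd.DataFrame({"c1": [1]}, index=["g"])
        with pytest.raises(KeyError):
            resample_group_sums(counts, ["c1"], "nope", group_size=1, reps=2)


class TestDifferentialExpression:
    @pytest.fixture()
    def fixture_lognorm(self):
        rng = np.random.default_rng(11)
        cells = [f"a{i}" for i in range(25)] + [f"b{i}" for i in range(25)]
        data = rng.lognormal(0.5, 0.4, size=(40, 50))
        data[:5, 25:] *= 3.0  # planted markers up in group B
        frame = pd.DataFrame(np.log1p(data), index=[f"g{i}" for i in range(40)],
                             columns=cells)
        return frame, cells[:25], cells[25:]

    def test_identical_groups_nothing_gated(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(rng.random((10, 12)), index=[f"g{i}" for i in range(10)],
                            columns=[f"c{i}" for i in range(12)])
        both = list(data.columns[:6])
        res = differential_expression(data, both, both)
        assert res.empty

    def test_label_swap_flips_logfc_sign(self, fixture_lognorm):
        frame, a, b = fixture_lognorm
        ab = differential_expression(frame, a, b)
        ba = differential_expression(frame, b, a)
        shared = ab.index.intersection(ba.index)
        assert len(shared) > 0
        assert np.allclose(ab.loc[shared, "logfc"], -ba.loc[shared, "logfc"])

    def test_planted_markers_detected(self, fixture_lognorm):
        frame, a, b = fixture_lognorm
        res = differential_expression(frame, b, a)
        planted = {f"g{i}" for i in range(5)}
        found = set(res.index[res["significant"]])
        assert planted <= found

    def test_matches_per_gene_welch_oracle(self, fixture_lognorm):
        # independent oracle: gate on expm1-mean logFC computed by hand,
        # then scipy per-gene Welch t + Bonferroni
        frame, a, b = fixture_lognorm
        res = differential_expression(frame, a, b, logfc_threshold=0.25)
        gated = []
        for g in frame.index:
            fa = np.log(np.expm1(frame.loc[g, a]).mean() + 1)
            fb = np.log(np.expm1(frame.loc[g, b]).mean() + 1)
            if abs(fa - fb) >= 0.25:
                gated.append(g)
        assert sorted(res.index) == sorted(gated)
        for g in gated:
            t, p = stats.ttest_ind(frame.loc[g, a], frame.loc[g, b], equal_var=False)
            assert res.at[g, "pval"] == pytest.approx(p, rel=1e-9)
            assert res.at[g, "padj"] == pytest.approx(min(1.0, p * len(gated)), rel=1e-9)

    def test_adjusted_p_never_below_raw(self, fixture_lognorm):
        frame, a, b = fixture_lognorm
        res = differential_expression(frame, a, b)
        assert (res["padj"] >= res["pval"]).all()

    def test_restricted_universe_unadjusted_mode(self, fixture_lognorm):
        frame, a, b = fixture_lognorm
        universe = [f"g{i}" for i in range(10)]
        res = differential_expression(frame, b, a, universe=universe, adjust="none")
        assert set(res.index) <= set(universe)
        assert np.allclose(res["padj"], res["pval"])


class TestTwoSampleTests:
    def test_equal_samples_give_zero_ks(self):
        x = np.arange(10.0)
        out = two_sample_tests(x, x)
        assert out["ks_stat"] == 0.0

    def test_ks_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 80), rng.normal(0.7, 1, 80)
        raw = two_sample_tests(a, b)
        transformed = two_sample_tests(np.exp(a), np.exp(b))
        assert raw["ks_stat"] == pytest.approx(transformed["ks_stat"])

    def test_power_on_shifted_normals(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            out = two_sample_tests(rng.normal(0, 1, 200), rng.normal(1, 1, 200))
            hits += out["ks_pval"] < 0.01
        assert hits == 5

    def test_tiny_sample_omits_t(self):
        out = two_sample_tests([1.0], [2.0, 3.0])
        assert not out["t_valid"] and np.isnan(out["t_stat"])


class TestQcGeneStats:
    def test_detection_and_cv_edge_cases(self):
        data = pd.DataFrame(
            {"c1": [4, 0, 5], "c2": [4, 0, 1]}, index=["const", "zero", "var"])
        qc = qc_gene_stats(CountMatrix("mRNA", data))
        assert qc.at["const", "detection_rate"] == 1.0
        assert qc.at["const", "cv"] == 0.0
        assert not qc.at["zero", "cv_defined"] and np.isnan(qc.at["zero", "cv"])

    def test_poisson_cv_closed_form(self):
        lam = 4.0
        rng = np.random.default_rng(14)
        data = pd.DataFrame(rng.poisson(lam, size=(1, 3000)), index=["g"],
                            columns=[f"c{i}" for i in range(3000)])
        qc = qc_gene_stats(data)
        assert qc.at["g", "cv"] == pytest.approx(lam ** -0.5, rel=0.1)
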