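"""Tests for summary-stat QC, LD clumping, scoring and PRS-PCA."""

import numpy as np
import pandas as pd
import pytest

import dietgxe as dg
from dietgxe import genetics


def _ss(rows):
    return pd.DataFrame(
        rows, columns=list(genetics.SUMMARY_STAT_COLUMNS)
    )


def _panel(dosages, chrom=None, pos=None, a1=None, a2=None):
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(m)],
            "chr": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (1 + np.arange(m) * 1000),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "maf": np.clip(dosages.mean(0) / 2, 0.01, 0.99),
            "info": 1.0,
        }
    )
    samples = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "chip": "gsa"})
    for k in range(1, 5):
        samples[f"pc{k}"] = 0.0
    return genetics.GenotypeData(dosages=dosages.astype(float), variants=variants, samples=samples)


class TestQC:
    def test_ambiguous_strand_removed(self):
        ss = _ss([
            ["rs1", "1", 100, "A", "T", 0.1, 0.5, 0.3, 1.0],
            ["rs2", "1", 200, "A", "G", 0.1, 0.5, 0.3, 1.0],
        ])
        out, report = genetics.qc_summary_stats(ss)
        assert list(out["snp"]) == ["rs2"]
        assert report["ambiguous"] == 1

    def test_empty_input_empty_output(self):
        out, report = genetics.qc_summary_stats(_ss([]))
        assert len(out) == 0
        assert report["output"] == 0

    def test_hand_enumerated_filters(self):
        """Duplicate id (both rows), C/G pair, low MAF, low INFO all drop;
        two clean variants survive."""
        ss = _ss([
            ["dup", "1", 100, "A", "G", 0.1, 0.5, 0.3, 1.0],
            ["dup", "1", 100, "A", "C", 0.2, 0.5, 0.3, 1.0],
            ["cg", "1", 200, "C", "G", 0.1, 0.5, 0.3, 1.0],
            ["lowmaf", "1", 300, "A", "G", 0.1, 0.5, 0.005, 1.0],
            ["lowinfo", "1", 400, "A", "G", 0.1, 0.5, 0.3, 0.5],
            ["ok1", "1", 500, "A", "G", 0.1, 0.5, 0.3, 1.0],
            ["ok2", "1", 600, "T", "G", 0.1, 0.5, 0.3, 0.95],
        ])
        out, report = genetics.qc_summary_stats(ss)
        assert sorted(out["snp"]) == ["ok1", "ok2"]
        assert report["multiallelic"] == 2
        assert report["ambiguous"] == 1
        assert report["maf"] == 1
        assert report["info"] == 1

    def test_panel_intersection(self, rng):
        panel = _panel(rng.integers(0, 3, size=(20, 2)).astype(float))
        ss = _ss([
            ["v0", "1", 1, "A", "G", 0.1, 0.5, 0.3, 1.0],
            ["rsX", "1", 2, "A", "G", 0.1, 0.5, 0.3, 1.0],
        ])
        out, report = genetics.qc_summary_stats(ss, panel=panel)
        assert list(out["snp"]) == ["v0"]
        assert report["not_in_panel"] == 1

    def test_nothing_surviving_raises(self):
        ss = _ss([["rs1", "1", 100, "A", "T", 0.1, 0.5, 0.3, 1.0]])
        with pytest.raises(genetics.EmptyResultError):
            genetics.qc_summary_stats(ss)

    def test_missing_column_raises(self):
        with pytest.raises(genetics.SummaryStatsFormatError):
            genetics.qc_summary_stats(pd.DataFrame({"snp": ["rs1"]}))


def _brute_force_clump(ss, ref, r2_max, window_kb):
    """Independent reference implementation: explicit loop over the
    p-ordered list, checking every removed-by pair."""
    order = ss.sort_values(["p", "pos"]).index.tolist()
    removed = set()
    selected = []
    var_idx = {s: i for i, s in enumerate(ref.variants["snp"])}
    for i in order:
        if i in removed:
            continue
        selected.append(i)
        for j in order:
            if j == i or j in removed or j in selected:
                continue
            if ss.loc[i, "chr"] != ss.loc[j, "chr"]:
                continue
            if abs(ss.loc[i, "pos"] - ss.loc[j, "pos"]) > window_kb * 1000:
                continue
            x = ref.dosages[:, var_idx[ss.loc[i, "snp"]]]
            y = ref.dosages[:, var_idx[ss.loc[j, "snp"]]]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r >= r2_max:
                removed.add(j)
    return sorted(ss.loc[selected, "snp"])


class TestClumping:
    def test_best_pvalue_dominates(self, rng):
        base = rng.integers(0, 3, size=500).astype(float)
        dosages = np.column_stack([base, base])
        ref = _panel(dosages, pos=[1000, 2000])
        ss = _ss([
            ["v0", "1", 1000, "A", "G", 0.1, 1e-8, 0.3, 1.0],
            ["v1", "1", 2000, "A", "G", 0.1, 1e-4, 0.3, 1.0],
        ])
        out = genetics.ld_clump(ss, ref)
        assert list(out["snp"]) == ["v0"]

    def test_window_bound(self, rng):
        base = rng.integers(0, 3, size=500).astype(float)
        ref = _panel(np.column_stack([base, base]), pos=[1000, 1000 + 251_000])
        ss = _ss([
            ["v0", "1", 1000, "A", "G", 0.1, 1e-8, 0.3, 1.0],
            ["v1", "1", 1000 + 251_000, "A", "G", 0.1, 1e-4, 0.3, 1.0],
        ])
        out = genetics.ld_clump(ss, ref)
        assert sorted(out["snp"]) == ["v0", "v1"]

    def test_missing_variant_raises(self, rng):
        ref = _panel(rng.integers(0, 3, size=(50, 1)).astype(float))
        ss = _ss([["nope", "1", 1, "A", "G", 0.1, 0.5, 0.3, 1.0]])
        with pytest.raises(genetics.VariantLookupError):
            genetics.ld_clump(ss, ref)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        m = int(rng.integers(5, 50))
        n = 300
        # correlated blocks of random size on two chromosomes
        dosages = np.empty((n, m))
        i = 0
        while i < m:
            width = int(rng.integers(1, 6))
            base = rng.binomial(2, rng.uniform(0.1, 0.5), size=n).astype(float)
            for j in range(i, min(i + width, m)):
                flip = rng.random(n) < 0.2
                col = base.copy()
                col[flip] = rng.binomial(2, 0.3, size=flip.sum())
                dosages[:, j] = col
            i += width
        chrom = np.where(np.arange(m) < m // 2, "1", "2")
        pos = 1000 + (rng.integers(0, 400, size=m) * 1000)
        ref = _panel(dosages, chrom=chrom, pos=pos)
        ss = ref.variants[["snp", "chr", "pos", "a1", "a2"]].copy()
        ss["beta"] = rng.normal(0, 0.1, m)
        ss["p"] = rng.uniform(1e-8, 1, m)
        ss["freq"] = 0.3
        ss["info"] = 1.0
        out = genetics.ld_clump(ss, ref, r2_max=0.1, window_kb=100)
        expected = _brute_force_clump(ss, ref, 0.1, 100)
        assert sorted(out["snp"]) == expected

    def test_survivor_pairs_below_r2(self, rng):
        cfg = dg.SimulationConfig(
            n_samples=400, n_variants=30, n_blocks=3, block_r=0.8, seed=3
        )
        g = dg.simulate_genotypes(cfg)
        ss = dg.simulate_summary_stats(g, cfg)
        ss_qc, _ = genetics.qc_summary_stats(ss, panel=g)
        out = genetics.ld_clump(ss_qc, g, r2_max=0.1, window_kb=250)
        var_idx = {s: i for i, s in enumerate(g.variants["snp"])}
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out.iloc[i], out.iloc[j]
                if a["chr"] != b["chr"] or abs(a["pos"] - b["pos"]) > 250_000:
                    continue
                r = np.corrcoef(
                    g.dosages[:, var_idx[a["snp"]]],
                    g.dosages[:, var_idx[b["snp"]]],
                )[0, 1]
                assert r * r < 0.1


class TestScoring:
    def test_single_variant_arithmetic(self):
        dosages = np.array([[0.0], [1.0], [2.0]])
        ref = _panel(dosages)
        ss = _ss([["v0", "1", 1, "A", "G", np.log(1.2), 1e-9, 0.3, 1.0]])
        panel = genetics.score_prs(ref, ss, thresholds=(5e-8, 1.0))
        raw = panel.raw_scores[5e-8].to_numpy()
        assert raw == pytest.approx([0.0, 0.18232155679, 0.36464311359])

    def test_zero_betas_degenerate(self, rng):
        ref = _panel(rng.integers(0, 3, size=(30, 2)).astype(float))
        ss = _ss([
            ["v0", "1", 1000, "A", "G", 0.0, 1e-9, 0.3, 1.0],
            ["v1", "1", 2000, "A", "G", 0.0, 1e-9, 0.3, 1.0],
        ])
        with pytest.warns(UserWarning):
            panel = genetics.score_prs(ref, ss, thresholds=(5e-8, 1.0))
        assert set(panel.degenerate) == {5e-8, 1.0}
        assert panel.scores.empty

    def test_hand_computed_matrix(self):
        """5 variants x 4 samples against a hand-multiplied expectation."""
        dosages = np.array(
            [
                [0, 1, 2, 0, 1],
                [2, 2, 0, 1, 0],
                [1, 0, 1, 2, 2],
                [0, 0, 0, 0, 0],
            ],
            dtype=float,
        )
        betas = np.array([0.1, -0.2, 0.05, 0.3, -0.1])
        pvals = np.array([1e-9, 1e-6, 1e-4, 0.03, 0.4])
        ref = _panel(dosages)
        ss = _ss(
            [
                [f"v{i}", "1", 1 + i * 1000, "A", "G", betas[i], pvals[i], 0.3, 1.0]
                for i in range(5)
            ]
        )
        panel = genetics.score_prs(ref, ss, thresholds=(1e-8, 1e-5, 0.05, 1.0))
        for t in (1e-8, 1e-5, 0.05, 1.0):
            include = pvals <= t
            expected = dosages[:, include] @ betas[include]
            assert np.allclose(panel.raw_scores[t], expected)
        assert list(panel.snp_counts) == [1, 2, 4, 5]

    def test_snp_counts_monotone(self, small_cohort):
        g = small_cohort.genotypes
        ss, _ = genetics.qc_summary_stats(small_cohort.summary_stats, panel=g)
        panel = genetics.score_prs(g, ss)
        counts = panel.snp_counts.to_numpy()
        assert (np.diff(counts) >= 0).all()

    def test_columns_standardized(self, small_cohort):
        g = small_cohort.genotypes
        ss, _ = genetics.qc_summary_stats(small_cohort.summary_stats, panel=g)
        panel = genetics.score_prs(g, ss)
        assert np.allclose(panel.scores.mean(), 0.0, atol=1e-8)
        assert np.allclose(panel.scores.std(ddof=0), 1.0, atol=1e-8)

    def test_scoring_linearity_over_samples(self, rng):
        dosages = rng.integers(0, 3, size=(40, 6)).astype(float)
        ss = _ss(
            [
                [f"v{i}", "1", 1 + i * 1000, "A", "G", rng.normal(), 0.01, 0.3, 1.0]
                for i in range(6)
            ]
        )
        full = genetics.score_prs(_panel(dosages), ss, thresholds=(0.05, 1.0))
        top = genetics.score_prs(_panel(dosages[:25]), ss, thresholds=(0.05, 1.0))
        bottom = genetics.score_prs(_panel(dosages[25:]), ss, thresholds=(0.05, 1.0))
        concat = np.concatenate(
            [top.raw_scores[1.0].to_numpy(), bottom.raw_scores[1.0].to_numpy()]
        )
        assert np.allclose(full.raw_scores[1.0].to_numpy(), concat)

    def test_allele_flip_harmonization(self, rng):
        """Swapping a1/a2 and negating beta leaves standardized scores
        unchanged (dosage flip 2-d)."""
        dosages = rng.integers(0, 3, size=(60, 3)).astype(float)
        ref = _panel(dosages)
        rows = [
            ["v0", "1", 1, "A", "G", 0.2, 1e-9, 0.3, 1.0],
            ["v1", "1", 1001, "A", "G", -0.1, 1e-9, 0.3, 1.0],
            ["v2", "1", 2001, "A", "G", 0.05, 1e-9, 0.3, 1.0],
        ]
        ss = _ss(rows)
        flipped = _ss(rows)
        flipped.loc[1, ["a1", "a2"]] = ["G", "A"]
        flipped.loc[1, "beta"] = 0.1
        a = genetics.score_prs(ref, ss, thresholds=(0.05, 1.0))
        b = genetics.score_prs(ref, flipped, thresholds=(0.05, 1.0))
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())

    def test_unresolvable_alleles_raise(self, rng):
        ref = _panel(rng.integers(0, 3, size=(30, 1)).astype(float))
        ss = _ss([["v0", "1", 1, "T", "C", 0.1, 1e-9, 0.3, 1.0]])
        with pytest.raises(genetics.AlleleMismatchError, match="v0"):
            genetics.score_prs(ref, ss, thresholds=(0.05, 1.0))

    def test_missing_dosage_mean_imputed(self):
        dosages = np.array([[0.0], [2.0], [np.nan], [2.0]])
        ref = _panel(dosages)
        ss = _ss([["v0", "1", 1, "A", "G", 1.0, 1e-9, 0.3, 1.0]])
        panel = genetics.score_prs(ref, ss, thresholds=(1.0,))
        assert panel.raw_scores[1.0].iloc[2] == pytest.approx(4.0 / 3)


class TestPRSPCA:
    def _panel_from(self, X):
        frame = pd.DataFrame(
            {t: X[:, j] for j, t in enumerate(np.linspace(0.01, 1, X.shape[1]))}
        )
        return genetics.PRSPanel(
            scores=frame,
            thresholds=tuple(frame.columns),
            snp_counts=pd.Series(dtype=int),
        )

    def test_identical_columns_rank_one(self, rng):
        col = rng.standard_normal(100)
        col = (col - col.mean()) / col.std()
        res = genetics.prs_pca(self._panel_from(np.column_stack([col, col])))
        assert res.variance_explained_by_pc1 == pytest.approx(1.0)
        assert np.allclose(res.loadings.iloc[0], res.loadings.iloc[1])

    def test_sign_invariance(self, rng):
        """Negating a minority of columns leaves the aggregated score
        identical (the mean-loading orientation re-anchors it); negating
        every column can only flip its sign, never change its content."""
        X = rng.standard_normal((200, 5))
        X += X[:, [0]]  # shared signal
        X = (X - X.mean(0)) / X.std(0)
        a = genetics.prs_pca(self._panel_from(X))
        flipped_one = X.copy()
        flipped_one[:, 2] = -flipped_one[:, 2]
        b = genetics.prs_pca(self._panel_from(flipped_one))
        assert np.allclose(a.score, b.score, atol=1e-10)
        c = genetics.prs_pca(self._panel_from(-X))
        assert np.allclose(np.abs(a.score), np.abs(c.score), atol=1e-10)

    def test_column_order_invariance(self, rng):
        X = rng.standard_normal((200, 6))
        X += 0.5 * X[:, [0]]
        X = (X - X.mean(0)) / X.std(0)
        a = genetics.prs_pca(self._panel_from(X))
        b = genetics.prs_pca(self._panel_from(X[:, ::-1]))
        assert np.allclose(a.score, b.score, atol=1e-10)

    def test_matches_eigen_oracle(self, rng):
        X = rng.standard_normal((500, 11))
        X += 0.8 * X[:, [0]]
        X = (X - X.mean(0)) / X.std(0)
        res = genetics.prs_pca(self._panel_from(X))
        corr = np.corrcoef(X, rowvar=False)
        w, v = np.linalg.eigh(corr)
        proj = X @ v[:, np.argmax(w)]
        proj = (proj - proj.mean()) / proj.std()
        r = np.corrcoef(res.score, proj)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_single_column_raises(self, rng):
        col = rng.standard_normal(50)
        panel = self._panel_from(((col - col.mean()) / col.std())[:, None])
        with pytest.raises(ValueError, match="single-threshold"):
            genetics.prs_pca(panel)


class TestRGECorrelations:
    def test_self_correlation(self, rng):
        prs = pd.Series(rng.standard_normal(100))
        out = genetics.rge_correlations(prs, pd.DataFrame({"prs": prs}))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_independent_null(self, rng):
        prs = pd.Series(rng.standard_normal(10_000))
        exp = pd.DataFrame({"x": rng.standard_normal(10_000)})
        out = genetics.rge_correlations(prs, exp)
        assert abs(out.loc[0, "r"]) < 0.03

    def test_constant_exposure_noted(self, rng):
        prs = pd.Series(rng.standard_normal(50))
        out = genetics.rge_correlations(prs, pd.DataFrame({"c": np.ones(50)}))
        assert np.isnan(out.loc[0, "r"])
        assert out.loc[0, "note"] == "constant exposure"


def test_end_to_end_prs_correlates_with_truth():
    """Full QC -> clump -> score -> PCA pipeline on a synthetic cohort:
    the estimated PRS correlates positively with the true genetic score."""
    cfg = dg.SimulationConfig(
        n_samples=5000, n_variants=100, n_blocks=10, block_r=0.3,
        causal_fraction=0.5, effect_sd=0.05, seed=42,
    )
    sc = dg.simulate.simulate(cfg)
    g = sc.genotypes
    ss, _ = genetics.qc_summary_stats(sc.summary_stats, panel=g)
    clumped = genetics.ld_clump(ss, g)
    panel = genetics.score_prs(g, clumped)
    prs_hat = genetics.prs_pca(panel).score
    truth = sc.cohort["prs"]
    from scipy import stats as sps

    r, p = sps.pearsonr(prs_hat.to_numpy(), truth.to_numpy())
    assert r > 0
    assert p < 0.01
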