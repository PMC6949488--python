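import numpy as np
import pandas as pd
import pytest

from tmesig.io import AnalysisConfig
from tmesig.signatures import (
    AXES,
    DEFAULT_PANEL,
    CollinearityError,
    MissingGeneError,
    PrototypePanel,
    SignatureSet,
    compute_prototype_scores,
    compute_signature_scores,
    derive_signatures,
    fit_gene_models,
    select_signature_genes,
)


def brute_force_scores(matrix, axis_genes):
    out = {}
    for axis, genes in axis_genes.items():
        present = [g for g in genes if g in matrix.index]
        out[axis] = np.array(
            [np.mean([matrix.loc[g, s] for g in present]) for s in matrix.columns]
        )
    return out


class TestPrototypeScores:
    def test_constant_sample_gives_constant_scores(self, panel_matrix):
        m = panel_matrix.copy()
        m["S00"] = 5.5
        scores = compute_prototype_scores(m)
        assert np.allclose(scores.loc["S00"], 5.5)

    def test_two_gene_mean(self):
        m = pd.DataFrame(
            {"s": {g: 8.0 for axis in AXES for g in DEFAULT_PANEL.genes(axis)}}
        )
        m.loc["MMP9", "s"] = 2.0
        m.loc["S100A8", "s"] = 4.0
        panel = PrototypePanel(neutrophil=("MMP9", "S100A8"))
        scores = compute_prototype_scores(m, panel)
        assert scores.loc["s", "neutrophil"] == 3.0

    def test_matches_brute_force_mean_oracle(self, panel_matrix):
        scores = compute_prototype_scores(panel_matrix)
        oracle = brute_force_scores(
            panel_matrix, {a: DEFAULT_PANEL.genes(a) for a in AXES}
        )
        for axis in AXES:
            assert np.abs(scores[axis].to_numpy() - oracle[axis]).max() < 1e-12

    def test_missing_axis_errors(self, panel_matrix):
        m = panel_matrix.drop(list(DEFAULT_PANEL.tgfb))
        with pytest.raises(MissingGeneError, match="tgfb"):
            compute_prototype_scores(m)

    def test_absent_genes_warn(self, panel_matrix):
        m = panel_matrix.drop(["MMP9"])
        with pytest.warns(UserWarning, match="MMP9"):
            compute_prototype_scores(m)

    def test_score_linearity_in_sample_shift(self, panel_matrix):
        base = compute_prototype_scores(panel_matrix)
        shifted = panel_matrix.copy()
        shifted["S03"] += 2.5
        new = compute_prototype_scores(shifted)
        assert np.allclose(new.loc["S03"] - base.loc["S03"], 2.5)
        others = [s for s in panel_matrix.columns if s != "S03"]
        assert np.allclose(new.loc[others], base.loc[others])

    def test_gene_order_permutation_invariance(self, panel_matrix, rng):
        perm = rng.permutation(len(panel_matrix))
        scores_a = compute_prototype_scores(panel_matrix)
        scores_b = compute_prototype_scores(panel_matrix.iloc[perm])
        pd.testing.assert_frame_equal(scores_a, scores_b)


class TestFitGeneModels:
    def test_exact_multiple_of_prototype_score(self, rng):
        n = 50
        samples = [f"S{i}" for i in range(n)]
        scores = pd.DataFrame(
            rng.normal(size=(n, 3)), index=samples, columns=list(AXES)
        )
        m = pd.DataFrame(
            {"TARGET": 2.0 * scores["neutrophil"], "OTHER": rng.normal(size=n)}
        ).T
        fit = fit_gene_models(m, scores)
        assert fit.loc["TARGET", "coef_neutrophil"] == pytest.approx(2.0, abs=1e-10)
        assert fit.loc["TARGET", "p_neutrophil"] < 1e-30

    def test_constant_gene_convention(self, rng):
        n = 20
        scores = pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"S{i}" for i in range(n)],
            columns=list(AXES),
        )
        m = pd.DataFrame(
            {"FLAT": np.full(n, 3.0), "VAR": rng.normal(size=n)},
            index=scores.index,
        ).T
        fit = fit_gene_models(m, scores)
        for axis in AXES:
            assert fit.loc["FLAT", f"coef_{axis}"] == 0.0
            assert fit.loc["FLAT", f"p_{axis}"] == 1.0

    def test_matches_normal_equations_oracle(self, rng):
        n, g = 60, 200
        samples = [f"S{i}" for i in range(n)]
        scores = pd.DataFrame(
            rng.normal(size=(n, 3)), index=samples, columns=list(AXES)
        )
        m = pd.DataFrame(
            rng.normal(size=(g, n)),
            index=[f"G{i}" for i in range(g)],
            columns=samples,
        )
        fit = fit_gene_models(m, scores)
        X = np.column_stack([np.ones(n), scores.to_numpy()])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = (xtx_inv @ X.T @ m.to_numpy().T).T
        resid = m.to_numpy() - beta @ X.T
        sigma2 = (resid**2).sum(axis=1) / (n - 4)
        se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
        tstats = beta / se
        got_coef = fit[[f"coef_{a}" for a in AXES]].to_numpy()
        got_t = fit[[f"t_{a}" for a in AXES]].to_numpy()
        assert np.abs(got_coef - beta[:, 1:]).max() < 1e-8
        assert np.abs(got_t - tstats[:, 1:]).max() < 1e-8

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        n = 40
        scores = pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"S{i}" for i in range(n)],
            columns=list(AXES),
        )
        y = rng.normal(size=n)
        m = pd.DataFrame({"G": y}, index=scores.index).T
        fit = fit_gene_models(m, scores)
        ref = sm.OLS(y, sm.add_constant(scores.to_numpy())).fit()
        for j, axis in enumerate(AXES, start=1):
            assert fit.loc["G", f"coef_{axis}"] == pytest.approx(ref.params[j], abs=1e-10)
            assert fit.loc["G", f"p_{axis}"] == pytest.approx(ref.pvalues[j], abs=1e-10)

    def test_collinear_scores_error(self, rng):
        n = 20
        base = rng.normal(size=n)
        scores = pd.DataFrame(
            {"neutrophil": base, "tcell": base, "tgfb": rng.normal(size=n)},
            index=[f"S{i}" for i in range(n)],
        )
        m = pd.DataFrame(
            rng.normal(size=(5, n)),
            index=[f"G{i}" for i in range(5)],
            columns=scores.index,
        )
        with pytest.raises(CollinearityError, match="neutrophil.*tcell"):
            fit_gene_models(m, scores)

    def test_too_few_samples_error(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"S{i}" for i in range(5)],
            columns=list(AXES),
        )
        m = pd.DataFrame(
            rng.normal(size=(3, 5)), index=["A", "B", "C"], columns=scores.index
        )
        with pytest.raises(ValueError, match="6 samples"):
            fit_gene_models(m, scores)


def make_fit(records):
    """Build a fit frame from (gene, axis->(coef, adjp)) records."""
    rows = {}
    for gene, per_axis, proto in records:
        row = {}
        for axis in AXES:
            coef, adjp = per_axis.get(axis, (0.0, 1.0))
            row[f"coef_{axis}"] = coef
            row[f"t_{axis}"] = 0.0
            row[f"p_{axis}"] = adjp
            row[f"adjp_{axis}"] = adjp
        row["prototype_axis"] = proto
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class TestSelectSignatureGenes:
    def panel(self):
        return PrototypePanel(
            neutrophil=("N1", "N2"), tcell=("T1",), tgfb=("F1",)
        )

    def proto_records(self):
        return [
            ("N1", {}, "neutrophil"),
            ("N2", {}, "neutrophil"),
            ("T1", {}, "tcell"),
            ("F1", {}, "tgfb"),
        ]

    def test_no_qualifying_genes_falls_back_to_prototypes(self):
        fit = make_fit(self.proto_records() + [("G1", {"neutrophil": (0.5, 0.9)}, "")])
        with pytest.warns(UserWarning, match="falling back"):
            sigs = select_signature_genes(fit, self.panel())
        assert sigs.axis_genes("neutrophil") == ["N1", "N2"]
        assert sigs.axis_genes("tcell") == ["T1"]

    def test_cap_keeps_prototypes_and_top_candidates(self):
        cands = [
            (f"G{i:02d}", {"neutrophil": (1.5, 0.001 * (i + 1))}, "") for i in range(80)
        ]
        fit = make_fit(self.proto_records() + cands)
        cfg = AnalysisConfig(max_genes=50)
        with pytest.warns(UserWarning):
            sigs = select_signature_genes(fit, self.panel(), cfg)
        neu = sigs.axis_genes("neutrophil")
        assert len(neu) == 50
        assert neu[:2] == ["N1", "N2"]
        assert neu[2:] == [f"G{i:02d}" for i in range(48)]  # ascending adjusted p

    def test_gene_assigned_to_axis_with_smallest_adjusted_p(self):
        fit = make_fit(
            self.proto_records()
            + [("G1", {"neutrophil": (2.0, 0.01), "tgfb": (2.0, 0.2)}, "")]
        )
        with pytest.warns(UserWarning):
            sigs = select_signature_genes(fit, self.panel())
        assert "G1" in sigs.axis_genes("neutrophil")
        assert "G1" not in sigs.axis_genes("tgfb")

    def test_negative_coefficients_excluded_by_default(self):
        fit = make_fit(self.proto_records() + [("G1", {"neutrophil": (-3.0, 0.001)}, "")])
        with pytest.warns(UserWarning):
            sigs = select_signature_genes(fit, self.panel())
        assert "G1" not in sigs.axis_genes("neutrophil")
        with pytest.warns(UserWarning):
            sigs_abs = select_signature_genes(
                fit, self.panel(), AnalysisConfig(absolute_coef=True)
            )
        assert "G1" in sigs_abs.axis_genes("neutrophil")

    @pytest.mark.parametrize(
        "loose", [AnalysisConfig(alpha_select=0.8), AnalysisConfig(min_coef=0.5)]
    )
    def test_selection_monotone_in_thresholds(self, rng, loose):
        cands = [
            (
                f"G{i:02d}",
                {
                    axis: (rng.uniform(0.0, 3.0), rng.uniform(0.0, 1.0))
                    for axis in AXES
                },
                "",
            )
            for i in range(40)
        ]
        fit = make_fit(self.proto_records() + cands)
        strict = AnalysisConfig()
        sel_strict = select_signature_genes(fit, self.panel(), strict)
        sel_loose = select_signature_genes(fit, self.panel(), loose)
        assert set(sel_strict.genes["gene"]) <= set(sel_loose.genes["gene"])


class TestSignatureScoresAndDerivation:
    def test_prototype_signatures_reduce_to_prototype_scores(self, panel_matrix):
        sigs, scores = derive_signatures(
            panel_matrix, config=AnalysisConfig(expand_signatures=False)
        )
        pd.testing.assert_frame_equal(
            scores, compute_prototype_scores(panel_matrix), check_like=True
        )
        assert not sigs.expanded
        assert set(sigs.genes["provenance"]) == {"prototype"}

    def test_single_gene_axis_score_equals_row(self, panel_matrix):
        genes = pd.DataFrame(
            [
                {"gene": "MMP9", "axis": "neutrophil", "provenance": "prototype",
                 "coefficient": np.nan, "adj_p": np.nan},
                {"gene": "CD8A", "axis": "tcell", "provenance": "prototype",
                 "coefficient": np.nan, "adj_p": np.nan},
                {"gene": "DCN", "axis": "tgfb", "provenance": "prototype",
                 "coefficient": np.nan, "adj_p": np.nan},
            ]
        )
        scores = compute_signature_scores(panel_matrix, SignatureSet(genes=genes))
        assert np.allclose(scores["neutrophil"], panel_matrix.loc["MMP9"])

    def test_signature_scores_match_oracle(self, panel_matrix):
        sigs, scores = derive_signatures(
            panel_matrix, config=AnalysisConfig(expand_signatures=False)
        )
        oracle = brute_force_scores(
            panel_matrix, {a: sigs.axis_genes(a) for a in AXES}
        )
        for axis in AXES:
            assert np.abs(scores[axis].to_numpy() - oracle[axis]).max() < 1e-12

    def test_small_cohort_uses_prototypes_only(self, panel_matrix):
        assert panel_matrix.shape[1] < 30
        sigs, _ = derive_signatures(panel_matrix, config=AnalysisConfig())
        assert not sigs.expanded

    def test_large_cohort_expands(self):
        from tmesig.simulate import generate_cohort

        matrix, _, truth = generate_cohort(seed=0)
        sigs, scores = derive_signatures(matrix)
        assert sigs.expanded
        for axis in AXES:
            axis_genes = sigs.axis_genes(axis)
            assert len(axis_genes) <= 50
            for g in DEFAULT_PANEL.genes(axis):
                assert g in axis_genes
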