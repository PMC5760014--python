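"""cis-eQTL ANCOVA, Bonferroni gating, pooled differential expression, cell types."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstrait.expression import (BONFERRONI_ALPHA, ancova_additive,
                                   bonferroni_gate, cell_type_assignment,
                                   cis_pairs, differential_expression)
from crosstrait.loci import GeneAnnotation
from crosstrait.simulate import ExpressionMatrix, simulate_expression


@pytest.fixture
def genes():
    return GeneAnnotation(pd.DataFrame({
        "chrom": ["1", "1", "1", "2"],
        "start": [1_000_000, 5_000_000, 9_000_000, 1_000_000],
        "end": [1_010_000, 5_050_000, 9_100_000, 1_500_000],
        "name": ["g1", "g2", "g3", "g4"],
        "strand": ["+", "-", "+", "+"],
    }))


class TestCisPairs:
    def test_variant_at_tss_is_paired(self, genes):
        v = pd.DataFrame({"snp": ["rsX"], "chrom": ["1"], "pos": [1_000_000]})
        out = cis_pairs(v, genes)
        assert ("rsX", "g1") in set(zip(out["snp"], out["gene"]))

    def test_window_boundary_is_inclusive_at_1mb(self, genes):
        v = pd.DataFrame({"snp": ["in", "out"], "chrom": ["1", "1"],
                          "pos": [2_000_000, 2_000_001]})
        out = cis_pairs(v, genes)
        pairs = set(zip(out["snp"], out["gene"]))
        assert ("in", "g1") in pairs and ("out", "g1") not in pairs

    def test_negative_strand_uses_interval_end_as_tss(self, genes):
        # g2 TSS = 5,050,000; a variant 1 Mb + 1 bp before interval start is
        # still within 1 Mb of the TSS on the minus strand
        v = pd.DataFrame({"snp": ["rsY"], "chrom": ["1"], "pos": [4_055_000]})
        out = cis_pairs(v, genes)
        assert ("rsY", "g2") in set(zip(out["snp"], out["gene"]))

    def test_matches_exhaustive_distance_scan(self, genes):
        rng = np.random.default_rng(0)
        v = pd.DataFrame({"snp": [f"v{i}" for i in range(5)],
                          "chrom": rng.choice(["1", "2"], 5),
                          "pos": rng.integers(1, 10_000_000, 5)})
        got = set(zip(*cis_pairs(v, genes)[["snp", "gene"]].to_numpy().T))
        iv = genes.intervals
        tss = {r["name"]: (r["chrom"], r["end"] if r["strand"] == "-" else r["start"])
               for _, r in iv.iterrows()}
        want = {(r["snp"], g) for _, r in v.iterrows() for g, (c, t) in tss.items()
                if c == r["chrom"] and abs(r["pos"] - t) <= 1_000_000}
        assert got == want


class TestAncova:
    def test_noiseless_recovery_exact_with_minimal_p(self):
        dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1])
        res = ancova_additive(2.0 * dosage + 1.0, dosage)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.pval < 1e-50

    def test_matches_simple_regression_closed_form(self):
        rng = np.random.default_rng(7)
        dosage = rng.binomial(2, 0.4, size=60).astype(float)
        y = 0.5 * dosage + rng.standard_normal(60)
        res = ancova_additive(y, dosage)
        ref = stats.linregress(dosage, y)
        assert res.slope == pytest.approx(ref.slope, abs=1e-10)
        assert res.pval == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_null_pvalues_uniform(self):
        rng = np.random.default_rng(19)
        passes = 0
        for rep in range(10):
            dosage = rng.binomial(2, 0.4, size=40).astype(float)
            pvals = []
            for _ in range(1000):
                y = rng.standard_normal(40)  # expression unrelated to dosage
                pvals.append(ancova_additive(y, dosage).pval)
            passes += stats.kstest(pvals, "uniform").pvalue > 0.01
        assert passes >= 9

    def test_constant_dosage_flagged_not_fatal(self):
        res = ancova_additive(np.arange(10.0), np.ones(10))
        assert res.error == "constant dosage"
        assert np.isnan(res.slope)

    def test_covariate_adjustment_changes_fit(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.5, 100).astype(float)
        age = rng.normal(60, 8, 100)
        y = 0.3 * dosage + 0.1 * age + rng.standard_normal(100)
        unadj = ancova_additive(y, dosage)
        adj = ancova_additive(y, dosage, covariates=age)
        assert adj.slope == pytest.approx(0.3, abs=0.3)
        assert adj.pval != unadj.pval

    def test_shift_equivariance(self):
        rng = np.random.default_rng(8)
        dosage = rng.binomial(2, 0.4, 50).astype(float)
        y = 0.7 * dosage + rng.standard_normal(50)
        a = ancova_additive(y, dosage)
        b = ancova_additive(y + 100.0, dosage)
        assert a.slope == pytest.approx(b.slope, abs=1e-10)
        assert a.tstat == pytest.approx(b.tstat, abs=1e-10)
        assert a.pval == pytest.approx(b.pval, abs=1e-10)


class TestBonferroniGate:
    def test_boundary_is_strict(self):
        df = pd.DataFrame({"pval": [BONFERRONI_ALPHA, 1e-12, 0.5, np.nan]})
        out = bonferroni_gate(df)
        assert out["pass"].tolist() == [False, True, False, False]

    def test_pass_count_matches_manual_enumeration(self):
        rng = np.random.default_rng(2)
        p = 10.0 ** rng.uniform(-8, 0, 100)
        out = bonferroni_gate(pd.DataFrame({"pval": p}))
        assert out["pass"].sum() == int((p < BONFERRONI_ALPHA).sum())


class TestDifferentialExpression:
    def test_null_shift_pvalues_uniform(self):
        passes = 0
        for seed in range(100):
            mat, _, _ = simulate_expression(n_samples=10, n_genes=40,
                                            de_shift=0.0, seed=seed)
            out = differential_expression(mat, "control", "case")
            passes += stats.kstest(out["pval"], "uniform").pvalue > 0.01
        assert passes >= 95

    def test_degenerate_equal_groups_give_maximal_p(self):
        values = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                              columns=list("abcd"))
        samples = pd.DataFrame({"group": ["x", "x", "y", "y"],
                                "region": ["r1"] * 4}, index=list("abcd"))
        out = differential_expression(ExpressionMatrix(values, samples), "x", "y")
        assert out["pval"].item() == 1.0
        assert not out["significant"].item()

    def test_group_swap_negates_statistic_preserves_p(self):
        mat, _, _ = simulate_expression(n_samples=8, n_genes=10, de_shift=1.0, seed=5)
        ab = differential_expression(mat, "control", "case")
        ba = differential_expression(mat, "case", "control")
        assert np.allclose(ab["stat"], -ba["stat"])
        assert np.array_equal(ab["pval"], ba["pval"])

    def test_absent_gene_recorded_not_available(self):
        mat, _, _ = simulate_expression(n_samples=5, n_genes=4, seed=1)
        out = differential_expression(mat, "control", "case",
                                      genes=list(mat.values.index) + ["LRRK2"])
        row = out[out["gene"] == "LRRK2"].iloc[0]
        assert not row["available"] and not row["significant"]

    def test_power_at_three_sigma_shift_17_vs_11(self):
        """Cohort-sized two-group comparison (17 patients vs 11 controls),
        shift = 3 x noise sd: at least 80% of true-DE genes at p <= 0.05."""
        hits, total = 0, 0
        for seed in range(5):
            mat, _, truth = simulate_expression(n_samples=17, n_genes=60,
                                                de_shift=3.0, noise_sd=1.0,
                                                seed=seed)
            # cases 17, controls truncated to 11
            controls = mat.samples.index[mat.samples["group"] == "control"][:11]
            cases = mat.samples.index[mat.samples["group"] == "case"]
            sub = ExpressionMatrix(mat.values[list(controls) + list(cases)],
                                   mat.samples.loc[list(controls) + list(cases)])
            out = differential_expression(sub, "control", "case").set_index("gene")
            de = truth[truth["is_de"]]["gene"]
            hits += out.loc[de, "significant"].sum()
            total += len(de)
        assert hits / total >= 0.80


class TestCellTypeAssignment:
    @pytest.fixture
    def profile(self):
        return pd.DataFrame(
            {"neurons": [1.0, 50.0, 3.0], "microglia/macrophages": [60.0, 2.0, 3.0]},
            index=["HLA-DRA", "MAPT", "TIE"])

    def test_argmax_assignment(self, profile):
        a, _ = cell_type_assignment(profile)
        assert a["HLA-DRA"] == "microglia/macrophages"
        assert a["MAPT"] == "neurons"

    def test_absent_gene_marked_not_found(self, profile):
        a, counts = cell_type_assignment(profile, genes=["HLA-DRA", "HLA-DRQ"])
        assert a["HLA-DRQ"] == "not found"
        assert counts["not found"] == 1

    def test_tie_broken_by_canonical_order(self, profile):
        a, _ = cell_type_assignment(profile)
        assert a["TIE"] == "neurons"  # neurons precede microglia canonically

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(
            rng.uniform(0, 10, size=(9, 3)),
            index=[f"g{i}" for i in range(9)],
            columns=["neurons", "fetal astrocytes", "microglia/macrophages"])
        # force 5 microglia, 2 neurons, 1 fetal astrocyte, 1 neuron-by-argmax
        prof.iloc[:5, 2] += 100
        prof.iloc[5:7, 0] += 100
        prof.iloc[7, 1] += 100
        prof.iloc[8, 0] += 100
        _, counts = cell_type_assignment(prof)
        assert counts["microglia/macrophages"] == 5
        assert counts["neurons"] == 3
        assert counts["fetal astrocytes"] == 1

    def test_scale_invariance_per_gene(self, profile):
        a1, _ = cell_type_assignment(profile)
        scaled = profile.copy()
        scaled.loc["HLA-DRA"] *= 1000.0
        a2, _ = cell_type_assignment(scaled)
        assert a1.equals(a2)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            cell_type_assignment(pd.DataFrame({"neurons": [-1.0]}, index=["g"]))
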