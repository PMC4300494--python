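import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensikit.proteomics import (
    MAXQUANT_LIKE,
    ProteinRatioTable,
    apply_regulation_filters,
    differential_analysis,
    filter_phosphosites,
    load_phosphosite_table,
    load_ratio_table,
    one_sample_test,
    phosphosite_ratio_table,
    two_sample_test,
    write_ratio_table,
)
from sensikit.simulate import ProteomeSimConfig, simulate_proteome


def make_table(ml, hl, hm, protein_id="P1"):
    row = {"protein_id": protein_id, "gene": "G1"}
    for r, v in enumerate(ml, 1):
        row[f"ml_log2_{r}"] = v
    for r, v in enumerate(hl, 1):
        row[f"hl_log2_{r}"] = v
    for r, v in enumerate(hm, 1):
        row[f"hm_log2_{r}"] = v
    return ProteinRatioTable(pd.DataFrame([row]), n_replicates=len(ml))


class TestOneSampleTest:
    def test_all_zero_not_significant(self):
        n, mean, p, degen = one_sample_test([0.0, 0.0, 0.0])
        assert mean == 0 and p == 1.0 and degen

    def test_textbook_example(self):
        # mean 1.0, sd 0.2, t = 1/(0.2/sqrt(3)) ≈ 8.660, df 2
        n, mean, p, degen = one_sample_test([1.0, 1.2, 0.8])
        t = 1.0 / (0.2 / math.sqrt(3))
        assert t == pytest.approx(8.660, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(0.3, 0.5, size=rng.integers(3, 8))
            _, _, p, _ = one_sample_test(x)
            assert p == pytest.approx(stats.ttest_1samp(x, 0.0).pvalue, abs=1e-10)

    def test_too_few_replicates_excluded(self):
        assert one_sample_test([1.0, 2.0]) is None
        assert one_sample_test([1.0, 2.0], min_replicates=2) is not None

    def test_zero_variance_nonzero_mean_flagged(self):
        n, mean, p, degen = one_sample_test([1.0, 1.0, 1.0])
        assert p == 0.0 and degen

    def test_type_I_rate_nominal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, size=(10_000, 3))
        rej = 0
        for row in x:
            _, _, p, _ = one_sample_test(row)
            rej += p < 0.05
        assert 0.04 <= rej / 10_000 <= 0.06


class TestTwoSampleTest:
    def test_identical_groups(self):
        n, d, p, _ = two_sample_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert d == 0 and p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        n, d, p, degen = two_sample_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert p == 0.0 and degen

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(0, 1, size=rng.integers(3, 7))
            b = rng.normal(0.5, 1, size=rng.integers(3, 7))
            _, _, p, _ = two_sample_test(a, b)
            assert p == pytest.approx(stats.ttest_ind(a, b).pvalue, abs=1e-10)
            _, _, pw, _ = two_sample_test(a, b, welch=True)
            assert pw == pytest.approx(
                stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-10
            )

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.4, 0.3, 4)
        b = rng.normal(0.0, 0.3, 4)
        _, d1, p1, _ = two_sample_test(a, b)
        _, d2, p2, _ = two_sample_test(-a, -b)
        assert d2 == pytest.approx(-d1)
        assert p2 == pytest.approx(p1, abs=1e-15)


class TestDifferentialAndFilters:
    def test_contrast_wiring(self):
        table = make_table(ml=[1.0, 1.1, 0.9], hl=[2.0, 2.1, 1.9], hm=[1.0, 1.0, 1.1])
        res = differential_analysis(table)
        by = res.set_index("contrast")
        assert by.loc["1d_vs_ctrl", "mean_log2_ratio"] == pytest.approx(1.0)
        assert by.loc["3d_vs_ctrl", "mean_log2_ratio"] == pytest.approx(2.0)
        assert by.loc["3d_vs_1d", "mean_log2_ratio"] == pytest.approx(1.0)

    def test_zero_mean_never_significant(self):
        table = make_table(ml=[0.1, -0.1, 0.0], hl=[0, 0, 0.01], hm=[0, 0, 0])
        summary = apply_regulation_filters(differential_analysis(table))
        assert not summary.results["significant"].any()

    def test_boundary_fold_change_inclusive(self):
        v = math.log2(1.5)
        res = pd.DataFrame(
            {
                "protein_id": ["P1", "P2"],
                "gene": ["A", "B"],
                "contrast": ["1d_vs_ctrl"] * 2,
                "n": 3,
                "mean_log2_ratio": [v, v - 1e-9],
                "p_value": [0.01, 0.01],
                "degenerate": False,
                "fold_change": [1.5, 1.499],
                "bh_adjusted_p": [0.02, 0.02],
            }
        )
        summary = apply_regulation_filters(res)
        assert summary.regulated["1d_vs_ctrl"] == {"P1"}

    def test_union_counts_unique_ids(self):
        cfg = ProteomeSimConfig(n_proteins=300, frac_regulated=0.2, noise_sd=0.1, seed=5)
        proteins, _, _ = simulate_proteome(cfg)
        table = ProteinRatioTable(proteins)
        summary = apply_regulation_filters(differential_analysis(table))
        total = sum(len(s) for s in summary.regulated.values())
        assert len(summary.union) <= total
        assert summary.union == set().union(*summary.regulated.values())

    def test_sign_antisymmetry_full_table(self):
        cfg = ProteomeSimConfig(n_proteins=50, frac_regulated=0.3, seed=6)
        proteins, _, _ = simulate_proteome(cfg)
        flipped = proteins.copy()
        cols = [c for c in proteins.columns if "_log2_" in c]
        flipped[cols] = -flipped[cols]
        r1 = differential_analysis(ProteinRatioTable(proteins))
        r2 = differential_analysis(ProteinRatioTable(flipped))
        assert np.allclose(r1["mean_log2_ratio"], -r2["mean_log2_ratio"])
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-15)

    def test_planted_recovery(self):
        """Planted 5% regulated at |log2 FC| = 1, sd 0.1: sensitivity >= 0.95,
        empirical FDR <= 0.1 (aggregated over seeds)."""
        tp = fp = fn = 0
        for seed in range(10):
            cfg = ProteomeSimConfig(
                n_proteins=500, frac_regulated=0.05,
                effect_log2fc_range=(1.0, 1.0), noise_sd=0.1, seed=seed,
            )
            proteins, _, truth = simulate_proteome(cfg)
            summary = apply_regulation_filters(
                differential_analysis(ProteinRatioTable(proteins))
            )
            planted = set(truth.loc[truth["is_planted"], "entity_id"])
            called = summary.regulated["1d_vs_ctrl"] | summary.regulated["3d_vs_ctrl"]
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        assert tp / (tp + fn) >= 0.95
        assert fp / max(tp + fp, 1) <= 0.1


class TestTableIO:
    def test_round_trip(self, tmp_path):
        cfg = ProteomeSimConfig(n_proteins=20, seed=7)
        proteins, _, _ = simulate_proteome(cfg)
        table = ProteinRatioTable(proteins)
        path = tmp_path / "prot.tsv"
        write_ratio_table(table, path)
        back = load_ratio_table(path)
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_decoy_and_contaminant_rows_removed(self, tmp_path):
        cfg = ProteomeSimConfig(n_proteins=5, seed=8)
        proteins, _, _ = simulate_proteome(cfg)
        proteins.loc[0, "protein_id"] = "REV__P00000"
        proteins.loc[1, "protein_id"] = "CON__P00001"
        path = tmp_path / "prot.tsv"
        proteins.to_csv(path, sep="\t", index=False)
        table = load_ratio_table(path)
        assert len(table.df) == 3
        assert not table.df["protein_id"].str.startswith(("REV__", "CON__")).any()

    def test_linear_dialect_log2(self, tmp_path):
        rows = {"Protein IDs": ["P1"], "Gene names": ["G1"]}
        for ch in ("M/L", "H/L", "H/M"):
            for r in (1, 2, 3):
                rows[f"Ratio {ch} normalized {r}"] = [1.0 if ch == "M/L" else 2.0]
        path = tmp_path / "mq.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        table = load_ratio_table(path, MAXQUANT_LIKE)
        assert table.df.loc[0, "ml_log2_1"] == pytest.approx(0.0)
        assert table.df.loc[0, "hl_log2_1"] == pytest.approx(1.0)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"x": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="protein_id"):
            load_ratio_table(path)


class TestPhosphosites:
    def test_boundary_inclusive(self):
        sites = pd.DataFrame(
            {
                "protein_id": ["P1", "P2"],
                "position": [10, 20],
                "residue": ["S", "T"],
                "localization_prob": [0.75, 0.74],
            }
        )
        kept, retention = filter_phosphosites(sites)
        assert kept["protein_id"].tolist() == ["P1"]
        assert retention == pytest.approx(0.5)

    def test_all_confident_full_retention(self):
        sites = pd.DataFrame(
            {
                "protein_id": ["P1"] * 4,
                "position": range(4),
                "residue": ["S"] * 4,
                "localization_prob": [1.0] * 4,
            }
        )
        _, retention = filter_phosphosites(sites)
        assert retention == 1.0

    def test_invalid_probability_rejected(self):
        sites = pd.DataFrame(
            {
                "protein_id": ["P1"],
                "position": [1],
                "residue": ["S"],
                "localization_prob": [1.2],
            }
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            filter_phosphosites(sites)

    def test_retention_matches_model_mass(self):
        cfg = ProteomeSimConfig(n_proteins=10_000, frac_phospho=1.0, seed=9)
        _, phospho, _ = simulate_proteome(cfg)
        _, retention = filter_phosphosites(phospho)
        assert abs(retention - cfg.loc_prob_model.mass_above(0.75)) < 0.02

    def test_site_table_round_trip_and_ids(self, tmp_path):
        cfg = ProteomeSimConfig(n_proteins=50, frac_phospho=0.5, seed=10)
        _, phospho, _ = simulate_proteome(cfg)
        path = tmp_path / "sites.tsv"
        phospho.to_csv(path, sep="\t", index=False)
        back = load_phosphosite_table(path)
        table = phosphosite_ratio_table(back)
        assert table.df["protein_id"].str.contains("_").all()
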