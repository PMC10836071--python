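"""Differential usage testing, BH adjustment and cryptic classification."""

import numpy as np
import pandas as pd
import pytest

from apascan import (
    benjamini_hochberg,
    classify_cryptic,
    differential_usage,
    select_background,
)
from apascan.cryptic import RESULT_COLUMNS, results_from_table
from apascan.simulate import simulate_null_usage
from apascan.usage import IsoformUsageMatrix, polya_usage

from oracles import bh_oracle


class TestBenjaminiHochberg:
    def test_matches_stepup_oracle_on_fixed_vector(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        assert np.allclose(benjamini_hochberg(np.array(p)), bh_oracle(p))

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(3, 40)))
            assert np.allclose(benjamini_hochberg(p), bh_oracle(list(p)))

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=50)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()


def usage_matrix_from_counts(counts: pd.DataFrame, iso2gene: dict):
    m = IsoformUsageMatrix(
        tpm=counts.astype(float),
        counts=counts.astype(float),
        iso2gene=pd.Series(iso2gene),
    )
    return polya_usage(m)


def design_for(samples):
    return pd.DataFrame(
        {"condition": [s.rsplit("_", 1)[0] for s in samples]}, index=samples
    )


class TestDifferentialUsage:
    def test_identical_counts_give_null_result(self):
        samples = ["CTRL_1", "CTRL_2", "CTRL_3", "KD_1", "KD_2", "KD_3"]
        counts = pd.DataFrame(
            {s: [100.0, 400.0] for s in samples}, index=["isoA", "isoB"]
        )
        m = usage_matrix_from_counts(counts, {"isoA": "g", "isoB": "g"})
        res = differential_usage(m, design_for(samples), control="CTRL")
        row = res.set_index("isoform_id").loc["isoA"]
        assert row["delta_usage"] == pytest.approx(0.0)
        assert row["p_value"] > 0.9

    def test_type_I_error_calibrated(self):
        """Empirical type-I at nominal 0.05 within [0.03, 0.07] (null sim)."""
        m, design = simulate_null_usage(n_genes=250, n_per_condition=3, seed=7)
        res = differential_usage(m, design, control="CTRL")
        rate = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_shift(self):
        """Usage 0.05 -> 0.30 with NB counts at depth 500: p < 0.05 in >=90%."""
        rng = np.random.default_rng(21)
        samples = ["CTRL_1", "CTRL_2", "CTRL_3", "KD_1", "KD_2", "KD_3"]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = {}
            for s in samples:
                u = 0.05 if s.startswith("CTRL") else 0.30
                frac = rng.dirichlet(np.array([u, 1 - u]) * 300)
                mu = 500 * frac
                lam = rng.gamma(shape=1 / 0.05, scale=0.05 * mu)
                counts[s] = rng.poisson(lam).astype(float)
            counts = pd.DataFrame(counts, index=["isoA", "isoB"])
            m = usage_matrix_from_counts(counts, {"isoA": "g", "isoB": "g"})
            res = differential_usage(m, design_for(samples), control="CTRL")
            p = res.set_index("isoform_id").loc["isoA", "p_value"]
            hits += p < 0.05
        assert hits >= 0.9 * n_rep

    def test_fewer_than_two_samples_errors(self):
        samples = ["CTRL_1", "KD_1", "KD_2"]
        counts = pd.DataFrame({s: [10.0, 20.0] for s in samples}, index=["a", "b"])
        m = usage_matrix_from_counts(counts, {"a": "g", "b": "g"})
        with pytest.raises(ValueError):
            differential_usage(m, design_for(samples), control="CTRL")

    def test_covariate_absorbed(self):
        """A strong batch effect aligned with batch, not condition, stays null."""
        rng = np.random.default_rng(31)
        samples = [f"{c}_{i}" for c in ("CTRL", "KD") for i in (1, 2, 3, 4)]
        design = design_for(samples)
        design["batch"] = ["b1", "b1", "b2", "b2"] * 2
        pvals = []
        for _ in range(60):
            counts = {}
            for s in samples:
                u = 0.2 if design.loc[s, "batch"] == "b1" else 0.5
                frac = rng.dirichlet(np.array([u, 1 - u]) * 400)
                counts[s] = rng.poisson(500 * frac).astype(float)
            counts = pd.DataFrame(counts, index=["a", "b"])
            m = usage_matrix_from_counts(counts, {"a": "g", "b": "g"})
            res = differential_usage(
                m, design, control="CTRL", covariates=["batch"]
            )
            pvals.append(res.set_index("isoform_id").loc["a", "p_value"])
        assert np.mean(np.array(pvals) < 0.05) < 0.15


def result_row(iso="isoA", padj=0.01, ctrl=0.05, delta=0.20, dataset="d1"):
    return {
        "isoform_id": iso,
        "gene_id": "g",
        "p_value": padj / 2,
        "padj": padj,
        "mean_usage_ctrl": ctrl,
        "mean_usage_kd": ctrl + delta,
        "delta_usage": delta,
        "dataset": dataset,
    }


def frame(*rows):
    return pd.DataFrame(list(rows))[RESULT_COLUMNS]


class TestCrypticClassification:
    def test_passing_all_criteria_is_cryptic(self, cfg):
        calls = classify_cryptic([frame(result_row())], cfg)
        assert bool(calls.set_index("isoform_id").loc["isoA", "is_cryptic"])

    def test_high_basal_usage_not_cryptic(self, cfg):
        calls = classify_cryptic([frame(result_row(ctrl=0.15))], cfg)
        assert not bool(calls.set_index("isoform_id").loc["isoA", "is_cryptic"])

    def test_delta_exactly_ten_percent_not_cryptic(self, cfg):
        """Strict '>' on the usage change."""
        calls = classify_cryptic([frame(result_row(delta=0.10))], cfg)
        assert not bool(calls.set_index("isoform_id").loc["isoA", "is_cryptic"])

    def test_padj_at_alpha_not_cryptic(self, cfg):
        calls = classify_cryptic([frame(result_row(padj=0.05))], cfg)
        assert not bool(calls.set_index("isoform_id").loc["isoA", "is_cryptic"])

    def test_cryptic_in_one_of_two_datasets_suffices(self, cfg):
        calls = classify_cryptic(
            [
                frame(result_row(dataset="d1")),
                frame(result_row(dataset="d2", padj=0.8, delta=0.0)),
            ],
            cfg,
        )
        assert bool(calls.set_index("isoform_id").loc["isoA", "is_cryptic"])


class TestCrossDatasetCategories:
    def test_cryptic_consistent(self, cfg):
        """ctrl {4%,6%}, deltas {15%,20%} -> cryptic_consistent."""
        calls = classify_cryptic(
            [
                frame(result_row(ctrl=0.04, delta=0.15, dataset="d1")),
                frame(result_row(ctrl=0.06, delta=0.20, dataset="d2")),
            ],
            cfg,
        )
        assert (
            calls.set_index("isoform_id").loc["isoA", "cross_dataset_category"]
            == "cryptic_consistent"
        )

    def test_low_basal_nonresponsive(self, cfg):
        calls = classify_cryptic(
            [
                frame(result_row(ctrl=0.03, delta=0.04, padj=0.5, dataset="d1")),
                frame(result_row(ctrl=0.05, delta=0.06, padj=0.6, dataset="d2")),
            ],
            cfg,
        )
        assert (
            calls.set_index("isoform_id").loc["isoA", "cross_dataset_category"]
            == "low_basal_nonresponsive"
        )

    def test_responsive_high_basal(self, cfg):
        """Significant increase but >10% median control usage."""
        calls = classify_cryptic(
            [
                frame(result_row(ctrl=0.20, delta=0.15, dataset="d1")),
                frame(result_row(ctrl=0.25, delta=0.12, dataset="d2")),
            ],
            cfg,
        )
        assert (
            calls.set_index("isoform_id").loc["isoA", "cross_dataset_category"]
            == "responsive_high_basal"
        )

    def test_background_category(self, cfg):
        calls = classify_cryptic(
            [
                frame(result_row(ctrl=0.4, delta=0.01, padj=0.5, dataset="d1")),
                frame(result_row(ctrl=0.45, delta=-0.01, padj=0.9, dataset="d2")),
            ],
            cfg,
        )
        assert (
            calls.set_index("isoform_id").loc["isoA", "cross_dataset_category"]
            == "background"
        )


class TestBackgroundSelection:
    def test_high_padj_everywhere_is_background(self, cfg):
        results = [
            frame(result_row(padj=0.5, dataset="d1")),
            frame(result_row(padj=0.9, dataset="d2")),
        ]
        assert select_background(results, ["d1", "d2"], cfg) == {"isoA"}

    def test_significant_in_one_dataset_excluded(self, cfg):
        results = [
            frame(result_row(padj=0.5, dataset="d1")),
            frame(result_row(padj=0.03, dataset="d2")),
        ]
        assert select_background(results, ["d1", "d2"], cfg) == set()

    def test_tested_in_only_one_dataset_excluded(self, cfg):
        results = [
            frame(result_row(padj=0.5, dataset="d1")),
            frame(result_row(iso="other", padj=0.5, dataset="d2")),
        ]
        assert select_background(results, ["d1", "d2"], cfg) == set()


class TestExternalResultsAdapter:
    def test_ingests_external_table(self):
        table = pd.DataFrame(
            {
                "isoform_id": ["a", "b"],
                "gene_id": ["g", "g"],
                "p_value": [0.001, 0.8],
                "mean_usage_ctrl": [0.05, 0.5],
                "mean_usage_kd": [0.30, 0.5],
            }
        )
        out = results_from_table(table, dataset="ext")
        assert list(out.columns) == RESULT_COLUMNS
        assert out["delta_usage"].tolist() == pytest.approx([0.25, 0.0])
        assert (out["padj"] >= out["p_value"]).all()
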