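"""Normalization, abundance filter, NB Wald test and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirflow.diffexpr import (
    CountMatrix,
    DifferentialExpressionModel,
    abundance_filter,
    benjamini_hochberg,
    nb_test,
    run_contrasts,
    size_factors,
)
from mirflow.simulate import SimulationSpec, simulate_counts

from conftest import make_count_matrix


class TestSizeFactors:
    def test_hand_computed_two_samples(self):
        cm = make_count_matrix({"s1": [10, 20, 30], "s2": [20, 40, 60]}, {"s1": "A", "s2": "A"})
        norm = size_factors(cm)
        assert norm.size_factors["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert norm.size_factors["s2"] == pytest.approx(np.sqrt(2), abs=1e-9)
        pd.testing.assert_series_equal(
            norm.normalized["s1"], norm.normalized["s2"], check_names=False
        )

    def test_identical_samples_unit_factors(self):
        cm = make_count_matrix({"s1": [5, 9, 14], "s2": [5, 9, 14]}, {"s1": "A", "s2": "A"})
        assert np.allclose(size_factors(cm).size_factors, 1.0)

    def test_scale_equivariance(self):
        # multiplying one sample by 10 multiplies its size factor by 10
        # relative to the others; normalized counts change only by the common
        # geometric-mean rescale constant
        base = {"s1": [10, 20, 30], "s2": [13, 27, 31], "s3": [8, 22, 35]}
        meta = {"s1": "A", "s2": "A", "s3": "A"}
        norm1 = size_factors(make_count_matrix(base, meta))
        scaled = dict(base, s2=[10 * c for c in base["s2"]])
        norm2 = size_factors(make_count_matrix(scaled, meta))
        ratio = norm2.size_factors / norm1.size_factors
        np.testing.assert_allclose(ratio["s2"] / ratio["s1"], 10.0, rtol=1e-9)
        np.testing.assert_allclose(ratio["s3"] / ratio["s1"], 1.0, rtol=1e-9)
        # cross-sample structure of normalized counts is preserved exactly
        np.testing.assert_allclose(
            norm2.normalized["s2"] / norm2.normalized["s1"],
            norm1.normalized["s2"] / norm1.normalized["s1"],
            rtol=1e-9,
        )

    def test_geomean_of_factors_is_one(self):
        cm = make_count_matrix(
            {"s1": [10, 200, 3], "s2": [20, 10, 60], "s3": [5, 50, 500]},
            {"s1": "A", "s2": "A", "s3": "A"},
        )
        sf = size_factors(cm).size_factors
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_error_when_no_all_positive_mirna(self):
        cm = make_count_matrix({"s1": [0, 5], "s2": [5, 0]}, {"s1": "A", "s2": "A"})
        with pytest.raises(ValueError, match="positive"):
            size_factors(cm)


class TestAbundanceFilter:
    def _norm(self, rows, types):
        samples = {f"s{i}": col for i, col in enumerate(zip(*rows))}
        cm = make_count_matrix(
            {k: list(v) for k, v in samples.items()},
            {f"s{i}": t for i, t in enumerate(types)},
        )
        return size_factors(cm)

    def test_two_samples_over_threshold_retained(self):
        norm = self._norm([[60, 55, 10], [1, 1, 1]], ["A", "A", "A"])
        norm.size_factors[:] = 1.0
        norm.normalized = norm.raw.counts / norm.size_factors
        assert abundance_filter(norm) == ["mir-1"]

    def test_boundary_is_strict(self):
        norm = self._norm([[50, 50, 50], [1, 1, 1]], ["A", "A", "A"])
        norm.size_factors[:] = 1.0
        norm.normalized = norm.raw.counts / norm.size_factors
        assert abundance_filter(norm) == []

    def test_single_huge_sample_not_enough(self):
        norm = self._norm([[1000, 1, 1], [2, 2, 2]], ["A", "A", "A"])
        norm.size_factors[:] = 1.0
        norm.normalized = norm.raw.counts / norm.size_factors
        assert abundance_filter(norm) == []

    def test_small_cell_type_warned_and_cannot_qualify(self):
        norm = self._norm([[100, 1, 1]], ["A", "B", "B"])
        norm.size_factors[:] = 1.0
        norm.normalized = norm.raw.counts / norm.size_factors
        with pytest.warns(UserWarning, match="fewer than"):
            assert abundance_filter(norm) == []


class TestNBTest:
    def test_identical_groups_null_result(self):
        cm = make_count_matrix(
            {"a1": [100, 50], "a2": [120, 60], "b1": [100, 50], "b2": [120, 60]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        de = nb_test(size_factors(cm), "A", "B")
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["pvalue"], 1.0)

    def test_zero_in_both_groups(self):
        cm = make_count_matrix(
            {"a1": [0, 50], "a2": [0, 60], "b1": [0, 50], "b2": [0, 60]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        de = nb_test(size_factors(cm), "A", "B").set_index("mirna_id")
        assert de.at["mir-1", "log2fc"] == 0.0 and de.at["mir-1", "pvalue"] == 1.0

    def test_antisymmetry_of_group_order(self):
        spec = SimulationSpec(n_mirnas=40, cell_types=("A", "B"), replicates=(3, 3), seed=21)
        cm, _ = simulate_counts(spec)
        norm = size_factors(cm)
        ab = nb_test(norm, "A", "B")
        ba = nb_test(norm, "B", "A")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"], atol=1e-12)

    def test_padj_at_least_pvalue_and_monotone(self):
        spec = SimulationSpec(n_mirnas=300, cell_types=("A", "B"), replicates=(3, 3), seed=22)
        cm, _ = simulate_counts(spec)
        de = nb_test(size_factors(cm), "A", "B").sort_values("pvalue")
        assert (de["padj"] >= de["pvalue"] - 1e-12).all()
        assert (np.diff(de["padj"]) >= -1e-12).all()

    def test_null_calibration(self):
        spec = SimulationSpec(
            n_mirnas=2000, cell_types=("A", "B"), replicates=(3, 3),
            baseline_mean=500, dispersion=0.1, seed=42,
        )
        cm, _ = simulate_counts(spec)
        de = nb_test(size_factors(cm), "A", "B")
        frac = (de["pvalue"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_fold_change_recovered(self):
        # 200 replicate simulations, each planting one 4-fold change at
        # baseline 500: the median estimated log2fc is close to 2
        estimates = []
        for rep in range(200):
            spec = SimulationSpec(
                n_mirnas=50, cell_types=("A", "B"), replicates=(3, 3),
                baseline_mean=500, dispersion=0.05,
                planted_groups={"G4": (1, (2.0, 0.0))}, seed=10_000 + rep,
            )
            cm, truth = simulate_counts(spec)
            de = nb_test(size_factors(cm), "A", "B").set_index("mirna_id")
            (mid,) = truth.group[truth.group == "G4"].index
            estimates.append(de.at[mid, "log2fc"])
        assert np.median(estimates) == pytest.approx(2.0, abs=0.2)


class TestRunContrasts:
    def test_contrast_orientation_and_antisymmetry(self):
        spec = SimulationSpec(n_mirnas=30, seed=24)
        cm, _ = simulate_counts(spec)
        norm = size_factors(cm)
        de1, de2 = run_contrasts(norm)
        assert de1["contrast"].iloc[0] == "NSC_vs_hESC"
        assert de2["contrast"].iloc[0] == "DiffNSC_vs_NSC"
        swapped = nb_test(norm, "NSC", "hESC")
        np.testing.assert_allclose(de1["log2fc"], -swapped["log2fc"], atol=1e-12)

    def test_missing_cell_type_errors(self):
        spec = SimulationSpec(n_mirnas=10, cell_types=("A", "B"), replicates=(3, 3), seed=25)
        cm, _ = simulate_counts(spec)
        with pytest.raises(ValueError, match="missing"):
            run_contrasts(size_factors(cm), design=("A", "B", "C"))

    def test_planted_group1_called_significant_in_both(self):
        spec = SimulationSpec(
            n_mirnas=100, baseline_mean=500, dispersion=0.05,
            planted_groups={"G1": (5, (2.0, -2.0))}, seed=26,
        )
        cm, truth = simulate_counts(spec)
        res = DifferentialExpressionModel(cm).fit()
        d1 = res.de1.set_index("mirna_id")
        d2 = res.de2.set_index("mirna_id")
        for mid in truth.group[truth.group == "G1"].index:
            assert d1.at[mid, "log2fc"] > 0.6 and d1.at[mid, "padj"] < 0.05
            assert d2.at[mid, "log2fc"] < -0.6 and d2.at[mid, "padj"] < 0.05


def bh_oracle(pvals):
    """Brute-force BH step-up: p_(i) * m / i with running minimum from the top."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    @given(st.integers(0, 2**32 - 1), st.integers(1, 1000))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_empty_and_single(self):
        assert benjamini_hochberg(np.array([])).size == 0
        assert benjamini_hochberg(np.array([0.03]))[0] == pytest.approx(0.03)


class TestModelResults:
    def test_fit_summary_reports_retained_universe(self):
        spec = SimulationSpec(n_mirnas=60, seed=27)
        cm, _ = simulate_counts(spec)
        res = DifferentialExpressionModel(cm).fit()
        assert set(res.de1["mirna_id"]) == set(res.retained)
        text = res.summary()
        assert f"{len(res.retained)} retained" in text
        assert "NSC_vs_hESC" in text

    def test_tsv_roundtrip(self, tmp_path):
        spec = SimulationSpec(n_mirnas=20, seed=28)
        cm, _ = simulate_counts(spec)
        cm.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        model = DifferentialExpressionModel.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert model.counts.cell_types() == ["hESC", "NSC", "DiffNSC"]
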