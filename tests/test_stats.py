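"""Entropy, baseline benchmarks, Spearman matrix, permutation null, ablation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from sigpolytope import (
    PipelineConfig,
    SimulationSpec,
    axis_ablation,
    baseline_metrics,
    baseline_metrics_table,
    entropy_ordering,
    permutation_null,
    permutation_p_value,
    shannon_entropy,
    simulate_null_atlas,
    spearman_matrix,
)
from sigpolytope.encoding import build_latent_tensor
from sigpolytope.errors import DomainError, InsufficientDataError
from sigpolytope.pipeline import distances_and_regimes
from sigpolytope.records import CircuitryTable

from conftest import make_side, make_survival


class TestEntropy:
    def test_uniform_maximum(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4), rel=1e-12)

    def test_degenerate_zero(self):
        assert shannon_entropy([1.0, 0.0, 0.0, 0.0]) == 0.0

    def test_four_class_regime_mix(self):
        # direct-formula oracle on an observed four-regime distribution
        p = (0.519, 0.216, 0.209, 0.056)
        expected = -sum(x * math.log(x) for x in p)
        assert shannon_entropy(p) == pytest.approx(expected, rel=1e-12)
        assert shannon_entropy(p) == pytest.approx(1.1599894742174475, abs=1e-12)

    def test_base2_option(self):
        assert shannon_entropy([0.5, 0.5], base="base2") == pytest.approx(1.0)

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            shannon_entropy([0.5, 0.6])
        with pytest.raises(DomainError):
            shannon_entropy([-0.1, 1.1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_bounds(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = shannon_entropy(p / p.sum())
        assert -1e-9 <= h <= math.log(len(p)) + 1e-9

    def test_ordering_by_dispersion(self):
        table = {
            "broad": [0.25, 0.25, 0.25, 0.25],
            "narrow": [0.9, 0.05, 0.03, 0.02],
            "middling": [0.5, 0.3, 0.15, 0.05],
        }
        ordered = entropy_ordering(table)
        assert [name for name, _ in ordered] == ["broad", "middling", "narrow"]
        # invariant to input ordering; ties break lexicographically
        ordered2 = entropy_ordering(dict(reversed(list(table.items()))))
        assert ordered == ordered2
        tied = entropy_ordering({"b": [0.5, 0.5], "a": [0.5, 0.5]})
        assert [name for name, _ in tied] == ["a", "b"]


def surv(direction, significant=True):
    return {
        e: make_survival(direction if significant else "ns", 0.01, 5.0, significant)
        for e in ("os", "dss", "dfi", "pfi")
    }


class TestBaselineMetrics:
    def test_identical_sides_all_zero(self):
        side = make_side(survival=surv("risk"))
        v = np.arange(18, dtype=float)
        m = baseline_metrics(v, v, side, side)
        assert m.euclid18 == 0.0
        assert m.cosine_dist == 0.0
        assert m.surv_mismatch == 0
        assert m.immune_mismatch == 0
        assert m.tn_mismatch == 0
        assert m.micro_absdiff == 0.0

    def test_single_endpoint_direction_flip(self):
        s = surv("risk")
        i = dict(s)
        i["os"] = make_survival("protective", 0.01, 5.0, True)
        sig = make_side(survival=s)
        int_ = make_side(survival=i)
        m = baseline_metrics(np.ones(18), np.ones(18), sig, int_)
        assert m.surv_mismatch == 1
        assert m.tn_mismatch == 0

    def test_mismatch_counts_need_both_sides_defined(self):
        sig = make_side(survival=surv("risk"))
        int_ = make_side(survival=surv("risk", significant=False))
        m = baseline_metrics(np.ones(18), np.ones(18), sig, int_)
        assert m.surv_mismatch == 0

    def test_zero_vector_cosine_flagged(self):
        side = make_side()
        m = baseline_metrics(np.zeros(18), np.ones(18), side, side)
        assert m.cosine_dist == 1.0
        assert m.cosine_degenerate

    def test_euclid_equals_full_pc_distance(self, small_atlas, config):
        """The standardized 18-D distance must match the full PC-score
        distance (orthogonal invariance cross-check with the embedding)."""
        from sigpolytope.embedding import fit_pca, standardize

        table, _ = small_atlas
        metrics = baseline_metrics_table(table, config)
        tensor, _ = build_latent_tensor(table, config)
        Z, m, s = standardize(tensor)
        model = fit_pca(Z, m, s)
        scores = model.project(tensor, n_components=18)
        for i, rec in enumerate(table.records[:10]):
            d_pc = np.linalg.norm(scores[2 * i] - scores[2 * i + 1])
            assert metrics.loc[rec.id, "euclid18"] == pytest.approx(d_pc, abs=1e-8)


class TestSpearmanMatrix:
    def test_matches_brute_force_rank_correlation(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        df["b"] = df["a"] ** 3 + rng.normal(size=40) * 0.1
        got = spearman_matrix(df)
        # brute force: Pearson on average ranks
        for x in df.columns:
            for y in df.columns:
                rx, ry = rankdata(df[x]), rankdata(df[y])
                brute = np.corrcoef(rx, ry)[0, 1]
                assert got.loc[x, y] == pytest.approx(brute, abs=1e-10)
        assert np.allclose(got.values, got.values.T)

    def test_monotone_transform_gives_unit_correlation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "expx": np.exp(x)})
        assert spearman_matrix(df).loc["x", "expx"] == pytest.approx(1.0)

    def test_constant_column_flagged_not_zeroed(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
        got = spearman_matrix(df)
        assert np.isnan(got.loc["x", "c"])
        assert np.isnan(got.loc["c", "c"])

    def test_needs_three_rows(self):
        with pytest.raises(InsufficientDataError):
            spearman_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestPermutationNull:
    @pytest.mark.parametrize("k,B,expected", [(1, 500, 2 / 501), (500, 500, 1.0), (0, 99, 1 / 100)])
    def test_estimator_formula(self, k, B, expected):
        assert permutation_p_value(k, B) == pytest.approx(expected, rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(DomainError):
            permutation_p_value(-1, 10)
        with pytest.raises(DomainError):
            permutation_p_value(11, 10)

    def test_determinism_and_p_bounds(self):
        table = simulate_null_atlas(SimulationSpec(n_circuitries=24, n_strata=3, seed=7))
        cfg = PipelineConfig(n_permutations=25, seed=13)
        r1 = permutation_null(table, cfg)
        r2 = permutation_null(table, cfg)
        np.testing.assert_array_equal(r1.null_draws, r2.null_draws)
        assert r1.null_draws.shape == (25, 3)
        for p in r1.p_values.values():
            assert 1 / 26 <= p <= 1.0

    def test_replicates_stable_under_larger_B(self):
        """Counter-derived substreams: growing B keeps earlier draws."""
        table = simulate_null_atlas(SimulationSpec(n_circuitries=20, n_strata=2, seed=3))
        small = permutation_null(table, PipelineConfig(n_permutations=10, seed=5))
        large = permutation_null(table, PipelineConfig(n_permutations=20, seed=5))
        np.testing.assert_array_equal(small.null_draws, large.null_draws[:10])

    def test_singleton_strata_cannot_permute(self):
        table = simulate_null_atlas(SimulationSpec(n_circuitries=4, n_strata=4, seed=1))
        with pytest.raises(InsufficientDataError):
            permutation_null(table, PipelineConfig(n_permutations=5, seed=0))

    def test_stratified_shuffle_preserves_stratum_multisets(self):
        """Each replicate must reshuffle int vectors within strata only."""
        table = simulate_null_atlas(SimulationSpec(n_circuitries=18, n_strata=3, seed=9))
        tensor, _ = build_latent_tensor(table)
        int_rows = tensor[1::2]
        strata = np.array(table.strata())
        # reproduce replicate 0's shuffle exactly as the implementation seeds it
        cfg = PipelineConfig(n_permutations=1, seed=77)
        result = permutation_null(table, cfg)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=77, spawn_key=(0,)))
        perm_int = int_rows.copy()
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            if len(idx) > 1:
                perm_int[idx] = int_rows[idx[rng.permutation(len(idx))]]
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            a = np.sort(perm_int[idx], axis=0)
            b = np.sort(int_rows[idx], axis=0)
            np.testing.assert_array_equal(a, b)
        # and the recomputed statistic from that shuffle matches the draw
        perm_tensor = tensor.copy()
        perm_tensor[1::2] = perm_int
        d, regimes = distances_and_regimes(perm_tensor, cfg)
        assert result.null_draws[0, 0] == pytest.approx(float(d.mean()), abs=1e-12)


class TestAxisAblation:
    def test_self_comparison_is_exact(self, small_atlas, config):
        table, _ = small_atlas
        res = axis_ablation(table, drop="none", scale=True, config=config)
        assert res.spearman_vs_reference == pytest.approx(1.0)
        assert res.regime_agreement == 1.0

    def test_dropping_constant_axis_changes_nothing(self, rng):
        """If every immune class is neutral the immune axis carries zero
        variance; removing it must leave the geometry untouched."""
        from sigpolytope.records import CircuitryRecord

        records = []
        for i in range(20):
            sig = make_side(rho=float(rng.uniform(-0.9, 0.9)), micro_score=float(rng.normal()),
                            immune_class="intermediate", survival=surv("risk", significant=bool(i % 2)))
            int_ = make_side(rho=float(rng.uniform(-0.9, 0.9)), micro_score=float(rng.normal()),
                             immune_class="excluded", survival=surv("protective", significant=bool(i % 3)))
            records.append(CircuitryRecord(id=f"c{i}", cancer_type=f"CT{i % 2}", sig=sig, int_=int_))
        table = CircuitryTable(records=records)
        res = axis_ablation(table, drop="immune")
        assert res.spearman_vs_reference == pytest.approx(1.0, abs=1e-12)
        assert res.regime_agreement == 1.0

    def test_survival_ablation_degrades_more_than_immune(self, small_atlas):
        """Survival axes carry 12 of 18 coordinates of inter-side signal in
        the generator; dropping them must hurt the ranking more than
        dropping the single immune axis."""
        table, _ = small_atlas
        surv = axis_ablation(table, drop="survival")
        imm = axis_ablation(table, drop="immune")
        assert surv.spearman_vs_reference < imm.spearman_vs_reference
        assert surv.regime_agreement < imm.regime_agreement
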