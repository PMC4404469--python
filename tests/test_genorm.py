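"""geNorm: pairwise variation, M values, stepwise exclusion, V_n/n+1."""

import math

import numpy as np
import pandas as pd
import pytest

from refstab.genorm import (
    GeNorm,
    classify_m,
    genorm_analysis,
    m_values,
    normalization_factor,
    pairwise_variation,
    rank_by_stepwise_exclusion,
    recommend_gene_count,
    v_n_series,
)

from _oracles import m_values_oracle, pairwise_v_oracle, v_series_oracle


def _frame(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(rows.shape[1])])


class TestPairwiseVariation:
    def test_constant_ratio_has_zero_variation(self):
        base = np.array([1.0, 0.5, 2.0, 0.25])
        q = _frame([base, 3.0 * base])
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(0.0, abs=1e-14)

    def test_two_sample_formula(self):
        # log2 ratios {0, 2}: SD of two points is |diff|/sqrt(2)
        q = _frame([[1.0, 4.0], [1.0, 1.0]])
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(math.sqrt(2.0))

    def test_matches_bruteforce_oracle(self, random_quantities):
        q = random_quantities(2, 10)
        expected = pairwise_v_oracle(q.to_numpy().tolist(), 0, 1)
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, random_quantities):
        q = random_quantities(3, 8)
        assert pairwise_variation(q, "g0", "g2") == pytest.approx(
            pairwise_variation(q, "g2", "g0"), abs=1e-15
        )

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            pairwise_variation(_frame([[1.0], [2.0]]), "g0", "g1")


class TestMValues:
    def test_all_constant_ratios_give_zero(self):
        base = np.array([1.0, 0.5, 0.125, 2.0])
        q = _frame([base, 2 * base, 0.5 * base])
        assert np.allclose(m_values(q), 0.0, atol=1e-14)

    def test_three_gene_hand_computation(self, rng):
        # genes 0 and 1 in constant ratio (V01=0); gene 2 deviates by noise
        # delta, so V02 = V12 = sd(delta) and M0 = M1 = v/2, M2 = v.
        base = 2.0 ** rng.normal(0, 1, size=12)
        delta = rng.normal(0, 0.7, size=12)
        q = _frame([base, 3.0 * base, base * 2.0 ** delta])
        v = np.std(delta, ddof=1)
        m = m_values(q)
        assert m["g0"] == pytest.approx(v / 2, abs=1e-12)
        assert m["g1"] == pytest.approx(v / 2, abs=1e-12)
        assert m["g2"] == pytest.approx(v, abs=1e-12)

    def test_matches_double_loop_oracle(self, random_quantities):
        q = random_quantities(5, 12)
        expected = m_values_oracle(q.to_numpy().tolist())
        np.testing.assert_allclose(m_values(q).to_numpy(), expected, atol=1e-12)

    def test_requires_three_genes(self, random_quantities):
        with pytest.raises(ValueError):
            m_values(random_quantities(2, 6))


class TestStepwiseExclusion:
    def test_noisy_gene_excluded_first(self, rng):
        # Three constant-ratio genes plus one noisy one: the noisy gene's M
        # is three times the others', so exclusion is deterministic.
        for _ in range(25):
            base = 2.0 ** rng.normal(0, 1, size=10)
            noisy = base * 2.0 ** rng.normal(0, 1.0, size=10)
            q = _frame([base, 2 * base, 0.5 * base, noisy],
                       genes=["a", "b", "c", "noisy"])
            assert rank_by_stepwise_exclusion(q).exclusion_order[0] == "noisy"

    def test_exact_ties_break_to_latest_input_gene(self, rng):
        base = 2.0 ** rng.normal(0, 1, size=8)
        noisy = base * 2.0 ** rng.normal(0, 0.8, size=8)
        # two identical noisy copies share M exactly; the later one goes first
        q = _frame([base, 2 * base, noisy, noisy.copy()],
                   genes=["a", "b", "dup1", "dup2"])
        result = rank_by_stepwise_exclusion(q)
        assert result.exclusion_order[0] == "dup2"

    def test_duplicated_pair_has_zero_mutual_variation_and_equal_m(self, rng):
        base = 2.0 ** rng.normal(0, 1, size=9)
        noisy = base * 2.0 ** rng.normal(0, 0.5, size=9)
        other = base * 2.0 ** rng.normal(0, 0.9, size=9)
        q = _frame([noisy, noisy.copy(), other, base])
        assert pairwise_variation(q, "g0", "g1") == pytest.approx(0.0, abs=1e-14)
        m = m_values(q)
        assert m["g0"] == pytest.approx(m["g1"], abs=1e-13)

    def test_three_gene_size_contract(self, random_quantities):
        result = rank_by_stepwise_exclusion(random_quantities(3, 6))
        assert len(result.exclusion_order) == 1
        assert len(result.final_pair) == 2
        assert set(result.exclusion_order) | set(result.final_pair) == {
            "g0", "g1", "g2"
        }

    def test_every_gene_appears_once(self, random_quantities):
        q = random_quantities(6, 10)
        result = rank_by_stepwise_exclusion(q)
        claimed = list(result.exclusion_order) + list(result.final_pair)
        assert sorted(claimed) == sorted(q.index)
        assert sorted(result.ranking.to_numpy()) == [1.5, 1.5, 3, 4, 5, 6]


class TestNormalizationFactor:
    def test_single_gene_identity(self, random_quantities):
        q = random_quantities(3, 5)
        pd.testing.assert_series_equal(
            normalization_factor(q, ["g1"]), q.loc["g1"], check_names=False
        )

    def test_two_gene_geometric_mean(self):
        q = _frame([[4.0], [1.0]])
        assert normalization_factor(q, ["g0", "g1"]).iloc[0] == pytest.approx(2.0)

    def test_matches_log_domain_oracle(self, random_quantities):
        q = random_quantities(5, 7)
        subset = ["g0", "g2", "g4"]
        expected = np.exp(np.mean(np.log(q.loc[subset].to_numpy()), axis=0))
        np.testing.assert_allclose(
            normalization_factor(q, subset).to_numpy(), expected, atol=1e-12
        )

    def test_empty_subset_rejected(self, random_quantities):
        with pytest.raises(ValueError):
            normalization_factor(random_quantities(3, 4), [])


class TestVSeries:
    def test_proportional_extra_gene_gives_zero_v(self, rng):
        q1 = 2.0 ** rng.normal(0, 1, size=8)
        q2 = 2.0 ** rng.normal(0, 1, size=8)
        # gene 3 proportional to NF of the first two
        q3 = 0.5 * np.sqrt(q1 * q2)
        series = v_n_series(_frame([q1, q2, q3]), ["g0", "g1", "g2"])
        assert series == [(2, pytest.approx(0.0, abs=1e-12))]

    def test_matches_bruteforce_oracle(self, random_quantities):
        q = random_quantities(5, 9)
        order = list(q.index)
        expected = v_series_oracle(q.to_numpy().tolist(), [0, 1, 2, 3, 4])
        got = [v for _, v in v_n_series(q, order)]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_three_gene_series_has_one_entry(self, random_quantities):
        series = v_n_series(random_quantities(3, 6), ["g0", "g1", "g2"])
        assert [n for n, _ in series] == [2]


class TestRecommendation:
    def test_printed_series_recommends_two_with_optional_third(self):
        rec = recommend_gene_count([(2, 0.13), (3, 0.177)], cutoff=0.15)
        assert rec.recommended_n == 2
        assert rec.optional_extra_n == 3
        assert rec.cutoff_met

    def test_nothing_under_cutoff_falls_back_to_full_panel(self):
        with pytest.warns(UserWarning):
            rec = recommend_gene_count([(2, 0.3), (3, 0.2)], cutoff=0.15)
        assert rec.recommended_n == 4
        assert not rec.cutoff_met

    def test_single_entry_series(self):
        rec = recommend_gene_count([(2, 0.05)])
        assert rec.recommended_n == 2
        assert rec.optional_extra_n == 3


class TestClassifyM:
    @pytest.mark.parametrize(
        "m,panel,expected",
        [
            (0.35, "homogeneous", "stable"),
            (0.61, "homogeneous", "unstable"),
            (0.74, "heterogeneous", "acceptable"),
            (0.5, "homogeneous", "stable"),
            (1.0, "heterogeneous", "acceptable"),
            (1.28, "heterogeneous", "unstable"),
        ],
    )
    def test_thresholds(self, m, panel, expected):
        assert classify_m(m, panel) == expected

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            classify_m(-0.1)


class TestInvariances:
    def test_scale_invariance(self, random_quantities):
        q = random_quantities(5, 10)
        scaled = q.copy()
        scaled.loc["g2"] *= 37.5
        r1 = genorm_analysis(q)
        r2 = genorm_analysis(scaled)
        np.testing.assert_allclose(
            r1.m_values.to_numpy(), r2.m_values.to_numpy(), atol=1e-12
        )
        assert r1.exclusion_order == r2.exclusion_order
        np.testing.assert_allclose(
            [v for _, v in r1.v_series], [v for _, v in r2.v_series], atol=1e-12
        )

    def test_sample_permutation_invariance(self, random_quantities, rng):
        q = random_quantities(5, 10)
        perm = q.iloc[:, rng.permutation(10)]
        r1, r2 = genorm_analysis(q), genorm_analysis(perm)
        np.testing.assert_allclose(
            r1.m_values.to_numpy(), r2.m_values.to_numpy(), atol=1e-12
        )
        assert r1.stability_order == r2.stability_order
        np.testing.assert_allclose(
            [v for _, v in r1.v_series], [v for _, v in r2.v_series], atol=1e-12
        )


class TestGeNormEstimator:
    def test_fit_exposes_analysis_attributes(self, random_quantities):
        q = random_quantities(5, 12)
        est = GeNorm().fit(q.T)  # sklearn orientation: samples x genes
        reference = genorm_analysis(q)
        np.testing.assert_allclose(
            est.m_values_, reference.m_values.loc[q.index].to_numpy()
        )
        assert est.stability_order_ == reference.stability_order
        assert est.recommended_n_ == reference.recommended_n
        assert list(est.feature_names_in_) == list(q.index)

    def test_plain_array_input(self, random_quantities):
        q = random_quantities(4, 8)
        est = GeNorm().fit(q.T.to_numpy())
        assert est.genes_ == ["gene0", "gene1", "gene2", "gene3"]

    def test_sklearn_params(self):
        from sklearn.base import clone

        est = GeNorm(v_cutoff=0.2)
        assert clone(est).get_params() == {"v_cutoff": 0.2}
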