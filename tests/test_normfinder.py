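"""NormFinder: variance decomposition, group effects, stability ranking."""

import numpy as np
import pandas as pd
import pytest

from refstab.normfinder import (
    NormFinder,
    grouped_stability,
    intragroup_variance,
    log_transform,
    rank_genes,
    two_way_residuals,
    ungrouped_stability,
)

from _oracles import two_way_residuals_oracle


def _frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestLogTransform:
    def test_known_values_and_round_trip(self, rng):
        q = _frame([[1.0, 0.5], [2.0, 8.0]])
        y = log_transform(q)
        assert y.at["g0", "s0"] == 0.0
        assert y.at["g0", "s1"] == -1.0
        back = 2.0 ** y
        np.testing.assert_allclose(back.to_numpy(), q.to_numpy(), atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_transform(_frame([[1.0, 0.0], [2.0, 3.0]]))


class TestResiduals:
    @pytest.mark.parametrize("shape", [(3, 3), (4, 2), (6, 4), (5, 3)])
    def test_matches_fourloop_oracle(self, shape, rng):
        y = rng.normal(0, 1, size=shape)
        expected = np.asarray(two_way_residuals_oracle(y.tolist()))
        np.testing.assert_allclose(two_way_residuals(y), expected, atol=1e-12)


class TestUngrouped:
    def test_row_equal_to_mean_of_others_has_zero_stability(self, rng):
        others = rng.normal(0, 1, size=(4, 8))
        row = others.mean(axis=0)  # zero residual after two-way centering
        y = _frame(np.vstack([row, others]))
        result = ungrouped_stability(y)
        assert result.stability["g0"] == 0.0
        assert result.rank["g0"] == 1.0

    def test_recovers_low_noise_genes(self):
        # Two-way model with per-gene noise SDs {0.05, 0.1, 0.4, 0.4, 0.4}:
        # the two quiet genes should occupy the top two stability positions.
        # (Separating 0.05 from 0.1 within the pair is not reliable at S=50:
        # the shared column-mean noise of the three SD-0.4 genes dominates a
        # 0.0075 variance difference, so the ordering *within* the pair is
        # close to a coin flip and both are frequently floored to zero.)
        sds = np.array([0.05, 0.1, 0.4, 0.4, 0.4])
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            alpha = rng.normal(25, 2, size=(5, 1))
            beta = rng.normal(0, 1, size=(1, 50))
            eps = rng.normal(0, 1, size=(5, 50)) * sds[:, None]
            result = ungrouped_stability(_frame(alpha + beta + eps))
            hits += set(result.stability_order[:2]) == {"g0", "g1"}
        assert hits >= 0.95 * n_seeds

    def test_too_few_genes_or_samples(self, rng):
        with pytest.raises(ValueError):
            ungrouped_stability(_frame(rng.normal(size=(2, 6))))
        with pytest.raises(ValueError):
            ungrouped_stability(_frame(rng.normal(size=(4, 2))))


class TestGrouped:
    def _labels(self, sizes):
        out = []
        for i, n in enumerate(sizes):
            out += [f"grp{i}"] * n
        return out

    def test_group_effects_sum_to_zero_within_each_group(self, rng):
        for sizes in [(4, 4), (3, 5, 6), (2, 2, 2)]:
            y = _frame(rng.normal(0, 1, size=(5, sum(sizes))))
            result = grouped_stability(y, self._labels(sizes))
            sums = result.inter_effect.sum(axis=0)
            np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-10)

    def test_gene_with_group_effect_ranked_last(self):
        # one gene shifted +1/-1 between two groups of 20, others pure noise
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            y = rng.normal(0, 0.2, size=(5, 40))
            y += rng.normal(0, 1, size=(1, 40))  # sample effects
            y[0, :20] += 1.0
            y[0, 20:] -= 1.0
            result = grouped_stability(_frame(y), self._labels((20, 20)))
            hits += result.rank["g0"] == 5.0
        assert hits >= 0.95 * n_seeds

    def test_null_data_tau2_shrinks_with_sample_size(self):
        tau2s = []
        for n_g in (10, 200):
            vals = []
            for seed in range(30):
                rng = np.random.default_rng(5000 + seed)
                y = rng.normal(0, 0.3, size=(6, 2 * n_g))
                result = grouped_stability(_frame(y), self._labels((n_g, n_g)))
                vals.append(result.tau2)
            tau2s.append(np.mean(vals))
        assert tau2s[1] < tau2s[0]
        assert tau2s[1] < 5e-3

    def test_identical_groups_fall_back_to_ungrouped(self, rng):
        block = rng.normal(0, 1, size=(4, 6))
        y = _frame(np.hstack([block, block]))
        result = grouped_stability(y, self._labels((6, 6)))
        assert result.fallback_ungrouped
        assert result.tau2 == 0.0
        reference = ungrouped_stability(y)
        pd.testing.assert_series_equal(result.rank, reference.rank)

    def test_single_group_agrees_with_ungrouped(self, rng):
        y = _frame(rng.normal(0, 1, size=(5, 9)))
        grouped = grouped_stability(y, ["only"] * 9)
        reference = ungrouped_stability(y)
        np.testing.assert_allclose(
            grouped.stability.to_numpy(), reference.stability.to_numpy(), atol=1e-12
        )

    def test_small_group_rejected(self, rng):
        y = _frame(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError, match="fewer than 2"):
            grouped_stability(y, ["a", "a", "a", "a", "b"])


class TestVarianceEstimator:
    def test_unfloored_estimates_can_be_negative(self, rng):
        y = _frame(rng.normal(0, 0.2, size=(4, 6)))
        raw = intragroup_variance(y, floor=False)
        floored = intragroup_variance(y, floor=True)
        assert (floored.to_numpy() >= 0).all()
        assert (floored.to_numpy() >= raw.to_numpy()).all()

    def test_quick_bias_check(self):
        # mean of un-floored estimates over simulated two-way datasets should
        # track the true per-gene variances (full check in the acceptance suite)
        sds = np.array([0.1, 0.2, 0.3, 0.5, 0.8, 1.0])
        rng = np.random.default_rng(7)
        estimates = np.empty((1500, 6))
        for r in range(1500):
            eps = rng.normal(size=(6, 8)) * sds[:, None]
            estimates[r] = intragroup_variance(
                _frame(eps + rng.normal(0, 1, size=(1, 8))), floor=False
            ).iloc[:, 0]
        mean = estimates.mean(axis=0)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(estimates.shape[0])
        assert (np.abs(mean - sds ** 2) <= 4 * se).all()


class TestInvariancesAndRanks:
    def test_location_invariance(self, rng):
        y = _frame(rng.normal(0, 1, size=(5, 12)))
        shifted = y + rng.normal(0, 3, size=(1, 12))  # per-sample constants
        shifted = shifted.add(
            pd.Series(rng.normal(0, 3, size=5), index=y.index), axis=0
        )
        groups = ["a"] * 6 + ["b"] * 6
        for func in (
            lambda m: ungrouped_stability(m).stability,
            lambda m: grouped_stability(m, groups).stability,
        ):
            np.testing.assert_allclose(
                func(y).to_numpy(), func(shifted).to_numpy(), atol=1e-10
            )

    def test_rank_semantics(self):
        from refstab.normfinder import _ranks

        # ascending stability fixes the ranking; ties share the mean rank
        base = pd.Series([0.33, 0.49, 0.8], index=["a", "b", "c"])
        assert _ranks(base).tolist() == [1.0, 2.0, 3.0]
        assert _ranks(pd.Series([0.2, 0.2], index=["a", "b"])).tolist() == [1.5, 1.5]

    def test_stability_order_and_rank_genes(self, rng):
        y = _frame(rng.normal(0, 1, size=(4, 10)))
        result = ungrouped_stability(y)
        order = rank_genes(result)
        stabilities = result.stability[order].to_numpy()
        assert (np.diff(stabilities) >= 0).all()


class TestNormFinderEstimator:
    def test_fit_matches_functions(self, rng):
        y = rng.normal(0, 1, size=(5, 12))
        q = pd.DataFrame(
            2.0 ** y,
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(12)],
        )
        est = NormFinder().fit(q.T)
        reference = ungrouped_stability(_frame(y))
        np.testing.assert_allclose(
            est.stability_, reference.stability.to_numpy(), atol=1e-10
        )
        assert est.stability_order_ == reference.stability_order

    def test_grouped_fit(self, rng):
        q = pd.DataFrame(
            2.0 ** rng.normal(0, 1, size=(12, 4)),
            columns=["g0", "g1", "g2", "g3"],
        )
        groups = ["a"] * 6 + ["b"] * 6
        est = NormFinder().fit(q, groups=groups)
        assert est.grouped_
        assert est.tau2_ is not None
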