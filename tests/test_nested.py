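"""Sequential greedy harmonization (Nested ComBat) and the dropping variant."""

import numpy as np
import pandas as pd
import pytest

from combatkit import NestedComBat, harmonize, ks_feature_pvalues
from combatkit.simulate import (
    BatchEffectSpec,
    CovariateSpec,
    HiddenGroupSpec,
    SimulationSpec,
    simulate,
)


def _two_effect_data(seed=7, n=150, g=60, strong=2.0, weak=0.4):
    spec = SimulationSpec(
        n_samples=n, n_features=g,
        batch_effects=(
            BatchEffectSpec("strong", location_sd=strong),
            BatchEffectSpec("weak", location_sd=weak),
        ),
        covariates=(CovariateSpec("cov", effect_size=1.0),),
        seed=seed,
    )
    return simulate(spec)


class TestNested:
    def test_single_effect_is_bit_identical_to_plain_combat(self, shifted_dataset):
        d = shifted_dataset
        plain = harmonize(d.features, d.metadata["scanner"], d.metadata[["histology"]])
        nested = NestedComBat(
            d.features, d.metadata[["scanner"]], d.metadata[["histology"]]
        ).fit()
        assert nested.order == ["scanner"]
        assert nested.harmonized.equals(plain)

    def test_first_selection_matches_brute_force_argmin(self):
        d = _two_effect_data()
        batches = d.metadata[["strong", "weak"]]
        cov = d.metadata[["cov"]]
        result = NestedComBat(d.features, batches, cov).fit()

        # oracle: exhaustively harmonize by each effect and count significant
        # features over both original effects
        totals = {}
        for effect in ["strong", "weak"]:
            cand = harmonize(d.features, d.metadata[effect], cov)
            totals[effect] = sum(
                int((ks_feature_pvalues(cand, d.metadata[e]) < 0.05).sum())
                for e in ["strong", "weak"]
            )
        assert result.order[0] == min(totals, key=totals.get)

        first = result.iteration_log.query("iteration == 1")
        logged = dict(zip(first["candidate"], first["total_significant"]))
        assert logged == totals

    def test_selected_candidate_attains_the_iteration_minimum(self):
        d = _two_effect_data(seed=21)
        result = NestedComBat(d.features, d.metadata[["strong", "weak"]]).fit()
        for _, grp in result.iteration_log.groupby("iteration"):
            sel = grp.loc[grp["selected"], "total_significant"]
            assert len(sel) == 1
            assert sel.iloc[0] == grp["total_significant"].min()

    def test_order_is_a_permutation_and_features_are_preserved(self):
        d = _two_effect_data(seed=13)
        result = NestedComBat(d.features, d.metadata[["strong", "weak"]]).fit()
        assert sorted(result.order) == ["strong", "weak"]
        assert list(result.harmonized.columns) == list(d.features.columns)
        assert result.dropped_features == []

    def test_batch_column_listed_as_covariate_is_rejected(self):
        d = _two_effect_data(seed=1)
        with pytest.raises(ValueError, match="both batch and covariate"):
            NestedComBat(
                d.features, d.metadata[["strong", "weak"]], d.metadata[["strong"]]
            )

    def test_empty_batch_list_is_rejected(self):
        d = _two_effect_data(seed=1)
        with pytest.raises(ValueError, match="at least one batch effect"):
            NestedComBat(d.features, d.metadata[[]])

    def test_deterministic_rerun(self):
        a = NestedComBat(
            *(lambda d: (d.features, d.metadata[["strong", "weak"]]))(_two_effect_data())
        ).fit()
        b = NestedComBat(
            *(lambda d: (d.features, d.metadata[["strong", "weak"]]))(_two_effect_data())
        ).fit()
        assert a.harmonized.equals(b.harmonized)
        assert a.order == b.order
        assert a.iteration_log.equals(b.iteration_log)


def _hard_to_harmonize(seed):
    """Small-n, wide-scale-range data that leaves residual significance."""
    spec = SimulationSpec(
        n_samples=60, n_features=100,
        batch_effects=(
            BatchEffectSpec("A", location_sd=1.5, scale_range=(0.5, 2.0)),
            BatchEffectSpec("B", location_sd=0.6, scale_range=(0.8, 1.25),
                            affected_fraction=0.6),
        ),
        covariates=(CovariateSpec("cov", effect_size=1.0, affected_fraction=0.4),),
        seed=seed,
    )
    return simulate(spec)


class TestNestedD:
    def test_dropped_features_leave_the_matrix_and_keep_the_denominator(self):
        d = _hard_to_harmonize(seed=2)
        result = NestedComBat(
            d.features, d.metadata[["A", "B"]], d.metadata[["cov"]], drop=True
        ).fit()
        assert set(result.dropped_features).isdisjoint(result.harmonized.columns)
        for report in result.final_reports.values():
            assert report.denominator == d.features.shape[1]

    def test_dropping_never_increases_the_final_significant_count(self):
        for seed in (2, 3, 4):
            d = _hard_to_harmonize(seed)
            kwargs = dict(covariates=d.metadata[["cov"]])
            nested = NestedComBat(d.features, d.metadata[["A", "B"]], **kwargs).fit()
            dropped = NestedComBat(
                d.features, d.metadata[["A", "B"]], drop=True, **kwargs
            ).fit()
            n_tot = sum(r.n_significant for r in nested.final_reports.values())
            d_tot = sum(r.n_significant for r in dropped.final_reports.values())
            assert d_tot <= n_tot

    def test_all_features_dropped_raises_with_iteration(self):
        # every feature is bimodal within one batch level: the location/scale
        # adjustment cannot make the distributions similar, so NestedD drops
        # all of them at the first iteration
        rng = np.random.default_rng(8)
        n = 120
        idx = [f"S{i}" for i in range(n)]
        batch = pd.Series(["a"] * 60 + ["b"] * 60, index=idx, name="A")
        cols = {}
        for j in range(3):
            a_vals = rng.normal(0, 1, 60)
            b_vals = np.concatenate([rng.normal(-6, 0.3, 30), rng.normal(6, 0.3, 30)])
            cols[f"f{j}"] = np.concatenate([a_vals, b_vals])
        features = pd.DataFrame(cols, index=idx)
        with pytest.raises(RuntimeError, match="iteration 1"):
            NestedComBat(features, batch.to_frame(), drop=True).fit()
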