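import itertools

import numpy as np
import pytest

from sdm_entropy import (
    ScreenResult,
    correlation_filter,
    fdr_filter,
    screen_variables,
    select_variables,
)

from conftest import make_dataset, random_dataset
from oracles import oracle_bh_reject


def _screen(names, p_values, groups=None):
    groups = groups or [None] * len(names)
    return [
        ScreenResult(v, g, 1.0, p) for v, g, p in zip(names, groups, p_values)
    ]


def _correlated_dataset(rng, corr_spec, n=300):
    """Build predictors with requested pairwise structure from a base draw."""
    base = rng.normal(size=n)
    cols = {}
    for name, r in corr_spec.items():
        noise = rng.normal(size=n)
        cols[name] = r * base + np.sqrt(max(0.0, 1 - r * r)) * noise if r else noise
    presence = rng.binomial(1, 0.4, size=n)
    presence[:2] = [0, 1]
    return make_dataset(presence, cols)


class TestCorrelationFilter:
    def test_duplicated_pair_drops_less_significant(self):
        rng = np.random.default_rng(0)
        ds = _correlated_dataset(rng, {"a": 1.0, "b": 1.0})
        report = correlation_filter(ds, _screen(["a", "b"], [0.01, 0.04]))
        assert report.stage1_retained == ["a"]
        assert report.stage1_dropped[0][0] == "b"

    def test_pair_below_strict_threshold_both_retained(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=5000)
        second = 0.6 * base + np.sqrt(1 - 0.36) * rng.normal(size=5000)
        presence = rng.binomial(1, 0.3, size=5000)
        ds = make_dataset(presence, {"a": base, "b": second})
        r = np.corrcoef(base, second)[0, 1]
        assert abs(r) < 0.8
        report = correlation_filter(ds, _screen(["a", "b"], [0.01, 0.04]))
        assert report.stage1_retained == ["a", "b"]

    def test_clique_keeps_only_most_significant(self):
        """All drop orders of a fully correlated clique converge on min-p."""
        rng = np.random.default_rng(2)
        ds = _correlated_dataset(rng, {"a": 0.95, "b": 0.97, "c": 0.99})
        corr = np.corrcoef(ds.predictors.to_numpy(), rowvar=False)
        assert np.all(np.abs(corr[np.triu_indices(3, 1)]) > 0.8)
        p = {"a": 0.03, "b": 0.001, "c": 0.2}
        report = correlation_filter(ds, _screen(["a", "b", "c"], [p[v] for v in "abc"]))
        # brute force: every legal greedy drop order must end at the same set
        outcomes = set()
        for order in itertools.permutations([("a", "b"), ("a", "c"), ("b", "c")]):
            retained = {"a", "b", "c"}
            for pair in order * 3:
                if set(pair) <= retained:
                    retained.discard(max(pair, key=p.__getitem__))
            outcomes.add(frozenset(retained))
        assert outcomes == {frozenset({"b"})}
        assert report.stage1_retained == ["b"]

    def test_within_group_filtering_spares_cross_group_pairs(self):
        rng = np.random.default_rng(3)
        ds = _correlated_dataset(rng, {"a": 0.95, "b": 0.96})
        ds.variable_group = {"a": "climate", "b": "human"}
        screen = _screen(["a", "b"], [0.01, 0.04], groups=["climate", "human"])
        report = correlation_filter(ds, screen, within_groups=True)
        assert report.stage1_retained == ["a", "b"]
        report_global = correlation_filter(ds, screen, within_groups=False)
        assert report_global.stage1_retained == ["a"]

    def test_zero_variance_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        presence = rng.binomial(1, 0.5, size=100)
        presence[:2] = [0, 1]
        ds = make_dataset(presence, {"flat": np.ones(100), "v": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="zero-variance"):
            report = correlation_filter(ds, _screen(["flat", "v"], [0.5, 0.5]))
        assert report.stage1_retained == ["v"]
        assert report.zero_variance == ["flat"]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        ds = _correlated_dataset(rng, {"a": 0.95, "b": 0.92, "c": 0.0, "d": 0.85})
        screen = screen_variables(ds)
        first = correlation_filter(ds, screen)
        surviving = [s for s in screen if s.variable in first.stage1_retained]
        second = correlation_filter(ds, surviving)
        assert second.stage1_retained == first.stage1_retained
        assert second.stage1_dropped == []

    def test_monotone_in_threshold(self):
        for seed in range(5):
            rng = np.random.default_rng(seed + 50)
            ds = _correlated_dataset(
                rng, {"a": 0.95, "b": 0.9, "c": 0.85, "d": 0.3, "e": 0.82}
            )
            screen = screen_variables(ds)
            previous: set[str] = set()
            for thr in (0.5, 0.7, 0.8, 0.9, 0.99):
                retained = set(correlation_filter(ds, screen, r_threshold=thr).stage1_retained)
                assert previous <= retained
                previous = retained


class TestFdrFilter:
    def test_hand_worked_rule(self):
        """p=(0.001,0.010,0.030,0.200), q=0.05, V=4: thresholds are
        I*(0.05/4) = (0.0125, 0.025, 0.0375, 0.05); largest qualifying
        rank is 3, so exactly the first three survive."""
        screen = _screen(["a", "b", "c", "d"], [0.001, 0.010, 0.030, 0.200])
        kept = fdr_filter(screen, q=0.05, V=4)
        assert [s.variable for s in kept] == ["a", "b", "c"]

    def test_nothing_qualifies(self):
        screen = _screen(["a", "b"], [0.2, 0.3])
        assert fdr_filter(screen, q=0.05, V=2) == []

    def test_zero_pvalue_always_retained(self):
        screen = _screen(["a", "b"], [0.0, 0.99])
        kept = fdr_filter(screen, q=0.05, V=2)
        assert "a" in {s.variable for s in kept}

    def test_empty_input(self):
        assert fdr_filter([], q=0.05, V=0) == []

    def test_equals_benjamini_hochberg(self):
        """Step-up rule coincides with the reference BH procedure."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = rng.integers(1, 30)
            p = np.where(rng.random(m) < 0.4, rng.random(m) * 0.02, rng.random(m))
            screen = _screen([f"v{i}" for i in range(m)], p)
            kept = {s.variable for s in fdr_filter(screen, q=0.05, V=m)}
            ref = {f"v{i}" for i in np.flatnonzero(oracle_bh_reject(p, 0.05))}
            assert kept == ref

    def test_ordered_by_increasing_p(self):
        screen = _screen(["a", "b", "c"], [0.01, 0.001, 0.005])
        kept = fdr_filter(screen, q=0.2, V=3)
        assert [s.variable for s in kept] == ["b", "c", "a"]


def test_select_variables_pipeline(bench_species):
    """End-to-end screen on the bench species: the planted duplicate goes
    at stage 1 and the informative gradients survive both stages."""
    report = select_variables(bench_species)
    assert "env1_dup" not in report.stage1_retained
    assert report.V == len(report.stage1_retained)
    assert set(report.stage2_retained) <= set(report.stage1_retained)
    assert {"env1", "env2", "env3"} <= set(report.stage2_retained)
    frame = report.to_frame()
    assert len(frame) == len(report.screen)
    assert frame.loc[frame.variable == "env1_dup", "drop_reason"].item() != ""
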