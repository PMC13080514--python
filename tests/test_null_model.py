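import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedprox import (
    MatchedSetSampler,
    NullConfig,
    NullResult,
    degree_bins,
    run_null_test,
    sample_matched_set,
)
from seedprox.neighborhood import STATISTICS, neighborhood_oracle
from seedprox.null_model import results_to_json, results_to_tsv

from conftest import make_network


class TestConfig:
    def test_defaults_match_reference_protocol(self):
        cfg = NullConfig()
        assert cfg.n_samples == 1000
        assert cfg.alpha == 0.05
        cfg.validate()

    @pytest.mark.parametrize(
        "kwargs", [{"n_samples": 0}, {"alpha": 0.0}, {"alpha": 1.0},
                   {"degree_matching": "cubic"}],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NullConfig(**kwargs).validate()


class TestDegreeBins:
    def test_exact_bins_are_degrees(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("C", "E"), ("C", "A")])
        bins = degree_bins(net, "exact")
        assert bins == {"A": 2, "B": 2, "C": 4, "D": 1, "E": 1}
        assert Counter(bins.values()) == {2: 2, 4: 1, 1: 2}

    def test_log2_binning(self):
        net = make_network([("H", f"X{i}") for i in range(5)])  # H has degree 5
        bins = degree_bins(net, "log2")
        assert bins["H"] == 2  # floor(log2 5)
        assert all(bins[f"X{i}"] == 0 for i in range(5))

    def test_degree_zero_own_bin(self):
        net = make_network([("A", "B")])
        net.graph.add_node("Z")
        assert degree_bins(net, "log2")["Z"] == -1

    def test_uniform_degrees_single_bin(self):
        net = make_network([("A", "B"), ("C", "D")])
        for scheme in ("exact", "log2"):
            assert len(set(degree_bins(net, scheme).values())) == 1


class TestSampler:
    def test_star_leaves_drawn_uniformly(self):
        net = make_network([("M", f"L{i}") for i in range(4)])
        sampler = MatchedSetSampler(net, seed="M")
        rng = np.random.default_rng(0)
        hits = Counter()
        n = 4000
        for _ in range(n):
            (pick,) = sampler.sample({"L0"}, rng)
            hits[pick] += 1
        assert set(hits) == {f"L{i}" for i in range(4)}
        for count in hits.values():  # each ~1/4; 5 sigma band
            assert abs(count / n - 0.25) < 5 * math.sqrt(0.25 * 0.75 / n)

    def test_empty_template(self):
        net = make_network([("A", "B")])
        assert sample_matched_set(net, set(), seed="A") == set()

    def test_seed_never_sampled(self, pa_network):
        seed = max(sorted(pa_network.nodes), key=pa_network.graph.degree)
        sampler = MatchedSetSampler(pa_network, seed)
        rng = np.random.default_rng(1)
        template = set(list(sorted(pa_network.nodes - {seed}))[:25])
        for _ in range(50):
            assert seed not in sampler.sample(template, rng)

    def test_exact_matching_preserves_degree_multiset(self, pa_network):
        """When every degree class holds at least twice the template's demand,
        every draw reproduces the template's degree multiset."""
        seed = max(sorted(pa_network.nodes), key=pa_network.graph.degree)
        by_degree: dict[int, list[str]] = {}
        for node in sorted(pa_network.nodes - {seed}):
            by_degree.setdefault(pa_network.degree(node), []).append(node)
        template = set()
        for nodes in by_degree.values():
            template.update(nodes[: len(nodes) // 2])
        template = set(sorted(template)[:60])
        want = sorted(pa_network.degree(v) for v in template)
        sampler = MatchedSetSampler(pa_network, seed)
        rng = np.random.default_rng(2)
        for _ in range(300):
            got = sampler.sample(template, rng)
            assert sorted(pa_network.degree(v) for v in got) == want

    def test_exhausted_bin_falls_back_to_nearest(self):
        net = make_network(
            [("H", "A"), ("H", "B"), ("H", "C"),  # H unique degree-3 node
             ("A", "B"), ("C", "D"), ("D", "E"), ("E", "F")]
        )
        sampler = MatchedSetSampler(net, seed="F")
        # simulate an exhausted degree-3 stratum
        sampler.bin_nodes[3] = np.array([], dtype=object)
        rng = np.random.default_rng(3)
        got = sampler.sample({"H", "A"}, rng)  # H demands a degree-3 draw
        assert len(got) == 2 and "F" not in got

    def test_whole_network_exhaustion_raises(self):
        net = make_network([("H", "A"), ("H", "B")])
        sampler = MatchedSetSampler(net, seed="B")
        for label in list(sampler.bin_nodes):
            sampler.bin_nodes[label] = np.array([], dtype=object)
        with pytest.raises(ValueError, match="exhausted"):
            sampler.sample({"A"}, np.random.default_rng(0))

    def test_template_larger_than_network_rejected(self):
        net = make_network([("A", "B"), ("B", "C")])
        sampler = MatchedSetSampler(net, seed="A")
        with pytest.raises(ValueError, match="exceeds"):
            sampler.sample({"B", "C", "X"} | set("DEFG"), np.random.default_rng(0))


class TestNullResult:
    def test_zero_observed_gives_p_one(self, toy_network):
        # D is at distance 3: all three observed statistics are 0
        results = run_null_test(toy_network, "M", {"D"}, NullConfig(n_samples=200, rng_seed=1))
        assert results["level1"].observed == 0
        assert results["level1"].p_value == 1.0

    def test_add_one_bounds(self, toy_network):
        results = run_null_test(toy_network, "M", {"A", "C"}, NullConfig(n_samples=99, rng_seed=2))
        for res in results.values():
            assert 1 / 100 <= res.p_value <= 1.0

    def test_fold_change_sentinels(self):
        zeros = NullResult("level1", observed=0, samples=np.zeros(10, dtype=int))
        assert zeros.fold_change == 1.0 and zeros.fold_defined
        undef = NullResult("level1", observed=3, samples=np.zeros(10, dtype=int))
        assert math.isnan(undef.fold_change) and not undef.fold_defined
        plain = NullResult("level1", observed=4, samples=np.full(10, 2))
        assert plain.fold_change == pytest.approx(2.0)

    def test_p_value_formula(self):
        res = NullResult("level2", observed=3, samples=np.array([1, 2, 3, 4, 5]))
        assert res.p_value == pytest.approx((1 + 3) / (1 + 5))

    def test_determinism(self, toy_network):
        cfg = NullConfig(n_samples=150, rng_seed=42)
        a = run_null_test(toy_network, "M", {"A", "C"}, cfg)
        b = run_null_test(toy_network, "M", {"A", "C"}, cfg)
        for stat in STATISTICS:
            assert np.array_equal(a[stat].samples, b[stat].samples)

    def test_serialization_shapes(self, toy_network):
        results = run_null_test(toy_network, "M", {"A"}, NullConfig(n_samples=50, rng_seed=3))
        text = results_to_tsv(results)
        assert text.splitlines()[0].startswith("statistic\tobserved")
        assert len(text.splitlines()) == 4
        import json

        payload = json.loads(results_to_json(results, rng_seed=3))
        assert set(payload) == set(STATISTICS)
        assert payload["level1"]["rng_seed"] == 3


class TestResultInvariants:
    """Property checks on the result container over arbitrary null vectors."""

    @given(
        observed=st.integers(min_value=0, max_value=50),
        samples=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=200),
    )
    @settings(deadline=None, derandomize=True)
    def test_p_bounds_and_fold_definedness(self, observed, samples):
        res = NullResult("level1", observed=observed, samples=np.array(samples))
        assert 1 / (len(samples) + 1) <= res.p_value <= 1.0
        if res.mean_null == 0 and observed > 0:
            assert not res.fold_defined
        else:
            assert res.fold_defined and res.fold_change >= 0.0


class TestEnumeration:
    def test_empirical_p_matches_exact_tail(self):
        """On a tiny graph with singleton gene sets the resampled p agrees
        with the exactly enumerated tail probability of the matched null."""
        net = make_network(
            [("M", "A"), ("M", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
             ("D", "E"), ("B", "E"), ("E", "F")]
        )
        bins = degree_bins(net, "exact")
        n_null = 400
        for i, target in enumerate(sorted(net.nodes - {"M"})):
            observed = neighborhood_oracle(net, "M", {target}).counts()
            results = run_null_test(
                net, "M", {target},
                NullConfig(n_samples=n_null, rng_seed=1000 + i),
            )
            peers = [v for v in net.nodes if v != "M" and bins[v] == bins[target]]
            for stat in STATISTICS:
                tail = [
                    neighborhood_oracle(net, "M", {u}).counts()[stat] >= observed[stat]
                    for u in peers
                ]
                q = sum(tail) / len(tail)
                expected = (1 + n_null * q) / (1 + n_null)
                se = math.sqrt(q * (1 - q) / n_null)
                assert abs(results[stat].p_value - expected) <= 3 * se + 1e-9
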