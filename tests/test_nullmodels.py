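import itertools

import numpy as np
import pytest

from fluencynet import (
    CorrelationMatrix,
    ERSpec,
    MetricDistribution,
    aspl,
    bootstrap_partial,
    build_pmfg,
    clustering,
    diameter,
    empirical_significance,
    simulate_er,
    two_sample_t,
)
from fluencynet.nullmodels import UndefinedStatisticError

from oracles import pooled_t


def test_er_spec_validation():
    with pytest.raises(ValueError):
        ERSpec(n=2, p=0.5)
    with pytest.raises(ValueError):
        ERSpec(n=10, p=0.0)
    with pytest.raises(ValueError):
        ERSpec(n=10, p=0.5, realizations=0)


def test_p_equal_one_is_degenerate():
    null = simulate_er(ERSpec(n=6, p=1.0, realizations=5, seed=0))
    assert set(null.l.values) == {1.0}
    assert set(null.d.values) == {1.0}
    assert set(null.cc.values) == {1.0}
    assert null.disconnected_fraction == 0.0


def test_same_spec_and_seed_reproduces_distributions():
    spec = ERSpec(n=20, p=0.2, realizations=50, seed=7)
    a, b = simulate_er(spec), simulate_er(spec)
    np.testing.assert_array_equal(a.l.values, b.l.values)
    np.testing.assert_array_equal(a.cc.values, b.cc.values)


def test_mean_clustering_approaches_edge_probability():
    """E[local CC | deg >= 2] = p in G(n, p); degree-<2 nodes contribute 0,
    deflating the mean by the probability of such nodes."""
    n, p, reps = 40, 0.15, 2000
    null = simulate_er(ERSpec(n=n, p=p, realizations=reps, seed=11))
    p_low_degree = (1 - p) ** (n - 1) + (n - 1) * p * (1 - p) ** (n - 2)
    expected = p * (1 - p_low_degree)
    assert null.cc.mean == pytest.approx(
        expected, abs=4 * null.cc.sd / np.sqrt(reps)
    )


def test_disconnected_fraction_matches_isolated_node_rate():
    """At the matched density of a 75-node PMFG, disconnection is driven by
    isolated nodes: P ~ 1 - exp(-n(1-p)^(n-1)) ~ 0.16."""
    spec = ERSpec(n=75, p=219 / 2775, realizations=400, seed=5)
    null = simulate_er(spec)
    assert 0.08 < null.disconnected_fraction < 0.26
    null_rs = simulate_er(spec, disconnection_policy="resample")
    assert 0.08 < null_rs.disconnected_fraction < 0.26
    assert np.isfinite(null_rs.l.values).all()


def test_charpath_convention_scales_aspl():
    null = simulate_er(ERSpec(n=30, p=0.3, realizations=30, seed=3),
                       disconnection_policy="resample")
    np.testing.assert_allclose(null.l_char.values, null.l.values * 29 / 30)


def test_empirical_significance_counting():
    dist = MetricDistribution("m", np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    # observed 3.5: greater -> (1+2)/6, less -> (1+3)/6, two -> 2*3/6 = 1
    assert empirical_significance(3.5, dist, "greater") == pytest.approx(3 / 6)
    assert empirical_significance(3.5, dist, "less") == pytest.approx(4 / 6)
    assert empirical_significance(3.5, dist, "two") == pytest.approx(1.0)
    # beyond every simulated value
    assert empirical_significance(99.0, dist, "greater") == pytest.approx(1 / 6)
    # equal to every simulated value
    flat = MetricDistribution("m", np.ones(5))
    assert empirical_significance(1.0, flat, "two") == 1.0


def test_two_sample_t_matches_hand_formula_and_df():
    x = [1.2, 0.8, 1.1, 1.4, 0.9]
    y = [0.7, 0.6, 1.0, 0.5]
    result = two_sample_t(x, y)
    t_hand, df_hand = pooled_t(x, y)
    assert result.t == pytest.approx(t_hand)
    assert result.df == df_hand == 7
    same = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same.t == 0.0 and same.p == pytest.approx(1.0)
    with pytest.raises(UndefinedStatisticError):
        two_sample_t([1.0, 1.0], [1.0, 1.0])
    assert two_sample_t(np.ones(75), np.zeros(75) + np.linspace(0, 1, 75)).df == 148


def _toy_wmcn_pair(n_words: int, seed: int):
    rng = np.random.default_rng(seed)
    labels = [f"w{i}" for i in range(n_words)]
    mats = []
    for _ in range(2):
        w = rng.uniform(-0.9, 0.9, size=(n_words, n_words))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        mats.append(CorrelationMatrix(vocabulary=labels, values=w))
    return mats


def test_bootstrap_full_vocabulary_reproduces_full_network_exactly():
    c_a, c_b = _toy_wmcn_pair(7, seed=1)
    comparison = bootstrap_partial(c_a, c_b, subset_size=7, realizations=4, seed=0)
    for c, label in zip((c_a, c_b), comparison.group_labels):
        net = build_pmfg(c)
        dist = comparison.distributions[label]
        assert set(dist["L"].values) == {aspl(net)}
        assert set(dist["D"].values) == {float(diameter(net))}
        assert set(dist["CC"].values) == {clustering(net)}


def test_bootstrap_means_match_exhaustive_enumeration():
    """6-word vocabulary, subsets of 4: only C(6,4)=15 partial networks
    exist, so the bootstrap mean must converge on the enumeration mean."""
    c_a, c_b = _toy_wmcn_pair(6, seed=2)
    vocab = sorted(c_a.vocabulary)
    exhaustive = {g: {"L": [], "D": [], "CC": []} for g in ("a", "b")}
    for subset in itertools.combinations(vocab, 4):
        for g, c in zip(("a", "b"), (c_a, c_b)):
            net = build_pmfg(c.restrict(list(subset)))
            exhaustive[g]["L"].append(aspl(net))
            exhaustive[g]["D"].append(float(diameter(net)))
            exhaustive[g]["CC"].append(clustering(net))
    comparison = bootstrap_partial(
        c_a, c_b, subset_size=4, realizations=3000, seed=9, group_labels=("a", "b")
    )
    for g in ("a", "b"):
        for metric in ("L", "D", "CC"):
            enum = np.asarray(exhaustive[g][metric])
            boot = comparison.distributions[g][metric]
            # all bootstrap values are realizable partial-network values
            assert set(np.round(boot.values, 12)) <= set(np.round(enum, 12))
            se = enum.std() / np.sqrt(boot.realizations)
            assert boot.mean == pytest.approx(enum.mean(), abs=max(5 * se, 1e-12))


def test_bootstrap_partial_networks_inherit_pmfg_invariants():
    import networkx as nx

    c_a, _ = _toy_wmcn_pair(10, seed=3)
    rng = np.random.default_rng(0)
    for _ in range(5):
        subset = sorted(rng.choice(sorted(c_a.vocabulary), size=6, replace=False))
        net = build_pmfg(c_a.restrict(subset))
        assert net.n_edges == 3 * (6 - 2)
        assert nx.is_connected(net.graph)
        assert nx.check_planarity(net.graph)[0]


def test_bootstrap_vocabulary_mismatch_raises():
    c_a, _ = _toy_wmcn_pair(6, seed=4)
    c_b, _ = _toy_wmcn_pair(7, seed=4)
    with pytest.raises(ValueError):
        bootstrap_partial(c_a, c_b, subset_size=4, realizations=2)


def test_bootstrap_seed_determinism_and_mode_flag():
    c_a, c_b = _toy_wmcn_pair(8, seed=6)
    kwargs = dict(subset_size=5, realizations=20, seed=21)
    r1 = bootstrap_partial(c_a, c_b, **kwargs)
    r2 = bootstrap_partial(c_a, c_b, **kwargs)
    np.testing.assert_array_equal(
        r1.distributions["a"]["L"].values, r2.distributions["a"]["L"].values
    )
    independent = bootstrap_partial(c_a, c_b, shared_subsets=False, **kwargs)
    assert independent.shared_subsets is False
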