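import numpy as np
import pytest

from fluencynet import (
    GeneratorSpec,
    GroupProfile,
    build_pmfg,
    build_response_matrix,
    builtin_profile,
    default_profiles,
    generate_group,
    generate_pair,
    restrict,
    select_wmcn_vocabulary,
    summarize,
    word_correlations,
)
from fluencynet.synthetic import profile_from_yaml, profile_to_yaml


SMALL = GeneratorSpec(
    n_subjects=15,
    subcategory_sizes=(8, 8, 8, 8),
    knowledge_decay=0.5,
    retrieval_mean=10,
    retrieval_sd=2.5,
    p_know=0.9,
)


def test_same_seed_reproduces_dataset_exactly():
    profile = GroupProfile("g", SMALL)
    assert generate_group(profile, seed=42).subjects == generate_group(profile, seed=42).subjects
    pair1 = generate_pair(profile, profile, seed=7)
    pair2 = generate_pair(profile, profile, seed=7)
    assert pair1[0].subjects == pair2[0].subjects
    assert pair1[1].subjects == pair2[1].subjects


def test_responses_are_duplicate_free_and_within_lexicon():
    profile = GroupProfile("g", SMALL)
    lexicon = set(SMALL.lexicon())
    for _, responses in generate_group(profile, seed=3).subjects:
        assert len(responses) == len(set(responses))
        assert set(responses) <= lexicon
        assert responses  # retained subjects are non-empty


def test_single_subcategory_with_no_switching():
    spec = GeneratorSpec(
        n_subjects=6, subcategory_sizes=(12,), knowledge_decay=0.0,
        retrieval_mean=5, retrieval_sd=1, p_switch=0.0, p_know=1.0,
    )
    ds = generate_group(GroupProfile("g", spec), seed=1)
    assert all(w.startswith("s00") for _, r in ds.subjects for w in r)


def test_infeasible_retrieval_length_rejected():
    with pytest.raises(ValueError):
        GeneratorSpec(subcategory_sizes=(3, 3), retrieval_mean=10)


def test_default_profiles_hit_distinct_word_anchors():
    """27-subject draws from the shipped profiles should produce distinct-
    word counts near the calibration anchors of 132 and 106 (within 25%)."""
    nh, ci = default_profiles()
    counts = {"nh": [], "ci": []}
    for seed in range(20):
        a, b = generate_pair(nh, ci, seed=seed)
        counts["nh"].append(len(a.vocabulary()))
        counts["ci"].append(len(b.vocabulary()))
    assert 132 * 0.75 <= np.mean(counts["nh"]) <= 132 * 1.25
    assert 106 * 0.75 <= np.mean(counts["ci"]) <= 106 * 1.25
    assert np.mean(counts["nh"]) > np.mean(counts["ci"])


def test_longer_retrieval_yields_more_distinct_words():
    base = dict(
        n_subjects=15, subcategory_sizes=(8, 8, 8, 8), knowledge_decay=0.4,
        retrieval_sd=2.0, p_know=0.9,
    )
    short = GroupProfile("s", GeneratorSpec(retrieval_mean=6, **base))
    long_ = GroupProfile("l", GeneratorSpec(retrieval_mean=14, **base))
    distinct_short = [len(generate_group(short, seed=s).vocabulary()) for s in range(10)]
    distinct_long = [len(generate_group(long_, seed=s).vocabulary()) for s in range(10)]
    assert np.mean(distinct_long) > np.mean(distinct_short)


def test_pair_yields_usable_word_matched_vocabulary():
    a, b = generate_pair(seed=11)
    ma, mb = build_response_matrix(a), build_response_matrix(b)
    vocab = select_wmcn_vocabulary(ma, mb)
    assert 0 < len(vocab) < min(len(ma.vocabulary), len(mb.vocabulary))


def test_within_subcategory_correlations_exceed_between():
    """The clustering/switching walk must induce the subcategory
    co-occurrence structure the network analysis presumes."""
    profile = GroupProfile("g", SMALL)
    wins = 0
    runs = 60
    for seed in range(runs):
        ds = generate_group(profile, seed=seed)
        c = word_correlations(build_response_matrix(ds))
        cats = np.array([int(w[1:3]) for w in c.vocabulary])
        same = cats[:, None] == cats[None, :]
        off = ~np.eye(len(cats), dtype=bool)
        within = c.values[same & off].mean()
        between = c.values[~same].mean()
        wins += within > between
    assert wins >= int(0.95 * runs)


def test_pmfg_edges_concentrate_within_subcategories():
    """Planted structure recovery: the share of network edges inside
    subcategories must beat the share of all word pairs inside them."""
    profile = GroupProfile("g", SMALL)
    for seed in range(8):
        ds = generate_group(profile, seed=100 + seed)
        m = build_response_matrix(ds)
        c = word_correlations(m)
        net = build_pmfg(c)
        cat = {w: w[:3] for w in net.vocabulary}
        edges = net.edge_set()
        edge_within = np.mean([cat[a] == cat[b] for a, b in edges])
        vocab = net.vocabulary
        pair_within = np.mean([
            cat[a] == cat[b]
            for i, a in enumerate(vocab) for b in vocab[i + 1:]
        ])
        assert edge_within > pair_within


def test_clustered_data_produces_small_world_networks():
    """PMFGs from the generator's clustered co-occurrence structure should
    show S > 1 against their matched random reference."""
    profile = GroupProfile("g", SMALL)
    for seed in range(6):
        ds = generate_group(profile, seed=200 + seed)
        net = build_pmfg(word_correlations(build_response_matrix(ds)))
        m = summarize(net, reference_realizations=20, seed=seed)
        assert m.small_worldness > 1


def test_builtin_profiles_load_and_round_trip(tmp_path):
    nh = builtin_profile("nh_like")
    ci = builtin_profile("ci_like")
    assert nh.label == "nh_like" and ci.label == "ci_like"
    assert nh.spec.retrieval_mean > ci.spec.retrieval_mean
    assert nh.spec.p_know > ci.spec.p_know
    path = tmp_path / "p.yaml"
    profile_to_yaml(nh, path)
    assert profile_from_yaml(path) == nh
    with pytest.raises(KeyError):
        builtin_profile("nope")
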