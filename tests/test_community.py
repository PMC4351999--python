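"""Fingerprint binning, diversity indices, dissimilarities, ANOSIM, NMDS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import distance as sdist

from barisa import (
    Fingerprint,
    anosim,
    bin_fragments,
    bray_curtis,
    build_otu_table,
    compare_primer_sets,
    distance_matrix,
    diversity_stats,
    jaccard,
    nmds,
    richness,
    shannon,
)

# ----------------------------------------------------------------- binning


def test_binning_examples():
    fp = Fingerprint("s", [(100.4, 1.0), (101.6, 2.0)])
    v = bin_fragments(fp)
    assert v[0] == 3.0 and v[1:].sum() == 0  # both in [100, 102)

    assert bin_fragments(Fingerprint("s", [(99.9, 5.0)])).sum() == 0  # below range

    fp = Fingerprint("s", [(100.0, 5.0), (103.0, 2.0), (1499.0, 1.0)])
    v = bin_fragments(fp)
    assert v[0] == 5.0 and v[1] == 2.0 and v[-1] == 1.0
    assert richness(v) == 3


def test_boundary_peak_goes_to_upper_bin():
    v = bin_fragments(Fingerprint("s", [(102.0, 1.0)]))
    assert v[1] == 1.0 and v[0] == 0.0


def test_binning_rejects_negative_abundance():
    with pytest.raises(ValueError, match="negative"):
        Fingerprint("s", [(120.0, -1.0)])


def test_binning_rejects_window_below_one():
    with pytest.raises(ValueError, match="window"):
        bin_fragments(Fingerprint("s", [(120.0, 1.0)]), window=0.5)


@given(
    peaks=st.lists(
        st.tuples(
            st.floats(min_value=50, max_value=1600, allow_nan=False),
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
        ),
        max_size=50,
    )
)
@settings(max_examples=60)
def test_binning_conserves_in_range_abundance(peaks):
    fp = Fingerprint("s", peaks)
    total_in_range = sum(a for length, a in peaks if 100 <= length < 1500)
    assert bin_fragments(fp).sum() == pytest.approx(total_in_range)


def test_otu_table_shape_and_labels():
    fps = [Fingerprint("a", [(100.5, 1.0)]), Fingerprint("b", [(1499.5, 2.0)])]
    table = build_otu_table(fps)
    assert table.shape == (2, 700)
    assert table.loc["a", 100.0] == 1.0 and table.loc["b", 1498.0] == 2.0


# --------------------------------------------------------------- diversity


def test_shannon_uniform_equals_log_n():
    for n in (2, 5, 64):
        assert shannon(np.ones(n)) == pytest.approx(math.log(n), abs=1e-12)


def test_shannon_single_bin_is_zero():
    assert shannon([0, 7.0, 0]) == 0.0


def test_shannon_hand_value_and_base():
    v = (1.0, 1.0, 2.0)
    expected = math.log(4) - 0.5 * math.log(2)
    assert shannon(v) == pytest.approx(expected)
    assert shannon(v, base=2) == pytest.approx(expected / math.log(2))


def test_shannon_all_zero_errors():
    with pytest.raises(ValueError):
        shannon([0.0, 0.0])


# ----------------------------------------------------------- dissimilarity


def test_identical_profiles_distance_zero():
    v = [1.0, 2.0, 3.0]
    assert bray_curtis(v, v) == 0.0
    assert jaccard(v, v) == 0.0


def test_disjoint_profiles_distance_one():
    a, b = [1.0, 0.0], [0.0, 2.0]
    assert bray_curtis(a, b) == 1.0
    assert jaccard(a, b) == 1.0


def test_hand_computed_dissimilarities():
    a, b = (2.0, 1.0, 0.0), (0.0, 1.0, 2.0)
    assert bray_curtis(a, b) == pytest.approx(4 / 6)
    assert jaccard(a, b) == pytest.approx(1 - 1 / 3)


def test_dissimilarities_cross_check_scipy():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.integers(0, 5, 12).astype(float)
        b = rng.integers(0, 5, 12).astype(float)
        if a.sum() == 0 or b.sum() == 0:
            continue
        assert bray_curtis(a, b) == pytest.approx(sdist.braycurtis(a, b))
        assert jaccard(a, b) == pytest.approx(sdist.jaccard(a > 0, b > 0))


def test_both_all_zero_errors():
    with pytest.raises(ValueError):
        bray_curtis([0.0], [0.0])
    with pytest.raises(ValueError):
        jaccard([0.0], [0.0])


# ------------------------------------------------------------------ ANOSIM


def brute_force_anosim(dist, groups):
    """Independent oracle: Clarke's R and the exact permutation p over all
    distinct label assignments, from first principles."""
    d = np.asarray(dist, float)
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [d[i, j] for i, j in pairs]
    # average ranks, hand-rolled
    order = sorted(range(len(vals)), key=lambda k: vals[k])
    ranks = [0.0] * len(vals)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[k]]:
            j += 1
        avg = (k + j) / 2 + 1
        for t in range(k, j + 1):
            ranks[order[t]] = avg
        k = j + 1

    def r_for(labels):
        within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
        between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
        m = len(pairs)
        return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2)

    observed = r_for(list(groups))
    all_r = [r_for(p) for p in set(itertools.permutations(groups))]
    p = sum(1 for r in all_r if r >= observed - 1e-12) / len(all_r)
    return observed, p


HAND_DIST = np.array(
    [
        [0.0, 0.1, 0.8, 0.7],
        [0.1, 0.0, 0.9, 0.6],
        [0.8, 0.9, 0.0, 0.2],
        [0.7, 0.6, 0.2, 0.0],
    ]
)


def test_anosim_matches_exhaustive_oracle():
    groups = ["a", "a", "b", "b"]
    expected_r, expected_p = brute_force_anosim(HAND_DIST, groups)
    res = anosim(HAND_DIST, groups, method="exact")
    assert res.R == pytest.approx(expected_r)
    assert res.p_value == pytest.approx(expected_p)
    # maximal separation: every between > every within
    assert res.R == pytest.approx(1.0)


def test_anosim_exact_oracle_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = 6
        x = rng.random((n, 3))
        d = sdist.squareform(sdist.pdist(x))
        groups = ["a"] * 3 + ["b"] * 3
        expected_r, expected_p = brute_force_anosim(d, groups)
        res = anosim(d, groups, method="exact")
        assert res.R == pytest.approx(expected_r)
        assert res.p_value == pytest.approx(expected_p)


def test_anosim_permutation_p_near_exact_p():
    groups = ["a", "a", "b", "b"]
    exact = anosim(HAND_DIST, groups, method="exact")
    perm = anosim(HAND_DIST, groups, permutations=999, seed=0)
    assert perm.R == pytest.approx(exact.R)
    assert perm.p_value == pytest.approx(exact.p_value, abs=0.08)


def test_anosim_seed_reproducible():
    rng = np.random.default_rng(3)
    d = sdist.squareform(sdist.pdist(rng.random((8, 4))))
    groups = ["a"] * 4 + ["b"] * 4
    r1 = anosim(d, groups, permutations=199, seed=42)
    r2 = anosim(d, groups, permutations=199, seed=42)
    assert (r1.R, r1.p_value) == (r2.R, r2.p_value)


def test_anosim_cross_check_scikit_bio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as skbio_anosim

    rng = np.random.default_rng(5)
    x = np.vstack([rng.random((5, 3)), rng.random((5, 3)) + 0.8])
    d = sdist.squareform(sdist.pdist(x))
    groups = ["a"] * 5 + ["b"] * 5
    ours = anosim(d, groups, permutations=999, seed=1)
    theirs = skbio_anosim(DistanceMatrix(d), grouping=groups, permutations=999)
    assert ours.R == pytest.approx(float(theirs["test statistic"]), abs=1e-12)


def test_anosim_validates_input():
    with pytest.raises(ValueError, match="square"):
        anosim(np.zeros((3, 2)), ["a", "a", "b"])
    with pytest.raises(ValueError, match=">=2 members"):
        anosim(HAND_DIST, ["a", "a", "a", "b"])
    with pytest.raises(ValueError, match="2 groups"):
        anosim(HAND_DIST, ["a", "a", "a", "a"])


# -------------------------------------------------------------------- NMDS


def test_nmds_three_equidistant_points_embed_with_no_stress():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
    coords, stress = nmds(d, seed=0)
    assert stress == pytest.approx(0.0, abs=1e-3)
    assert np.allclose(coords.mean(axis=0), 0, atol=1e-8)


def test_nmds_duplicate_points_coincide():
    d = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
    )
    coords, _ = nmds(d, seed=0)
    assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.0, abs=1e-2)
    assert np.linalg.norm(coords[2] - coords[3]) == pytest.approx(0.0, abs=1e-2)


def test_nmds_stress_non_increasing_with_dimensions():
    rng = np.random.default_rng(11)
    d = sdist.squareform(sdist.pdist(rng.random((9, 5))))
    stresses = [nmds(d, n_components=k, seed=0, n_init=12)[1] for k in (1, 2, 3)]
    assert stresses[1] <= stresses[0] + 1e-3
    assert stresses[2] <= stresses[1] + 1e-3


def test_nmds_too_few_samples_errors():
    with pytest.raises(ValueError, match="at least"):
        nmds(np.zeros((2, 2)), n_components=2)


# -------------------------------------------------- primer-set comparison


def _stats(rich, shan, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rich))]
    return pd.DataFrame(
        {"otu_richness": rich, "shannon": shan}, index=pd.Index(ids, name="sample_id")
    )


def test_identical_stats_correlate_perfectly():
    a = _stats([5, 9, 12, 20], [1.0, 1.4, 2.0, 2.2])
    res = compare_primer_sets(a, a)
    assert res.r_richness == pytest.approx(1.0)
    assert res.r_shannon == pytest.approx(1.0)


def test_opposite_stats_correlate_negatively():
    a = _stats([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
    b = _stats([4, 3, 2, 1], [0.4, 0.3, 0.2, 0.1])
    res = compare_primer_sets(a, b)
    assert res.r_richness == pytest.approx(-1.0)
    assert res.r_shannon == pytest.approx(-1.0)


def test_hand_computed_pearson():
    a = _stats([1, 2, 3, 4], [1, 2, 3, 4])
    b = _stats([1, 3, 2, 4], [1, 3, 2, 4])
    res = compare_primer_sets(a, b)
    assert res.r_richness == pytest.approx(0.8)


def test_compare_requires_matched_samples_and_variance():
    a = _stats([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="identical sample sets"):
        compare_primer_sets(a, _stats([1, 2, 3], [1, 2, 3], ids=["x", "y", "z"]))
    with pytest.raises(ValueError, match="zero variance"):
        compare_primer_sets(a, _stats([2, 2, 2], [1, 2, 3]))


def test_diversity_stats_and_distance_matrix_roundtrip():
    fps = [
        Fingerprint("a", [(100.5, 1.0), (200.5, 1.0)]),
        Fingerprint("b", [(100.5, 2.0)]),
    ]
    table = build_otu_table(fps)
    stats = diversity_stats(table)
    assert stats.loc["a", "otu_richness"] == 2
    assert stats.loc["b", "shannon"] == 0.0
    d = distance_matrix(table, "jaccard")
    assert d.loc["a", "b"] == pytest.approx(0.5)
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
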