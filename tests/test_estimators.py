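"""Estimator layer: plug-in identities, Kendall transformation, transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vistla import (
    Feature,
    discretize,
    entropy,
    estimate_mi,
    interaction_info,
    kendall_transform,
    mutual_info,
    split_categorical,
)
from vistla.estimators import KT_DOWN, KT_TIE, KT_UP

LN2 = math.log(2)


def feat(values, kind="categorical", name="x"):
    return Feature(name, kind, np.asarray(values))


# --------------------------------------------------------------------- entropy

@pytest.mark.parametrize(
    "values,expected",
    [
        (["a"] * 10, 0.0),                       # single outcome
        ([0] * 5 + [1] * 5, LN2),                # uniform binary
        # counts (1,2,3)/6, hand-evaluated plug-in sum
        ([0, 1, 1, 2, 2, 2], 1.0114042647073518),
    ],
)
def test_entropy_closed_forms(values, expected):
    assert entropy(feat(values)) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_empty():
    with pytest.raises(ValueError):
        entropy(np.array([]))


# ---------------------------------------------------------------- mutual info

def _from_joint(counts):
    """Expand a 2x2 contingency table into two code vectors."""
    xs, ys = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            xs += [i] * c
            ys += [j] * c
    return feat(xs), feat(ys, name="y")


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([[1, 1], [1, 1]], 0.0),                 # product-form joint
        # [[3,1],[1,3]]/8: hand-computed plug-in sum over the 4 cells
        ([[3, 1], [1, 3]], 0.1308120359411371),
    ],
)
def test_mutual_info_closed_forms(counts, expected):
    x, y = _from_joint(counts)
    assert mutual_info(x, y) == pytest.approx(expected, abs=1e-12)


def test_mutual_info_of_self_is_entropy():
    x = feat([0, 1, 0, 1])
    assert mutual_info(x, x) == pytest.approx(LN2, abs=1e-12)


def test_mutual_info_rejects_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        mutual_info(feat([0, 1]), feat([0, 1, 0]))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=40),
    st.data(),
)
def test_mutual_info_symmetric_nonnegative_bounded(xs, data):
    ys = data.draw(st.lists(st.integers(0, 3), min_size=len(xs), max_size=len(xs)))
    x, y = feat(xs), feat(ys, name="y")
    mxy, myx = mutual_info(x, y), mutual_info(y, x)
    assert mxy == pytest.approx(myx, abs=1e-12)
    assert mxy >= 0.0
    assert mxy <= min(entropy(x), entropy(y)) + 1e-12
    assert mutual_info(x, x) == pytest.approx(entropy(x), abs=1e-12)


# -------------------------------------------------------- interaction info

def test_interaction_info_xor_synergy():
    """Independent uniform inputs with an XOR collider: I(a;b)=0 but
    I(a;b|c)=ln2, so the triple information is -ln2."""
    a = feat([0, 0, 1, 1], name="a")
    b = feat([0, 1, 0, 1], name="b")
    c = feat([0, 1, 1, 0], name="c")
    t = interaction_info(a, b, c)
    assert t.i_ab == pytest.approx(0.0, abs=1e-12)
    assert t.i_ab_given_c == pytest.approx(LN2, abs=1e-12)
    assert t.ii_abc == pytest.approx(-LN2, abs=1e-12)


def test_interaction_info_copy_chain_redundancy():
    a = feat([0, 1, 0, 1], name="a")
    t = interaction_info(a, a, a)
    assert t.i_ab == pytest.approx(LN2, abs=1e-12)
    assert t.i_ab_given_c == pytest.approx(0.0, abs=1e-12)
    assert t.ii_abc == pytest.approx(LN2, abs=1e-12)


def test_interaction_info_noisy_chain_exact(chain3_exact):
    """On the exactly-weighted 8-cell chain joint the plug-in values equal
    the analytic ones computed from the distribution itself."""
    a, b, c = (chain3_exact.feature(n) for n in ("a", "b", "c"))
    t = interaction_info(a, b, c)
    assert t.i_ab == pytest.approx(0.36806420716849697, abs=1e-12)
    assert t.i_ab_given_c == pytest.approx(0.1463105134186461, abs=1e-12)
    assert t.ii_abc == pytest.approx(0.22175369374985088, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_interaction_info_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    cols = [feat(rng.integers(0, 3, 30), name=n) for n in "abc"]
    ref = interaction_info(*cols).ii_abc
    import itertools

    for perm in itertools.permutations(cols):
        assert interaction_info(*perm).ii_abc == pytest.approx(ref, abs=1e-12)


# ------------------------------------------------------- Kendall transform

@pytest.mark.parametrize(
    "values,expected_counts",
    [
        ((1, 2, 3), {KT_UP: 3, KT_DOWN: 3, KT_TIE: 0}),
        ((5, 5, 5), {KT_UP: 0, KT_DOWN: 0, KT_TIE: 6}),
        ((1, 1, 2), {KT_UP: 2, KT_DOWN: 2, KT_TIE: 2}),
    ],
)
def test_kendall_transform_token_counts(values, expected_counts):
    out = kendall_transform(feat(values, kind="ordinal"))
    n = len(values)
    assert out.n == n * (n - 1)
    got = {tok: int((out.values == tok).sum()) for tok in (KT_UP, KT_DOWN, KT_TIE)}
    assert got == expected_counts


def test_kendall_transform_alignment_is_shared():
    """Two features transformed separately stay row-aligned: identical
    inputs yield identical token vectors."""
    x = feat([3, 1, 2, 2], kind="ordinal")
    y = feat([3, 1, 2, 2], kind="ordinal", name="y")
    assert np.array_equal(kendall_transform(x).values, kendall_transform(y).values)


def test_kendall_transform_rejects_multicategory():
    with pytest.raises(ValueError, match="split"):
        kendall_transform(feat(["a", "b", "c", "a"], kind="categorical"))


def test_kendall_transform_needs_two_observations():
    with pytest.raises(ValueError):
        kendall_transform(feat([1], kind="ordinal"))


# ------------------------------------------------------------- estimate_mi

def test_estimate_mi_kt_perfect_monotone_agreement():
    x = feat([1, 2, 3, 4], kind="ordinal")
    y = feat([1, 2, 3, 4], kind="ordinal", name="y")
    got = estimate_mi(x, y, method="kt")
    assert got == pytest.approx(entropy(kendall_transform(x)), abs=1e-12)


def test_estimate_mi_kt_antimonotone_equals_monotone():
    x = feat([1, 2, 3, 4], kind="ordinal")
    y_up = feat([1, 2, 3, 4], kind="ordinal", name="y")
    y_dn = feat([4, 3, 2, 1], kind="ordinal", name="y")
    assert estimate_mi(x, y_dn, method="kt") == pytest.approx(
        estimate_mi(x, y_up, method="kt"), abs=1e-12
    )


def test_estimate_mi_mle_dispatch_identity_on_categorical():
    x = feat([0, 1, 1, 0, 2], name="x")
    y = feat([1, 1, 0, 0, 2], name="y")
    assert estimate_mi(x, y, method="mle") == mutual_info(x, y)


def test_estimate_mi_unknown_method():
    with pytest.raises(ValueError, match="method"):
        estimate_mi(feat([0, 1]), feat([1, 0]), method="knn")


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.integers(-50, 50), min_size=3, max_size=25, unique=True), st.data())
def test_estimate_mi_kt_monotone_invariant(xs, data):
    """Rank-based MI is unchanged by strictly monotone maps of either input."""
    ys = data.draw(st.permutations(xs))
    x = feat(np.array(xs, dtype=float), kind="ordinal")
    y = feat(np.array(ys, dtype=float), kind="ordinal", name="y")
    base = estimate_mi(x, y, method="kt")
    x2 = feat(np.exp(np.array(xs) / 25.0), kind="ordinal")
    y2 = feat(np.array(ys) ** 3, kind="ordinal", name="y")
    assert estimate_mi(x2, y, method="kt") == pytest.approx(base, abs=1e-12)
    assert estimate_mi(x, y2, method="kt") == pytest.approx(base, abs=1e-12)


def test_independent_mi_shrinks_with_sample_size():
    """Plug-in MI of independent features decays toward 0 as n grows."""
    means = []
    for n in (100, 1000, 10000):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = feat(rng.integers(0, 4, n))
            y = feat(rng.integers(0, 4, n), name="y")
            vals.append(mutual_info(x, y))
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
    assert means[2] < 0.005


# -------------------------------------------------------------- discretize

def test_discretize_median_split():
    out = discretize(feat(np.arange(1, 11), kind="ordinal"), bins=2)
    counts = np.bincount(out.values)
    assert list(counts) == [5, 5]


def test_discretize_constant_single_category():
    out = discretize(feat(np.ones(7), kind="ordinal"), bins=4)
    assert len(np.unique(out.values)) == 1


def test_discretize_never_exceeds_distinct_values():
    out = discretize(feat(np.array([1.0, 2.0, 3.0] * 5), kind="ordinal"), bins=10)
    assert len(np.unique(out.values)) == 3


def test_discretize_ties_share_bins():
    x = feat(np.repeat([1.0, 2.0, 3.0, 4.0], [10, 10, 1, 1]), kind="ordinal")
    out = discretize(x, bins=2)
    codes = out.values
    for v in (1.0, 2.0, 3.0, 4.0):
        assert len(np.unique(codes[x.values == v])) == 1


def test_discretize_rejects_small_bins():
    with pytest.raises(ValueError):
        discretize(feat(np.arange(5), kind="ordinal"), bins=1)


# -------------------------------------------------------- split_categorical

def test_split_categorical_one_hot():
    x = feat(["a", "b", "c", "a", "b"], name="g")
    parts = split_categorical(x)
    assert [p.name for p in parts] == ["g=a", "g=b", "g=c"]
    stacked = np.stack([p.values for p in parts])
    assert np.array_equal(stacked.sum(axis=0), np.ones(5, dtype=int))


def test_split_categorical_indicators_reconstruct_original():
    rng = np.random.default_rng(0)
    x = feat(rng.integers(0, 3, 50), name="g")
    parts = split_categorical(x)
    recon = np.argmax(np.stack([p.values for p in parts]), axis=0)
    # indicator argmax recovers the original codes up to the category order
    assert np.array_equal(recon, x.codes())


def test_split_categorical_rejects_binary():
    with pytest.raises(ValueError):
        split_categorical(feat([0, 1, 0], name="b"))
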