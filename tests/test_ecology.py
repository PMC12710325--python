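"""Rarefaction, Hellinger, Bray-Curtis, PERMANOVA, niche breadth."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abyssalgv import (AbundanceMatrix, bray_curtis, compare_breadth,
                       hellinger, levins_ba, niche_breadth_table, permanova,
                       rarefy, rarefy_table)


def _mat(values, unit="counts"):
    arr = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        unit=unit)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def test_rarefy_full_depth_is_identity():
    counts = np.array([5, 3, 2])
    np.testing.assert_array_equal(rarefy(counts, 10, rng=0), counts)


def test_rarefy_conserves_depth_and_is_seeded():
    counts = np.array([100, 50, 25, 0, 3])
    out1 = rarefy(counts, 60, rng=42)
    out2 = rarefy(counts, 60, rng=42)
    assert out1.sum() == 60
    np.testing.assert_array_equal(out1, out2)
    assert (out1 <= counts).all()


def test_rarefy_depth_exceeding_total_errors():
    with pytest.raises(ValueError):
        rarefy(np.array([3, 2]), 6, rng=0)


def test_rarefy_preserves_expected_proportions():
    """Mean of 1,000 rarefied draws matches source proportions to 3 SE."""
    rng = np.random.default_rng(7)
    counts = np.array([500, 300, 150, 50])
    depth = 200
    draws = np.array([rarefy(counts, depth, rng) for _ in range(1000)])
    p = counts / counts.sum()
    se = np.sqrt(p * (1 - p) * depth) / np.sqrt(1000)
    assert (np.abs(draws.mean(axis=0) - p * depth) <= 3 * se + 1e-9).all()


def test_rarefy_table_drops_shallow_samples():
    mat = _mat([[50, 5], [50, 2]])
    out = rarefy_table(mat, depth=60, rng=0)
    assert out.sample_ids == ["s0"]
    assert out.df["s0"].sum() == 60


# ---------------------------------------------------------------------------
# Hellinger and Bray-Curtis
# ---------------------------------------------------------------------------

def test_hellinger_values():
    out = hellinger(_mat([[1, 4, 0], [1, 0, 0]]))
    np.testing.assert_allclose(out.df["s0"], [0.7071067811865476] * 2)
    np.testing.assert_allclose(out.df["s1"], [1.0, 0.0])
    np.testing.assert_allclose(out.df["s2"], [0.0, 0.0])  # empty stays empty


def test_hellinger_unit_sum_of_squares():
    rng = np.random.default_rng(1)
    mat = _mat(rng.integers(0, 50, size=(20, 6)))
    out = hellinger(mat)
    ss = (out.values ** 2).sum(axis=0)
    np.testing.assert_allclose(ss, 1.0, rtol=1e-12)


def test_bray_curtis_values():
    mat = _mat([[2, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 4]])
    d = bray_curtis(mat)
    assert d.loc["s0", "s0"] == 0.0
    assert d.loc["s0", "s1"] == pytest.approx(0.2)   # x=(2,1), y=(1,1)
    assert d.loc["s0", "s3"] == pytest.approx(1.0)   # disjoint support
    assert d.loc["s2", "s3"] == pytest.approx(1.0)
    assert d.loc["s2", "s2"] == 0.0                  # both empty
    np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
    assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _dist(values, ids):
    return pd.DataFrame(values, index=ids, columns=ids)


def _oracle_permanova(d, labels):
    """Brute-force pseudo-F and exact p by complete label enumeration."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]

    def pseudo_f(lab):
        groups = sorted(set(lab))
        ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in groups:
            idx = [i for i in range(n) if lab[i] == g]
            ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        ss_a = ss_t - ss_w
        if ss_w == 0:
            return np.inf if ss_a > 0 else 0.0
        return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    f_obs = pseudo_f(labels)
    arrangements = set(permutations(labels))
    hits = sum(1 for lab in arrangements if pseudo_f(lab) >= f_obs - 1e-12)
    return f_obs, hits / len(arrangements)


def test_permanova_equal_distances_null():
    # equidistant samples: every labeling yields the same pseudo-F, so the
    # permutation p value is exactly 1
    ids = list("abcd")
    d = _dist(0.5 * (1 - np.eye(4)), ids)
    groups = pd.Series(["x", "x", "y", "y"], index=ids)
    res = permanova(d, groups, n_permutations=999, rng=0)
    assert res.p == 1.0


def test_permanova_matches_enumeration_oracle():
    ids = list("abcd")
    vals = np.full((4, 4), 0.9)
    vals[0, 1] = vals[1, 0] = 0.1
    vals[2, 3] = vals[3, 2] = 0.1
    np.fill_diagonal(vals, 0.0)
    groups = pd.Series(["x", "x", "y", "y"], index=ids)
    res = permanova(_dist(vals, ids), groups, n_permutations=9999, rng=0)
    f_oracle, p_oracle = _oracle_permanova(vals, list(groups))
    assert res.pseudo_F == pytest.approx(f_oracle)
    assert res.p == pytest.approx(p_oracle)


def test_permanova_p_bounds_and_determinism():
    rng = np.random.default_rng(2)
    n = 12
    vals = rng.uniform(0.1, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    ids = [f"s{i}" for i in range(n)]
    groups = pd.Series(["x"] * 6 + ["y"] * 6, index=ids)
    res1 = permanova(_dist(vals, ids), groups, n_permutations=199, rng=5)
    res2 = permanova(_dist(vals, ids), groups, n_permutations=199, rng=5)
    assert res1.p == res2.p
    assert 1 / (1 + 199) <= res1.p <= 1.0
    assert 0.0 <= res1.R2 <= 1.0


def test_permanova_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import permanova as sk_permanova
    rng = np.random.default_rng(4)
    n = 16
    vals = rng.uniform(0.05, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    ids = [f"s{i}" for i in range(n)]
    groups = pd.Series(["x"] * 8 + ["y"] * 8, index=ids)
    res = permanova(_dist(vals, ids), groups, n_permutations=999, rng=0)
    sk = sk_permanova(skbio.DistanceMatrix(vals, ids), groups.to_numpy(),
                      permutations=999)
    assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-9)
    assert res.p == pytest.approx(sk["p-value"], abs=0.05)


def test_permanova_rejects_degenerate_groups():
    ids = list("abcd")
    d = _dist(0.5 * (1 - np.eye(4)), ids)
    with pytest.raises(ValueError):
        permanova(d, pd.Series(["x", "x", "x", "y"], index=ids))
    with pytest.raises(ValueError):
        permanova(d, pd.Series(["x", "x", "x", "x"], index=ids))


# ---------------------------------------------------------------------------
# Niche breadth
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("profile, b, ba", [
    ([1, 1, 1, 1], 4.0, 1.0),
    ([0, 5, 0, 0], 1.0, 0.0),
    ([0.5, 0.5, 0, 0], 2.0, 1.0 / 3.0),
])
def test_levins_ba_values(profile, b, ba):
    got_b, got_ba = levins_ba(profile)
    assert got_b == pytest.approx(b)
    assert got_ba == pytest.approx(ba)


def test_levins_ba_errors():
    with pytest.raises(ValueError):
        levins_ba([0, 0, 0])
    with pytest.raises(ValueError):
        levins_ba([1.0])


@given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                min_size=2, max_size=20).filter(lambda p: sum(p) > 0),
       st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=50)
def test_levins_ba_scale_invariant(profile, scale):
    _, ba1 = levins_ba(np.asarray(profile))
    _, ba2 = levins_ba(np.asarray(profile) * scale)
    assert ba1 == pytest.approx(ba2, rel=1e-9, abs=1e-12)
    assert 0.0 <= ba1 <= 1.0 + 1e-12


def test_niche_breadth_table_skips_empty_features():
    mat = _mat([[1, 1], [0, 0]], unit="relative")
    out = niche_breadth_table(mat)
    assert list(out.index) == ["f0"]
    assert out.loc["f0", "BA"] == pytest.approx(1.0)


def test_compare_breadth_identical_and_separated():
    _, p_same = compare_breadth([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
    assert p_same >= 0.5
    _, p_sep = compare_breadth([0.7, 0.8, 0.9], [0.1, 0.2])
    assert p_sep == pytest.approx(0.1)  # 1 / C(5,2)


def test_compare_breadth_detects_shift():
    rng = np.random.default_rng(9)
    surface = rng.beta(2, 5, size=120)
    deep = np.clip(surface + 0.2, 0, 1)
    _, p = compare_breadth(deep, rng.permutation(surface))
    assert p < 0.001
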