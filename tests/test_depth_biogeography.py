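"""Mann-Whitney, BH correction, depth-specificity rules, region summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abyssalgv import (AbundanceMatrix, SampleTable, SimulationConfig,
                       bh_adjust, classify_depth_specific, exclusivity,
                       mann_whitney_u, region_summary,
                       simulate_depth_abundance)


def _oracle_mw(x, y, alternative="greater"):
    """Enumerate every assignment of the pooled values to the two groups
    and count pair dominances directly (no ranks)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(x, y)
    mu = nx * len(y) / 2.0
    us = []
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    if alternative == "greater":
        p = np.mean(us >= u_obs - 1e-9)
    elif alternative == "less":
        p = np.mean(us <= u_obs + 1e-9)
    else:
        p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9)
    return u_obs, p


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mw_fully_separated_groups():
    u, p = mann_whitney_u([3, 4, 5], [1, 2])
    assert u == 6.0
    assert p == pytest.approx(0.1)  # 1 / C(5,2)


def test_mw_all_tied_is_null():
    _, p = mann_whitney_u([1, 1], [1, 1])
    assert p == 1.0


def test_mw_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
def test_mw_exact_equals_enumeration_oracle(alternative):
    rng = np.random.default_rng(0)
    for nx in range(1, 5):
        for ny in range(1, 5):
            vals = rng.integers(0, 4, size=nx + ny).astype(float)  # many ties
            u, p = mann_whitney_u(vals[:nx], vals[nx:], alternative=alternative)
            u_o, p_o = _oracle_mw(vals[:nx], vals[nx:], alternative=alternative)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)


def test_mw_exact_and_normal_approximation_agree():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        _, p_exact = mann_whitney_u(x, y, exact_max_n=20)
        _, p_approx = mann_whitney_u(x, y, exact_max_n=0)
        assert p_exact == pytest.approx(p_approx, abs=0.01)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.2], [0.2]),
    ([0.01, 0.04, 0.03], [0.03, 0.04, 0.04]),
])
def test_bh_hand_computed(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
@settings(deadline=None, max_examples=50)
def test_bh_dominates_p_and_is_monotone(p):
    q = bh_adjust(p)
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(1)
    p = rng.uniform(size=30)
    np.testing.assert_allclose(bh_adjust(p),
                               statsmodels.fdrcorrection(p)[1], rtol=1e-12)


def test_bh_false_discoveries_controlled_under_null():
    """Under a global null the expected number of BH discoveries stays
    below m * alpha (500 replicates, 3 SE slack)."""
    rng = np.random.default_rng(5)
    m, alpha, reps = 20, 0.05, 500
    fd = np.array([(bh_adjust(rng.uniform(size=m)) < alpha).sum()
                   for _ in range(reps)])
    assert fd.mean() <= m * alpha + 3 * fd.std(ddof=1) / np.sqrt(reps)


# ---------------------------------------------------------------------------
# Depth-specificity classification
# ---------------------------------------------------------------------------

def _toy_dataset():
    samples = SampleTable(pd.DataFrame({
        "sample_id": ["su1", "su2", "su3", "d1", "d2", "d3"],
        "depth": [10, 30, 50, 500, 800, 1200],
        "region": ["r1"] * 6,
        "date": ["2021-01-15"] * 6,
        "fraction": ["pico"] * 6,
        "assay": ["metagenome"] * 6,
    }))
    abund = AbundanceMatrix(pd.DataFrame(
        {"su1": [0, 0, 1.0], "su2": [0, 0, 2.0], "su3": [0, 0, 1.5],
         "d1": [5.0, 0, 1.2], "d2": [0.0, 0, 0.9], "d3": [2.0, 0, 1.1]},
        index=["deep_only_g", "allzero_g", "flat_g"]), unit="tpm")
    return samples, abund


def test_deep_only_rule():
    samples, abund = _toy_dataset()
    labels = classify_depth_specific(abund, samples)
    assert labels.loc["deep_only_g", "rule"] == "deep_only"
    assert labels.loc["deep_only_g", "is_deep_specific"]


def test_all_zero_genome_never_specific():
    samples, abund = _toy_dataset()
    labels = classify_depth_specific(abund, samples)
    assert labels.loc["allzero_g", "rule"] == "none"
    assert not labels.loc["allzero_g", "is_deep_specific"]
    assert not labels.loc["flat_g", "is_deep_specific"]


def test_classifier_invariant_to_order_and_scale():
    samples, abund = _toy_dataset()
    base = classify_depth_specific(abund, samples)
    shuffled = AbundanceMatrix(abund.df[["d2", "su1", "d3", "su3", "su2", "d1"]],
                               unit="tpm")
    scaled = AbundanceMatrix(abund.df * 37.5, unit="tpm")
    for variant in (shuffled, scaled):
        got = classify_depth_specific(variant, samples)
        pd.testing.assert_series_equal(got["is_deep_specific"],
                                       base["is_deep_specific"])
        pd.testing.assert_series_equal(got["q"], base["q"])


def test_classifier_requires_both_layers():
    samples, abund = _toy_dataset()
    surface_only = abund.subset_samples(["su1", "su2", "su3"])
    with pytest.raises(ValueError):
        classify_depth_specific(surface_only, samples)


def test_classifier_recovers_planted_truth(depth_data):
    samples, abund, truth = depth_data
    labels = classify_depth_specific(abund, samples)
    spec = truth.deep_specific
    pred = labels["is_deep_specific"]
    sensitivity = (pred & spec).sum() / spec.sum()
    specificity = (~pred & ~spec).sum() / (~spec).sum()
    assert sensitivity >= 0.9
    assert specificity >= 0.95


def test_deep_only_flags_attain_minimal_p(depth_data):
    """Rule-2 genomes have the most extreme zero pattern their test could
    see: detected at depth, never elsewhere."""
    samples, abund, _ = depth_data
    labels = classify_depth_specific(abund, samples)
    deep = samples.is_deep().to_numpy()
    for gid in labels.index[labels["rule"] == "deep_only"]:
        row = abund.df.loc[gid].to_numpy()
        assert (row[deep] > 0).any()
        assert (row[~deep] == 0).all()


# ---------------------------------------------------------------------------
# Exclusivity
# ---------------------------------------------------------------------------

def test_exclusivity_rules():
    samples, abund = _toy_dataset()
    flags = exclusivity(abund, ["d1", "d2", "d3"])
    assert flags["deep_only_g"]
    assert not flags["flat_g"]       # positive outside the target group
    assert not flags["allzero_g"]    # no signal at all
    with pytest.raises(ValueError):
        exclusivity(abund, [])


def test_exclusivity_matches_brute_force_on_synthetic(depth_data):
    samples, abund, _ = depth_data
    targets = [s for s in abund.sample_ids if s.startswith("deep")][:10]
    flags = exclusivity(abund, targets)
    others = [s for s in abund.sample_ids if s not in targets]
    for gid in abund.feature_ids[:50]:
        row = abund.df.loc[gid]
        expected = (row[targets] > 0).any() and not (row[others] > 0).any()
        assert flags[gid] == expected


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def test_region_summary_toy_counts():
    samples = SampleTable(pd.DataFrame({
        "sample_id": ["a", "b"],
        "depth": [500, 600],
        "region": ["r1", "r2"],
        "date": ["2021-01-15"] * 2,
        "fraction": ["pico"] * 2,
        "assay": ["metagenome"] * 2,
    }))
    abund = AbundanceMatrix(pd.DataFrame(
        {"a": [1.0, 1.0, 0.0], "b": [0.0, 1.0, 1.0]},
        index=["g1", "g2", "g3"]), unit="tpm")
    summary = region_summary(abund, samples)
    assert summary.per_region.loc["r1", "n_detected"] == 2
    assert summary.per_region.loc["r1", "n_unique"] == 1
    assert summary.per_region.loc["r1", "unique_fraction"] == pytest.approx(0.5)
    assert summary.shared.loc["r1", "r2"] == 1
    assert summary.n_regions["g2"] == 2
    assert summary.fraction_in_at_least(2) == pytest.approx(1 / 3)
    assert summary.per_region["n_unique"].sum() <= len(summary.n_regions)


def test_region_summary_empty_abundance():
    samples = SampleTable(pd.DataFrame({
        "sample_id": ["a"], "depth": [500], "region": ["r1"],
        "date": ["2021-01-15"], "fraction": ["pico"], "assay": ["metagenome"],
    }))
    abund = AbundanceMatrix(pd.DataFrame({"a": [0.0]}, index=["g1"]),
                            unit="tpm")
    summary = region_summary(abund, samples)
    assert summary.per_region["n_detected"].sum() == 0
    assert len(summary.n_regions) == 0


def test_region_summary_consistent_with_planted_regions(depth_data):
    samples, abund, truth = depth_data
    summary = region_summary(abund, samples)
    # a genome can only be detected inside its simulated region set
    for gid in summary.n_regions.index:
        detected = summary.shared.columns[
            (abund.df.loc[gid, samples.df.index[samples.is_deep()]]
             .groupby(samples.df.loc[samples.is_deep(), "region"]).max() > 0)
        ]
        assert set(detected) <= truth.regions[gid]
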