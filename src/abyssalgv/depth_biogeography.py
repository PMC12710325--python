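"""Deep-sea-specificity classification and biogeographic summaries.

A genome is called deep-sea-specific when either

* Rule 1 (overrepresentation): a one-sided Mann-Whitney U test finds its
  abundance higher in deep samples (depth > 200 m) than elsewhere, with
  Benjamini-Hochberg adjusted p < alpha across the genome set, or
* Rule 2 (deep-only detection): it has signal (TPM > 0) in at least one
  deep sample and none in any shallower sample.

The same detection rule (value strictly above a threshold, 0 by default)
drives the biogeography summaries: per-region detected/unique genome
counts, pairwise region sharing, and per-genome region ranges; and a
generic exclusivity test (signal confined to one sample group) used for
mesopelagic-exclusive genomes at a single site.

The Mann-Whitney p value is exact — full enumeration of rank assignments
over midranks — whenever the combined sample size is small (<= 12 by
default, at most C(12, 6) = 924 configurations); larger samples use the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds, get_logger
from .core_tables import AbundanceMatrix, SampleTable

__all__ = [
    "mann_whitney_u",
    "bh_adjust",
    "classify_depth_specific",
    "exclusivity",
    "region_summary",
    "RegionSummary",
]

logger = get_logger(__name__)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x: np.ndarray, y: np.ndarray, alternative: str = "greater",
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` against ``y``.

    U counts the pairs with x > y plus half the tied pairs.  For combined
    sample sizes up to ``exact_max_n`` the p value is exact: the
    permutation distribution of U is enumerated over all assignments of
    the pooled midranks to the two groups (ties handled naturally).
    Beyond that, the normal approximation with tie correction and a 0.5
    continuity correction is used.

    Parameters
    ----------
    x, y : array-like
        Non-empty value vectors (x is the putatively larger group for
        ``alternative="greater"``).
    alternative : str
        ``"greater"``, ``"less"``, or ``"two-sided"``.

    Returns ``(U, p)`` where U is the statistic of the x sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0

    if n <= exact_max_n:
        u_all = np.array([
            ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            for idx in combinations(range(n), nx)
        ])
        if alternative == "greater":
            p = np.mean(u_all >= u_obs - _EPS)
        elif alternative == "less":
            p = np.mean(u_all <= u_obs + _EPS)
        else:
            p = np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - _EPS)
        return float(u_obs), float(p)

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # every observation tied
        return float(u_obs), 1.0
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u_obs - mu + 0.5) / sigma
        p = stats.norm.cdf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return float(u_obs), float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1 and mapped back
    to the input order.  Elementwise ``q >= p`` always holds.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Depth-specificity classification
# ---------------------------------------------------------------------------

def classify_depth_specific(abund: AbundanceMatrix, samples: SampleTable,
                            depth_cutoff: float = Thresholds.depth_cutoff,
                            alpha: float = Thresholds.alpha,
                            alternative: str = "greater",
                            detection_threshold: float = Thresholds.detection_threshold,
                            ) -> pd.DataFrame:
    """Label every genome as deep-sea-specific or not.

    For each genome a one-sided Mann-Whitney test compares its abundance
    in deep samples (depth strictly greater than ``depth_cutoff``) against
    all other samples; p values are BH-adjusted across the whole genome
    set (Rule 1, ``q < alpha``).  Genomes detected (value strictly above
    ``detection_threshold``) in at least one deep sample and in no other
    sample satisfy Rule 2 regardless of the test.  A genome is
    deep-sea-specific iff Rule 1 or Rule 2 holds; all-zero genomes are
    never specific.

    Returns a DataFrame indexed by genome_id with columns ``U``, ``p``,
    ``q``, ``rule`` (``overrepresentation`` / ``deep_only`` / ``none``)
    and ``is_deep_specific``.  The classification depends only on ranks
    and the zero pattern, so it is invariant to sample order and to
    rescaling all abundances by a positive constant.
    """
    common = [s for s in abund.sample_ids if s in samples.df.index]
    if len(common) < len(abund.sample_ids):
        missing = set(abund.sample_ids) - set(common)
        raise KeyError(f"samples missing metadata: {sorted(missing)}")
    deep_mask = samples.is_deep(depth_cutoff).reindex(abund.sample_ids).to_numpy()
    if deep_mask.sum() == 0:
        raise ValueError("no deep samples below the cutoff")
    if deep_mask.sum() == len(deep_mask):
        raise ValueError("no non-deep comparison samples")

    values = abund.values
    deep = values[:, deep_mask]
    other = values[:, ~deep_mask]

    u_stats = np.empty(values.shape[0])
    p_vals = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        u_stats[i], p_vals[i] = mann_whitney_u(deep[i], other[i],
                                               alternative=alternative)
    q_vals = bh_adjust(p_vals)

    detected_deep = (deep > detection_threshold).any(axis=1)
    detected_other = (other > detection_threshold).any(axis=1)
    rule2 = detected_deep & ~detected_other
    rule1 = q_vals < alpha
    any_signal = detected_deep | detected_other

    rule = np.where(rule2, "deep_only",
                    np.where(rule1 & any_signal, "overrepresentation", "none"))
    out = pd.DataFrame({
        "U": u_stats,
        "p": p_vals,
        "q": q_vals,
        "rule": rule,
        "is_deep_specific": rule != "none",
    }, index=pd.Index(abund.feature_ids, name="genome_id"))
    return out


def exclusivity(abund: AbundanceMatrix, target_samples: Iterable[str],
                detection_threshold: float = Thresholds.detection_threshold,
                ) -> pd.Series:
    """Flag features whose signal is confined to a target sample group.

    True iff the feature exceeds the detection threshold in at least one
    target sample and in none of the remaining samples of the matrix.
    Used, e.g., to find genomes exclusive to mesopelagic metagenomes at a
    single site.
    """
    targets = [str(s) for s in target_samples]
    if not targets:
        raise ValueError("target sample group is empty")
    unknown = set(targets) - set(abund.sample_ids)
    if unknown:
        raise KeyError(f"target samples not in matrix: {sorted(unknown)}")
    others = [s for s in abund.sample_ids if s not in set(targets)]
    in_target = (abund.df[targets] > detection_threshold).any(axis=1)
    in_other = (abund.df[others] > detection_threshold).any(axis=1) if others \
        else pd.Series(False, index=abund.df.index)
    out = in_target & ~in_other
    out.name = "exclusive"
    return out


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSummary:
    """Biogeographic sharing summary over deep samples.

    Attributes
    ----------
    per_region : DataFrame
        Indexed by region with columns ``n_detected`` (genomes with
        signal in >= 1 deep sample of the region), ``n_unique`` (genomes
        detected in that region only) and ``unique_fraction``.
    shared : DataFrame
        Symmetric region x region counts of genomes detected in both.
    n_regions : Series
        Per detected genome, the number of regions it occurs in.
    """

    per_region: pd.DataFrame
    shared: pd.DataFrame
    n_regions: pd.Series

    def fraction_in_at_least(self, k: int) -> float:
        """Fraction of detected genomes found in >= k regions."""
        if len(self.n_regions) == 0:
            return 0.0
        return float((self.n_regions >= k).mean())


def region_summary(abund: AbundanceMatrix, samples: SampleTable,
                   feature_ids: Iterable[str] | None = None,
                   depth_cutoff: float = Thresholds.depth_cutoff,
                   deep_only: bool = True,
                   detection_threshold: float = Thresholds.detection_threshold,
                   ) -> RegionSummary:
    """Presence, uniqueness and sharing of genomes across oceanic regions.

    Detection: value strictly above ``detection_threshold`` in at least
    one (deep, by default) sample of the region.  ``feature_ids``
    restricts the summary, e.g. to the deep-sea-specific genomes.
    """
    meta = samples.df.reindex(abund.sample_ids)
    if meta["sample_id"].isna().any():
        missing = [s for s in abund.sample_ids if s not in samples.df.index]
        raise KeyError(f"samples missing metadata: {missing}")
    if deep_only:
        meta = meta[meta["depth"] > depth_cutoff]
    if meta["region"].isna().any() or (meta["region"] == "").any():
        raise ValueError("every sample used in a region summary needs a region")

    df = abund.df
    if feature_ids is not None:
        df = df.loc[list(feature_ids)]

    regions = sorted(meta["region"].unique())
    presence = pd.DataFrame(False, index=df.index, columns=regions)
    for region in regions:
        cols = meta.index[meta["region"] == region]
        presence[region] = (df[cols] > detection_threshold).any(axis=1)

    detected = presence.any(axis=1)
    n_regions = presence.sum(axis=1)[detected]
    n_regions.name = "n_regions"

    per_region = pd.DataFrame(index=pd.Index(regions, name="region"))
    per_region["n_detected"] = presence.sum(axis=0)
    unique_mask = presence.to_numpy() & (presence.sum(axis=1).to_numpy() == 1)[:, None]
    per_region["n_unique"] = unique_mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = per_region["n_unique"] / per_region["n_detected"]
    per_region["unique_fraction"] = frac.fillna(0.0)

    pm = presence.to_numpy().astype(int)
    shared = pd.DataFrame(pm.T @ pm, index=regions, columns=regions)
    return RegionSummary(per_region=per_region, shared=shared, n_regions=n_regions)
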