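"""Community-ecology statistics for ASV count tables.

Implements the metabarcoding workflow: rarefaction to a common read depth,
Hellinger transformation, Bray-Curtis dissimilarity, one-way permutational
multivariate analysis of variance (PERMANOVA) with a pseudo-F statistic,
and Levins' standardized niche breadth (BA) with a one-sided group
comparison.

PERMANOVA uses the distance-based one-way decomposition
``SS_T = (1/N) * sum_{i<j} d_ij^2``,
``SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2``, ``SS_A = SS_T - SS_W``
and ``F = (SS_A / (a - 1)) / (SS_W / (N - a))``; the p value is the
permutation tail probability ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import get_logger
from .core_tables import AbundanceMatrix, SampleTable
from .depth_biogeography import mann_whitney_u

__all__ = [
    "rarefy",
    "rarefy_table",
    "hellinger",
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "levins_ba",
    "niche_breadth_table",
    "compare_breadth",
]

logger = get_logger(__name__)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts: np.ndarray, depth: int,
           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Subsample one sample's feature counts to ``depth`` reads without
    replacement (multivariate hypergeometric draw).

    Raises if the sample has fewer than ``depth`` reads.  The output
    always sums exactly to ``depth``; a fixed seed gives identical draws.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.astype(int).copy()
    rng = np.random.default_rng(rng)
    return rng.multivariate_hypergeometric(counts.astype(int), depth)


def rarefy_table(matrix: AbundanceMatrix, depth: int | None = None,
                 rng: np.random.Generator | int | None = None
                 ) -> AbundanceMatrix:
    """Rarefy every sample of a count table to a common depth.

    ``depth=None`` uses the minimum per-sample total.  Samples with fewer
    reads than an explicit depth are dropped with a logged warning rather
    than raising, since partial failures are routine at table level.
    """
    if matrix.unit != "counts":
        raise ValueError("rarefaction requires a count matrix")
    rng = np.random.default_rng(rng)
    totals = matrix.df.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    keep = totals.index[totals >= depth].tolist()
    dropped = sorted(set(matrix.sample_ids) - set(keep))
    if dropped:
        logger.warning("dropping %d samples below rarefaction depth %d: %s",
                       len(dropped), depth, dropped)
    out = {}
    for sid in keep:
        out[sid] = rarefy(matrix.df[sid].to_numpy(), depth, rng)
    rarefied = pd.DataFrame(out, index=matrix.df.index)
    return AbundanceMatrix(rarefied, unit="counts")


# ---------------------------------------------------------------------------
# Transforms and distances
# ---------------------------------------------------------------------------

def hellinger(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Hellinger transform per sample: ``h_ij = sqrt(x_ij / sum_i x_ij)``.

    An all-zero sample stays all-zero (logged).  After the transform each
    non-empty sample has unit sum of squares.
    """
    values = matrix.values.astype(float)
    totals = values.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.warning("Hellinger transform: %d all-zero samples left as zero",
                       int(empty.sum()))
    safe = np.where(empty, 1.0, totals)
    out = np.sqrt(values / safe)
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.df.index,
                                        columns=matrix.df.columns),
                           unit="relative")


def bray_curtis(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns).

    ``d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i)``, with d = 0 when
    both samples are entirely empty.  Returns a symmetric sample x sample
    DataFrame with zero diagonal, values in [0, 1].
    """
    values = matrix.values.T.astype(float)  # samples x features
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(values[i] - values[i + 1:]).sum(axis=1)
        tot = (values[i] + values[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(tot == 0, 0.0, diff / np.where(tot == 0, 1.0, tot))
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA summary."""

    pseudo_F: float
    R2: float
    p: float
    n_permutations: int

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int
              ) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _ss_within(d2, codes, n_groups)
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        f = np.inf if ss_a > 0 else 0.0
    else:
        f = (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))
    r2 = 0.0 if ss_t == 0 else ss_a / ss_t
    return f, r2, ss_t


def _multiset_permutations(counts: np.ndarray):
    """All distinct arrangements of group codes with the given counts."""
    n = int(counts.sum())
    out = np.empty(n, dtype=int)

    def rec(pos, remaining):
        if pos == n:
            yield out.copy()
            return
        for g in range(len(remaining)):
            if remaining[g]:
                remaining[g] -= 1
                out[pos] = g
                yield from rec(pos + 1, remaining)
                remaining[g] += 1

    yield from rec(0, list(counts))


def permanova(distances: pd.DataFrame, groups: pd.Series,
              n_permutations: int = 9999,
              rng: np.random.Generator | int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutation.

    When the number of distinct label arrangements does not exceed
    ``n_permutations`` the full permutation distribution is enumerated and
    the p value is exact (``#{F_perm >= F_obs} / n_arrangements``, the
    observed arrangement included); otherwise ``n_permutations`` uniform
    random permutations are drawn and ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)``.

    Parameters
    ----------
    distances : DataFrame
        Symmetric sample x sample dissimilarities, zero diagonal.
    groups : Series
        Sample id -> group label; at least two groups, each with at least
        two samples.
    n_permutations : int
        Number of uniform random label permutations (default 9,999).
    rng : Generator or int
        Seeded randomness source; same seed, same p value.
    """
    ids = list(distances.index)
    if list(distances.columns) != ids:
        raise ValueError("distance matrix rows and columns must match")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = groups.reindex(ids)
    if labels.isna().any():
        raise KeyError("every sample needs a group label")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")

    d2 = d ** 2
    f_obs, r2, _ = _pseudo_f(d2, codes, a)

    from math import comb
    n_arrangements = 1
    remaining = len(codes)
    for c in counts:
        n_arrangements *= comb(remaining, int(c))
        remaining -= int(c)

    if n_arrangements <= n_permutations:
        hits = sum(
            1 for perm in _multiset_permutations(counts)
            if _pseudo_f(d2, perm, a)[0] >= f_obs - 1e-12
        )
        p = hits / n_arrangements
        n_done = n_arrangements
    else:
        rng = np.random.default_rng(rng)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            f_perm, _, _ = _pseudo_f(d2, perm, a)
            if f_perm >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        n_done = n_permutations
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p),
                           n_permutations=n_done)


# ---------------------------------------------------------------------------
# Niche breadth
# ---------------------------------------------------------------------------

def levins_ba(profile: np.ndarray) -> tuple[float, float]:
    """Levins niche breadth for one feature's abundance profile.

    The profile over n samples is renormalised to proportions p_j; Levins'
    ``B = 1 / sum_j p_j^2`` lies in [1, n] and the standardized index
    ``BA = (B - 1) / (n - 1)`` lies in [0, 1]: 0 means occupancy of a
    single sample, 1 a perfectly uniform spread.  Requires n >= 2 and a
    non-zero profile; invariant to positive rescaling.

    Returns ``(B, BA)``.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    if n < 2:
        raise ValueError("niche breadth needs at least two samples")
    if (profile < 0).any():
        raise ValueError("profile values must be >= 0")
    total = profile.sum()
    if total == 0:
        raise ValueError("all-zero profile; niche breadth undefined")
    p = profile / total
    b = 1.0 / np.sum(p ** 2)
    ba = (b - 1.0) / (n - 1.0)
    return float(b), float(ba)


def niche_breadth_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """BA for every feature of an abundance table (columns = the paired
    sample set over which breadth is measured).

    Features with all-zero profiles are skipped with a logged note.
    Returns a DataFrame indexed by feature id with columns ``B``, ``BA``,
    ``n``.
    """
    rows = {}
    n = len(matrix.sample_ids)
    skipped = 0
    for fid, profile in matrix.df.iterrows():
        if profile.sum() == 0:
            skipped += 1
            continue
        b, ba = levins_ba(profile.to_numpy())
        rows[fid] = {"B": b, "BA": ba, "n": n}
    if skipped:
        logger.info("niche breadth: skipped %d all-zero features", skipped)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out


def compare_breadth(ba_deep: np.ndarray, ba_surface: np.ndarray
                    ) -> tuple[float, float]:
    """One-sided Mann-Whitney test that deep/mesopelagic BA values exceed
    surface BA values.  Returns ``(U, p)``."""
    return mann_whitney_u(np.asarray(ba_deep, dtype=float),
                          np.asarray(ba_surface, dtype=float),
                          alternative="greater")
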