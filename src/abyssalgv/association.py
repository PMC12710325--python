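"""Functional enrichment and co-occurrence association tests.

Two questions about the deep-sea-specific genome set are answered here:

* Which annotation terms (KEGG orthologs, Pfam domains) are over- or
  under-represented among deep-sea-specific genomes?  Genome-level
  presence/absence of each term is cross-tabulated against the
  depth-specificity label and tested with a two-sided Fisher exact test,
  BH-corrected across terms; rare terms (present in <= 2 genomes) are
  excluded before testing.
* Which microeukaryote ASVs co-occur with giant-virus transcriptional
  activity?  Spearman rank correlations are computed over the shared
  (mesopelagic) sample set for every virus x ASV pair; a pair is a
  candidate host link when rho > 0 and p < alpha (uncorrected by default,
  with an optional BH mode).

The Fisher p value is the minimum-likelihood two-sided sum: over all
tables with the observed margins, the hypergeometric probabilities not
exceeding that of the observed table (within a 1e-7 relative tolerance).
Spearman p values are exact permutation enumerations for n <= 8 and the
t approximation beyond.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds, get_logger
from .core_tables import AbundanceMatrix
from .depth_biogeography import bh_adjust

__all__ = ["fisher_exact", "enrich_terms", "spearman", "cooccurrence"]

logger = get_logger(__name__)

_REL_TOL = 1e-7


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates every table sharing the observed margins and sums the
    hypergeometric probabilities that do not exceed the observed table's
    probability (relative tolerance 1e-7 on the comparison) — the
    minimum-likelihood convention.
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_TOL)].sum()))


def enrich_terms(annotations: pd.DataFrame, labels: pd.Series,
                 alpha: float = Thresholds.alpha,
                 min_total_frequency: int = 3) -> pd.DataFrame:
    """Term-by-term enrichment of deep-sea-specific genomes.

    Parameters
    ----------
    annotations : DataFrame
        Genome x term gene counts; presence means count >= 1.
    labels : Series
        Genome id -> bool (True = deep-sea-specific); must cover every
        genome in ``annotations`` and contain both classes.
    alpha : float
        BH-adjusted significance level.
    min_total_frequency : int
        Minimum number of genomes carrying a term for it to be tested
        (default 3, i.e. terms with total frequency <= 2 are excluded).

    Returns a DataFrame indexed by term with the 2x2 cells
    ``a`` (deep-specific, term present), ``b`` (deep-specific, absent),
    ``c`` (other, present), ``d`` (other, absent), the two-sided Fisher
    ``p``, BH ``q`` and ``enriched_in`` (``deep`` / ``non_deep`` /
    ``none``), assigned by the side with the greater relative frequency
    when ``q < alpha``.
    """
    labels = labels.reindex(annotations.index.astype(str))
    if labels.isna().any():
        missing = annotations.index[labels.isna().to_numpy()].tolist()
        raise KeyError(f"genomes without labels: {missing}")
    labels = labels.astype(bool)
    n_deep = int(labels.sum())
    n_other = int((~labels).sum())
    if n_deep == 0 or n_other == 0:
        raise ValueError("labels must contain both classes")

    presence = annotations >= 1
    a_col = presence.loc[labels.to_numpy()].sum(axis=0)
    c_col = presence.loc[(~labels).to_numpy()].sum(axis=0)
    total = a_col + c_col
    tested = total.index[total >= min_total_frequency]
    n_excluded = len(total) - len(tested)
    if n_excluded:
        logger.info("enrichment: excluded %d rare terms (total frequency < %d)",
                    n_excluded, min_total_frequency)

    rows = []
    for term in tested:
        a = int(a_col[term])
        c = int(c_col[term])
        b, d = n_deep - a, n_other - c
        rows.append({"term_id": term, "a": a, "b": b, "c": c, "d": d,
                     "p": fisher_exact(a, b, c, d)})
    out = pd.DataFrame(rows, columns=["term_id", "a", "b", "c", "d", "p"])
    if len(out) == 0:
        out["q"] = []
        out["enriched_in"] = []
        return out.set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    freq_deep = out["a"] / n_deep
    freq_other = out["c"] / n_other
    side = np.where(freq_deep > freq_other, "deep",
                    np.where(freq_other > freq_deep, "non_deep", "none"))
    out["enriched_in"] = np.where(out["q"] < alpha, side, "none")
    return out.set_index("term_id")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8
             ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    rho is the Pearson correlation of midranks.  For n <= ``exact_max_n``
    the p value is exact: all n! orderings of one rank vector are
    enumerated and the fraction with |rho| at least the observed |rho| is
    reported.  For larger n the usual t approximation is used.

    Constant input vectors leave rho undefined and raise; callers that
    scan many pairs should catch and exclude those pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_max_n:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p

    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
    p = float(min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2)))
    return rho, p


def cooccurrence(gv_abund: AbundanceMatrix, asv_abund: AbundanceMatrix,
                 alpha: float = Thresholds.alpha,
                 bh_correct: bool = False) -> pd.DataFrame:
    """Score all giant-virus x ASV pairs for positive co-occurrence.

    Profiles are matched on the shared sample set (>= 3 samples
    required).  Pairs involving a constant profile are excluded with a
    logged reason.  ``significant_positive`` requires rho > 0 and
    p < alpha on raw p values by default; with ``bh_correct=True`` the BH
    q value is thresholded instead.

    Returns a DataFrame with columns ``gv_id``, ``asv_id``, ``rho``,
    ``p`` (plus ``q`` when correcting) and ``significant_positive``.
    """
    shared = [s for s in gv_abund.sample_ids if s in set(asv_abund.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    gv = gv_abund.df[shared]
    asv = asv_abund.df[shared]

    const_gv = [g for g in gv.index if np.ptp(gv.loc[g].to_numpy()) == 0]
    const_asv = [a for a in asv.index if np.ptp(asv.loc[a].to_numpy()) == 0]
    if const_gv:
        logger.warning("excluding %d constant-abundance viruses: %s",
                       len(const_gv), const_gv)
    if const_asv:
        logger.warning("excluding %d constant-abundance ASVs", len(const_asv))

    rows = []
    for g in gv.index.difference(const_gv, sort=False):
        xg = gv.loc[g].to_numpy()
        for a in asv.index.difference(const_asv, sort=False):
            rho, p = spearman(xg, asv.loc[a].to_numpy())
            rows.append({"gv_id": g, "asv_id": a, "rho": rho, "p": p})
    out = pd.DataFrame(rows, columns=["gv_id", "asv_id", "rho", "p"])
    if len(out) == 0:
        out["significant_positive"] = []
        return out
    if bh_correct:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant_positive"] = (out["rho"] > 0) & (out["q"] < alpha)
    else:
        out["significant_positive"] = (out["rho"] > 0) & (out["p"] < alpha)
    return out
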