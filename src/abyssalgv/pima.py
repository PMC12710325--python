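"""Phylogeny-informed MAG assessment (PIMA).

Genome completeness/contamination checks built for cellular organisms do
not transfer to giant viruses, whose gene content varies enormously between
lineages.  PIMA instead assesses each MAG against its own phylogenetic
neighbourhood: a rooted marker-gene tree is cut into rank-comparable
lineages using relative evolutionary divergence (RED), a per-lineage core
gene set is derived from orthologous-group (OG) prevalence, and each member
is scored for

* consistency — the fraction of lineage core OGs it carries (a
  completeness proxy), and
* redundancy — the fraction of core OGs whose copy number exceeds the
  lineage-wide mode (a contamination/chimera proxy).

MAGs with redundancy strictly above 50% are removed as likely chimeric.

RED follows the GTDB convention: RED(root) = 0, RED(leaf) = 1, and for an
internal node n with parent p at branch distance d,
``RED(n) = RED(p) + (d / u) * (1 - RED(p))`` where u is the mean branch
length from p to all leaves descending through n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .config import Thresholds, get_logger
from .core_tables import is_rooted

__all__ = ["red", "delineate_lineages", "consistency", "redundancy",
           "core_ogs", "pima_assess"]

logger = get_logger(__name__)


def _ensure_rooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a tree whose seed node is a basal polytomy."""
    if is_rooted(tree):
        return tree
    logger.warning("input tree is unrooted; midpoint-rooting")
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def red(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Relative evolutionary divergence for every node of a rooted tree.

    Returns a mapping from node to RED in [0, 1] (0 at the root, 1 at each
    leaf).  A zero-length branch leaves the child at its parent's RED.
    Unrooted input (basal polytomy) is midpoint-rooted first, with a
    logged warning; RED values are then reported on the rerooted clone, so
    callers needing the tree should use :func:`pima_assess` or reroot
    themselves beforehand.
    """
    tree = _ensure_rooted(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("branch lengths must be >= 0")

    # mean branch-length distance from each node down to its leaves
    mean_leaf_dist: dict[dendropy.Node, float] = {}
    n_leaves: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mean_leaf_dist[node] = 0.0
            n_leaves[node] = 1
        else:
            total, count = 0.0, 0
            for child in node.child_nodes():
                d = child.edge.length or 0.0
                total += n_leaves[child] * (d + mean_leaf_dist[child])
                count += n_leaves[child]
            mean_leaf_dist[node] = total / count
            n_leaves[node] = count

    values: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        elif node.is_leaf():
            values[node] = 1.0
        else:
            p = values[node.parent_node]
            d = node.edge.length or 0.0
            u = d + mean_leaf_dist[node]
            values[node] = p if u == 0 else p + (d / u) * (1.0 - p)
            values[node] = min(max(values[node], 0.0), 1.0)
    return values


def delineate_lineages(tree: dendropy.Tree,
                       red_values: dict[dendropy.Node, float] | None = None,
                       threshold: float = Thresholds.red_threshold,
                       ) -> pd.Series:
    """Cut a rooted tree into lineages at a RED threshold.

    Lineages are the maximal subtrees rooted at the shallowest node (the
    one closest to the root on each path) whose RED is >= ``threshold``;
    when qualifying nodes are nested, the cut is at the shallower one.
    Since leaves have RED 1, every leaf not under a qualifying internal
    node becomes a singleton lineage, so the result is always a partition
    of the leaves.

    Returns a Series mapping leaf name -> lineage id (``"L001"`` ...),
    numbered in tree traversal order.
    """
    tree = _ensure_rooted(tree)
    if red_values is None or tree.seed_node not in red_values:
        red_values = red(tree)
    assignment: dict[str, str] = {}
    counter = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if red_values[node] >= threshold:
            counter += 1
            lid = f"L{counter:03d}"
            for leaf in node.leaf_iter():
                assignment[leaf.taxon.label] = lid
        else:
            stack.extend(reversed(node.child_nodes()))
    out = pd.Series(assignment, name="lineage_id")
    out.index.name = "genome_id"
    return out


def core_ogs(member_ids: list[str], og_table: pd.DataFrame,
             core_fraction: float = Thresholds.core_fraction) -> list[str]:
    """OGs present (copy >= 1) in strictly more than ``core_fraction`` of
    the lineage members."""
    if not member_ids:
        raise ValueError("lineage has no members")
    presence = (og_table.loc[member_ids] >= 1).mean(axis=0)
    return presence.index[presence > core_fraction].tolist()


def consistency(genome_id: str, core: list[str], og_table: pd.DataFrame) -> float:
    """Fraction of lineage core OGs present (copy >= 1) in the genome."""
    if not core:
        raise ValueError("core OG set is empty; lineage too small to assess")
    row = og_table.loc[genome_id, core]
    return float((row >= 1).mean())


def _mode_smallest(values: np.ndarray) -> int:
    """Mode of an integer sample; ties broken toward the smallest value."""
    counts = np.bincount(values.astype(int))
    return int(np.argmax(counts))


def redundancy(genome_id: str, core: list[str], og_table: pd.DataFrame,
               member_ids: list[str]) -> float:
    """Fraction of core OGs whose copy number in this genome strictly
    exceeds the mode copy number across the lineage members.

    The per-OG mode is taken over all lineage members (ties toward the
    smallest copy number, the conservative choice — it flags more
    duplication).  Requires >= 2 members for the mode to be meaningful.
    """
    if not core:
        raise ValueError("core OG set is empty; lineage too small to assess")
    if len(member_ids) < 2:
        raise ValueError("redundancy undefined for a singleton lineage")
    sub = og_table.loc[member_ids, core].to_numpy()
    modes = np.array([_mode_smallest(sub[:, j]) for j in range(len(core))])
    own = og_table.loc[genome_id, core].to_numpy()
    return float(np.mean(own > modes))


def pima_assess(tree: dendropy.Tree, og_table: pd.DataFrame,
                red_threshold: float = Thresholds.red_threshold,
                core_fraction: float = Thresholds.core_fraction,
                redundancy_cutoff: float = Thresholds.redundancy_cutoff,
                ) -> pd.DataFrame:
    """Full PIMA pass: delineate lineages, derive per-lineage cores, score
    every member, and flag removals.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted marker-gene tree whose leaf names are genome ids
        (midpoint-rooted with a warning if unrooted).
    og_table : DataFrame
        Genome x OG integer copy numbers covering every leaf.
    red_threshold : float
        RED value at which lineages are cut (default 0.65, roughly
        genus/family level for giant viruses).
    core_fraction : float
        Prevalence defining lineage core OGs (strictly greater than).
    redundancy_cutoff : float
        Redundancy above which (strictly) a MAG is removed.

    Returns a DataFrame indexed by genome_id with columns ``lineage_id``,
    ``n_members``, ``consistency``, ``redundancy``, ``removed``.  For
    singleton lineages (or lineages with an empty core set) consistency
    and redundancy are NaN and the MAG is flagged unassessable, never
    removed.
    """
    tree = _ensure_rooted(tree)
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(leaves) - set(og_table.index.astype(str))
    if missing:
        raise KeyError(f"tree leaves missing from OG table: {sorted(missing)}")
    lineages = delineate_lineages(tree, threshold=red_threshold)

    rows = []
    for lid, members in lineages.groupby(lineages):
        member_ids = members.index.tolist()
        core: list[str] = []
        if len(member_ids) >= 2:
            core = core_ogs(member_ids, og_table, core_fraction)
        if not core:
            if len(member_ids) >= 2:
                logger.warning("lineage %s has no core OGs; members unassessable", lid)
            for gid in member_ids:
                rows.append({"genome_id": gid, "lineage_id": lid,
                             "n_members": len(member_ids),
                             "consistency": np.nan, "redundancy": np.nan,
                             "removed": False})
            continue
        for gid in member_ids:
            c = consistency(gid, core, og_table)
            r = redundancy(gid, core, og_table, member_ids)
            rows.append({"genome_id": gid, "lineage_id": lid,
                         "n_members": len(member_ids),
                         "consistency": c, "redundancy": r,
                         "removed": r > redundancy_cutoff})
    out = pd.DataFrame(rows).set_index("genome_id")
    return out.loc[sorted(out.index)]
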