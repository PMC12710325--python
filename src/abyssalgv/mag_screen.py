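"""Screening, decontamination, and dereplication of giant-virus bins.

The decision rules operate on evidence tables produced upstream (marker-gene
hits, per-contig classifier verdicts, pairwise ANI) and turn raw metagenomic
bins into a screened, decontaminated, dereplicated set of giant-virus MAGs:

1. gene-density ("NCLDV") index screen for nucleocytovirus candidates,
2. HK97 major-capsid-protein rule for mirusvirus candidates,
3. per-contig decontamination by an OR-rule over two viral classifiers,
4. genome-size window filter (50 kbp - 3 Mbp),
5. single-linkage ANI clustering and representative selection.

The exact published form of the gene-density index is defined in external
tooling; the default used here — distinct markers present per Mb of genome —
is a documented reconstruction and the index function is pluggable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import Thresholds, get_logger
from .core_tables import ANIMatrix, EvidenceTable, GenomeRecord, MarkerHitTable

__all__ = [
    "ncldv_index",
    "screen_ncv",
    "screen_mv",
    "decontaminate",
    "cluster_ani",
    "select_representative",
    "recovery_percent",
    "SIZE_MIN_BP",
    "SIZE_MAX_BP",
    "MV_EVALUE_MAX",
    "MV_BITSCORE_MIN",
]

logger = get_logger(__name__)

#: Genome-size window for retained giant-virus MAGs.
SIZE_MIN_BP = 50_000
SIZE_MAX_BP = 3_000_000

#: HK97-MCP hit thresholds for the mirusvirus rule (strict comparisons).
MV_EVALUE_MAX = 1.0e-3
MV_BITSCORE_MIN = 100.0

#: Index function signature: (n distinct markers present, genome size bp) -> score.
IndexFn = Callable[[int, int], float]


def _markers_per_mb(n_markers: int, size_bp: int) -> float:
    return n_markers / (size_bp / 1e6)


def ncldv_index(genome: GenomeRecord, marker_row: pd.Series | Mapping[str, int],
                index_fn: IndexFn | None = None) -> float:
    """Gene-density index of a bin: distinct conserved giant-virus markers
    present (copy >= 1) per Mb of genome, by default.

    Presence ignores hit scores; a marker counts once however many copies.
    Pass ``index_fn`` to substitute a different formula.
    """
    if genome.size <= 0:
        raise ValueError(f"{genome.genome_id}: genome size must be > 0")
    n_present = int(sum(1 for v in dict(marker_row).values() if v >= 1))
    fn = index_fn or _markers_per_mb
    return float(fn(n_present, genome.size))


def screen_ncv(bins: Mapping[str, GenomeRecord], markers: MarkerHitTable,
               threshold: float = Thresholds.ncldv_threshold,
               index_fn: IndexFn | None = None) -> pd.DataFrame:
    """Flag candidate nucleocytovirus MAGs by the gene-density index.

    A bin is a candidate iff its index is strictly greater than
    ``threshold`` (default 5.75).  Every bin must have a marker row, which
    may be all-zero.  Also reports the genome-size window filter
    (50 kbp <= size <= 3 Mbp), applied to the sizes as given (i.e. after
    any decontamination the caller has performed).

    Returns a DataFrame indexed by genome_id with columns
    ``ncldv_index``, ``is_ncv_candidate``, ``passed_size_filter``, ``size``.
    """
    missing = set(bins) - set(markers.genome_ids)
    if missing:
        raise KeyError(f"bins missing from marker table: {sorted(missing)}")
    rows = []
    for gid in sorted(bins):
        rec = bins[gid]
        idx = ncldv_index(rec, markers.counts.loc[gid], index_fn=index_fn)
        rows.append({
            "genome_id": gid,
            "size": rec.size,
            "ncldv_index": idx,
            "is_ncv_candidate": idx > threshold,
            "passed_size_filter": SIZE_MIN_BP <= rec.size <= SIZE_MAX_BP,
        })
    out = pd.DataFrame(rows, columns=["genome_id", "size", "ncldv_index",
                                      "is_ncv_candidate", "passed_size_filter"])
    return out.set_index("genome_id")


def screen_mv(markers: MarkerHitTable, mcp_marker: str = "HK97-MCP",
              evalue_max: float = MV_EVALUE_MAX,
              bitscore_min: float = MV_BITSCORE_MIN) -> pd.Series:
    """Flag mirusvirus candidates: at least one HK97 major-capsid-protein
    hit with E-value < 1e-3 AND bit score > 100 (both strict).

    Requires the scored hit table; returns a boolean Series over all
    genomes in the copy-count table.
    """
    if markers.hits is None:
        raise ValueError("screen_mv requires per-hit scores (hits table)")
    flags = pd.Series(False, index=markers.counts.index, name="is_mv_candidate")
    hits = markers.hits
    ok = (
        (hits["marker_id"] == mcp_marker)
        & (hits["evalue"] < evalue_max)
        & (hits["bitscore"] > bitscore_min)
    )
    for gid in hits.loc[ok, "genome_id"].unique():
        if gid in flags.index:
            flags.loc[gid] = True
    return flags


def decontaminate(contig_ids: Iterable[str], evidence: EvidenceTable,
                  missing: str = "drop") -> list[str]:
    """Retain the contigs of a bin that look viral by either classifier.

    A contig is retained iff its VirSorter max-score group is ``"NCLDV"``
    OR its ViralRecall score is strictly greater than 0.  Contigs absent
    from the evidence table are dropped by default (``missing="drop"``) or
    raise (``missing="error"``).
    """
    if missing not in ("drop", "error"):
        raise ValueError("missing must be 'drop' or 'error'")
    retained = []
    for cid in contig_ids:
        if cid not in evidence.df.index:
            if missing == "error":
                raise KeyError(f"contig {cid!r} missing from evidence table")
            logger.warning("contig %s has no evidence row; dropped", cid)
            continue
        row = evidence.df.loc[cid]
        if row["virsorter_group"] == "NCLDV" or row["viralrecall_score"] > 0:
            retained.append(cid)
    return retained


def cluster_ani(ani: ANIMatrix,
                threshold: float = Thresholds.ani_threshold) -> pd.Series:
    """Single-linkage dereplication clusters at an ANI threshold.

    Clusters are the connected components of the graph whose edges join
    genome pairs with ANI >= ``threshold`` (dRep's ``--clusterAlg single``
    behaviour on a precomputed identity matrix).  Returns a Series
    genome_id -> cluster_id, with cluster ids numbered by order of first
    appearance of a member in the (sorted) genome list.
    """
    values = ani.df.to_numpy()
    adjacency = csr_matrix(values >= threshold)
    n_comp, labels = connected_components(adjacency, directed=False)
    ids = ani.genome_ids
    # renumber components so cluster ids are deterministic in genome order
    remap: dict[int, int] = {}
    out = {}
    for gid, lab in zip(ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[gid] = remap[lab]
    return pd.Series(out, name="cluster_id")


def select_representative(members: Sequence[GenomeRecord]) -> str:
    """Pick a cluster representative: the highest-N50 genome among the top
    30% largest members.

    The candidate pool is the ``ceil(0.3 * n)`` largest genomes by size
    (so never empty); among them the genome with the greatest N50 wins,
    with ties broken toward the lexicographically smallest genome id.
    Permutation-invariant over member order.
    """
    if len(members) == 0:
        raise ValueError("cluster has no members")
    k = math.ceil(0.3 * len(members))
    # sort by (size desc, id asc) for a deterministic top-k cut
    pool = sorted(members, key=lambda r: (-r.size, r.genome_id))[:k]
    best = min(pool, key=lambda r: (-r.n50, r.genome_id))
    return best.genome_id


def recovery_percent(recovered_ids: Iterable[str],
                     reference_ids: Iterable[str]) -> float:
    """Percentage of a reference marker-sequence set recovered in the MAGs.

    Used to gauge how completely a MAG catalogue captures the lineages
    present in the raw assembly — e.g. the fraction of giant-virus-origin
    family-B DNA polymerase (PolB) sequences found inside binned genomes.
    Ids in ``recovered_ids`` not present in the reference are ignored.
    """
    reference = set(reference_ids)
    if not reference:
        raise ValueError("reference set is empty")
    recovered = set(recovered_ids) & reference
    return 100.0 * len(recovered) / len(reference)
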