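"""Shared domain types, readers/writers, and elementary genome computations.

Everything downstream of assembly/binning/mapping is driven by a handful of
plain tables: per-sample metadata, non-negative feature-by-sample abundance
matrices (TPM or counts), genome-by-gene copy tables, per-contig classifier
evidence, and pairwise ANI matrices.  This module defines those containers
as thin, validated wrappers around :class:`pandas.DataFrame`, with TSV
round-trip IO (UTF-8, header row, ``.`` decimal, values preserved to 12
significant digits), plus the two elementary per-genome computations used
throughout: TPM normalisation and N50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .config import get_logger

__all__ = [
    "SampleTable",
    "AbundanceMatrix",
    "GenomeRecord",
    "MarkerHitTable",
    "EvidenceTable",
    "ANIMatrix",
    "compute_tpm",
    "compute_n50",
    "read_bins",
    "write_bins",
    "read_tree",
    "write_tree",
    "is_rooted",
    "FLOAT_FORMAT",
]

logger = get_logger(__name__)

#: TSV float format: 12 significant digits, enough for lossless round trips
#: of every statistic the pipeline produces.
FLOAT_FORMAT = "%.12g"

FRACTIONS = frozenset({"pico", "total", "nano_micro"})
ASSAYS = frozenset({"metagenome", "metatranscriptome", "rDNA", "rRNA"})


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

class SampleTable:
    """Per-sample metadata: depth (m), region, date, size fraction, assay.

    The table drives every stratification in the pipeline; the only derived
    quantity is the depth layer (deep iff ``depth > depth_cutoff``).
    """

    REQUIRED = ("sample_id", "depth", "region", "date", "fraction", "assay")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        df["depth"] = pd.to_numeric(df["depth"], errors="raise").astype(float)
        if not np.isfinite(df["depth"]).all() or (df["depth"] < 0).any():
            raise ValueError("depths must be finite and >= 0")
        bad_frac = set(df["fraction"]) - FRACTIONS
        if bad_frac:
            raise ValueError(f"unknown size fractions: {sorted(bad_frac)}")
        bad_assay = set(df["assay"]) - ASSAYS
        if bad_assay:
            raise ValueError(f"unknown assays: {sorted(bad_assay)}")
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def is_deep(self, depth_cutoff: float = 200.0) -> pd.Series:
        """Boolean per sample: strictly deeper than the cutoff."""
        return self.df["depth"] > depth_cutoff

    def layer(self, depth_cutoff: float = 200.0) -> pd.Series:
        return self.is_deep(depth_cutoff).map({True: "deep", False: "surface"})

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.df.index)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return SampleTable(self.df.loc[ids].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

class AbundanceMatrix:
    """Non-negative feature x sample matrix (TPM, read counts, or relative
    abundance), features as rows.

    Parameters
    ----------
    df : DataFrame
        Rows indexed by feature id, columns by sample id.
    unit : str
        One of ``"tpm"``, ``"counts"``, ``"relative"`` — informational tag
        carried through the pipeline.
    """

    UNITS = ("tpm", "counts", "relative")

    def __init__(self, df: pd.DataFrame, unit: str = "tpm"):
        if unit not in self.UNITS:
            raise ValueError(f"unit must be one of {self.UNITS}, got {unit!r}")
        if df.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if (values < 0).any():
            raise ValueError("abundance values must be >= 0")
        self.df = df.astype(float)
        self.df.index = self.df.index.astype(str)
        self.df.columns = self.df.columns.astype(str)
        self.df.index.name = "feature_id"
        self.unit = unit

    @property
    def feature_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.df.loc[:, list(sample_ids)], unit=self.unit)

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str = "tpm") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        non_numeric = df.columns[
            [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
        ]
        if len(non_numeric):
            raise ValueError(f"non-numeric cells in columns: {list(non_numeric)}")
        return cls(df, unit=unit)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Genome records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRecord:
    """A binned genome: its contigs' lengths (bp) and optional GC fraction."""

    genome_id: str
    contig_lengths: tuple[int, ...]
    gc: float | None = None
    contig_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.contig_lengths) == 0:
            raise ValueError(f"{self.genome_id}: at least one contig required")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError(f"{self.genome_id}: contig lengths must be > 0")
        if self.gc is not None and not 0 <= self.gc <= 1:
            raise ValueError(f"{self.genome_id}: gc must lie in [0, 1]")
        if self.contig_ids and len(self.contig_ids) != len(self.contig_lengths):
            raise ValueError(f"{self.genome_id}: contig ids/lengths mismatch")
        if not self.contig_ids:
            object.__setattr__(
                self,
                "contig_ids",
                tuple(f"{self.genome_id}_c{i + 1}" for i in range(len(self.contig_lengths))),
            )

    @property
    def size(self) -> int:
        """Genome size in bp (sum of contig lengths)."""
        return int(sum(self.contig_lengths))

    @property
    def n50(self) -> int:
        return compute_n50(self.contig_lengths)


def read_bins(path: str | Path) -> dict[str, GenomeRecord]:
    """Read a long-format bin table (genome_id, contig_id, length[, gc])."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str})
    for col in ("genome_id", "contig_id", "length"):
        if col not in df.columns:
            raise ValueError(f"bin table missing column {col!r}")
    records = {}
    for gid, grp in df.groupby("genome_id", sort=True):
        gc = None
        if "gc" in df.columns and grp["gc"].notna().any():
            gc = float(grp["gc"].iloc[0])
        records[gid] = GenomeRecord(
            genome_id=gid,
            contig_lengths=tuple(int(x) for x in grp["length"]),
            contig_ids=tuple(grp["contig_id"]),
            gc=gc,
        )
    return records


def write_bins(records: Mapping[str, GenomeRecord], path: str | Path) -> None:
    rows = []
    for rec in records.values():
        for cid, length in zip(rec.contig_ids, rec.contig_lengths):
            rows.append(
                {"genome_id": rec.genome_id, "contig_id": cid,
                 "length": length, "gc": rec.gc}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Marker hits
# ---------------------------------------------------------------------------

class MarkerHitTable:
    """Genome x marker copy-count matrix with optional scored hits.

    ``counts`` holds non-negative integer copy numbers (genomes as rows).
    ``hits`` optionally holds per-hit scores as a long table with columns
    (genome_id, marker_id, evalue, bitscore) — used only by rules that
    require score thresholds (e.g. the HK97-MCP mirusvirus rule).
    """

    HIT_COLUMNS = ("genome_id", "marker_id", "evalue", "bitscore")

    def __init__(self, counts: pd.DataFrame, hits: pd.DataFrame | None = None):
        if counts.index.duplicated().any():
            raise ValueError("duplicate genome ids")
        values = counts.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("copy counts must be finite")
        if (values < 0).any():
            raise ValueError("copy counts must be >= 0")
        if not np.array_equal(values, np.round(values)):
            raise ValueError("copy counts must be integral")
        self.counts = counts.astype(int)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "genome_id"
        if hits is not None:
            missing = [c for c in self.HIT_COLUMNS if c not in hits.columns]
            if missing:
                raise ValueError(f"hit table missing columns: {missing}")
            hits = hits.loc[:, list(self.HIT_COLUMNS)].copy()
        self.hits = hits

    @property
    def genome_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def marker_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def presence(self) -> pd.DataFrame:
        """Boolean presence (copy >= 1) per genome x marker."""
        return self.counts >= 1

    def n_markers_present(self) -> pd.Series:
        return self.presence().sum(axis=1)

    @classmethod
    def from_tsv(cls, path: str | Path, hits_path: str | Path | None = None
                 ) -> "MarkerHitTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        hits = None
        if hits_path is not None:
            hits = pd.read_csv(hits_path, sep="\t", dtype={"genome_id": str,
                                                           "marker_id": str})
        return cls(counts, hits)

    def to_tsv(self, path: str | Path, hits_path: str | Path | None = None) -> None:
        self.counts.to_csv(path, sep="\t")
        if hits_path is not None and self.hits is not None:
            self.hits.to_csv(hits_path, sep="\t", index=False,
                             float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Per-contig classifier evidence
# ---------------------------------------------------------------------------

class EvidenceTable:
    """Per-contig verdicts from external viral classifiers.

    One row per contig: a ViralRecall score (real), a VirSorter max-score
    group (text) and an optional taxonomic label.  The classifiers
    themselves run upstream; this table only records their output.
    """

    REQUIRED = ("contig_id", "viralrecall_score", "virsorter_group")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"evidence table missing columns: {missing}")
        df = df.copy()
        df["contig_id"] = df["contig_id"].astype(str)
        if df["contig_id"].duplicated().any():
            raise ValueError("duplicate contig ids in evidence table")
        df["viralrecall_score"] = pd.to_numeric(df["viralrecall_score"],
                                                errors="raise")
        if "taxon" not in df.columns:
            df["taxon"] = ""
        self.df = df.set_index("contig_id", drop=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvidenceTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"contig_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# ANI matrices
# ---------------------------------------------------------------------------

class ANIMatrix:
    """Symmetric genome x genome average nucleotide identity matrix (%).

    Diagonal must equal 100; off-diagonal values lie in [0, 100].
    """

    def __init__(self, df: pd.DataFrame, atol: float = 1e-8):
        if list(df.index) != list(df.columns):
            raise ValueError("ANI matrix rows and columns must match")
        values = df.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=atol):
            raise ValueError("ANI matrix must be symmetric")
        if not np.allclose(np.diag(values), 100.0, atol=atol):
            raise ValueError("ANI matrix diagonal must be 100")
        if (values < 0).any() or (values > 100 + atol).any():
            raise ValueError("ANI values must lie in [0, 100]")
        self.df = df.astype(float)
        self.df.index = self.df.index.astype(str)
        self.df.columns = self.df.columns.astype(str)

    @property
    def genome_ids(self) -> list[str]:
        return self.df.index.tolist()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ANIMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree, preserving the rooting stated in the file."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf names in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def is_rooted(tree: dendropy.Tree) -> bool:
    """A tree with more than two children at the seed node is unrooted."""
    return len(tree.seed_node.child_nodes()) <= 2


# ---------------------------------------------------------------------------
# Elementary computations
# ---------------------------------------------------------------------------

def compute_tpm(counts: Sequence[float] | np.ndarray,
                lengths: Sequence[float] | np.ndarray) -> np.ndarray:
    """Transcripts-per-million normalisation of read counts.

    TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6.  An all-zero count
    vector maps to an all-zero TPM vector (empty samples are legitimate in
    simulations).

    Parameters
    ----------
    counts : array-like
        Per-feature read counts, >= 0.
    lengths : array-like
        Per-feature lengths in bp, > 0, same length as ``counts``.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError(
            f"counts and lengths differ in shape: {counts.shape} vs {lengths.shape}"
        )
    if (lengths <= 0).any():
        raise ValueError("lengths must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(counts)
    return rate / total * 1e6


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50: length at which the cumulative sum of descending-sorted contig
    lengths first reaches half the total.

    Always a member of ``contig_lengths``; invariant to input order.
    """
    lengths = np.asarray(contig_lengths)
    if lengths.size == 0:
        raise ValueError("contig length list is empty")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be > 0")
    ordered = np.sort(lengths)[::-1]
    half = ordered.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(ordered), half))
    return int(ordered[idx])
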