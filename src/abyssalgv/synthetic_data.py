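"""Synthetic data generators with recorded ground truth.

Every downstream stage of the pipeline (bin screening, PIMA, depth
classification, ecology, enrichment, co-occurrence) is exercised on data
from this module, so each generator plants a known signal and returns the
truth labels needed to score recovery:

* :func:`simulate_depth_abundance` — depth-stratified log-normal TPM
  profiles with structural zeros; a configurable fraction of genomes is
  planted as deep-sea-specific (elevated mean in deep samples, heavy
  zero inflation at the surface); genomes occupy a Bernoulli-drawn set of
  oceanic regions.
* :func:`simulate_bins` — giant-virus, cellular and chimeric bins with
  marker-gene tables and per-contig classifier evidence shaped so that the
  gene-density screen separates them.
* :func:`simulate_lineages` — a lineage-structured marker tree plus an
  orthologous-group copy table with planted chimeras (two single-copy-core
  genomes merged), the substrate for PIMA.
* :func:`simulate_asv_table` — compositional ASV count tables by
  multinomial sampling of log-normal latent abundances, with planted
  monotone giant-virus/host-ASV links through a shared latent factor.

One global seed drives everything; sub-generators derive child seeds
deterministically, so the same config yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core_tables import (AbundanceMatrix, ANIMatrix, EvidenceTable,
                          GenomeRecord, MarkerHitTable, SampleTable,
                          write_bins, write_tree)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_depth_abundance",
           "simulate_bins", "simulate_lineages", "simulate_asv_table",
           "write_fixture_set", "REGIONS", "NCLDV_MARKERS", "MCP_MARKER"]

#: Eight named oceanic regions used for biogeography simulations.
REGIONS = ("arctic", "north_atlantic", "south_atlantic", "north_pacific",
           "south_pacific", "indian", "southern", "mediterranean")

#: The 20 conserved nucleocytovirus marker genes tracked by the screen.
NCLDV_MARKERS = tuple(f"ncvog_{i:02d}" for i in range(1, 21))

#: Mirusvirus diagnostic marker (major capsid protein).
MCP_MARKER = "HK97-MCP"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic data.

    Defaults mirror a depth-stratified survey: two balanced sample layers,
    a genome catalogue with 30% planted deep-sea-specific members at a
    10-fold deep enrichment, moderate log-normal dispersion and sparse
    zero-inflated profiles.
    """

    # depth-stratified abundance survey
    n_deep_samples: int = 20
    n_surface_samples: int = 20
    n_genomes: int = 200
    frac_deep_specific: float = 0.3
    effect_size: float = 10.0          # deep/surface fold change, > 1
    dispersion: float = 0.2            # log-scale sd of abundances
    zero_inflation: float = 0.3        # structural-zero probability
    surface_dropout: float = 0.9       # zero probability of planted genomes
                                       # at the surface (>= zero_inflation)
    region_occupancy: float = 0.7      # Bernoulli region-membership prob
    n_regions: int = 8
    # bin simulation
    n_gv_bins: int = 20
    n_cellular_bins: int = 20
    n_mv_bins: int = 5
    n_chimera_bins: int = 5
    # lineage / PIMA simulation
    n_lineages: int = 5
    genomes_per_lineage: int = 8
    n_core_ogs: int = 15
    n_accessory_ogs: int = 30
    core_dropout: float = 0.05         # chance a clean genome misses a core OG
    core_duplication: float = 0.02     # chance a clean genome duplicates one
    # ASV / co-occurrence simulation
    n_asvs: int = 200
    n_asv_samples: int = 12
    asv_library_size: int = 20_000
    n_host_links: int = 10
    host_link_loading: float = 0.9     # shared-factor loading of planted links
    seed: int = 0

    def __post_init__(self):
        counts = ("n_deep_samples", "n_surface_samples", "n_genomes",
                  "n_regions", "n_gv_bins", "n_cellular_bins", "n_mv_bins",
                  "n_lineages", "genomes_per_lineage", "n_core_ogs",
                  "n_accessory_ogs", "n_asvs", "n_asv_samples",
                  "asv_library_size", "n_host_links")
        for name in counts:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_chimera_bins < 0:
            raise ValueError("n_chimera_bins must be >= 0")
        probs = ("frac_deep_specific", "zero_inflation", "surface_dropout",
                 "region_occupancy", "core_dropout", "core_duplication",
                 "host_link_loading")
        for name in probs:
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_regions > len(REGIONS):
            raise ValueError(f"n_regions must be <= {len(REGIONS)}")
        if self.surface_dropout < self.zero_inflation:
            raise ValueError("surface_dropout must be >= zero_inflation")
        if self.n_host_links > min(self.n_asvs, self.n_asv_samples * 50):
            raise ValueError("n_host_links too large for the ASV table")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for an independent simulation stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted labels recorded alongside each simulated table."""

    deep_specific: pd.Series | None = None     # genome_id -> bool
    regions: dict[str, frozenset] | None = None  # genome_id -> region set
    is_gv: pd.Series | None = None             # bin -> bool
    is_chimera: pd.Series | None = None        # bin/leaf -> bool
    host_links: frozenset | None = None        # {(gv_id, asv_id), ...}
    gv_abundance: AbundanceMatrix | None = None

    def to_tsv(self, path: str | Path) -> None:
        """Serialise all recorded labels as one long (entity, key, value)
        table."""
        rows = []
        if self.deep_specific is not None:
            for gid, flag in self.deep_specific.items():
                rows.append((gid, "deep_specific", str(bool(flag))))
        if self.regions is not None:
            for gid, regs in self.regions.items():
                rows.append((gid, "regions", ",".join(sorted(regs))))
        if self.is_gv is not None:
            for gid, flag in self.is_gv.items():
                rows.append((gid, "is_gv", str(bool(flag))))
        if self.is_chimera is not None:
            for gid, flag in self.is_chimera.items():
                rows.append((gid, "is_chimera", str(bool(flag))))
        if self.host_links is not None:
            for gv, asv in sorted(self.host_links):
                rows.append((gv, "host_link", asv))
        pd.DataFrame(rows, columns=["entity", "key", "value"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Depth-stratified abundance
# ---------------------------------------------------------------------------

def _make_samples(config: SimulationConfig, rng: np.random.Generator
                  ) -> SampleTable:
    regions = REGIONS[: config.n_regions]
    rows = []
    dates = pd.date_range("2021-01-15", periods=12, freq="MS").strftime("%Y-%m-%d")
    for i in range(config.n_deep_samples):
        rows.append({"sample_id": f"deep_{i + 1:03d}",
                     "depth": float(rng.uniform(300, 3000)),
                     "region": regions[i % len(regions)],
                     "date": dates[i % len(dates)],
                     "fraction": "pico", "assay": "metagenome"})
    for i in range(config.n_surface_samples):
        rows.append({"sample_id": f"surf_{i + 1:03d}",
                     "depth": float(rng.uniform(5, 150)),
                     "region": regions[i % len(regions)],
                     "date": dates[i % len(dates)],
                     "fraction": "pico", "assay": "metagenome"})
    return SampleTable(pd.DataFrame(rows))


def simulate_depth_abundance(config: SimulationConfig
                             ) -> tuple[SampleTable, AbundanceMatrix, GroundTruth]:
    """Depth-stratified TPM profiles with planted deep-specific genomes.

    Non-specific genomes are exchangeable between layers: the same
    log-normal law and the same structural-zero probability everywhere.
    Planted genomes get their deep-sample mean multiplied by
    ``effect_size`` and are zeroed at the surface with probability
    ``surface_dropout`` (>= the background ``zero_inflation``), emulating
    taxa that are abundant at depth and only sporadically advected to the
    surface.  Each genome occupies a Bernoulli-drawn, non-empty region
    set; outside its regions it is absent from both layers.
    """
    if config.n_deep_samples < 1 or config.n_surface_samples < 1:
        raise ValueError("both layers need at least one sample")
    rng = config.rng(1)
    samples = _make_samples(config, rng)
    regions = REGIONS[: config.n_regions]
    sample_regions = samples.df["region"].to_numpy()
    deep_mask = samples.is_deep().to_numpy()

    n_g, n_s = config.n_genomes, len(samples)
    genome_ids = [f"G{i + 1:04d}" for i in range(n_g)]
    n_spec = int(round(config.frac_deep_specific * n_g))
    spec_idx = rng.choice(n_g, size=n_spec, replace=False)
    is_spec = np.zeros(n_g, dtype=bool)
    is_spec[spec_idx] = True

    # region occupancy: independent Bernoulli per region, at least one region
    occupancy = rng.random((n_g, len(regions))) < config.region_occupancy
    for i in np.flatnonzero(~occupancy.any(axis=1)):
        occupancy[i, rng.integers(len(regions))] = True
    region_idx = {r: j for j, r in enumerate(regions)}
    in_region = occupancy[:, [region_idx[r] for r in sample_regions]]

    base = rng.normal(3.0, 1.0, size=n_g)
    latent = np.exp(rng.normal(base[:, None], config.dispersion, size=(n_g, n_s)))
    latent[is_spec[:, None] & deep_mask[None, :]] *= config.effect_size

    zeros = rng.random((n_g, n_s)) < config.zero_inflation
    # planted genomes are consistently present at depth within their range;
    # detection dropout models exchangeable genomes and the surface side
    zeros &= ~(is_spec[:, None] & deep_mask[None, :])
    extra = rng.random((n_g, n_s)) < config.surface_dropout
    zeros |= is_spec[:, None] & ~deep_mask[None, :] & extra
    latent[zeros | ~in_region] = 0.0

    totals = latent.sum(axis=0)
    tpm = np.divide(latent, np.where(totals == 0, 1.0, totals)) * 1e6
    abund = AbundanceMatrix(
        pd.DataFrame(tpm, index=genome_ids, columns=samples.sample_ids),
        unit="tpm")
    truth = GroundTruth(
        deep_specific=pd.Series(is_spec, index=genome_ids, name="deep_specific"),
        regions={gid: frozenset(np.array(regions)[occupancy[i]])
                 for i, gid in enumerate(genome_ids)},
    )
    return samples, abund, truth


# ---------------------------------------------------------------------------
# Bin simulation
# ---------------------------------------------------------------------------

def _split_contigs(size: int, n_contigs: int, rng: np.random.Generator
                   ) -> tuple[int, ...]:
    """Break a genome into contigs of random, >= 1 kb lengths summing to
    ``size``."""
    weights = rng.dirichlet(np.full(n_contigs, 2.0))
    lengths = np.maximum((weights * size).astype(int), 1000)
    lengths[-1] += size - lengths.sum()
    if lengths[-1] < 1000:
        lengths[-1] = 1000
    return tuple(int(v) for v in lengths)


def simulate_bins(config: SimulationConfig
                  ) -> tuple[dict[str, GenomeRecord], MarkerHitTable,
                             EvidenceTable, GroundTruth]:
    """Giant-virus, mirusvirus, cellular, and chimeric bins.

    Giant-virus bins are 80-800 kb with 8-16 of the 20 conserved markers,
    so their gene-density index clears the screening threshold; cellular
    bins are 1-5 Mb with at most one spurious marker; chimeras concatenate
    two giant-virus bins (contigs appended, marker copies summed).
    Mirusvirus bins carry a scored HK97-MCP hit passing both thresholds,
    while one cellular bin gets a weak HK97 hit that must be rejected.
    Per-contig evidence mixes mostly-viral verdicts into giant-virus bins
    and uniformly cellular verdicts elsewhere.
    """
    rng = config.rng(2)
    records: dict[str, GenomeRecord] = {}
    counts: dict[str, dict[str, int]] = {}
    hit_rows: list[dict] = []
    evid_rows: list[dict] = []
    is_gv: dict[str, bool] = {}
    is_chimera: dict[str, bool] = {}

    def add_evidence(rec: GenomeRecord, viral: bool) -> None:
        for cid in rec.contig_ids:
            if viral and rng.random() < 0.9:
                group = "NCLDV" if rng.random() < 0.8 else "other"
                score = float(rng.normal(1.5, 0.8))
                if group != "NCLDV":
                    score = abs(score) + 0.1  # keep the OR-rule satisfied
            else:
                group = "other"
                score = float(-abs(rng.normal(1.0, 0.5)) - 0.1)
            evid_rows.append({"contig_id": cid, "viralrecall_score": score,
                              "virsorter_group": group,
                              "taxon": "NCLDV" if viral else "cellular"})

    gv_ids = []
    for i in range(config.n_gv_bins):
        gid = f"gv_{i + 1:03d}"
        size = int(rng.integers(80_000, 800_000))
        rec = GenomeRecord(gid, _split_contigs(size, int(rng.integers(5, 30)), rng),
                           gc=float(rng.uniform(0.24, 0.53)))
        records[gid] = rec
        marker_set = rng.choice(len(NCLDV_MARKERS), size=int(rng.integers(8, 17)),
                                replace=False)
        counts[gid] = {NCLDV_MARKERS[j]: int(1 + (rng.random() < 0.1))
                       for j in marker_set}
        add_evidence(rec, viral=True)
        is_gv[gid] = True
        is_chimera[gid] = False
        gv_ids.append(gid)

    for i in range(config.n_mv_bins):
        gid = f"mv_{i + 1:03d}"
        size = int(rng.integers(80_000, 600_000))
        rec = GenomeRecord(gid, _split_contigs(size, int(rng.integers(5, 20)), rng),
                           gc=float(rng.uniform(0.24, 0.53)))
        records[gid] = rec
        counts[gid] = {MCP_MARKER: 1}
        hit_rows.append({"genome_id": gid, "marker_id": MCP_MARKER,
                         "evalue": float(10 ** rng.uniform(-30, -4)),
                         "bitscore": float(rng.uniform(120, 400))})
        add_evidence(rec, viral=True)
        is_gv[gid] = True
        is_chimera[gid] = False

    for i in range(config.n_cellular_bins):
        gid = f"cell_{i + 1:03d}"
        size = int(rng.integers(1_000_000, 5_000_000))
        rec = GenomeRecord(gid, _split_contigs(size, int(rng.integers(50, 200)), rng),
                           gc=float(rng.uniform(0.3, 0.7)))
        records[gid] = rec
        counts[gid] = ({NCLDV_MARKERS[int(rng.integers(20))]: 1}
                       if rng.random() < 0.4 else {})
        if i == 0:
            # weak HK97 hit that must fail both score thresholds
            hit_rows.append({"genome_id": gid, "marker_id": MCP_MARKER,
                             "evalue": 1e-2, "bitscore": 50.0})
        add_evidence(rec, viral=False)
        is_gv[gid] = False
        is_chimera[gid] = False

    for i in range(config.n_chimera_bins):
        a, b = rng.choice(len(gv_ids), size=2, replace=False)
        ra, rb = records[gv_ids[a]], records[gv_ids[b]]
        gid = f"chim_{i + 1:03d}"
        rec = GenomeRecord(
            gid, ra.contig_lengths + rb.contig_lengths,
            contig_ids=tuple(f"{gid}_c{k + 1}" for k in
                             range(len(ra.contig_lengths) + len(rb.contig_lengths))),
            gc=float((ra.gc + rb.gc) / 2))
        records[gid] = rec
        merged: dict[str, int] = dict(counts[gv_ids[a]])
        for m, c in counts[gv_ids[b]].items():
            merged[m] = merged.get(m, 0) + c
        counts[gid] = merged
        add_evidence(rec, viral=True)
        is_gv[gid] = True
        is_chimera[gid] = True

    all_markers = list(NCLDV_MARKERS) + [MCP_MARKER]
    count_df = pd.DataFrame(0, index=sorted(records), columns=all_markers)
    for gid, row in counts.items():
        for m, c in row.items():
            count_df.loc[gid, m] = c
    hits = pd.DataFrame(hit_rows, columns=MarkerHitTable.HIT_COLUMNS)
    markers = MarkerHitTable(count_df, hits)
    evidence = EvidenceTable(pd.DataFrame(evid_rows))
    truth = GroundTruth(is_gv=pd.Series(is_gv, name="is_gv"),
                        is_chimera=pd.Series(is_chimera, name="is_chimera"))
    return records, markers, evidence, truth


# ---------------------------------------------------------------------------
# Lineage / PIMA simulation
# ---------------------------------------------------------------------------

def _clade_newick(leaves: list[str]) -> str:
    return "(" + ",".join(f"{l}:1.0" for l in leaves) + "):2.0"


def _balanced(items: list[str]) -> str:
    """Binary spine over pre-rendered clade strings with short internal
    branches, keeping internal divergence below the lineage cut."""
    if len(items) == 1:
        return items[0]
    mid = len(items) // 2
    return f"({_balanced(items[:mid])},{_balanced(items[mid:])}):0.05"


def simulate_lineages(config: SimulationConfig
                      ) -> tuple[dendropy.Tree, pd.DataFrame, GroundTruth]:
    """Lineage-structured tree and OG copy table with planted chimeras.

    Each lineage has its own single-copy core OG set (plus shared
    accessory OGs at random); clean genomes miss a core OG with
    probability ``core_dropout`` and duplicate one with probability
    ``core_duplication``.  Each planted chimera merges the OG profiles of
    two clean members of one lineage and is appended as an extra leaf of
    that lineage's clade, so its core copy numbers sit at twice the
    lineage mode.

    Clade stem branches are long relative to within-clade branches, so the
    relative-evolutionary-divergence cut at the default threshold
    recovers exactly the simulated lineages.
    """
    rng = config.rng(3)
    lineage_members: dict[str, list[str]] = {}
    core_sets: dict[str, list[str]] = {}
    og_rows: dict[str, dict[str, int]] = {}
    accessory = [f"og_acc_{k:03d}" for k in range(config.n_accessory_ogs)]
    is_chimera: dict[str, bool] = {}

    for li in range(config.n_lineages):
        lid = f"L{li + 1}"
        core = [f"og_{lid}_{k:02d}" for k in range(config.n_core_ogs)]
        core_sets[lid] = core
        members = []
        for j in range(config.genomes_per_lineage):
            gid = f"{lid}_g{j + 1:02d}"
            row = {}
            for og in core:
                if rng.random() < config.core_dropout:
                    copy = 0
                elif rng.random() < config.core_duplication:
                    copy = 2
                else:
                    copy = 1
                row[og] = copy
            for og in accessory:
                if rng.random() < 0.3:
                    row[og] = 1
            og_rows[gid] = row
            members.append(gid)
            is_chimera[gid] = False
        lineage_members[lid] = members

    lineage_ids = list(lineage_members)
    for i in range(config.n_chimera_bins):
        lid = lineage_ids[int(rng.integers(len(lineage_ids)))]
        pool = [g for g in lineage_members[lid] if not is_chimera[g]]
        a, b = rng.choice(len(pool), size=2, replace=False)
        gid = f"{lid}_chim{i + 1:02d}"
        merged: dict[str, int] = dict(og_rows[pool[a]])
        for og, c in og_rows[pool[b]].items():
            merged[og] = merged.get(og, 0) + c
        og_rows[gid] = merged
        lineage_members[lid].append(gid)
        is_chimera[gid] = True

    all_ogs = sorted({og for row in og_rows.values() for og in row})
    og_table = pd.DataFrame(0, index=sorted(og_rows), columns=all_ogs)
    for gid, row in og_rows.items():
        for og, c in row.items():
            og_table.loc[gid, og] = c
    og_table.index.name = "genome_id"

    clades = [_clade_newick(lineage_members[lid]) for lid in lineage_ids]
    newick = _balanced(clades)
    # strip the root edge length introduced by the recursion
    newick = newick.rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    truth = GroundTruth(is_chimera=pd.Series(is_chimera, name="is_chimera"))
    return tree, og_table, truth


# ---------------------------------------------------------------------------
# ASV tables with planted host links
# ---------------------------------------------------------------------------

def simulate_asv_table(config: SimulationConfig
                       ) -> tuple[AbundanceMatrix, GroundTruth]:
    """Compositional ASV count table with planted giant-virus/host links.

    Latent per-sample log-abundances are normal; each planted
    (giant-virus, ASV) pair loads on a shared per-sample factor with
    loading ``host_link_loading``, so their abundances co-vary monotonely
    and Spearman's rho is positive in expectation.  Counts are drawn by a
    multinomial per sample (columns sum exactly to
    ``asv_library_size``).  The paired giant-virus transcript TPM matrix
    and the link set are recorded in the returned truth.
    """
    rng = config.rng(4)
    n_s = config.n_asv_samples
    sample_ids = [f"meso_{i + 1:03d}" for i in range(n_s)]
    asv_ids = [f"asv_{i + 1:04d}" for i in range(config.n_asvs)]
    gv_ids = [f"gv_{i + 1:03d}" for i in range(config.n_host_links)]

    factors = rng.normal(size=(config.n_host_links, n_s))
    loading = config.host_link_loading
    resid = np.sqrt(1.0 - loading ** 2)

    linked_asv_idx = rng.choice(config.n_asvs, size=config.n_host_links,
                                replace=False)
    base = rng.normal(0.0, 1.0, size=config.n_asvs)
    latent = base[:, None] + rng.normal(size=(config.n_asvs, n_s))
    # the linked ASV is the host: its log-abundance is the shared factor,
    # and the paired virus tracks it at the configured loading
    for k, ai in enumerate(linked_asv_idx):
        latent[ai] = base[ai] + factors[k]

    probs = np.exp(latent)
    probs /= probs.sum(axis=0)
    counts = np.column_stack([
        rng.multinomial(config.asv_library_size, probs[:, j])
        for j in range(n_s)
    ])
    asv_counts = AbundanceMatrix(
        pd.DataFrame(counts, index=asv_ids, columns=sample_ids), unit="counts")

    gv_latent = np.exp(loading * factors + resid * rng.normal(
        size=(config.n_host_links, n_s)))
    # viral transcripts are a small fraction of the metatranscriptome, so
    # the TPM closure is dominated by a cellular background expression pool
    background = 100.0 * gv_latent.sum(axis=0).mean()
    gv_tpm = gv_latent / (gv_latent.sum(axis=0) + background) * 1e6
    gv_abund = AbundanceMatrix(
        pd.DataFrame(gv_tpm, index=gv_ids, columns=sample_ids), unit="tpm")

    links = frozenset(
        (gv_ids[k], asv_ids[ai]) for k, ai in enumerate(linked_asv_idx))
    truth = GroundTruth(host_links=links, gv_abundance=gv_abund)
    return asv_counts, truth


# ---------------------------------------------------------------------------
# Fixture set on disk
# ---------------------------------------------------------------------------

def write_fixture_set(config: SimulationConfig, outdir: str | Path) -> None:
    """Write the full synthetic input set as TSV/newick files plus a
    combined ``truth.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    samples, abund, truth_depth = simulate_depth_abundance(config)
    samples.to_tsv(outdir / "samples.tsv")
    abund.to_tsv(outdir / "tpm.tsv")

    bins, markers, evidence, truth_bins = simulate_bins(config)
    write_bins(bins, outdir / "bins.tsv")
    markers.to_tsv(outdir / "markers.tsv", outdir / "marker_hits.tsv")
    evidence.to_tsv(outdir / "evidence.tsv")

    tree, og_table, truth_lineage = simulate_lineages(config)
    write_tree(tree, outdir / "tree.nwk")
    og_table.to_csv(outdir / "ogs.tsv", sep="\t")

    asv_counts, truth_asv = simulate_asv_table(config)
    asv_counts.to_tsv(outdir / "asv_counts.tsv")
    truth_asv.gv_abundance.to_tsv(outdir / "gv_tpm.tsv")
    dates = pd.date_range("2021-01-15", periods=12, freq="MS").strftime("%Y-%m-%d")
    asv_meta = pd.DataFrame({
        "sample_id": asv_counts.sample_ids,
        "depth": 300.0,
        "region": "site",
        "date": [dates[i % len(dates)] for i in range(len(asv_counts.sample_ids))],
        "fraction": ["pico" if i % 2 == 0 else "total"
                     for i in range(len(asv_counts.sample_ids))],
        "assay": "rRNA",
    })
    SampleTable(asv_meta).to_tsv(outdir / "asv_samples.tsv")

    combined = GroundTruth(
        deep_specific=truth_depth.deep_specific,
        regions=truth_depth.regions,
        is_gv=truth_bins.is_gv,
        is_chimera=pd.concat([truth_bins.is_chimera,
                              truth_lineage.is_chimera]),
        host_links=truth_asv.host_links,
    )
    combined.to_tsv(outdir / "truth.tsv")
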