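"""Analysis-wide thresholds and logging setup.

All decision rules in the pipeline hang off a small number of scalar
thresholds (depth cutoff for "deep sea", significance level, ANI
dereplication identity, relative-evolutionary-divergence cut, gene-density
index cut).  They are collected here so a whole run can be reconfigured
from one YAML file.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["Thresholds", "load_thresholds", "get_logger"]


@dataclass(frozen=True)
class Thresholds:
    """Scalar decision thresholds used across the pipeline.

    Attributes
    ----------
    depth_cutoff : float
        Depth in metres above which a sample counts as "deep sea"
        (strictly ``depth > depth_cutoff``).  Default 200 m, the base of
        the epipelagic zone.
    alpha : float
        Significance level for BH-adjusted and raw p values.
    ani_threshold : float
        Average nucleotide identity (%) for single-linkage dereplication
        into species-level clusters.
    red_threshold : float
        Relative evolutionary divergence at which lineages are delineated
        on the rooted marker-gene tree (genus/family level).
    ncldv_threshold : float
        Gene-density (NCLDV) index above which a bin is a candidate
        nucleocytovirus MAG (strict ``>``).
    core_fraction : float
        Prevalence above which an orthologous group counts as "core"
        within a lineage.
    redundancy_cutoff : float
        Redundancy above which a MAG is removed as likely chimeric
        (strict ``>``).
    detection_threshold : float
        Abundance strictly above which a genome counts as detected in a
        sample (TPM > 0 by default).
    """

    depth_cutoff: float = 200.0
    alpha: float = 0.05
    ani_threshold: float = 95.0
    red_threshold: float = 0.65
    ncldv_threshold: float = 5.75
    core_fraction: float = 0.5
    redundancy_cutoff: float = 0.5
    detection_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_cutoff < 0:
            raise ValueError("depth_cutoff must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.ani_threshold <= 100:
            raise ValueError("ani_threshold must lie in [0, 100]")
        for name in ("red_threshold", "core_fraction", "redundancy_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def load_thresholds(path: str | Path) -> Thresholds:
    """Load :class:`Thresholds` from a YAML mapping, filling defaults.

    Unknown keys are rejected so that typos in config files fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(Thresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Thresholds(**raw)


_configured = False


def get_logger(name: str = "abyssalgv") -> logging.Logger:
    """Return the package logger, attaching a stderr handler once."""
    global _configured
    logger = logging.getLogger(name)
    if not _configured:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        root = logging.getLogger("abyssalgv")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        _configured = True
    return logger
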