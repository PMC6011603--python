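"""Experiment layout constants and configuration objects.

The study design is two contrasting genotypes -- a salt-tolerant line
(``E``) and a salt-sensitive line (``N``) -- sampled at 0, 4 and 24 h of
salt treatment.  Each of the six samples has a single mRNA-seq library, a
single small-RNA library and three iTRAQ proteomic replicates.  Treated
samples are compared against the time-0 control of the same genotype,
giving four comparisons: E4/E0, E24/E0, N4/N0 and N24/N0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: genotype codes: E = salt-tolerant, N = salt-sensitive
GENOTYPES = ("E", "N")
TOLERANT, SENSITIVE = GENOTYPES
TIMES = (0, 4, 24)
TREATED_TIMES = (4, 24)

#: sample identifiers in fixed column order
SAMPLES = ("SE0", "SE4", "SE24", "SN0", "SN4", "SN24")

#: comparison -> (treated sample, control sample)
COMPARISONS: Mapping[str, tuple[str, str]] = {
    "E4/E0": ("SE4", "SE0"),
    "E24/E0": ("SE24", "SE0"),
    "N4/N0": ("SN4", "SN0"),
    "N24/N0": ("SN24", "SN0"),
}

AS_EVENT_TYPES = ("IR", "ES", "A5SS", "A3SS")

CATEGORIES = ("I", "II", "III", "IV", "V", "VI")

SCREEN_RULES = ("i", "ii", "iii", "iv", "v")


def sample_name(genotype: str, time: int) -> str:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if time not in TIMES:
        raise ValueError(f"unknown time point {time!r}")
    return f"S{genotype}{time}"


def comparison_name(genotype: str, time: int) -> str:
    """The treated-vs-control comparison for a genotype at 4 or 24 h."""
    if time not in TREATED_TIMES:
        raise ValueError(f"no comparison at time {time!r}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    return f"{genotype}{time}/{genotype}0"


def comparison_genotype(comparison: str) -> str:
    return comparison[0]


def comparison_time(comparison: str) -> int:
    return int(comparison.split("/")[0][1:])


@dataclass
class Thresholds:
    """All published decision thresholds of the workflow, surfaced in one place.

    Defaults are the printed values: DEGs require |log2 ratio| >= 1 at
    FDR < 0.001; DAPs require a mean iTRAQ ratio > 1.2 or < 0.833 at
    P < 0.05; miRNAs are eligible when RPM >= 10 in a compared sample and
    the six-sample RPM sum exceeds 60, and DE when P < 0.05 with
    |log2 fold change| > 1; target sites must score fewer than 3 mismatch
    units; screening rule (i) uses a 0.5 log2 margin; PPI edges require a
    combined score above 160.
    """

    deg_log2fc: float = 1.0
    deg_fdr: float = 0.001
    dap_hi: float = 1.2
    dap_lo: float = 0.833
    dap_p: float = 0.05
    mirna_rpm_min: float = 10.0
    mirna_rpm_sum: float = 60.0
    mirna_p: float = 0.05
    mirna_log2fc: float = 1.0
    target_penalty_max: float = 3.0
    rule_i_margin: float = 0.5
    ppi_score_min: float = 160.0
    #: RPKM/RPM floor used before forming ratios so absent genes get a
    #: finite log2 fold change
    expr_floor: float = 0.01
    #: weight of a G:U wobble pair in the target-site penalty
    wobble_weight: float = 0.5
    #: 'either' (default) or 'both': which compared samples must reach
    #: mirna_rpm_min
    mirna_rpm_rule: str = "either"
    #: require AS candidates to carry tolerant-genotype AS
    require_tolerant_as: bool = True


@dataclass
class PipelineConfig:
    """Paths, thresholds and the master seed for a full pipeline run."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "saltomics_out"
    # input table paths (may be None when running from an in-memory dataset)
    expression: str | None = None
    proteins: str | None = None
    mirna_counts: str | None = None
    mirna_fasta: str | None = None
    cds_fasta: str | None = None
    as_events: str | None = None
    ortholog_map: str | None = None
    ppi_edges: str | None = None
    osmotic_genes: str | None = None
    annotation: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)
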