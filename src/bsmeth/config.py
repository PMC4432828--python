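"""Run configuration: one YAML file drives both pipelines.

Every threshold the analysis applies is explicit here and echoed into the
run summary, so a run is reproducible from its archived config plus seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid run configuration (caught before any compute)."""


def _default_arms() -> dict:
    return {
        "control": {"p_cpg": 0.75, "p_chg": 0.01, "p_chh": 0.01},
        "treated": {"p_cpg": 0.85, "p_chg": 0.01, "p_chh": 0.01},
    }


def _default_mixtures() -> dict:
    # control: one population whose mean CG retention (level + (1-level)*u)
    # puts the per-read CG count at ~10 of the 16 Alu consensus CpGs, i.e.
    # centred between the 8/12 tail thresholds; treated: a minor
    # hypomethylated and a major hypermethylated population falling below
    # and above those thresholds respectively
    return {
        "control": {"weights": [1.0], "levels": [0.60], "dispersion": [40.0]},
        "treated": {
            "weights": [0.25, 0.75],
            "levels": [0.30, 0.85],
            "dispersion": [40.0, 40.0],
        },
    }


@dataclass
class RunConfig:
    """Generator parameters and analysis thresholds for a full run."""

    seed: int = 0
    outdir: str = "bsmeth_run"
    # --- generator: genome arm
    reference_length: int = 20000
    gc_fraction: float = 0.5
    cpg_factor: float = 1.0
    n_reads: int = 10000
    read_len: int = 100
    paired: bool = False
    arms: dict = field(default_factory=_default_arms)
    n_genes: int = 20
    # --- generator: spike-in
    spike_in_length: int = 5000
    spike_in_reads: int = 2000
    # --- generator: conversion chemistry
    under_conversion: float = 0.05
    over_conversion: float = 0.0
    # --- generator: amplicon arm
    amplicon_family: str = "alu"
    amplicon_fasta: str = ""  # overrides amplicon_family when set
    amplicon_mixtures: dict = field(default_factory=_default_mixtures)
    n_molecules: int = 600
    # fraction of molecules sequenced as incomplete inserts; the default run
    # models gel-purified full-length products, so truncation is off
    p_truncate: float = 0.0
    min_observed_len: int = 50
    # --- analysis thresholds
    qc_min_efficiency: float = 95.0
    alpha: float = 0.01
    conversion_error: float = 0.05
    min_len: int = 100
    tail_low: float = 8.0
    tail_high: float = 12.0
    split: float = 7.5
    gene_distance: int = 5000
    flank_radius: int = 100
    histogram_bin_width: float = 1.0
    # per-read metric the tail/split thresholds and the mixture fit apply to:
    # "n_cg" (CG count per read; the 8/12 and 7.5 thresholds bracket the
    # consensus CpG ranges on this scale) or "cg_pct" (per-window %)
    tail_metric: str = "n_cg"

    def validate(self) -> "RunConfig":
        checks = [
            (self.reference_length >= 100, "reference_length must be >= 100"),
            (0 <= self.gc_fraction <= 1, "gc_fraction outside [0, 1]"),
            (self.cpg_factor >= 0, "cpg_factor must be >= 0"),
            (self.n_reads >= 0, "n_reads must be >= 0"),
            (1 <= self.read_len <= self.reference_length,
             "read_len must be in [1, reference_length]"),
            (0 <= self.under_conversion <= 1, "under_conversion outside [0, 1]"),
            (0 <= self.over_conversion <= 1, "over_conversion outside [0, 1]"),
            (0 < self.alpha < 1, "alpha outside (0, 1)"),
            (0 <= self.conversion_error < 1, "conversion_error outside [0, 1)"),
            (self.min_len >= 1, "min_len must be >= 1"),
            (0 < self.tail_low < self.tail_high,
             "need 0 < tail_low < tail_high"),
            (self.split > 0, "split must be positive"),
            (self.gene_distance >= 0, "gene_distance must be >= 0"),
            (self.flank_radius >= 1, "flank_radius must be >= 1"),
            (0 <= self.qc_min_efficiency <= 100,
             "qc_min_efficiency outside [0, 100]"),
            (0 <= self.p_truncate <= 1, "p_truncate outside [0, 1]"),
            (set(self.arms) == {"control", "treated"},
             "arms must define exactly 'control' and 'treated'"),
            (set(self.amplicon_mixtures) == {"control", "treated"},
             "amplicon_mixtures must define exactly 'control' and 'treated'"),
            (self.tail_metric in ("n_cg", "cg_pct"),
             "tail_metric must be 'n_cg' or 'cg_pct'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        for name, arm in self.arms.items():
            for key in ("p_cpg", "p_chg", "p_chh"):
                p = arm.get(key, 0.0)
                if not 0 <= p <= 1:
                    raise ConfigError(f"arms.{name}.{key}={p} outside [0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
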