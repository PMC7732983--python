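"""Pipeline configuration: one YAML file, strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its default.

    Unknown keys in the YAML are rejected by name; ranges are checked on
    load. All randomness derives from ``seed``.
    """

    # paths (defaults match what `isomirseq simulate` writes)
    hairpin_fasta: str = "hairpins.fasta"
    arm_gff3: str = "arms.gff3"
    sample_sheet: str = "samples.tsv"
    utr_fasta: str | None = "utrs.fasta"
    gmt: str | None = "genesets.gmt"
    output_dir: str = "results"

    # reference handling
    flank_len: int = 10

    # trimming / filtering
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 3
    min_len: int = 15
    max_len: int = 28
    min_mean_quality: float = 20.0

    # alignment / assignment
    max_mismatch: int = 1
    cap_5p: int = 4
    cap_3p: int = 6
    min_templated: int = 15
    strict_denominator: bool = False

    # quantification / stats
    pool: str = "sum"
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    global_test: str = "chi2"

    # targets
    site_types: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1")
    skip_targets: bool = False

    # simulation
    reads_per_sample: int = 100000
    sequencing_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.flank_len <= self.cap_3p:
            raise ConfigError(
                f"flank_len ({self.flank_len}) must exceed the 3' offset cap "
                f"({self.cap_3p}) so templated additions stay resolvable")
        if not (0 < self.fdr_threshold < 1):
            raise ConfigError("fdr_threshold must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        if self.max_mismatch not in (0, 1):
            raise ConfigError("max_mismatch must be 0 or 1")
        if self.min_len > self.max_len:
            raise ConfigError("min_len must be <= max_len")
        if self.pool not in ("sum", "mean"):
            raise ConfigError("pool must be 'sum' or 'mean'")
        if self.global_test not in ("chi2", "permutation"):
            raise ConfigError("global_test must be 'chi2' or 'permutation'")
        if not (0 <= self.sequencing_error_rate < 1):
            raise ConfigError("sequencing_error_rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                "unknown config key(s): " + ", ".join(sorted(unknown)))
        if "site_types" in data:
            data["site_types"] = tuple(data["site_types"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["site_types"] = list(self.site_types)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
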