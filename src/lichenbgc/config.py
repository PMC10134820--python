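"""Pipeline configuration: validated parameters shared by all stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    k/s control MinHash sketching; derep_cutoff (99.5% ANI) collapses
    clonal strains and species_cutoff (96% ANI) delineates putative
    species; contig_min_bp drops short contigs before region analysis;
    link_cutoff thresholds genomic links; tanimoto_threshold, fp_radius
    and fp_bits control chemical edges; t_core/t_putative stratify GCF
    membership; mf_min_size filters the reported MF list.
    """

    k: int = 21
    s: int = 1000
    derep_cutoff: float = 0.005
    species_cutoff: float = 0.04
    contig_min_bp: int = 5000
    link_cutoff: float = 0.2
    tanimoto_threshold: float = 0.5
    fp_radius: int = 2
    fp_bits: int = 2048
    t_core: float = 900.0
    t_putative: float = 1800.0
    mf_min_size: int = 1
    seed: int = 0

    def __post_init__(self):
        checks = [
            (11 <= self.k <= 32, "k", "must be in [11, 32]"),
            (self.s >= 1, "s", "must be >= 1"),
            (0.0 <= self.derep_cutoff <= 1.0, "derep_cutoff", "must be in [0, 1]"),
            (0.0 <= self.species_cutoff <= 1.0, "species_cutoff", "must be in [0, 1]"),
            (self.contig_min_bp >= 0, "contig_min_bp", "must be >= 0"),
            (0.0 <= self.link_cutoff <= 1.0, "link_cutoff", "must be in [0, 1]"),
            (0.0 <= self.tanimoto_threshold <= 1.0, "tanimoto_threshold", "must be in [0, 1]"),
            (self.fp_radius >= 0, "fp_radius", "must be >= 0"),
            (self.fp_bits >= 8, "fp_bits", "must be >= 8"),
            (0 <= self.t_core < self.t_putative, "t_core", "need 0 <= t_core < t_putative"),
            (self.mf_min_size >= 1, "mf_min_size", "must be >= 1"),
            (self.seed >= 0, "seed", "must be >= 0"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ConfigError(f"config field {name!r} {msg} (got {getattr(self, name)})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a ``key = value`` or JSON text file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        defaults = cls()
        field_names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in field_names:
                raise ConfigError(f"unknown config field {key!r}")
            kwargs[key] = type(getattr(defaults, key))(value)
        return cls(**kwargs)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""
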