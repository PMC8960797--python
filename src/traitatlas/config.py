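"""Pipeline configuration.

A single config object carries every threshold used across the pipeline so
that a bare run reproduces the default analysis settings: affinity
propagation preference quantile q = 0.5, FDR alpha 0.05, 3% trait
prevalence prefilter, the >50% LTC presence rules, the core/common/ancillary
category cuts, the 16S identity-threshold ladder and the down-sampling
fractions of the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datatypes import ValidationError

__all__ = ["PipelineConfig", "read_config", "write_config"]


@dataclass
class PipelineConfig:
    #: quantile of off-diagonal similarities used as AP preference
    q_preference: float = 0.5
    #: FDR level for retaining trait-pair correlations
    fdr_alpha: float = 0.05
    #: minimum trait prevalence (fraction of genomes) entering LTC clustering
    prevalence_min: float = 0.03
    #: optional absolute-count override for the prevalence prefilter
    prevalence_min_count: int | None = None
    #: an LTC is present in a genome when > this fraction of its traits are
    ltc_genome_frac: float = 0.5
    #: an LTC is present in a GFC when present in > this fraction of genomes
    ltc_gfc_frac: float = 0.5
    #: LTC category cuts: core > core_frac, ancillary <= ancillary_frac
    core_frac: float = 0.9
    ancillary_frac: float = 0.3
    #: 16S percent-identity ladder (species-new, species-OTU, genus, family)
    identity_thresholds: tuple[float, ...] = (100.0, 97.0, 94.5, 86.5)
    #: hit cap per OTU per threshold
    max_hits: int = 20
    #: down-sampling fractions for the taxon-coverage sensitivity analysis
    downsample_fracs: tuple[float, ...] = (0.8, 0.6, 0.4)
    #: a taxon is "overrepresented" above this fraction of all genomes
    overrepresented_frac: float = 0.05
    #: affinity propagation numerics
    ap_damping: float = 0.9
    ap_maxit: int = 1000
    ap_convits: int = 100
    ap_jitter_scale: float = 1e-9
    #: strict module completeness (no one-missing-reaction tolerance)
    strict_modules: bool = False
    #: permutations / randomizations for empirical tests
    n_permutations: int = 999
    #: taxonomic rank for coherence labels and down-sampling
    coherence_rank: str = "genus"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "q_preference", "fdr_alpha", "prevalence_min", "ltc_genome_frac",
            "ltc_gfc_frac", "core_frac", "ancillary_frac", "overrepresented_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} not in [0, 1]")
        self.identity_thresholds = tuple(float(t) for t in self.identity_thresholds)
        if list(self.identity_thresholds) != sorted(
            self.identity_thresholds, reverse=True
        ):
            raise ValidationError("identity_thresholds must be descending")
        self.downsample_fracs = tuple(float(f) for f in self.downsample_fracs)
        if any(not 0.0 < f <= 1.0 for f in self.downsample_fracs):
            raise ValidationError("downsample_fracs must be in (0, 1]")
        if not 0.5 <= self.ap_damping < 1.0:
            raise ValidationError("ap_damping must be in [0.5, 1)")
        for name in ("max_hits", "ap_maxit", "ap_convits", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.ap_jitter_scale < 0:
            raise ValidationError("ap_jitter_scale must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["identity_thresholds"] = list(self.identity_thresholds)
        d["downsample_fracs"] = list(self.downsample_fracs)
        return d


def read_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
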