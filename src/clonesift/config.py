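"""Run configuration: nested dataclasses with strict YAML (de)serialization.

Unknown keys are rejected so that typos in config files fail loudly instead
of silently running with defaults.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .types import ConfigurationError


def _from_dict(cls, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{cls.__name__}: expected mapping, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _NESTED.get((cls.__name__, name))
        if sub is not None and value is not None:
            value = _from_dict(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def _to_dict(obj) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = _to_dict(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        elif isinstance(v, dict):
            out[f.name] = dict(v)
        else:
            out[f.name] = v
    return out


@dataclass
class PanelConfig:
    n_amplicons: int = 30
    amplicon_length: tuple[int, int] = (120, 180)
    overlap_fraction: float = 0.1
    ras_mapk_share: float = 0.419
    n_genes: Optional[int] = None
    n_neutral_genes: int = 2
    n_chroms: int = 4
    fwd_primer_len: int = 20
    rev_primer_len: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.amplicon_length
        if lo - self.fwd_primer_len - self.rev_primer_len < 10:
            raise ConfigurationError(
                "amplicon length range leaves <10 bp of callable sequence"
            )
        if not 0.0 <= self.overlap_fraction <= 0.5:
            raise ConfigurationError("overlap_fraction must lie in [0, 0.5]")
        if not 0.0 <= self.ras_mapk_share < 1.0:
            raise ConfigurationError("ras_mapk_share must lie in [0, 1)")


@dataclass
class LayoutConfig:
    n_testes: int = 2
    slices_per_testis: int = 3
    biopsies_per_slice: int = 8
    n_replicates: int = 0
    n_flow_cells: int = 2
    lanes_per_flow_cell: int = 2
    mean_base_quality: float = 35.0
    base_quality_sd: float = 1.5

    @property
    def n_biopsies(self) -> int:
        return self.n_testes * self.slices_per_testis * self.biopsies_per_slice

    def __post_init__(self) -> None:
        if min(self.n_testes, self.slices_per_testis, self.biopsies_per_slice) < 1:
            raise ConfigurationError("layout dimensions must be >= 1")
        if self.n_replicates > self.n_biopsies:
            raise ConfigurationError(
                f"{self.n_replicates} replicates requested on "
                f"{self.n_biopsies} biopsies"
            )


@dataclass
class CloneConfig:
    n_clones: int = 6
    walk_length: tuple[int, int] = (2, 5)
    vaf_range: tuple[float, float] = (0.002, 0.02)
    vaf_decay: float = 0.6
    tandem_fraction: float = 0.0
    n_postzygotic: int = 0
    postzygotic_vaf: float = 0.011
    postzygotic_biopsies: tuple[int, int] = (6, 10)

    def __post_init__(self) -> None:
        lo, hi = self.vaf_range
        if hi >= 0.03 or lo <= 0.0 or lo > hi:
            # mirrors the pipeline's mosaic ceiling: candidate VAFs >= 3% are
            # treated as constitutional signal, so spiking them is rejected
            raise ConfigurationError(
                f"requested VAF range ({lo}, {hi}) must lie inside (0, 0.03)"
            )
        if not 0.0 < self.vaf_decay <= 1.0:
            raise ConfigurationError("vaf_decay must lie in (0, 1]")
        if not 0.0 < self.postzygotic_vaf < 0.03:
            raise ConfigurationError("postzygotic_vaf must lie in (0, 0.03)")


@dataclass
class ErrorModelConfig:
    median_rate: float = 1e-4
    log_sigma: float = 1.0
    flow_cell_sd: float = 0.2
    lane_sd: float = 0.2
    lane_effects: Optional[dict] = None  # explicit logit-scale shifts by lane
    flow_cell_effects: Optional[dict] = None
    bq_slope: float = -0.05  # logit-rate change per base-quality unit
    rho: float = 1e-5  # beta-binomial overdispersion of count sampling

    def __post_init__(self) -> None:
        if not 0.0 < self.median_rate < 0.01:
            raise ConfigurationError("median_rate must lie in (0, 0.01)")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must lie in [0, 1)")


@dataclass
class DepthConfig:
    mean_depth: int = 15000
    dispersion: float = 0.05  # gamma-Poisson; CV ~ sqrt(dispersion)
    n_templates: int = 1000  # input template molecules per amplicon
    bq_position_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if self.n_templates < 1:
            raise ConfigurationError("n_templates must be >= 1")


@dataclass
class CallConfig:
    mode: str = "betabinom"  # betabinom | robust_z
    p_cutoff: float = 20.0  # emit iff -log10 P exceeds this
    min_alt_reads: int = 10
    min_samples: int = 8
    mad_floor: float = 0.05  # logit units; guards degenerate vectors
    trim_fraction: float = 0.1  # top fraction excluded from the null fit
    min_amplicon_depth: float = 5000.0

    def __post_init__(self) -> None:
        if self.mode not in ("robust_z", "betabinom"):
            raise ConfigurationError(f"unknown calling mode {self.mode!r}")


@dataclass
class FilterConfig:
    min_alt_reads: int = 10
    min_median_depth: float = 5000.0
    max_vaf_cap: float = 0.03
    primer_proximal_bp: int = 1
    excess_iqr_factor: float = 3.0
    excess_min_calls: int = 25  # floor below which nobody is "excessive"
    tier2_min_vaf: float = 0.002
    tier3_min_vaf: float = 0.001
    tandem_r_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not self.tier3_min_vaf < self.tier2_min_vaf < self.max_vaf_cap:
            raise ConfigurationError(
                "require tier3_min_vaf < tier2_min_vaf < max_vaf_cap"
            )


@dataclass
class PostzygoticConfig:
    min_slices: int = 3
    min_components: int = 2
    min_biopsies: int = 6


@dataclass
class EnrichmentConfig:
    tandem_background_rate: float = 0.003

    def __post_init__(self) -> None:
        if not 0.0 < self.tandem_background_rate < 1.0:
            raise ConfigurationError("tandem_background_rate must lie in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "clonesift_run"
    panel: PanelConfig = field(default_factory=PanelConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)
    error_model: ErrorModelConfig = field(default_factory=ErrorModelConfig)
    depth: DepthConfig = field(default_factory=DepthConfig)
    calling: CallConfig = field(default_factory=CallConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    postzygotic: PostzygoticConfig = field(default_factory=PostzygoticConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    make_plots: bool = False

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _from_dict(cls, data)

    def to_dict(self) -> dict[str, Any]:
        return _to_dict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_NESTED = {
    ("RunConfig", "panel"): PanelConfig,
    ("RunConfig", "layout"): LayoutConfig,
    ("RunConfig", "clones"): CloneConfig,
    ("RunConfig", "error_model"): ErrorModelConfig,
    ("RunConfig", "depth"): DepthConfig,
    ("RunConfig", "calling"): CallConfig,
    ("RunConfig", "filters"): FilterConfig,
    ("RunConfig", "postzygotic"): PostzygoticConfig,
    ("RunConfig", "enrichment"): EnrichmentConfig,
}
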