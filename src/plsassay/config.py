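"""Run configuration with a strict YAML schema.

Unknown keys are rejected outright so a mistyped threshold can never be
silently ignored.  Defaults equal the assay's published conventions
(significance at FDR q < 0.25; connectivity selection at p < 0.05 /
tau < −90 with top-100 up/down query genes; the single-cell QC
thresholds).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .enrichment import EnrichmentParams
from .single_cell import CellQCParams

__all__ = ["ConnectivityThresholds", "RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class ConnectivityThresholds:
    cmap_p: float = 0.05
    lincs_tau: float = -90.0
    top_k: int = 100
    n_background_queries: int = 1000


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid config under {path!r}: {e}") from e


@dataclass(frozen=True)
class RunConfig:
    alpha: float = 0.25
    seed: int = 0
    min_coverage: float = 0.5
    hk_pseudocount: float = 0.5
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    connectivity: ConnectivityThresholds = field(default_factory=ConnectivityThresholds)
    qc: CellQCParams = field(default_factory=CellQCParams)
    verbosity: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        nested = {
            "enrichment": EnrichmentParams,
            "connectivity": ConnectivityThresholds,
            "qc": CellQCParams,
        }
        built = {}
        user_set_enrichment_seed = isinstance(data.get("enrichment"), dict) and "seed" in data["enrichment"]
        for key, sub_cls in nested.items():
            if key in data:
                sub = data.pop(key)
                if not isinstance(sub, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                if key == "qc" and "mito_prefixes" in sub:
                    sub["mito_prefixes"] = tuple(sub["mito_prefixes"])
                built[key] = _build(sub_cls, sub, key)
        top = _build(cls, {**data, **built}, "<root>")
        # seed threading: the enrichment seed defaults to the run seed
        if not user_set_enrichment_seed:
            er = built.get("enrichment", top.enrichment)
            er = EnrichmentParams(
                weight_p=er.weight_p,
                n_perm=er.n_perm,
                perm_mode=er.perm_mode,
                seed=top.seed,
                metric=er.metric,
            )
            object.__setattr__(top, "enrichment", er)
        return top

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
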