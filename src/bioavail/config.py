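"""Run configuration: documented flat key-value file, strict key checking,
and a content hash echoed into every output for provenance."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

from .chemstruct import DescriptorRangeConfig
from .pbpk import PBPKParams

LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")
RANGE_CHECK_MODES = ("off", "warn", "strict")


@dataclass(frozen=True)
class RunConfig:
    """All tunable keys with defaults.

    liver_blood_flow_ml_min: hepatic blood flow Q (adult human).
    gut_extraction_cyp3a4 / gut_extraction_phenol: constant gut-wall extraction
        fractions for CYP3A4 substrates / phenols.
    efflux_penalty: multiplicative absorption penalty for MDR-1/BCRP substrates.
    active_uptake_floor: minimum permeability-limited absorption for
        quinolone / beta-lactam classes.
    signature_max_height: maximum signature-descriptor height (0-3).
    cv_folds: cross-validation folds for model training.
    seed: master seed for all randomness.
    descriptor_range_check: "off", "warn" (advisory) or "strict" (out of domain)
        for the training-domain property ranges (log P, H-bond counts).
    """

    liver_blood_flow_ml_min: float = 1500.0
    gut_extraction_cyp3a4: float = 0.3
    gut_extraction_phenol: float = 0.3
    efflux_penalty: float = 0.7
    active_uptake_floor: float = 0.9
    signature_max_height: int = 2
    cv_folds: int = 10
    seed: int = 0
    log_level: str = "INFO"
    descriptor_range_check: str = "warn"

    def __post_init__(self):
        if self.log_level not in LOG_LEVELS:
            raise ValueError(f"log_level must be one of {LOG_LEVELS}")
        if self.descriptor_range_check not in RANGE_CHECK_MODES:
            raise ValueError(f"descriptor_range_check must be one of {RANGE_CHECK_MODES}")
        if not 0 <= self.signature_max_height <= 3:
            raise ValueError("signature_max_height must be in [0, 3]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def pbpk_params(self) -> PBPKParams:
        return PBPKParams(
            liver_blood_flow=self.liver_blood_flow_ml_min,
            gut_extraction_cyp3a4=self.gut_extraction_cyp3a4,
            gut_extraction_phenol=self.gut_extraction_phenol,
            efflux_penalty=self.efflux_penalty,
            active_uptake_floor=self.active_uptake_floor,
        )

    def descriptor_ranges(self) -> DescriptorRangeConfig | None:
        if self.descriptor_range_check == "off":
            return None
        return DescriptorRangeConfig(warn_only=self.descriptor_range_check == "warn")

    def provenance(self) -> str:
        return f"config_hash={self.config_hash()} seed={self.seed}"
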