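"""Run configuration: every threshold and training constant in one place.

Defaults reproduce the framework's published operating point: binding rank
thresholds 2 (MHC-I) / 10 (MHC-II); PHBR <= 2 for neoantigen burden;
dual-immunogenicity >= 0.16 for the immunogenicity burden; CCF >= 0.85 for
clonal mutations; ioTNL elimination cutoff e = 1.4; CSiN rank cutoffs
{0.375, 0.5, 0.625, 0.75, 1.25, 1.75, 2} with VAF >= 0.05 and a 500-mutation
cap; triplet margin 1; 100 epochs at learning rate 0.005 (AdamW).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # binding rank thresholds (%rank, lower = stronger)
    rank_threshold_i: float = 2.0
    rank_threshold_ii: float = 10.0
    # burdens
    phbr_threshold: float = 2.0
    npb_dual_threshold: float = 0.16
    # clonality
    ccf_clonal_threshold: float = 0.85
    iotnl_e: float = 1.4
    csin_cutoffs: tuple = (0.375, 0.5, 0.625, 0.75, 1.25, 1.75, 2.0)
    csin_vaf_min: float = 0.05
    csin_max_mutations: int = 500
    # model training
    margin: float = 1.0
    epochs: int = 100
    lr: float = 0.005
    # aggregation / integration defaults
    aggregation_method: str = "maximum"
    aggregation_masked: bool = True
    dual_integration: str = "product"
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["csin_cutoffs"] = list(self.csin_cutoffs)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "csin_cutoffs" in data:
            data["csin_cutoffs"] = tuple(data["csin_cutoffs"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
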