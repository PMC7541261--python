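"""Run configuration: one object holding every threshold the analysis uses.

Defaults are the published analysis constants (MAF 1% autosomal / 0.1% X,
constraint at <= 5 homozygous Dmis and <= 2 homozygous PTVs, brain expression
at >= 1 RPKM, co-expression |r| >= 0.8, PPI score >= 400, soft-threshold
powers 4 and 3).  Every run writes the resolved configuration, with a hash,
next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    # inputs
    ped: str = ""
    vcf: str = ""
    annotations: str = ""
    gene_info: str = ""
    expression: str = ""
    sample_meta: str = ""
    sc_expression: str = ""
    type_classes: str = ""
    ppi: str = ""
    rigs: str = ""
    dngs: str = ""
    # thresholds
    autosomal_maf: float = 0.01
    x_maf: float = 0.001
    max_hom_dmis: int = 5
    max_hom_ptv: int = 2
    brain_rpkm_min: float = 1.0
    coexpression_r_min: float = 0.8
    ppi_score_min: float = 400.0
    power_spatiotemporal: float = 4.0
    power_laminar: float = 3.0
    min_module_size: int = 10
    cut_height: float = 0.9
    n_perm: int = 1000
    alpha: float = 0.05
    event_groups: str = "ptv_and_dmis"
    seed: int = 0
    out_dir: str = "quadrec_out"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        extras = {k: v for k, v in data.items() if k not in known}
        data = {k: v for k, v in data.items() if k in known}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.extras.update(extras)
        return cfg

    def resolved_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def write_resolved(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        data = asdict(self)
        data["config_hash"] = self.resolved_hash()
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path
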