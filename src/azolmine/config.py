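"""Run configuration: one object grouping every stage's tunables, loadable
from a YAML file.  CLI flags override file values, which override defaults;
the effective configuration is embedded in every run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .mining import MiningConfig
from .motifs import MotifConfig


@dataclass
class PipelineConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    motifs: MotifConfig = field(default_factory=MotifConfig)
    precursor_flank_bp: int = 1000
    precursor_min_aa: int = 5
    precursor_max_aa: int = 170
    dedup_identity: float = 0.9
    dedup_coverage: float = 0.9
    network_cutoff: float = 0.5
    network_w_dom: float = 0.7
    network_w_prec: float = 0.3

    def snapshot(self) -> dict:
        data = asdict(self)
        for key, value in data["mining"].items():
            if isinstance(value, set):
                data["mining"][key] = sorted(value)
        return data


_SET_FIELDS = {
    "ycao_accessions", "e1_accessions", "thif_accessions", "lanb_accessions",
    "prp_accessions", "protease_accessions", "dehydrogenase_accessions",
    "transporter_accessions", "permissive_seed_accessions", "biosynthetic_accessions",
}


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    mining_kwargs = {}
    for key, value in dict(data.pop("mining", {})).items():
        mining_kwargs[key] = set(value) if key in _SET_FIELDS and value is not None else value
    motif_kwargs = dict(data.pop("motifs", {}))
    return PipelineConfig(mining=MiningConfig(**mining_kwargs),
                          motifs=MotifConfig(**motif_kwargs), **data)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
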