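"""Run configuration: one YAML file drives the whole pipeline.

Defaults reproduce the reference analysis settings: K = 30 latent
dimensions, 1000 Gibbs iterations with 500 burn-in, 10-fold CV, 999 Mantel
permutations, and the 13 widening frequency bands.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .brrr import BRRRConfig
from .synthdata import CohortConfig


@dataclass
class CohortSection:
    n_subjects: int = 60
    seed: int = 0
    generator: CohortConfig = field(default_factory=CohortConfig)


@dataclass
class FingerprintSection:
    train_segments: list = field(default_factory=lambda: ["N2a", "N2b"])
    pair: list = field(default_factory=lambda: ["N2a", "N2b"])
    methods: list = field(default_factory=lambda: ["brrr", "correlation"])
    folds: int = 10
    run_cv: bool = True


@dataclass
class StatsSection:
    enabled: bool = True
    n_perm_cluster: int = 1000
    n_perm_mantel: int = 999
    cluster_alpha: float = 0.01


@dataclass
class RunConfig:
    cohort: CohortSection = field(default_factory=CohortSection)
    brrr: BRRRConfig = field(default_factory=BRRRConfig)
    fingerprint: FingerprintSection = field(default_factory=FingerprintSection)
    stats: StatsSection = field(default_factory=StatsSection)
    output_dir: str = "sleepprint_output"

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(dc_type, payload):
            kwargs = {}
            for f in fields(dc_type):
                if f.name not in payload:
                    continue
                val = payload[f.name]
                if f.name == "generator":
                    val = CohortConfig(**val)
                kwargs[f.name] = val
            return dc_type(**kwargs)

        return cls(
            cohort=build(CohortSection, d.get("cohort", {})),
            brrr=BRRRConfig(**d.get("brrr", {})),
            fingerprint=build(FingerprintSection, d.get("fingerprint", {})),
            stats=build(StatsSection, d.get("stats", {})),
            output_dir=d.get("output_dir", "sleepprint_output"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """Scaled-down configuration for a quick end-to-end demonstration."""
    cfg = RunConfig()
    cfg.cohort.n_subjects = 30
    cfg.cohort.seed = seed
    cfg.brrr = BRRRConfig(K=10, n_iter=600, burn_in=300, seed=seed)
    cfg.fingerprint.folds = 10
    cfg.stats.n_perm_cluster = 300
    return cfg
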