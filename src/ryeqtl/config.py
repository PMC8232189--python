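"""Study configuration and run manifest."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "RunManifest", "load_config"]


@dataclass
class StudyConfig:
    """Validated configuration for a pipeline run.

    Either a simulation preset (``simulate=True``) or paths to existing
    genotype/phenotype CSVs must be given.
    """

    output_dir: str = "ryeqtl_out"
    seed: int = 0
    simulate: bool = True
    n_genotypes: int = 178
    genotype_csv: str | None = None
    phenotype_csv: str | None = None
    max_missing_fraction: float = 0.10
    rf_max: float = 0.35
    lod_min: float = 6.0
    alpha: float = 0.05
    pca_share: float = 0.995
    cofactors: str = "none"  # none | cm1 | cm2
    traits: list[str] = field(default_factory=lambda: ["perenniality", "fertility"])
    epistasis: bool = False
    build_map: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.pca_share <= 1:
            raise ValueError("pca_share must be in (0, 1]")
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if self.cofactors not in ("none", "cm1", "cm2"):
            raise ValueError("cofactors must be none, cm1 or cm2")
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be at least 2")
        if not self.simulate:
            for p in (self.genotype_csv, self.phenotype_csv):
                if p is None:
                    raise ValueError("genotype_csv and phenotype_csv required without simulation")
                if not Path(p).exists():
                    raise ValueError(f"input file does not exist: {p}")


def load_config(path: str | Path) -> StudyConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(StudyConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = StudyConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    """Per-stage accounting of a pipeline run."""

    config: dict
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                    "failed_stage": self.failed_stage,
                },
                fh,
                sort_keys=False,
            )
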