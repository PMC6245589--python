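"""Run configuration: YAML-serializable defaults for the whole framework.

The defaults reproduce the reference parametrization: stratified 80/20
test split then 50/50 train/stability split, 5-fold CV with weighted-F1
scoring, S = 100 stability subsamples of T = 80% of the stability set,
stability threshold W = 100, and the full 3 x 4 x 3 experiment menus.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .pipeline_core import CLASSIFIERS, FS_METHODS, SAMPLING_METHODS


@dataclass
class RunConfig:
    # input paths (dosage TSV mode); ignored when simulating
    genotypes: str | None = None
    snp_map: str | None = None
    covariates: str | None = None
    labels: str | None = None
    format: str = "dosage-tsv"

    test_frac: float = 0.2
    stability_frac: float = 0.5
    k: int = 5
    S: int = 100
    T: float = 0.8
    W: int = 100
    fs_methods: list = field(default_factory=lambda: list(FS_METHODS))
    samplings: list = field(default_factory=lambda: list(SAMPLING_METHODS))
    classifiers: list = field(default_factory=lambda: list(CLASSIFIERS))
    grids: dict | None = None  # None = built-in grid-search menus
    fs_fractions: dict | None = None  # None = built-in keep/step fractions
    include_covariates: bool = True
    seed: int = 0
    jobs: int = 1

    def __post_init__(self):
        if not 0 < self.W <= self.S:
            raise ValueError("require 0 < W <= S")
        if not 0 < self.T <= 1:
            raise ValueError("require 0 < T <= 1")
        for m in self.fs_methods:
            if m not in FS_METHODS:
                raise ValueError(f"unknown FS method {m!r}")
        for m in self.samplings:
            if m not in SAMPLING_METHODS:
                raise ValueError(f"unknown sampling method {m!r}")
        for m in self.classifiers:
            if m not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {m!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
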