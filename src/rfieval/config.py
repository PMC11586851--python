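"""Configuration objects for the synthetic herd generator and pipeline runs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class TraitVariances:
    """Additive and residual variance of a single trait (trait units squared)."""

    additive: float
    residual: float

    @property
    def phenotypic(self) -> float:
        return self.additive + self.residual

    @property
    def h2(self) -> float:
        return self.additive / self.phenotypic


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic herd.

    Defaults reproduce the structure of the source herd: a multi-generation
    Holstein pedigree with reused sires (half-sib families), cow records over
    days in milk 100-240 in 26 trial levels and 2 lactations, heifer feed
    trials of ~70 d with biweekly body weights, and the published residual
    feed intake (RFI) variance components (cow: additive 1.16, residual 1.55
    kg^2 DM/d^2; genetic correlation 0.42 between heifer and cow RFI).
    """

    n_founders: int = 200
    n_generations: int = 4
    n_offspring_per_generation: int | None = None  # default: n_founders
    sire_fraction: float = 0.08  # fraction of available males used as sires
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 29
    n_trials_cow: int = 26
    n_lactations: int = 2
    second_lactation_fraction: float = 420 / 2538
    # cow RFI variance components (kg^2 DM/d^2)
    cow: TraitVariances = field(default_factory=lambda: TraitVariances(1.16, 1.55))
    # heifer RFI: phenotypic variance 0.86^2 split at the cow h2 (0.43)
    heifer: TraitVariances = field(
        default_factory=lambda: TraitVariances(0.318, 0.4216)
    )
    genetic_correlation: float = 0.42
    residual_correlation: float = 0.0
    outlier_rate: float = 0.02
    # heifer trial layout
    heifer_trial_size: int = 50
    heifer_test_days: int = 70
    bw_weigh_interval: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cow, dict):
            self.cow = TraitVariances(**self.cow)
        if isinstance(self.heifer, dict):
            self.heifer = TraitVariances(**self.heifer)
        for tv in (self.cow, self.heifer):
            if tv.additive <= 0 or tv.residual <= 0:
                raise ValueError("variance components must be positive")
        if abs(self.genetic_correlation) > 1:
            raise ValueError("|genetic correlation| must be <= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def genetic_covariance(self):
        """2x2 additive (co)variance matrix K for (RFI_heifer, RFI_cow)."""
        import numpy as np

        cov = self.genetic_correlation * (self.heifer.additive * self.cow.additive) ** 0.5
        return np.array(
            [[self.heifer.additive, cov], [cov, self.cow.additive]]
        )

    @property
    def residual_covariance(self):
        import numpy as np

        cov = self.residual_correlation * (self.heifer.residual * self.cow.residual) ** 0.5
        return np.array(
            [[self.heifer.residual, cov], [cov, self.cow.residual]]
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class RunConfig:
    """A full pipeline run: simulation block (or input paths), stage toggles,
    seed and output directory.  Fully JSON-serializable so an archived config
    plus its seed reproduces the run."""

    outdir: str = "rfieval_run"
    seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    pedigree_path: str | None = None
    genotype_path: str | None = None
    cow_daily_path: str | None = None
    stages: tuple[str, ...] = (
        "simulate",
        "phenotypes",
        "matrices",
        "reml",
        "gblup",
        "cohorts",
    )
    gblup_training_fraction: float = 0.6
    close_relative_threshold: float = 0.45

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        self.stages = tuple(self.stages)
        known = {"simulate", "phenotypes", "matrices", "reml", "gblup", "cohorts"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "simulate" not in self.stages:
            if self.pedigree_path is None or self.cow_daily_path is None:
                raise ValueError(
                    "without the simulate stage, pedigree_path and "
                    "cow_daily_path must be given"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(**d)


def stage_seed(seed: int, stage: str) -> int:
    """Expand a single run seed into a per-stage seed (documented counter
    scheme: stable stage index into a SeedSequence spawn key)."""
    import numpy as np

    order = [
        "simulate",
        "phenotypes",
        "matrices",
        "reml",
        "gblup",
        "cohorts",
        "recovery",
    ]
    idx = order.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))
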