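"""Simulation configuration.

The defaults describe the study design the pipeline targets: two hatchery
lines propagated for four generations from shared wild founders, 50-100
sampled adults per population, thousands of biallelic RAD loci spread over
34 linkage groups, six polygenic fitness traits confounded by line, sex and
year, and negative-binomial RAD read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from hatchscan.containers import TRAITS


@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    n_causal loci receive additive effects drawn N(0, effect_sd); the
    environmental noise is scaled so the realized narrow-sense heritability
    matches ``h2``.  ``line_effect``, ``sex_effect`` and ``year_effect``
    inject the confounding the association step must correct for (line
    effect is added to the segregated line, year effect is multiplied by
    the generation index).
    """

    n_causal: int = 10
    effect_sd: float = 1.0
    h2: float = 0.3
    line_effect: float = 0.0
    sex_effect: float = 0.0
    year_effect: float = 0.0
    # "gaussian": per-allele effects ~ N(0, effect_sd); "standardized":
    # effects scaled by the inverse dosage SD so every causal locus
    # contributes an equal share h2/n_causal of the phenotypic variance
    # (the calibrated design for power scenarios).
    effect_kind: str = "gaussian"
    min_causal_maf: float = 0.05  # causal loci drawn among loci above this MAF

    def validate(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.effect_kind not in ("gaussian", "standardized"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if not 0.0 <= self.min_causal_maf < 0.5:
            raise ValueError("min_causal_maf must be in [0, 0.5)")


@dataclass
class DepthModel:
    """Negative-binomial sequencing-depth model for RAD loci.

    Total depth per (individual, locus) is NB(mean_depth, dispersion); for
    heterozygotes the two alleles split the reads Binomial(total, 0.5), for
    homozygotes the off-allele receives Binomial(total, error_rate) reads.
    """

    mean_depth: float = 40.0
    dispersion: float = 10.0
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


@dataclass
class SimConfig:
    """Full configuration of the synthetic study.

    All randomness downstream of a given config flows from ``seed``;
    identical configs therefore produce bit-identical outputs.
    """

    n_loci: int = 2000
    n_chromosomes: int = 34
    founder_maf_dist: tuple[float, float] = (0.8, 0.8)  # Beta(a, b) on allele freq
    n_generations: int = 4
    n_founders: int = 100
    samples_per_population: int = 75
    ne_integrated: int = 150
    ne_segregated: int = 60
    ne_wild: int = 1000
    gene_flow_integrated: float = 1.0  # fraction of wild-origin parents per generation
    mapped_fraction: float = 0.5
    selected_loci: list[tuple[str, float]] = field(default_factory=list)
    trait_architectures: dict[str, TraitArchitecture] = field(default_factory=dict)
    depth_model: DepthModel = field(default_factory=DepthModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in TRAITS:
            self.trait_architectures.setdefault(name, TraitArchitecture())
        self.validate()

    def validate(self) -> None:
        a, b = self.founder_maf_dist
        if a <= 0 or b <= 0:
            raise ValueError("founder_maf_dist Beta parameters must be positive")
        if not 0.0 <= self.gene_flow_integrated <= 1.0:
            raise ValueError("gene_flow_integrated must be in [0, 1]")
        if min(self.ne_integrated, self.ne_segregated, self.ne_wild) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValueError("mapped_fraction must be in [0, 1]")
        for arch in self.trait_architectures.values():
            arch.validate()
        self.depth_model.validate()

    # -- YAML round trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trait_architectures" in raw:
            raw["trait_architectures"] = {
                k: TraitArchitecture(**v) for k, v in raw["trait_architectures"].items()
            }
        if "depth_model" in raw:
            raw["depth_model"] = DepthModel(**raw["depth_model"])
        if "founder_maf_dist" in raw:
            raw["founder_maf_dist"] = tuple(raw["founder_maf_dist"])
        if "selected_loci" in raw:
            raw["selected_loci"] = [tuple(x) for x in raw["selected_loci"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_loci": self.n_loci,
            "n_chromosomes": self.n_chromosomes,
            "founder_maf_dist": list(self.founder_maf_dist),
            "n_generations": self.n_generations,
            "n_founders": self.n_founders,
            "samples_per_population": self.samples_per_population,
            "ne_integrated": self.ne_integrated,
            "ne_segregated": self.ne_segregated,
            "ne_wild": self.ne_wild,
            "gene_flow_integrated": self.gene_flow_integrated,
            "mapped_fraction": self.mapped_fraction,
            "selected_loci": [list(x) for x in self.selected_loci],
            "trait_architectures": {
                k: vars(v) for k, v in self.trait_architectures.items()
            },
            "depth_model": vars(self.depth_model),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
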