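"""Run and simulation configuration.

:class:`SimConfig` pins down the synthetic study design: a 12-sample
layout (3 ground controls and 3 flight individuals at each of two growth
stages), planted differentially methylated regions, planted expression
fold changes, planted co-expression rewiring, and planted miRNA target
sites. :class:`RunConfig` carries the analysis thresholds used throughout
the pipeline. Both load from YAML and validate on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass(frozen=True)
class DmrPlanItem:
    """One planted differentially methylated region."""

    context: str              # CG / CHG / CHH
    delta: float              # methylation-level shift in flight samples
    n_sites: int = 10         # cytosines of this context in the region
    depth: int = 20           # read depth at the planted sites
    region_length: int = 400  # maximal genomic span of the region, bp

    def __post_init__(self):
        if self.context not in ("CG", "CHG", "CHH"):
            raise ValueError(f"bad context {self.context!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


@dataclass(frozen=True)
class DegPlanItem:
    """A slice of molecules receiving a planted log2 fold change."""

    fraction: float
    log2fc: float
    direction: str = "up"

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be up/down")

    @property
    def signed_log2fc(self) -> float:
        return abs(self.log2fc) if self.direction == "up" else -abs(self.log2fc)


@dataclass(frozen=True)
class TargetPlan:
    """Planted miRNA target sites in MR transcripts."""

    n_sites: int = 8
    budget: int = 1  # non-seed mismatches per planted site (expectation units)


def _default_dmr_plan() -> list[DmrPlanItem]:
    # more hypo- than hypermethylated regions, context-typical magnitudes
    return (
        [DmrPlanItem("CG", -0.4)] * 4
        + [DmrPlanItem("CG", +0.3)] * 2
        + [DmrPlanItem("CHG", -0.25)] * 3
        + [DmrPlanItem("CHG", +0.25)]
        + [DmrPlanItem("CHH", -0.08)] * 2
        + [DmrPlanItem("CHH", +0.3)] * 2
    )


def _default_deg_plan() -> list[DegPlanItem]:
    return [DegPlanItem(0.05, 2.0, "up"), DegPlanItem(0.05, 2.0, "down")]


@dataclass
class SimConfig:
    """Parameters of the synthetic 12-sample multi-omics study."""

    seed: int = 0
    n_genes: int = 150
    n_mirnas: int = 80
    genome_length: int = 1_000_000
    n_control: int = 3
    n_flight: int = 3
    stages: tuple[str, ...] = ("tillering", "heading")
    gene_length: tuple[int, int] = (1000, 2000)
    min_gene_gap: int = 4000

    # methylome layer
    baseline_levels: dict = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.3, "CHH": 0.1}
    )
    beta_concentration: float = 30.0  # site-to-site baseline overdispersion
    mean_depth: int = 20
    site_fraction: float = 0.12       # fraction of genomic cytosines emitted
    dmr_plan: list[DmrPlanItem] = field(default_factory=_default_dmr_plan)

    # expression layer
    noise_cv: float = 0.2             # lognormal CV of expression
    module_corr: float = 0.9          # within-module Pearson correlation
    module_size_range: tuple[int, int] = (8, 35)
    deg_plan: list[DegPlanItem] = field(default_factory=_default_deg_plan)
    demir_plan: list[DegPlanItem] = field(default_factory=_default_deg_plan)
    dig_fraction: float = 0.10
    dimir_fraction: float = 0.10
    n_allzero_genes: int = 3
    n_allzero_mirnas: int = 2

    # miRNA targeting layer
    target_plan: TargetPlan = field(default_factory=TargetPlan)
    mirna_length: int = 21
    n_planted_pairs: int = 4          # opposite-direction DEmiR/DEMR pairs

    def __post_init__(self):
        for frac in (self.dig_fraction, self.dimir_fraction, self.site_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.mean_depth < 1:
            raise ValueError("mean depth must be >= 1")
        lo, hi = self.module_size_range
        if lo < 3:
            raise ValueError("module size < 3 rejected (correlation undefined)")

    @property
    def sample_sheet(self) -> list[dict]:
        rows = []
        for stage in self.stages:
            prefix = stage[0].upper()
            for i in range(1, self.n_control + 1):
                rows.append(
                    {"sample_id": f"{prefix}C{i}", "group": "control",
                     "stage": stage, "individual": i}
                )
            for i in range(1, self.n_flight + 1):
                rows.append(
                    {"sample_id": f"{prefix}S{i}", "group": "flight",
                     "stage": stage, "individual": i}
                )
        return rows

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        if "dmr_plan" in kwargs:
            kwargs["dmr_plan"] = [DmrPlanItem(**d) for d in kwargs["dmr_plan"]]
        for key in ("deg_plan", "demir_plan"):
            if key in kwargs:
                kwargs[key] = [DegPlanItem(**d) for d in kwargs[key]]
        if "target_plan" in kwargs:
            kwargs["target_plan"] = TargetPlan(**kwargs["target_plan"])
        for key in ("stages", "gene_length", "module_size_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Analysis thresholds for a full pipeline run."""

    seed: int = 0
    min_coverage: int = 4
    dmr_site_alpha: float = 0.01
    dmr_min_delta: float = 0.1
    dmr_max_gap: int = 200
    dmr_min_sites: int = 3
    dmr_region_alpha: float = 0.05
    de_alpha: float = 0.05
    de_lfc_gate: float = 1.0
    eps: float = 0.01
    tau: float = 0.8
    target_cutoff: float = 5.0
    target_max_gaps: int = 1
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.de_alpha < 1 or not 0 < self.dmr_region_alpha < 1:
            raise ValueError("alphas must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        # one seed drives both the simulation and any downstream randomness
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
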