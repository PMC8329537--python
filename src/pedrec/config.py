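"""Configuration objects for the simulator and the pipeline.

``SimConfig`` holds every generative parameter of the synthetic-data module;
``RunConfig`` holds paths, thresholds and stage toggles for the end-to-end
pipeline.  All study constants (50K panel floor, 45-crossover cap, 26.67/4.44
degree-C temperature cutoffs, age bins) live here with their standard values
as defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Nominal marker counts of common bovine genotyping panels.  The panel label
# carried in the pedigree decides whether a family survives the chip-density
# filter; the simulated marker set itself is desk-scale.
CHIP_PANELS: dict[str, int] = {
    "HD77K": 77000,
    "GGP50K": 54609,
    "LD7K": 6909,
    "LD3K": 2900,
}

#: Temperature above which the environment counts as heat stress (degrees C).
HOT_THRESHOLD_C = 26.67
#: Temperature below which the environment counts as cold stress (degrees C).
COLD_THRESHOLD_C = 4.44
#: Genome-wide crossover-count cap; meioses above it are treated as artefacts.
MAX_CROSSOVERS = 45
#: Minimum nominal panel density (markers) for a family to be analysed.
MIN_PANEL_MARKERS = 50000


@dataclass
class SimConfig:
    """Parameters of the synthetic cattle-pedigree generator.

    The defaults describe the study conditions the generator emulates: a
    multi-generation dairy pedigree genotyped on 50K-class panels, maternal
    genome-wide crossover counts with marginal mean 23.2 and variance 98.3,
    a narrow-sense heritability of 0.10 on the count scale, a quadratic
    maternal-age effect and hot/cold temperature effects during fetal
    development of the offspring.

    Effect sizes are on the count (rate) scale: the latent expected count of
    one meiosis is ``alpha + beta . x + g + e`` where ``g`` is the dam's
    additive genetic value and ``e`` a non-genetic latent deviation; the
    observed count is Poisson given that latent rate.
    """

    n_founders: int = 60
    n_generations: int = 3
    n_chromosomes: int = 5
    markers_per_chrom: int = 400
    #: Genetic length of each chromosome in Morgans.  ``None`` means
    #: base_rate_mu / n_chromosomes so the map length matches the expected
    #: genome-wide count.
    genetic_map_length_per_chrom: float | None = None
    #: Founder minor-allele frequencies are drawn Uniform(low, high).
    founder_maf_range: tuple[float, float] = (0.05, 0.5)

    # --- crossover-count model (latent-rate scale) ---
    base_rate_mu: float = 23.2
    rate_variance: float = 98.3
    h2_true: float = 0.10
    beta_age: float = -0.082
    beta_age2: float = 4.69e-4
    beta_birthyear: float = 5.02e-3
    beta_birthyear2: float = -4.41e-7
    beta_hot: float = 0.167
    beta_cold: float = -0.194
    beta_t2_hot: float = 0.0
    beta_t2_cold: float = 0.0

    #: (annual mean degC, seasonal amplitude degC, month-to-month noise sd degC)
    seasonal_temp: tuple[float, float, float] = (15.0, 13.0, 2.5)

    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0

    n_farms: int = 8
    founder_birth_years: tuple[int, int] = (2000, 2006)
    #: Sampling weights of panel labels assigned to animals.
    chip_mix: dict[str, float] = field(
        default_factory=lambda: {"GGP50K": 0.8, "HD77K": 0.2}
    )
    bp_per_chrom: int = 100_000_000
    #: Maternal age at calving: 20 + Gamma(shape, scale) months.
    age_gamma: tuple[float, float] = (1.6, 14.0)
    #: Floor applied to the latent Poisson rate.
    rate_floor: float = 0.5

    seed: int = 2021

    def __post_init__(self) -> None:
        self.validate()

    @property
    def map_length_per_chrom(self) -> float:
        if self.genetic_map_length_per_chrom is not None:
            return self.genetic_map_length_per_chrom
        return self.base_rate_mu / self.n_chromosomes

    @property
    def sigma_g2(self) -> float:
        """Additive-genetic variance of the latent rate implied by h2_true."""
        return self.h2_true * self.rate_variance

    def validate(self) -> None:
        for name in ("n_founders", "n_generations", "n_chromosomes",
                     "markers_per_chrom", "n_farms", "bp_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must lie in [0, 1], got {self.h2_true}")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.map_length_per_chrom <= 0:
            raise ValueError("genetic map length must be positive")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"founder_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.founder_maf_range}")
        if self.base_rate_mu <= 0 or self.rate_variance <= 0:
            raise ValueError("base_rate_mu and rate_variance must be positive")
        unknown = set(self.chip_mix) - set(CHIP_PANELS)
        if unknown:
            raise ValueError(f"unknown chip classes in chip_mix: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Pipeline configuration: paths, thresholds, stage toggles, seed."""

    outdir: str = "pedrec_run"
    # Inputs; ignored when simulate=True (the simulator writes them).
    pedigree_csv: str | None = None
    genotypes_vcf: str | None = None
    temperature_csv: str | None = None
    region_mask_bed: str | None = None

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    min_panel_markers: int = MIN_PANEL_MARKERS
    max_crossovers: int = MAX_CROSSOVERS
    hot_threshold_c: float = HOT_THRESHOLD_C
    cold_threshold_c: float = COLD_THRESHOLD_C
    #: Families with a higher fraction of Mendelian-inconsistent sites are dropped.
    max_inconsistency_rate: float = 0.02
    #: Month used for the temperature covariates: the calendar month before
    #: birth ("pre_birth_month") or the month before conception assuming a
    #: 280-day gestation ("conception_month").
    temperature_reference: str = "pre_birth_month"
    age_group_start: int = 20
    age_group_width: int = 10
    n_age_groups: int = 10

    run_temperature_stage: bool = True
    run_model_stage: bool = True

    seed: int = 2021

    def validate(self) -> None:
        if self.min_panel_markers < 0 or self.max_crossovers <= 0:
            raise ValueError("thresholds must be positive")
        if self.temperature_reference not in ("pre_birth_month", "conception_month"):
            raise ValueError(f"unknown temperature_reference {self.temperature_reference!r}")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {}) or {}
        known_sim = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_raw) - known_sim
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        for key in ("seasonal_temp", "founder_birth_years", "founder_maf_range", "age_gamma"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimConfig(**sim_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d
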