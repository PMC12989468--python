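"""Configuration objects for the simulator and the analysis stages.

All tunable parameters of the pipeline live in small dataclasses so that a
single YAML file can drive a fully reproducible run.  Defaults encode the
study conditions the pipeline is designed around: a 205-participant
enrollment funnelling to a 150-participant final cohort, an 8-week
machine-based resistance program on 7 strength machines, three stool
sampling timepoints (W0/W4/W8) at ~69k reads/sample, and a mean strength
gain of 24 +/- 16 percent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: The seven strength machines of the training protocol.
MACHINES: tuple[str, ...] = (
    "Leg press",
    "Leg curl",
    "Back trainer",
    "Abdominal trainer",
    "Chest press",
    "Seated row",
    "Lat pull",
)

#: Typical maximum-strength scale of each machine relative to the leg press.
#: Used both by the simulator (baseline strength per machine) and by the
#: age-strength reference curve (machine-specific reference level).
MACHINE_STRENGTH_FRACTION: dict[str, float] = {
    "Leg press": 1.00,
    "Leg curl": 0.35,
    "Back trainer": 0.45,
    "Abdominal trainer": 0.40,
    "Chest press": 0.45,
    "Seated row": 0.50,
    "Lat pull": 0.50,
}

TIMEPOINTS: tuple[str, ...] = ("W0", "W4", "W8")


@dataclass
class CohortConfig:
    """Enrollment funnel and demographics of the simulated cohort."""

    n_enrolled: int = 205
    n_dropout: int = 43
    n_quality_excluded: int = 6
    n_validation_excluded: int = 6
    sex_fraction_male: float = 0.426
    age_mean: float = 41.7
    age_sd: float = 11.6
    age_min: float = 24.0
    age_max: float = 61.0
    bmi_mean: float = 24.5
    bmi_sd: float = 3.5
    #: fraction of participants assigned to regular resistance training (RRT);
    #: the remainder train the muscle-building program (MBRT).
    group_split: float = 0.487
    seed: int = 0

    @property
    def final_size(self) -> int:
        return (
            self.n_enrolled
            - self.n_dropout
            - self.n_quality_excluded
            - self.n_validation_excluded
        )

    def validate(self) -> None:
        counts = (
            self.n_enrolled,
            self.n_dropout,
            self.n_quality_excluded,
            self.n_validation_excluded,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("cohort counts must be nonnegative")
        if self.final_size < 0:
            raise ConfigError("exclusions exceed enrollment")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ConfigError("sex_fraction_male must be a proportion")
        if not 0.0 <= self.group_split <= 1.0:
            raise ConfigError("group_split must be a proportion")


#: (program name, repetitions per machine per set, concentric %, eccentric %)
#: for each of the four 2-week phases, per training group.  The isokinetic
#: phase performs 2 x 8 repetitions per set, encoded as 16.
PHASE_SCHEDULE: dict[str, tuple[tuple[str, int, float, float], ...]] = {
    "RRT": (
        ("regular", 20, 45.0, 45.0),
        ("negative", 15, 38.0, 58.0),
        ("regular", 20, 45.0, 45.0),
        ("negative", 15, 38.0, 58.0),
    ),
    "MBRT": (
        ("negative", 15, 38.0, 58.0),
        ("adaptive", 10, 68.0, 68.0),
        ("isokinetic", 16, 73.0, 105.0),
        ("adaptive", 10, 68.0, 68.0),
    ),
}


@dataclass
class TrainingSimConfig:
    """Session-log and strength-trajectory generator parameters.

    The per-participant total strength gain (percent, W0 -> W8) is drawn from
    a normal distribution; the week-4 fitness test captures ``w4_fraction``
    of the total gain on the log2 scale, reflecting the faster improvement in
    the first program half.  ``baseline_gain_corr`` is the Gaussian-copula
    correlation between baseline strength and subsequent gain (negative:
    weaker participants improve relatively more).
    """

    machines: tuple[str, ...] = MACHINES
    sessions_per_week: tuple[int, int] = (2, 3)
    weeks: int = 8
    sets_per_machine: int = 2
    phase_schedule: Mapping[str, tuple] = field(
        default_factory=lambda: dict(PHASE_SCHEDULE)
    )
    gain_mean: float = 24.0  # percent
    gain_sd: float = 16.0  # percent
    gain_floor: float = -90.0  # percent; truncation to keep strengths positive
    baseline_legpress_mean: float = 154.0  # kg
    baseline_legpress_sd: float = 54.0  # kg
    baseline_legpress_min: float = 40.0  # kg
    #: per-machine multiplicative spread of baseline strength (log-normal sd)
    machine_baseline_sd: float = 0.15
    #: per-machine deviation of the individual gain, in log2 units
    machine_noise_sd: float = 0.05
    w4_fraction: float = 0.7
    baseline_gain_corr: float = -0.35
    #: sex effect on absolute strength, normalized to leave the cohort mean
    #: at baseline_legpress_mean for the default sex ratio
    sex_strength_factor: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.22, "female": 0.84}
    )
    #: Beta(a, b) prior of the per-participant repetition-miss propensity
    compliance_beta: tuple[float, float] = (2.0, 38.0)
    start_date: str = "2022-05-02"  # a Monday
    seed: int = 0

    def validate(self) -> None:
        if len(self.machines) != 7:
            raise ConfigError("exactly 7 machines are required")
        for group, phases in self.phase_schedule.items():
            if len(phases) != 4:
                raise ConfigError(f"group {group!r} needs 4 two-week phases")
            for prog, reps, conc, ecc in phases:
                if not (0 < conc <= 150 and 0 < ecc <= 150):
                    raise ConfigError(
                        f"phase percentages must lie in (0, 150]: {prog}"
                    )
                if reps <= 0:
                    raise ConfigError("repetitions must be positive")
        lo, hi = self.sessions_per_week
        if not 1 <= lo <= hi:
            raise ConfigError("invalid sessions_per_week range")


@dataclass
class MicrobiomeSimConfig:
    """Hierarchical log-normal -> multinomial ASV count simulator.

    Per-ASV baseline log-abundances are i.i.d. normal; each participant
    carries an ASV-specific random intercept so repeated samples of one gut
    are correlated; sample-level noise is added on top; the softmax of the
    log-abundances is the composition from which reads are drawn
    multinomially at a negative-binomial depth.  A designated set of
    "planted" ASVs shifts at W4 (partial effect) and W8 (full effect), the
    magnitude coupled to the participant's strength-gain percentile through
    ``coupling_strength``.
    """

    n_asv: int = 300
    mean_depth: float = 69_000.0
    #: negative-binomial size parameter; variance = mu + mu^2 / dispersion
    depth_dispersion: float = 25.0
    baseline_log_abundance_sd: float = 1.5
    within_subject_correlation: float = 0.5
    #: per-sample log-scale noise sd (natural log)
    within_sd: float = 0.5
    n_planted_up: int = 16
    n_planted_down: int = 11
    planted_up: Optional[tuple[str, ...]] = None
    planted_down: Optional[tuple[str, ...]] = None
    effect_log2fc_w4: float = 1.25
    effect_log2fc_w8: float = 2.5
    #: the planted shift of participant p is effect * coupling_strength *
    #: percentile(gain_p): with coupling on, the community shift grows with
    #: the participant's strength-gain rank and vanishes at the bottom of
    #: the cohort; coupling_strength = 0 silences the planted effects.
    coupling_strength: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.n_asv <= 0:
            raise ConfigError("n_asv must be positive")
        if not 0.0 <= self.within_subject_correlation < 1.0:
            raise ConfigError("within_subject_correlation must lie in [0, 1)")
        import math

        for eff in (self.effect_log2fc_w4, self.effect_log2fc_w8):
            if not math.isfinite(eff):
                raise ConfigError("effect sizes must be finite")
        if self.planted_up is not None and self.planted_down is not None:
            if set(self.planted_up) & set(self.planted_down):
                raise ConfigError("planted sets must be disjoint")


@dataclass
class BioAgeParams:
    """Exponential age-strength reference surrogate.

    The reference relative strength (max strength / body weight) is modeled
    as R(age) = peak_relative_strength * sex_factor * machine_factor *
    exp(-decline_rate * (age - peak_age)) for age >= peak_age.  The age
    equivalent of an observed relative strength is the analytic inverse of
    this curve, averaged over machines, and never reported below ``floor``.
    This is a transparent surrogate, not the proprietary gym-equipment model.
    """

    peak_age: float = 25.0
    peak_relative_strength: float = 2.2  # leg-press strength / body weight
    decline_rate: float = 0.01  # per year
    floor: float = 21.0  # years
    sex_factor: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.15, "female": 0.90}
    )
    machine_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(MACHINE_STRENGTH_FRACTION)
    )

    def validate(self) -> None:
        if self.decline_rate <= 0:
            raise ConfigError("decline_rate must be positive")
        if self.floor < 0:
            raise ConfigError("floor must be nonnegative")

    def reference(self, age: float, sex: str, machine: str) -> float:
        """Reference relative strength at ``age`` (constant before peak_age)."""
        import math

        base = (
            self.peak_relative_strength
            * self.sex_factor[sex]
            * self.machine_factor[machine]
        )
        if age <= self.peak_age:
            return base
        return base * math.exp(-self.decline_rate * (age - self.peak_age))


@dataclass
class DaaConfig:
    """Differential-abundance thresholds and contrasts."""

    pseudocount: float = 0.5
    prevalence_min: float = 0.25
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    contrasts: tuple[str, ...] = ("W4", "W8")
    baseline: str = "W0"

    def validate(self) -> None:
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.baseline in self.contrasts:
            raise ConfigError("contrasts must reference the baseline")


@dataclass
class DietSimConfig:
    """Stable per-participant diet profiles with small survey noise."""

    food_noise_sd: float = 0.5  # ordinal frequency units
    drink_noise_frac: float = 0.10  # multiplicative
    seed: int = 0


@dataclass
class PredictConfig:
    """Random-forest responder-prediction benchmark parameters."""

    n_estimators: int = 500
    n_perm: int = 1000
    n_folds: int = 5
    seed: int = 0


@dataclass
class PipelineConfig:
    """One config to drive every stage of ``run_all``."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    training: TrainingSimConfig = field(default_factory=TrainingSimConfig)
    microbiome: MicrobiomeSimConfig = field(default_factory=MicrobiomeSimConfig)
    diet_sim: DietSimConfig = field(default_factory=DietSimConfig)
    daa: DaaConfig = field(default_factory=DaaConfig)
    bioage: BioAgeParams = field(default_factory=BioAgeParams)
    predict: PredictConfig = field(default_factory=PredictConfig)
    rarefaction_depth: Optional[int] = None  # None: 90% of min sample depth
    n_subsets: int = 100
    responder_low_q: float = 0.2
    responder_high_q: float = 0.8
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "strength",
        "responders",
        "diversity",
        "coupling",
        "daa",
        "permtest",
        "diet",
        "predict",
        "report",
    )


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "training": TrainingSimConfig,
    "microbiome": MicrobiomeSimConfig,
    "diet_sim": DietSimConfig,
    "daa": DaaConfig,
    "bioage": BioAgeParams,
    "predict": PredictConfig,
}


def _build(cls, data: Mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        coerced[key] = value
    return cls(**coerced)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a YAML mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build(_SECTION_TYPES[key], value or {})
        elif key == "stages":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    config = _build_pipeline(kwargs)
    return config


def _build_pipeline(kwargs: dict) -> PipelineConfig:
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(kwargs) - names
    if unknown:
        raise ConfigError(f"unknown pipeline fields: {sorted(unknown)}")
    return PipelineConfig(**kwargs)
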