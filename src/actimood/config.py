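"""Configuration objects for the synthetic cohort and the analysis pipeline.

The synthetic cohort emulates a three-group case-control design — probable
bipolar disorder (BD), probable unipolar mania/hypomania (UM) and a no-mood-
disorder control group — plus the two strata the phenotyping stage removes
(participants meeting exclusion criteria, and depression-only participants).
Group-conditional defaults (demographic distributions, questionnaire response
probabilities, rest-activity signal parameters) are fixed constants of the
emulated study design; see ``docs/methods.md`` for their provenance.

All configuration is plain dataclasses, round-trippable through YAML with
unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "Demographics",
    "QuestionnaireProbs",
    "ActigraphyParams",
    "GroupParams",
    "InjectedEffect",
    "CohortConfig",
    "SleepDetectorParams",
    "StatsParams",
    "RunConfig",
    "load_config",
    "save_config",
    "GROUPS",
    "STRATA",
    "EXCLUSION_FLAGS",
    "EDUCATION_LEVELS",
    "ETHNICITY_LEVELS",
    "SMOKING_LEVELS",
    "ALCOHOL_LEVELS",
    "CHRONOTYPE_LEVELS",
    "GETTING_UP_LEVELS",
    "SLEEPLESSNESS_LEVELS",
    "HAPPINESS_LEVELS",
    "NAPPING_LEVELS",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


GROUPS = ("BD", "UM", "control")
STRATA = GROUPS + ("depression_only", "excluded")

EXCLUSION_FLAGS = (
    "neurological",
    "brain_cancer_injury",
    "personality_disorder",
    "psychosis",
    "schizophrenia",
    "sleep_apnoea_insomnia",
    "shift_work",
)

EDUCATION_LEVELS = ("incomplete", "compulsory", "continued", "college", "university")
ETHNICITY_LEVELS = ("white", "mixed", "asian", "black", "chinese", "other")
SMOKING_LEVELS = ("never", "previous", "current")
ALCOHOL_LEVELS = ("never", "previous", "current")
CHRONOTYPE_LEVELS = (
    "definitely_morning",
    "more_morning",
    "more_evening",
    "definitely_evening",
    "do_not_know",
    "prefer_not_answer",
)
GETTING_UP_LEVELS = ("very_easy", "fairly_easy", "not_very_easy", "not_at_all_easy")
SLEEPLESSNESS_LEVELS = ("never_rarely", "sometimes", "usually")
HAPPINESS_LEVELS = (
    "extremely_happy",
    "very_happy",
    "moderately_happy",
    "moderately_unhappy",
    "very_unhappy",
    "extremely_unhappy",
)
NAPPING_LEVELS = ("never", "sometimes", "regular")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


def _check_probs(name: str, ps, n: int) -> None:
    if len(ps) != n:
        raise ConfigError(f"{name} must have {n} entries, got {len(ps)}")
    for p in ps:
        _check_prob(name, p)
    total = float(sum(ps))
    if abs(total - 1.0) > 1e-8:
        raise ConfigError(f"{name} must sum to 1, got {total}")


def _check_nonneg(name: str, x: float) -> None:
    if x < 0:
        raise ConfigError(f"{name} must be >= 0, got {x!r}")


@dataclass
class Demographics:
    """Group-conditional demographic / covariate distributions."""

    age_mean: float = 57.06
    age_sd: float = 7.56
    p_female: float = 0.4665
    townsend_mean: float = -2.00
    townsend_sd: float = 2.67
    education_probs: tuple = (0.0816, 0.1445, 0.0607, 0.2707, 0.4425)
    ethnicity_probs: tuple = (0.9706, 0.0037, 0.0098, 0.0084, 0.0027, 0.0048)
    smoking_probs: tuple = (0.6146, 0.3305, 0.0549)
    alcohol_probs: tuple = (0.0301, 0.0191, 0.9508)
    bmi_mean: float = 26.53
    bmi_sd: float = 4.14
    p_psychotropic: float = 0.0033

    def __post_init__(self) -> None:
        # Allow slightly off-one printed proportions by renormalising.
        for name in ("education_probs", "ethnicity_probs", "smoking_probs", "alcohol_probs"):
            ps = tuple(float(p) for p in getattr(self, name))
            total = sum(ps)
            if total <= 0:
                raise ConfigError(f"{name} must have positive sum")
            if abs(total - 1.0) > 1e-9:  # keep already-normalised tuples bit-stable
                ps = tuple(p / total for p in ps)
            object.__setattr__(self, name, ps)

    def validate(self) -> None:
        _check_nonneg("age_sd", self.age_sd)
        _check_nonneg("townsend_sd", self.townsend_sd)
        _check_nonneg("bmi_sd", self.bmi_sd)
        _check_prob("p_female", self.p_female)
        _check_prob("p_psychotropic", self.p_psychotropic)
        _check_probs("education_probs", self.education_probs, len(EDUCATION_LEVELS))
        _check_probs("ethnicity_probs", self.ethnicity_probs, len(ETHNICITY_LEVELS))
        _check_probs("smoking_probs", self.smoking_probs, len(SMOKING_LEVELS))
        _check_probs("alcohol_probs", self.alcohol_probs, len(ALCOHOL_LEVELS))


@dataclass
class QuestionnaireProbs:
    """Group-conditional self-report response probabilities.

    The mania/depression items drive the phenotyping algorithm; the defaults
    are chosen so that a participant's generated answers satisfy (or fail)
    their own group's diagnostic criteria with probability >= 0.99.
    """

    # mania module (gate items + whether the symptom count clears the >= 3 rule)
    p_hyper: float = 0.03
    p_irritable: float = 0.04
    p_mania_symptoms_meet: float = 0.02
    # depression module
    p_depressed: float = 0.20
    p_anhedonia: float = 0.10
    p_dep_symptoms_meet: float = 0.015
    p_consulted: float = 0.60
    # mental health / wellbeing
    p_anxiety: float = 0.0571
    p_self_harm: float = 0.0079
    p_risk_taker: float = 0.2465
    neuroticism_mean: float = 2.54  # out of 12 binary items
    p_unhappy: float = 0.0105
    p_unhappy_health: float = 0.0603
    # subjective sleep
    chronotype_probs: tuple = (0.2503, 0.3058, 0.3058, 0.0682, 0.04, 0.03)
    sleeplessness_probs: tuple = (0.35, 0.41, 0.24)
    getting_up_probs: tuple = (0.3210, 0.5706, 0.0867, 0.0217)
    napping_probs: tuple = (0.61, 0.35, 0.04)
    subjective_sleep_mean_h: float = 7.2
    subjective_sleep_sd_h: float = 0.85

    def __post_init__(self) -> None:
        # printed-precision proportions may be off one by ~1e-4; renormalise
        for name in ("chronotype_probs", "sleeplessness_probs", "getting_up_probs", "napping_probs"):
            ps = tuple(float(p) for p in getattr(self, name))
            total = sum(ps)
            if total <= 0:
                raise ConfigError(f"{name} must have positive sum")
            if abs(total - 1.0) > 1e-9:  # keep already-normalised tuples bit-stable
                ps = tuple(p / total for p in ps)
            object.__setattr__(self, name, ps)

    def validate(self) -> None:
        for name in (
            "p_hyper",
            "p_irritable",
            "p_mania_symptoms_meet",
            "p_depressed",
            "p_anhedonia",
            "p_dep_symptoms_meet",
            "p_consulted",
            "p_anxiety",
            "p_self_harm",
            "p_risk_taker",
            "p_unhappy",
            "p_unhappy_health",
        ):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.neuroticism_mean <= 12.0):
            raise ConfigError("neuroticism_mean must be in [0, 12]")
        _check_probs("chronotype_probs", self.chronotype_probs, len(CHRONOTYPE_LEVELS))
        _check_probs("sleeplessness_probs", self.sleeplessness_probs, len(SLEEPLESSNESS_LEVELS))
        _check_probs("getting_up_probs", self.getting_up_probs, len(GETTING_UP_LEVELS))
        _check_probs("napping_probs", self.napping_probs, len(NAPPING_LEVELS))
        _check_nonneg("subjective_sleep_sd_h", self.subjective_sleep_sd_h)


@dataclass
class ActigraphyParams:
    """Rest-activity signal model parameters for one group.

    The daytime profile is ``mesor + amplitude * max(0, cos(2*pi*(t - peak)/24))``
    (milli-g) plus zero-truncated Gaussian noise; the nightly sleep window is
    near-zero activity interrupted by Bernoulli wake bouts; fragmentation
    inserts low-activity bouts into the daytime.
    """

    mesor: float = 34.0  # milli-g
    amplitude: float = 25.0  # milli-g
    peak_time_h: float = 15.0  # clock hour of the diurnal activity peak
    noise_sd: float = 8.0  # milli-g, awake epochs
    sleep_noise_sd: float = 1.0  # milli-g, asleep epochs
    sleep_onset_mean_h: float = 23.25  # clock hour
    sleep_onset_sd_h: float = 0.5
    sleep_length_mean_h: float = 9.5
    sleep_length_sd_h: float = 0.5
    phase_jitter_sd_h: float = 0.6  # day-to-day shift of the whole profile
    fragmentation_rate_per_h: float = 1.0  # expected daytime low-activity bouts/h
    fragment_length_mean_min: float = 15.0
    wake_bout_prob: float = 0.18  # per-epoch wake probability inside sleep
    nonwear_fraction: float = 0.0
    epoch_s: int = 60
    n_days: int = 7

    def validate(self) -> None:
        for name in ("noise_sd", "sleep_noise_sd", "sleep_onset_sd_h", "sleep_length_sd_h",
                     "phase_jitter_sd_h", "fragmentation_rate_per_h", "fragment_length_mean_min"):
            _check_nonneg(name, getattr(self, name))
        _check_prob("wake_bout_prob", self.wake_bout_prob)
        _check_prob("nonwear_fraction", self.nonwear_fraction)
        if self.mesor < 0 or self.amplitude < 0:
            raise ConfigError("mesor and amplitude must be >= 0")
        if self.sleep_length_mean_h <= 0:
            raise ConfigError("sleep_length_mean_h must be > 0")
        if self.epoch_s <= 0 or 3600 % self.epoch_s != 0:
            raise ConfigError(f"epoch_s must be a positive divisor of 3600, got {self.epoch_s}")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")


@dataclass
class GroupParams:
    demographics: Demographics = field(default_factory=Demographics)
    questionnaire: QuestionnaireProbs = field(default_factory=QuestionnaireProbs)
    actigraphy: ActigraphyParams = field(default_factory=ActigraphyParams)

    def validate(self) -> None:
        self.demographics.validate()
        self.questionnaire.validate()
        self.actigraphy.validate()


@dataclass
class InjectedEffect:
    """A named binary exposure with known group-conditional log odds ratios.

    ``baseline_prob`` is the control-group prevalence; ``log_or`` maps a group
    label to the log odds ratio of exposure in that group relative to control
    (pairwise BD-vs-UM log-ORs follow by differencing). Used for
    parameter-recovery tests of the downstream models.
    """

    name: str
    baseline_prob: float = 0.2
    log_or: dict = field(default_factory=dict)

    def validate(self) -> None:
        _check_prob(f"injected effect {self.name!r} baseline_prob", self.baseline_prob)
        for g in self.log_or:
            if g not in STRATA:
                raise ConfigError(f"injected effect {self.name!r}: unknown group {g!r}")


def _default_groups() -> dict:
    bd = GroupParams(
        demographics=Demographics(
            age_mean=52.11, age_sd=7.31, p_female=0.6166,
            townsend_mean=-1.02, townsend_sd=3.16,
            education_probs=(0.0615, 0.1505, 0.0736, 0.2914, 0.4231),
            ethnicity_probs=(0.9630, 0.0114, 0.0098, 0.0085, 0.0017, 0.0056),
            smoking_probs=(0.4818, 0.3716, 0.1466),
            alcohol_probs=(0.0245, 0.0559, 0.9196),
            bmi_mean=27.81, bmi_sd=5.19, p_psychotropic=0.0377,
        ),
        questionnaire=QuestionnaireProbs(
            p_hyper=0.96, p_irritable=0.96, p_mania_symptoms_meet=0.998,
            p_depressed=0.96, p_anhedonia=0.96, p_dep_symptoms_meet=0.998,
            p_consulted=0.998,
            p_anxiety=0.7416, p_self_harm=0.1786, p_risk_taker=0.3934,
            neuroticism_mean=6.95, p_unhappy=0.1997, p_unhappy_health=0.2967,
            chronotype_probs=(0.2272, 0.2843, 0.2843, 0.1342, 0.04, 0.03),
            sleeplessness_probs=(0.25, 0.30, 0.45),
            getting_up_probs=(0.2537, 0.4509, 0.2363, 0.0591),
            napping_probs=(0.52, 0.40, 0.08),
            subjective_sleep_mean_h=7.05, subjective_sleep_sd_h=1.10,
        ),
        actigraphy=ActigraphyParams(
            mesor=31.0, amplitude=22.0, sleep_onset_mean_h=23.7, sleep_onset_sd_h=0.6,
            sleep_length_mean_h=10.6, sleep_length_sd_h=0.6, phase_jitter_sd_h=0.8,
            fragmentation_rate_per_h=1.2, wake_bout_prob=0.22,
        ),
    )
    um = GroupParams(
        demographics=Demographics(
            age_mean=54.05, age_sd=7.76, p_female=0.3912,
            townsend_mean=-1.71, townsend_sd=2.82,
            education_probs=(0.0360, 0.1213, 0.0695, 0.2828, 0.4904),
            ethnicity_probs=(0.9582, 0.0059, 0.0142, 0.0092, 0.0017, 0.0108),
            smoking_probs=(0.5563, 0.3703, 0.0734),
            alcohol_probs=(0.0208, 0.0258, 0.9534),
            bmi_mean=27.25, bmi_sd=4.36, p_psychotropic=0.0033,
        ),
        questionnaire=QuestionnaireProbs(
            p_hyper=0.96, p_irritable=0.96, p_mania_symptoms_meet=0.998,
            p_depressed=0.25, p_anhedonia=0.10, p_dep_symptoms_meet=0.02,
            p_consulted=0.50,
            p_anxiety=0.1541, p_self_harm=0.0382, p_risk_taker=0.4352,
            neuroticism_mean=4.35, p_unhappy=0.0348, p_unhappy_health=0.1278,
            chronotype_probs=(0.2777, 0.2765, 0.2765, 0.0993, 0.04, 0.03),
            sleeplessness_probs=(0.30, 0.38, 0.32),
            getting_up_probs=(0.3044, 0.5412, 0.1236, 0.0309),
            napping_probs=(0.56, 0.38, 0.06),
            subjective_sleep_mean_h=7.10, subjective_sleep_sd_h=0.95,
        ),
        actigraphy=ActigraphyParams(
            mesor=38.0, amplitude=28.0, sleep_onset_mean_h=23.1, sleep_onset_sd_h=0.5,
            sleep_length_mean_h=8.6, sleep_length_sd_h=0.5, phase_jitter_sd_h=0.6,
            fragmentation_rate_per_h=1.1, wake_bout_prob=0.20,
        ),
    )
    control = GroupParams()  # class defaults are the control-group parameters
    depression_only = GroupParams(
        questionnaire=QuestionnaireProbs(
            p_hyper=0.03, p_irritable=0.03, p_mania_symptoms_meet=0.05,
            p_depressed=0.97, p_anhedonia=0.97, p_dep_symptoms_meet=0.998,
            p_consulted=0.998,
            p_anxiety=0.45, p_self_harm=0.08, p_risk_taker=0.26,
            neuroticism_mean=6.0, p_unhappy=0.12, p_unhappy_health=0.20,
        ),
    )
    excluded = GroupParams()
    return {
        "BD": bd,
        "UM": um,
        "control": control,
        "depression_only": depression_only,
        "excluded": excluded,
    }


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort draw."""

    n_participants: int = 2000
    # BD / UM / control shares among retained, mood-classifiable participants
    group_proportions: tuple = (0.075, 0.019, 0.906)
    p_depression_only: float = 0.10  # of the non-excluded cohort
    p_excluded: float = 0.055  # meets >= 1 exclusion criterion
    seed: int = 0
    actigraphy_fraction: float = 0.4
    p_online: float = 0.4  # completed the online follow-up instrument
    p_missing_gate: float = 0.0  # missingness of the mania/depression gate items
    wear_start_range: tuple = ("2013-06-01", "2015-12-31")
    groups: dict = field(default_factory=_default_groups)
    injected_effects: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        _check_probs("group_proportions", self.group_proportions, 3)
        for name in ("p_depression_only", "p_excluded", "actigraphy_fraction",
                     "p_online", "p_missing_gate"):
            _check_prob(name, getattr(self, name))
        missing = [g for g in STRATA if g not in self.groups]
        if missing:
            raise ConfigError(f"groups missing parameter sets for: {missing}")
        for g, gp in self.groups.items():
            if g not in STRATA:
                raise ConfigError(f"groups contains unknown stratum {g!r}")
            gp.validate()
        for eff in self.injected_effects:
            eff.validate()


@dataclass
class SleepDetectorParams:
    """Threshold / longest-low-block sleep detector constants."""

    threshold_frac: float = 0.10  # of the participant's typical daytime activity
    daytime_quantile: float = 0.75  # worn-activity quantile used as the daytime reference
    min_block_h: float = 3.0
    smoothing_min: float = 30.0  # rolling-median width
    min_wear_h: float = 20.0  # per noon-to-noon day

    def validate(self) -> None:
        _check_prob("threshold_frac", self.threshold_frac)
        _check_prob("daytime_quantile", self.daytime_quantile)
        for name in ("min_block_h", "smoothing_min", "min_wear_h"):
            _check_nonneg(name, getattr(self, name))


@dataclass
class StatsParams:
    fdr_alpha: float = 0.05
    fisher_min_expected: float = 5.0  # expected-cell trigger for the exact test
    ra_per_day: bool = True  # average daily RA values (vs RA of averaged M10/L5)
    hourly_completeness_min: float = 0.5
    day_completeness_min_h: float = 20.0

    def validate(self) -> None:
        _check_prob("fdr_alpha", self.fdr_alpha)
        _check_nonneg("fisher_min_expected", self.fisher_min_expected)
        _check_prob("hourly_completeness_min", self.hourly_completeness_min)
        if not (0 < self.day_completeness_min_h <= 24):
            raise ConfigError("day_completeness_min_h must be in (0, 24]")


@dataclass
class RunConfig:
    """One end-to-end pipeline run: simulate -> phenotype -> metrics -> compare."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    detector: SleepDetectorParams = field(default_factory=SleepDetectorParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        self.detector.validate()
        self.stats.validate()
        if self.verbosity not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"verbosity must be a logging level name, got {self.verbosity!r}")


def null_cohort_config(n_participants: int = 2000, seed: int = 0) -> CohortConfig:
    """A cohort in which the three groups differ ONLY in the diagnostic
    criterion items (so phenotyping still works) while every exposure,
    covariate and actigraphy parameter is identical across groups — the
    global-null condition for calibration checks of the comparison pipeline.
    """
    cfg = CohortConfig(n_participants=n_participants, seed=seed)
    control = cfg.groups["control"]
    criterion_fields = (
        "p_hyper", "p_irritable", "p_mania_symptoms_meet",
        "p_depressed", "p_anhedonia", "p_dep_symptoms_meet", "p_consulted",
    )
    for g in ("BD", "UM", "depression_only", "excluded"):
        keep = {f: getattr(cfg.groups[g].questionnaire, f) for f in criterion_fields}
        cfg.groups[g] = GroupParams(
            demographics=dataclasses.replace(control.demographics),
            questionnaire=dataclasses.replace(control.questionnaire, **keep),
            actigraphy=dataclasses.replace(control.actigraphy),
        )
    return cfg


# ---------------------------------------------------------------------------
# (de)serialisation


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def _from_dict(cls: type, data: Mapping[str, Any], path: str = "") -> Any:
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = f"{path}.{name}" if path else name
        ftype = f.type if isinstance(f.type, type) else None
        if name == "groups":
            kwargs[name] = {g: _from_dict(GroupParams, v, f"{sub}.{g}") for g, v in value.items()}
        elif name == "injected_effects":
            kwargs[name] = [_from_dict(InjectedEffect, v, f"{sub}[{i}]") for i, v in enumerate(value)]
        elif ftype is not None and dataclasses.is_dataclass(ftype):
            kwargs[name] = _from_dict(ftype, value, sub)
        elif name in ("cohort", "detector", "stats", "demographics", "questionnaire", "actigraphy"):
            target = {
                "cohort": CohortConfig,
                "detector": SleepDetectorParams,
                "stats": StatsParams,
                "demographics": Demographics,
                "questionnaire": QuestionnaireProbs,
                "actigraphy": ActigraphyParams,
            }[name]
            kwargs[name] = _from_dict(target, value, sub)
        elif isinstance(value, list) and "tuple" in str(f.type):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str, cls: type = RunConfig) -> Any:
    """Load a YAML config file into ``cls`` (default :class:`RunConfig`)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(cls, data)
    cfg.validate()
    return cfg


def save_config(cfg: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)
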