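"""Synthetic three-group cohort generator.

Generates a reproducible cohort of probable-BD, probable-UM and control
participants (plus excluded and depression-only strata) with group-conditional
demographics, questionnaire responses, and wrist-acceleration time series, so
the full phenotyping -> circadian metrics -> group comparison pipeline can be
exercised without access-restricted data.

The accelerometer signal model
------------------------------
Days run noon-to-noon so every day contains exactly one main sleep period.
For day ``d`` a phase shift ``delta_d ~ N(0, phase_jitter_sd)`` moves the whole
profile. Awake epochs follow

    mesor + amplitude * max(0, cos(2*pi*(t - peak - delta_d) / 24)) + |N(0, noise_sd)|

in milli-g. The nightly sleep window (onset ~ N(onset_mean, onset_sd) + delta_d,
length ~ N(length_mean, length_sd)) has half-normal residual activity
``|N(0, sleep_noise_sd)|`` except for per-epoch Bernoulli wake bouts, which
return to daytime magnitude. Daytime fragmentation bouts (Poisson-like starts,
geometric lengths) drop activity to the sleep level, raising intradaily
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import (
    ALCOHOL_LEVELS,
    CHRONOTYPE_LEVELS,
    EDUCATION_LEVELS,
    ETHNICITY_LEVELS,
    EXCLUSION_FLAGS,
    GETTING_UP_LEVELS,
    HAPPINESS_LEVELS,
    NAPPING_LEVELS,
    SLEEPLESSNESS_LEVELS,
    SMOKING_LEVELS,
    STRATA,
    ActigraphyParams,
    CohortConfig,
    QuestionnaireProbs,
)

__all__ = [
    "EpochSeries",
    "Participant",
    "generate_actigraphy",
    "generate_cohort",
    "cohort_participants",
    "write_actigraphy_csv",
    "read_actigraphy_csv",
]

SECONDS_PER_DAY = 86400

# touchscreen instrument counts 4 mania symptoms, the online follow-up 8
MANIA_SYMPTOM_MAX = {"ts": 4, "ol": 8}
MANIA_DURATION_CODES = {
    "ts": ("lt_1w", "gt_2d_lt_1w", "ge_1w"),
    "ol": ("lt_24h", "gt_1d_lt_1w", "ge_1w"),
}
PROBLEMATIC_CODES = ("no_problems", "needed_help", "serious_problems")


@dataclass
class EpochSeries:
    """Timestamped nonnegative acceleration magnitudes with wear flags."""

    start: pd.Timestamp
    epoch_s: int
    values: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.values.shape != self.wear.shape or self.values.ndim != 1:
            raise ValueError("values and wear must be 1-D arrays of equal length")
        if (self.values < 0).any():
            raise ValueError("acceleration magnitudes must be nonnegative")
        if self.epoch_s <= 0 or SECONDS_PER_DAY % self.epoch_s != 0:
            raise ValueError("epoch_s must be a positive divisor of 86400")

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_s

    @property
    def n_days(self) -> int:
        return self.n_epochs // self.epochs_per_day

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(self.n_epochs) * self.epoch_s, unit="s")

    def clock_hours(self) -> np.ndarray:
        """Clock hour (0-24) of each epoch start."""
        start_h = self.start.hour + self.start.minute / 60 + self.start.second / 3600
        return (start_h + np.arange(self.n_epochs) * self.epoch_s / 3600.0) % 24.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps(), "magnitude_mg": self.values, "wear": self.wear.astype(int)}
        )


def write_actigraphy_csv(series: EpochSeries, path) -> None:
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_actigraphy_csv(path) -> EpochSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if len(df) < 2:
        raise ValueError(f"{path}: need at least two epochs")
    epoch_s = int((df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds())
    return EpochSeries(
        start=df["timestamp"].iloc[0],
        epoch_s=epoch_s,
        values=df["magnitude_mg"].to_numpy(),
        wear=df["wear"].to_numpy().astype(bool),
    )


@dataclass
class Participant:
    """One participant: identifiers, covariates and questionnaire record."""

    id: int
    group_truth: str
    data: dict = field(default_factory=dict)
    actigraphy: Optional[EpochSeries] = None


def generate_actigraphy(
    params: ActigraphyParams,
    seed,
    start: str | pd.Timestamp = "2014-06-02 12:00:00",
    return_truth: bool = False,
):
    """Simulate one participant's epoch series.

    Parameters
    ----------
    params : ActigraphyParams
    seed : int or numpy Generator
    start : series start (noon, so noon-to-noon days align with epochs)
    return_truth : also return a per-day DataFrame of true sleep window
        epoch indices (columns ``day, onset_idx, offset_idx, n_wake_epochs``)
        for detector-recovery tests.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    epoch_h = params.epoch_s / 3600.0
    ne_day = SECONDS_PER_DAY // params.epoch_s
    n = params.n_days * ne_day
    clock = (12.0 + np.arange(ne_day) * epoch_h) % 24.0  # day starts at noon

    values = np.empty(n)
    truth_rows = []
    for d in range(params.n_days):
        delta = rng.normal(0.0, params.phase_jitter_sd_h) if params.phase_jitter_sd_h > 0 else 0.0
        onset = (rng.normal(params.sleep_onset_mean_h, params.sleep_onset_sd_h)
                 if params.sleep_onset_sd_h > 0 else params.sleep_onset_mean_h) + delta
        length = (rng.normal(params.sleep_length_mean_h, params.sleep_length_sd_h)
                  if params.sleep_length_sd_h > 0 else params.sleep_length_mean_h)
        length = max(length, 0.0)
        peak = params.peak_time_h + delta

        profile = params.mesor + params.amplitude * np.maximum(
            0.0, np.cos(2.0 * np.pi * (clock - peak) / 24.0)
        )
        noise = np.abs(rng.normal(0.0, params.noise_sd, ne_day)) if params.noise_sd > 0 else 0.0
        day = profile + noise

        rel_onset = (onset - 12.0) % 24.0
        i0 = min(int(round(rel_onset / epoch_h)), ne_day - 1)
        i1 = min(i0 + int(round(length / epoch_h)), ne_day)
        m = i1 - i0
        n_wake = 0
        if m > 0:
            asleep = (np.abs(rng.normal(0.0, params.sleep_noise_sd, m))
                      if params.sleep_noise_sd > 0 else np.zeros(m))
            if params.wake_bout_prob > 0:
                wake = rng.random(m) < params.wake_bout_prob
                n_wake = int(wake.sum())
                if n_wake:
                    asleep[wake] = params.mesor + np.abs(rng.normal(0.0, params.noise_sd, n_wake))
            day[i0:i1] = asleep

        if params.fragmentation_rate_per_h > 0:
            p_start = min(params.fragmentation_rate_per_h * epoch_h, 1.0)
            starts = np.flatnonzero(rng.random(ne_day) < p_start)
            starts = starts[(starts < i0) | (starts >= i1)]  # daytime only
            mean_len_epochs = max(params.fragment_length_mean_min / (params.epoch_s / 60.0), 1.0)
            for s in starts:
                bout = int(rng.geometric(1.0 / mean_len_epochs))
                e = min(s + bout, i0 if s < i0 else ne_day)
                day[s:e] = np.abs(rng.normal(0.0, params.sleep_noise_sd, e - s))

        values[d * ne_day : (d + 1) * ne_day] = day
        truth_rows.append(
            {"day": d, "onset_idx": d * ne_day + i0, "offset_idx": d * ne_day + i1,
             "n_wake_epochs": n_wake}
        )

    wear = np.ones(n, dtype=bool)
    if params.nonwear_fraction > 0:
        wear &= rng.random(n) >= params.nonwear_fraction

    series = EpochSeries(start=start, epoch_s=params.epoch_s, values=values, wear=wear)
    if return_truth:
        return series, pd.DataFrame(truth_rows)
    return series


# ---------------------------------------------------------------------------
# questionnaire and covariate generation (vectorised per stratum)


def _yes_no(rng, p, n):
    return np.where(rng.random(n) < p, "yes", "no")


def _categorical(rng, levels, probs, n):
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=np.asarray(probs, float))


def _draw_mood_items(rng, qp: QuestionnaireProbs, n: int, dialect: str, p_missing: float) -> dict:
    """Mania and depression module answers for one instrument dialect.

    Symptom counts are only asked when a gate item is answered yes (mirroring
    the branching questionnaires), so they are missing otherwise.
    """
    sym_max = MANIA_SYMPTOM_MAX[dialect]
    hyper = _yes_no(rng, qp.p_hyper, n)
    irritable = _yes_no(rng, qp.p_irritable, n)
    if p_missing > 0:
        hyper = np.where(rng.random(n) < p_missing, None, hyper)
        irritable = np.where(rng.random(n) < p_missing, None, irritable)
    gate = (hyper == "yes") | (irritable == "yes")

    meets = rng.random(n) < qp.p_mania_symptoms_meet
    sym_hi = rng.integers(3, sym_max + 1, n).astype(float)
    sym_lo = rng.integers(0, 3, n).astype(float)
    mania_symptoms = np.where(meets, sym_hi, sym_lo)
    mania_symptoms[~gate] = np.nan
    duration = _categorical(rng, MANIA_DURATION_CODES[dialect], (0.3, 0.4, 0.3), n).astype(object)
    problematic = _categorical(rng, PROBLEMATIC_CODES, (0.5, 0.3, 0.2), n).astype(object)
    duration[~gate] = None
    problematic[~gate] = None

    depressed = _yes_no(rng, qp.p_depressed, n)
    anhedonia = _yes_no(rng, qp.p_anhedonia, n)
    dep_gate = (depressed == "yes") | (anhedonia == "yes")
    dep_meets = rng.random(n) < qp.p_dep_symptoms_meet
    dep_hi = rng.integers(5, 8, n).astype(float)
    dep_lo = rng.integers(0, 5, n).astype(float)
    dep_symptoms = np.where(dep_meets, dep_hi, dep_lo)
    dep_symptoms[~dep_gate] = np.nan
    consulted = _yes_no(rng, qp.p_consulted, n).astype(object)
    consulted[~dep_gate] = None

    return {
        "hyper": hyper,
        "irritable": irritable,
        "mania_symptoms": mania_symptoms,
        "mania_duration": duration,
        "mania_problematic": problematic,
        "depressed": depressed,
        "anhedonia": anhedonia,
        "dep_symptoms": dep_symptoms,
        "consulted": consulted,
    }


def _split_happiness(rng, p_unhappy, n):
    """Draw a 6-level happiness item with the given unhappy mass."""
    probs = [0.15 * (1 - p_unhappy), 0.45 * (1 - p_unhappy), 0.40 * (1 - p_unhappy),
             0.50 * p_unhappy, 0.30 * p_unhappy, 0.20 * p_unhappy]
    return _categorical(rng, HAPPINESS_LEVELS, probs, n)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the participant table (one row per participant).

    Deterministic given ``config.seed``. Columns are documented in the
    package README; questionnaire answers are drawn group-conditionally so the
    phenotyping rules recover ``group_truth`` with >= 99% accuracy under the
    default response probabilities.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_participants

    pe, pdep = config.p_excluded, config.p_depression_only
    bd, um, ctrl = config.group_proportions
    strata_probs = np.array([
        (1 - pe) * (1 - pdep) * bd,
        (1 - pe) * (1 - pdep) * um,
        (1 - pe) * (1 - pdep) * ctrl,
        (1 - pe) * pdep,
        pe,
    ])
    strata_probs /= strata_probs.sum()
    group_truth = rng.choice(np.asarray(STRATA, dtype=object), size=n, p=strata_probs)

    df = pd.DataFrame({"id": np.arange(1, n + 1), "group_truth": group_truth})

    # exclusion flags: only the excluded stratum carries any
    excluded_mask = group_truth == "excluded"
    flags = np.zeros((n, len(EXCLUSION_FLAGS)), dtype=int)
    n_excl = int(excluded_mask.sum())
    if n_excl:
        draw = rng.random((n_excl, len(EXCLUSION_FLAGS))) < 0.25
        none = ~draw.any(axis=1)
        draw[none, rng.integers(0, len(EXCLUSION_FLAGS), int(none.sum()))] = True
        flags[excluded_mask] = draw.astype(int)
    for j, name in enumerate(EXCLUSION_FLAGS):
        df[f"excl_{name}"] = flags[:, j]

    # column containers filled stratum-by-stratum in a fixed order
    float_cols = ["age", "townsend", "bmi", "neuroticism_p"]
    for c in float_cols:
        df[c] = np.nan
    obj_cols = ["sex", "education", "ethnicity", "smoking", "alcohol",
                "napping", "chronotype", "sleeplessness", "getting_up",
                "happiness", "happiness_health"]
    for c in obj_cols:
        df[c] = pd.Series([None] * n, dtype=object)
    int_like = ["psychotropic", "anxiety", "self_harm", "risk_taker", "subjective_sleep_h"]
    for c in int_like:
        df[c] = np.nan
    mood_cols = ["hyper", "irritable", "mania_duration", "mania_problematic",
                 "depressed", "anhedonia", "consulted"]
    for pre in ("ts", "ol"):
        for c in mood_cols:
            df[f"{pre}_{c}"] = pd.Series([None] * n, dtype=object)
        df[f"{pre}_mania_symptoms"] = np.nan
        df[f"{pre}_dep_symptoms"] = np.nan

    online = rng.random(n) < config.p_online
    df["ol_present"] = online

    for stratum in STRATA:
        mask = group_truth == stratum
        m = int(mask.sum())
        if m == 0:
            continue
        gp = config.groups[stratum]
        demo, qp = gp.demographics, gp.questionnaire

        df.loc[mask, "age"] = rng.normal(demo.age_mean, demo.age_sd, m).round(1)
        df.loc[mask, "sex"] = np.where(rng.random(m) < demo.p_female, "female", "male")
        df.loc[mask, "townsend"] = rng.normal(demo.townsend_mean, demo.townsend_sd, m).round(3)
        df.loc[mask, "education"] = _categorical(rng, EDUCATION_LEVELS, demo.education_probs, m)
        df.loc[mask, "ethnicity"] = _categorical(rng, ETHNICITY_LEVELS, demo.ethnicity_probs, m)
        df.loc[mask, "smoking"] = _categorical(rng, SMOKING_LEVELS, demo.smoking_probs, m)
        df.loc[mask, "alcohol"] = _categorical(rng, ALCOHOL_LEVELS, demo.alcohol_probs, m)
        df.loc[mask, "bmi"] = np.maximum(rng.normal(demo.bmi_mean, demo.bmi_sd, m), 14.0).round(2)
        df.loc[mask, "psychotropic"] = (rng.random(m) < demo.p_psychotropic).astype(int)

        ts = _draw_mood_items(rng, qp, m, "ts", config.p_missing_gate)
        ol = _draw_mood_items(rng, qp, m, "ol", config.p_missing_gate)
        for key, arr in ts.items():
            df.loc[mask, f"ts_{key}"] = arr
        sub_online = online[mask]
        idx = df.index[mask][sub_online]
        for key, arr in ol.items():
            df.loc[idx, f"ol_{key}"] = arr[sub_online]

        df.loc[mask, "anxiety"] = (rng.random(m) < qp.p_anxiety).astype(int)
        df.loc[mask, "self_harm"] = (rng.random(m) < qp.p_self_harm).astype(int)
        df.loc[mask, "risk_taker"] = (rng.random(m) < qp.p_risk_taker).astype(int)
        df.loc[mask, "neuroticism_p"] = qp.neuroticism_mean / 12.0
        df.loc[mask, "happiness"] = _split_happiness(rng, qp.p_unhappy, m)
        df.loc[mask, "happiness_health"] = _split_happiness(rng, qp.p_unhappy_health, m)
        df.loc[mask, "napping"] = _categorical(rng, NAPPING_LEVELS, qp.napping_probs, m)
        df.loc[mask, "chronotype"] = _categorical(rng, CHRONOTYPE_LEVELS, qp.chronotype_probs, m)
        df.loc[mask, "sleeplessness"] = _categorical(rng, SLEEPLESSNESS_LEVELS, qp.sleeplessness_probs, m)
        df.loc[mask, "getting_up"] = _categorical(rng, GETTING_UP_LEVELS, qp.getting_up_probs, m)
        hours = np.clip(np.round(rng.normal(qp.subjective_sleep_mean_h, qp.subjective_sleep_sd_h, m)), 1, 16)
        df.loc[mask, "subjective_sleep_h"] = hours

    # neuroticism: 12 binary items, iid with the group mean/12 rate
    neuro = rng.random((n, 12)) < df["neuroticism_p"].to_numpy()[:, None]
    for j in range(12):
        df[f"neuro_{j + 1:02d}"] = neuro[:, j].astype(int)
    df = df.drop(columns="neuroticism_p")

    # injected exposures: Bernoulli with group-conditional log-odds vs control
    for eff in config.injected_effects:
        logit0 = np.log(eff.baseline_prob / (1 - eff.baseline_prob))
        shift = np.array([float(eff.log_or.get(g, 0.0)) for g in group_truth])
        p = 1.0 / (1.0 + np.exp(-(logit0 + shift)))
        df[f"inj_{eff.name}"] = (rng.random(n) < p).astype(int)

    start, end = (pd.Timestamp(d) for d in config.wear_start_range)
    span = int((end - start).days) + 1
    dates = start + pd.to_timedelta(rng.integers(0, span, n), unit="D")
    df["wear_start_date"] = dates.strftime("%Y-%m-%d")
    df["has_actigraphy"] = rng.random(n) < config.actigraphy_fraction
    df["actigraphy_seed"] = rng.integers(0, 2**31 - 1, n)

    for c in int_like:
        df[c] = df[c].astype("Int64")
    return df


def cohort_participants(df: pd.DataFrame, config: CohortConfig) -> Iterator[Participant]:
    """Yield Participant records, generating actigraphy for flagged rows."""
    for row in df.itertuples(index=False):
        data = row._asdict()
        series = None
        if data.get("has_actigraphy"):
            params = config.groups[data["group_truth"]].actigraphy
            series = generate_actigraphy(
                params,
                int(data["actigraphy_seed"]),
                start=f"{data['wear_start_date']} 12:00:00",
            )
        yield Participant(id=data["id"], group_truth=data["group_truth"], data=data, actigraphy=series)
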