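"""Synthetic spontaneous-reporting-system tables with known ground truth.

The generator emits the four report tables (DEMO, DRUG, REAC, HIST) in the
canonical schema together with the latent state that produced them, so
every downstream stage has a recoverable target: demographic covariate
effects and per-drug odds ratios feed a logistic event model, and each
effect drug carries a Weibull onset-latency distribution.

Generation is latent-then-band: continuous heights and weights are drawn
per sex and only then collapsed into the 10-unit ranges the reporting
format carries, so the banded eBMI class used by both the generator's
event model and the analysis pipeline is well defined.  Field-level
missingness is applied to the *emitted* strings; the latent values keep
driving the event and onset mechanics, as in real reports where the event
happened whether or not the form records a date.

Drug exposures are independent across drugs (no co-prescription
structure).  Non-event reports carry one noise reaction so every report
has at least one REAC row.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import classify_ebmi, compute_ebmi, age_band_ge60

AGE_BANDS = ("<10", "10-19", "20-29", "30-39", "40-49", "50-59",
             "60-69", "70-79", "80-89", "90-99", "100-109")

#: Clinical outcome mixture for target-event rows (recovered/improved
#: dominate; sequelae and death absent, as in mild colitis reports).
DEFAULT_OUTCOME_WEIGHTS = {
    "Uncertain": 8 / 161, "Recovered": 77 / 161, "Improved": 74 / 161,
    "Unimproved": 2 / 161, "WithSequelae": 0.0, "Death": 0.0,
}

#: Mostly-elderly age mixture typical of a national adverse-event registry.
DEFAULT_AGE_WEIGHTS = {
    "<10": 0.02, "10-19": 0.02, "20-29": 0.05, "30-39": 0.07,
    "40-49": 0.10, "50-59": 0.12, "60-69": 0.20, "70-79": 0.22,
    "80-89": 0.15, "90-99": 0.04, "100-109": 0.01,
}

#: Default catalog: one high-prevalence proton-pump inhibitor carrying a
#: large injected odds ratio, one antiplatelet with a moderate one, and
#: twenty null co-medications at registry-plausible exposure prevalences.
DEFAULT_DRUG_CATALOG: tuple[tuple[str, float], ...] = (
    ("lansoprazole", 0.091),
    ("aspirin", 0.083),
    ("amlodipine", 0.060),
    ("furosemide", 0.055),
    ("loxoprofen", 0.040),
    ("nicorandil", 0.017),
    ("allopurinol", 0.030),
    ("magnesium oxide", 0.105),
    ("candesartan", 0.035),
    ("rosuvastatin", 0.040),
    ("carvedilol", 0.025),
    ("etizolam", 0.020),
    ("olmesartan", 0.025),
    ("alendronic acid", 0.015),
    ("rebamipide", 0.050),
    ("bisoprolol", 0.025),
    ("clopidogrel", 0.030),
    ("mecobalamin", 0.030),
    ("diclofenac", 0.022),
    ("valsartan", 0.025),
    ("atorvastatin", 0.035),
    ("teprenone", 0.025),
)

DEFAULT_DRUG_EFFECTS = {
    "lansoprazole": math.log(35.0),
    "aspirin": math.log(2.0),
}

#: Onset latencies: scale α (days) back-derived from a ~72.5-day median at
#: shape 0.93 and a ~116-day median at shape 0.57 (α = median / ln2^(1/β)).
DEFAULT_ONSET_MODELS = {
    "lansoprazole": (107.5, 0.93),
    "aspirin": (220.6, 0.57),
}


class ConfigError(ValueError):
    """Invalid simulation configuration; message lists all violations."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic registry draw.

    Defaults describe a mid-sized registry slice: 20,000 reports, ~55%
    female, elderly-skewed ages, Japanese adult anthropometrics, per-field
    demographic missingness that retains roughly a third of reports with
    complete demographics, a 22-drug catalog with two effect drugs
    (odds ratios 35 and 2) and Weibull onset latencies, and a baseline
    event rate of about 2% so desk-scale runs carry information.
    """
    n_cases: int = 20_000
    seed: int = 0
    sex_proportion_female: float = 0.55
    age_band_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS))
    height_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 165.0, "female": 152.0})
    height_sd_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 7.0, "female": 7.0})
    weight_mean_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 62.0, "female": 51.0})
    weight_sd_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 10.0, "female": 9.0})
    missing_rate: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.05, "age_band": 0.10,
                                 "height_band": 0.35, "weight_band": 0.35})
    drug_catalog: Sequence[tuple[str, float]] = DEFAULT_DRUG_CATALOG
    target_pt_code: str = "10056979"
    target_pt_name: str = "Colitis microscopic"
    baseline_event_logodds: float = math.log(0.02 / 0.98)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"female": math.log(3.26),
                                 "age_ge60": math.log(3.94),
                                 "obese": math.log(1.2),
                                 "underweight": math.log(1.2)})
    drug_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_EFFECTS))
    onset_models: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ONSET_MODELS))
    background_onset: tuple[float, float] = (180.0, 1.0)
    date_window: tuple[str, str] = ("20040401", "20210831")
    start_date_missing_rate: float = 0.30
    onset_date_missing_rate: float = 0.15
    outcome_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_WEIGHTS))
    noise_pt_code: str = "10012735"
    noise_pt_name: str = "Diarrhoea"

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violation at once."""
        errors: list[str] = []
        if self.n_cases <= 0:
            errors.append(f"n_cases must be positive, got {self.n_cases}")
        if not 0.0 <= self.sex_proportion_female <= 1.0:
            errors.append("sex_proportion_female outside [0, 1]")
        for name, rate in dict(self.missing_rate).items():
            if not 0.0 <= rate < 1.0:
                errors.append(f"missing_rate[{name}] outside [0, 1)")
        if not 0.0 <= self.start_date_missing_rate < 1.0:
            errors.append("start_date_missing_rate outside [0, 1)")
        if not 0.0 <= self.onset_date_missing_rate < 1.0:
            errors.append("onset_date_missing_rate outside [0, 1)")
        for label, weights in (("age_band_weights", self.age_band_weights),
                               ("outcome_weights", self.outcome_weights)):
            w = dict(weights)
            if any(v < 0 for v in w.values()):
                errors.append(f"{label} has negative weights")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                errors.append(f"{label} do not sum to 1")
        catalog_names = {name for name, _ in self.drug_catalog}
        for name, p in self.drug_catalog:
            if not 0.0 <= p <= 1.0:
                errors.append(f"exposure_probability[{name}] outside [0, 1]")
        for name in self.drug_effects:
            if name not in catalog_names:
                errors.append(f"drug_effects names unknown drug {name!r}")
        for name, (alpha, beta) in dict(self.onset_models).items():
            if name not in catalog_names:
                errors.append(f"onset_models names unknown drug {name!r}")
            if alpha <= 0 or beta <= 0:
                errors.append(f"onset_models[{name}] needs alpha, beta > 0")
        if self.background_onset[0] <= 0 or self.background_onset[1] <= 0:
            errors.append("background_onset needs alpha, beta > 0")
        first, last = self.date_window
        if not (len(first) == len(last) == 8 and first <= last):
            errors.append("date_window must be (YYYYMMDD, YYYYMMDD), ordered")
        if errors:
            raise ConfigError("; ".join(errors))

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "drug_catalog" in raw:
            raw["drug_catalog"] = [tuple(item) for item in raw["drug_catalog"]]
        if "onset_models" in raw:
            raw["onset_models"] = {k: tuple(v)
                                   for k, v in raw["onset_models"].items()}
        for key in ("background_onset", "date_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_catalog"] = [list(item) for item in d["drug_catalog"]]
        d["onset_models"] = {k: list(v) for k, v in d["onset_models"].items()}
        d["background_onset"] = list(d["background_onset"])
        d["date_window"] = list(d["date_window"])
        return d


@dataclass
class GroundTruth:
    """Latent state behind one simulated table set."""
    config: SimulationConfig
    cases: pd.DataFrame        # per-case latent values and event mechanics
    drugs: pd.DataFrame        # per-drug truth: OR, onset params, exposure


def _band_label(values: np.ndarray) -> np.ndarray:
    lo = (np.floor(values / 10.0) * 10).astype(int)
    return np.array([f"{a}-{a + 9}" for a in lo])


def _date_strings(base: _dt.date, offsets: np.ndarray) -> np.ndarray:
    stamps = pd.to_datetime(str(base)) + pd.to_timedelta(offsets, unit="D")
    return stamps.strftime("%Y%m%d").to_numpy()


def simulate(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Draw one synthetic registry under ``config``.

    Returns ``(tables, truth)`` where ``tables`` maps "demo"/"drug"/
    "reac"/"hist" to canonical-schema DataFrames and ``truth`` carries the
    latent per-case state.  Identical config and seed give identical
    tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    case_ids = np.array([f"C{i:07d}" for i in range(1, n + 1)])

    # demographics
    female = rng.random(n) < config.sex_proportion_female
    sex = np.where(female, "female", "male")
    bands = list(config.age_band_weights)
    weights = np.array([config.age_band_weights[b] for b in bands], dtype=float)
    age_band = rng.choice(np.array(bands, dtype=object), size=n,
                          p=weights / weights.sum()).astype(object)

    height = np.empty(n)
    weight = np.empty(n)
    for s in ("male", "female"):
        mask = sex == s
        height[mask] = rng.normal(config.height_mean_cm[s],
                                  config.height_sd_cm[s], mask.sum())
        weight[mask] = rng.normal(config.weight_mean_kg[s],
                                  config.weight_sd_kg[s], mask.sum())
    height = np.clip(height, 60.0, 219.0)
    weight = np.clip(weight, 10.0, 199.0)
    height_band = _band_label(height)
    weight_band = _band_label(weight)

    # covariates used by the event model — computed from the *banded*
    # values so the generator and the pipeline share one definition
    ebmi = np.array([compute_ebmi(h, w)
                     for h, w in zip(height_band, weight_band)])
    ebmi_class = np.array([classify_ebmi(e) for e in ebmi], dtype=object)
    ge60 = np.array([age_band_ge60(b) for b in age_band])

    # drug exposures, independent per catalog entry
    drug_names = [name for name, _ in config.drug_catalog]
    probs = np.array([p for _, p in config.drug_catalog])
    exposure = rng.random((n, len(drug_names))) < probs[None, :]

    first = _dt.date(int(config.date_window[0][:4]),
                     int(config.date_window[0][4:6]),
                     int(config.date_window[0][6:]))
    last = _dt.date(int(config.date_window[1][:4]),
                    int(config.date_window[1][4:6]),
                    int(config.date_window[1][6:]))
    window_days = (last - first).days
    start_offsets = rng.integers(0, window_days + 1,
                                 size=(n, len(drug_names)))

    # event model
    eff = config.covariate_effects
    logodds = np.full(n, config.baseline_event_logodds)
    logodds += np.where(female, eff.get("female", 0.0), 0.0)
    logodds += np.where(ge60, eff.get("age_ge60", 0.0), 0.0)
    logodds += np.where(ebmi_class == "obese", eff.get("obese", 0.0), 0.0)
    logodds += np.where(ebmi_class == "underweight",
                        eff.get("underweight", 0.0), 0.0)
    drug_logor = np.array([config.drug_effects.get(d, 0.0)
                           for d in drug_names])
    logodds += exposure @ drug_logor
    p_event = 1.0 / (1.0 + np.exp(-logodds))
    event = rng.random(n) < p_event

    # onset latency: anchored at an exposed effect-drug's latent start
    effect_idx = [i for i, d in enumerate(drug_names)
                  if config.drug_effects.get(d, 0.0) != 0.0]
    onset_offsets = np.full(n, -1, dtype=int)
    onset_drug = np.full(n, "", dtype=object)
    bg_alpha, bg_beta = config.background_onset
    for i in np.flatnonzero(event):
        carriers = [j for j in effect_idx if exposure[i, j]]
        if carriers:
            j = carriers[int(rng.integers(0, len(carriers)))]
            name = drug_names[j]
            alpha, beta = config.onset_models.get(name, (bg_alpha, bg_beta))
            anchor = int(start_offsets[i, j])
            onset_drug[i] = name
        else:
            exposed = np.flatnonzero(exposure[i])
            alpha, beta = bg_alpha, bg_beta
            if exposed.size:
                j = exposed[int(rng.integers(0, exposed.size))]
                anchor = int(start_offsets[i, j])
                onset_drug[i] = drug_names[j]
            else:
                anchor = int(rng.integers(0, window_days + 1))
        latency = int(math.ceil(alpha * rng.weibull(beta)))
        onset_offsets[i] = anchor + max(latency, 1)

    outcome_cats = list(config.outcome_weights)
    outcome_p = np.array([config.outcome_weights[c] for c in outcome_cats])
    outcomes = rng.choice(np.array(outcome_cats, dtype=object), size=n,
                          p=outcome_p / outcome_p.sum()).astype(object)

    # emitted DEMO with field-level missingness
    demo = pd.DataFrame({
        "case_id": case_ids, "sex": sex.astype(object),
        "age_band": age_band.copy(),
        "height_band": height_band.astype(object),
        "weight_band": weight_band.astype(object),
    })
    for col in ("sex", "age_band", "height_band", "weight_band"):
        rate = config.missing_rate.get(col, 0.0)
        mask = rng.random(n) < rate
        demo.loc[mask, col] = ""

    # DRUG table
    case_idx, drug_idx = np.nonzero(exposure)
    start_str = _date_strings(first, start_offsets[case_idx, drug_idx])
    start_missing = rng.random(len(case_idx)) < config.start_date_missing_rate
    drug = pd.DataFrame({
        "case_id": case_ids[case_idx],
        "drug_name": np.array(drug_names, dtype=object)[drug_idx],
        "role": "suspected",
        "start_date": np.where(start_missing, "", start_str),
        "end_date": "",
    })

    # REAC table: one target row per event case, one noise row otherwise
    ev = np.flatnonzero(event)
    onset_str = _date_strings(first, onset_offsets[ev])
    onset_missing = rng.random(ev.size) < config.onset_date_missing_rate
    reac_event = pd.DataFrame({
        "case_id": case_ids[ev],
        "pt_code": config.target_pt_code,
        "pt_name": config.target_pt_name,
        "onset_date": np.where(onset_missing, "", onset_str),
        "outcome": outcomes[ev],
    })
    nv = np.flatnonzero(~event)
    noise_offsets = rng.integers(0, window_days + 1, size=nv.size)
    reac_noise = pd.DataFrame({
        "case_id": case_ids[nv],
        "pt_code": config.noise_pt_code,
        "pt_name": config.noise_pt_name,
        "onset_date": _date_strings(first, noise_offsets),
        "outcome": outcomes[nv],
    })
    reac = (pd.concat([reac_event, reac_noise], ignore_index=True)
            .sort_values("case_id", kind="mergesort")
            .reset_index(drop=True))

    hist = pd.DataFrame({"case_id": case_ids, "history_term": ""})

    truth_cases = pd.DataFrame({
        "case_id": case_ids, "sex": sex, "age_band": age_band,
        "age_ge60": ge60, "latent_height_cm": height,
        "latent_weight_kg": weight, "ebmi": ebmi,
        "ebmi_class": ebmi_class, "event_prob": p_event, "event": event,
        "onset_drug": onset_drug,
    })
    for j, name in enumerate(drug_names):
        truth_cases[f"exposed::{name}"] = exposure[:, j]

    truth_drugs = pd.DataFrame({
        "drug": drug_names,
        "true_or": np.exp(drug_logor),
        "exposure_prob": probs,
        "n_exposed": exposure.sum(axis=0),
        "weibull_alpha": [config.onset_models.get(d, (np.nan, np.nan))[0]
                          for d in drug_names],
        "weibull_beta": [config.onset_models.get(d, (np.nan, np.nan))[1]
                         for d in drug_names],
    })

    tables = {"demo": demo, "drug": drug, "reac": reac, "hist": hist}
    return tables, GroundTruth(config=config, cases=truth_cases,
                               drugs=truth_drugs)


def ground_truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-drug truth table: injected OR, onset parameters, exposure."""
    return truth.drugs.copy()
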