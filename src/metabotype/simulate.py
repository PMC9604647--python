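"""Synthetic cohort generator with a planted three-group metabolic structure.

Emulates a two-wave population cohort (baseline examination plus one
follow-up roughly seven years later): 14 standard clinical parameters,
socio-demographics, six cardiometabolic disease flags at baseline and at
follow-up, missingness, and group-dependent attrition.  Every participant
carries a latent metabolic group (1 = favorable, 3 = unfavorable) that drives
parameter locations, disease risk and retention; the analysis pipeline never
reads it — it exists so recovery can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "LOG_SCALE_PARAMS",
    "DISEASES",
    "PARAMETER_UNITS",
    "GeneratorConfig",
    "ConfigError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: The 14 candidate clustering parameters, in canonical order.
PARAMETERS = (
    "tg", "bmi", "uric_acid", "glucose", "insulin", "hdlc", "non_hdlc",
    "hba1c", "hscrp", "ggt", "got", "gpt", "ap", "leukocytes",
)

#: Parameters simulated log-normally (right-skewed in real cohorts).
LOG_SCALE_PARAMS = frozenset({"tg", "hscrp", "ggt", "got", "gpt", "insulin"})

#: The six disease endpoints tracked at baseline and follow-up.
DISEASES = ("hypertension", "t2d", "dyslipidemia", "hyperuricemia", "mi", "stroke")

PARAMETER_UNITS = {
    "tg": "mmol/L", "bmi": "kg/m^2", "uric_acid": "umol/L",
    "glucose": "mg/dL", "insulin": "uU/mL", "hdlc": "mmol/L",
    "non_hdlc": "mmol/L", "hba1c": "%", "hscrp": "mg/L", "ggt": "ukat/L",
    "got": "ukat/L", "gpt": "ukat/L", "ap": "ukat/L", "leukocytes": "10^9/L",
}

# Per-group parameter locations (arithmetic means on the natural scale),
# favorable -> intermediate -> unfavorable.  Values sit at the cluster-median
# scale typical of middle-aged European cohorts.
_DEFAULT_MEANS = {
    "tg": (0.85, 1.50, 1.85),
    "bmi": (24.2, 28.2, 33.2),
    "uric_acid": (243.0, 334.0, 376.0),
    "glucose": (89.0, 96.0, 122.0),
    "insulin": (6.6, 10.0, 18.0),
    "hdlc": (1.70, 1.26, 1.18),
    "non_hdlc": (3.59, 4.49, 4.05),
    "hba1c": (5.30, 5.50, 6.10),
    "hscrp": (0.90, 1.55, 2.60),
    "ggt": (0.33, 0.52, 0.66),
    "got": (0.38, 0.43, 0.46),
    "gpt": (0.29, 0.41, 0.49),
    "ap": (1.00, 1.14, 1.21),
    "leukocytes": (5.4, 5.9, 6.4),
}

# Coefficients of variation; larger for the right-skewed analytes.
_DEFAULT_CVS = {
    "tg": 0.35, "bmi": 0.08, "uric_acid": 0.13, "glucose": 0.06,
    "insulin": 0.32, "hdlc": 0.13, "non_hdlc": 0.16, "hba1c": 0.045,
    "hscrp": 0.70, "ggt": 0.45, "got": 0.20, "gpt": 0.32, "ap": 0.20,
    "leukocytes": 0.20,
}

# Logistic models for disease status: base log-odds (group 1) plus additive
# group effects.  Baseline coefficients give cluster-wise prevalences on the
# scale seen in population cohorts (hypertension ~20-75% across groups, MI and
# stroke rare); incident coefficients apply to baseline-free participants over
# one follow-up wave.
_DEFAULT_BASELINE_LOGITS = {
    "hypertension": (-1.32, (0.0, 1.03, 2.51)),
    "t2d": (-4.36, (0.0, 1.07, 4.24)),
    "dyslipidemia": (-2.37, (0.0, 0.38, 1.53)),
    "hyperuricemia": (-4.33, (0.0, 1.15, 2.22)),
    "mi": (-4.60, (0.0, 0.98, 2.13)),
    "stroke": (-4.12, (0.0, 0.33, 1.26)),
}
_DEFAULT_INCIDENT_LOGITS = {
    "hypertension": (-2.24, (0.0, 0.19, 0.39)),
    "t2d": (-4.18, (0.0, 1.10, 3.34)),
    "dyslipidemia": (-3.48, (0.0, 1.19, 1.91)),
    "hyperuricemia": (-5.30, (0.0, 1.60, 3.05)),
    "mi": (-6.20, (0.0, 2.30, 2.50)),
    "stroke": (-4.50, (0.0, 0.31, 1.47)),
}

# Group-conditional demographics: median-scale ages and female shares echoing
# the favorable cluster being younger and predominantly female.
_AGE_MEAN = (51.0, 57.0, 64.0)
_AGE_SD = 12.0
_FEMALE_SHARE = (0.76, 0.35, 0.39)

_EDUCATION_LEVELS = ("<10y", "10-<12y", ">=12y")
_EDUCATION_P = (0.087, 0.500, 0.413)
_ACTIVITY_LEVELS = ("active", "inactive")
_SMOKING_LEVELS = ("smoker", "ex-smoker", "never-smoker")
_SMOKING_P = (0.175, 0.406, 0.419)
_ALCOHOL_LEVELS = (">=40g/day", "20-<40g/day", "0-<20g/day", "0g/day")
_ALCOHOL_P = (0.112, 0.180, 0.407, 0.301)


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass
class GeneratorConfig:
    """Conditions under which the synthetic cohort is drawn.

    Defaults describe a baseline wave of 3001 participants split
    40/48/12% across the three latent metabolic groups, ~70% overall
    follow-up retention (lowest in the unfavorable group), 5% missingness
    per parameter cell, and ~1.75% non-fasting blood draws.
    """

    n_participants: int = 3001
    latent_proportions: tuple[float, float, float] = (0.40, 0.48, 0.12)
    component_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS))
    component_cvs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CVS))
    log_scale_params: frozenset[str] = LOG_SCALE_PARAMS
    sex_effect: dict[str, float] = field(
        default_factory=lambda: {"hdlc": -0.10, "uric_acid": 20.0})
    missing_rate: float = 0.05
    missing_mechanism: str = "mcar"  # or "mar_bmi": rate doubles in top BMI tertile
    disease_flag_missing_rate: float = 0.002
    disease_baseline_logits: dict[str, tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_LOGITS))
    disease_incident_logits: dict[str, tuple[float, tuple[float, float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_INCIDENT_LOGITS))
    followup_retention: tuple[float, float, float] = (0.75, 0.71, 0.55)
    nonfasting_rate: float = 0.0175
    shared_factor_sd: float = 0.0  # optional common "adiposity" factor, off by default
    shared_factor_loadings: dict[str, float] = field(
        default_factory=lambda: {"bmi": 1.0, "insulin": 0.8, "tg": 0.6, "hscrp": 0.5})
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        props = np.asarray(self.latent_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ConfigError("latent_proportions must be 3 non-negative values summing to 1")
        for name in PARAMETERS:
            if name not in self.component_means:
                raise ConfigError(f"component_means missing parameter {name!r}")
            means = self.component_means[name]
            if len(means) != 3:
                raise ConfigError(f"component_means[{name!r}] must give 3 group values")
            if name in self.log_scale_params and min(means) <= 0:
                raise ConfigError(
                    f"component_means[{name!r}] must be strictly positive (log-scale)")
            cv = self.component_cvs.get(name)
            if cv is None or cv <= 0:
                raise ConfigError(f"component_cvs[{name!r}] must be positive")
        for label, rate in [("missing_rate", self.missing_rate),
                            ("nonfasting_rate", self.nonfasting_rate),
                            ("disease_flag_missing_rate", self.disease_flag_missing_rate)]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1]")
        if self.missing_rate > 0.1:
            raise ConfigError("missing_rate must be in [0, 0.1]")
        if self.missing_mechanism not in ("mcar", "mar_bmi"):
            raise ConfigError("missing_mechanism must be 'mcar' or 'mar_bmi'")
        if len(self.followup_retention) != 3 or not all(
                0.0 <= r <= 1.0 for r in self.followup_retention):
            raise ConfigError("followup_retention must be 3 probabilities")
        for attr in ("disease_baseline_logits", "disease_incident_logits"):
            coeffs = getattr(self, attr)
            for dz in DISEASES:
                if dz not in coeffs:
                    raise ConfigError(f"{attr} missing disease {dz!r}")


def _draw_parameters(cfg: GeneratorConfig, group: np.ndarray, male: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = group.size
    shared = rng.normal(0.0, 1.0, n) if cfg.shared_factor_sd > 0 else None
    out = {}
    for name in PARAMETERS:
        means = np.asarray(cfg.component_means[name], float)[group - 1]
        cv = cfg.component_cvs[name]
        if name in cfg.log_scale_params:
            sigma2 = np.log1p(cv * cv)
            mu = np.log(means) - sigma2 / 2.0
            vals = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
        else:
            vals = rng.normal(means, cv * means)
        if shared is not None and name in cfg.shared_factor_loadings:
            vals = vals + (cfg.shared_factor_sd * cfg.shared_factor_loadings[name]
                           * cv * means * shared)
        shift = cfg.sex_effect.get(name, 0.0)
        if shift:
            vals = vals + shift * male
        # clinical analytes are strictly positive; reflect rare negatives
        np.abs(vals, out=vals)
        vals[vals == 0] = means[vals == 0] * 1e-3
        out[name] = vals
    return pd.DataFrame(out)


def _logistic_draw(base: float, effects: tuple[float, float, float],
                   group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    logit = base + np.asarray(effects, float)[group - 1]
    p = 1.0 / (1.0 + np.exp(-logit))
    return rng.random(group.size) < p


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a baseline + follow-up cohort table.

    Deterministic for a fixed ``config.seed``.  Incident disease flags are
    drawn only for participants who are disease-free at baseline and who
    participate in the follow-up; elsewhere they are missing.  The returned
    frame carries ``latent_group`` purely as ground truth for validation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    group = rng.choice([1, 2, 3], size=n, p=np.asarray(config.latent_proportions, float))
    male = rng.random(n) >= np.asarray(_FEMALE_SHARE)[group - 1]
    params = _draw_parameters(config, group, male.astype(float), rng)

    # missingness on the parameter block
    if config.missing_rate > 0:
        if config.missing_mechanism == "mar_bmi":
            tert = np.quantile(params["bmi"], 2 / 3)
            cell_rate = np.where(params["bmi"].to_numpy() > tert,
                                 2 * config.missing_rate, config.missing_rate)
            cell_rate = cell_rate * (config.missing_rate / cell_rate.mean())
            mask = rng.random((n, len(PARAMETERS))) < cell_rate[:, None]
        else:
            mask = rng.random((n, len(PARAMETERS))) < config.missing_rate
        vals = params.to_numpy()
        vals[mask] = np.nan
        params = pd.DataFrame(vals, columns=list(PARAMETERS))

    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "latent_group": group,
        "fasting_hours_ok": rng.random(n) >= config.nonfasting_rate,
        "sex": np.where(male, "male", "female"),
        "age_years": np.clip(rng.normal(np.asarray(_AGE_MEAN)[group - 1], _AGE_SD),
                             25, 94).round(0),
        "education_class": rng.choice(_EDUCATION_LEVELS, size=n, p=_EDUCATION_P),
        "activity_class": np.where(rng.random(n) < 0.55, *_ACTIVITY_LEVELS),
        "smoking_class": rng.choice(_SMOKING_LEVELS, size=n, p=_SMOKING_P),
        "alcohol_class": rng.choice(_ALCOHOL_LEVELS, size=n, p=_ALCOHOL_P),
    })
    df = pd.concat([df, params], axis=1)

    retention = np.asarray(config.followup_retention, float)[group - 1]
    in_followup = rng.random(n) < retention
    df["in_followup"] = in_followup

    for dz in DISEASES:
        base, eff = config.disease_baseline_logits[dz]
        baseline = _logistic_draw(base, eff, group, rng).astype(float)
        if config.disease_flag_missing_rate > 0:
            baseline[rng.random(n) < config.disease_flag_missing_rate] = np.nan
        df[f"baseline_{dz}"] = baseline

        base_i, eff_i = config.disease_incident_logits[dz]
        incident = _logistic_draw(base_i, eff_i, group, rng).astype(float)
        at_risk = (baseline == 0.0) & in_followup
        incident[~at_risk] = np.nan
        if config.disease_flag_missing_rate > 0:
            drop = at_risk & (rng.random(n) < config.disease_flag_missing_rate)
            incident[drop] = np.nan
        df[f"followup_{dz}"] = incident

    return df


def write_cohort(df: pd.DataFrame, outdir: str | Path) -> Path:
    """Write the cohort as UTF-8 CSV plus a JSON data dictionary sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "cohort.csv"
    df.to_csv(csv_path, index=False, na_rep="")
    dictionary = []
    categories = {
        "sex": ["male", "female"],
        "education_class": list(_EDUCATION_LEVELS),
        "activity_class": list(_ACTIVITY_LEVELS),
        "smoking_class": list(_SMOKING_LEVELS),
        "alcohol_class": list(_ALCOHOL_LEVELS),
    }
    for col in df.columns:
        if col in PARAMETERS:
            entry = {"name": col, "type": "continuous", "unit": PARAMETER_UNITS[col]}
        elif col in categories:
            entry = {"name": col, "type": "categorical", "unit": None,
                     "allowed": categories[col]}
        elif col.startswith(("baseline_", "followup_")) or col in (
                "fasting_hours_ok", "in_followup"):
            entry = {"name": col, "type": "boolean", "unit": None}
        else:
            entry = {"name": col, "type": "integer" if col != "age_years" else "years",
                     "unit": None}
        dictionary.append(entry)
    (outdir / "cohort.dictionary.json").write_text(json.dumps(dictionary, indent=2))
    return csv_path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    for col in ("fasting_hours_ok", "in_followup"):
        if col in df and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["log_scale_params"] = sorted(config.log_scale_params)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "log_scale_params" in d:
        d["log_scale_params"] = frozenset(d["log_scale_params"])
    for key in ("latent_proportions", "followup_retention"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("disease_baseline_logits", "disease_incident_logits"):
        if key in d:
            d[key] = {dz: (float(v[0]), tuple(v[1])) for dz, v in d[key].items()}
    if "component_means" in d:
        d["component_means"] = {k: tuple(v) for k, v in d["component_means"].items()}
    return GeneratorConfig(**d)
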