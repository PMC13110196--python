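"""Synthetic SDTM-like study generator.

Emulates the structural properties the detector assumes — a region ->
country -> site -> subject hierarchy, multiple measurement parameters with
realistic location/scale, staggered enrollment (prefix-length series),
randomly missing visits, rounded parameters (weight), unscheduled visits and
screening failures — while containing *no site-level signal by construction*:
values are subject baseline + linear visit trend + noise, with no site,
country or region effect terms.  An optional ``site_effect_sd`` knob adds a
site-level random intercept for mixed-model power experiments only.

Measurement presets (ALT, creatinine, systolic BP, weight) use plausible
synthetic means and spreads; they are generator defaults, not estimates from
any real trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import COLUMNS, Study


@dataclass
class ParameterSpec:
    """Name, baseline mean/SD across subjects, per-visit trend, residual SD,
    and optional rounding (decimal places) of the recorded values."""

    name: str
    baseline_mean: float
    baseline_sd: float
    trend: float
    residual_sd: float
    decimals: int | None = None


#: synthetic defaults for the four measurement types exercised end-to-end
DEFAULT_PARAMETERS = (
    ParameterSpec("Alanine Aminotransferase", 30.0, 8.0, 0.2, 5.0),
    ParameterSpec("Creatinine", 0.9, 0.15, 0.0, 0.08),
    ParameterSpec("Systolic Blood Pressure", 125.0, 10.0, -0.3, 6.0),
    ParameterSpec("Weight", 78.0, 12.0, 0.1, 1.5, decimals=0),
)


@dataclass
class SynthConfig:
    n_regions: int = 1
    n_countries: int = 1
    n_sites: int = 20
    subjects_per_site: int | tuple[int, int] = 15
    n_visits: int = 8
    parameters: tuple[ParameterSpec, ...] = DEFAULT_PARAMETERS
    missing_rate: float = 0.05
    staggered_fraction: float = 0.30
    stagger_depth: float | None = 0.5  # prefix fraction; None = uniform random
    unscheduled_rate: float = 0.05
    screen_failure_rate: float = 0.05
    site_effect_sd: float = 0.0  # power-testing knob; 0 = no site signal
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.staggered_fraction,
                     self.unscheduled_rate, self.screen_failure_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")


def _site_counts(config: SynthConfig, rng: np.random.Generator) -> list[int]:
    if isinstance(config.subjects_per_site, tuple):
        lo, hi = config.subjects_per_site
        return [int(rng.integers(lo, hi + 1)) for _ in range(config.n_sites)]
    return [int(config.subjects_per_site)] * config.n_sites


def generate_study(config: SynthConfig) -> Study:
    """Generate a deterministic synthetic study from a config and seed."""
    rng = np.random.default_rng(config.seed)

    regions = [f"R{i+1}" for i in range(config.n_regions)]
    countries = [f"C{i+1}" for i in range(config.n_countries)]
    country_region = {c: regions[i % len(regions)] for i, c in enumerate(countries)}
    sites = [f"S{i+1:03d}" for i in range(config.n_sites)]
    site_country = {s: countries[i % len(countries)] for i, s in enumerate(sites)}

    counts = _site_counts(config, rng)
    rows: list[tuple] = []
    subj_no = 0
    for site, n_subjects in zip(sites, counts):
        country = site_country[site]
        region = country_region[country]
        site_shift = rng.normal(0.0, config.site_effect_sd) if config.site_effect_sd else 0.0
        for _ in range(n_subjects):
            subj_no += 1
            subject = f"P{subj_no:05d}"
            screen_fail = rng.random() < config.screen_failure_rate
            if screen_fail:
                n_visits_subj = 1  # screening visit only
            elif rng.random() < config.staggered_fraction and config.n_visits > 1:
                if config.stagger_depth is not None:
                    n_visits_subj = max(1, int(round(config.stagger_depth * config.n_visits)))
                else:
                    n_visits_subj = int(rng.integers(1, config.n_visits))
            else:
                n_visits_subj = config.n_visits

            for spec in config.parameters:
                baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
                rel_shift = site_shift * spec.baseline_sd  # site knob in SD units
                for visit in range(1, n_visits_subj + 1):
                    if visit > 1 and rng.random() < config.missing_rate:
                        continue
                    value = (baseline + rel_shift + spec.trend * (visit - 1)
                             + rng.normal(0.0, spec.residual_sd))
                    if spec.decimals is not None:
                        value = round(value, spec.decimals)
                    rows.append((subject, site, country, region, spec.name,
                                 visit, True, screen_fail, value))
                # unscheduled visits get indices past the schedule and are
                # dropped by cleaning
                n_unsched = rng.binomial(n_visits_subj, config.unscheduled_rate)
                for k in range(n_unsched):
                    value = (baseline + rel_shift
                             + spec.trend * rng.uniform(0, n_visits_subj)
                             + rng.normal(0.0, spec.residual_sd))
                    if spec.decimals is not None:
                        value = round(value, spec.decimals)
                    rows.append((subject, site, country, region, spec.name,
                                 config.n_visits + 1 + k, False, screen_fail, value))

    records = pd.DataFrame(rows, columns=COLUMNS)
    return Study(records)


def fig1_fixture() -> Study:
    """Deterministic 8-subject, 8-visit, single-parameter study.

    Three subjects complete all 8 visits, three have exactly the first 4,
    and two have fewer than 4 — the canonical worked example for automatic
    group discovery (expected groups: length 8 with 3 subjects, length 4
    with 6 subjects; the last two subjects qualify for neither).  S7 and S8
    hold mid-schedule visits (they miss visit 1), so no shorter window can
    grow the eligible count further.
    """
    subject_visits = {"S1": range(1, 9), "S2": range(1, 9), "S3": range(1, 9),
                      "S4": range(1, 5), "S5": range(1, 5), "S6": range(1, 5),
                      "S7": (2, 3), "S8": (5,)}
    rows = []
    for i, (subject, visits) in enumerate(subject_visits.items()):
        for visit in visits:
            value = 10.0 + i + 0.5 * visit  # arbitrary but fixed
            rows.append((subject, "SITE1", "C1", "R1", "ALT",
                         visit, True, False, value))
    return Study(pd.DataFrame(rows, columns=COLUMNS))


def default_validation_study(seed: int, parameter_index: int = 0) -> tuple[Study, str]:
    """The default benchmark study: 20 sites x 15 subjects x 8 visits,
    single parameter, generated and cleaned.  Returns (study, parameter name)."""
    from .study import clean_study

    spec = DEFAULT_PARAMETERS[parameter_index]
    config = SynthConfig(parameters=(spec,), seed=seed)
    return clean_study(generate_study(config)), spec.name
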