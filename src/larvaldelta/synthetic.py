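"""Synthetic survey generator with the statistical structure the delta
analysis assumes.

Each area × season × survey × species cell draws a larval abundance from a
per-species log-normal, a presence indicator from a Bernoulli whose logit is
linear in species, season, area and log-abundance, and — when present — a
parasitized-larva count from the configured positive family (gamma draws are
continuous and are rounded up to >= 1, then capped at the abundance: the
generator must emit integer counts while the gamma analysis model treats
them as continuous, exactly the mismatch inherent in fitting gamma GLMs to
count frequencies).  Each parasitized larva carries 1 + Poisson(λ_extra)
parasites, and paired host/parasite lengths are emitted for correlation
checks.  A single seeded stream is consumed in fixed field order per cell,
so identical seeds give bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .survey_data import Dataset, LengthPair, SurveyRecord, ValidationError


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give a small generic two-part design.

    Effect dictionaries map factor levels to additive effects on the link
    scale (logit for presence, log for the positive mean); missing levels
    default to zero, so the alphabetically-first (reference) level should be
    left at zero to match treatment-coded fits.  ``abundance`` enters both
    linear predictors as log1p(larvae collected).
    """

    areas: Tuple[str, ...] = ("COL", "ISM")
    seasons: Tuple[str, ...] = ("autumn_winter", "spring_summer")
    n_surveys_per_stratum: int = 5
    species: Tuple[str, ...] = ("Ac", "Gm", "Hc", "Msp", "Oj")

    abundance_median: Dict[str, float] = field(
        default_factory=lambda: {"Ac": 120.0, "Gm": 40.0, "Hc": 250.0, "Msp": 15.0, "Oj": 15.0}
    )
    abundance_sigma: float = 1.2

    presence_intercept: float = -2.5
    presence_species: Dict[str, float] = field(default_factory=dict)
    presence_season: Dict[str, float] = field(default_factory=dict)
    presence_area: Dict[str, float] = field(default_factory=dict)
    presence_abundance_slope: float = 0.35

    positive_family: str = "gamma_log"
    positive_intercept: float = 1.0
    positive_species: Dict[str, float] = field(default_factory=dict)
    positive_season: Dict[str, float] = field(default_factory=dict)
    positive_area: Dict[str, float] = field(default_factory=dict)
    positive_abundance_slope: float = 0.0
    gamma_shape: float = 2.0
    nb_theta: float = 2.0

    lambda_extra: float = 0.07

    host_length_range: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "Ac": (3.0, 8.1), "Gm": (1.9, 6.6), "Hc": (3.8, 10.1),
            "Msp": (4.1, 6.1), "Oj": (2.3, 7.5),
        }
    )
    parasite_length_intercept: float = 0.1
    parasite_length_slope: float = 0.2
    parasite_length_noise_sd: float = 0.15

    seed: int = 0

    def validate(self) -> None:
        if self.abundance_sigma <= 0 or self.gamma_shape <= 0 or self.nb_theta <= 0:
            raise ValidationError("variance/shape parameters must be > 0")
        if self.lambda_extra < 0 or self.parasite_length_noise_sd < 0:
            raise ValidationError("rates and noise SDs must be nonnegative")
        if self.positive_family not in ("gamma_log", "negbin_log", "poisson_log"):
            raise ValidationError(f"unknown positive family {self.positive_family!r}")
        if self.n_surveys_per_stratum < 1:
            raise ValidationError("need at least one survey per stratum")


def _effect(table: Dict[str, float], level: str) -> float:
    return float(table.get(level, 0.0))


def true_design_params(config: SimConfig, part: str) -> Dict[str, float]:
    """Generating coefficients in treatment-coded design parametrization.

    Keyed by the column names :func:`larvaldelta.glm_core.build_design`
    produces (alphabetically-first reference levels), so simulated fits can
    be compared to truth coefficient-by-coefficient.
    """
    if part == "presence":
        icept, sp, se, ar, slope = (
            config.presence_intercept, config.presence_species,
            config.presence_season, config.presence_area,
            config.presence_abundance_slope,
        )
    elif part == "positive":
        icept, sp, se, ar, slope = (
            config.positive_intercept, config.positive_species,
            config.positive_season, config.positive_area,
            config.positive_abundance_slope,
        )
    else:
        raise ValueError("part must be 'presence' or 'positive'")
    ref_sp, ref_se, ref_ar = (sorted(config.species)[0], sorted(config.seasons)[0],
                              sorted(config.areas)[0])
    out = {"Intercept": icept + _effect(sp, ref_sp) + _effect(se, ref_se) + _effect(ar, ref_ar)}
    for lvl in sorted(config.species)[1:]:
        out[f"species[{lvl}]"] = _effect(sp, lvl) - _effect(sp, ref_sp)
    for lvl in sorted(config.seasons)[1:]:
        out[f"season[{lvl}]"] = _effect(se, lvl) - _effect(se, ref_se)
    for lvl in sorted(config.areas)[1:]:
        out[f"area[{lvl}]"] = _effect(ar, lvl) - _effect(ar, ref_ar)
    if slope != 0.0:
        out["abundance"] = slope
    return out


def generate_dataset(config: SimConfig) -> Tuple[Dataset, dict]:
    """Draw one survey Dataset plus the true-parameter record.

    Cells are visited in fixed (area, season, survey, species) order and
    sub-draws are consumed in fixed field order (abundance, presence,
    positive count, parasites, lengths), keeping determinism under config
    edits that do not touch earlier fields.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records, lengths = [], []
    for ai, area in enumerate(config.areas):
        for si, season in enumerate(config.seasons):
            base_survey = si * config.n_surveys_per_stratum
            for s in range(config.n_surveys_per_stratum):
                survey_id = base_survey + s + 1
                for species in config.species:
                    median = config.abundance_median.get(species, 50.0)
                    n_collected = int(round(float(
                        rng.lognormal(mean=np.log(median), sigma=config.abundance_sigma)
                    )))
                    n_collected = max(n_collected, 0)
                    n_par = 0
                    if n_collected >= 1:
                        eta_p = (
                            config.presence_intercept
                            + _effect(config.presence_species, species)
                            + _effect(config.presence_season, season)
                            + _effect(config.presence_area, area)
                            + config.presence_abundance_slope * np.log1p(n_collected)
                        )
                        present = rng.random() < 1.0 / (1.0 + np.exp(-eta_p))
                        if present:
                            eta_d = (
                                config.positive_intercept
                                + _effect(config.positive_species, species)
                                + _effect(config.positive_season, season)
                                + _effect(config.positive_area, area)
                                + config.positive_abundance_slope * np.log1p(n_collected)
                            )
                            mu = float(np.exp(eta_d))
                            if config.positive_family == "gamma_log":
                                draw = rng.gamma(shape=config.gamma_shape,
                                                 scale=mu / config.gamma_shape)
                                n_par = int(np.ceil(draw))
                            elif config.positive_family == "poisson_log":
                                n_par = int(rng.poisson(mu))
                            else:
                                th = config.nb_theta
                                n_par = int(rng.negative_binomial(th, th / (th + mu)))
                            n_par = max(1, min(n_par, n_collected))
                    n_parasites = n_par + (int(rng.poisson(config.lambda_extra * n_par))
                                           if n_par > 0 else 0)
                    records.append(
                        SurveyRecord(
                            area=area, season=season, survey_id=survey_id,
                            species=species, n_collected=n_collected,
                            n_parasitized=n_par, n_parasites=n_parasites,
                        )
                    )
                    if n_par > 0:
                        lo, hi = config.host_length_range.get(species, (2.0, 8.0))
                        for _ in range(n_par):
                            host = float(rng.uniform(lo, hi))
                            par = (
                                config.parasite_length_intercept
                                + config.parasite_length_slope * host
                                + float(rng.normal(0.0, config.parasite_length_noise_sd))
                            )
                            lengths.append(
                                LengthPair(species=species, area=area,
                                           host_length=host,
                                           parasite_length=max(par, 1e-3))
                            )
    truth = {
        "presence": true_design_params(config, "presence"),
        "positive": true_design_params(config, "positive"),
        "positive_family": config.positive_family,
        "gamma_shape": config.gamma_shape,
        "nb_theta": config.nb_theta,
        "lambda_extra": config.lambda_extra,
        "seed": config.seed,
    }
    return (
        Dataset(records=records, lengths=lengths,
                provenance=f"synthetic (seed={config.seed})"),
        truth,
    )


def paper_like_scenario(seed: int = 0) -> SimConfig:
    """Preset emulating the study's shape: 2 areas × 2 seasons × 5 surveys
    each × 5 species, species-skewed abundances spanning roughly 1–6000
    larvae per cell, zero-heavy presence (most cells unparasitized), and
    low intensities (mostly one parasite per larva, occasionally two)."""
    return SimConfig(
        abundance_median={"Ac": 120.0, "Gm": 40.0, "Hc": 250.0, "Msp": 15.0, "Oj": 15.0},
        abundance_sigma=1.4,
        presence_intercept=-3.6,
        presence_species={"Gm": 1.0, "Hc": 0.6, "Msp": -0.3, "Oj": -0.2},
        presence_season={"spring_summer": -1.2},
        presence_area={"ISM": 0.8},
        presence_abundance_slope=0.45,
        positive_intercept=0.9,
        positive_species={"Gm": 0.3, "Hc": 1.0, "Msp": -0.2, "Oj": -0.1},
        positive_season={"spring_summer": -0.8},
        gamma_shape=2.0,
        lambda_extra=0.07,
        seed=seed,
    )
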