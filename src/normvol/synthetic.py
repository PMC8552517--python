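"""Synthetic cohort generator.

Emulates the statistical structure of a population brain-volumetry study:
a reference group of non-demented (ND) adults sampled uniformly over age,
a smaller Alzheimer's-disease (AD) patient group in a narrower, older age
range, six subcortical regions, and several segmentation "methods" that
observe the same underlying anatomy through method-specific systematic
distortions (scale, offset), independent measurement noise, occasional
pipeline failures and gross outliers.

The generative model is latent-variable: each subject carries one true
volume per region, drawn as

    v = psi_lambda^{-1}( psi_lambda(m(age, sex, height)) + sigma_t * z ),
    z ~ N(0, 1),

where ``psi_lambda`` is the Yeo-Johnson transform, ``m`` the median curve
(linear in age, additive sex and height effects) and ``sigma_t`` a
transformed-scale SD calibrated so the coefficient of variation of ``v``
matches the configured value.  AD subjects' latent volumes are shrunk by a
per-region atrophy factor before any method observes them.  Each method
then reports ``scale * v + offset + N(0, noise_sd)``.  Because the skew is
injected through the inverse Yeo-Johnson, the normative fitter's model
family matches the generator exactly when lambda = 1, enabling clean
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import CohortTable
from .normative import yeo_johnson, yeo_johnson_inverse

log = logging.getLogger("normvol")

#: fixed left/right share of a bilateral region's total volume
HEMI_SPLIT = (0.48, 0.52)
#: caudate vs accumbens share of their combined volume (for methods that
#: segment them separately)
CAUDATE_SPLIT = (14 / 15, 1 / 15)

REGION_CAUDATE = "caudate_nucleus"
REGION_ACCUMBENS = "accumbens"
REGION_CAUDATE_ACCUMBENS = "caudate_nucleus_accumbens"


class GeneratorError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclasses.dataclass
class RegionPopulationParams:
    """Population parameters of one region's true-volume distribution."""

    median_at_ref_age: float  # mm^3
    age_slope: float  # mm^3 per year, typically negative
    coef_variation: float  # SD / median, dimensionless
    ref_age: float = 70.0  # years
    skew_lambda: float = 1.0  # Yeo-Johnson lambda of the true distribution
    sex_effect: float = 0.0  # mm^3, additive male - female
    height_effect: float = 0.0  # mm^3 per cm, centered at 170 cm

    def validate(self, name: str) -> None:
        if self.median_at_ref_age <= 0:
            raise GeneratorError(f"{name}: median_at_ref_age must be > 0")
        if self.coef_variation <= 0:
            raise GeneratorError(f"{name}: coef_variation must be > 0")

    def median(self, age, sex, height):
        """Median true volume at the given covariates (mm^3)."""
        return (
            self.median_at_ref_age
            + self.age_slope * (np.asarray(age, float) - self.ref_age)
            + self.sex_effect * np.asarray(sex, float)
            + self.height_effect * (np.asarray(height, float) - 170.0)
        )

    def transformed_scale(self, age, sex, height):
        """Transformed-scale SD giving CV ~= coef_variation (delta method)."""
        m = self.median(age, sex, height)
        dpsi = np.power(m + 1.0, self.skew_lambda - 1.0)  # d psi / dv at the median
        return dpsi * self.coef_variation * m


@dataclasses.dataclass
class MethodDistortion:
    """Systematic and random errors of one segmentation method."""

    scale: float = 1.0  # multiplicative
    offset: float = 0.0  # mm^3 additive
    noise_sd: float = 0.0  # mm^3 independent noise
    failure_rate: float = 0.0  # P(no segmentation produced)
    outlier_rate: float = 0.0  # P(gross error injected)
    outlier_magnitude: float = 8.0  # multiples of population SD

    def validate(self, name: str) -> None:
        if self.scale <= 0:
            raise GeneratorError(f"{name}: scale must be > 0")
        if self.noise_sd < 0:
            raise GeneratorError(f"{name}: noise_sd must be >= 0")
        for rate_name in ("failure_rate", "outlier_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise GeneratorError(f"{name}: {rate_name} must be in [0, 1]")


@dataclasses.dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort."""

    regions: Mapping[str, RegionPopulationParams]
    methods: Mapping[str, MethodDistortion]
    ad_atrophy: Mapping[str, float]
    n_nd: int = 988
    n_ad: int = 42
    age_range_nd: tuple[float, float] = (45.0, 95.0)
    age_range_ad: tuple[float, float] = (71.0, 91.0)
    seed: int = 0
    #: methods that report caudate+accumbens as a single pre-merged region
    premerged_methods: frozenset[str] = frozenset()
    #: mean height (cm) by sex code; SD fixed at 7 cm
    height_mean: tuple[float, float] = (163.0, 177.0)

    def validate(self) -> None:
        if self.n_nd < 2:
            raise GeneratorError("n_nd must be >= 2")
        if self.n_ad < 0:
            raise GeneratorError("n_ad must be >= 0")
        for rng_name in ("age_range_nd", "age_range_ad"):
            lo, hi = getattr(self, rng_name)
            if not lo < hi:
                raise GeneratorError(f"{rng_name} must be non-degenerate (low < high)")
        if not self.regions:
            raise GeneratorError("at least one region required")
        if not self.methods:
            raise GeneratorError("at least one method required")
        for name, params in self.regions.items():
            params.validate(name)
        for name, dist in self.methods.items():
            dist.validate(name)
        for region, factor in self.ad_atrophy.items():
            if region not in self.regions:
                raise GeneratorError(f"ad_atrophy references unknown region {region!r}")
            if not 0.0 < factor <= 1.0:
                raise GeneratorError(f"ad_atrophy[{region!r}] must be in (0, 1]")
        unknown = set(self.premerged_methods) - set(self.methods)
        if unknown:
            raise GeneratorError(f"premerged_methods not in methods: {sorted(unknown)}")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default study conditions: 988 ND subjects aged 45-95, 42 AD patients
    aged 71-91, six subcortical regions with realistic medians and CVs, and
    five methods with distinct systematic distortions (the last one reports
    caudate and accumbens as a single region).
    """
    regions = {
        "hippocampus": RegionPopulationParams(6200.0, -22.0, 0.13, skew_lambda=0.8,
                                              sex_effect=350.0, height_effect=12.0),
        "amygdala": RegionPopulationParams(2200.0, -7.0, 0.13, skew_lambda=0.8,
                                           sex_effect=150.0, height_effect=5.0),
        REGION_CAUDATE_ACCUMBENS: RegionPopulationParams(7800.0, -18.0, 0.14,
                                                         sex_effect=420.0, height_effect=15.0),
        "thalamus": RegionPopulationParams(12400.0, -45.0, 0.13,
                                           sex_effect=650.0, height_effect=25.0),
        "putamen": RegionPopulationParams(8200.0, -35.0, 0.13,
                                          sex_effect=480.0, height_effect=16.0),
        "globus_pallidus": RegionPopulationParams(2300.0, -6.0, 0.13,
                                                  sex_effect=140.0, height_effect=5.0),
    }
    methods = {
        "segA": MethodDistortion(1.00, 0.0, 80.0, failure_rate=0.001, outlier_rate=0.001),
        "segB": MethodDistortion(1.12, -150.0, 120.0, failure_rate=0.009, outlier_rate=0.002),
        "segC": MethodDistortion(0.92, 250.0, 100.0, outlier_rate=0.001),
        "segD": MethodDistortion(1.00, 400.0, 150.0, outlier_rate=0.002),
        "segE": MethodDistortion(0.96, -120.0, 90.0, outlier_rate=0.001),
    }
    ad_atrophy = {
        "hippocampus": 0.75,
        "amygdala": 0.78,
        REGION_CAUDATE_ACCUMBENS: 0.95,
        "thalamus": 0.96,
        "putamen": 0.95,
        "globus_pallidus": 0.96,
    }
    return GeneratorConfig(
        regions=regions,
        methods=methods,
        ad_atrophy=ad_atrophy,
        seed=seed,
        premerged_methods=frozenset({"segE"}),
    )


def true_z(config: GeneratorConfig, age, sex, height, latent_volume, region: str):
    """Generative z-score of a latent volume under the configured ND norms.

    ND latent volumes have ``true_z ~ N(0, 1)`` by construction; this is the
    oracle against which the fitted normative models are checked.
    """
    if region not in config.regions:
        raise GeneratorError(f"unknown region {region!r}")
    params = config.regions[region]
    m = params.median(age, sex, height)
    sigma_t = params.transformed_scale(age, sex, height)
    lam = params.skew_lambda
    return (yeo_johnson(latent_volume, lam) - yeo_johnson(m, lam)) / sigma_t


def _draw_group(rng: np.random.Generator, config: GeneratorConfig, group: str,
                n: int, age_range: tuple[float, float], id_prefix: str,
                tally: dict) -> list[dict]:
    """Sample one group; returns long-format row dicts (hemisphere split)."""
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sexes = rng.integers(0, 2, size=n)
    heights = rng.normal(np.where(sexes == 1, config.height_mean[1], config.height_mean[0]), 7.0)
    heights = np.clip(heights, 140.0, 210.0)
    subject_ids = [f"{id_prefix}{i:05d}" for i in range(n)]

    rows: list[dict] = []
    region_names = list(config.regions)
    method_names = list(config.methods)
    for region in region_names:
        params = config.regions[region]
        m = params.median(ages, sexes, heights)
        if np.any(m <= 0):
            raise GeneratorError(f"{region}: median curve non-positive in the age range")
        sigma_t = params.transformed_scale(ages, sexes, heights)
        z = rng.standard_normal(n)
        latent = yeo_johnson_inverse(
            yeo_johnson(m, params.skew_lambda) + sigma_t * z, params.skew_lambda
        )
        if group == "AD":
            latent = latent * config.ad_atrophy.get(region, 1.0)
        pop_sd = params.coef_variation * params.median_at_ref_age

        for method in method_names:
            dist = config.methods[method]
            observed = dist.scale * latent + dist.offset
            if dist.noise_sd > 0:
                observed = observed + rng.normal(0.0, dist.noise_sd, size=n)
            # gross errors: shift by a fixed number of population SDs
            is_outlier = rng.random(n) < dist.outlier_rate
            observed = observed + is_outlier * dist.outlier_magnitude * pop_sd
            failed = rng.random(n) < dist.failure_rate
            # a non-positive observation is treated as a failed segmentation
            observed = np.where(failed | (observed <= 0.0), np.nan, observed)
            key = (group, method, region)
            tally[key] = {
                "outliers_injected": int(is_outlier.sum()),
                "failures_injected": int(np.isnan(observed).sum()),
            }

            premerged = method in config.premerged_methods
            if region == REGION_CAUDATE_ACCUMBENS and not premerged:
                emitted = [
                    (REGION_CAUDATE, observed * CAUDATE_SPLIT[0]),
                    (REGION_ACCUMBENS, observed * CAUDATE_SPLIT[1]),
                ]
            else:
                emitted = [(region, observed)]
            for region_out, totals in emitted:
                for hemi, frac in zip(("left", "right"), HEMI_SPLIT):
                    vols = totals * frac
                    for i in range(n):
                        rows.append({
                            "subject_id": subject_ids[i],
                            "age": ages[i],
                            "sex": int(sexes[i]),
                            "height": heights[i],
                            "group": group,
                            "method": method,
                            "region": region_out,
                            "hemisphere": hemi,
                            "volume_mm3": vols[i],
                        })
    return rows


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a cohort table from the configuration; fully reproducible
    from ``config.seed`` (same config + seed gives a byte-identical table).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tally: dict = {}
    rows = _draw_group(rng, config, "ND", config.n_nd, config.age_range_nd, "nd", tally)
    rows += _draw_group(rng, config, "AD", config.n_ad, config.age_range_ad, "ad", tally)
    df = pd.DataFrame(rows)
    df["exclude"] = 0
    log.info("generated cohort: %d ND + %d AD subjects, %d rows",
             config.n_nd, config.n_ad, len(df))
    return CohortTable(df, provenance={"generator_seed": config.seed,
                                       "n_nd": config.n_nd, "n_ad": config.n_ad,
                                       "injection_tally": tally})
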