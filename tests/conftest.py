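import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import normvol as nv
from normvol.synthetic import GeneratorConfig, MethodDistortion, RegionPopulationParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_records(rows):
    """Build a cohort DataFrame from (sid, age, sex, height, group, method,
    region, hemi, vol) tuples."""
    cols = ["subject_id", "age", "sex", "height", "group", "method",
            "region", "hemisphere", "volume_mm3"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def tiny_table():
    """Three ND subjects, one method/region, already bilateral."""
    df = make_records([
        ("s1", 60.0, 1, 170.0, "ND", "segA", "thalamus", "both", 12000.0),
        ("s2", 70.0, 0, 165.0, "ND", "segA", "thalamus", "both", 11500.0),
        ("s3", 80.0, 1, 180.0, "ND", "segA", "thalamus", "both", 11000.0),
    ])
    return nv.CohortTable(df)


def wellspec_config(seed, n_nd=2000, height_effect=60.0):
    """Single-region, single-method cohort where the generator's model
    family coincides exactly with the fitter's (identity transform)."""
    params = RegionPopulationParams(
        12400.0, -45.0, 0.13, skew_lambda=1.0,
        sex_effect=650.0, height_effect=height_effect,
    )
    return GeneratorConfig(
        regions={"thalamus": params},
        methods={"segA": MethodDistortion()},
        ad_atrophy={},
        n_nd=n_nd, n_ad=0, seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_fits():
    """Twenty seeded well-specified cohorts with their fitted models
    (shared by the recovery and calibration checks)."""
    out = []
    for seed in range(20):
        cfg = wellspec_config(seed)
        table = nv.generate_cohort(cfg)
        prep, _, _ = nv.preprocess(table, nv.RunConfig())
        nd = prep.df[prep.df["group"] == "ND"]
        model = nv.fit_lms(nd["age"], nd["volume_mm3"], nd["sex"], nd["height"],
                           delta=2, method="segA", region="thalamus")
        out.append((cfg, nd, model))
    return out


@pytest.fixture(scope="session")
def small_pipeline_cohort():
    """Reduced full-structure cohort: 3 methods (one premerged), all six
    regions, 250 ND / 24 AD."""
    cfg = nv.default_config(seed=11)
    keep = {"segA", "segB", "segE"}
    cfg = dataclasses.replace(
        cfg,
        n_nd=250, n_ad=24,
        methods={m: d for m, d in cfg.methods.items() if m in keep},
        premerged_methods=frozenset({"segE"}),
    )
    return cfg, nv.generate_cohort(cfg)
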