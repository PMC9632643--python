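"""Shared fixtures: small synthetic cohorts and derived feature tables.

Session-scoped so the expensive simulations run once per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dysmetrix as dx
from dysmetrix import pipeline as pl
from dysmetrix import preprocess as pp
from dysmetrix import irregularity as irr
from dysmetrix import connectivity as conn

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort_20():
    """20 dysmetric / 20 control recordings under the default generator."""
    return dx.generate_cohort(20, 20, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def feature_df_20(cohort_20):
    """The 14-feature table of the 20/20 cohort."""
    return pl.feature_table(cohort_20)


@pytest.fixture(scope="session")
def extended_df_20(cohort_20):
    """Extra single-scale and coupling features of the 20/20 cohort
    (sample entropy, fluctuation dispersion entropy, Pearson correlation)
    on the 0.08-5 Hz band."""
    rows = []
    for rec in cohort_20:
        lo_l = pp.preprocess_channel(rec.left_x, rec.fs, pp.BAND_LOW)
        lo_r = pp.preprocess_channel(rec.right_x, rec.fs, pp.BAND_LOW)
        rows.append({
            "label": rec.label,
            "sampen": 0.5 * (irr.sample_entropy(lo_l)
                             + irr.sample_entropy(lo_r)),
            "fdispen": 0.5 * (irr.fluctuation_dispersion_entropy(lo_l)
                              + irr.fluctuation_dispersion_entropy(lo_r)),
            "corr": conn.linear_correlation(lo_l, lo_r),
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_152_features():
    """14-feature table of the full-size 72/80 synthetic cohort."""
    recs = dx.generate_cohort(72, 80, seed=5)
    return pl.feature_table(recs)


def assert_direction(df, name, higher_label, alpha=0.05):
    """Mann-Whitney check that `higher_label`'s group median is larger with
    p below alpha."""
    a = df.loc[df.label == "dysmetric", name].to_numpy()
    b = df.loc[df.label == "control", name].to_numpy()
    _, p = dx.mann_whitney_u(a, b)
    med_a, med_b = np.median(a), np.median(b)
    if higher_label == "dysmetric":
        assert med_a > med_b, f"{name}: expected dysmetric median higher"
    else:
        assert med_b > med_a, f"{name}: expected control median higher"
    assert p < alpha, f"{name}: p={p:.3g} not significant"
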