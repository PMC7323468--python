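"""Repeated-measures statistics: brute-force sums-of-squares oracle, Sidak
closed form, covariate adjustment, and the injected level pattern."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbarqmri import phantom
from lumbarqmri.roi import LEVELS, MUSCLES
from lumbarqmri.stats import (
    MuscleLevelANOVA,
    UnbalancedDataError,
    sidak_adjust,
    sidak_posthoc,
)


def brute_force_rm_anova(table: pd.DataFrame, metric: str) -> dict:
    """Textbook two-way within-subject ANOVA by explicit sums of squares,
    written with plain loops — independent of the fitting code."""
    subjects = sorted(table["subject"].unique())
    n, a, b = len(subjects), len(MUSCLES), len(LEVELS)
    y = np.zeros((n, a, b))
    for i, s in enumerate(subjects):
        for j, m in enumerate(MUSCLES):
            for k, l in enumerate(LEVELS):
                y[i, j, k] = table.query(
                    "subject == @s and muscle == @m and level == @l"
                )[metric].iloc[0]
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2
    ).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_abs = 0.0
    for i in range(n):
        for j in range(a):
            for k in range(b):
                ss_abs += (
                    y[i, j, k]
                    - m_sa[i, j]
                    - m_sb[i, k]
                    - m_ab[j, k]
                    + m_s[i]
                    + m_a[j]
                    + m_b[k]
                    - gm
                ) ** 2
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return {"muscle": f_a, "level": f_b, "muscle * level": f_ab}


def _random_table(n_subjects, seed, muscle_shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        base = rng.normal()
        for m in MUSCLES:
            for l in LEVELS:
                rows.append(
                    dict(
                        subject=s,
                        muscle=m,
                        level=l,
                        y=base
                        + rng.normal()
                        + (muscle_shift if m == "multifidus" else 0.0),
                    )
                )
    return pd.DataFrame(rows)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n_subjects", [4, 5])
def test_omnibus_f_matches_brute_force_oracle(n_subjects, seed):
    table = _random_table(n_subjects, seed, muscle_shift=0.8)
    res = MuscleLevelANOVA(table, "y").fit()
    oracle = brute_force_rm_anova(table, "y")
    for effect, f_oracle in oracle.items():
        assert res.effect(effect)["F"] == pytest.approx(f_oracle, abs=1e-8)


def test_sidak_closed_form():
    assert sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99**6, abs=1e-15)
    assert sidak_adjust(0.01, 6) == pytest.approx(0.05852, abs=5e-6)
    assert sidak_adjust(0.0, 6) == 0.0
    assert sidak_adjust(1.0, 6) == 1.0


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    p=st.floats(min_value=0.0, max_value=1.0),
    q=st.floats(min_value=0.0, max_value=1.0),
)
def test_sidak_monotone_and_bounded(p, q):
    lo, hi = min(p, q), max(p, q)
    assert sidak_adjust(lo, 6) <= sidak_adjust(hi, 6)
    assert sidak_adjust(p, 6) >= p
    assert sidak_adjust(p, 6) <= min(1.0, 6 * p) + 1e-12


def test_zero_variance_everywhere_reports_null_result():
    table = _random_table(4, 0)
    table["y"] = 5.0
    res = MuscleLevelANOVA(table, "y").fit()
    assert np.isnan(res.effects["F"]).all()
    assert (res.effects["p"] == 1.0).all()
    # post hoc exact ties -> p = 1
    assert (res.posthoc["p_raw"] == 1.0).all()
    assert not res.posthoc["significant"].any()


def test_posthoc_exact_separation_gets_p_zero():
    table = _random_table(4, 0)
    table["y"] = np.where(table["muscle"] == "multifidus", 2.0, 1.0)
    ph = sidak_posthoc(table, "y")
    assert (ph["p_raw"] == 0.0).all()
    assert (ph["mean_diff"] == 1.0).all()


def test_incomplete_subjects_dropped_and_reported():
    table = _random_table(5, 3)
    table = table.drop(table[(table.subject == 4) & (table.level == "L2")].index[:1])
    model = MuscleLevelANOVA(table, "y")
    assert model.dropped_subjects == [4]
    assert model.n_subjects == 4
    tiny = _random_table(3, 0)
    tiny = tiny.drop(tiny[tiny.subject == 2].index[:1])
    with pytest.raises(UnbalancedDataError):
        MuscleLevelANOVA(tiny, "y")


def test_default_phantom_table_shows_the_level_pattern():
    """The generator injects the published pattern: all omnibus effects
    significant for volume; multifidus larger at L5/S1, smaller at L1–L4."""
    cfg = phantom.default_config(n_subjects=10, between_subject_cv=0.10, seed=0)
    table = phantom.simulate_level_table(cfg)
    res = MuscleLevelANOVA(table, "volume_ml").fit()
    assert all(p < 0.05 for p in res.effects["p"])
    ph = res.posthoc.set_index("level")
    for lv in ("L1", "L2", "L3", "L4"):
        assert ph.loc[lv, "mean_diff"] < 0 and ph.loc[lv, "significant"]
    for lv in ("L5", "S1"):
        assert ph.loc[lv, "mean_diff"] > 0 and ph.loc[lv, "significant"]


def test_constant_covariate_changes_nothing():
    table = _random_table(6, 1, muscle_shift=0.5)
    table["fat_fraction"] = 0.2
    model = MuscleLevelANOVA(table, "y")
    base = model.fit()
    adj = model.fit_ancova(table, "fat_fraction")
    for e in ("muscle", "level", "muscle * level"):
        assert adj.effect(e)["F"] == pytest.approx(base.effect(e)["F"], rel=1e-12)
    assert adj.matches_unadjusted


def test_uncorrelated_covariate_leaves_f_nearly_unchanged():
    rng = np.random.default_rng(8)
    table = _random_table(12, 2, muscle_shift=1.0)
    table["fat_fraction"] = rng.normal(size=len(table))
    model = MuscleLevelANOVA(table, "y")
    base = model.fit()
    adj = model.fit_ancova(table, "fat_fraction")
    for e in ("muscle", "level", "muscle * level"):
        assert adj.effect(e)["F"] == pytest.approx(base.effect(e)["F"], rel=0.05)


def test_phantom_ancova_keeps_the_significance_pattern():
    cfg = phantom.default_config(n_subjects=10, between_subject_cv=0.10, seed=1)
    table = phantom.simulate_level_table(cfg)
    model = MuscleLevelANOVA(table, "volume_ml")
    adj = model.fit_ancova(table, "fat_fraction")
    assert adj.matches_unadjusted
    assert all(p < 0.05 for p in adj.effects["p"])


def test_summary_is_readable():
    table = _random_table(5, 4, muscle_shift=0.5)
    res = MuscleLevelANOVA(table, "y").fit()
    text = res.summary()
    assert "muscle * level" in text
    assert "Sidak" in text
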