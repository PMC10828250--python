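"""Cohort simulation, the three-individual exemplars, and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from agevar import (
    CohortError,
    CohortSample,
    Design,
    ScenarioSpec,
    SpecError,
    analytic_moments,
    bin_cohort,
    draw_individuals,
    exemplar_cohort,
    read_cohort,
    simulate_cross_sectional,
    simulate_longitudinal,
    write_cohort,
)

from conftest import spec_for


# ---------------------------------------------------------------- drawing

def test_zero_variance_draws_are_all_at_the_mean():
    draws = draw_individuals(spec_for("S1", baseline_sd=0.0), 3, seed=0)
    assert [d.baseline for d in draws] == [80.0, 80.0, 80.0]
    assert [d.subject_id for d in draws] == ["s0001", "s0002", "s0003"]


def test_draws_are_deterministic_given_seed():
    spec = spec_for("S3")
    a = draw_individuals(spec, 50, seed=123)
    b = draw_individuals(spec, 50, seed=123)
    assert a == b
    c = draw_individuals(spec, 50, seed=124)
    assert a != c


def test_draw_mean_obeys_clt_bound():
    draws = draw_individuals(spec_for("S1", baseline_sd=10.0), 100_000, seed=7)
    mean = np.mean([d.baseline for d in draws])
    assert abs(mean - 80.0) < 3 * 10.0 / np.sqrt(100_000)


def test_degenerate_truncation_is_a_configuration_error():
    # baseline floor for S2 is d*span = 50; a mean far below it cannot be
    # sampled by rejection
    with pytest.raises(SpecError, match="degenerate truncation"):
        draw_individuals(spec_for("S2", baseline_mean=1.0, baseline_sd=1.0,
                                  absolute_rate=1.0), 10, seed=0)
    with pytest.raises(SpecError, match="floor"):
        draw_individuals(spec_for("S4", baseline_mean=10.0, baseline_sd=0.0,
                                  convergence_floor=20.0), 10, seed=0)


# ------------------------------------------------------------- simulation

def test_noise_free_cross_sectional_values_follow_the_trajectory():
    spec = spec_for("S1", baseline_mean=100.0, baseline_sd=0.0)
    sample = simulate_cross_sectional(spec, 200, seed=5)
    expected = 100.0 * (1.0 - 0.01 * (sample.data["age"] - 30.0))
    assert sample.data["value"].to_numpy() == pytest.approx(expected.to_numpy())
    assert sample.design is Design.CROSS_SECTIONAL
    assert sample.n_subjects == 200


def test_single_subject_cohort():
    sample = simulate_cross_sectional(spec_for("S1"), 1, seed=0)
    assert len(sample) == 1


def test_same_seed_reproduces_the_cohort_exactly():
    spec = spec_for("S3", noise_sd=3.0)
    a = simulate_cross_sectional(spec, 500, seed=9)
    b = simulate_cross_sectional(spec, 500, seed=9)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_noise_does_not_perturb_which_individuals_are_drawn():
    """Sub-streams per stage: switching noise on changes values only."""
    quiet = simulate_cross_sectional(spec_for("S1"), 100, seed=4)
    noisy = simulate_cross_sectional(spec_for("S1", noise_sd=5.0), 100, seed=4)
    assert quiet.data["age"].to_numpy() == pytest.approx(noisy.data["age"].to_numpy())
    assert not np.allclose(quiet.data["value"], noisy.data["value"])


def test_s2_binned_sd_is_flat_at_sigma_b(default_edges):
    """Constant absolute loss leaves the absolute spread untouched in every
    age bin (up to sampling error and the within-bin age gradient)."""
    spec = spec_for("S2")
    sample = simulate_cross_sectional(spec, 10_000, seed=21)
    curve = bin_cohort(sample, default_edges)
    target = analytic_moments(spec, 30.0).sd
    for b in curve.bins:
        # within-bin decline of the mean adds d^2 * width^2 / 12 variance
        expect = np.sqrt(target ** 2 + 1.0 * 10.0 ** 2 / 12.0)
        assert b.sd == pytest.approx(expect, rel=0.08)


def test_binned_variance_adds_measurement_noise_quadratically():
    """Observed per-bin variance ~ population variance + noise variance
    (+ the within-bin age-gradient term); the framework classifies the
    observed dispersion."""
    eps = 8.0
    spec = spec_for("S2", noise_sd=eps)
    sample = simulate_cross_sectional(spec, 40_000, seed=3)
    edges = np.arange(30.0, 81.0, 5.0)
    curve = bin_cohort(sample, edges)
    base_var = analytic_moments(spec, 30.0).sd ** 2
    expect = base_var + eps ** 2 + 1.0 * 5.0 ** 2 / 12.0
    for b in curve.bins:
        assert b.sd ** 2 == pytest.approx(expect, rel=0.10)


def test_longitudinal_constant_absolute_loss_between_visits():
    spec = spec_for("S2", baseline_mean=90.0, baseline_sd=0.0)
    sample = simulate_longitudinal(spec, 1, ages=list(range(30, 81)), seed=0)
    diffs = np.diff(sample.data.sort_values("age")["value"].to_numpy())
    assert diffs == pytest.approx(np.full(50, -1.0))
    assert sample.design is Design.LONGITUDINAL


def test_longitudinal_every_subject_at_every_age():
    sample = simulate_longitudinal(spec_for("S1", noise_sd=1.0), 7,
                                   ages=[30, 50, 70], seed=2)
    assert len(sample) == 21
    per_subject = sample.data.groupby("subject_id")["age"].apply(sorted)
    assert all(ages == [30.0, 50.0, 70.0] for ages in per_subject)
    again = simulate_longitudinal(spec_for("S1", noise_sd=1.0), 7,
                                  ages=[30, 50, 70], seed=2)
    pd.testing.assert_frame_equal(sample.data, again.data)


def test_longitudinal_requires_increasing_ages():
    with pytest.raises(SpecError):
        simulate_longitudinal(spec_for("S1"), 3, ages=[50.0], seed=0)
    with pytest.raises(SpecError):
        simulate_longitudinal(spec_for("S1"), 3, ages=[50.0, 40.0], seed=0)


# -------------------------------------------------------------- exemplars

def _values_at(sample, age):
    df = sample.data
    return df[df["age"] == age].sort_values("subject_id")["value"].to_numpy()


def test_exemplar_s1_endpoint_values():
    sample = exemplar_cohort("S1")
    assert _values_at(sample, 30.0) == pytest.approx([100.0, 80.0, 60.0])
    assert _values_at(sample, 80.0) == pytest.approx([50.0, 40.0, 30.0])


def test_exemplar_s2_sd_constant_at_every_age():
    sample = exemplar_cohort("S2")
    sds = sample.data.groupby("age")["value"].std(ddof=1)
    assert sds.to_numpy() == pytest.approx(np.full(51, 20.0))


def test_exemplar_s4_endpoint_values():
    assert _values_at(exemplar_cohort("S4"), 80.0) == pytest.approx(
        [36.0, 32.0, 28.0])


def test_exemplar_s3_spread_grows():
    sample = exemplar_cohort("S3")
    v30, v80 = _values_at(sample, 30.0), _values_at(sample, 80.0)
    assert v80.std(ddof=1) > v30.std(ddof=1)
    assert np.all(v80 >= 0)


# ----------------------------------------------------------------- file IO

def test_csv_round_trip_is_exact(tmp_path):
    sample = simulate_cross_sectional(spec_for("S3", noise_sd=2.0), 200, seed=8)
    path = tmp_path / "cohort.csv"
    write_cohort(sample, path)
    back = read_cohort(path)
    assert back.design is Design.CROSS_SECTIONAL
    pd.testing.assert_frame_equal(
        back.data.reset_index(drop=True), sample.data.reset_index(drop=True))


def test_longitudinal_design_inferred_on_read(tmp_path):
    sample = simulate_longitudinal(spec_for("S1"), 4, ages=[30, 60], seed=0)
    path = tmp_path / "long.csv"
    write_cohort(sample, path)
    assert read_cohort(path).design is Design.LONGITUDINAL


@pytest.mark.parametrize("body, match", [
    ("", "empty"),
    ("subject_id,age,value\n", "empty cohort"),
    ("id,age,value\ns1,40,10\n", "header"),
    ("subject_id,age,value\ns1,forty,10\n", "line 2"),
    ("subject_id,age,value\ns1,-4,10\n", "line 2"),
    ("subject_id,age,value\ns1,40,10\ns1,40,11\n", "line 3"),
    ("subject_id,age,value\ns1,40\n", "line 2"),
])
def test_read_cohort_parse_errors(tmp_path, body, match):
    path = tmp_path / "bad.csv"
    path.write_text(body)
    with pytest.raises(CohortError, match=match):
        read_cohort(path)


def test_mixed_multiplicity_is_rejected(tmp_path):
    path = tmp_path / "mixed.csv"
    path.write_text("subject_id,age,value\n"
                    "s1,40,10\ns1,50,9\ns2,45,11\n")
    with pytest.raises(CohortError, match="mixed"):
        read_cohort(path)


def test_cohort_sample_validates_columns_and_values():
    with pytest.raises(CohortError, match="columns"):
        CohortSample(pd.DataFrame({"a": [1]}), Design.CROSS_SECTIONAL)
    df = pd.DataFrame({"subject_id": ["a"], "age": [40.0], "value": [np.nan]})
    with pytest.raises(CohortError, match="finite"):
        CohortSample(df, Design.CROSS_SECTIONAL)
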