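"""Synthetic cohort generator: determinism, calibration, structure."""

import dataclasses

import numpy as np
import pytest

from neogrowth.cumulative import estimate_cumulative, subsample_daily
from neogrowth.simulate import (
    AA_KNOTS,
    CohortSpec,
    DeltaZGenerator,
    KnotDistribution,
    generate_cohort,
    generate_daily_trajectories,
    generate_growth,
    solve_knot_correlation,
)


def test_correlation_solver_roundtrip(rng):
    sds = (0.7, 0.77, 0.9, 1.0)
    rho = solve_knot_correlation(sds, 8.3)
    w = np.array([1.5, 3.0, 5.5, 4.0])
    ws = w * np.array(sds)
    var = (1 - rho) * np.sum(ws**2) + rho * np.sum(ws) ** 2
    assert np.sqrt(var) == pytest.approx(8.3)
    with pytest.raises(ValueError, match="unreachable"):
        solve_knot_correlation(sds, 100.0)


def test_zero_sd_zero_noise_reproduces_knot_means(rng):
    knots = KnotDistribution(
        means=(1.1, 2.0, 2.9, 3.2), sds=(0, 0, 0, 0), daily_noise_sd=0.0, correlation=0.0
    )
    traj = generate_daily_trajectories(knots, 5, rng)
    assert traj.shape == (5, 14)
    for row in traj:
        assert row.sum() == pytest.approx(36.4)
        est = estimate_cumulative(subsample_daily(row))
        assert est == pytest.approx(row.sum())  # noiseless => estimator exact


def test_noiseless_trajectories_are_piecewise_linear(rng):
    knots = dataclasses.replace(AA_KNOTS, daily_noise_sd=0.0)
    traj = generate_daily_trajectories(knots, 50, rng)
    days = np.arange(1, 15)
    for row in traj:
        interp = np.interp(days, [1, 3, 7, 14], row[[0, 2, 6, 13]])
        assert np.allclose(row, interp)


def test_trajectory_determinism():
    a = generate_daily_trajectories(AA_KNOTS, 20, np.random.default_rng(9))
    b = generate_daily_trajectories(AA_KNOTS, 20, np.random.default_rng(9))
    assert np.array_equal(a, b)


def test_cumulative_calibration_recovered():
    """Large-n cumulative mean/SD match the configured 37.0 +/- 8.3 g/kg."""
    traj = generate_daily_trajectories(AA_KNOTS, 20000, np.random.default_rng(3))
    cums = traj.sum(axis=1)
    assert cums.mean() == pytest.approx(37.0, abs=3 * 8.3 / np.sqrt(20000) + 0.15)
    assert cums.std() == pytest.approx(8.3, rel=0.05)
    assert (traj >= 0).all()


def test_growth_marginals(rng):
    spec = CohortSpec()
    n = 100_000
    tert = np.full(n, 2.0)
    ff = np.full(n, 11.7)
    zb, z36 = generate_growth(n, rng, spec, tert, ff)
    assert zb.mean() == pytest.approx(-0.17, abs=3 * 0.88 / np.sqrt(n) + 0.005)
    assert zb.std() == pytest.approx(0.88, rel=0.02)
    # at the covariate means the configured change model gives -0.80
    assert (z36 - zb).mean() == pytest.approx(-0.80, abs=0.01)


def test_zero_noise_zero_effects_constant_delta(rng):
    spec = CohortSpec(
        delta_z=DeltaZGenerator(intercept=-0.8, tertile_effect=0, full_feed_day_effect=0, noise_sd=0)
    )
    zb, z36 = generate_growth(500, rng, spec, np.ones(500), np.ones(500))
    assert np.allclose(z36 - zb, -0.8)


def test_spec_validation():
    with pytest.raises(ValueError, match="ga_counts"):
        CohortSpec(n_infants=100, ga_counts=((30, 10), (31, 10), (32, 10), (33, 10)))
    with pytest.raises(ValueError, match="p_male"):
        CohortSpec(p_male=1.5)


def test_spec_json_roundtrip(tmp_path):
    spec = CohortSpec(seed=11)
    path = tmp_path / "spec.json"
    spec.to_json(path)
    assert CohortSpec.from_json(path) == spec


def test_cohort_ga_counts_exact(default_cohort):
    weeks = [r.ga_weeks for r in default_cohort.records]
    assert [weeks.count(g) for g in (30, 31, 32, 33)] == [64, 68, 76, 68]
    assert len(default_cohort.records) == 276
    assert len(default_cohort.questionnaires) == 25 * 2


def test_cohort_determinism():
    a = generate_cohort(CohortSpec(n_infants=40, n_units=4,
                                   ga_counts=((30, 10), (31, 10), (32, 10), (33, 10)), seed=5))
    b = generate_cohort(CohortSpec(n_infants=40, n_units=4,
                                   ga_counts=((30, 10), (31, 10), (32, 10), (33, 10)), seed=5))
    assert a.trajectories.equals(b.trajectories)
    assert a.growth.equals(b.growth)
    assert a.records == b.records


def test_sparse_observations_are_exact_subsample(small_cohort):
    obs = small_cohort.sparse_observations("aa")
    wide = small_cohort.trajectories.pivot(index="infant_id", columns="dol", values="aa_g_kg_d")
    for iid, o in obs.items():
        assert o.values == tuple(wide.loc[iid, [1, 3, 7, 14]])


def test_practice_probability_one_forces_flag():
    spec = CohortSpec(
        n_infants=40, n_units=4, ga_counts=((30, 10), (31, 10), (32, 10), (33, 10)),
        p_pn_dol1=1.0, p_cvl=1.0, seed=2,
    )
    cohort = generate_cohort(spec)
    assert all(r.cvl_dol1 for r in cohort.records)
    assert all(r.pn_dol1 for r in cohort.records)


def test_roundtrip_z_through_reference(small_cohort):
    from neogrowth.growth import default_reference

    ref = default_reference()
    for r, (_, g) in zip(small_cohort.records, small_cohort.growth.iterrows()):
        z = ref.zscore(r.birth_weight_g, r.sex, r.ga_days, "weight")
        assert z == pytest.approx(g["z_birth"], abs=1e-9)


def test_delta_generated_from_fitted_model(small_cohort):
    """The generated change equals the configured linear model plus noise."""
    g = small_cohort.growth
    dz = small_cohort.spec.delta_z
    resid = (
        g["delta_z"]
        - dz.intercept
        - dz.tertile_effect * g["tertile_aa"]
        - dz.full_feed_day_effect * g["full_feed_dol"]
    )
    assert abs(resid.mean()) < 4 * dz.noise_sd / np.sqrt(len(g))
    assert resid.std() == pytest.approx(dz.noise_sd, rel=0.2)
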