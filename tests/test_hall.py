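"""Energy-balance weight model: fixed point, oracles, channel isolation."""

import numpy as np
import pytest

import labelsim as ls
from labelsim.hall import body_fat_fraction

from conftest import weighted_mean


def _delta(cohort, scenario="main_canada"):
    d = ls.scenario_deltas(cohort, ls.get_scenario(scenario))
    return d["d_total_kcal"].to_numpy(), d["d_sodium_mg"].to_numpy()


def test_zero_perturbation_is_a_fixed_point(state_small, params):
    traj = ls.simulate(state_small, params)
    assert np.abs(traj.delta_weight).max() < 0.01
    assert not traj.metadata["clamped"]


def test_body_fat_regression_sex_and_range(reference_adult):
    """Female fat exceeds male at equal age/BMI; reference fat is physiologic."""
    f = body_fat_fraction(np.array([40.0]), np.array([True]), np.array([28.34]))
    m = body_fat_fraction(np.array([40.0]), np.array([False]), np.array([28.34]))
    assert f > m
    state = ls.init_state(reference_adult)
    frac = state.F[0] / 72.38
    assert 0.15 < frac < 0.40


def test_init_rejects_nonphysiologic_records(reference_adult):
    skeletal = reference_adult.copy()
    skeletal.loc[0, ["sex", "age", "bmi"]] = ["male", 20, 14.5]
    skeletal.loc[0, "weight"] = 14.5 * skeletal.loc[0, "height"] ** 2
    with pytest.raises(ValueError, match="person_id"):
        ls.init_state(skeletal)
    with pytest.raises(ValueError, match="pal"):
        ls.init_state(reference_adult, pal=1.05)


def test_reference_adult_five_year_weight_change(reference_adult):
    """A mean Mexican adult under the mean caloric change loses ~1.7 kg."""
    state = ls.init_state(reference_adult)
    traj = ls.simulate(state, delta=(-36.8, 0.0))
    assert -1.8 <= traj.delta_weight[0, -1] <= -1.6


def test_step_halving_agreement(state_small, params, cohort_small):
    d_kcal, d_na = _delta(cohort_small)
    sub = slice(0, 20)
    st20 = ls.init_state(cohort_small.iloc[sub], params)
    t1 = ls.simulate(st20, params, (d_kcal[sub], d_na[sub]), dt_days=1.0)
    t2 = ls.simulate(st20, params, (d_kcal[sub], d_na[sub]), dt_days=0.5)
    assert np.abs(t1.weight[:, -1] - t2.weight[:, -1]).max() < 1e-3


def test_rk4_matches_fine_step_euler(cohort_small, params):
    """4th-order at dt=1 day agrees with 1st-order at dt=0.01 on 20 adults."""
    sub = cohort_small.iloc[:20]
    st = ls.init_state(sub, params)
    d_kcal, d_na = _delta(sub)
    rk = ls.simulate(st, params, (d_kcal, d_na), dt_days=1.0, method="rk4")
    eu = ls.simulate(st, params, (d_kcal, d_na), dt_days=0.01, method="euler")
    assert np.abs(rk.weight[:, -1] - eu.weight[:, -1]).max() < 5e-3


def test_monotone_dose_response(reference_adult, params):
    """More negative intake change gives strictly more weight loss."""
    clones = reference_adult.loc[reference_adult.index.repeat(11)].reset_index(drop=True)
    clones["person_id"] = np.arange(11)
    state = ls.init_state(clones, params)
    deltas = -10.0 * np.arange(11)
    traj = ls.simulate(state, params, (deltas, np.zeros(11)))
    final = traj.delta_weight[:, -1]
    assert final[0] == pytest.approx(0.0, abs=1e-9)
    assert (np.diff(final) < 0).all()


def test_sodium_channel_isolation(state_small, params):
    """Sodium-only perturbation moves fluid and weight, never fat or lean."""
    n = len(state_small)
    traj = ls.simulate(state_small, params, (np.zeros(n), np.full(n, -500.0)))
    base = ls.simulate(state_small, params)
    np.testing.assert_allclose(traj.fat, base.fat, atol=1e-12)
    np.testing.assert_allclose(traj.lean, base.lean, atol=1e-12)
    assert (traj.ecf[:, -1] < base.ecf[:, -1]).all()
    assert (traj.delta_weight[:, -1] < 0).all()


def test_weight_loss_monotone_in_time_and_bounded(reference_adult, params):
    state = ls.init_state(reference_adult, params)
    traj = ls.simulate(state, params, (-36.8, 0.0), horizon_days=3650)
    dw = traj.delta_weight[0]
    assert (np.diff(dw) < 0).all()
    plateau = ls.steady_state_weight_change(state, params, (-36.8, 0.0))[0]
    assert dw[-1] > 2.0 * plateau  # bounded below


def test_energy_accounting_closes(state_small, params, cohort_small):
    """Tissue energy change equals the integrated tissue-directed balance."""
    d = _delta(cohort_small)
    traj = ls.simulate(state_small, params, d)
    stored = params.rho_F * (traj.fat[:, -1] - traj.fat[:, 0]) + params.rho_L * (
        traj.lean[:, -1] - traj.lean[:, 0]
    )
    integral = traj.metadata["tissue_energy_integral_kcal"]
    np.testing.assert_allclose(stored, integral, rtol=1e-6, atol=1e-6)


def test_steady_state_oracle(reference_adult, params):
    state = ls.init_state(reference_adult, params)
    assert ls.steady_state_weight_change(state, params, (0.0, 0.0))[0] == 0.0
    # epsilon follows its defining formula and is physiologically plausible
    p = params.forbes_C / (params.forbes_C + state.F[0])
    q = (p / params.rho_L) / (p / params.rho_L + (1 - p) / params.rho_F)
    eps = q * params.gamma_L + (1 - q) * params.gamma_F + state.delta_PA[0]
    cf = ls.steady_state_weight_change(state, params, (-36.8, 0.0))[0]
    assert cf == pytest.approx((1 - params.beta_TEF - params.beta_AT) * -36.8 / eps)
    assert 12.0 < eps < 30.0
    # a long-horizon integration approaches the closed form within 10%
    traj = ls.simulate(state, params, (-36.8, 0.0), horizon_days=3650)
    assert traj.delta_weight[0, -1] == pytest.approx(cf, rel=0.10)


def test_extreme_deficit_clamps_instead_of_crashing(reference_adult, params):
    state = ls.init_state(reference_adult, params)
    traj = ls.simulate(state, params, (-2100.0, 0.0))
    assert traj.metadata["clamped"]
    assert 0 in traj.metadata["clamped_person_ids"]
    assert np.isfinite(traj.weight).all()
    assert (traj.fat >= 0).all() and (traj.lean >= 0).all()


def test_solver_preconditions(state_small, params):
    with pytest.raises(ValueError, match="dt_days"):
        ls.simulate(state_small, params, dt_days=8.0)
    with pytest.raises(ValueError, match="multiple of 365"):
        ls.simulate(state_small, params, horizon_days=1000)
    with pytest.raises(ValueError, match="whole number"):
        ls.simulate(state_small, params, dt_days=0.3)
    with pytest.raises(ValueError, match="method"):
        ls.simulate(state_small, params, method="rk2")


def test_trajectory_shape_and_bmi_identity(cohort_small, state_small, params):
    traj = ls.simulate(state_small, params, _delta(cohort_small))
    assert traj.weight.shape == (len(cohort_small), 6)
    np.testing.assert_allclose(
        traj.bmi, traj.weight / state_small.height[:, None] ** 2, rtol=1e-12
    )
    long = traj.to_frame()
    assert len(long) == 6 * len(cohort_small)
    assert set(long.columns) == {"person_id", "year", "weight", "bmi"}


def test_parameter_validation():
    with pytest.raises(ValueError, match="strictly positive"):
        ls.HallParameters(rho_F=-1.0)
    with pytest.raises(ValueError, match="beta_TEF"):
        ls.HallParameters(beta_TEF=0.6, beta_AT=0.5)
    # Forbes constant defaults to 10.4 kg scaled by the density ratio
    p = ls.HallParameters()
    assert p.forbes_C == pytest.approx(10.4 * p.rho_L / p.rho_F)
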