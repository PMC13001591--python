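"""Penalized quasi-Poisson GAM fitting, GCV, smooth tests, prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import coccitrend as ct


def _nb(rng, mean, phi):
    if phi == 1.0:
        return rng.poisson(mean)
    return rng.negative_binomial(mean / (phi - 1.0), 1.0 / phi)


def _units(seed=0, rate=4.0, phi=3.0, n_per_year=6, years=(1993, 2023), shape=None, effort=50.0):
    rng = np.random.default_rng(seed)
    yrs = np.repeat(np.arange(years[0], years[1] + 1), n_per_year)
    log_r = np.log(rate) + (shape(yrs) if shape else np.zeros(len(yrs)))
    mu = np.exp(log_r) * effort
    return pd.DataFrame(
        {"year": yrs, "captures": np.asarray(_nb(rng, mu, phi), float), "effort": effort}
    )


def test_constant_rate_recovered_at_standard_effort():
    # oracle: intercept-only quasi-Poisson GLM, intercept = log(sum y / sum effort)
    units = _units(seed=1, rate=4.0, phi=1.0, n_per_year=40)
    fit = ct.fit_gam(units)
    glm_rate = units["captures"].sum() / units["effort"].sum()
    pred = ct.predict_standardized(fit, np.arange(1993, 2024), standard_effort=50)
    within = np.abs(np.log(pred["fit"]) - np.log(50 * 4.0)) <= 2 * pred["se_link"]
    assert within.all()
    # and the fitted level matches the closed-form GLM rate closely
    assert np.median(pred["fit"]) == pytest.approx(50 * glm_rate, rel=0.02)


def test_large_sp_limit_equals_loglinear_glm():
    # oracle: unpenalized GLM with linear year term (statsmodels)
    import statsmodels.api as sm

    units = _units(seed=42, rate=2.0, phi=1.0, shape=lambda y: 0.01 * (y - 2000))
    fit = ct.fit_gam(units, ct.GAMConfig(sp=1e10))
    years = np.arange(1993, 2024, dtype=float)
    glm = sm.GLM(
        units["captures"], sm.add_constant(units["year"].astype(float)),
        family=sm.families.Poisson(), offset=np.log(units["effort"]),
    ).fit()
    link_glm = glm.params.iloc[0] + glm.params.iloc[1] * years
    pred = ct.predict_standardized(fit, years, standard_effort=1.0)
    np.testing.assert_allclose(np.log(pred["fit"]), link_glm, atol=1e-4)
    assert fit.edf_by_term["s(year)"] == pytest.approx(1.0, abs=0.05)


def test_dispersion_recovered_for_poisson_data():
    units = _units(seed=2, rate=5.0, phi=1.0, n_per_year=80)  # n = 2480
    fit = ct.fit_gam(units)
    assert fit.dispersion == pytest.approx(1.0, abs=0.2)


def test_edf_monotone_in_sp_and_bounded():
    units = _units(seed=3, shape=lambda y: 0.4 * np.sin((y - 1993) / 4))
    edfs = [
        ct.fit_gam(units, ct.GAMConfig(sp=sp)).edf_by_term["s(year)"]
        for sp in (0.01, 0.5, 10.0, 1e4, 1e8)
    ]
    assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
    assert all(1.0 - 1e-6 <= e <= 4.0 + 1e-6 for e in edfs)  # k - 1 = 4


def test_offset_rescaling_shifts_intercept_only():
    units = _units(seed=4, shape=lambda y: 0.2 * np.cos((y - 1993) / 5))
    c = 3.7
    f1 = ct.fit_gam(units)
    f2 = ct.fit_gam(units.assign(effort=units["effort"] * c))
    assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(c), abs=1e-8)
    np.testing.assert_allclose(f1.beta[1:], f2.beta[1:], atol=1e-8)
    # fitted per-trap rates at the original efforts are unchanged
    p1 = ct.predict_standardized(f1, [2000, 2010], standard_effort=50)
    p2 = ct.predict_standardized(f2, [2000, 2010], standard_effort=50)
    np.testing.assert_allclose(p1["fit"] / p2["fit"], c, rtol=1e-8)


def test_gcv_is_permutation_invariant():
    units = _units(seed=5)
    shuffled = units.sample(frac=1.0, random_state=6).reset_index(drop=True)
    assert ct.fit_gam(units).gcv == pytest.approx(ct.fit_gam(shuffled).gcv, rel=1e-10)


def test_zero_effort_units_dropped_and_counted():
    units = _units(seed=7)
    units.loc[:4, "effort"] = 0.0
    fit = ct.fit_gam(units)
    assert fit.n_dropped_zero_effort == 5
    assert fit.n == len(units) - 5
    with pytest.raises(ct.GAMError):
        ct.fit_gam(units.iloc[:9])


def test_nonconvergence_raises_with_trace():
    units = _units(seed=8)
    with pytest.raises(ct.ConvergenceError) as exc:
        ct.fit_gam(units, ct.GAMConfig(max_iter=1, tol=1e-16))
    assert len(exc.value.trace) == 1


def test_doubling_dispersion_halves_smooth_F():
    units = _units(seed=9, shape=lambda y: 0.3 * np.sin((y - 1993) / 4))
    fit = ct.fit_gam(units)
    t1 = ct.smooth_significance(fit)
    inflated = dataclasses.replace(fit, cov=2.0 * fit.cov, dispersion=2.0 * fit.dispersion)
    t2 = ct.smooth_significance(inflated)
    assert t2.F == pytest.approx(t1.F / 2.0, rel=1e-9)


def test_prediction_offset_arithmetic():
    units = _units(seed=10)
    fit = ct.fit_gam(units)
    years = [1995, 2005, 2015]
    p50 = ct.predict_standardized(fit, years, standard_effort=50)
    p100 = ct.predict_standardized(fit, years, standard_effort=100)
    np.testing.assert_allclose(p100["fit"], 2.0 * p50["fit"], rtol=1e-12)
    # response-scale ribbon is the monotone transform of link +/- 1 SE
    link = np.log(p50["fit"])
    np.testing.assert_allclose(p50["lower"], np.exp(link - p50["se_link"]), rtol=1e-12)
    np.testing.assert_allclose(p50["upper"], np.exp(link + p50["se_link"]), rtol=1e-12)
    assert (p50["lower"] < p50["fit"]).all() and (p50["fit"] < p50["upper"]).all()
    with pytest.raises(ct.GAMError, match="extrapolation"):
        ct.predict_standardized(fit, [2030])


def _two_habitat_units(seed, annual_amp=0.8):
    rng = np.random.default_rng(seed)
    years = np.arange(1993, 2024)
    frames = []
    for hab, amp in (("annual", annual_amp), ("forest", 0.0)):
        yrs = np.repeat(years, 6)
        shape = amp * np.sin((yrs - 1993) * 2 * np.pi / 20)
        mu = 3.0 * np.exp(shape) * 50.0
        frames.append(
            pd.DataFrame(
                {"year": yrs, "captures": _nb(rng, mu, 2.0).astype(float),
                 "effort": 50.0, "habitat": hab}
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_habitat_partition_detects_structure_where_present():
    """Strong nonlinear trajectory in annual habitat, flat forest: the annual
    smooth should be significant with larger F, the forest smooth not, in
    >= 90% of replicates."""
    ok = 0
    n_rep = 200
    for seed in range(n_rep):
        fit = ct.fit_gam(_two_habitat_units(seed), by_habitat=True)
        ta = ct.smooth_significance(fit, "s(year):annual")
        tf = ct.smooth_significance(fit, "s(year):forest")
        ok += ta.significant and (not tf.significant) and (ta.F > tf.F)
    assert ok / n_rep >= 0.90


def test_smooth_significance_null_calibration():
    rej = 0
    n_rep = 200
    for seed in range(n_rep):
        fit = ct.fit_gam(_units(seed=10_000 + seed))
        rej += ct.smooth_significance(fit).significant
    assert rej / n_rep <= 0.10


def test_superfluous_partition_increases_gcv():
    """On a habitat-homogeneous generator, splitting the smooth by habitat
    should worsen (raise) GCV in >= 70% of replicates."""
    worse = 0
    n_rep = 200
    for seed in range(n_rep):
        units = _two_habitat_units(seed, annual_amp=0.0)
        # both habitats share one mild trajectory: add it to both
        pooled = ct.fit_gam(units)
        parted = ct.fit_gam(units, by_habitat=True)
        worse += parted.gcv > pooled.gcv
    assert worse / n_rep >= 0.70
    assert ct.compare_gcv(pooled, pooled) == 0  # ties are reported as ties
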