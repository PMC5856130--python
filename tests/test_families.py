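"""Distribution family registry: densities, MLE fits, sampling."""

import math

import numpy as np
import pytest
from scipy import integrate

from popkld.families import (FAILURE_DEGENERATE, FAILURE_SUPPORT, ParamVector,
                             fit_mle, get_family, list_families, sample)

# representative, well-conditioned parameters per family (canonical order)
REP_PARAMS = {
    "normal": (100.0, 15.0),
    "lognormal": (4.9, 0.25),
    "gamma": (8.0, 18.0),
    "weibull": (3.5, 15.0),
    "logistic": (100.0, 9.0),
    "uniform": (60.0, 140.0),
    "student_t": (6.0, 100.0, 12.0),
    "rayleigh": (80.0,),
    "gev": (95.0, 20.0, 0.15),
}

ALL_FAMILIES = sorted(REP_PARAMS)


def test_registry_contains_the_expected_families():
    names = set(list_families())
    assert {"gev", "lognormal", "gamma"} <= names
    assert len(names) >= 9
    assert set(ALL_FAMILIES) <= names


@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_density_integrates_to_one_over_support(name):
    fam = get_family(name)
    params = REP_PARAMS[name]
    lo, hi = fam.support(params)
    total, _ = integrate.quad(lambda x: fam.pdf(x, params), lo, hi, limit=200)
    assert total == pytest.approx(1.0, abs=1e-3)


@pytest.mark.parametrize("name", ALL_FAMILIES)
def test_density_is_finite_and_positive_at_the_center(name):
    fam = get_family(name)
    params = REP_PARAMS[name]
    center = fam.location_like(params)
    val = float(fam.pdf(center, params))
    assert math.isfinite(val) and val > 0


def test_registry_is_extensible(monkeypatch):
    import popkld.families as fm
    fam = fm.DistributionFamily(
        name="_exp_test", param_names=("scale",), param_roles={"scale": "scale"},
        dist=__import__("scipy.stats", fromlist=["expon"]).expon,
        to_scipy=lambda p: (0.0, p[0]), from_scipy=lambda r: (r[1],),
        max_support=(0.0, np.inf), support_fn=lambda p: (0.0, np.inf),
        closed_form_mle=lambda x: (float(np.mean(x)),),
    )
    monkeypatch.setitem(fm.FAMILY_REGISTRY, "_exp_test", fam)
    x = fam.sample((3.0,), 500, seed=0)
    fit = fit_mle(x, "_exp_test")
    assert fit.converged
    assert fit.params.values[0] == pytest.approx(3.0, rel=0.15)


class TestFitMLE:
    def test_normal_closed_form(self):
        fit = fit_mle([0.0, 2.0], "normal")
        assert fit.converged
        assert fit.params.values == pytest.approx((1.0, 1.0))  # divisor-n sd

    def test_lognormal_rejects_nonpositive_values(self):
        fit = fit_mle([-1.0, 2.0, 3.0], "lognormal")
        assert not fit.converged
        assert fit.failure_reason == FAILURE_SUPPORT

    def test_gamma_fit_agrees_with_moment_matching_oracle(self):
        x = sample("gamma", (2.0, 3.0), 10_000, seed=42)
        fit = fit_mle(x, "gamma")
        assert fit.converged
        a_mm = np.mean(x) ** 2 / np.var(x)  # independent moment oracle
        assert fit.params.values[0] == pytest.approx(2.0, rel=0.05)
        assert fit.params.values[0] == pytest.approx(a_mm, rel=0.05)

    @pytest.mark.parametrize("name", ALL_FAMILIES)
    def test_constant_data_reports_degenerate_not_crash(self, name):
        fit = fit_mle([7.5] * 25, name)
        assert not fit.converged
        assert fit.failure_reason == FAILURE_DEGENERATE

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fit_mle([], "normal")

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError):
            fit_mle([1.0, np.inf], "normal")

    @pytest.mark.parametrize("name", ALL_FAMILIES)
    def test_fit_not_worse_than_moment_initialization(self, name):
        fam = get_family(name)
        x = fam.sample(REP_PARAMS[name], 2000, seed=3)
        fit = fam.fit(x)
        assert fit.converged
        if fam.initial_guess is not None:
            guess = fam.initial_guess(np.asarray(x))
            assert fit.log_likelihood >= fam.log_likelihood(x, guess) - 1e-9


@pytest.mark.parametrize("name", ALL_FAMILIES)
@pytest.mark.parametrize("seed", range(5))
def test_parameter_recovery_from_large_samples(name, seed):
    """MLE on 10^4 draws recovers the generating parameters.

    Tolerances: scale-like 10% relative, location-like 0.1 x scale absolute,
    shape-like 15% relative (tail parameters carry less information).
    """
    fam = get_family(name)
    true = REP_PARAMS[name]
    x = fam.sample(true, 10_000, seed=seed)
    fit = fam.fit(x)
    assert fit.converged
    scale_val = next((v for p, v in zip(fam.param_names, true)
                      if fam.param_roles[p] == "scale"), None)
    for pname, est, tv in zip(fam.param_names, fit.params.values, true):
        role = fam.param_roles[pname]
        if role == "scale":
            assert est == pytest.approx(tv, rel=0.10), pname
        elif role == "location":
            ref = scale_val if scale_val is not None else max(abs(tv), 1.0)
            assert abs(est - tv) <= 0.1 * ref, pname
        else:
            assert est == pytest.approx(tv, rel=0.15), pname


class TestSample:
    def test_zero_draws_gives_empty(self):
        assert sample("normal", (0.0, 1.0), 0, seed=1).size == 0

    def test_seeded_sampling_is_deterministic(self):
        a = sample("normal", (0.0, 1.0), 5, seed=7)
        b = sample("normal", (0.0, 1.0), 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_negative_gev_shape_has_hard_upper_bound(self):
        loc, scl, shape = 100.0, 10.0, -0.2
        x = sample("gev", (loc, scl, shape), 100_000, seed=9)
        upper = loc - scl / shape  # analytic endpoint for shape < 0
        assert x.max() <= upper
        lo, hi = get_family("gev").support((loc, scl, shape))
        assert hi == pytest.approx(upper)

    @pytest.mark.parametrize("name", ALL_FAMILIES)
    def test_samples_fall_inside_support(self, name):
        fam = get_family(name)
        params = REP_PARAMS[name]
        x = fam.sample(params, 5000, seed=2)
        lo, hi = fam.support(params)
        assert np.all(x >= lo) and np.all(x <= hi)

    def test_invalid_scale_names_the_parameter(self):
        with pytest.raises(ValueError, match="scale"):
            sample("normal", (0.0, -1.0), 5, seed=1)

    def test_param_vector_length_checked(self):
        with pytest.raises(ValueError):
            ParamVector("normal", (1.0,))
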