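import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetraped.lmm import FitResult, ModelError, ModelSpec, build_design, reml_fit
from tetraped.summary import (heritability, lrt, variance_proportions,
                              clone_mean_heritability, LRTResult, summary_report)


def fake_fit(components, traits=("y",), include_sca=True, m2ll=100.0,
             converged=True, n_obs=100):
    terms = ["additive", "line", "gxty"] + (["sca"] if include_sca else [])
    spec = ModelSpec(traits=traits, include_sca=include_sca)
    t = len(traits)
    vc = {k: np.atleast_2d(np.asarray(v, dtype=float))
          for k, v in components.items()}
    return FitResult(spec=spec, vc=vc, vc_se={k: np.zeros((t, t)) for k in vc},
                     minus2logl=m2ll, blue=None, blup={}, converged=converged,
                     iterations=1, boundary=False, n_obs=n_obs)


class TestHeritability:
    def test_worked_example(self):
        fit = fake_fit({"additive": 2.0, "line": 1.0, "gxty": 0.5,
                        "sca": 0.5, "residual": 1.0})
        h = heritability(fit, d_A=1.0)[0]
        assert h.h2 == pytest.approx(0.4)
        assert h.H2 == pytest.approx(0.7)

    def test_pure_additive_limit(self):
        fit = fake_fit({"additive": 3.0, "line": 0.0, "gxty": 0.0,
                        "sca": 0.0, "residual": 0.0})
        h = heritability(fit, d_A=1.0)[0]
        assert h.h2 == h.H2 == pytest.approx(1.0)

    def test_m1_omits_sca(self):
        fit = fake_fit({"additive": 2.0, "line": 1.0, "gxty": 0.5,
                        "residual": 1.0}, include_sca=False)
        h = heritability(fit, d_A=1.0)[0]
        assert h.h2 == pytest.approx(2.0 / 4.5)

    def test_d_a_scales_additive(self):
        fit = fake_fit({"additive": 2.0, "line": 1.0, "gxty": 0.5,
                        "sca": 0.5, "residual": 1.0})
        h = heritability(fit, d_A=1.25)[0]
        assert h.h2 == pytest.approx(2.5 / 5.5)

    def test_scale_invariance(self):
        comp = {"additive": 2.0, "line": 1.0, "gxty": 0.5, "sca": 0.5,
                "residual": 1.0}
        c = 7.3
        scaled = {k: v * c * c for k, v in comp.items()}
        h1 = heritability(fake_fit(comp), 1.1)[0]
        h2 = heritability(fake_fit(scaled), 1.1)[0]
        assert h2.h2 == pytest.approx(h1.h2, abs=1e-10)
        assert h2.H2 == pytest.approx(h1.H2, abs=1e-10)

    def test_negative_component_is_an_error(self):
        fit = fake_fit({"additive": -1.0, "line": 1.0, "gxty": 0.5,
                        "sca": 0.5, "residual": 1.0})
        with pytest.raises(ModelError):
            heritability(fit, 1.0)

    def test_clone_mean_heritability_exceeds_plot_level(self):
        fit = fake_fit({"additive": 2.0, "line": 0.5, "gxty": 1.0,
                        "sca": 0.5, "residual": 2.0})
        plot = heritability(fit, 1.0)[0]
        mean = clone_mean_heritability(fit, 1.0, n_plots=4, n_cells=2)[0]
        assert mean.h2 > plot.h2


class TestVarianceProportions:
    def test_equal_components(self):
        fit = fake_fit({k: 1.0 for k in
                        ("additive", "line", "gxty", "sca", "residual")})
        shares = variance_proportions(fit, 1.0)
        assert np.allclose(shares["share"], 0.2)

    def test_residual_only(self):
        fit = fake_fit({"additive": 0.0, "line": 0.0, "gxty": 0.0,
                        "sca": 0.0, "residual": 2.0})
        shares = variance_proportions(fit, 1.0).set_index("term")["share"]
        assert shares["residual"] == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 50.0), min_size=5, max_size=5),
           st.floats(0.9, 1.5))
    def test_shares_sum_to_one(self, vals, d_a):
        fit = fake_fit(dict(zip(("additive", "line", "gxty", "sca",
                                 "residual"), vals)))
        assert variance_proportions(fit, d_a)["share"].sum() == \
            pytest.approx(1.0, abs=1e-12)


class TestLRT:
    def test_chi_square_example(self):
        r = lrt(fake_fit({"additive": 1, "line": 1, "gxty": 1, "residual": 1},
                         include_sca=False, m2ll=100.0),
                fake_fit({"additive": 1, "line": 1, "gxty": 1, "sca": 1,
                          "residual": 1}, m2ll=90.0))
        assert r.stat == pytest.approx(10.0)
        assert r.df == 1
        # bivariate SCA block: three extra free parameters
        r2 = lrt(fake_fit({"additive": np.eye(2), "line": np.eye(2),
                           "gxty": np.eye(2), "residual": np.eye(2)},
                          traits=("a", "b"), include_sca=False, m2ll=100.0),
                 fake_fit({"additive": np.eye(2), "line": np.eye(2),
                           "gxty": np.eye(2), "sca": np.eye(2),
                           "residual": np.eye(2)},
                          traits=("a", "b"), m2ll=90.0))
        assert r2.df == 3
        assert r2.p == pytest.approx(0.018566, abs=1e-5)

    def test_identical_fits(self):
        a = fake_fit({"additive": 1, "line": 1, "gxty": 1, "residual": 1},
                     include_sca=False, m2ll=50.0)
        b = fake_fit({"additive": 1, "line": 1, "gxty": 1, "sca": 1,
                      "residual": 1}, m2ll=50.0)
        r = lrt(a, b)
        assert r.stat == 0.0
        assert r.p == pytest.approx(1.0)

    def test_non_nested_is_an_error(self):
        a = fake_fit({"additive": 1, "line": 1, "gxty": 1, "sca": 1,
                      "residual": 1})
        with pytest.raises(ModelError):
            lrt(a, a)

    def test_unconverged_is_an_error(self):
        a = fake_fit({"additive": 1, "line": 1, "gxty": 1, "residual": 1},
                     include_sca=False, converged=False)
        b = fake_fit({"additive": 1, "line": 1, "gxty": 1, "sca": 1,
                      "residual": 1})
        with pytest.raises(ModelError):
            lrt(a, b)


def test_h2_increase_with_sca_on_fitted_models(small_truth):
    ph, ped = small_truth.phenotypes, small_truth.pedigree
    f1 = reml_fit(build_design(ph, ped, ModelSpec(traits=("DMC",))))
    am2 = build_design(ph, ped, ModelSpec(traits=("DMC",), include_sca=True))
    f2 = reml_fit(am2)
    d_A = float(np.diagonal(am2.Aff).mean())
    h1 = heritability(f1, d_A)[0]
    h2 = heritability(f2, d_A)[0]
    if f2.vc["sca"][0, 0] > 1e-6:
        assert h2.H2 >= h1.H2 - 0.05
    rep = summary_report(f2, d_A)
    assert set(rep) >= {"model", "vc", "shares", "heritability"}
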