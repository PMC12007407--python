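import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tetraped.lmm import (ModelError, ModelSpec, build_design,
                          predict_breeding_values, reml_fit, solve_mme,
                          _System)
from tetraped.pedigree import Pedigree, PedigreeRecord


def one_way_data(g=6, n=4, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"G{i}" for i in range(g)]
    ped = Pedigree([PedigreeRecord(i) for i in ids])
    ge = rng.normal(0, 1.5, g)
    rows = [(cid, "T1", "2005", 10 + ge[i] + rng.normal(0, 1.0))
            for i, cid in enumerate(ids) for _ in range(n)]
    ph = pd.DataFrame(rows, columns=["line_id", "trial", "year", "y"])
    return ph, ped


def dense_v_m2ll(am, sig):
    """Independent dense-V evaluation of the REML deviance."""
    n = am.n_obs
    X = am.X.toarray()
    t, nc = am.n_traits, am.n_clones
    G = np.zeros((t * nc, t * nc))
    for term in am.spec.terms:
        if term in ("additive", "line", "sca"):
            K = am.clone_matrix(term)
            K = np.eye(nc) if K is None else K
            G += np.kron(sig[term], K)
    V = am.Z.toarray() @ G @ am.Z.T.toarray()
    tr, pl, cell = am.obs_trait, am.obs_plot, am.obs_cell
    if "gxty" in am.spec.terms:
        V = V + sig["gxty"][np.ix_(tr, tr)] * (cell[:, None] == cell[None, :])
    V = V + sig["residual"][np.ix_(tr, tr)] * (pl[:, None] == pl[None, :])
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    b = np.linalg.solve(XVX, X.T @ Vi @ am.y)
    r = am.y - X @ b
    return ((n - X.shape[1]) * np.log(2 * np.pi)
            + np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
            + r @ Vi @ r)


class TestBuildDesign:
    def test_hand_countable_incidence(self):
        ped = Pedigree([PedigreeRecord("c1"), PedigreeRecord("c2")])
        rows = [("c1", "T1", "2005", 1.0), ("c1", "T2", "2005", 2.0),
                ("c2", "T1", "2005", 3.0), ("c2", "T2", "2005", 4.0)]
        ph = pd.DataFrame(rows, columns=["line_id", "trial", "year", "y"])
        am = build_design(ph, ped, ModelSpec(traits=("y",), alpha=0.0))
        assert am.p_tot == 2                       # intercept + trial contrast
        assert len(am.cell_keys) == 4              # one G x T x Y cell per plot
        assert am.Z.shape == (4, 2)

    def test_full_sibs_share_sca_level_half_sibs_do_not(self, family):
        rows = [(c, "T1", "2004", 1.0) for c in ("C1", "C2", "H")]
        ph = pd.DataFrame(rows, columns=["line_id", "trial", "year", "y"])
        spec = ModelSpec(traits=("y",), include_sca=True)
        am = build_design(ph, family, spec)
        key = dict(zip(am.clone_ids, np.asarray(am.S.argmax(axis=1)).ravel()))
        assert key["C1"] == key["C2"]
        assert key["H"] != key["C1"]

    def test_unknown_parent_gets_singleton_sca_level(self):
        ped = Pedigree([PedigreeRecord("A"),
                        PedigreeRecord("U1", "A", None, 2000),
                        PedigreeRecord("U2", "A", None, 2000)])
        ph = pd.DataFrame([("U1", "T", "2002", 1.0), ("U2", "T", "2002", 2.0)],
                          columns=["line_id", "trial", "year", "y"])
        am = build_design(ph, ped, ModelSpec(traits=("y",), include_sca=True))
        assert am.S.shape[1] == 2                  # one level per line

    def test_gxty_unidentifiable_warns(self):
        ped = Pedigree([PedigreeRecord("c1"), PedigreeRecord("c2")])
        ph = pd.DataFrame([("c1", "T", "2005", 1.0), ("c2", "T", "2005", 2.0)],
                          columns=["line_id", "trial", "year", "y"])
        with pytest.warns(UserWarning, match="unidentifiable"):
            build_design(ph, ped, ModelSpec(traits=("y",)))

    def test_missing_line_in_pedigree_is_an_error(self, trio):
        ph = pd.DataFrame([("nope", "T", "2005", 1.0)],
                          columns=["line_id", "trial", "year", "y"])
        with pytest.raises(ModelError, match="absent"):
            build_design(ph, trio, ModelSpec(traits=("y",)))


class TestRemlFit:
    def test_balanced_one_way_matches_anova(self):
        ph, ped = one_way_data()
        spec = ModelSpec(traits=("y",), alpha=0.0, random_terms=("additive",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(build_design(ph, ped, spec))
        y = ph["y"].to_numpy().reshape(6, 4)
        mse = float(((y - y.mean(1, keepdims=True)) ** 2).sum() / (6 * 3))
        msb = 4 * float(y.mean(1).var(ddof=1))
        assert fit.vc["residual"][0, 0] == pytest.approx(mse, abs=1e-8)
        assert fit.vc["additive"][0, 0] == pytest.approx((msb - mse) / 4,
                                                         abs=1e-8)

    def test_twelve_plot_toy_matches_brute_force(self, family):
        rng = np.random.default_rng(4)
        clones = ["C1", "C2", "H", "S"]
        rows = [(c, t, "2006", rng.normal(5, 2))
                for c in clones for t in ("T1", "T2", "T3")]
        ph = pd.DataFrame(rows, columns=["line_id", "trial", "year", "y"])
        spec = ModelSpec(traits=("y",), alpha=0.1,
                         random_terms=("additive", "line"))
        am = build_design(ph, family, spec)
        fit = reml_fit(am)

        def obj(logv):
            sig = {k: np.array([[np.exp(v)]])
                   for k, v in zip(("additive", "line", "residual"), logv)}
            return dense_v_m2ll(am, sig)

        best = min(
            (minimize(obj, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 4000})
             for x0 in ([0.0, 0.0, 0.0], [1.0, -2.0, 0.5])),
            key=lambda r: r.fun)
        assert fit.minus2logl == pytest.approx(best.fun, abs=1e-6)

    def test_likelihood_matches_dense_v(self, small_truth):
        spec = ModelSpec(traits=("DMC",), include_sca=True, alpha=0.05)
        ph = small_truth.phenotypes.iloc[:80]
        am = build_design(ph, small_truth.pedigree, spec)
        sig = {k: np.array([[v]]) for k, v in
               {"additive": 2.0, "line": 0.4, "sca": 0.3, "gxty": 0.5,
                "residual": 1.1}.items()}
        st = _System(am, sig)
        assert st.m2ll == pytest.approx(dense_v_m2ll(am, sig), abs=1e-8)

    def test_shift_invariance(self, small_truth):
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        ph = small_truth.phenotypes
        f1 = reml_fit(build_design(ph, small_truth.pedigree, spec))
        ph2 = ph.assign(DMC=ph["DMC"] + 100.0)
        f2 = reml_fit(build_design(ph2, small_truth.pedigree, spec))
        for term in f1.vc:
            assert f2.vc[term][0, 0] == pytest.approx(f1.vc[term][0, 0],
                                                      rel=1e-4, abs=1e-8)
        ic1 = f1.blue.query("effect == 'intercept'")["estimate"].iloc[0]
        ic2 = f2.blue.query("effect == 'intercept'")["estimate"].iloc[0]
        assert ic2 - ic1 == pytest.approx(100.0, abs=1e-3)

    def test_m1_nested_in_m2(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        f1 = reml_fit(build_design(ph, ped, ModelSpec(traits=("DMC",))))
        f2 = reml_fit(build_design(ph, ped, ModelSpec(traits=("DMC",),
                                                      include_sca=True)))
        assert f2.minus2logl <= f1.minus2logl + 1e-6

    def test_bivariate_with_one_trait_missing_equals_univariate(
            self, small_truth_bi):
        ph = small_truth_bi.phenotypes.copy()
        ped = small_truth_bi.pedigree
        ph["RY"] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fbi = reml_fit(build_design(
                ph, ped, ModelSpec(traits=("DMC", "RY"), alpha=0.05)))
            funi = reml_fit(build_design(
                ph, ped, ModelSpec(traits=("DMC",), alpha=0.05)))
        assert fbi.minus2logl == pytest.approx(funi.minus2logl, abs=1e-4)

    def test_sca_truth_zero_hits_boundary(self):
        from tetraped.simulate import simulate_program, univariate_config
        cfg = univariate_config(
            n_founders=20, n_cycles=4, crosses_per_cycle=10,
            progeny_per_cross=5, seed=31,
            vc_true={"additive": 2.0, "line": 0.3, "gxty": 0.3,
                     "sca": 0.0, "residual": 1.0})
        truth = simulate_program(cfg)
        ph, ped = truth.phenotypes, truth.pedigree
        f1 = reml_fit(build_design(ph, ped, ModelSpec(traits=("DMC",))))
        f2 = reml_fit(build_design(ph, ped, ModelSpec(traits=("DMC",),
                                                      include_sca=True)))
        assert f2.minus2logl <= f1.minus2logl + 1e-6
        # under the null the deviance gap is a (conservative) chi-square
        # draw with 1 df; 6.63 is its 99th percentile
        assert f1.minus2logl - f2.minus2logl < 6.63


class TestPredictions:
    def test_unphenotyped_offspring_is_parent_average(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        fit = reml_fit(build_design(ph, ped, spec))
        a = fit.blup["additive"]["DMC"]
        p1, p2 = a.index[0], a.index[1]
        # graft a phantom offspring with no data and no descendants
        recs = list(ped.records) + [PedigreeRecord("phantom", p1, p2, 2099)]
        ped2 = Pedigree(recs)
        fit2 = reml_fit(build_design(ph, ped2, spec))
        pred = predict_breeding_values(fit2, ["phantom", p1, p2])
        assert pred.loc["phantom", "DMC"] == pytest.approx(
            (pred.loc[p1, "DMC"] + pred.loc[p2, "DMC"]) / 2, abs=1e-8)

    def test_constant_phenotypes_give_zero_breeding_values(self, trio):
        ph = pd.DataFrame([("C", "T", "2006", 5.0), ("C", "T", "2006", 5.0)],
                          columns=["line_id", "trial", "year", "y"])
        spec = ModelSpec(traits=("y",), random_terms=("additive",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(build_design(ph, trio, spec))
        assert abs(fit.blup["additive"]["y"]).max() < 1e-8

    def test_blup_correlates_with_truth(self, small_truth):
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        fit = reml_fit(build_design(small_truth.phenotypes,
                                    small_truth.pedigree, spec))
        a = fit.blup["additive"]["DMC"]
        r = np.corrcoef(a, small_truth.additive.loc[a.index, "DMC"])[0, 1]
        assert r > 0.4

    def test_unknown_id_is_an_error(self, small_truth):
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        fit = reml_fit(build_design(small_truth.phenotypes,
                                    small_truth.pedigree, spec))
        with pytest.raises(ModelError):
            predict_breeding_values(fit, ["not-a-clone"])


def test_solve_mme_reproduces_fit_solutions(small_truth):
    spec = ModelSpec(traits=("DMC",), alpha=0.05)
    am = build_design(small_truth.phenotypes, small_truth.pedigree, spec)
    fit = reml_fit(am)
    solved = solve_mme(am, fit.vc)
    np.testing.assert_allclose(solved.blup["additive"].to_numpy(),
                               fit.blup["additive"].to_numpy(), atol=1e-10)
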