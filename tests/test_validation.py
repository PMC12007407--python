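import numpy as np
import pandas as pd
import pytest

from tetraped.lmm import ModelSpec, build_design, reml_fit, solve_mme
from tetraped.pedigree import Pedigree, PedigreeRecord
from tetraped.validation import (CVScheme, corrected_clone_means, make_folds,
                                 run_cv)


class TestMakeFolds:
    def test_five_fold_sizes_and_reproducibility(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        s1 = make_folds(ph, ped, "five_fold", seed=4)
        s2 = make_folds(ph.sample(frac=1.0, random_state=0), ped,
                        "five_fold", seed=4)
        sizes = sorted(len(f) for f in s1.folds)
        assert max(sizes) - min(sizes) <= 1
        assert s1.folds == s2.folds            # row-order invariant
        union = set().union(*s1.folds)
        assert union == set(ph["line_id"].astype(str))

    def test_ten_clones_two_each(self):
        ids = [f"G{i}" for i in range(10)]
        ped = Pedigree([PedigreeRecord(i, crossing_year=2000) for i in ids])
        ph = pd.DataFrame([(i, "T", "2002", 1.0) for i in ids],
                          columns=["line_id", "trial", "year", "y"])
        s = make_folds(ph, ped, "five_fold", seed=0)
        assert sorted(len(f) for f in s.folds) == [2, 2, 2, 2, 2]

    def test_too_few_clones(self, trio):
        ph = pd.DataFrame([("C", "T", "2002", 1.0)],
                          columns=["line_id", "trial", "year", "y"])
        with pytest.raises(Exception):
            make_folds(ph, trio, "five_fold", seed=0)

    def test_lbco_one_fold_per_year(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        s = make_folds(ph, ped, "lbco")
        years = {ped.records[ped.index[c]].crossing_year
                 for c in ph["line_id"].astype(str)}
        assert len(s.folds) == len(years)

    def test_lbco_masks_half_sibs(self):
        # a half sib crossed in another year is masked with the cycle
        recs = [PedigreeRecord("A"), PedigreeRecord("B"), PedigreeRecord("C"),
                PedigreeRecord("X", "A", "B", 2003),
                PedigreeRecord("Y", "A", "C", 2004),
                PedigreeRecord("Z", "B", "C", 2005)]
        ped = Pedigree(recs)
        ph = pd.DataFrame([(i, "T", "2006", 1.0) for i in ("X", "Y", "Z")],
                          columns=["line_id", "trial", "year", "y"])
        s = make_folds(ph, ped, "lbco")
        fold_2003 = s.labels.index(2003)
        assert set(s.folds[fold_2003]) == {"X"}
        assert set(s.mask_sets[fold_2003]) == {"X", "Y", "Z"}


class TestCorrectedMeans:
    def test_two_identical_plots_mean_equals_either(self, trio):
        ph = pd.DataFrame([("C", "T", "2006", 7.0), ("C", "T", "2006", 7.0)],
                          columns=["line_id", "trial", "year", "y"])
        spec = ModelSpec(traits=("y",), random_terms=("additive",))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            am = build_design(ph, trio, spec)
            fit = reml_fit(am)
        ybar = corrected_clone_means(am, fit)
        resid = 7.0 - fit.blue["estimate"].iloc[0]
        assert ybar.loc["C", "y"] == pytest.approx(resid, abs=1e-8)

    def test_correlates_with_true_additive(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        am = build_design(ph, ped, spec)
        fit = reml_fit(am)
        ybar = corrected_clone_means(am, fit)
        truth_a = small_truth.additive.loc[ybar.index, "DMC"]
        assert np.corrcoef(ybar["DMC"], truth_a)[0, 1] > 0.4


class TestRunCV:
    def test_degenerate_no_masking_gives_rc_one(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        clones = sorted(set(ph["line_id"]))
        scheme = CVScheme(kind="five_fold", folds=[clones],
                          mask_sets=[[]], labels=[1], seed=0)
        res = run_cv(ph, ped, spec, scheme)
        assert res.rc["DMC"] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.predictions["DMC"],
                                   res.full_predictions["DMC"], atol=1e-10)

    def test_masking_is_total(self, small_truth):
        # shuffling the phenotypes of masked clones cannot change their
        # predictions, because their rows are removed from the training data
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        am = build_design(ph, ped, spec)
        fit = reml_fit(am)
        scheme = make_folds(ph, ped, "five_fold", seed=8)
        masked = scheme.mask_sets[0]
        cidx = {c: k for k, c in enumerate(am.clone_ids)}
        keep = ~np.isin(am.obs_clone, [cidx[c] for c in masked])
        s1 = solve_mme(am.subset(keep), fit.vc)

        ph2 = ph.copy()
        rows = ph2["line_id"].isin(masked)
        ph2.loc[rows, "DMC"] = ph2.loc[rows, "DMC"].sample(
            frac=1.0, random_state=1).to_numpy()
        am2 = build_design(ph2, ped, spec)
        keep2 = ~np.isin(am2.obs_clone, [cidx[c] for c in masked])
        s2 = solve_mme(am2.subset(keep2), fit.vc)
        a1 = s1.blup["additive"].loc[masked].to_numpy()
        a2 = s2.blup["additive"].loc[masked].to_numpy()
        assert np.array_equal(a1, a2)          # bit-identical

    def test_pa_below_theoretical_max(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        scheme = make_folds(ph, ped, "five_fold", seed=2)
        res = run_cv(ph, ped, spec, scheme)
        n = int(res.predictions["DMC"].notna().sum())
        mc_se = 1.0 / np.sqrt(n - 3)
        assert res.pa["DMC"] <= res.theoretical_max["DMC"] + 2 * mc_se
        assert -1.0 <= res.pa["DMC"] <= 1.0
        assert 0.0 < res.rc["DMC"] <= 1.0

    def test_per_fold_table_complete(self, small_truth):
        ph, ped = small_truth.phenotypes, small_truth.pedigree
        spec = ModelSpec(traits=("DMC",), alpha=0.05)
        scheme = make_folds(ph, ped, "five_fold", seed=2)
        res = run_cv(ph, ped, spec, scheme)
        assert len(res.per_fold) == 5
        assert (res.per_fold["n_eval"] > 0).all()
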