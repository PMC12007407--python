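"""Cross-validation of breeding-value prediction.

Two schemes are implemented:

* **5-fold** - phenotyped clones are split into five random non-overlapping
  subsets (all plots of a clone stay together); each subset is masked in
  turn and its breeding values predicted from the rest.
* **Leave-one-breeding-cycle-out (LBCO)** - clones are grouped by crossing
  year (one breeding cycle per year); when a cycle is masked, every
  phenotyped clone sharing at least one known parent with any clone of the
  cycle (its full and half siblings) is masked with it, emulating the
  prediction of a new, not-yet-phenotyped generation from parental and
  historical data.

Predictive ability (PA) is the Pearson correlation between fixed-effect
corrected clone-mean phenotypes and the breeding values predicted with the
clone's data masked; the accuracy ratio (RC) correlates masked-data with
full-data predictions.  PA is bounded above by the square root of the
heritability of the corrected clone means, which is reconstructed from the
variance components with harmonic-mean replication numbers.

Variance components are estimated once on the full data and held fixed
inside the folds (only the mixed-model equations are re-solved), unless
per-fold re-estimation is requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lmm import (AssembledModel, FitResult, ModelError, ModelSpec,
                  build_design, reml_fit, solve_mme)
from .pedigree import Pedigree
from .summary import clone_mean_heritability

log = logging.getLogger(__name__)


@dataclass
class CVScheme:
    kind: str                       # "five_fold" or "lbco"
    folds: list                     # per fold: list of evaluated clone ids
    mask_sets: list                 # per fold: clone ids whose data is masked
    labels: list                    # fold labels (fold number / crossing year)
    seed: Optional[int] = None


@dataclass
class CVResult:
    scheme: CVScheme
    pa: dict                        # trait -> pooled predictive ability
    rc: dict                        # trait -> accuracy ratio
    theoretical_max: dict           # trait -> sqrt(h2 of corrected clone mean)
    per_fold: pd.DataFrame
    n_masked: list
    predictions: pd.DataFrame       # clone x trait masked-model predictions
    corrected_means: pd.DataFrame
    full_predictions: pd.DataFrame


def make_folds(pheno: pd.DataFrame, ped: Pedigree, kind: str,
               seed: Optional[int] = None, n_folds: int = 5) -> CVScheme:
    """Build a cross-validation scheme over the phenotyped clones.

    The five-fold partition is seeded and invariant to the input row order
    (clone ids are sorted before permutation).
    """
    clones = sorted(set(pheno["line_id"].astype(str)))
    missing = [c for c in clones if c not in ped.index]
    if missing:
        raise ModelError(f"phenotyped clones absent from pedigree: {missing[:5]}")
    if kind == "five_fold":
        if len(clones) < n_folds:
            raise ModelError(f"need at least {n_folds} clones for {n_folds}-fold CV")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(clones))
        folds = [sorted(np.asarray(clones)[idx])
                 for idx in np.array_split(perm, n_folds)]
        return CVScheme(kind=kind, folds=folds, mask_sets=[list(f) for f in folds],
                        labels=list(range(1, n_folds + 1)), seed=seed)
    if kind == "lbco":
        years = {}
        for c in clones:
            yr = ped.records[ped.index[c]].crossing_year
            if yr is None:
                warnings.warn(f"clone {c} lacks a crossing year; excluded from LBCO")
                continue
            years.setdefault(int(yr), []).append(c)
        if not years:
            raise ModelError("no phenotyped clone has a crossing year")
        # parents of each phenotyped clone, for the sibling-masking rule
        parents = {}
        for c in clones:
            r = ped.records[ped.index[c]]
            parents[c] = {p for p in (r.parent1, r.parent2) if p is not None}
        folds, mask_sets, labels = [], [], []
        for yr in sorted(years):
            fold = sorted(years[yr])
            shared = set()
            fold_parents = set().union(*(parents[c] for c in fold))
            for c in clones:
                if c not in fold and parents[c] & fold_parents:
                    shared.add(c)
            folds.append(fold)
            mask_sets.append(sorted(set(fold) | shared))
            labels.append(yr)
        return CVScheme(kind=kind, folds=folds, mask_sets=mask_sets,
                        labels=labels, seed=seed)
    raise ModelError(f"unknown CV scheme kind {kind!r}")


def corrected_clone_means(am: AssembledModel, fit: FitResult) -> pd.DataFrame:
    """Per-clone means of phenotypes after subtracting the fixed effects
    estimated on the full data (y - X b_hat, averaged over a clone's plots)."""
    resid = am.y - am.X @ _blue_vector(am, fit)
    out = {}
    for ti, trait in enumerate(am.spec.traits):
        sel = am.obs_trait == ti
        df = pd.DataFrame({"clone": np.asarray(am.clone_ids)[am.obs_clone[sel]],
                           "value": resid[sel]})
        out[trait] = df.groupby("clone")["value"].mean()
    return pd.DataFrame(out)


def _blue_vector(am: AssembledModel, fit: FitResult) -> np.ndarray:
    """Fixed-effect solutions of ``fit`` ordered for this design's X."""
    vals = []
    bl = fit.blue.set_index(["trait", "effect"])["estimate"]
    for ti, trait in enumerate(am.spec.traits):
        for j in am.keep_cols[ti]:
            vals.append(bl.get((trait, am.dcols[j]), 0.0))
    return np.asarray(vals)


def _replication_numbers(am: AssembledModel) -> tuple:
    """Harmonic-mean plots and trial-year cells per clone (per trait pooled)."""
    df = pd.DataFrame({"clone": am.obs_clone, "plot": am.obs_plot,
                       "cell": am.obs_cell})
    per = df.groupby("clone").agg(plots=("plot", "nunique"),
                                  cells=("cell", "nunique"))
    n_bar = len(per) / (1.0 / per["plots"]).sum()
    t_bar = len(per) / (1.0 / per["cells"]).sum()
    return float(n_bar), float(t_bar)


def run_cv(pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
           scheme: CVScheme, reestimate: bool = False,
           full_fit: Optional[FitResult] = None) -> CVResult:
    """Run one cross-validation scheme.

    Masked clones' phenotypes are removed entirely from the training data of
    their fold, so no masked observation can influence the fold's
    predictions.  Predictive ability is pooled over all masked clones
    jointly, each clone contributing in its own fold.
    """
    if full_fit is not None and full_fit.design is not None:
        am = full_fit.design
    else:
        am = build_design(pheno, ped, spec)
    if full_fit is None:
        full_fit = reml_fit(am)
    if not full_fit.converged:
        warnings.warn("full-data REML fit did not converge; CV results may "
                      "be unreliable")
    ybar = corrected_clone_means(am, full_fit)
    a_full = full_fit.blup["additive"]

    traits = list(spec.traits)
    preds = pd.DataFrame(np.nan, index=am.clone_ids, columns=traits)
    fold_rows = []
    n_masked = []
    clone_index = {c: k for k, c in enumerate(am.clone_ids)}
    for fold, masked, label in zip(scheme.folds, scheme.mask_sets,
                                   scheme.labels):
        mask_idx = [clone_index[c] for c in masked if c in clone_index]
        keep = ~np.isin(am.obs_clone, mask_idx)
        eval_ids = [c for c in fold if c in clone_index]
        if not eval_ids:
            warnings.warn(f"fold {label}: no masked phenotyped clones; skipped")
            continue
        sub = am.subset(keep)
        if reestimate:
            fit_r = reml_fit(sub, start=full_fit.vc)
        else:
            fit_r = solve_mme(sub, full_fit.vc)
        a_r = fit_r.blup["additive"]
        preds.loc[eval_ids] = a_r.loc[eval_ids].to_numpy()
        for trait in traits:
            common = [c for c in eval_ids if c in ybar.index
                      and not np.isnan(ybar.loc[c, trait])]
            r = np.nan
            if len(common) > 2:
                r = float(np.corrcoef(ybar.loc[common, trait],
                                      a_r.loc[common, trait])[0, 1])
            fold_rows.append((label, trait, len(common), r))
        n_masked.append(len(masked))

    pa, rc, tmax = {}, {}, {}
    n_bar, t_bar = _replication_numbers(am)
    d_A = float(np.diagonal(am.Aff).mean())   # over phenotyped clones
    h_mean = clone_mean_heritability(full_fit, d_A, n_bar, t_bar)
    for ti, trait in enumerate(traits):
        got = preds[trait].notna() & ybar.reindex(preds.index)[trait].notna().to_numpy()
        ids = preds.index[got]
        pa[trait] = float(np.corrcoef(ybar.loc[ids, trait],
                                      preds.loc[ids, trait])[0, 1]) \
            if got.sum() > 2 else np.nan
        rc[trait] = float(np.corrcoef(a_full.loc[ids, trait],
                                      preds.loc[ids, trait])[0, 1]) \
            if got.sum() > 2 else np.nan
        tmax[trait] = float(np.sqrt(h_mean[ti].h2))
    per_fold = pd.DataFrame(fold_rows,
                            columns=["fold", "trait", "n_eval", "pa"])
    return CVResult(scheme=scheme, pa=pa, rc=rc, theoretical_max=tmax,
                    per_fold=per_fold, n_masked=n_masked, predictions=preds,
                    corrected_means=ybar, full_predictions=a_full)
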