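"""Plot-level heritabilities, variance proportions and model comparison.

Narrow-sense plot-level heritability uses the average diagonal d(A) of the
relationship matrix to put the additive variance on the phenotypic scale:

    h2 = d(A) sa2 / (d(A) sa2 + sg2 + si2 + ss2 + se2)
    H2 = (d(A) sa2 + sg2 + ss2) / (d(A) sa2 + sg2 + si2 + ss2 + se2)

For the baseline model (M1) the SCA variance ss2 is absent from both
formulas.  Models are compared by a likelihood-ratio test on the REML
deviances with degrees of freedom equal to the number of additional free
(co)variance parameters (3 for a bivariate SCA block, 1 univariate); the
plain chi-square reference is used, which is conservative because the null
places variances on the boundary of the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

from .lmm import FitResult, ModelError, _vc_pairs


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    H2: float
    d_A: float
    components: dict
    model: str


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


def _scalar_components(fit: FitResult, trait_idx: int) -> dict:
    comp = {}
    for term in list(fit.spec.terms) + ["residual"]:
        v = float(fit.vc[term][trait_idx, trait_idx])
        if v < 0:
            raise ModelError(f"negative variance component for {term}")
        comp[term] = v
    return comp


def heritability(fit: FitResult, d_A: float) -> list:
    """Plot-level narrow- and broad-sense heritability, one entry per trait."""
    out = []
    for ti, trait in enumerate(fit.spec.traits):
        comp = _scalar_components(fit, ti)
        denom = d_A * comp.get("additive", 0.0) + sum(
            v for k, v in comp.items() if k != "additive")
        if denom <= 0:
            raise ModelError("zero phenotypic variance")
        h2 = d_A * comp.get("additive", 0.0) / denom
        H2 = (d_A * comp.get("additive", 0.0) + comp.get("line", 0.0)
              + comp.get("sca", 0.0)) / denom
        out.append(HeritabilityEstimate(trait=trait, h2=h2, H2=H2, d_A=d_A,
                                        components=comp,
                                        model=fit.spec.label))
    return out


def variance_proportions(fit: FitResult, d_A: float) -> pd.DataFrame:
    """Share of total phenotypic variance per term (additive scaled by d(A));
    shares sum to one per trait."""
    rows = []
    for ti, trait in enumerate(fit.spec.traits):
        comp = _scalar_components(fit, ti)
        weighted = {k: (d_A * v if k == "additive" else v)
                    for k, v in comp.items()}
        tot = sum(weighted.values())
        if tot <= 0:
            raise ModelError("zero phenotypic variance")
        for k, v in weighted.items():
            rows.append((trait, k, v / tot))
    return pd.DataFrame(rows, columns=["trait", "term", "share"])


def clone_mean_heritability(fit: FitResult, d_A: float, n_plots: float,
                            n_cells: float) -> list:
    """Heritability of a clone mean given its replication.

    ``n_plots`` and ``n_cells`` are the (harmonic mean) numbers of plots and
    of trial-year cells per clone; the G x T x Y variance is divided by the
    cell count and the residual variance by the plot count.
    """
    out = []
    for ti, trait in enumerate(fit.spec.traits):
        comp = _scalar_components(fit, ti)
        denom = (d_A * comp.get("additive", 0.0) + comp.get("line", 0.0)
                 + comp.get("sca", 0.0)
                 + comp.get("gxty", 0.0) / max(n_cells, 1e-12)
                 + comp.get("residual", 0.0) / max(n_plots, 1e-12))
        out.append(HeritabilityEstimate(
            trait=trait, h2=d_A * comp.get("additive", 0.0) / denom,
            H2=(d_A * comp.get("additive", 0.0) + comp.get("line", 0.0)
                + comp.get("sca", 0.0)) / denom,
            d_A=d_A, components=comp, model=fit.spec.label))
    return out


def lrt(fit_reduced: FitResult, fit_full: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested REML fits (same data, fixed effects
    and double-reduction rate; the full model adds covariance blocks)."""
    red, full = fit_reduced.spec, fit_full.spec
    if red.traits != full.traits or red.alpha != full.alpha:
        raise ModelError("fits are not comparable (traits or alpha differ)")
    if not set(red.terms) < set(full.terms):
        raise ModelError("reduced model is not nested in the full model")
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ModelError("fits use different data")
    if not (fit_reduced.converged and fit_full.converged):
        raise ModelError("both fits must have converged")
    t = len(full.traits)
    extra = set(full.terms) - set(red.terms)
    df = len(extra) * len(_vc_pairs(t))
    stat = max(0.0, fit_reduced.minus2logl - fit_full.minus2logl)
    return LRTResult(stat=stat, df=df, p=float(chi2.sf(stat, df)))


def summary_report(fit: FitResult, d_A: float) -> dict:
    """Machine-readable summary: variance components with SEs, shares and
    heritabilities for one fit."""
    her = heritability(fit, d_A)
    return {
        "model": fit.spec.label,
        "alpha": fit.spec.alpha,
        "minus2logl": fit.minus2logl,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "loglik_trace": [float(x) for x in fit.loglik_trace],
        "d_A": d_A,
        "vc": fit.vc_table().to_dict(orient="records"),
        "shares": variance_proportions(fit, d_A).to_dict(orient="records"),
        "heritability": [
            {"trait": h.trait, "h2": h.h2, "H2": h.H2} for h in her],
    }
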