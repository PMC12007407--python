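"""Multi-trait pedigree mixed models fitted by average-information REML.

The model for plot-level phenotypes y (one or two traits) is

    y = X b + Z1 a + Z2 g + Z3 i [+ Z4 s] + e

with fixed trial, year and trial x year effects (b), additive genetic effects
a ~ N(0, A (x) Sigma_a) with A the tetraploid pedigree relationship matrix,
clone ("line") effects g ~ N(0, I (x) Sigma_g), genotype x trial x year
effects i ~ N(0, I (x) Sigma_i), optionally specific-combining-ability
effects s keyed by unordered parent pair, s ~ N(0, I (x) Sigma_s), and
residuals with unstructured cross-trait covariance Sigma_e.  The baseline
model (M1) omits the SCA term; M2 includes it.

Implementation notes
--------------------
The clone-level random terms (additive, line, SCA) are folded into a single
combined clone effect with covariance
``Sigma_a (x) A_ff + Sigma_g (x) I + Sigma_s (x) S S'`` (S the clone ->
parent-pair incidence and A_ff the relationship matrix restricted to
phenotyped clones), while the G x T x Y and residual terms are folded into
block-diagonal per-cell residual covariance (a cell is one clone x trial x
year combination).  This keeps the mixed-model equations at clone dimension.
Per-term variance estimates, BLUPs and likelihoods are identical to the
expanded formulation; predictions for unphenotyped pedigree members flow
through the relationship matrix afterwards.

Restricting the additive covariance to phenotyped clones leaves the REML
likelihood and all BLUPs unchanged because unphenotyped ancestors enter the
likelihood only through the marginal covariance of phenotyped clones, and
their BLUPs are recovered exactly as conditional means through A.

The REML criterion is maximized by average-information (AI) updates on a
log-Cholesky parameterization of every covariance block, which keeps each
block positive (semi)definite by construction; when an AI step does not
improve the criterion the step is halved, with a ridge on the AI matrix as a
further fallback.  Standard errors are read from the inverse AI matrix at
convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg import qr as _qr
from scipy.linalg.lapack import dpotri

from .kinship import TetraKinship, build_amatrix
from .pedigree import Pedigree
from .simulate import sca_key

log = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

CLONE_TERMS = ("additive", "line", "sca")


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Specification of one analysis model.

    ``traits`` lists one or two phenotype columns; ``include_sca``
    distinguishes the baseline model (M1) from the SCA model (M2);
    ``alpha`` is the double-reduction rate used to build A.
    ``random_terms`` may drop "line" or "gxty" for reduced designs, but the
    additive term is always present.
    """

    traits: Sequence[str]
    include_sca: bool = False
    alpha: float = 0.05
    random_terms: Sequence[str] = ("additive", "line", "gxty")

    def __post_init__(self):
        self.traits = tuple(self.traits)
        if not 1 <= len(self.traits) <= 2:
            raise ModelError("one or two traits are supported")
        self.random_terms = tuple(self.random_terms)
        if "additive" not in self.random_terms:
            raise ModelError("the additive term is always present")
        for term in self.random_terms:
            if term not in ("additive", "line", "gxty"):
                raise ModelError(f"unknown random term {term!r}")

    @property
    def terms(self) -> tuple:
        """All random terms except the residual, in canonical order."""
        out = [x for x in ("additive", "line") if x in self.random_terms]
        if self.include_sca:
            out.append("sca")
        if "gxty" in self.random_terms:
            out.append("gxty")
        return tuple(out)

    @property
    def label(self) -> str:
        return "M2" if self.include_sca else "M1"

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _vc_pairs(t: int) -> list:
    """(row, col) order of free parameters of a t x t symmetric block."""
    return [(r, c) for r in range(t) for c in range(r + 1)]


# ======================================================================
# design assembly
# ======================================================================

@dataclass(eq=False)
class AssembledModel:
    """Design matrices and covariance-structure handles for one dataset."""

    spec: ModelSpec
    pedigree: Pedigree                 # traced to phenotyped clones
    pedigree_full: Pedigree            # the pedigree as supplied
    kinship: TetraKinship              # A over the traced pedigree
    clone_ids: list                    # phenotyped clones, pedigree order
    clone_pos: np.ndarray              # positions of clone_ids in kinship
    Aff: np.ndarray                    # A restricted to phenotyped clones
    S: sp.csr_matrix                   # clone -> SCA-level incidence
    sca_levels: list
    D: np.ndarray                      # plot-level fixed-effect dummies
    dcols: list                        # dummy column names
    keep_cols: list                    # per trait: kept column indices of D
    plot_frame: pd.DataFrame           # line_id/trial/year/segment per plot
    plot_clone: np.ndarray             # clone index per plot
    # observation-level structures (built by _finalize)
    obs_plot: np.ndarray = None
    obs_trait: np.ndarray = None
    obs_clone: np.ndarray = None
    y: np.ndarray = None
    X: sp.csr_matrix = None
    Z: sp.csr_matrix = None
    W: sp.csr_matrix = None
    sigs: list = None                  # residual-block signatures
    cell_keys: list = None
    obs_cell: np.ndarray = None
    varP: np.ndarray = None
    p_tot: int = 0

    @property
    def n_traits(self) -> int:
        return self.spec.n_traits

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def has_gxty(self) -> bool:
        return "gxty" in self.spec.terms

    # ------------------------------------------------------------------
    def clone_matrix(self, term: str):
        """Covariance structure over clones for one clone-level term."""
        if term == "additive":
            return self.Aff
        if term == "line":
            return None  # identity
        if term == "sca":
            return (self.S @ self.S.T).toarray()
        raise KeyError(term)

    def with_alpha(self, alpha: float) -> "AssembledModel":
        """Same design under a different double-reduction rate."""
        tk = build_amatrix(self.pedigree, alpha)
        pos = np.asarray([tk.index[c] for c in self.clone_ids])
        out = replace(self, spec=replace(self.spec, alpha=alpha), kinship=tk,
                      clone_pos=pos, Aff=tk.A[np.ix_(pos, pos)])
        return out

    def subset(self, obs_keep: np.ndarray) -> "AssembledModel":
        """Restrict to a boolean mask over observations (clone levels and
        fixed-effect columns are retained, so solutions stay comparable)."""
        idx = np.flatnonzero(np.asarray(obs_keep))
        out = replace(self)
        _finalize(out, self.obs_plot[idx], self.obs_trait[idx],
                  self.y[idx], check_rank=False)
        return out


def build_design(pheno: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
                 kinship: Optional[TetraKinship] = None) -> AssembledModel:
    """Assemble fixed/random design matrices and covariance handles.

    ``pheno`` has one row per plot with columns line_id, trial, year,
    market_segment and the trait columns named in ``spec.traits``; a missing
    trait value is simply absent from the stacked observation vector.
    """
    for col in ("line_id", "trial", "year"):
        if col not in pheno.columns:
            raise ModelError(f"phenotype table lacks column {col!r}")
    for tr in spec.traits:
        if tr not in pheno.columns:
            raise ModelError(f"phenotype table lacks trait column {tr!r}")
    pheno = pheno.reset_index(drop=True)
    lines = pheno["line_id"].astype(str)
    missing = sorted(set(lines) - set(ped.index))
    if missing:
        raise ModelError(f"phenotyped lines absent from pedigree: {missing[:5]}")

    traced = ped.trace(sorted(set(lines)))
    tk = kinship if kinship is not None else build_amatrix(traced, spec.alpha)
    phenotyped = set(lines)
    clone_ids = [i for i in tk.ids if i in phenotyped]
    clone_pos = np.asarray([tk.index[c] for c in clone_ids])
    Aff = tk.A[np.ix_(clone_pos, clone_pos)]
    clone_index = {c: k for k, c in enumerate(clone_ids)}

    # SCA incidence (unordered parent pair; unknown parent -> singleton level)
    keys = []
    for c in clone_ids:
        r = traced.records[traced.index[c]]
        keys.append(sca_key(r.parent1, r.parent2, c))
    sca_levels = sorted(set(keys))
    sidx = {k: j for j, k in enumerate(sca_levels)}
    S = sp.csr_matrix(
        (np.ones(len(keys)), (np.arange(len(keys)), [sidx[k] for k in keys])),
        shape=(len(clone_ids), len(sca_levels)))

    # plot-level fixed-effect dummies: intercept, trial, year, trial x year
    trial = pheno["trial"].astype(str).to_numpy()
    year = pheno["year"].astype(str).to_numpy()
    tlev = sorted(set(trial))
    ylev = sorted(set(year))
    cols = [("intercept", np.ones(len(pheno)))]
    for lv in tlev[1:]:
        cols.append((f"trial[{lv}]", (trial == lv).astype(float)))
    for lv in ylev[1:]:
        cols.append((f"year[{lv}]", (year == lv).astype(float)))
    seen = sorted(set(zip(trial, year)))
    for tv, yv in seen:
        if tv != tlev[0] and yv != ylev[0]:
            cols.append((f"trial[{tv}]:year[{yv}]",
                         ((trial == tv) & (year == yv)).astype(float)))
    D = np.column_stack([c for _, c in cols])
    dcols = [n for n, _ in cols]

    am = AssembledModel(
        spec=spec, pedigree=traced, pedigree_full=ped, kinship=tk,
        clone_ids=clone_ids,
        clone_pos=clone_pos, Aff=Aff, S=S, sca_levels=sca_levels,
        D=D, dcols=dcols, keep_cols=None,
        plot_frame=pheno[["line_id", "trial", "year"]
                         + (["market_segment"] if "market_segment"
                            in pheno.columns else [])].copy(),
        plot_clone=np.asarray([clone_index[c] for c in lines]),
    )

    obs_plot, obs_trait, yvals = [], [], []
    for ti, trname in enumerate(spec.traits):
        v = pd.to_numeric(pheno[trname], errors="coerce").to_numpy(dtype=float)
        ok = np.flatnonzero(~np.isnan(v))
        obs_plot.append(ok)
        obs_trait.append(np.full(ok.size, ti))
        yvals.append(v[ok])
    obs_plot = np.concatenate(obs_plot)
    obs_trait = np.concatenate(obs_trait)
    yvals = np.concatenate(yvals)
    if yvals.size == 0:
        raise ModelError("no non-missing trait observations")
    order = np.lexsort((obs_trait, obs_plot))
    _finalize(am, obs_plot[order], obs_trait[order], yvals[order],
              check_rank=True)
    return am


def _finalize(am: AssembledModel, obs_plot, obs_trait, y, check_rank: bool):
    """Build observation-level structures for a given set of observations."""
    spec = am.spec
    t = spec.n_traits
    am.obs_plot = obs_plot
    am.obs_trait = obs_trait
    am.obs_clone = am.plot_clone[obs_plot]
    am.y = y
    n_obs = y.size
    n_c = am.n_clones

    # per-trait fixed-effect columns; rank-reduced on the full data once
    if am.keep_cols is None or check_rank:
        keep_cols = []
        for ti in range(t):
            rows = obs_plot[obs_trait == ti]
            M = am.D[rows]
            if M.shape[0] == 0:
                keep_cols.append(np.array([], dtype=int))
                continue
            nz = np.flatnonzero((M != 0).any(axis=0))
            R, piv = _qr(M[:, nz], mode="r", pivoting=True)
            diag = np.abs(np.diagonal(R))
            rank = int((diag > 1e-9 * max(diag[0], 1.0)).sum()) if diag.size else 0
            kept = np.sort(nz[piv[:rank]])
            if kept.size < len(am.dcols):
                log.info("trait %s: dropped %d singular fixed-effect columns",
                         spec.traits[ti], len(am.dcols) - kept.size)
            keep_cols.append(kept)
        am.keep_cols = keep_cols
    am.p_tot = int(sum(k.size for k in am.keep_cols))

    # sparse X: per-trait blocks of the plot dummies
    xr, xc, xv = [], [], []
    offset = 0
    for ti in range(t):
        kept = am.keep_cols[ti]
        rows = np.flatnonzero(obs_trait == ti)
        blk = am.D[np.ix_(obs_plot[rows], kept)]
        rr, cc = np.nonzero(blk)
        xr.append(rows[rr])
        xc.append(cc + offset)
        xv.append(blk[rr, cc])
        offset += kept.size
    am.X = sp.csr_matrix((np.concatenate(xv),
                          (np.concatenate(xr), np.concatenate(xc))),
                         shape=(n_obs, am.p_tot))
    am.Z = sp.csr_matrix((np.ones(n_obs),
                          (np.arange(n_obs), obs_trait * n_c + am.obs_clone)),
                         shape=(n_obs, t * n_c))
    am.W = sp.hstack([am.X, am.Z]).tocsr()

    # residual cells: clone x trial x year if a G x T x Y term is present,
    # otherwise one cell per plot
    if am.has_gxty:
        pf = am.plot_frame
        key_of_plot = list(zip(pf["line_id"].astype(str),
                               pf["trial"].astype(str),
                               pf["year"].astype(str)))
        cell_map, cell_keys = {}, []
        cell_of_obs = np.zeros(n_obs, dtype=np.int64)
        for o in range(n_obs):
            k = key_of_plot[obs_plot[o]]
            if k not in cell_map:
                cell_map[k] = len(cell_keys)
                cell_keys.append(k)
            cell_of_obs[o] = cell_map[k]
    else:
        uplots, cell_of_obs = np.unique(obs_plot, return_inverse=True)
        cell_keys = [("plot", str(p)) for p in uplots]
    am.cell_keys = cell_keys
    am.obs_cell = cell_of_obs

    # group cells by signature (pattern of local plot / trait), batch-ready
    order = np.lexsort((obs_trait, obs_plot, cell_of_obs))
    cells = {}
    for o in order:
        cells.setdefault(cell_of_obs[o], []).append(o)
    by_sig: dict = {}
    for ck, obs in cells.items():
        plots = [obs_plot[o] for o in obs]
        loc = {}
        lp = [loc.setdefault(p, len(loc)) for p in plots]
        sig = tuple(zip(lp, (int(obs_trait[o]) for o in obs)))
        by_sig.setdefault(sig, []).append(obs)
    sigs = []
    for sig, group in sorted(by_sig.items()):
        k = len(sig)
        oi = np.asarray(group, dtype=np.int64)            # (m, k)
        lp = np.asarray([p for p, _ in sig])
        ta = np.asarray([q for _, q in sig])
        sigs.append({
            "k": k, "obs": oi,
            "same_plot": (lp[:, None] == lp[None, :]),
            "ta": ta,
            "rows": np.repeat(oi, k, axis=1).ravel(),
            "cols": np.tile(oi, (1, k)).ravel(),
        })
    am.sigs = sigs

    if am.has_gxty and check_rank:
        # every cell holding a single plot leaves sigma_i and sigma_e
        # separated by nothing (univariate) or by cross-trait structure only
        if all(s["same_plot"].all() for s in sigs):
            warnings.warn("no clone is replicated within any trial-year cell; "
                          "G x T x Y and residual variances are jointly "
                          "unidentifiable")

    am.varP = np.array([np.var(y[obs_trait == ti]) if (obs_trait == ti).any()
                        else 1.0 for ti in range(t)])


# ======================================================================
# variance-parameter bookkeeping
# ======================================================================

def _sigma_from_theta(th: np.ndarray, t: int) -> np.ndarray:
    if t == 1:
        return np.array([[np.exp(2.0 * th[0])]])
    a, c, b = th
    L = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
    return L @ L.T


def _theta_from_sigma(S: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    S = np.atleast_2d(np.asarray(S, dtype=float))
    t = S.shape[0]
    w, V = np.linalg.eigh(S)
    S = (V * np.clip(w, floor, None)) @ V.T
    L = np.linalg.cholesky(S)
    if t == 1:
        return np.array([np.log(L[0, 0])])
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _jac_block(th: np.ndarray, t: int) -> np.ndarray:
    """d vech(Sigma) / d theta, rows ordered as _vc_pairs(t)."""
    if t == 1:
        return np.array([[2.0 * np.exp(2.0 * th[0])]])
    a, c, b = th
    ea, eb = np.exp(a), np.exp(b)
    # vc order: (0,0), (1,0), (1,1)
    return np.array([
        [2.0 * ea * ea, 0.0, 0.0],
        [c * ea, ea, 0.0],
        [0.0, 2.0 * c, 2.0 * eb * eb],
    ])


@dataclass
class FitResult:
    """REML estimates, likelihood, solutions and diagnostics for one fit."""

    spec: ModelSpec
    vc: dict                     # term -> (t, t) covariance block
    vc_se: dict                  # term -> (t, t) asymptotic SEs
    minus2logl: float
    blue: pd.DataFrame           # fixed-effect solutions (trait, name, value)
    blup: dict                   # term -> DataFrame of solutions
    converged: bool
    iterations: int
    boundary: bool
    n_obs: int
    loglik_trace: list = field(default_factory=list, repr=False)
    design: AssembledModel = field(default=None, repr=False)
    w: np.ndarray = field(default=None, repr=False)   # Z' P y
    py: np.ndarray = field(default=None, repr=False)

    def vc_table(self) -> pd.DataFrame:
        rows = []
        t = self.spec.n_traits
        for term, S in self.vc.items():
            for r, c in _vc_pairs(t):
                rows.append((term, self.spec.traits[r], self.spec.traits[c],
                             S[r, c], self.vc_se[term][r, c]))
        return pd.DataFrame(rows, columns=["term", "trait_i", "trait_j",
                                           "estimate", "se"])


# ======================================================================
# likelihood evaluation
# ======================================================================

class _System:
    """One evaluation of the REML criterion and its factorizations."""

    def __init__(self, am: AssembledModel, sigmas: dict, need_m2ll=True):
        self.am = am
        self.sig = sigmas
        t = am.n_traits
        n_c = am.n_clones
        qt = t * n_c

        # residual blocks per signature
        Se = sigmas["residual"]
        Si = sigmas.get("gxty")
        data, logdetR = [], 0.0
        self.Binv = []
        for s in am.sigs:
            ta = s["ta"]
            B = Se[np.ix_(ta, ta)] * s["same_plot"]
            if Si is not None:
                B = B + Si[np.ix_(ta, ta)]
            Binv = np.linalg.inv(B)
            sign, ld = np.linalg.slogdet(B)
            if sign <= 0:
                raise np.linalg.LinAlgError("residual block not PD")
            logdetR += ld * s["obs"].shape[0]
            self.Binv.append(Binv)
            data.append(np.tile(Binv.ravel(), s["obs"].shape[0]))
        rows = np.concatenate([s["rows"] for s in am.sigs])
        cols = np.concatenate([s["cols"] for s in am.sigs])
        self.Rinv = sp.csr_matrix((np.concatenate(data), (rows, cols)),
                                  shape=(am.n_obs, am.n_obs))
        self.logdetR = logdetR

        # combined clone-level covariance
        G = np.zeros((qt, qt))
        for term in am.spec.terms:
            if term not in CLONE_TERMS:
                continue
            K = am.clone_matrix(term)
            St = sigmas[term]
            for r in range(t):
                for c in range(t):
                    blk = G[r * n_c:(r + 1) * n_c, c * n_c:(c + 1) * n_c]
                    if K is None:
                        blk[np.diag_indices(n_c)] += St[r, c]
                    else:
                        blk += St[r, c] * K
        try:
            cG = cho_factor(G, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            G = G + np.eye(qt) * (1e-10 * np.trace(G) / qt)
            cG = cho_factor(G, lower=True, check_finite=False)
        self.logdetG = 2.0 * np.log(np.diagonal(cG[0])).sum()
        # dpotri fills the lower triangle only; the Cholesky below reads
        # only the lower triangle of C, so no symmetrization is needed
        Ginv, info = dpotri(cG[0], lower=True)
        del G

        self.RiW = (self.Rinv @ am.W).tocsr()
        M = (am.W.T @ self.RiW).toarray()
        p = am.p_tot
        # only the lower triangle of C is ever factorized or solved against,
        # so the junk dpotri leaves above the diagonal is harmless
        M[p:, p:] += Ginv
        del Ginv
        # guard empty fixed-effect columns (possible in masked re-solves)
        d = np.diagonal(M[:p, :p]).copy()
        empty = np.flatnonzero(d == 0.0)
        if empty.size:
            M[empty, empty] = 1.0
        self.C = M
        self.ridged = False
        try:
            self.cC = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            if need_m2ll:
                raise
            # masked re-solves can lose fixed-effect rank; a tiny ridge on
            # the fixed-effect block pins the unidentified contrasts near 0
            ridge = 1e-8 * max(np.abs(np.diagonal(M[:p, :p])).max(), 1.0)
            for _ in range(6):
                M[np.arange(p), np.arange(p)] += ridge
                try:
                    self.cC = cho_factor(M, lower=True, check_finite=False)
                    self.ridged = True
                    break
                except np.linalg.LinAlgError:
                    ridge *= 100.0
            else:
                raise
        self.logdetC = 2.0 * np.log(np.diagonal(self.cC[0])).sum()
        self.rhs = am.W.T @ (self.Rinv @ am.y)
        self.sol = cho_solve(self.cC, self.rhs, check_finite=False)
        self.yRy = float(am.y @ (self.Rinv @ am.y))
        self.yPy = self.yRy - float(self.sol @ self.rhs)
        self.py = self.Rinv @ (am.y - am.W @ self.sol)
        self.w = am.Z.T @ self.py
        if need_m2ll and empty.size == 0:
            self.m2ll = ((am.n_obs - p) * LOG2PI + self.logdetR + self.logdetG
                         + self.logdetC + self.yPy)
        else:
            self.m2ll = float("nan")
        self._Cinv = None

    @property
    def Cinv(self):
        if self._Cinv is None:
            inv, info = dpotri(self.cC[0], lower=True)
            self._Cinv = np.tril(inv) + np.tril(inv, -1).T
        return self._Cinv

    # ------------------------------------------------------------------
    def apply_P(self, Fmat: np.ndarray) -> np.ndarray:
        """P f for a stack of vectors (columns)."""
        Rf = self.Rinv @ Fmat
        return Rf - self.RiW @ cho_solve(self.cC, self.am.W.T @ Rf,
                                         check_finite=False)

    def param_list(self) -> list:
        t = self.am.n_traits
        out = []
        for term in list(self.am.spec.terms) + ["residual"]:
            if term == "gxty" and "gxty" not in self.am.spec.terms:
                continue
            for (r, c) in _vc_pairs(t):
                out.append((term, r, c))
        return out

    def derivatives(self):
        """Gradient of -2logL and the average-information matrix, both in
        covariance coordinates (order of :meth:`param_list`)."""
        am = self.am
        t, n_c = am.n_traits, am.n_clones
        p = am.p_tot
        params = self.param_list()
        d = len(params)

        # Z' P Z, dense (t n_c)^2
        ZtRiZ = (am.Z.T @ (self.Rinv @ am.Z)).toarray()
        Nw = (am.W.T @ (self.Rinv @ am.Z)).tocsr()        # (p+qt) x qt
        E = (Nw.T @ self.Cinv)                            # qt x (p+qt) dense
        ZPZ = ZtRiZ - (Nw.T @ E.T).T
        del ZtRiZ

        grad = np.zeros(d)
        Fs = np.zeros((am.n_obs, d))
        w = self.w.reshape(t, n_c)
        Kw = {}
        for term in am.spec.terms:
            if term in CLONE_TERMS:
                K = am.clone_matrix(term)
                Kw[term] = w.copy() if K is None else (K @ w.T).T

        for k, (term, r, c) in enumerate(params):
            if term in CLONE_TERMS:
                K = am.clone_matrix(term)
                # trace term against Z'PZ
                blk = ZPZ[r * n_c:(r + 1) * n_c, c * n_c:(c + 1) * n_c]
                if K is None:
                    tr = np.trace(blk)
                else:
                    tr = float(np.sum(K * blk))
                if r != c:
                    tr *= 2.0
                # V-dot @ Py
                u = np.zeros((t, n_c))
                u[r] += Kw[term][c]
                if r != c:
                    u[c] += Kw[term][r]
                f = am.Z @ u.ravel()
            else:  # gxty or residual: residual-structure side
                tr_r = 0.0
                mrows, mcols, mvals = [], [], []
                f = np.zeros(am.n_obs)
                for s, Binv in zip(am.sigs, self.Binv):
                    ta = s["ta"]
                    Bdot = np.zeros((s["k"], s["k"]))
                    pat = np.outer(ta == r, ta == c)
                    Bdot[pat] = 1.0
                    if r != c:
                        Bdot[pat.T] = 1.0
                    if term == "residual":
                        Bdot *= s["same_plot"]
                    if not Bdot.any():
                        continue
                    m = s["obs"].shape[0]
                    tr_r += m * float(np.sum(Binv * Bdot))
                    N = Binv @ Bdot @ Binv
                    mrows.append(s["rows"])
                    mcols.append(s["cols"])
                    mvals.append(np.tile(N.ravel(), m))
                    pyb = self.py[s["obs"]]               # (m, k)
                    np.add.at(f, s["obs"].ravel(),
                              (pyb @ Bdot.T).ravel())
                if mrows:
                    Nmat = sp.csr_matrix(
                        (np.concatenate(mvals),
                         (np.concatenate(mrows), np.concatenate(mcols))),
                        shape=(am.n_obs, am.n_obs))
                    Mk = (am.W.T @ (Nmat @ am.W)).tocoo()
                    tr = tr_r - float(np.sum(
                        Mk.data * self.Cinv[Mk.col, Mk.row]))
                else:
                    tr = 0.0
            q = float(f @ self.py)
            grad[k] = tr - q
            Fs[:, k] = f

        PF = self.apply_P(Fs)
        AI = 0.5 * (Fs.T @ PF)
        return grad, AI, params


# ======================================================================
# REML driver
# ======================================================================

def _start_theta(am: AssembledModel, start: Optional[dict]) -> np.ndarray:
    t = am.n_traits
    blocks = list(am.spec.terms) + ["residual"]
    theta = []
    for b in blocks:
        if start is not None and b in start:
            theta.append(_theta_from_sigma(start[b]))
        else:
            share = np.diag(am.varP / (len(blocks)))
            theta.append(_theta_from_sigma(share[:t, :t] if t > 1
                                           else share[:1, :1]))
    return np.concatenate(theta)


def _univariate_view(am: AssembledModel, ti: int) -> AssembledModel:
    """Single-trait working copy of a bivariate design (same clones/columns)."""
    out = replace(am, spec=replace(am.spec, traits=(am.spec.traits[ti],)),
                  keep_cols=[am.keep_cols[ti]])
    sel = am.obs_trait == ti
    _finalize(out, am.obs_plot[sel], np.zeros(int(sel.sum()), dtype=np.int64),
              am.y[sel], check_rank=False)
    return out


def _univariate_prestart(am: AssembledModel, max_iter: int) -> dict:
    """Starting blocks for a bivariate fit: variances from cheap univariate
    fits of each trait, cross-trait covariances at zero."""
    blocks = list(am.spec.terms) + ["residual"]
    start = {b: np.diag(am.varP / len(blocks)).astype(float) for b in blocks}
    for ti in range(2):
        if not (am.obs_trait == ti).any():
            continue
        try:
            sub = _univariate_view(am, ti)
            # rough starting values only: a loose tolerance is plenty
            fit = reml_fit(sub, max_iter=min(max_iter, 40), tol=1e-2)
            for b in blocks:
                start[b][ti, ti] = max(fit.vc[b][0, 0], 1e-8 * am.varP[ti])
        except (np.linalg.LinAlgError, ModelError):  # pragma: no cover
            continue
    return start


def reml_fit(am: AssembledModel, start: Optional[dict] = None,
             max_iter: int = 200, tol: float = 1e-8,
             verbose: bool = False) -> FitResult:
    """Fit the model by AI-REML; see the module docstring for the algorithm.

    ``start`` optionally maps term names (including "residual") to starting
    covariance blocks; by default the phenotypic variance is split equally
    across all terms with zero cross-trait covariances.
    """
    t = am.n_traits
    if am.n_obs <= am.p_tot:
        raise ModelError("fewer observations than fixed-effect parameters")
    blocks = list(am.spec.terms) + ["residual"]
    npar = len(_vc_pairs(t))
    floor_lo = np.array([0.5 * np.log(1e-10 * am.varP[ti])
                         for ti in range(t)])

    def clip_theta(th):
        out = th.copy()
        for bi in range(len(blocks)):
            off = bi * npar
            out[off] = max(out[off], floor_lo[0])
            if t == 2:
                out[off + 2] = max(out[off + 2], floor_lo[1])
        return out

    if start is None and t == 2:
        start = _univariate_prestart(am, max_iter=max_iter)

    theta = clip_theta(_start_theta(am, start))
    state = _System(am, _sigmas(blocks, theta, t))
    trace = [state.m2ll]
    converged = False
    it = 0
    lam_prev = 1.0
    last_delta_f = np.inf
    for it in range(1, max_iter + 1):
        grad_vc, AI, params = state.derivatives()
        J = _full_jacobian(blocks, theta, t)
        g = J.T @ grad_vc
        H = J.T @ (2.0 * AI) @ J
        H = 0.5 * (H + H.T)
        scale = max(np.abs(np.diagonal(H)).max(), 1e-12)
        accepted = False
        ridge = 0.0
        for attempt in range(4):
            try:
                step = np.linalg.solve(
                    H + (ridge + 1e-10 * scale) * np.eye(len(theta)), -g)
            except np.linalg.LinAlgError:
                step = -g / scale
            # trust region: near the variance floor the log-Cholesky surface
            # is almost flat and the AI step can be enormous
            biggest = np.max(np.abs(step))
            if biggest > 2.0:
                step = step * (2.0 / biggest)
            # remember the step fraction that worked last iteration to avoid
            # re-walking the halving ladder while the surface is still curved
            lam = min(1.0, 2.0 * lam_prev) if attempt == 0 else 1.0
            for _ in range(9):
                cand = clip_theta(theta + lam * step)
                try:
                    st = _System(am, _sigmas(blocks, cand, t))
                except np.linalg.LinAlgError:
                    lam *= 0.5
                    continue
                if st.m2ll <= state.m2ll + 1e-10:
                    accepted = True
                    lam_prev = lam
                    break
                lam *= 0.5
            if accepted:
                break
            ridge = scale if ridge == 0.0 else ridge * 10.0
            lam_prev = 1.0
        if not accepted:
            converged = bool(last_delta_f < 1e-6 * max(1.0, abs(state.m2ll)))
            break
        delta_f = state.m2ll - st.m2ll
        delta_x = np.max(np.abs(cand - theta))
        theta, state = cand, st
        trace.append(state.m2ll)
        if verbose:
            log.info("iter %d  -2logL=%.6f  |dx|=%.2e", it, state.m2ll, delta_x)
        if delta_f < tol and delta_x < tol:
            converged = True
            break
        # deviance flat on two consecutive iterations: parameters are
        # drifting along a likelihood ridge (typically at a variance floor)
        if delta_f < tol and last_delta_f < tol:
            converged = True
            break
        last_delta_f = delta_f

    sigmas = _sigmas(blocks, theta, t)
    boundary = any(
        np.diagonal(sigmas[b]).min() <= 1.05e-10 * am.varP.max()
        for b in blocks)
    grad_vc, AI, params = state.derivatives()
    try:
        cov_vc = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_vc = np.linalg.pinv(AI)
    se_map = {}
    for (term, r, c), v in zip(params, np.diagonal(cov_vc)):
        se_map.setdefault(term, np.zeros((t, t)))
        se = np.sqrt(max(v, 0.0))
        se_map[term][r, c] = se_map[term][c, r] = se

    return _finalize_fit(am, sigmas, se_map, state, converged, it,
                         boundary, trace)


def _sigmas(blocks, theta, t):
    npar = len(_vc_pairs(t))
    return {b: _sigma_from_theta(theta[i * npar:(i + 1) * npar], t)
            for i, b in enumerate(blocks)}


def _full_jacobian(blocks, theta, t):
    npar = len(_vc_pairs(t))
    J = np.zeros((len(blocks) * npar, len(blocks) * npar))
    for i in range(len(blocks)):
        off = i * npar
        J[off:off + npar, off:off + npar] = _jac_block(
            theta[off:off + npar], t)
    return J


def _term_blups(am: AssembledModel, sigmas: dict, w: np.ndarray,
                py: np.ndarray) -> dict:
    """Per-term random-effect solutions from w = Z' P y and P y."""
    t, n_c = am.n_traits, am.n_clones
    wm = w.reshape(t, n_c)
    out = {}
    for term in am.spec.terms:
        St = sigmas[term]
        if term in ("additive", "line"):
            K = am.clone_matrix(term)
            base = wm if K is None else (K @ wm.T).T
            vals = (St @ base.reshape(t, -1)).reshape(t, n_c).T
            out[term] = pd.DataFrame(vals, index=am.clone_ids,
                                     columns=list(am.spec.traits))
        elif term == "sca":
            base = np.asarray((am.S.T @ wm.T))           # n_sca x t
            out[term] = pd.DataFrame(base @ St.T, index=am.sca_levels,
                                     columns=list(am.spec.traits))
        elif term == "gxty":
            n_cell = len(am.cell_keys)
            acc = np.zeros((n_cell, t))
            np.add.at(acc, (am.obs_cell, am.obs_trait), py)
            out[term] = pd.DataFrame(
                acc @ St.T,
                index=pd.MultiIndex.from_tuples(am.cell_keys),
                columns=list(am.spec.traits))
    return out


def _finalize_fit(am, sigmas, se_map, state, converged, iterations,
                  boundary, trace) -> FitResult:
    t = am.n_traits
    blue_rows = []
    off = 0
    for ti in range(t):
        for j in am.keep_cols[ti]:
            blue_rows.append((am.spec.traits[ti], am.dcols[j],
                              state.sol[off]))
            off += 1
    blue = pd.DataFrame(blue_rows, columns=["trait", "effect", "estimate"])
    blup = _term_blups(am, sigmas, state.w, state.py)
    return FitResult(
        spec=am.spec,
        vc=dict(sigmas),
        vc_se={k: se_map.get(k, np.full((t, t), np.nan))
               for k in list(am.spec.terms) + ["residual"]},
        minus2logl=float(state.m2ll),
        blue=blue, blup=blup, converged=converged, iterations=iterations,
        boundary=boundary, n_obs=am.n_obs, loglik_trace=trace,
        design=am, w=state.w.copy(), py=state.py.copy(),
    )


def solve_mme(am: AssembledModel, vc: dict) -> FitResult:
    """Solve the mixed-model equations at fixed variance components
    (no REML iteration); used for cross-validation re-solves."""
    state = _System(am, vc, need_m2ll=False)
    t = am.n_traits
    se = {k: np.full((t, t), np.nan) for k in list(am.spec.terms) + ["residual"]}
    return _finalize_fit(am, vc, se, state, True, 0, False, [])


def predict_breeding_values(fit: FitResult, ids: Sequence) -> pd.DataFrame:
    """Additive-effect predictions for any pedigree members.

    Unphenotyped individuals are predicted through the relationship matrix:
    a_hat = (Sigma_a (x) A[ids, phenotyped]) Z' P y.
    """
    am = fit.design
    tk = am.kinship
    outside = [i for i in ids if i not in tk.index]
    if outside:
        # ids beyond the traced ancestor closure (e.g. descendants): rebuild
        # the relationship matrix over the union against the full pedigree
        missing = [i for i in outside if i not in am.pedigree_full.index]
        if missing:
            raise ModelError(f"ids not in pedigree: {missing[:5]}")
        traced = am.pedigree_full.trace(set(am.clone_ids) | set(ids))
        tk = build_amatrix(traced, am.spec.alpha)
    rows = np.asarray([tk.index[i] for i in ids])
    Asub = tk.A[np.ix_(rows, am.clone_pos)]              # ids x phenotyped
    t, n_c = am.n_traits, am.n_clones
    wm = fit.w.reshape(t, n_c)
    Sa = fit.vc["additive"]
    base = (Asub @ wm.T)                                 # ids x t
    return pd.DataFrame(base @ Sa.T, index=list(ids),
                        columns=list(am.spec.traits))
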