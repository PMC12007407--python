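"""Synthetic autotetraploid breeding programs.

Generates (i) multi-cycle pedigrees with overlapping generations and shared
parents, (ii) tetraploid genomes by gene dropping with double reduction,
(iii) plot-level phenotypes with additive, line, parent-pair (SCA),
genotype x trial x year and residual components with unstructured cross-trait
covariance, and (iv) a Monte-Carlo identity-by-descent oracle used to verify
the analytic relationship-matrix recursion.

Gamete model: with probability ``alpha`` the gamete carries two copies of one
uniformly chosen parental allele (double reduction); otherwise it carries two
distinct uniformly chosen parental alleles (random bivalent-style segregation
of the four homologues).  Loci are unlinked and exchangeable, so no linkage
map is tracked; the analysis touches genotypes only through IBD.

Additive trait values are polygenic: ``n_loci`` independent loci are gene
dropped and every founder allele at every locus receives an effect drawn
with covariance Sigma_a / (4 n_loci).  The additive value is the sum over
the four alleles at all loci, so its covariance is Sigma_a-scaled by the
realized IBD fractions averaged over loci, which converges to
A(alpha) (x) Sigma_a at rate 1/sqrt(n_loci).  A single-locus drop (the
``n_reps`` axis of :func:`gene_drop`) doubles as the Monte-Carlo IBD oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord


def _as_block(x, t: int) -> np.ndarray:
    """Coerce a scalar / (t,t) array to a (t,t) covariance block."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        x = np.eye(t) * float(x)
    if x.shape != (t, t):
        raise ValueError(f"covariance block has shape {x.shape}, expected {(t, t)}")
    if not np.allclose(x, x.T):
        raise ValueError("covariance block is not symmetric")
    w = np.linalg.eigvalsh(x)
    if w.min() < -1e-10 * max(1.0, abs(w).max()):
        raise ValueError("covariance block is not positive semidefinite")
    return x


def _chol_psd(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding program.

    Defaults emulate the structure of a multi-decade tetraploid potato
    program analysed for two correlated traits in a dry-matter-content /
    relative-yield-like regime: a large additive share with small SCA for
    trait 1, a more residual-dominated trait 2, replication heavily skewed
    toward single-trial testing (76% one trial, 14% two, 10% three), and a
    low double-reduction rate of 0.05.
    """

    n_founders: int = 50
    n_cycles: int = 14
    crosses_per_cycle: int = 20
    progeny_per_cross: int = 8
    selection_fraction: float = 0.2
    parent_window: int = 3          # parents drawn from this many previous cycles
    selfing_rate: float = 0.0
    first_year: int = 2000
    alpha_true: float = 0.05
    n_loci: int = 100               # unlinked loci behind the additive values
    trait_names: tuple = ("DMC", "RY")
    # per-term covariance blocks (scalar or (t,t)); DMC/RY-like regime
    vc_true: dict = field(default_factory=lambda: {
        "additive": np.array([[3.2, 4.9], [4.9, 83.3]]),
        "line": np.array([[0.2, 0.7], [0.7, 28.0]]),
        "gxty": np.array([[0.25, 0.6], [0.6, 35.0]]),
        "sca": np.array([[0.27, 0.3], [0.3, 7.5]]),
        "residual": np.array([[0.8, 1.2], [1.2, 186.0]]),
    })
    # fixed-effect standard deviations per trait
    trial_sd: tuple = (1.0, 8.0)
    year_sd: tuple = (0.5, 4.0)
    trial_year_sd: tuple = (0.5, 4.0)
    intercept: tuple = (23.5, 96.3)
    market_segments: tuple = ("table", "starch")
    trials_per_segment: int = 3
    # replication: P(number of trials a clone is tested in)
    trials_per_clone_probs: tuple = ((1, 0.76), (2, 0.14), (3, 0.10))
    two_plot_cell_prob: float = 0.35
    test_year_spread: int = 2       # test years drawn from crossing_year+2 .. +1+spread
    missing_rate: float = 0.04      # per-trait missing probability per plot
    seed: int = 0

    def __post_init__(self):
        t = len(self.trait_names)
        self.vc_true = {k: _as_block(v, t) for k, v in self.vc_true.items()}
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders")
        if not (0.0 < self.selection_fraction <= 1.0):
            raise ValueError("selection_fraction must be in (0, 1]")
        for name in ("trial_sd", "year_sd", "trial_year_sd", "intercept"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.size == 1:
                v = np.repeat(v, t)
            if v.size != t:
                raise ValueError(f"{name} must have one value per trait")
            setattr(self, name, tuple(v))

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def univariate_config(**kw) -> SimConfig:
    """A single-trait configuration in the trait-1 (dry-matter-like) regime."""
    base = dict(
        trait_names=("DMC",),
        vc_true={"additive": 3.2, "line": 0.2, "gxty": 0.25, "sca": 0.27,
                 "residual": 0.8},
        trial_sd=(1.0,), year_sd=(0.5,), trial_year_sd=(0.5,),
        intercept=(23.5,),
    )
    base.update(kw)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Ground truth of one simulated program (the recovery target)."""

    pedigree: Pedigree
    genomes: np.ndarray            # (n, n_loci, 4) founder-allele labels
    additive: pd.DataFrame         # true additive values, id x trait
    line_effects: pd.DataFrame
    sca_effects: pd.DataFrame      # indexed by unordered parent-pair key
    gxty_effects: pd.DataFrame     # indexed by (line, trial, year)
    fixed_effects: dict
    phenotypes: pd.DataFrame
    config: SimConfig


# ----------------------------------------------------------------------
# pedigree generation
# ----------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig, rng: Optional[np.random.Generator] = None
                      ) -> Pedigree:
    """Multi-cycle pedigree with overlapping generations and reused parents."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records = [PedigreeRecord(f"F{i:04d}") for i in range(cfg.n_founders)]
    by_cycle = {0: [r.id for r in records]}
    for cyc in range(1, cfg.n_cycles + 1):
        pool: list = []
        for back in range(1, cfg.parent_window + 1):
            pool.extend(by_cycle.get(cyc - back, []))
        if cyc <= cfg.parent_window:
            pool.extend(by_cycle[0])
        pool = sorted(set(pool))
        k = max(2, int(round(cfg.selection_fraction * len(pool))))
        parents = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        if len(parents) < 2:
            raise ValueError("selection_fraction yields fewer than 2 parents")
        year = cfg.first_year + cyc
        new_ids = []
        for c in range(cfg.crosses_per_cycle):
            if cfg.selfing_rate > 0 and rng.random() < cfg.selfing_rate:
                p1 = p2 = parents[rng.integers(len(parents))]
            else:
                i1, i2 = rng.choice(len(parents), size=2, replace=False)
                p1, p2 = parents[i1], parents[i2]
            for j in range(cfg.progeny_per_cross):
                cid = f"C{cyc:02d}_{c:03d}_{j:02d}"
                records.append(PedigreeRecord(cid, p1, p2, crossing_year=year))
                new_ids.append(cid)
        by_cycle[cyc] = new_ids
    return Pedigree(records)


# ----------------------------------------------------------------------
# gene dropping
# ----------------------------------------------------------------------

def _gametes_from_known(genomes: np.ndarray, alpha: float,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_reps, 4) parent genomes -> (n_reps, 2) gamete allele labels."""
    n = genomes.shape[0]
    dr = rng.random(n) < alpha
    i1 = rng.integers(0, 4, n)
    i2 = (i1 + 1 + rng.integers(0, 3, n)) % 4
    a = genomes[np.arange(n), i1]
    b = np.where(dr, a, genomes[np.arange(n), i2])
    return np.stack([a, b], axis=1)


def gene_drop(ped: Pedigree, alpha: float, seed=None, n_reps: int = 1
              ) -> np.ndarray:
    """Drop founder-allele labels down the pedigree.

    Returns an int64 array of shape ``(n_individuals, n_reps, 4)``.  Founders
    carry four unique labels.  An unknown parent behaves as an unrelated
    non-inbred individual in which double reduction still occurs, so its
    gamete is two fresh labels, identical with probability ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    out = np.zeros((n, n_reps, 4), dtype=np.int64)
    counter = 0

    def fresh_gamete():
        nonlocal counter
        dr = rng.random(n_reps) < alpha
        a = counter + 2 * np.arange(n_reps, dtype=np.int64)
        b = np.where(dr, a, a + 1)
        counter += 2 * n_reps
        return np.stack([a, b], axis=1)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            out[i] = counter + np.arange(4 * n_reps,
                                         dtype=np.int64).reshape(n_reps, 4)
            counter += 4 * n_reps
            continue
        g1 = _gametes_from_known(out[s], alpha, rng) if s >= 0 else fresh_gamete()
        g2 = _gametes_from_known(out[d], alpha, rng) if d >= 0 else fresh_gamete()
        out[i] = np.concatenate([g1, g2], axis=1)
    return out


def ibd_oracle(ped: Pedigree, alpha: float, pairs: Sequence[tuple],
               n_reps: int = 100_000, seed=None) -> pd.DataFrame:
    """Monte-Carlo estimates of A entries with standard errors.

    For an off-diagonal pair the per-replicate statistic is 4x the IBD
    fraction over the 16 ordered allele pairs; for a diagonal entry it is
    1 + 3x the IBD fraction over the 6 within-individual pairs.
    """
    genomes = gene_drop(ped, alpha, seed=seed, n_reps=n_reps)
    rows = []
    for id_i, id_j in pairs:
        i, j = ped.index[id_i], ped.index[id_j]
        gi = genomes[i]
        if i == j:
            m = np.zeros(n_reps, dtype=np.int64)
            for a in range(4):
                for b in range(a + 1, 4):
                    m += gi[:, a] == gi[:, b]
            stat = 1.0 + 3.0 * m / 6.0
        else:
            gj = genomes[j]
            m = (gi[:, :, None] == gj[:, None, :]).sum(axis=(1, 2))
            stat = 4.0 * m / 16.0
        rows.append((id_i, id_j, stat.mean(),
                     stat.std(ddof=1) / np.sqrt(n_reps)))
    return pd.DataFrame(rows, columns=["id_i", "id_j", "estimate", "se"])


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def sca_key(parent1: Optional[str], parent2: Optional[str], line_id: str) -> str:
    """Unordered parent-pair key; lines with an unknown parent get a
    singleton level keyed by their own id."""
    if parent1 is None or parent2 is None:
        return f"__solo__{line_id}"
    a, b = sorted((parent1, parent2))
    return f"{a}|{b}"


def simulate_phenotypes(ped: Pedigree, genomes: np.ndarray, cfg: SimConfig,
                        rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Phenotypes for all non-founder clones under the full covariance model.

    ``genomes`` is the output of :func:`gene_drop` with ``n_reps`` unlinked
    loci (shape (n, n_loci, 4)); a (n, 4) single-locus array is accepted.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    t = cfg.n_traits
    g = genomes.reshape(len(ped), -1, 4)       # (n, L, 4)
    n_loci = g.shape[1]

    # founder-allele effects, covariance Sigma_a / (4 n_loci) per allele
    n_labels = int(g.max()) + 1
    La = _chol_psd(cfg.vc_true["additive"] / (4.0 * n_loci))
    allele_eff = rng.standard_normal((n_labels, t)) @ La.T
    additive = allele_eff[g].sum(axis=(1, 2))  # (n, t)

    Lg = _chol_psd(cfg.vc_true["line"])
    Ls = _chol_psd(cfg.vc_true["sca"])
    Li = _chol_psd(cfg.vc_true["gxty"])
    Le = _chol_psd(cfg.vc_true["residual"])

    pheno_idx = [i for i in range(len(ped))
                 if ped.sire[i] >= 0 or ped.dam[i] >= 0]
    line_eff = {}
    sca_eff = {}
    gxty_eff = {}
    fixed = {"trial": {}, "year": {}, "trial_year": {}}
    trial_sd = np.asarray(cfg.trial_sd)
    year_sd = np.asarray(cfg.year_sd)
    ty_sd = np.asarray(cfg.trial_year_sd)
    intercept = np.asarray(cfg.intercept)

    def eff(store, key, sd):
        if key not in store:
            store[key] = rng.standard_normal(t) * sd
        return store[key]

    seg_trials = {s: [f"{s}_T{k + 1}" for k in range(cfg.trials_per_segment)]
                  for s in cfg.market_segments}
    n_choices = np.array([k for k, _ in cfg.trials_per_clone_probs])
    n_probs = np.array([p for _, p in cfg.trials_per_clone_probs])
    n_probs = n_probs / n_probs.sum()

    rows = []
    for i in pheno_idx:
        rec = ped.records[i]
        seg = cfg.market_segments[rng.integers(len(cfg.market_segments))]
        a_i = additive[i]
        g_i = line_eff.setdefault(rec.id, Lg @ rng.standard_normal(t))
        p1 = rec.parent1
        p2 = rec.parent2
        skey = sca_key(p1, p2, rec.id)
        s_i = sca_eff.setdefault(skey, Ls @ rng.standard_normal(t))
        cy = rec.crossing_year if rec.crossing_year is not None else cfg.first_year
        ntr = int(rng.choice(n_choices, p=n_probs))
        trials = list(rng.choice(seg_trials[seg], size=min(ntr, len(seg_trials[seg])),
                                 replace=False))
        for trial in trials:
            year = int(cy + 2 + rng.integers(cfg.test_year_spread))
            cell = (rec.id, trial, year)
            i_c = gxty_eff.setdefault(cell, Li @ rng.standard_normal(t))
            nplots = 2 if rng.random() < cfg.two_plot_cell_prob else 1
            mu = (intercept
                  + eff(fixed["trial"], trial, trial_sd)
                  + eff(fixed["year"], year, year_sd)
                  + eff(fixed["trial_year"], (trial, year), ty_sd))
            for _ in range(nplots):
                e = Le @ rng.standard_normal(t)
                y = mu + a_i + g_i + s_i + i_c + e
                vals = list(y)
                if t > 1 and cfg.missing_rate > 0:
                    miss = rng.random(t) < cfg.missing_rate
                    if miss.all():          # keep at least one trait per plot
                        miss[rng.integers(t)] = False
                    for k in range(t):
                        if miss[k]:
                            vals[k] = np.nan
                rows.append((rec.id, trial, year, seg, *vals))

    phen = pd.DataFrame(rows, columns=["line_id", "trial", "year",
                                       "market_segment", *cfg.trait_names])
    ids = [ped.records[i].id for i in pheno_idx]
    return SimTruth(
        pedigree=ped,
        genomes=g,
        additive=pd.DataFrame(additive, index=ped.ids,
                              columns=list(cfg.trait_names)),
        line_effects=pd.DataFrame([line_eff[i] for i in ids], index=ids,
                                  columns=list(cfg.trait_names)),
        sca_effects=pd.DataFrame.from_dict(sca_eff, orient="index",
                                           columns=list(cfg.trait_names)),
        gxty_effects=pd.DataFrame.from_dict(
            {"|".join(map(str, k)): v for k, v in gxty_eff.items()},
            orient="index", columns=list(cfg.trait_names)),
        fixed_effects=fixed,
        phenotypes=phen,
        config=cfg,
    )


def simulate_program(cfg: SimConfig) -> SimTruth:
    """Pedigree + gene drop at ``cfg.alpha_true`` + phenotypes, all from
    ``cfg.seed``; identical configs give bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    genomes = gene_drop(ped, cfg.alpha_true, seed=rng.integers(2 ** 31),
                        n_reps=cfg.n_loci)
    return simulate_phenotypes(ped, genomes, cfg, rng)
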