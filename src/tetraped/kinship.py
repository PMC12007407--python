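"""Autotetraploid numerator relationship matrices under double reduction.

Double reduction is the meiotic event in which the two alleles of a gamete
are copies of a single parental allele (sister chromatids migrating to the
same pole after multivalent pairing).  Its rate ``alpha`` inflates gametic
homozygosity and therefore inbreeding, so the pedigree relationship matrix A
becomes a function of ``alpha``.

Recursion (pedigree in topological order; Theta denotes kinship, i.e. the
probability that one random allele of i and one of j are identical by
descent; F the tetrasomic inbreeding coefficient, the IBD probability of two
distinct alleles of the same individual):

* self-kinship            phi_i   = 1/4 + (3/4) F_i
* within-gamete IBD       gamma_p = alpha + (1 - alpha) F_p  (alpha if p unknown)
* offspring i of s x d    F_i     = gamma_s/6 + gamma_d/6 + (2/3) kappa_sd
  with kappa_sd = Theta_sd for distinct known parents, phi_s for selfing,
  and 0 when either parent is unknown;
* Theta_ij = (Theta_sj + Theta_dj)/2 for earlier j (Theta_pj = 0 for an
  unknown p; Theta_sj = phi_s when j = s).

Reported on the founder-at-1 scale: A_ij = 4 Theta_ij, A_ii = 1 + 3 F_i.
Founders are non-inbred and mutually unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree


@dataclass
class TetraKinship:
    """Additive relationship matrix A and inbreeding F for one pedigree.

    ``A[i, j]`` is indexed by pedigree (topological) order; ``ids`` gives the
    order.  Diagonal entries equal ``1 + 3 F`` and the matrix is positive
    semidefinite for every ``alpha`` in [0, 1].
    """

    A: np.ndarray
    F: np.ndarray
    alpha: float
    ids: list
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {v: i for i, v in enumerate(self.ids)}

    @property
    def d_A(self) -> float:
        """Average diagonal of A (scales additive variance in heritability)."""
        return float(np.diagonal(self.A).mean())

    def submatrix(self, ids: Sequence) -> np.ndarray:
        idx = np.asarray([self.index[i] for i in ids])
        return self.A[np.ix_(idx, idx)]


def build_amatrix(pedigree: Pedigree, alpha: float) -> TetraKinship:
    """Build the tetraploid A matrix for one double-reduction rate.

    Parameters
    ----------
    pedigree : Pedigree
        Topologically ordered pedigree (guaranteed by the Pedigree class).
    alpha : float
        Double-reduction rate in [0, 1], applied genome-wide.
    """
    alpha = float(alpha)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"double-reduction rate must be in [0, 1], got {alpha}")
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    # K holds kinships with phi on the diagonal, so A = 4 K throughout.
    K = np.zeros((n, n))
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= i or d >= i:
            raise ValueError("pedigree is not topologically ordered")
        if s < 0 and d < 0:  # founder
            K[i, i] = 0.25
            continue
        gam_s = alpha + (1.0 - alpha) * F[s] if s >= 0 else alpha
        gam_d = alpha + (1.0 - alpha) * F[d] if d >= 0 else alpha
        kappa = K[s, d] if (s >= 0 and d >= 0) else 0.0  # K[s,s]=phi_s covers selfing
        F[i] = gam_s / 6.0 + gam_d / 6.0 + (2.0 / 3.0) * kappa
        row = np.zeros(i)
        if s >= 0:
            row += K[s, :i]
        if d >= 0:
            row += K[d, :i]
        row *= 0.5
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = 0.25 + 0.75 * F[i]
    return TetraKinship(A=4.0 * K, F=F, alpha=alpha, ids=pedigree.ids)


def amatrix_grid(pedigree: Pedigree, alphas: Sequence[float]) -> list:
    """One TetraKinship per alpha, identical individual order."""
    alphas = list(alphas)
    if not alphas:
        raise ValueError("empty alpha grid")
    return [build_amatrix(pedigree, a) for a in alphas]


def mean_diagonal(k: TetraKinship) -> float:
    """Arithmetic mean of the diagonal of A, d(A)."""
    return k.d_A


#: The 10-point double-reduction grid used for profile-likelihood scans.
DEFAULT_ALPHA_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def write_kinship(k: TetraKinship, triples_path, table_path, tol: float = 0.0):
    """Write lower-triangle nonzeros (row id, col id, value) and the per-id
    (id, F, A_ii) table as tab-separated text."""
    rows = []
    A = k.A
    for i in range(A.shape[0]):
        for j in range(i + 1):
            if abs(A[i, j]) > tol or i == j:
                rows.append((k.ids[i], k.ids[j], A[i, j]))
    pd.DataFrame(rows, columns=["row", "col", "value"]).to_csv(
        triples_path, sep="\t", index=False)
    pd.DataFrame({"id": k.ids, "F": k.F,
                  "A_ii": np.diagonal(A)}).to_csv(table_path, sep="\t",
                                                  index=False)


def read_kinship(triples_path, table_path) -> TetraKinship:
    """Read a kinship written by :func:`write_kinship` (alpha is not stored
    in the files and is recorded as nan)."""
    tab = pd.read_csv(table_path, sep="\t", dtype={"id": str})
    ids = tab["id"].tolist()
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    tri = pd.read_csv(triples_path, sep="\t", dtype={"row": str, "col": str})
    for r, c, v in tri.itertuples(index=False):
        i, j = index[r], index[c]
        A[i, j] = A[j, i] = v
    return TetraKinship(A=A, F=tab["F"].to_numpy(), alpha=float("nan"), ids=ids)
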