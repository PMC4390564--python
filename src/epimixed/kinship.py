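"""Epigenetic relationship matrix T, its sparse inverse, and parameter maps.

The transgenerational epigenetic effect w_i of an individual regresses on
each parental effect with coefficient lambda = (1 - v)/2, where v is the
reset coefficient (the expected fraction of epigenetic marks erased at
meiosis).  Stacking the recursion w = P w + eps gives

    V(w) = T sigma_w^2 = (I - P)^{-1} V(eps) (I - P')^{-1},

with V(eps) diagonal: sigma_w^2 for founders, (1 - lam^2) sigma_w^2 with
one known parent, (1 - 2 lam^2) sigma_w^2 with both known.  T has unit
diagonal whenever no mates are epigenetically related, interpolating
between I (lam = 0, total reset) and the numerator relationship matrix A
(lam = 1/2, no reset, non-inbred pedigree).

T^-1 is assembled in a single pedigree pass from per-individual rank-one
rules analogous to Henderson's rules for A^-1; only the numeric values
depend on lambda, the sparsity pattern is fixed by the pedigree, which is
what makes re-evaluation inside a Gibbs cycle cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import DENSE_CAP, UNKNOWN, Pedigree, _recursive_inverse_triplets

__all__ = [
    "EpiParams",
    "lambda_from_reset",
    "reset_from_lambda",
    "build_T",
    "build_T_inverse",
    "TInverseTemplate",
    "epi_residual_scales",
    "expected_relative_covariance",
    "variance_ratios",
]

RELATIONSHIPS = ("parent_offspring", "full_sibs", "half_sibs", "uncle_nephew")


def lambda_from_reset(v: float) -> float:
    """Autorecursive parameter lambda = (1 - v)/2 from the reset coefficient."""
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"reset coefficient v must be in [0, 1], got {v}")
    return (1.0 - v) / 2.0


def reset_from_lambda(lam: float) -> float:
    """Reset coefficient v = 1 - 2*lambda."""
    _check_lambda(lam)
    return 1.0 - 2.0 * lam


def _check_lambda(lam: float) -> None:
    if not 0.0 <= lam <= 0.5:
        raise ValueError(f"lambda must be in [0, 0.5], got {lam}")


@dataclass(frozen=True)
class EpiParams:
    """Coupled (lambda, v) pair; construct from either parameter."""

    lam: float

    def __post_init__(self):
        _check_lambda(self.lam)

    @property
    def v(self) -> float:
        return reset_from_lambda(self.lam)

    @classmethod
    def from_reset(cls, v: float) -> "EpiParams":
        return cls(lambda_from_reset(v))

    @property
    def transmission(self) -> float:
        """Epigenetic transmission coefficient 1 - v = 2*lambda."""
        return 1.0 - self.v


def epi_residual_scales(ped: Pedigree, lam: float) -> np.ndarray:
    """Diagonal of V(eps)/sigma_w^2: 1, 1-lam^2, or 1-2 lam^2 per individual."""
    _check_lambda(lam)
    n_known = (ped.sire != UNKNOWN).astype(float) + (ped.dam != UNKNOWN)
    return 1.0 - n_known * lam * lam


def build_T(ped: Pedigree, lam: float, cap: int = DENSE_CAP) -> np.ndarray:
    """Dense T = (I-P)^{-1} V(eps)/sigma_w^2 (I-P')^{-1} (small-n oracle)."""
    _check_lambda(lam)
    n = ped.n
    if n > cap:
        raise ValueError(f"dense T refused for n={n} > cap={cap}")
    P = np.zeros((n, n))
    for i in range(n):
        for p in (int(ped.sire[i]), int(ped.dam[i])):
            if p != UNKNOWN:
                P[i, p - 1] = lam
    L = np.linalg.inv(np.eye(n) - P)  # lower triangular by pedigree order
    return L @ np.diag(epi_residual_scales(ped, lam)) @ L.T


def _tinv_structure(ped: Pedigree):
    """Triplet (rows, cols, kind) encoding of the T^-1 rules.

    Kind codes index the per-lambda value table
    [1, d2, -lam*d2, lam^2*d2, d1, -lam*d1, lam^2*d1] with
    d2 = 1/(1-2 lam^2), d1 = 1/(1-lam^2), so the numeric refresh for a
    new lambda is a 7-entry table lookup plus one sparse aggregation.
    """
    rows, cols, kinds = [], [], []

    def add(i, j, k):
        rows.append(i)
        cols.append(j)
        kinds.append(k)
        if i != j:
            rows.append(j)
            cols.append(i)
            kinds.append(k)

    for i in range(ped.n):
        ps = [p - 1 for p in (int(ped.sire[i]), int(ped.dam[i])) if p != UNKNOWN]
        if len(ps) == 0:
            add(i, i, 0)
        elif len(ps) == 1:
            add(i, i, 4)
            add(i, ps[0], 5)
            add(ps[0], ps[0], 6)
        else:
            a, b = ps
            add(i, i, 1)
            add(i, a, 2)
            add(i, b, 2)
            add(a, a, 3)
            add(b, b, 3)
            add(a, b, 3)
    return (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64),
            np.asarray(kinds, dtype=np.int64))


def _tinv_value_table(lam: float) -> np.ndarray:
    _check_lambda(lam)
    d2 = 1.0 / (1.0 - 2.0 * lam * lam)
    d1 = 1.0 / (1.0 - lam * lam)
    return np.array(
        [1.0, d2, -lam * d2, lam * lam * d2, d1, -lam * d1, lam * lam * d1])


class TInverseTemplate:
    """Reusable sparse pattern for T^-1 on a fixed pedigree.

    The CSR pattern depends only on the pedigree; `values(lam)` refreshes
    the numeric entries for a new lambda without re-allocating, which the
    Gibbs sampler exploits every cycle.
    """

    def __init__(self, ped: Pedigree):
        from ._sparse import csr_slots

        self.ped = ped
        rows, cols, self._kinds = _tinv_structure(ped)
        n = ped.n
        coo = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        pattern = coo.tocsr()
        pattern.sum_duplicates()
        self.pattern = pattern
        slots = csr_slots(pattern, rows, cols)
        # aggregation: pattern-data vector = _agg @ per-triplet values
        self._agg = sp.csr_matrix(
            (np.ones(len(rows)), (slots, np.arange(len(rows)))),
            shape=(pattern.nnz, len(rows)))

    def values(self, lam: float, out: np.ndarray | None = None) -> np.ndarray:
        """CSR data vector of T^-1(lam) on the fixed pattern."""
        vals = self._agg @ _tinv_value_table(lam)[self._kinds]
        if out is None:
            return vals
        out[:] = vals
        return out

    def matrix(self, lam: float) -> sp.csr_matrix:
        M = self.pattern.copy()
        M.data = self.values(lam)
        return M


def _tinv_triplets(ped: Pedigree, lam: float):
    _check_lambda(lam)
    return _recursive_inverse_triplets(ped, lam)


def build_T_inverse(ped: Pedigree, lam: float) -> sp.csr_matrix:
    """Sparse T^-1 in one pedigree pass.

    Per individual i: with both parents known and d = 1/(1 - 2 lam^2),
    add d at (i,i), -lam*d at (i,sire) and (i,dam), lam^2*d at
    (sire,sire), (dam,dam) and (sire,dam); with one known parent p and
    d = 1/(1 - lam^2), add d at (i,i), -lam*d at (i,p), lam^2*d at (p,p);
    founders contribute 1 at (i,i).
    """
    rows, cols, vals = _tinv_triplets(ped, lam)
    n = ped.n
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


_EXPECTED_COV = {
    "parent_offspring": lambda su, sw, lam: 0.5 * su + lam * sw,
    "full_sibs": lambda su, sw, lam: 0.5 * su + 2.0 * lam**2 * sw,
    "half_sibs": lambda su, sw, lam: 0.25 * su + lam**2 * sw,
    "uncle_nephew": lambda su, sw, lam: 0.25 * su + 2.0 * lam**3 * sw,
}


def expected_relative_covariance(
    relationship: str, sigma_u2: float, sigma_w2: float, lam: float
) -> float:
    """Expected phenotypic covariance for a class of relatives.

    parent_offspring: su2/2 + lam*sw2;  full_sibs: su2/2 + 2 lam^2 sw2;
    half_sibs: su2/4 + lam^2 sw2;  uncle_nephew: su2/4 + 2 lam^3 sw2.
    Parent-offspring exceeds full sibs (and half sibs exceed
    uncle-nephew) for interior lambda, even though the additive
    relationships coincide — the epigenetic signature that identifies v.
    """
    if relationship not in _EXPECTED_COV:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}")
    if sigma_u2 < 0 or sigma_w2 < 0:
        raise ValueError("variances must be nonnegative")
    _check_lambda(lam)
    return _EXPECTED_COV[relationship](sigma_u2, sigma_w2, lam)


def variance_ratios(sigma_u2: float, sigma_w2: float, sigma_e2: float):
    """(h2, gamma2): additive and epigenetic fractions of phenotypic variance."""
    if min(sigma_u2, sigma_w2, sigma_e2) < 0:
        raise ValueError("variances must be nonnegative")
    tot = sigma_u2 + sigma_w2 + sigma_e2
    if tot == 0:
        raise ValueError("at least one variance component must be positive")
    return sigma_u2 / tot, sigma_w2 / tot
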