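"""Model specification and mixed-model-equation assembly.

The models handled here are Gaussian linear mixed models on pedigreed
populations,

    y = Xb + Z u + Z w + e            (epigenetic animal model)
    y = Xb + Z1 u + Z2 m + Z2 p + Z3 h + Z1 w + e   (generalized form)

with u additive genetic (covariance A sigma_u2), w transgenerational
epigenetic (covariance T(lambda) sigma_w2), optional maternal genetic m
correlated with u through a 2x2 matrix G, and any number of
identity-structured random terms (permanent environment, herd-year-season,
...).  The coefficient matrix of the mixed model equations,

    C = W'W + Sigma,   r = W'y,   W = [X  Z_1  Z_2 ...],

adds A^-1 * alpha to the u block (alpha = sigma_e2/sigma_u2),
T^-1 * psi to the w block (psi = sigma_e2/sigma_w2), sigma_e2/sigma_x2 on
the diagonal of identity-structured blocks, and sigma_e2 * G^{-1} kron
A^-1 to a correlated (u, m) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree

__all__ = [
    "FixedTerm",
    "RandomTerm",
    "CorrelatedPair",
    "ModelSpec",
    "PriorSpec",
    "GibbsConfig",
    "MMESystem",
    "build_mme",
]

STRUCTURES = ("iid", "additive", "epigenetic")


@dataclass(frozen=True)
class FixedTerm:
    """A categorical fixed effect, treatment-coded (first level dropped)."""

    label: str
    codes: np.ndarray  # record -> column index, -1 for the dropped level
    n_columns: int
    level_labels: tuple = ()


@dataclass(frozen=True)
class RandomTerm:
    label: str
    codes: np.ndarray  # record -> 0-based level index
    n_levels: int
    structure: str = "iid"
    level_labels: tuple = ()

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass(frozen=True)
class CorrelatedPair:
    """Direct + maternal genetic effects sharing pedigree structure A."""

    direct_label: str
    maternal_label: str
    direct_codes: np.ndarray   # record -> individual index (0-based)
    maternal_codes: np.ndarray  # record -> dam index (0-based)


@dataclass
class ModelSpec:
    """Response, design terms and covariance structures for one analysis."""

    y: np.ndarray
    pedigree: Pedigree | None = None
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)
    pair: CorrelatedPair | None = None
    intercept: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        needs_ped = self.pair is not None or any(
            t.structure in ("additive", "epigenetic") for t in self.random
        )
        if needs_ped and self.pedigree is None:
            raise ValueError("pedigree-structured terms require a pedigree")
        for t in self.random:
            if t.structure in ("additive", "epigenetic") and t.n_levels != self.pedigree.n:
                raise ValueError(
                    f"term {t.label!r}: pedigree-structured terms must have one "
                    f"level per individual")
        if sum(t.structure == "epigenetic" for t in self.random) > 1:
            raise ValueError("at most one epigenetic term")

    @property
    def ndat(self) -> int:
        return len(self.y)

    @property
    def epigenetic_term(self) -> RandomTerm | None:
        for t in self.random:
            if t.structure == "epigenetic":
                return t
        return None

    @classmethod
    def from_frame(
        cls,
        data: pd.DataFrame,
        pedigree: Pedigree | None = None,
        response: str = "y",
        individual: str = "individual",
        fixed: tuple = (),
        iid: tuple = (),
        maternal: str | None = None,
        additive: bool = True,
        epigenetic: bool = True,
    ) -> "ModelSpec":
        """Assemble a spec from a records table.

        `individual` names the column of pedigree ids carrying the direct
        genetic (and epigenetic) effects; `maternal` optionally names a
        column of dam ids, turning (u, m) into a correlated pair;
        `fixed` and `iid` name categorical columns.
        """
        y = data[response].to_numpy(dtype=float)
        fixed_terms = []
        for col in fixed:
            codes, levels = pd.factorize(data[col], sort=True)
            if codes.min() < 0:
                raise ValueError(f"missing values in fixed factor {col!r}")
            fixed_terms.append(
                FixedTerm(col, codes - 1, len(levels) - 1, tuple(levels)))
        random_terms = []
        pair = None
        ind_codes = None
        if additive or epigenetic or maternal:
            if pedigree is None:
                raise ValueError("genetic terms require a pedigree")
            ind_codes = np.array(
                [pedigree.internal_id(v) - 1 for v in data[individual]])
        if maternal is not None:
            mat_codes = np.array(
                [pedigree.internal_id(v) - 1 for v in data[maternal]])
            pair = CorrelatedPair("u", "m", ind_codes, mat_codes)
        elif additive:
            random_terms.append(RandomTerm("u", ind_codes, pedigree.n, "additive"))
        if epigenetic:
            random_terms.append(RandomTerm("w", ind_codes, pedigree.n, "epigenetic"))
        for col in iid:
            codes, levels = pd.factorize(data[col], sort=True)
            if codes.min() < 0:
                raise ValueError(f"missing values in grouping column {col!r}")
            random_terms.append(
                RandomTerm(col, codes, len(levels), "iid", tuple(levels)))
        return cls(y=y, pedigree=pedigree, fixed=fixed_terms,
                   random=random_terms, pair=pair)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the conjugate priors.

    Each variance sigma_x2 has a scaled inverse-chi-square prior with
    scale s2 and degrees of belief n; (s2=0, n=-2) is the flat improper
    prior on the variance.  A correlated (u, m) pair takes an
    inverse-Wishart IW(n_G, G0); (n_G=-3, G0=0) is flat.  The prior on
    lambda is fixed: uniform on (0, 0.5).
    """

    variances: dict = field(default_factory=dict)  # label -> (s2, n)
    n_G: float = -3.0
    G0: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def for_term(self, label: str) -> tuple:
        s2, n = self.variances.get(label, (0.0, -2.0))
        if s2 < 0:
            raise ValueError(f"prior scale for {label!r} must be >= 0")
        return float(s2), float(n)


@dataclass(frozen=True)
class GibbsConfig:
    """Chain protocol. Defaults are desk-scale; paper-scale runs set
    n_iter=1_250_000, burn_in=250_000, thin=1."""

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = 0
    lambda_update: str = "paper_tn"  # or "metropolis_exact"
    store_effects: bool = False
    store_fitted: bool = False
    fix_lambda: float | None = None  # hold lambda constant (no update)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lambda_update not in ("paper_tn", "metropolis_exact"):
            raise ValueError(f"unknown lambda_update {self.lambda_update!r}")
        if self.fix_lambda is not None and not 0.0 <= self.fix_lambda <= 0.5:
            raise ValueError("fix_lambda must be in [0, 0.5]")


@dataclass
class MMESystem:
    """Assembled mixed model equations C s = r with current state s."""

    C: sp.csr_matrix
    r: np.ndarray
    s: np.ndarray
    W: sp.csr_matrix                 # record-by-equation design
    blocks: dict                     # label -> slice into the equations
    ratios: dict                     # label -> sigma_e2 / sigma_x2

    @property
    def n_equations(self) -> int:
        return len(self.r)


def design_matrix(spec: ModelSpec) -> tuple[sp.csr_matrix, dict]:
    """Sparse W = [X | Z-blocks] and the label -> equation-slice map."""
    ndat = spec.ndat
    cols = []
    blocks = {}
    pos = 0
    if spec.intercept:
        cols.append(sp.csr_matrix(np.ones((ndat, 1))))
        blocks["intercept"] = slice(0, 1)
        pos = 1
    for t in spec.fixed:
        mask = t.codes >= 0
        Z = sp.coo_matrix(
            (np.ones(mask.sum()), (np.nonzero(mask)[0], t.codes[mask])),
            shape=(ndat, t.n_columns)).tocsr()
        cols.append(Z)
        blocks[t.label] = slice(pos, pos + t.n_columns)
        pos += t.n_columns
    if spec.pair is not None:
        n = spec.pedigree.n
        for label, codes in (
            (spec.pair.direct_label, spec.pair.direct_codes),
            (spec.pair.maternal_label, spec.pair.maternal_codes),
        ):
            Z = sp.coo_matrix(
                (np.ones(ndat), (np.arange(ndat), codes)), shape=(ndat, n)
            ).tocsr()
            cols.append(Z)
            blocks[label] = slice(pos, pos + n)
            pos += n
    for t in spec.random:
        Z = sp.coo_matrix(
            (np.ones(ndat), (np.arange(ndat), t.codes)),
            shape=(ndat, t.n_levels)).tocsr()
        cols.append(Z)
        blocks[t.label] = slice(pos, pos + t.n_levels)
        pos += t.n_levels
    W = sp.hstack(cols, format="csr")
    return W, blocks


def _offset(M: sp.spmatrix, i: int, j: int, n: int) -> sp.coo_matrix:
    M = M.tocoo()
    return sp.coo_matrix((M.data, (M.row + i, M.col + j)), shape=(n, n))


def prior_precision(
    spec: ModelSpec,
    blocks: dict,
    n_eq: int,
    variances: dict,
    A_inv: sp.spmatrix | None,
    T_inv: sp.spmatrix | None,
) -> sp.coo_matrix:
    """Sigma: the variance-ratio-scaled prior precision added to W'W.

    `variances` maps term labels to sigma_x2, 'e' to sigma_e2, and 'G' to
    the 2x2 genetic covariance matrix for a correlated pair.
    """
    se2 = variances["e"]
    parts = []
    for t in spec.random:
        sx2 = variances[t.label]
        if sx2 <= 0:
            raise ValueError(
                f"term {t.label!r}: zero/negative variance gives a degenerate "
                f"variance ratio")
        ratio = se2 / sx2
        sl = blocks[t.label]
        if t.structure == "iid":
            base = sp.identity(t.n_levels, format="coo")
        elif t.structure == "additive":
            base = A_inv
        else:
            base = T_inv
        if base is None:
            raise ValueError(f"term {t.label!r} needs its structure matrix")
        parts.append(_offset(base * ratio, sl.start, sl.start, n_eq))
    if spec.pair is not None:
        G = np.asarray(variances["G"], dtype=float)
        Ginv = np.linalg.inv(G)
        su = blocks[spec.pair.direct_label]
        sm = blocks[spec.pair.maternal_label]
        offs = {(0, 0): (su.start, su.start), (0, 1): (su.start, sm.start),
                (1, 0): (sm.start, su.start), (1, 1): (sm.start, sm.start)}
        for (a, b), (i, j) in offs.items():
            parts.append(_offset(A_inv * (se2 * Ginv[a, b]), i, j, n_eq))
    if not parts:
        return sp.coo_matrix((n_eq, n_eq))
    return sum(parts[1:], start=parts[0])


def build_mme(
    spec: ModelSpec,
    variances: dict,
    A_inv: sp.spmatrix | None = None,
    T_inv: sp.spmatrix | None = None,
) -> MMESystem:
    """Assemble C s = r at the given variance components.

    One-shot assembly for direct use and testing; the Gibbs engine uses an
    incremental workspace that refreshes only the numeric values.
    """
    W, blocks = design_matrix(spec)
    n_eq = W.shape[1]
    C0 = (W.T @ W).tocoo()
    Sigma = prior_precision(spec, blocks, n_eq, variances, A_inv, T_inv)
    C = (C0 + Sigma).tocsr()
    r = W.T @ spec.y
    ratios = {
        t.label: variances["e"] / variances[t.label] for t in spec.random
    }
    return MMESystem(C=C, r=r, s=np.zeros(n_eq), W=W, blocks=blocks,
                     ratios=ratios)
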