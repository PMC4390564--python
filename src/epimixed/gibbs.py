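"""Gibbs sampler for the epigenetic mixed model.

One cycle updates, in fixed order: all location effects by single-site
sweeps over the mixed model equations; lambda from its truncated-normal
full conditional on (0, 0.5) (or by an exact Metropolis-within-Gibbs
step); the values of T^-1, which depend on lambda; and every variance
component from its scaled inverse-chi-square (or inverse-Wishart for a
correlated genetic pair) full conditional.

The coefficient matrix C is never re-allocated: its sparsity pattern is
the union of W'W, A^-1, T^-1 and the identity blocks, fixed once, and
only the numeric data vector is refreshed each cycle.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.special import ndtr, ndtri

from ._sparse import csr_slots
from ._sweep import gauss_seidel_sample
from .diagnostics import PosteriorSamples
from .kinship import TInverseTemplate
from .model import GibbsConfig, MMESystem, ModelSpec, PriorSpec, design_matrix
from .pedigree import UNKNOWN, Pedigree, build_A_inverse

__all__ = [
    "sample_location",
    "sample_lambda",
    "sample_variance",
    "sample_G",
    "run_gibbs",
]

_LAM_INIT = 0.25
_TINY_PRECISION = 1e-300


def sample_location(sys: MMESystem, sigma_e2: float, rng) -> np.ndarray:
    """One full single-site sweep; updates and returns sys.s in place."""
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    C = sys.C
    z = rng.standard_normal(sys.n_equations)
    gauss_seidel_sample(C.indptr, C.indices, C.data, sys.r, sys.s, z, sigma_e2)
    return sys.s


def _lambda_groups(ped: Pedigree):
    """(child, sire, dam) index triples split by parent-knowledge class."""
    s, d = ped.sire, ped.dam
    both = np.nonzero((s != UNKNOWN) & (d != UNKNOWN))[0]
    only = np.nonzero((s != UNKNOWN) ^ (d != UNKNOWN))[0]
    parent_of_only = np.where(s[only] != UNKNOWN, s[only], d[only]) - 1
    return both, s[both] - 1, d[both] - 1, only, parent_of_only


def _tn_params(w, groups, sigma_w2, lam_ref):
    """Mean/sd of the truncated-normal conditional, (1 - k lam^2) factors
    evaluated at lam_ref.  Returns None when the data carry no information
    (zero precision)."""
    i_b, f_b, m_b, i_s, p_s = groups
    den_b = 1.0 - 2.0 * lam_ref * lam_ref
    den_s = 1.0 - lam_ref * lam_ref
    sw = w[f_b] + w[m_b]
    a = np.dot(sw, sw) / den_b
    b = np.dot(sw, w[i_b]) / den_b
    if len(i_s):
        wp = w[p_s]
        a += np.dot(wp, wp) / den_s
        b += np.dot(wp, w[i_s]) / den_s
    prec = a / sigma_w2
    if not np.isfinite(prec) or prec < _TINY_PRECISION:
        return None
    return b / a, 1.0 / np.sqrt(prec)


def _log_conditional(lam, w, groups, sigma_w2):
    """Exact log full conditional of lambda (up to a constant) on [0, 0.5]."""
    i_b, f_b, m_b, i_s, p_s = groups
    den_b = 1.0 - 2.0 * lam * lam
    den_s = 1.0 - lam * lam
    res_b = w[i_b] - lam * (w[f_b] + w[m_b])
    out = -0.5 * (
        len(i_b) * np.log(den_b) + np.dot(res_b, res_b) / (den_b * sigma_w2))
    if len(i_s):
        res_s = w[i_s] - lam * w[p_s]
        out -= 0.5 * (
            len(i_s) * np.log(den_s) + np.dot(res_s, res_s) / (den_s * sigma_w2))
    return out


def _tn_rvs(mu, sd, rng):
    """Inverse-CDF truncated-normal draw on [0, 0.5]; scipy fallback for
    far-tail cases where the plain CDF difference underflows."""
    a, b = (0.0 - mu) / sd, (0.5 - mu) / sd
    fa, fb = ndtr(a), ndtr(b)
    if fb - fa > 1e-12:
        return float(mu + sd * ndtri(fa + rng.uniform() * (fb - fa)))
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def sample_lambda(
    w: np.ndarray,
    ped: Pedigree,
    sigma_w2: float,
    current_lam: float,
    rng,
    mode: str = "paper_tn",
) -> float:
    """Draw lambda given the epigenetic effects.

    `paper_tn` draws directly from the truncated-normal conditional with
    the (1 - k lam^2) factors frozen at `current_lam` (the published
    scheme).  `metropolis_exact` uses that truncated normal as a proposal
    and accepts/rejects against the exact conditional, which keeps the
    lambda-dependence of the residual epigenetic variances.
    """
    lam, _ = _sample_lambda(w, ped, sigma_w2, current_lam, rng, mode)
    return lam


def _sample_lambda(w, ped, sigma_w2, current_lam, rng, mode):
    if sigma_w2 <= 0:
        raise ValueError("sigma_w2 must be positive")
    groups = _lambda_groups(ped)
    if len(groups[0]) + len(groups[3]) == 0:
        warnings.warn("pedigree has no non-founders; lambda is unidentifiable, "
                      "drawing from its uniform prior")
        return float(rng.uniform(0.0, 0.5)), True
    params = _tn_params(w, groups, sigma_w2, current_lam)
    if params is None:
        return float(rng.uniform(0.0, 0.5)), True
    if mode == "paper_tn":
        return _tn_rvs(*params, rng), True
    if mode != "metropolis_exact":
        raise ValueError(f"unknown lambda mode {mode!r}")
    prop = _tn_rvs(*params, rng)
    lp_prop = _log_conditional(prop, w, groups, sigma_w2)
    lp_cur = _log_conditional(current_lam, w, groups, sigma_w2)
    mu, sd = params
    a, b = -mu / sd, (0.5 - mu) / sd
    log_q_prop = stats.truncnorm.logpdf(prop, a, b, loc=mu, scale=sd)
    rev = _tn_params(w, groups, sigma_w2, prop)
    if rev is None:
        log_q_rev = np.log(2.0)
    else:
        mu_r, sd_r = rev
        log_q_rev = stats.truncnorm.logpdf(
            current_lam, -mu_r / sd_r, (0.5 - mu_r) / sd_r, loc=mu_r, scale=sd_r)
    log_alpha = lp_prop - lp_cur + log_q_rev - log_q_prop
    if np.log(rng.uniform()) < log_alpha:
        return float(prop), True
    return float(current_lam), False


def sample_variance(
    quadratic: float, count: int, prior_s2: float, prior_n: float, rng
) -> float:
    """Scaled inverse-chi-square draw: (quadratic + s2) / chi2(count + n)."""
    df = count + prior_n
    if df <= 0:
        raise ValueError(
            f"nonpositive posterior degrees of freedom ({count} + {prior_n}); "
            f"the scaled inverse-chi-square is improper")
    if quadratic < 0:
        raise ValueError("quadratic form must be nonnegative")
    return float((quadratic + prior_s2) / rng.chisquare(df))


def sample_G(
    u: np.ndarray, m: np.ndarray, A_inv: sp.spmatrix, prior: PriorSpec, rng
) -> np.ndarray:
    """Inverse-Wishart draw for the 2x2 direct/maternal genetic covariance."""
    nan = len(u)
    if len(m) != nan:
        raise ValueError("u and m must have equal length")
    df = nan + prior.n_G
    if df <= 1:
        raise ValueError("posterior Wishart degrees of freedom must exceed 1")
    Au = A_inv @ u
    Am = A_inv @ m
    scale = np.array([[u @ Au, u @ Am], [u @ Am, m @ Am]]) + prior.G0
    # guard: the quadratic-form matrix must be PD for the draw to exist
    if np.linalg.eigvalsh(scale).min() <= 0:
        raise np.linalg.LinAlgError("inverse-Wishart scale matrix not PD")
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


class GibbsWorkspace:
    """Precomputed structures for fast per-cycle refresh of C."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.W, self.blocks = design_matrix(spec)
        self.n_eq = self.W.shape[1]
        ped = spec.pedigree
        self.A_inv = build_A_inverse(ped) if ped is not None and (
            spec.pair is not None
            or any(t.structure == "additive" for t in spec.random)
        ) else None
        self.t_template = (
            TInverseTemplate(ped) if spec.epigenetic_term is not None else None)

        C0 = (self.W.T @ self.W).tocoo()
        parts = [C0]
        comps = []  # (kind, label/None, rows, cols, vals or None)
        for t in spec.random:
            sl = self.blocks[t.label]
            if t.structure == "iid":
                idx = np.arange(sl.start, sl.stop)
                comps.append(("scaled", t.label, idx, idx,
                              np.ones(t.n_levels)))
            elif t.structure == "additive":
                A = self.A_inv.tocoo()
                comps.append(("scaled", t.label, A.row + sl.start,
                              A.col + sl.start, A.data))
            else:
                P = self.t_template.pattern.tocoo()
                comps.append(("tinv", t.label, P.row + sl.start,
                              P.col + sl.start, None))
        if spec.pair is not None:
            A = self.A_inv.tocoo()
            su = self.blocks[spec.pair.direct_label].start
            sm = self.blocks[spec.pair.maternal_label].start
            for (a, b), (i, j) in {(0, 0): (su, su), (0, 1): (su, sm),
                                   (1, 0): (sm, su), (1, 1): (sm, sm)}.items():
                comps.append(("pair", (a, b), A.row + i, A.col + j, A.data))
        for kind, lab, rows, cols, vals in comps:
            parts.append(sp.coo_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(self.n_eq, self.n_eq)))
        U = sum(parts[1:], start=parts[0]).tocsr()
        U.sum_duplicates()
        self.C = U
        self.base_data = np.zeros(U.nnz)
        c0slots = csr_slots(U, C0.row, C0.col)
        np.add.at(self.base_data, c0slots, C0.data)
        self.components = []
        for kind, lab, rows, cols, vals in comps:
            slots = csr_slots(U, rows, cols)
            # slots within one component are unique (canonical CSR source),
            # allowing fast fancy-indexed accumulation per cycle
            if len(np.unique(slots)) != len(slots):
                raise AssertionError("duplicate slots in prior component")
            self.components.append((kind, lab, slots, vals))
        self.r = self.W.T @ spec.y
        self.s = np.zeros(self.n_eq)
        # standalone T^-1 with refreshable data, for w' T^-1 w
        self.T_cur = (self.t_template.pattern.copy()
                      if self.t_template is not None else None)
        self._t_vals = (np.zeros(self.T_cur.nnz)
                        if self.T_cur is not None else None)

    def set_lambda(self, lam: float) -> None:
        if self.t_template is None:
            return
        self.t_template.values(lam, out=self._t_vals)
        self.T_cur.data = self._t_vals

    def refresh_C(self, variances: dict) -> None:
        """Recompute C.data from W'W plus ratio-scaled prior precisions."""
        se2 = variances["e"]
        data = self.base_data.copy()
        Ginv = None
        if self.spec.pair is not None:
            Ginv = np.linalg.inv(np.asarray(variances["G"], dtype=float))
        for kind, lab, slots, vals in self.components:
            if kind == "scaled":
                data[slots] += (se2 / variances[lab]) * vals
            elif kind == "tinv":
                data[slots] += (se2 / variances[lab]) * self._t_vals
            else:
                a, b = lab
                data[slots] += (se2 * Ginv[a, b]) * vals
        self.C.data = data

    def system(self, variances: dict) -> MMESystem:
        self.refresh_C(variances)
        ratios = {t.label: variances["e"] / variances[t.label]
                  for t in self.spec.random}
        return MMESystem(C=self.C, r=self.r, s=self.s, W=self.W,
                         blocks=self.blocks, ratios=ratios)


def _init_variances(spec: ModelSpec) -> dict:
    vy = max(float(np.var(spec.y)), 1e-8)
    k = len(spec.random) + (2 if spec.pair is not None else 0) + 1
    variances = {"e": vy / 2.0}
    for t in spec.random:
        variances[t.label] = vy / (2.0 * k)
    if spec.pair is not None:
        g = vy / (2.0 * k)
        variances["G"] = np.array([[g, 0.0], [0.0, g]])
    return variances


def run_gibbs(
    spec: ModelSpec, priors: PriorSpec, config: GibbsConfig
) -> PosteriorSamples:
    """Run the full sampler and return stored draws of every scalar unknown.

    Stored columns: one per fixed-effect equation, one per variance
    component (sigma2_u, sigma2_w, sigma2_e, ... and sigma2_m/sigma_um
    for a correlated pair), and, when an epigenetic term is present,
    lambda, the reset coefficient v = 1 - 2*lambda, the transmission
    coefficient 1 - v, plus the per-cycle variance ratios h2 (and gamma2,
    m2 as applicable) computed draw-by-draw.
    """
    rng = np.random.default_rng(config.seed)
    ws = GibbsWorkspace(spec)
    ped = spec.pedigree
    epi = spec.epigenetic_term
    variances = _init_variances(spec)
    if config.fix_lambda is not None:
        lam = config.fix_lambda
    else:
        lam = _LAM_INIT if epi is not None else 0.0
    ws.set_lambda(lam)

    store_iters = range(config.burn_in, config.n_iter, config.thin)
    n_store = len(store_iters)
    cols = _column_labels(spec, ws)
    draws = np.empty((n_store, len(cols)))
    fitted = np.empty((n_store, spec.ndat)) if config.store_fitted else None
    effects = (
        {t.label: np.empty((n_store, t.n_levels)) for t in spec.random}
        if config.store_effects else None)
    if config.store_effects and spec.pair is not None:
        effects[spec.pair.direct_label] = np.empty((n_store, ped.n))
        effects[spec.pair.maternal_label] = np.empty((n_store, ped.n))

    n_fixed_eq = ws.blocks[_last_fixed_label(spec)].stop
    s_sum = np.zeros(ws.n_eq)
    accept = 0
    n_lambda = 0
    k_store = 0
    next_store = config.burn_in
    y = spec.y
    for it in range(config.n_iter):
        sysm = ws.system(variances)
        sample_location(sysm, variances["e"], rng)
        s = ws.s
        if epi is not None and config.fix_lambda is None:
            w = s[ws.blocks[epi.label]]
            lam, acc = _sample_lambda(
                w, ped, variances[epi.label], lam, rng, config.lambda_update)
            accept += acc
            n_lambda += 1
            ws.set_lambda(lam)
        for t in spec.random:
            block = s[ws.blocks[t.label]]
            if t.structure == "iid":
                quad = float(block @ block)
            elif t.structure == "additive":
                quad = float(block @ (ws.A_inv @ block))
            else:
                quad = float(block @ (ws.T_cur @ block))
            s2, n_pr = priors.for_term(t.label)
            variances[t.label] = sample_variance(quad, t.n_levels, s2, n_pr, rng)
        if spec.pair is not None:
            u = s[ws.blocks[spec.pair.direct_label]]
            m = s[ws.blocks[spec.pair.maternal_label]]
            variances["G"] = sample_G(u, m, ws.A_inv, priors, rng)
        resid = y - ws.W @ s
        s2e, ne = priors.for_term("e")
        variances["e"] = sample_variance(
            float(resid @ resid), spec.ndat, s2e, ne, rng)
        if not all(np.all(np.isfinite(np.atleast_1d(v)))
                   for v in variances.values()):
            raise RuntimeError(
                f"non-finite variance draw at cycle {it}: {variances}")
        if it == next_store:
            draws[k_store] = _scalar_row(spec, ws, variances, lam, n_fixed_eq)
            s_sum += s
            if fitted is not None:
                fitted[k_store] = y - resid
            if effects is not None:
                for lab, arr in effects.items():
                    arr[k_store] = s[ws.blocks[lab]]
            k_store += 1
            next_store = config.burn_in + k_store * config.thin
    meta = {
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "seed": config.seed,
        "lambda_update": config.lambda_update,
        "lambda_acceptance": accept / n_lambda if n_lambda else None,
        "ndat": spec.ndat,
    }
    return PosteriorSamples(
        draws=pd.DataFrame(draws[:k_store], columns=cols),
        fitted=fitted[:k_store] if fitted is not None else None,
        effects=effects,
        location_mean=s_sum / max(k_store, 1),
        blocks=dict(ws.blocks),
        meta=meta,
    )


def _last_fixed_label(spec: ModelSpec) -> str:
    lab = "intercept" if spec.intercept else None
    if spec.fixed:
        lab = spec.fixed[-1].label
    if lab is None:
        raise ValueError("model needs at least an intercept or one fixed term")
    return lab


def _column_labels(spec: ModelSpec, ws: GibbsWorkspace) -> list:
    cols = []
    if spec.intercept:
        cols.append("b:intercept")
    for t in spec.fixed:
        # first level dropped (treatment coding)
        for lev in t.level_labels[1:]:
            cols.append(f"b:{t.label}={lev}")
    if spec.pair is not None:
        cols += ["sigma2_u", "sigma2_m", "sigma_um"]
    for t in spec.random:
        cols.append(f"sigma2_{t.label}")
    cols.append("sigma2_e")
    epi = spec.epigenetic_term
    cols.append("h2")
    if spec.pair is not None:
        cols.append("m2")
    if epi is not None:
        cols += ["gamma2", "lambda", "v", "one_minus_v"]
    return cols


def _scalar_row(spec, ws, variances, lam, n_fixed_eq):
    row = list(ws.s[:n_fixed_eq])
    total = variances["e"]
    if spec.pair is not None:
        G = variances["G"]
        row += [G[0, 0], G[1, 1], G[0, 1]]
        total += G[0, 0] + G[1, 1]
        su2 = G[0, 0]
    for t in spec.random:
        row.append(variances[t.label])
        total += variances[t.label]
        if t.structure == "additive":
            su2 = variances[t.label]
    row.append(variances["e"])
    if spec.pair is None and not any(
            t.structure == "additive" for t in spec.random):
        su2 = 0.0
    row.append(su2 / total)
    if spec.pair is not None:
        row.append(variances["G"][1, 1] / total)
    epi = spec.epigenetic_term
    if epi is not None:
        row.append(variances[epi.label] / total)
        row += [lam, 1.0 - 2.0 * lam, 2.0 * lam]
    return row
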