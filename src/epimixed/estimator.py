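"""scikit-learn style estimator wrapping the Gibbs sampler.

`EpigeneticMixedModel` fits the Bayesian animal model with an optional
transgenerational epigenetic term to a records table.  The pedigree is a
structural hyperparameter (set in the constructor); `fit(X, y)` takes a
DataFrame of record-level covariates (individual id, fixed-effect
factors, grouping ids) and the phenotype vector.  Fitted state lives in
trailing-underscore attributes, so the estimator composes with sklearn
clone/get_params machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .diagnostics import log_cpo, summarize
from .gibbs import run_gibbs
from .model import GibbsConfig, ModelSpec, PriorSpec
from .pedigree import Pedigree

__all__ = ["EpigeneticMixedModel"]


class EpigeneticMixedModel(BaseEstimator):
    """Bayesian pedigree mixed model with transgenerational epigenetic term.

    Parameters
    ----------
    pedigree : Pedigree
        Genealogy providing the additive (A) and epigenetic (T(lambda))
        covariance structures.
    fixed : tuple of str
        Names of categorical fixed-effect columns in X (an intercept is
        always included; factors are treatment-coded).
    iid : tuple of str
        Names of grouping columns fitted as identity-structured random
        effects (e.g. permanent environment, herd-year-season).
    individual : str
        Column of X holding the pedigree id of each record.
    maternal : str or None
        Optional column of dam ids; when set, direct and maternal genetic
        effects form a correlated pair with a 2x2 covariance G under an
        inverse-Wishart prior.
    additive, epigenetic : bool
        Include the additive genetic term u and/or the epigenetic term w.
    priors : PriorSpec or None
        Defaults to flat priors on every variance (s2=0, n=-2; n_G=-3,
        G0=0); lambda is always uniform on (0, 0.5).
    n_iter, burn_in, thin : int
        Chain protocol (total cycles, discarded cycles, storage stride).
    lambda_update : {"paper_tn", "metropolis_exact"}
        Truncated-normal conditional with residual scales frozen at the
        current lambda, or an exact Metropolis-within-Gibbs step.
    store_effects, store_fitted : bool
        Keep per-draw effect vectors / per-draw location predictions
        (the latter enables `log_cpo_`).
    random_state : int
        Seed for the single chain stream.

    Attributes
    ----------
    samples_ : PosteriorSamples
    summary_ : DataFrame with PM, PSD and HPD95 per scalar parameter
    posterior_mean_ : dict of parameter -> posterior mean
    log_cpo_ : float (only when store_fitted=True)
    """

    def __init__(
        self,
        pedigree: Pedigree | None = None,
        *,
        fixed: tuple = (),
        iid: tuple = (),
        individual: str = "individual",
        maternal: str | None = None,
        additive: bool = True,
        epigenetic: bool = True,
        priors: PriorSpec | None = None,
        n_iter: int = 120_000,
        burn_in: int = 20_000,
        thin: int = 5,
        lambda_update: str = "paper_tn",
        store_effects: bool = False,
        store_fitted: bool = False,
        random_state: int = 0,
    ):
        self.pedigree = pedigree
        self.fixed = fixed
        self.iid = iid
        self.individual = individual
        self.maternal = maternal
        self.additive = additive
        self.epigenetic = epigenetic
        self.priors = priors
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.lambda_update = lambda_update
        self.store_effects = store_effects
        self.store_fitted = store_fitted
        self.random_state = random_state

    def _build_spec(self, X: pd.DataFrame, y) -> ModelSpec:
        data = X.copy()
        data["__response__"] = np.asarray(y, dtype=float)
        return ModelSpec.from_frame(
            data,
            pedigree=self.pedigree,
            response="__response__",
            individual=self.individual,
            fixed=tuple(self.fixed),
            iid=tuple(self.iid),
            maternal=self.maternal,
            additive=self.additive,
            epigenetic=self.epigenetic,
        )

    def fit(self, X: pd.DataFrame, y):
        """Run the Gibbs sampler on the records in X with responses y."""
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y disagree on the number of records")
        spec = self._build_spec(X, y)
        config = GibbsConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            lambda_update=self.lambda_update,
            store_effects=self.store_effects,
            store_fitted=self.store_fitted,
        )
        priors = self.priors if self.priors is not None else PriorSpec()
        self.spec_ = spec
        self.samples_ = run_gibbs(spec, priors, config)
        self.summary_ = summarize(self.samples_)
        self.posterior_mean_ = dict(
            zip(self.summary_["parameter"], self.summary_["PM"]))
        if self.store_fitted:
            self.log_cpo_ = log_cpo(self.samples_, y)
        self.n_records_ = len(y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean location prediction for records described by X.

        Individuals must belong to the fitted pedigree; unseen levels of
        fixed factors or grouping columns contribute zero (they carry no
        information in the fit).
        """
        if not hasattr(self, "samples_"):
            raise NotFittedError("call fit before predict")
        spec = self.spec_
        mu = self.samples_.location_mean
        blocks = self.samples_.blocks
        yhat = np.zeros(len(X))
        if spec.intercept:
            yhat += mu[blocks["intercept"]][0]
        for t in spec.fixed:
            sl = blocks[t.label]
            index = {lev: k - 1 for k, lev in enumerate(t.level_labels)}
            for r, val in enumerate(X[t.label]):
                k = index.get(val, -1)
                if k >= 0:
                    yhat[r] += mu[sl][k]
        ped = spec.pedigree
        if spec.pair is not None:
            for label, col in ((spec.pair.direct_label, self.individual),
                               (spec.pair.maternal_label, self.maternal)):
                sl = blocks[label]
                idx = np.array([ped.internal_id(v) - 1 for v in X[col]])
                yhat += mu[sl][idx]
        for t in spec.random:
            sl = blocks[t.label]
            if t.structure in ("additive", "epigenetic"):
                idx = np.array(
                    [ped.internal_id(v) - 1 for v in X[self.individual]])
                yhat += mu[sl][idx]
            else:
                index = {lev: k for k, lev in enumerate(t.level_labels)}
                for r, val in enumerate(X[t.label]):
                    k = index.get(val, -1)
                    if k >= 0:
                        yhat[r] += mu[sl][k]
        return yhat
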