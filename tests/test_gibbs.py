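import numpy as np
import pandas as pd
import pytest

from epimixed import (
    EpigeneticMixedModel,
    GibbsConfig,
    PriorSpec,
    run_gibbs,
)
from epimixed.diagnostics import effective_sample_size
from epimixed.gibbs import sample_lambda, sample_location, sample_variance
from epimixed.kinship import build_T
from epimixed.model import ModelSpec, RandomTerm, build_mme
from epimixed.pedigree import build_A_inverse, build_A_tabular
from epimixed.kinship import build_T_inverse
from epimixed.simulate import preset, simulate_population

from conftest import layered_pedigree


def fit_sim(sim, seed=0, **kw):
    X = sim.phenotype_frame()
    est = EpigeneticMixedModel(pedigree=sim.pedigree, random_state=seed, **kw)
    return est.fit(X, X["y"])


class TestRunGibbs:
    def test_deterministic_given_seed(self):
        sim = simulate_population(
            preset("dataset1", n_base=60, n_families=30, family_size=2, seed=1))
        a = fit_sim(sim, seed=5, n_iter=800, burn_in=200, thin=2)
        b = fit_sim(sim, seed=5, n_iter=800, burn_in=200, thin=2)
        pd.testing.assert_frame_equal(a.samples_.draws, b.samples_.draws)

    def test_different_seeds_differ(self):
        sim = simulate_population(
            preset("dataset1", n_base=60, n_families=30, family_size=2, seed=1))
        a = fit_sim(sim, seed=5, n_iter=400, burn_in=100, thin=2)
        b = fit_sim(sim, seed=6, n_iter=400, burn_in=100, thin=2)
        assert not a.samples_.draws.equals(b.samples_.draws)

    def test_no_w_model_reduces_to_animal_model(self):
        """Without the epigenetic term the sampler is a standard animal
        model; on sigma_w2=0 data the true h2 falls inside HPD95 and the
        posterior mean is near the large-sample GLS value."""
        sim = simulate_population(
            preset("dataset1", n_base=500, n_families=250, family_size=4,
                   sigma_w2=0.0, seed=2))
        est = fit_sim(sim, seed=3, epigenetic=False,
                      n_iter=6000, burn_in=1500, thin=5)
        assert "lambda" not in est.samples_.draws.columns
        assert "sigma2_w" not in est.samples_.draws.columns
        row = est.summary_.set_index("parameter")
        h2_true = 210.0 / 480.0
        assert row.loc["h2", "HPD95_low"] <= h2_true <= row.loc["h2", "HPD95_high"]

    def test_lambda_fixed_at_zero_stable(self):
        """lambda = 0 makes T = I: u and w are separated only by structure
        vs residual; the sampler must stay finite over 10^4 cycles."""
        sim = simulate_population(
            preset("dataset2", n_base=80, n_families=40, family_size=2, seed=3))
        spec = ModelSpec(
            y=sim.phenotypes, pedigree=sim.pedigree,
            random=[
                RandomTerm("u", np.arange(sim.pedigree.n), sim.pedigree.n,
                           "additive"),
                RandomTerm("w", np.arange(sim.pedigree.n), sim.pedigree.n,
                           "epigenetic"),
            ])
        out = run_gibbs(spec, PriorSpec(),
                        GibbsConfig(n_iter=10_000, burn_in=1000, thin=10,
                                    seed=4, fix_lambda=0.0))
        assert np.isfinite(out.draws.to_numpy()).all()
        assert (out.draws["lambda"] == 0.0).all()

    def test_permutation_equivariance(self):
        """Relabeling/shuffling pedigree ids leaves posterior summaries
        unchanged up to Monte Carlo error."""
        cfg = preset("dataset1", n_base=200, n_families=100, family_size=3,
                     seed=5)
        sim = simulate_population(cfg)
        X = sim.phenotype_frame()
        est_a = fit_sim(sim, seed=7, n_iter=6000, burn_in=1500, thin=5)
        # shuffle record order and relabel ids by an affine map
        perm = np.random.default_rng(0).permutation(len(X))
        from epimixed.pedigree import Pedigree
        relabel = {lab: 10 * lab + 3 for lab in sim.pedigree.labels}
        recs = []
        for i in range(sim.pedigree.n):
            s, d = int(sim.pedigree.sire[i]), int(sim.pedigree.dam[i])
            recs.append((
                relabel[sim.pedigree.labels[i]],
                relabel[sim.pedigree.labels[s - 1]] if s else 0,
                relabel[sim.pedigree.labels[d - 1]] if d else 0))
        ped_b = Pedigree.from_records(recs)
        Xb = X.iloc[perm].reset_index(drop=True)
        Xb["individual"] = [relabel[v] for v in Xb["individual"]]
        est_b = EpigeneticMixedModel(
            pedigree=ped_b, random_state=7, n_iter=6000, burn_in=1500, thin=5
        ).fit(Xb, Xb["y"])
        for col in ("sigma2_u", "sigma2_w", "sigma2_e", "lambda"):
            xa = est_a.samples_.draws[col].to_numpy()
            xb = est_b.samples_.draws[col].to_numpy()
            se = np.sqrt(
                xa.var() / effective_sample_size(xa)
                + xb.var() / effective_sample_size(xb))
            assert abs(xa.mean() - xb.mean()) < 5 * se, col

    def test_generalized_model_with_maternal_pair(self):
        """Extended model with correlated direct/maternal genetic effects,
        a permanent-environment term and a herd term: chains stay finite,
        the G draws are SPD, and all derived ratios are reported."""
        rng = np.random.default_rng(12)
        sim = simulate_population(
            preset("dataset2", n_base=100, n_families=80, family_size=3,
                   seed=13))
        ped = sim.pedigree
        df = sim.phenotype_frame()
        mask = ped.dam != 0
        df = df[mask].reset_index(drop=True)
        df["dam_id"] = ped.labels[ped.dam[mask] - 1]
        df["herd"] = rng.integers(0, 8, len(df))
        df["sex"] = rng.integers(0, 2, len(df))
        est = EpigeneticMixedModel(
            pedigree=ped, fixed=("sex",), iid=("herd",), maternal="dam_id",
            n_iter=1500, burn_in=400, thin=5, random_state=14,
        ).fit(df, df["y"])
        d = est.samples_.draws
        assert {"sigma2_u", "sigma2_m", "sigma_um", "sigma2_herd",
                "sigma2_w", "m2", "b:sex=1"} <= set(d.columns)
        assert np.isfinite(d.to_numpy()).all()
        # per-draw G = [[su2, sum], [sum, sm2]] positive definite
        det = d["sigma2_u"] * d["sigma2_m"] - d["sigma_um"] ** 2
        assert (det > 0).all()
        # predictions cover new-ordering input
        yhat = est.predict(df.head(5))
        assert np.isfinite(yhat).all()

    def test_divergence_guard_configuration_error(self):
        sim = simulate_population(
            preset("dataset1", n_base=20, n_families=10, family_size=2, seed=6))
        X = sim.phenotype_frame()
        est = EpigeneticMixedModel(
            pedigree=sim.pedigree,
            priors=PriorSpec(variances={"e": (0.0, -200.0)}),
            n_iter=100, burn_in=10, thin=1)
        with pytest.raises(ValueError, match="degrees of freedom"):
            est.fit(X, X["y"])


class TestJointCalibration:
    def test_successive_conditional_simulation(self):
        """Geweke-style joint check on a 30-individual model with proper
        priors: moments of (sigma2_u, sigma2_w, sigma2_e, lambda) from the
        successive-conditional chain (location sweep + exact Metropolis
        lambda + variance conditionals + data regeneration) agree with
        direct prior sampling."""
        rng = np.random.default_rng(42)
        ped = layered_pedigree(10, 2, 10, rng, single_parent_frac=0.2)
        n = ped.n  # 30
        A = build_A_tabular(ped)
        La = np.linalg.cholesky(A)
        Ai = build_A_inverse(ped)
        priors = dict(u=(3.0, 10.0), w=(3.0, 10.0), e=(6.0, 10.0))

        def prior_draw(rng):
            su2 = priors["u"][0] / rng.chisquare(priors["u"][1])
            sw2 = priors["w"][0] / rng.chisquare(priors["w"][1])
            se2 = priors["e"][0] / rng.chisquare(priors["e"][1])
            lam = rng.uniform(0, 0.5)
            return su2, sw2, se2, lam

        def draw_effects(su2, sw2, lam, rng):
            u = La @ rng.standard_normal(n) * np.sqrt(su2)
            T = build_T(ped, lam)
            w = np.linalg.cholesky(T) @ rng.standard_normal(n) * np.sqrt(sw2)
            return u, w

        # marginal-conditional: direct prior draws
        m_draws = []
        for _ in range(20_000):
            su2, sw2, se2, lam = prior_draw(rng)
            m_draws.append((su2, sw2, se2, lam))
        m_draws = np.array(m_draws)

        # successive-conditional chain
        su2, sw2, se2, lam = prior_draw(rng)
        u, w = draw_effects(su2, sw2, lam, rng)
        codes = np.arange(n)
        s_draws = np.empty((30_000, 4))
        for k in range(s_draws.shape[0]):
            y = u + w + rng.normal(0, np.sqrt(se2), n)
            spec = ModelSpec(y=y, pedigree=ped, intercept=False, random=[
                RandomTerm("u", codes, n, "additive"),
                RandomTerm("w", codes, n, "epigenetic")])
            sysm = build_mme(spec, {"u": su2, "w": sw2, "e": se2},
                             Ai, build_T_inverse(ped, lam))
            sysm.s[:n] = u
            sysm.s[n:] = w
            sample_location(sysm, se2, rng)
            u, w = sysm.s[:n].copy(), sysm.s[n:].copy()
            lam = sample_lambda(w, ped, sw2, lam, rng, mode="metropolis_exact")
            Ti = build_T_inverse(ped, lam)
            su2 = sample_variance(float(u @ (Ai @ u)), n, *priors["u"], rng)
            sw2 = sample_variance(float(w @ (Ti @ w)), n, *priors["w"], rng)
            resid = y - u - w
            se2 = sample_variance(float(resid @ resid), n, *priors["e"], rng)
            s_draws[k] = (su2, sw2, se2, lam)

        for j, name in enumerate(["sigma2_u", "sigma2_w", "sigma2_e", "lambda"]):
            for f in (lambda x: x, np.log if name != "lambda" else np.square):
                a = f(m_draws[:, j])
                b = f(s_draws[:, j])
                se = np.sqrt(a.var() / len(a)
                             + b.var() / effective_sample_size(b))
                z = (a.mean() - b.mean()) / se
                assert abs(z) < 4.0, (name, f.__name__, z)
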