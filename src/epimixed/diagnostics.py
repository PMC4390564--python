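"""Posterior summaries, convergence checks, and LogCPO model comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "PosteriorSamples",
    "SummaryRow",
    "summarize",
    "hpd_interval",
    "effective_sample_size",
    "geweke_z",
    "convergence_diagnostics",
    "log_cpo",
    "compare_log_cpo",
]


@dataclass
class PosteriorSamples:
    """Stored MCMC draws plus the ingredients for predictive densities.

    draws: one row per stored cycle, one labelled column per scalar
    unknown.  `fitted` (optional) holds the per-cycle location
    predictions for every record, which together with the sigma2_e column
    is what the conditional predictive ordinate needs.
    """

    draws: pd.DataFrame
    fitted: np.ndarray | None = None
    effects: dict | None = None
    location_mean: np.ndarray | None = None
    blocks: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return len(self.draws)

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        return cls(draws=pd.read_csv(path))


@dataclass(frozen=True)
class SummaryRow:
    label: str
    pm: float        # posterior mean
    psd: float       # posterior standard deviation
    hpd_low: float
    hpd_high: float


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `prob` of the draws (empirical HPD)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    k = max(int(np.ceil(prob * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def summarize(samples: PosteriorSamples, prob: float = 0.95) -> pd.DataFrame:
    """PM, PSD and HPD bounds per stored scalar parameter."""
    if samples.n_stored < 50:
        warnings.warn("fewer than 50 stored draws; HPD bounds are unstable")
    rows = []
    for col in samples.draws.columns:
        x = samples.draws[col].to_numpy()
        lo, hi = hpd_interval(x, prob)
        psd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        if psd == 0.0:
            warnings.warn(f"constant chain for {col!r}; degenerate HPD")
        rows.append(SummaryRow(col, float(x.mean()), psd, lo, hi))
    return pd.DataFrame(
        [(r.label, r.pm, r.psd, r.hpd_low, r.hpd_high) for r in rows],
        columns=["parameter", "PM", "PSD", "HPD95_low", "HPD95_high"],
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial-monotone-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    if np.dot(x, x) == 0:
        return float(n)
    # FFT autocorrelations
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real
    rho = acov / acov[0]
    # Geyer: pair sums Gamma_m = rho_{2m} + rho_{2m+1}; keep the initial
    # positive monotone-decreasing sequence; tau = 2*sum(Gamma) - 1
    k = (n - 1) // 2
    gamma = rho[0 : 2 * k : 2] + rho[1 : 2 * k + 1 : 2]
    pos = gamma > 0
    stop = int(np.argmin(pos)) if not pos.all() else len(gamma)
    if stop == 0:
        return float(n)
    gamma = np.minimum.accumulate(gamma[:stop])
    tau = max(2.0 * float(gamma.sum()) - 1.0, 1e-8)
    return float(n / tau)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence score: z of mean(first 10%) - mean(last 50%),
    variances adjusted by the effective sample size of each segment."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    va = a.var(ddof=1) / effective_sample_size(a)
    vb = b.var(ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def convergence_diagnostics(
    samples: PosteriorSamples, z_warn: float = 3.0, ess_warn: float = 100.0
) -> pd.DataFrame:
    """Advisory per-parameter report: Geweke z and effective sample size."""
    if samples.n_stored < 100:
        warnings.warn("fewer than 100 stored draws; diagnostics unreliable")
    rows = []
    for col in samples.draws.columns:
        x = samples.draws[col].to_numpy()
        z = geweke_z(x)
        ess = effective_sample_size(x)
        status = "ok"
        if abs(z) > z_warn:
            status = "warn:geweke"
        elif ess < ess_warn:
            status = "warn:ess"
        rows.append((col, z, ess, status))
    return pd.DataFrame(rows, columns=["parameter", "geweke_z", "ess", "status"])


def log_cpo(samples: PosteriorSamples, y: np.ndarray) -> float:
    """Pseudo-log-marginal probability of the data.

    For each datum, the conditional predictive ordinate is the harmonic
    mean over stored draws of the observation density
    N(y_i; fitted_i(theta_j), sigma2_e(theta_j)):

        CPO_i = Ns / sum_j 1 / p(y_i | theta_j),   LogCPO = sum_i ln CPO_i,

    computed with log-sum-exp stabilization.  Larger is better.
    """
    if samples.fitted is None:
        raise ValueError(
            "samples lack stored location predictions; rerun with "
            "store_fitted=True")
    y = np.asarray(y, dtype=float)
    fitted = samples.fitted
    ns, ndat = fitted.shape
    if len(y) != ndat:
        raise ValueError("y length does not match stored predictions")
    se2 = samples.draws["sigma2_e"].to_numpy()[:, None]
    logp = -0.5 * (np.log(2.0 * np.pi * se2) + (y[None, :] - fitted) ** 2 / se2)
    # log CPO_i = log Ns - logsumexp_j(-logp_ij)
    log_cpo_i = np.log(ns) - logsumexp(-logp, axis=0)
    return float(np.sum(log_cpo_i))


def compare_log_cpo(results: dict, y: np.ndarray) -> pd.DataFrame:
    """LogCPO per fitted model; the highest value is flagged preferred."""
    rows = [(name, log_cpo(s, y)) for name, s in results.items()]
    df = pd.DataFrame(rows, columns=["model", "LogCPO"])
    df["preferred"] = df["LogCPO"] == df["LogCPO"].max()
    return df.sort_values("LogCPO", ascending=False, ignore_index=True)
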