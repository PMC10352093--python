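"""Convergence, goodness-of-fit and posterior-summary diagnostics.

* Gelman-Rubin potential scale reduction (classical two-stage, non-split;
  gate at 1.05 for full fits, 1.1 for rarefied refits).
* Posterior-predictive Bayesian p-value on per-individual encounter totals
  with a Freeman-Tukey discrepancy; models are rejected when p falls
  outside (0.15, 0.85).
* Shortest-window highest-posterior-density intervals.
* Pairwise posterior correlations as a parameter-redundancy screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from secrsearch.sampler import GibbsSampler, PosteriorSamples

__all__ = [
    "gelman_rubin", "hpd_interval", "bayesian_p_value",
    "parameter_redundancy", "DiagnosticsReport", "diagnose", "summary_table",
    "RHAT_FULL", "RHAT_RAREFIED", "GOF_LO", "GOF_HI",
]

RHAT_FULL = 1.05
RHAT_RAREFIED = 1.1
GOF_LO, GOF_HI = 0.15, 0.85


@dataclass
class DiagnosticsReport:
    rhat: dict
    bayesian_p: float | None
    gof_pass: bool | None
    hpd: dict
    pairwise_corr: pd.DataFrame
    redundant_pairs: list
    converged: bool

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "bayesian_p": self.bayesian_p,
            "gof_pass": self.gof_pass,
            "hpd": {k: list(v) for k, v in self.hpd.items()},
            "redundant_pairs": self.redundant_pairs,
            "converged": self.converged,
        }


def gelman_rubin(chains, split: bool = False) -> float:
    """Classical (non-split) potential scale reduction factor.

    ``chains`` is an (m, n) array of m >= 2 chains with n >= 2 draws each.
    ``split=True`` halves each chain first (the split-chain variant).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs at least two chains")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    m, n = chains.shape
    if n < 2:
        raise ValueError("each chain needs at least two draws")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        if B == 0:
            return 1.0
        warnings.warn("zero within-chain variance: degenerate chains")
        return np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def hpd_interval(draws, mass: float = 0.95) -> tuple:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws.

    Ties are broken toward the smallest lower endpoint.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))       # first minimum -> smallest lower endpoint
    return float(x[i]), float(x[i + k - 1])


def _cell_probs(prep: GibbsSampler, draw) -> tuple:
    """Per-included-individual detection probabilities over active cells.

    Returns ``(pi, e_obs)`` with ``pi`` of shape (n_included, C).
    """
    p = draw.params
    inc = np.flatnonzero(draw.z)
    male = draw.sex[inc].astype(float)
    sig2 = np.where(male == 1, p.sigma_m, p.sigma_f)[:, None] ** 2
    effpow = prep.cell_eff ** p.beta_eff
    if prep.spec.spatial:
        d2 = prep.D2[np.ix_(draw.s[inc], prep.cell_j)]
    else:
        d2 = np.zeros((len(inc), len(prep.cell_j)))
    h = p.lambda0 * np.exp(p.beta_sex * male)[:, None] * effpow[None, :] \
        * np.exp(-d2 / (2.0 * sig2))
    pi = -np.expm1(-h)
    e_obs = np.zeros(len(inc))
    e_obs[inc < prep.n] = prep.obs_encounters[inc[inc < prep.n]]
    return pi, e_obs


def _freeman_tukey(e, expected) -> float:
    return float(np.sum((np.sqrt(e) - np.sqrt(expected)) ** 2))


def bayesian_p_value(samples: PosteriorSamples, ch, effort, space, spec,
                     n_rep: int = 100, rng=None) -> float:
    """Posterior-predictive p-value on individual encounter totals.

    For each of ``n_rep`` retained latent snapshots, a replicate capture
    tensor is simulated from that draw's parameters and latent state and the
    Freeman-Tukey discrepancy ``sum_i (sqrt(e_i) - sqrt(E[e_i]))^2`` over
    included individuals is compared between replicate and observed data.
    """
    if n_rep < 50:
        warnings.warn("n_rep < 50 gives an unstable Bayesian p-value")
    if rng is None:
        rng = np.random.default_rng(0)
    prep = GibbsSampler(spec, ch, effort, space, samples.config)
    latents = [d for chain in samples.latents for d in chain]
    if not latents:
        raise ValueError("no latent snapshots stored in PosteriorSamples")
    idx = np.resize(np.arange(len(latents)), n_rep)
    exceed = 0
    for ix in idx:
        draw = latents[ix]
        pi, e_obs = _cell_probs(prep, draw)
        expected = pi.sum(axis=1)
        t_obs = _freeman_tukey(e_obs, expected)
        e_rep = (rng.random(pi.shape) < pi).sum(axis=1)
        t_rep = _freeman_tukey(e_rep, expected)
        exceed += t_rep >= t_obs
    return exceed / n_rep


def parameter_redundancy(samples: PosteriorSamples, threshold: float = 0.9):
    """Pairwise posterior correlations; |rho| above threshold is flagged."""
    names = [p for p in samples.param_names if np.std(samples.draws(p)) > 0]
    if len(names) < 2:
        raise ValueError("need at least two varying parameters")
    mat = np.corrcoef(np.vstack([samples.draws(p) for p in names]))
    corr = pd.DataFrame(mat, index=names, columns=names)
    flagged = [(a, b, float(corr.loc[a, b]))
               for i, a in enumerate(names) for b in names[i + 1:]
               if abs(corr.loc[a, b]) > threshold]
    return corr, flagged


def summary_table(samples: PosteriorSamples, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean / SD / HPD bounds for every sampled parameter."""
    rows = []
    for p in samples.param_names:
        d = samples.draws(p)
        lo, hi = hpd_interval(d, mass)
        rows.append({"parameter": p, "mean": d.mean(), "sd": d.std(ddof=1),
                     "hpd_lower": lo, "hpd_upper": hi})
    return pd.DataFrame(rows)


def diagnose(samples: PosteriorSamples, ch=None, effort=None, space=None,
             n_rep: int = 100, rng=None, rhat_threshold: float = RHAT_FULL,
             corr_threshold: float = 0.9) -> DiagnosticsReport:
    """Full diagnostics bundle for one fitted model."""
    rhat = {}
    for p in samples.param_names:
        chains = samples.get(p)
        if chains.shape[0] >= 2 and np.std(chains) > 0:
            rhat[p] = gelman_rubin(chains)
    hpd = {p: hpd_interval(samples.draws(p)) for p in samples.param_names}
    corr, flagged = parameter_redundancy(samples, corr_threshold)
    bp = gof = None
    if ch is not None:
        bp = bayesian_p_value(samples, ch, effort, space, samples.spec,
                              n_rep=n_rep, rng=rng)
        gof = GOF_LO < bp < GOF_HI
    converged = bool(rhat) and all(v < rhat_threshold for v in rhat.values())
    return DiagnosticsReport(rhat=rhat, bayesian_p=bp, gof_pass=gof, hpd=hpd,
                             pairwise_corr=corr, redundant_pairs=flagged,
                             converged=converged)
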