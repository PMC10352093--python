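"""Metropolis-within-Gibbs sampler for the augmented SECR model.

Per sweep: random-walk Metropolis on the continuous detection parameters
(log scale for lambda0 and the sigmas), Gibbs draws for the inclusion
indicators z and the sexes of augmented individuals, a masked
uniform-disc Metropolis move for activity centres, and conjugate Beta
draws for psi / psi_sex.  Multiple chains are run from overdispersed
starting points with independent seeded streams; identical inputs, seed
and configuration reproduce the samples bit for bit.

The per-sweep likelihood work is organised around the identity

    sum_k effort_jk^beta  ->  w_j,

so each evaluation costs O(n_included x J) instead of O(M x J x K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from secrsearch.ingest import CaptureHistory, EffortMatrix, StateSpace
from secrsearch.model import (
    ModelSpec, DetectionParams, Priors, ModelError, apply_effort_floor,
)

__all__ = ["SamplerConfig", "PosteriorSamples", "ChainState", "GibbsSampler",
           "run", "metropolis_step"]


@dataclass
class SamplerConfig:
    n_iter: int = 31000
    burn_in: int = 1000
    n_chains: int = 4
    thin: int = 1
    seed: int = 0
    M: int = 200
    proposal_scales: dict = field(default_factory=lambda: {
        "log_lambda0": 0.15, "beta_eff": 0.1, "beta_sex": 0.2,
        "log_sigma_f": 0.1, "log_sigma_m": 0.1,
    })
    adapt: bool = True
    extra_discard: int = 0          # post-hoc additional discard, per chain
    latent_every: int = 25          # store (z, sex, s, params) snapshots
    effort_floor_km: float = 0.1
    s_proposal_sigmas: float = 3.0  # activity-centre proposal radius, in sigmas
    prior_normal_sd: float = 10.0

    def validate(self, n_detected: int) -> None:
        if self.n_iter <= self.burn_in:
            raise ModelError("n_iter must exceed burn_in")
        if self.burn_in < 0 or self.n_chains < 1 or self.thin < 1:
            raise ModelError("invalid sampler configuration")
        if self.M <= n_detected:
            raise ModelError(f"augmented size M={self.M} must exceed n={n_detected}")


@dataclass
class LatentDraw:
    params: DetectionParams
    z: np.ndarray
    sex: np.ndarray
    s: np.ndarray


@dataclass
class PosteriorSamples:
    """Retained posterior draws, per chain, plus latent-state snapshots."""

    chains: list                   # list of {param: np.ndarray of draws}
    pixel_counts: list             # per chain (P,) summed z=1 centre tallies
    n_draws: list                  # retained draws per chain
    latents: list                  # per chain list[LatentDraw]
    acceptance: list               # per chain {param: rate}
    spec: ModelSpec
    config: SamplerConfig
    n_detected: int
    space_area_km2: float
    n_pixels: int

    @property
    def param_names(self) -> list:
        return list(self.chains[0].keys())

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter as a (n_chains, n_draws) array."""
        return np.stack([c[name] for c in self.chains])

    def draws(self, name: str) -> np.ndarray:
        """All chains pooled into a flat vector."""
        return np.concatenate([c[name] for c in self.chains])

    def save(self, outdir) -> None:
        """Write draws, pixel tallies, latent snapshots and a manifest as text."""
        import json
        import os

        import pandas as pd

        os.makedirs(outdir, exist_ok=True)
        for c, chain in enumerate(self.chains):
            pd.DataFrame(chain).to_csv(
                os.path.join(outdir, f"draws_chain{c}.csv"), index=False)
        pd.DataFrame({f"chain{c}": pc for c, pc in enumerate(self.pixel_counts)}) \
            .to_csv(os.path.join(outdir, "pixel_counts.csv"), index=False)
        lat = []
        for c, chain in enumerate(self.latents):
            for d in chain:
                lat.append({"chain": c,
                            "params": {k: getattr(d.params, k) for k in
                                       ("lambda0", "beta_eff", "beta_sex",
                                        "sigma_f", "sigma_m", "theta")},
                            "z": d.z.tolist(), "sex": d.sex.tolist(),
                            "s": d.s.tolist()})
        with open(os.path.join(outdir, "latents.json"), "w") as fh:
            json.dump(lat, fh)
        cfg = {k: v for k, v in vars(self.config).items()}
        manifest = {
            "spec": {"model_id": self.spec.model_id,
                     "lambda0_sex_specific": self.spec.lambda0_sex_specific,
                     "sigma_sex_specific": self.spec.sigma_sex_specific,
                     "spatial": self.spec.spatial, "theta": self.spec.theta},
            "config": cfg, "n_detected": self.n_detected,
            "space_area_km2": self.space_area_km2, "n_pixels": self.n_pixels,
            "n_draws": self.n_draws, "acceptance": self.acceptance,
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, outdir) -> "PosteriorSamples":
        import json
        import os

        import pandas as pd

        from secrsearch.model import DetectionParams

        with open(os.path.join(outdir, "manifest.json")) as fh:
            man = json.load(fh)
        spec = ModelSpec(**man["spec"])
        config = SamplerConfig(**man["config"])
        chains = []
        c = 0
        while os.path.exists(os.path.join(outdir, f"draws_chain{c}.csv")):
            df = pd.read_csv(os.path.join(outdir, f"draws_chain{c}.csv"))
            chains.append({k: df[k].to_numpy() for k in df.columns})
            c += 1
        pix = pd.read_csv(os.path.join(outdir, "pixel_counts.csv"))
        pixel_counts = [pix[f"chain{i}"].to_numpy() for i in range(c)]
        with open(os.path.join(outdir, "latents.json")) as fh:
            lat_raw = json.load(fh)
        latents = [[] for _ in range(c)]
        for d in lat_raw:
            latents[d["chain"]].append(LatentDraw(
                params=DetectionParams(**d["params"]),
                z=np.asarray(d["z"], dtype=np.int8),
                sex=np.asarray(d["sex"], dtype=np.int8),
                s=np.asarray(d["s"], dtype=int)))
        return cls(chains=chains, pixel_counts=pixel_counts,
                   n_draws=man["n_draws"], latents=latents,
                   acceptance=man["acceptance"], spec=spec, config=config,
                   n_detected=man["n_detected"],
                   space_area_km2=man["space_area_km2"],
                   n_pixels=man["n_pixels"])

    def discard(self, n: int) -> "PosteriorSamples":
        """Drop a further n leading draws from every chain (post-hoc burn).

        Applies to the scalar draws only; prefer ``SamplerConfig.extra_discard``
        when pixel tallies and latent snapshots must stay aligned.
        """
        out = replace(self)
        out.chains = [{k: v[n:] for k, v in c.items()} for c in self.chains]
        out.n_draws = [m - n for m in self.n_draws]
        out.latents = self.latents
        out.pixel_counts = self.pixel_counts
        return out


def metropolis_step(logpost, x: float, scale: float, rng) -> tuple:
    """One Gaussian random-walk Metropolis step on a scalar.

    ``logpost`` maps a value to its log target density.  Nonfinite proposal
    densities are rejected.  Returns ``(x_new, accepted)``.
    """
    prop = x + scale * rng.standard_normal()
    lp0, lp1 = logpost(x), logpost(prop)
    if not np.isfinite(lp1):
        return x, False
    if math.log(rng.random()) < lp1 - lp0:
        return prop, True
    return x, False


@dataclass
class ChainState:
    log_lambda0: float
    beta_eff: float
    beta_sex: float
    log_sigma_f: float
    log_sigma_m: float
    z: np.ndarray
    sex: np.ndarray
    s: np.ndarray
    psi: float
    psi_sex: float

    def params(self, spec: ModelSpec) -> DetectionParams:
        sf = math.exp(self.log_sigma_f)
        sm = math.exp(self.log_sigma_m) if spec.sigma_sex_specific else sf
        return DetectionParams(
            lambda0=math.exp(self.log_lambda0), beta_eff=self.beta_eff,
            beta_sex=self.beta_sex if spec.lambda0_sex_specific else 0.0,
            sigma_f=sf, sigma_m=sm, theta=spec.theta)


class GibbsSampler:
    """Prepared data + update kernels for one model fit."""

    def __init__(self, spec: ModelSpec, ch: CaptureHistory, effort: EffortMatrix,
                 space: StateSpace, cfg: SamplerConfig, priors: Priors | None = None):
        cfg.validate(ch.n_individuals)
        self.spec = spec
        self.cfg = cfg
        self.space = space
        self.n = ch.n_individuals
        self.M = cfg.M
        effort = apply_effort_floor(effort, ch, cfg.effort_floor_km)
        self.priors = priors if priors is not None else \
            Priors.for_space(space, cfg.prior_normal_sd)

        if spec.spatial:
            eff = effort.values                                   # (J, K)
            y = ch.y
            self.trap_xy = effort.trap_xy
        else:
            eff = effort.values.sum(axis=0, keepdims=True)        # (1, K)
            y = ch.y.max(axis=1, keepdims=True)
            self.trap_xy = np.zeros((1, 2))
        self.J, self.K = eff.shape
        self.eff = eff
        jj, kk = np.nonzero(eff)
        self.cell_j, self.cell_k = jj, kk
        self.cell_eff = eff[jj, kk]
        if np.any((y > 0) & (eff[None, :, :] == 0)):
            raise ModelError("detection in a zero-effort cell; apply an effort floor")

        # flattened detections: (individual, trap, occasion)
        di, dj, dk = np.nonzero(y)
        self.det_i, self.det_j = di, dj
        self.det_eff = eff[dj, dk]
        self.obs_encounters = np.zeros(self.n)
        np.add.at(self.obs_encounters, di, 1.0)

        self.P = space.n_pixels if spec.spatial else 1
        if spec.spatial:
            cx = space.centroids
            self.D2 = ((cx[:, None, :] - self.trap_xy[None, :, :]) ** 2).sum(-1)
            self.D2pix = ((cx[:, None, :] - cx[None, :, :]) ** 2).sum(-1)
        else:
            self.D2 = np.zeros((1, 1))
            self.D2pix = np.zeros((1, 1))

        self.sex_obs = (ch.sexes == "male").astype(np.int8)
        self.ch = ch
        self.effort = effort
        self._w_cache = None
        # per-individual detection-cell slices for the activity-centre kernel
        self._det_of = [np.flatnonzero(self.det_i == i) for i in range(self.n)]

    # -- cached per-beta effort aggregates ---------------------------------
    def _w(self, beta_eff: float):
        cached = self._w_cache
        if cached is not None and cached[0] == beta_eff:
            return cached[1]
        ep = self.cell_eff ** beta_eff
        w = np.zeros(self.J)
        np.add.at(w, self.cell_j, ep)
        self._w_cache = (beta_eff, w)
        return w

    # -- likelihood of included individuals' detection rows ----------------
    def loglik_y(self, st: ChainState, override: dict | None = None) -> float:
        """Detection log likelihood summed over included (z=1) individuals."""
        p = {"log_lambda0": st.log_lambda0, "beta_eff": st.beta_eff,
             "beta_sex": st.beta_sex, "log_sigma_f": st.log_sigma_f,
             "log_sigma_m": st.log_sigma_m}
        if override:
            p.update(override)
        lam0 = math.exp(p["log_lambda0"])
        bsex = p["beta_sex"] if self.spec.lambda0_sex_specific else 0.0
        sf = math.exp(p["log_sigma_f"])
        sm = math.exp(p["log_sigma_m"]) if self.spec.sigma_sex_specific else sf

        w = self._w(p["beta_eff"])
        idx = np.flatnonzero(st.z)
        male = st.sex[idx].astype(float)
        if self.spec.spatial:
            sig2 = np.where(male == 1, sm, sf)[:, None] ** 2
            Krows = np.exp(-self.D2[st.s[idx], :] / (2.0 * sig2))   # (Nz, J)
            haz = lam0 * np.exp(bsex * male) * (Krows @ w)
        else:
            haz = lam0 * np.exp(bsex * male) * w[0]
        total = -float(np.sum(haz))

        if len(self.det_i):
            dmale = st.sex[self.det_i].astype(float)
            dsig2 = np.where(dmale == 1, sm, sf) ** 2
            if self.spec.spatial:
                d2 = self.D2[st.s[self.det_i], self.det_j]
            else:
                d2 = 0.0
            h = lam0 * np.exp(bsex * dmale) * self.det_eff ** p["beta_eff"] \
                * np.exp(-d2 / (2.0 * dsig2))
            total += float(np.sum(np.log(-np.expm1(-h)) + h))
        return total

    def _hazsum(self, st: ChainState, rows: np.ndarray, sex_override=None) -> np.ndarray:
        """Total detection hazard for the given individuals at their centres."""
        p = st.params(self.spec)
        sex = st.sex[rows] if sex_override is None else np.full(len(rows), sex_override)
        male = sex.astype(float)
        w = self._w(st.beta_eff)
        if self.spec.spatial:
            sig2 = np.where(male == 1, p.sigma_m, p.sigma_f)[:, None] ** 2
            Krows = np.exp(-self.D2[st.s[rows], :] / (2.0 * sig2))
            return p.lambda0 * np.exp(p.beta_sex * male) * (Krows @ w)
        return p.lambda0 * np.exp(p.beta_sex * male) * w[0]

    # -- update kernels ----------------------------------------------------
    def _param_list(self):
        names = ["log_lambda0", "beta_eff"]
        if self.spec.lambda0_sex_specific:
            names.append("beta_sex")
        if self.spec.spatial:
            names.append("log_sigma_f")
            if self.spec.sigma_sex_specific:
                names.append("log_sigma_m")
        return names

    def _log_prior(self, name: str, value: float) -> float:
        pr = self.priors
        if name == "log_lambda0":
            return pr.lp_log_lambda0(value)
        if name in ("beta_eff", "beta_sex"):
            return pr.lp_beta(value)
        # sigma ~ Uniform(0, sigma_max), sampled on the log scale: the
        # Jacobian contributes + log(sigma)
        sigma = math.exp(value)
        return pr.lp_sigma(sigma) + value

    def update_continuous(self, st: ChainState, scales: dict, rng) -> dict:
        """RW-Metropolis sweep over the model's continuous parameters."""
        accepted = {}
        cur_ll = self.loglik_y(st)
        for name in self._param_list():
            x = getattr(st, name)
            prop = x + scales[name] * rng.standard_normal()
            lp1 = self.loglik_y(st, {name: prop}) + self._log_prior(name, prop)
            lp0 = cur_ll + self._log_prior(name, x)
            ok = np.isfinite(lp1) and math.log(rng.random()) < lp1 - lp0
            if ok:
                setattr(st, name, prop)
                cur_ll = lp1 - self._log_prior(name, prop)
            accepted[name] = bool(ok)
        return accepted

    def update_z(self, st: ChainState, rng) -> None:
        """Gibbs draw of inclusion indicators for augmented individuals."""
        if self.M == self.n:
            return
        rows = np.arange(self.n, self.M)
        q = np.exp(-self._hazsum(st, rows))
        p1 = st.psi * q
        prob = p1 / (p1 + (1.0 - st.psi))
        st.z[rows] = (rng.random(len(rows)) < prob).astype(np.int8)

    def update_sex(self, st: ChainState, rng) -> None:
        """Gibbs draw of sex for augmented individuals (detected are fixed)."""
        if self.M == self.n:
            return
        rows = np.arange(self.n, self.M)
        lw_m = np.log(st.psi_sex) - np.where(st.z[rows] == 1,
                                             self._hazsum(st, rows, sex_override=1), 0.0)
        lw_f = np.log1p(-st.psi_sex) - np.where(st.z[rows] == 1,
                                                self._hazsum(st, rows, sex_override=0), 0.0)
        pm = 1.0 / (1.0 + np.exp(lw_f - lw_m))
        st.sex[rows] = (rng.random(len(rows)) < pm).astype(np.int8)

    def _ll_one(self, st: ChainState, i: int, pixel: int,
                p: DetectionParams | None = None) -> float:
        """Detection log likelihood of individual i with centre at `pixel`."""
        if p is None:
            p = st.params(self.spec)
        male = float(st.sex[i])
        sig2 = (p.sigma_m if st.sex[i] == 1 else p.sigma_f) ** 2
        w = self._w(st.beta_eff)
        scale = p.lambda0 * math.exp(p.beta_sex * male)
        haz = scale * float(np.exp(-self.D2[pixel, :] / (2.0 * sig2)) @ w)
        ll = -haz
        det = self._det_of[i] if i < self.n else ()
        if len(det):
            h = scale * self.det_eff[det] ** st.beta_eff \
                * np.exp(-self.D2[pixel, self.det_j[det]] / (2.0 * sig2))
            ll += float(np.sum(np.log(-np.expm1(-h)) + h))
        return ll

    def update_activity_centres(self, st: ChainState, rng) -> None:
        """Move activity centres: uniform Gibbs for excluded individuals,
        masked uniform-disc Metropolis for included ones."""
        if not self.spec.spatial:
            return
        out = np.flatnonzero(st.z == 0)
        if len(out):
            st.s[out] = rng.integers(0, self.P, size=len(out))
        p = st.params(self.spec)
        for i in np.flatnonzero(st.z == 1):
            sig = p.sigma_m if st.sex[i] == 1 else p.sigma_f
            r2 = (self.cfg.s_proposal_sigmas * sig) ** 2
            cur = st.s[i]
            nbr = np.flatnonzero(self.D2pix[cur] <= r2)
            prop = int(nbr[rng.integers(len(nbr))])
            if prop == cur:
                continue
            nbr_back = int(np.count_nonzero(self.D2pix[prop] <= r2))
            logr = (self._ll_one(st, i, prop, p) - self._ll_one(st, i, cur, p)
                    + math.log(len(nbr)) - math.log(nbr_back))
            if math.log(rng.random()) < logr:
                st.s[i] = prop

    def update_psi(self, st: ChainState, rng) -> None:
        nz = int(st.z.sum())
        st.psi = float(rng.beta(1 + nz, 1 + self.M - nz))

    def update_psi_sex(self, st: ChainState, rng) -> None:
        inc = st.z == 1
        m = int(st.sex[inc].sum())
        st.psi_sex = float(rng.beta(1 + m, 1 + int(inc.sum()) - m))

    # -- initialisation ----------------------------------------------------
    def initial_state(self, rng) -> ChainState:
        n, M = self.n, self.M
        z = np.zeros(M, dtype=np.int8)
        z[:n] = 1
        psi0 = float(rng.uniform(0.2, 0.8))
        z[n:] = (rng.random(M - n) < psi0).astype(np.int8)
        sex = np.zeros(M, dtype=np.int8)
        sex[:n] = self.sex_obs
        sex[n:] = (rng.random(M - n) < 0.5).astype(np.int8)

        s = rng.integers(0, self.P, size=M)
        sigma0 = 2.0
        if self.spec.spatial:
            spreads = []
            for i in range(n):
                mask = self.det_i == i
                xy = self.trap_xy[self.det_j[mask]]
                # nearest state-space pixel to the mean detection location
                mu = xy.mean(axis=0)
                s[i] = int(np.argmin(((self.space.centroids - mu) ** 2).sum(axis=1)))
                if len(xy) > 1:
                    spreads.append(np.sqrt(((xy - mu) ** 2).sum(axis=1).mean()))
            if spreads:
                sigma0 = max(float(np.mean(spreads)), 0.25)
        log_sig = math.log(sigma0) + 0.3 * rng.standard_normal()
        st = ChainState(
            log_lambda0=math.log(0.01) + 0.5 * rng.standard_normal(),
            beta_eff=0.3 * rng.standard_normal(),
            beta_sex=0.3 * rng.standard_normal(),
            log_sigma_f=log_sig,
            log_sigma_m=log_sig + 0.2 * rng.standard_normal(),
            z=z, sex=sex, s=s,
            psi=psi0, psi_sex=float(rng.uniform(0.3, 0.7)),
        )
        if not np.isfinite(self.loglik_y(st)):
            raise ModelError("nonfinite initial likelihood")
        return st

    # -- main loop ---------------------------------------------------------
    def run_chain(self, seed_seq) -> tuple:
        cfg = self.cfg
        rng = np.random.default_rng(seed_seq)
        for _attempt in range(5):
            try:
                st = self.initial_state(rng)
                break
            except ModelError:
                continue
        else:
            raise ModelError("could not find a finite starting state")

        scales = dict(cfg.proposal_scales)
        names = self._param_list()
        acc_count = {p: 0 for p in names}
        win_count = {p: 0 for p in names}
        acc_total = {p: 0 for p in names}
        n_kept_total = 0

        keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
        draws = {k: np.empty(keep) for k in
                 ["lambda0", "beta_eff", "beta_sex", "sigma_f", "sigma_m",
                  "psi", "psi_sex", "N_super"]}
        pix = np.zeros(self.P)
        latents = []
        kept = 0
        for it in range(cfg.n_iter):
            acc = self.update_continuous(st, scales, rng)
            for pname, ok in acc.items():
                win_count[pname] += 1
                acc_count[pname] += ok
                acc_total[pname] += ok
            self.update_z(st, rng)
            self.update_sex(st, rng)
            self.update_activity_centres(st, rng)
            self.update_psi(st, rng)
            self.update_psi_sex(st, rng)

            if cfg.adapt and it < cfg.burn_in and (it + 1) % 50 == 0:
                for pname in names:
                    rate = acc_count[pname] / max(win_count[pname], 1)
                    scales[pname] = float(np.clip(
                        scales[pname] * math.exp(rate - 0.3), 1e-4, 10.0))
                    acc_count[pname] = 0
                    win_count[pname] = 0

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                p = st.params(self.spec)
                draws["lambda0"][kept] = p.lambda0
                draws["beta_eff"][kept] = p.beta_eff
                draws["beta_sex"][kept] = p.beta_sex
                draws["sigma_f"][kept] = p.sigma_f
                draws["sigma_m"][kept] = p.sigma_m
                draws["psi"][kept] = st.psi
                draws["psi_sex"][kept] = st.psi_sex
                draws["N_super"][kept] = st.z.sum()
                if kept >= cfg.extra_discard:
                    inc = np.flatnonzero(st.z)
                    if self.spec.spatial:
                        np.add.at(pix, st.s[inc], 1.0)
                    if (kept - cfg.extra_discard) % cfg.latent_every == 0:
                        latents.append(LatentDraw(params=p, z=st.z.copy(),
                                                  sex=st.sex.copy(), s=st.s.copy()))
                kept += 1
        n_kept_total = kept
        rates = {p: acc_total[p] / cfg.n_iter for p in names}
        if cfg.extra_discard:
            d = cfg.extra_discard
            draws = {k: v[d:kept] for k, v in draws.items()}
            n_kept_total = kept - d
        else:
            draws = {k: v[:kept] for k, v in draws.items()}
        if not self.spec.spatial:
            for k in ("sigma_f", "sigma_m"):
                draws.pop(k)
        if not self.spec.lambda0_sex_specific:
            draws.pop("beta_sex")
        return draws, pix, n_kept_total, latents, rates


def run(spec: ModelSpec, ch: CaptureHistory, effort: EffortMatrix,
        space: StateSpace, cfg: SamplerConfig,
        priors: Priors | None = None) -> PosteriorSamples:
    """Fit one candidate model; returns retained draws from all chains."""
    sampler = GibbsSampler(spec, ch, effort, space, cfg, priors)
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains, pixels, ndraws, latents, rates = [], [], [], [], []
    for seq in seqs:
        d, pix, nk, lat, rt = sampler.run_chain(seq)
        chains.append(d)
        pixels.append(pix)
        ndraws.append(nk)
        latents.append(lat)
        rates.append(rt)
    return PosteriorSamples(
        chains=chains, pixel_counts=pixels, n_draws=ndraws, latents=latents,
        acceptance=rates, spec=spec, config=cfg, n_detected=ch.n_individuals,
        space_area_km2=space.total_area_km2, n_pixels=space.n_pixels)
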