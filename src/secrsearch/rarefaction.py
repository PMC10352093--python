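"""Effort-rarefaction experiment: precision and bias versus km searched.

Whole-day chronological prefixes of the track set are accumulated to each
target effort; detections outside retained days are dropped; the
sex-specific model (1) is refit per subset (falling back to the
sex-pooled model 3 when either sex has too few spatial recaptures) and the
coefficient of variation and relative bias of the headline estimates are
scored against the full-data fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from secrsearch import sampler as _sampler
from secrsearch.derived import density_draws
from secrsearch.diagnostics import RHAT_RAREFIED, gelman_rubin
from secrsearch.ingest import (
    build_capture_history, build_state_space, compute_effort,
    summarize_captures,
)
from secrsearch.model import ModelSpec

__all__ = ["rarefy_tracks", "cv", "relative_bias", "run_rarefaction",
           "RarefactionResult", "CV_THRESHOLD", "RB_THRESHOLD"]

CV_THRESHOLD = 0.20
RB_THRESHOLD = 0.15

MONITORED = ("sigma_f", "sigma_m", "psi_sex", "N_super", "D_per_100km2")


def rarefy_tracks(tracks: list, target_km: float) -> list:
    """Chronological whole-day prefix reaching the target cumulative length.

    The day whose track crosses the threshold is included whole.  A target
    at or beyond the total returns the full set (with a warning when it
    exceeds it).
    """
    if target_km <= 0:
        raise ValueError("target_km must be positive")
    ordered = sorted(tracks, key=lambda t: t.day)
    total = sum(t.length_km for t in ordered)
    if target_km > total:
        warnings.warn(f"target {target_km} km exceeds total {total:.1f} km; "
                      "returning the full track set")
        return list(ordered)
    out, acc = [], 0.0
    for t in ordered:
        out.append(t)
        acc += t.length_km
        if acc >= target_km:
            break
    return out


def cv(estimate_mean: float, estimate_sd: float) -> float:
    """Coefficient of variation: SD / |mean|."""
    if estimate_mean == 0:
        raise ValueError("cv undefined for zero mean")
    return estimate_sd / abs(estimate_mean)


def relative_bias(estimate: float, reference: float) -> float:
    """(estimate - reference) / reference."""
    if reference == 0:
        raise ValueError("relative bias undefined for zero reference")
    return (estimate - reference) / reference


@dataclass
class RarefactionResult:
    table: pd.DataFrame
    reference_means: dict
    fits: dict                     # target_km -> PosteriorSamples (or None)


def _sex_spatial_recaptures(ch) -> dict:
    """Per-sex spatial recaptures: sum of (distinct traps - 1) per individual."""
    distinct = (ch.y.max(axis=2) > 0).sum(axis=1)
    return {s: int((distinct[ch.sexes == s] - 1).sum()) for s in ("female", "male")}


def _summaries(samples) -> dict:
    out = {}
    for p in ("sigma_f", "sigma_m", "psi_sex", "N_super"):
        if p in samples.param_names:
            d = samples.draws(p)
            out[p] = (float(d.mean()), float(d.std(ddof=1)))
    dd = density_draws(samples.draws("N_super"), samples.space_area_km2)
    out["D_per_100km2"] = (float(dd.mean()), float(dd.std(ddof=1)))
    return out


def run_rarefaction(tracks: list, sightings: list, boundary,
                    increments_km: list | None = None,
                    cfg: "_sampler.SamplerConfig | None" = None,
                    pixel_area_km2: float = 0.5,
                    fallback_min_recaptures: int = 2,
                    per_subset_cfg: dict | None = None) -> RarefactionResult:
    """Refit nested effort subsets and score CV / RB against the full fit.

    ``sightings`` are already-filtered records (known IDs and sexes).  The
    reference fit is produced through the identical code path at full
    effort, so the full-effort subset has RB exactly 0.  Per-subset sampler
    overrides (e.g. more iterations for sparse subsets) are given as
    ``{target_km: SamplerConfig}``.
    """
    if cfg is None:
        cfg = _sampler.SamplerConfig()
    space = build_state_space(boundary, pixel_area_km2)
    ordered = sorted(tracks, key=lambda t: t.day)
    total_km = sum(t.length_km for t in ordered)
    if increments_km is None:
        increments_km = [k for k in range(1000, int(total_km) + 1, 1000)]
    targets = sorted(set(list(increments_km) + [total_km]))

    results, fits = [], {}
    reference = None
    # fit the full data first so every subset can be scored against it
    for target in [total_km] + [t for t in targets if t < total_km]:
        sub = rarefy_tracks(ordered, min(target, total_km))
        days = {t.day for t in sub}
        recs = [r for r in sightings if r.day in days]
        effort = compute_effort(sub, space)
        realised = float(sum(t.length_km for t in sub))
        row = {"target_km": float(target), "realised_km": realised,
               "n_individuals": 0, "n_recaptures": 0,
               "avg_spatial_recaptures": np.nan, "model_used": None,
               "converged": None, "adequate": False}
        if not recs:
            row["note"] = "no detections in subset; fit skipped"
            results.append(row)
            fits[target] = None
            continue
        ch, effort = build_capture_history(recs, effort, space)
        summ = summarize_captures(ch)
        row.update(n_individuals=summ["n_individuals"],
                   n_recaptures=summ["recaptures"],
                   avg_spatial_recaptures=summ["avg_spatial_recaptures"])
        if summ["recaptures"] == 0:
            row["note"] = "zero recaptures; fit skipped"
            results.append(row)
            fits[target] = None
            continue
        by_sex = _sex_spatial_recaptures(ch)
        model_id = 1 if min(by_sex.values()) >= fallback_min_recaptures else 3
        row["model_used"] = model_id
        sub_cfg = (per_subset_cfg or {}).get(target, cfg)
        samples = _sampler.run(ModelSpec.from_id(model_id), ch, effort, space, sub_cfg)
        fits[target] = samples
        if sub_cfg.n_chains >= 2:
            rhats = [gelman_rubin(samples.get(p)) for p in samples.param_names
                     if np.std(samples.get(p)) > 0]
            row["converged"] = bool(rhats) and max(rhats) <= RHAT_RAREFIED
        summaries = _summaries(samples)
        if reference is None:
            reference = summaries
        ok = True
        for p in MONITORED:
            if p not in summaries:
                continue
            mean, sd = summaries[p]
            row[f"{p}_mean"] = mean
            row[f"cv_{p}"] = cv(mean, sd)
            if p in reference:
                row[f"rb_{p}"] = relative_bias(mean, reference[p][0])
            cv_ok = row[f"cv_{p}"] < CV_THRESHOLD
            rb_ok = abs(row.get(f"rb_{p}", 0.0)) < RB_THRESHOLD
            ok = ok and cv_ok and rb_ok
        row["adequate"] = ok
        results.append(row)

    table = pd.DataFrame(results).sort_values("target_km").reset_index(drop=True)
    return RarefactionResult(table=table,
                             reference_means={k: v[0] for k, v in reference.items()}
                             if reference else {},
                             fits=fits)
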