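"""Management quantities derived from posterior draws.

Density per 100 km^2, abundance, sex ratio, sex-specific home-range size
(pi * sigma^2 * 5.99, the 95% home-range area of a half-normal use
distribution), the detected fraction of the estimated population, and the
per-pixel posterior density surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from secrsearch.diagnostics import hpd_interval
from secrsearch.sampler import PosteriorSamples

__all__ = [
    "density_draws", "sex_ratio", "home_range_draws", "pixel_density_map",
    "detected_fraction", "DerivedSummary", "derive_summary", "HR_CHI2_95",
]

HR_CHI2_95 = 5.99   # 95% quantile of chi-square(2 df), as conventionally printed


def density_draws(n_draws, area_km2: float) -> np.ndarray:
    """Per-draw density: N / area x 100 (individuals per 100 km^2)."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return np.asarray(n_draws, dtype=float) / area_km2 * 100.0


def sex_ratio(psi_sex_mean: float) -> float:
    """Females per male implied by the posterior mean proportion male."""
    if not 0 < psi_sex_mean < 1:
        raise ValueError("psi_sex must lie strictly in (0, 1)")
    return (1.0 - psi_sex_mean) / psi_sex_mean


def home_range_draws(sigma_draws) -> np.ndarray:
    """Draw-wise 95% home-range area pi * sigma^2 * 5.99 (km^2)."""
    sig = np.asarray(sigma_draws, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma draws must be positive")
    return math.pi * sig ** 2 * HR_CHI2_95


def pixel_density_map(samples: PosteriorSamples) -> np.ndarray:
    """Posterior mean count of included activity centres per pixel.

    Sums (over pixels) to the posterior mean of N_super.
    """
    total = np.sum(samples.pixel_counts, axis=0)
    return total / float(np.sum(samples.n_draws))


def detected_fraction(n_detected: int, n_mean: float) -> int:
    """Detected percentage of the estimated population, nearest integer."""
    if not n_mean >= n_detected > 0:
        raise ValueError("need N_mean >= n_detected > 0")
    return int(round(100.0 * n_detected / n_mean))


@dataclass
class DerivedSummary:
    table: pd.DataFrame            # parameter, mean, sd, hpd_lower, hpd_upper
    sex_ratio_f_per_m: float | None
    detected_pct: int
    pixel_map: pd.DataFrame | None


def _row(name, draws):
    lo, hi = hpd_interval(draws)
    return {"parameter": name, "mean": float(np.mean(draws)),
            "sd": float(np.std(draws, ddof=1)), "hpd_lower": lo, "hpd_upper": hi}


def derive_summary(samples: PosteriorSamples, space=None) -> DerivedSummary:
    """Posterior summaries of the reported quantities for one fit."""
    rows = []
    for p in samples.param_names:
        if p == "N_super":
            continue
        rows.append(_row(p, samples.draws(p)))
    nd = samples.draws("N_super")
    rows.append(_row("N_super", nd))
    area = samples.space_area_km2
    dens = density_draws(nd, area)
    rows.append(_row("D_per_100km2", dens))
    if "sigma_f" in samples.param_names:
        rows.append(_row("home_range_f_km2", home_range_draws(samples.draws("sigma_f"))))
        rows.append(_row("home_range_m_km2", home_range_draws(samples.draws("sigma_m"))))
    table = pd.DataFrame(rows)

    psis = samples.draws("psi_sex").mean()
    ratio = sex_ratio(psis) if 0 < psis < 1 else None
    pct = detected_fraction(samples.n_detected, float(nd.mean()))

    pixel_map = None
    if space is not None and samples.spec.spatial:
        mean_counts = pixel_density_map(samples)
        pixel_map = pd.DataFrame({
            "pixel_id": space.pixel_ids,
            "x_km": space.centroids[:, 0],
            "y_km": space.centroids[:, 1],
            "mean_count": mean_counts,
        })
    return DerivedSummary(table=table, sex_ratio_f_per_m=ratio,
                          detected_pct=pct, pixel_map=pixel_map)
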