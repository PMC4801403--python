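"""Density, abundance and ship-strike sustainability arithmetic.

Conventional distance sampling: D = n / (2 mu L) x 1/g(0), N = A x D, with
an effort-deflation correction for overlapping area at zigzag transect
corners (divide by 1 - o).  Uncertainty combines the encounter-rate CV, the
ESHW CV and the g(0) CV in quadrature (delta method), with log-normal
confidence intervals.  The sustainability check compares the maximum
recruitment r_max x N against the observed annual mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EffortTable:
    """Per-transect survey effort and detection counts."""

    transects: pd.DataFrame  # columns: id, length_km, detections
    overlap_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap fraction must be in [0, 1)")
        if (self.transects["length_km"] <= 0).any():
            raise ValueError("transect lengths must be positive")

    @property
    def L(self) -> float:
        return float(self.transects["length_km"].sum())

    @property
    def K(self) -> int:
        return len(self.transects)

    @property
    def n(self) -> int:
        return int(self.transects["detections"].sum())

    @classmethod
    def from_csv(cls, path, overlap_fraction: float = 0.0) -> "EffortTable":
        return cls(pd.read_csv(path), overlap_fraction)


def estimate_density(n: int, mu_hat_km: float, L_km: float,
                     o: float = 0.0, g0: float = 1.0) -> float:
    """Whale density per km^2: D = n / (2 mu L (1 - o)) / g(0).

    ``o`` is the fraction of surveyed area counted twice at zigzag corners,
    applied as an effort deflation; o = 0 recovers the plain estimator.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if mu_hat_km <= 0 or L_km <= 0:
        raise ValueError("mu and L must be positive")
    if not 0.0 <= o < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if not 0.0 < g0 <= 1.0:
        raise ValueError("g(0) must be in (0, 1]")
    return n / (2.0 * mu_hat_km * L_km * (1.0 - o)) / g0


def estimate_abundance(D_per_km2: float, A_km2: float) -> float:
    if D_per_km2 < 0 or A_km2 <= 0:
        raise ValueError("need D >= 0 and A > 0")
    return D_per_km2 * A_km2


def encounter_rate_cv(effort: EffortTable) -> float:
    """CV of the encounter rate n/L from between-transect variation.

    var(n/L) = K / (L^2 (K-1)) * sum_k l_k^2 (n_k/l_k - n/L)^2 — the standard
    transect-as-sampling-unit estimator for systematic designs.
    """
    if effort.K < 2:
        raise ValueError("need at least 2 transects for a variance estimate")
    l = effort.transects["length_km"].to_numpy(dtype=float)
    nk = effort.transects["detections"].to_numpy(dtype=float)
    L, K, n = effort.L, effort.K, effort.n
    if n == 0:
        return 0.0
    rate = n / L
    var = K / (L**2 * (K - 1)) * float(np.sum(l**2 * (nk / l - rate) ** 2))
    return float(np.sqrt(var) / rate)


def combine_cv(components) -> float:
    """Delta-method combination: cv_total = sqrt(sum cv_i^2)."""
    c = np.asarray(list(components), dtype=float)
    if np.any(c < 0):
        raise ValueError("CVs must be non-negative")
    return float(np.sqrt(np.sum(c**2)))


def lognormal_ci(estimate: float, cv: float, z: float = 1.96):
    """95% log-normal interval (lo, hi) = (est/C, est*C),
    C = exp(z sqrt(ln(1 + cv^2))).  Satisfies lo*hi = est^2."""
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    C = float(np.exp(z * np.sqrt(np.log1p(cv**2))))
    return estimate / C, estimate * C


@dataclass
class DensityEstimate:
    """Full density/abundance estimate with propagated uncertainty."""

    n: int
    mu_hat_km: float
    L_km: float
    o: float
    g0: float
    g0_sd: float
    A_km2: float
    D_per_km2: float
    N: float
    cv_n: float
    cv_mu: float
    cv_g0: float
    cv_total: float
    ci_lo_D: float
    ci_hi_D: float
    ci_lo_N: float
    ci_hi_N: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["D_per_1000km2"] = self.D_per_km2 * 1000.0
        return d

    def summary(self) -> str:
        return (
            f"n = {self.n} detections, ESHW = {self.mu_hat_km * 1000:.0f} m, "
            f"L = {self.L_km:.0f} km, overlap = {self.o:.1%}, "
            f"g(0) = {self.g0:.2f} (sd {self.g0_sd:.3f})\n"
            f"D = {self.D_per_km2 * 1000:.2f} whales/1000 km^2 "
            f"(95% CI {self.ci_lo_D * 1000:.2f}-{self.ci_hi_D * 1000:.2f})\n"
            f"N = {self.N:.0f} whales in {self.A_km2:.0f} km^2 "
            f"(95% CI {self.ci_lo_N:.0f}-{self.ci_hi_N:.0f}), "
            f"CV = {self.cv_total:.1%}"
        )


def full_estimate(n: int, mu_hat_km: float, cv_mu: float, L_km: float,
                  o: float, g0: float, g0_sd: float, A_km2: float,
                  cv_n: float) -> DensityEstimate:
    """Assemble the complete estimate from its components.

    All intermediates stay unrounded; rounding happens only in reports.
    The g(0) CV enters as g0_sd / g0 (delta method).
    """
    D = estimate_density(n, mu_hat_km, L_km, o, g0)
    N = estimate_abundance(D, A_km2)
    cv_g0 = g0_sd / g0 if g0 > 0 else 0.0
    cv_total = combine_cv([cv_n, cv_mu, cv_g0])
    lo_D, hi_D = lognormal_ci(D, cv_total)
    lo_N, hi_N = lognormal_ci(N, cv_total)
    return DensityEstimate(n, mu_hat_km, L_km, o, g0, g0_sd, A_km2, D, N,
                           cv_n, cv_mu, cv_g0, cv_total, lo_D, hi_D, lo_N, hi_N)


@dataclass
class SustainabilityReport:
    N: float
    r_max: float
    recruitment_per_yr: float
    mortality_per_yr: float
    verdict: str  # "exceeds" (mortality >= recruitment) or "within"
    margin_per_yr: float

    def summary(self) -> str:
        return (
            f"N = {self.N:.0f} whales, r_max = {self.r_max:.1%}/yr -> maximum "
            f"recruitment {self.recruitment_per_yr:.1f} whales/yr; observed "
            f"mortality {self.mortality_per_yr:.1f} whales/yr -> mortality "
            f"{self.verdict} the recruitment capacity "
            f"(margin {self.margin_per_yr:.1f} whales/yr)"
        )


def sustainability(N: float, r_max: float,
                   mortality_per_yr: float) -> SustainabilityReport:
    """Compare maximum annual recruitment r_max x N with observed mortality."""
    if N < 0 or r_max < 0 or mortality_per_yr < 0:
        raise ValueError("inputs must be non-negative")
    recruitment = r_max * N
    verdict = "exceeds" if mortality_per_yr >= recruitment else "within"
    return SustainabilityReport(N, r_max, recruitment, mortality_per_yr,
                                verdict, abs(recruitment - mortality_per_yr))
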