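"""Position-dependent diffusivity from restrained time series.

For a permeant held by a harmonic umbrella restraint, the local
diffusion coefficient follows from the fluctuation statistics of the
restrained coordinate (Hummer's estimator):

    D(z₀) = var(z) / τ

where var(z) is the positional variance of the window's z(t) series and
τ its integrated autocorrelation time (IACT),

    τ = Δt · (½ + Σ_{k≥1} ρ(k)),

with ρ(k) the normalised position autocorrelation function and Δt the
saved-sample spacing.  The ACF sum is truncated at the first negative
value (initial-positive-sequence rule); a Sokal self-consistent window
is available behind the ``truncation="sokal"`` flag for comparison.

Variance uses the population (n-denominator) form; at the ≥10⁴-sample
floor enforced here the distinction from n−1 is immaterial, but the
choice is fixed for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSeriesError, ValidationError
from .synthetic import UmbrellaWindow

__all__ = [
    "DiffusivityEstimate",
    "DiffusivityProfile",
    "autocorrelation",
    "integrated_autocorrelation_time",
    "hummer_diffusivity",
    "diffusivity_profile",
]


@dataclass(frozen=True)
class DiffusivityEstimate:
    """One window's variance, IACT and their ratio D = σ²/τ."""

    center: float  # nm
    variance: float  # nm^2
    tau: float  # ps
    d: float  # nm^2/ps
    truncation_lag: int

    def __post_init__(self):
        if self.variance < 0:
            raise ValidationError("variance must be non-negative")
        if self.tau <= 0:
            raise ValidationError("IACT must be positive")
        if not np.isclose(self.d, self.variance / self.tau, rtol=1e-12, atol=0.0):
            raise ValidationError("D must equal variance / tau exactly")


@dataclass
class DiffusivityProfile:
    """Per-window diffusivity estimates ordered by center."""

    estimates: list[DiffusivityEstimate]

    def __post_init__(self):
        centers = [e.center for e in self.estimates]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValidationError("profile centers must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.array([e.center for e in self.estimates])

    @property
    def d(self) -> np.ndarray:
        return np.array([e.d for e in self.estimates])

    @property
    def log10_d(self) -> np.ndarray:
        """Order-of-magnitude view, as diffusivity profiles are usually read."""
        return np.log10(self.d)

    def __len__(self) -> int:
        return len(self.estimates)


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised ACF ρ(0..max_lag) of a uniformly sampled series.

    Uses the mean-removed biased (1/n) sample autocovariance computed by
    FFT, normalised so ρ(0) = 1.  Raises on zero-variance input.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 2 * max_lag:
        raise ValidationError(f"series length {n} must be >= 2*max_lag ({2 * max_lag})")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        raise DegenerateSeriesError("zero-variance series has no autocorrelation")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conjugate(fx), nfft)[: max_lag + 1].real / n
    return acov / acov[0]


def _truncation_ips(rho: np.ndarray) -> int:
    """Initial-positive-sequence cutoff: index of first negative ρ(k), k ≥ 1."""
    neg = np.flatnonzero(rho[1:] < 0)
    return int(neg[0] + 1) if neg.size else rho.size


def integrated_autocorrelation_time(
    series: np.ndarray,
    dt: float,
    max_lag: int | None = None,
    truncation: str = "ips",
) -> float:
    """IACT τ = dt·(½ + Σ ρ(k)) with automatic truncation.

    ``truncation="ips"`` (default) sums up to the first negative ACF
    value; ``"sokal"`` uses the self-consistent window K = min{k: k ≥
    c·τ(k)/dt} with c = 5.  If no truncation point is found before
    ``max_lag`` a warning flags the estimate as a lower bound.
    """
    x = np.asarray(series, float)
    if max_lag is None:
        max_lag = x.size // 2
    rho = autocorrelation(x, max_lag)
    if truncation == "ips":
        k = _truncation_ips(rho)
        if k == rho.size:
            warnings.warn(
                "ACF never crossed zero before max_lag; IACT is truncated "
                "at max_lag and may underestimate the true value",
                stacklevel=2,
            )
        tau = dt * (0.5 + float(rho[1:k].sum()))
    elif truncation == "sokal":
        c = 5.0
        cum = 0.5 + np.cumsum(rho[1:])
        ks = np.arange(1, rho.size)
        hits = np.flatnonzero(ks >= c * cum[: ks.size])
        if hits.size == 0:
            warnings.warn("Sokal window not reached before max_lag", stacklevel=2)
            k = rho.size
        else:
            k = int(ks[hits[0]])
        tau = dt * (0.5 + float(rho[1:k].sum()))
    else:
        raise ValidationError(f"unknown truncation rule {truncation!r}")
    # the +1/2 term keeps tau positive even for anticorrelated data,
    # but guard against pathological inputs anyway
    return max(tau, 0.5 * dt * 1e-6)


def hummer_diffusivity(
    window: UmbrellaWindow,
    min_samples: int = 10_000,
    max_lag: int | None = None,
    truncation: str = "ips",
) -> DiffusivityEstimate:
    """Local diffusivity of one restrained window, D = var(z)/τ."""
    n = window.positions.size
    if n < min_samples:
        raise ValidationError(
            f"window at {window.center:.3g} nm has {n} samples; "
            f"need at least {min_samples} (configurable via min_samples)"
        )
    dt = window.dt_sample
    if max_lag is None:
        max_lag = n // 2
    rho = autocorrelation(window.positions, max_lag)
    k = _truncation_ips(rho) if truncation == "ips" else None
    tau = integrated_autocorrelation_time(window.positions, dt, max_lag, truncation)
    var = float(np.var(window.positions))  # population form
    return DiffusivityEstimate(
        center=window.center,
        variance=var,
        tau=tau,
        d=var / tau,
        truncation_lag=int(k if k is not None else max_lag),
    )


def diffusivity_profile(
    windows: Sequence[UmbrellaWindow],
    min_samples: int = 10_000,
    max_lag: int | None = None,
    truncation: str = "ips",
) -> DiffusivityProfile:
    """Per-window Hummer estimates ordered by window center."""
    if len(windows) == 0:
        raise ValidationError("need at least one window")
    centers = [w.center for w in windows]
    if len(set(centers)) != len(centers):
        raise ValidationError("duplicate window centers")
    est = [
        hummer_diffusivity(w, min_samples=min_samples, max_lag=max_lag, truncation=truncation)
        for w in sorted(windows, key=lambda w: w.center)
    ]
    return DiffusivityProfile(estimates=est)
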