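"""Power-law exponent fits for degree and clustering spectra.

Scale-freeness shows up as n(k) ∝ k^−α: on log-log axes the degree
histogram is a straight line of slope −α.  Hierarchical modularity
shows up as c(k) ~ k^−γ: the mean clustering coefficient of degree-k
vertices decays as a power of k.  Both exponents are estimated by
ordinary least squares on (log10 k, log10 value) over the raw,
unbinned points with zero values excluded — the straightforward
log-log regression matching how such plots are read.  A discrete
maximum-likelihood (Hill-type) estimate of α is available behind a
method flag for comparison; it applies to degree data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from bigramnet.graph import BigramNetwork, c_of_k, degree_histogram

__all__ = ["PowerLawFit", "fit_powerlaw", "fit_degree_alpha", "fit_ck_gamma"]


@dataclass
class PowerLawFit:
    """Result of a log-log power-law fit value ≈ 10^intercept · k^−exponent."""

    exponent: float
    intercept: float  # log10 of the amplitude
    r_squared: float
    n_points: int
    k_range: tuple[float, float]
    method: str = "ols"

    def predict(self, k: np.ndarray) -> np.ndarray:
        return 10.0**self.intercept * np.asarray(k, dtype=float) ** (-self.exponent)


def fit_powerlaw(points: Mapping[int, float]) -> PowerLawFit:
    """OLS on log10-transformed points; exponent is the negated slope.

    Points with k < 1 or non-positive value are excluded (log
    undefined); fewer than two usable points is an error.
    """
    ks = np.array([k for k, v in points.items() if k >= 1 and v > 0], dtype=float)
    vs = np.array([v for k, v in points.items() if k >= 1 and v > 0], dtype=float)
    if ks.size < 2:
        raise ValueError(
            f"power-law fit needs >= 2 usable points (k >= 1, value > 0); "
            f"got {ks.size}"
        )
    x, y = np.log10(ks), np.log10(vs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(
        exponent=-float(slope),
        intercept=float(intercept),
        r_squared=min(1.0, r2),
        n_points=int(ks.size),
        k_range=(float(ks.min()), float(ks.max())),
    )


def _fit_degree_mle(net: BigramNetwork, k_min: int = 1) -> PowerLawFit:
    # discrete Hill/Clauset-style estimate: alpha = 1 + n / sum ln(k/(kmin - 1/2))
    degrees = np.array(
        [d for _, d in net.graph.degree() if d >= k_min], dtype=float
    )
    if degrees.size < 2:
        raise ValueError("MLE fit needs >= 2 vertices with degree >= k_min")
    alpha = 1.0 + degrees.size / float(np.sum(np.log(degrees / (k_min - 0.5))))
    return PowerLawFit(
        exponent=alpha,
        intercept=float("nan"),
        r_squared=float("nan"),
        n_points=int(degrees.size),
        k_range=(float(degrees.min()), float(degrees.max())),
        method="mle",
    )


def fit_degree_alpha(
    net: BigramNetwork, method: Literal["ols", "mle"] = "ols"
) -> PowerLawFit:
    """Fit n(k) ∝ k^−α to the network's degree histogram."""
    if net.n_vertices == 0:
        raise ValueError("empty network")
    if method == "mle":
        return _fit_degree_mle(net)
    return fit_powerlaw({k: float(v) for k, v in degree_histogram(net).items()})


def fit_ck_gamma(net: BigramNetwork) -> PowerLawFit:
    """Fit c(k) ~ k^−γ to the per-degree mean clustering coefficient.

    Only degrees with positive mean clustering enter the fit; a
    network whose clustering spectrum is entirely zero (e.g. a tree)
    has no defined γ and raises.
    """
    if net.n_vertices == 0:
        raise ValueError("empty network")
    return fit_powerlaw({k: v for k, v in c_of_k(net).items() if v > 0})
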