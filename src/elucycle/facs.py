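"""Phase-proportion estimation from DNA-content histograms.

Implements the pragmatic cell-cycle model: Gaussian G1 and G2&M peaks plus
an S-phase component modeled as a constant synthesis-rate plateau between
the two peak means convolved with the peak widths (difference-of-error-
functions form). Also provides a forward simulator used as the fitting
oracle in tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf


@dataclass
class DnaHistogram:
    bin_centers: np.ndarray
    counts: np.ndarray
    gate: tuple[float, float] | None = None

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    def gated(self) -> tuple[np.ndarray, np.ndarray]:
        if self.gate is None:
            return self.bin_centers, self.counts
        lo, hi = self.gate
        m = (self.bin_centers >= lo) & (self.bin_centers <= hi)
        return self.bin_centers[m], self.counts[m]


@dataclass
class WatsonFit:
    mu_g1: float
    sigma_g1: float
    mu_g2: float
    sigma_g2: float
    proportions: tuple[float, float, float]  # (G1, S, G2M)
    residual: float

    def __post_init__(self):
        ratio = self.mu_g2 / self.mu_g1
        if not 1.8 <= ratio <= 2.2 + 1e-9:
            raise ValueError(f"G2/G1 mean ratio {ratio:.3f} outside [1.8, 2.2]")


def _model_density(x, mu1, sigma1, mu2, sigma2, a1, a2, a_s):
    g1 = a1 / (sigma1 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - mu1) / sigma1) ** 2)
    g2 = a2 / (sigma2 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - mu2) / sigma2) ** 2)
    # plateau of total area a_s between the peaks, edges blurred by the
    # respective peak widths
    plateau = 0.5 * (erf((x - mu1) / (math.sqrt(2) * sigma1))
                     - erf((x - mu2) / (math.sqrt(2) * sigma2)))
    s = a_s / (mu2 - mu1) * plateau
    return g1 + g2 + s


def _locate_g1_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Heuristic G1-mean guess: the global mode, unless the histogram has
    clearly more mass near half that position (then the mode is G2)."""
    mode = x[int(np.argmax(y))]
    half = np.interp(mode / 2.0, x, y)
    at_mode = y.max()
    if half > 0.5 * at_mode:
        return mode / 2.0
    return mode


def fit_watson(hist: DnaHistogram) -> WatsonFit:
    """Nonlinear least-squares fit of the two-Gaussian + blurred-plateau
    model; proportions are the component areas over their total.

    Raises when the histogram does not bracket both peaks (suggesting
    different gating bounds).
    """
    x, y = hist.gated()
    if y.sum() <= 0:
        raise ValueError("empty histogram")
    mu1 = _locate_g1_peak(x, y)
    if x.max() < 1.9 * mu1:
        raise ValueError(
            "histogram does not bracket the G2 peak; widen the gating bounds"
        )
    binw = np.median(np.diff(x))
    total = y.sum() * binw
    sigma1 = 0.05 * mu1

    # params: mu1, sigma1, ratio (mu2/mu1), k (sigma2/sigma1), a1, a2, a_s
    p0 = np.array([mu1, sigma1, 2.0, 1.3, 0.5 * total, 0.25 * total, 0.25 * total])
    lo = np.array([0.7 * mu1, 1e-3 * mu1, 1.8, 1.0, 0.0, 0.0, 0.0])
    hi = np.array([1.3 * mu1, 0.5 * mu1, 2.2, 2.5, 2 * total, 2 * total, 2 * total])

    def resid(p):
        m1, s1, ratio, k, a1, a2, a_s = p
        model = _model_density(x, m1, s1, ratio * m1, k * s1, a1, a2, a_s) * binw
        return model - y

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    m1, s1, ratio, k, a1, a2, a_s = sol.x
    areas = np.array([a1, a_s, a2])
    props = areas / areas.sum()
    rms = float(np.sqrt(np.mean(sol.fun ** 2)) / (y.sum() / len(y)))
    return WatsonFit(
        mu_g1=float(m1), sigma_g1=float(s1),
        mu_g2=float(ratio * m1), sigma_g2=float(k * s1),
        proportions=(float(props[0]), float(props[1]), float(props[2])),
        residual=rms,
    )


def simulate_histogram(
    proportions: tuple[float, float, float],
    mu_g1: float = 100.0,
    cv: float = 0.05,
    n_cells: int = 100_000,
    seed: int = 0,
    n_bins: int = 256,
    g2_sigma_factor: float = 1.0,
) -> DnaHistogram:
    """Forward-simulate per-cell DNA content and bin it.

    G1 ~ N(mu, cv*mu); G2 ~ N(2mu, 2*cv*mu*factor); S uniform in (mu, 2mu)
    blurred with the G1 width.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    n = rng.multinomial(n_cells, p)
    g1 = rng.normal(mu_g1, max(cv * mu_g1, 1e-9), n[0])
    s = rng.uniform(mu_g1, 2 * mu_g1, n[1]) + rng.normal(0, max(cv * mu_g1, 1e-9), n[1])
    g2 = rng.normal(2 * mu_g1, max(2 * cv * mu_g1 * g2_sigma_factor, 1e-9), n[2])
    values = np.concatenate([g1, s, g2])
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 3.0 * mu_g1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DnaHistogram(centers, counts.astype(float))
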