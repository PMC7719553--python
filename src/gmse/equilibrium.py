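"""Equilibrium predictions for the G matrix and genetic correlation.

Closed forms and Monte-Carlo expectations for the additive genetic
covariance matrix of pleiotropically mutating traits at
mutation-selection(-drift) balance, in the two classical regimes:

* **Gaussian**: frequent mutations of small effect.  Without drift the
  equilibrium is, in coordinate-free form, proportional to the matrix
  geometric mean of the selection matrix V and mutation matrix M::

      G = n * sqrt(2*mu) * V^{1/2} (V^{-1/2} M V^{-1/2})^{1/2} V^{1/2}

  so the scalar prefactor (the single-trait Gaussian balance variance
  sqrt(2*mu*Va*Vs) per locus) carries all dependence on the overall scales
  Vs and Va, and the shape of G - including every genetic correlation - is
  invariant to the overall strength of selection.  With drift of intensity
  1/(2*Ne) per generation the equilibrium expectation becomes

      Gbar = n*sqrt(2*mu) * V^{1/2} [ (kappa'^2 I + V^{-1/2} M V^{-1/2})^{1/2}
                                       - kappa' I ] V^{1/2}

  with kappa' = 1/(4*Ne*sqrt(2*mu)).  In the two-trait scalar
  parameterization this is governed by the single compound parameter
  kappa = sqrt(Vs / ((4*Ne)^2 * 2*mu*Va)): kappa -> 0 recovers the
  infinite-population balance, kappa -> infinity the neutral mutation-drift
  equilibrium Gbar -> 4*Ne*n*mu*M (correlation rho_m).

* **House of Cards (HoC)**: rare mutations of large effect.  Without drift
  the genetic correlation has the closed form of :func:`rho_g_hoc`, which
  coincides exactly with the Gaussian-regime correlation.  With drift the
  stochastic-HoC expectation is estimated by Monte Carlo::

      Gbar = 4*Ne*n*mu * E[ a a^T / (1 + Ne * a^T V^{-1} a) ],  a ~ N(0, M)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import ShapeSummary, as_cov_matrix, cov_to_shape, params_from_cov

__all__ = [
    "EquilibriumPrediction",
    "rho_g_hoc",
    "g_gaussian_infinite",
    "g_gaussian_drift",
    "g_hoc_drift",
    "kappa",
    "ne_from_kappa",
    "wishart_compare",
    "shared_eigenvector_check",
]

#: relative eigenvalue clipping threshold for principal matrix square roots
_SQRT_CLIP = 1e-14


def _sqrtm_psd(A: np.ndarray) -> np.ndarray:
    """Principal (symmetric PSD) matrix square root via eigendecomposition."""
    w, U = np.linalg.eigh(A)
    w = np.where(w < _SQRT_CLIP * max(w[-1], 0.0), 0.0, w)
    R = (U * np.sqrt(w)) @ U.T
    return 0.5 * (R + R.T)


def _correlation(G: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(G))
    return G / np.outer(d, d)


@dataclass(frozen=True)
class EquilibriumPrediction:
    """Expected equilibrium G matrix with its correlation summary.

    ``rho_g`` is the genetic correlation between traits 1 and 2 (NaN for
    k > 2, where ``correlations`` carries the full pairwise matrix).
    ``kappa`` is the drift-vs-selection compound parameter (Gaussian regime
    with drift, two-trait parameterization); ``mc_se`` the Monte-Carlo
    standard error of ``rho_g`` where the prediction is stochastic.
    """

    G: np.ndarray
    regime: str
    kappa: Optional[float] = None
    mc_se: Optional[float] = None
    correlations: np.ndarray = field(init=False, repr=False)
    rho_g: float = field(init=False)

    def __post_init__(self) -> None:
        corr = _correlation(self.G)
        object.__setattr__(self, "correlations", corr)
        rho = float(corr[0, 1]) if self.G.shape[0] == 2 else float("nan")
        object.__setattr__(self, "rho_g", rho)

    def shape_summary(self) -> ShapeSummary:
        return cov_to_shape(self.G)


def rho_g_hoc(rho_m: float, rho_s: float, phi: float) -> float:
    """Genetic correlation at mutation-selection balance (House-of-Cards).

    ``phi = phi_s / phi_m`` is the ratio of the selection-width ratio to the
    mutational-variance ratio between the two traits; the result is invariant
    under ``phi -> 1/phi`` and does not depend on the overall scales Vs, Va::

        rho_G = [rho_s*sqrt(1-rho_m^2) + rho_m*sqrt(1-rho_s^2)] /
                sqrt(2 - (rho_m^2+rho_s^2)
                     + sqrt((1-rho_s^2)*(1-rho_m^2)) * (sqrt(phi) + 1/sqrt(phi)))

    At ``phi = 1`` this reduces to
    ``(rho_s*sqrt(1-rho_m^2) + rho_m*sqrt(1-rho_s^2)) / (sqrt(1-rho_m^2) + sqrt(1-rho_s^2))``.
    The same value is the genetic correlation of the Gaussian-regime
    equilibrium :func:`g_gaussian_infinite`.
    """
    if not -1.0 < rho_m < 1.0:
        raise ValueError(f"rho_m must lie in (-1, 1), got {rho_m}")
    if not -1.0 < rho_s < 1.0:
        raise ValueError(f"rho_s must lie in (-1, 1), got {rho_s}")
    if not phi > 0:
        raise ValueError(f"phi must be positive, got {phi}")
    cm = np.sqrt(1.0 - rho_m**2)
    cs = np.sqrt(1.0 - rho_s**2)
    num = rho_s * cm + rho_m * cs
    den = 2.0 - (rho_m**2 + rho_s**2) + cs * cm * (np.sqrt(phi) + 1.0 / np.sqrt(phi))
    return float(num / np.sqrt(den))


def _shape_operator(M: np.ndarray, V: np.ndarray):
    Vh = _sqrtm_psd(V)
    Vmh = np.linalg.inv(Vh)
    return Vh, 0.5 * ((C := Vmh @ M @ Vmh) + C.T)


def g_gaussian_infinite(M, V, n: int, mu: float) -> EquilibriumPrediction:
    """Equilibrium G in the Gaussian regime, infinite population.

    ``G = n*sqrt(2*mu) * V^{1/2}(V^{-1/2} M V^{-1/2})^{1/2} V^{1/2}``; for a
    single trait this is ``n*sqrt(2*mu*Va*Vs)``.  Rescaling Vs or Va alone
    changes only the size of G, never its correlations or orientation.
    """
    M = as_cov_matrix(M, "M", require_pd=True)
    V = as_cov_matrix(V, "V", require_pd=True)
    if M.shape != V.shape:
        raise ValueError("M and V must have the same dimension")
    Vh, C = _shape_operator(M, V)
    G = n * np.sqrt(2.0 * mu) * (Vh @ _sqrtm_psd(C) @ Vh)
    return EquilibriumPrediction(G=0.5 * (G + G.T), regime="gaussian", kappa=0.0)


def g_gaussian_drift(M, V, n: int, mu: float, Ne: float) -> EquilibriumPrediction:
    """Expected equilibrium G in the Gaussian regime with drift (finite Ne).

    Continuous interpolation in kappa between the infinite-population balance
    (kappa -> 0) and the neutral mutation-drift equilibrium ``4*Ne*n*mu*M``
    (kappa -> infinity, correlation rho_m).
    """
    M = as_cov_matrix(M, "M", require_pd=True)
    V = as_cov_matrix(V, "V", require_pd=True)
    if M.shape != V.shape:
        raise ValueError("M and V must have the same dimension")
    if not Ne > 0:
        raise ValueError("Ne must be positive")
    Vh, C = _shape_operator(M, V)
    kp = 1.0 / (4.0 * Ne * np.sqrt(2.0 * mu))  # scale-free drift parameter
    # (kp^2 I + C)^{1/2} - kp I, evaluated on C's eigenvalues in the
    # cancellation-free form w / (sqrt(kp^2 + w) + kp)
    w, U = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    vals = w / (np.sqrt(kp**2 + w) + kp)
    inner = (U * vals) @ U.T
    G = n * np.sqrt(2.0 * mu) * (Vh @ (0.5 * (inner + inner.T)) @ Vh)
    kap = kappa(float(V[0, 0]), Ne, mu, float(M[0, 0]))
    return EquilibriumPrediction(G=0.5 * (G + G.T), regime="gaussian-drift", kappa=kap)


def g_hoc_drift(
    M,
    V,
    n: int,
    mu: float,
    Ne: float,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> EquilibriumPrediction:
    """Stochastic House-of-Cards expectation of G under selection and drift.

    Monte-Carlo estimate of ``4*Ne*n*mu * E[a a^T / (1 + Ne a^T V^{-1} a)]``
    over ``n_draws`` mutation effects ``a ~ N(0, M)``.  The scalar
    ``Vs/(Ne*Va)`` governs the balance: small values give the
    selection-dominated limit (correlation :func:`rho_g_hoc`), large values
    the drift-dominated limit (G proportional to M, correlation rho_m).
    The standard error of the correlation is estimated from 10 batches.
    """
    M = as_cov_matrix(M, "M", require_pd=True)
    V = as_cov_matrix(V, "V", require_pd=True)
    if M.shape != V.shape:
        raise ValueError("M and V must have the same dimension")
    if not Ne > 0:
        raise ValueError("Ne must be positive")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or Generator) is required for the Monte-Carlo expectation")
        rng = np.random.default_rng(seed)
    k = M.shape[0]
    L = np.linalg.cholesky(M)
    a = rng.standard_normal((n_draws, k)) @ L.T
    iV = np.linalg.inv(V)
    denom = 1.0 + Ne * np.einsum("ij,jk,ik->i", a, iV, a)
    scale = 4.0 * Ne * n * mu
    G = scale * np.einsum("ij,ik,i->jk", a, a, 1.0 / denom) / n_draws
    G = 0.5 * (G + G.T)

    # batch-means standard error of the correlation (ratio estimator)
    n_batches = 10
    edges = np.linspace(0, n_draws, n_batches + 1).astype(int)
    rhos = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        Gb = np.einsum("ij,ik,i->jk", a[lo:hi], a[lo:hi], 1.0 / denom[lo:hi]) / (hi - lo)
        if k == 2:
            rhos.append(Gb[0, 1] / np.sqrt(Gb[0, 0] * Gb[1, 1]))
    mc_se = float(np.std(rhos, ddof=1) / np.sqrt(n_batches)) if rhos else None
    return EquilibriumPrediction(G=G, regime="hoc-drift", mc_se=mc_se)


def kappa(Vs: float, Ne: float, mu: float, Va: float) -> float:
    """Compound drift-vs-selection parameter of the Gaussian-regime equilibrium.

    ``kappa = sqrt(Vs / ((4*Ne)^2 * 2*mu*Va))``: strictly increasing in Vs,
    strictly decreasing in Ne, mu and Va.  kappa << 1 when
    ``Vs << (4*Ne)^2 * 2*mu*Va`` (selection-dominated); kappa >> 1 gives the
    drift-dominated (neutral) limit.
    """
    for name, x in (("Vs", Vs), ("Ne", Ne), ("mu", mu), ("Va", Va)):
        if not x > 0:
            raise ValueError(f"{name} must be positive, got {x}")
    return float(np.sqrt(Vs / (2.0 * mu * Va)) / (4.0 * Ne))


def ne_from_kappa(kap: float, Vs: float, mu: float, Va: float) -> float:
    """Effective size at which the Gaussian-regime compound parameter equals kappa."""
    if not kap > 0:
        raise ValueError("kappa must be positive")
    return float(np.sqrt(Vs / (2.0 * mu * Va)) / (4.0 * kap))


def wishart_compare(
    n_pairs: int,
    dimension: int = 2,
    df: int = 10,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Gaussian-regime vs House-of-Cards genetic correlation on random matrices.

    Draws ``n_pairs`` independent (V, M) pairs from a Wishart distribution
    scaled to expectation I (scale matrix I/df), computes the genetic
    correlation both from the Gaussian matrix equilibrium
    (:func:`g_gaussian_infinite`) and from the closed HoC form
    (:func:`rho_g_hoc` on the extracted shape parameters), and returns the
    paired table with columns ``pair_id, rho_gaussian, rho_hoc, abs_diff``.
    The two regimes predict identical correlations; the table quantifies the
    agreement.  Only the two-trait case is supported (the closed form is a
    two-trait expression).
    """
    if dimension != 2:
        raise ValueError("wishart_compare is defined for dimension 2 (pairwise closed form)")
    if df < dimension + 1:
        raise ValueError(f"df must be at least dimension + 1 = {dimension + 1}")
    rng = np.random.default_rng(seed)
    scale = np.eye(dimension) / df
    rows = []
    for i in range(n_pairs):
        V = stats.wishart.rvs(df, scale, random_state=rng)
        M = stats.wishart.rvs(df, scale, random_state=rng)
        pred = g_gaussian_infinite(M, V, n=1, mu=0.5)
        p = params_from_cov(M, V)
        rho_h = rho_g_hoc(p.rho_m, p.rho_s, p.phi)
        rows.append((i, pred.rho_g, rho_h, abs(pred.rho_g - rho_h)))
    return pd.DataFrame(rows, columns=["pair_id", "rho_gaussian", "rho_hoc", "abs_diff"])


def shared_eigenvector_check(
    M,
    V,
    ne_values: Sequence[float],
    n: int = 20,
    mu: float = 0.01,
    comm_rtol: float = 1e-10,
) -> float:
    """Largest angle between eigenvectors of Gbar and of V across drift levels.

    Requires M and V to commute (share eigenvectors, e.g. phi_s = phi_m = 1);
    non-commuting inputs are rejected.  When they commute, the equilibrium
    expectation preserves the common eigenvectors at every drift intensity -
    drift and selection strength re-weight the eigenvalues without rotating
    G - so the returned maximal angle is numerically zero.
    """
    M = as_cov_matrix(M, "M", require_pd=True)
    V = as_cov_matrix(V, "V", require_pd=True)
    comm = M @ V - V @ M
    scale = np.linalg.norm(M, 2) * np.linalg.norm(V, 2)
    if np.linalg.norm(comm, 2) > comm_rtol * scale:
        raise ValueError("M and V do not commute (no shared eigenvectors)")
    _, Uv = np.linalg.eigh(V)
    max_angle = 0.0
    for Ne in ne_values:
        G = g_gaussian_drift(M, V, n=n, mu=mu, Ne=Ne).G
        _, Ug = np.linalg.eigh(G)
        # best alignment of each eigenvector of G with some eigenvector of V,
        # measured through the sine (residual norm), which stays accurate for
        # nearly perfect alignment where arccos of the cosine saturates
        for j in range(Ug.shape[1]):
            b = Ug[:, j]
            i = int(np.argmax(np.abs(Uv.T @ b)))
            a = Uv[:, i]
            sine = np.linalg.norm(b - a * (a @ b))
            max_angle = max(max_angle, float(np.arcsin(min(sine, 1.0))))
    return max_angle
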