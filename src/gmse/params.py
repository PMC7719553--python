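"""Parameterization of mutation and selection, covariance-matrix utilities,
and the selection-aware effective-population-size correction.

Two pleiotropically coupled quantitative traits are described by a per-locus
mutation covariance matrix ``M`` and a stabilizing-selection width matrix
``V`` acting on breeding values, each factored into an overall scale and a
shape/correlation part::

    M = Va * [[1, rho_m*sqrt(phi_m)], [rho_m*sqrt(phi_m), phi_m]]
    V = Vs * [[1, rho_s*sqrt(phi_s)], [rho_s*sqrt(phi_s), phi_s]]

``Va`` is the variance of mutational effects on trait 1, ``phi_m`` the ratio
of mutational variances (trait 2 over trait 1) and ``rho_m`` the mutational
correlation; ``Vs`` is the width of the fitness peak on breeding values for
trait 1 (large ``Vs`` = weak selection), ``phi_s`` the ratio of widths and
``rho_s`` the correlational-selection coefficient.  Selection on the
expressed phenotype uses ``Omega = V - E`` where ``E`` is the covariance of
the residual (environmental) component of the phenotype.

General k x k covariance matrices are accepted everywhere a matrix argument
appears; the scalar parameterizations above cover the two-trait case.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "MutationParams",
    "SelectionParams",
    "ShapeSummary",
    "ExtractedParams",
    "as_cov_matrix",
    "build_mutation_matrix",
    "build_selection_matrix",
    "peak_on_phenotype",
    "effective_size",
    "census_for_target_ne",
    "cov_to_shape",
    "params_from_cov",
    "read_matrix",
    "write_matrix",
    "load_config",
]

#: relative tolerance for symmetry / positive-semidefiniteness checks
PSD_RTOL = 1e-12


def _check_correlation(rho: float, name: str) -> None:
    if not -1.0 < rho < 1.0:
        raise ValueError(f"{name} must lie strictly inside (-1, 1), got {rho}")


def _check_positive(x: float, name: str) -> None:
    if not x > 0.0:
        raise ValueError(f"{name} must be positive, got {x}")


@dataclass(frozen=True)
class MutationParams:
    """Per-locus pleiotropic mutation kernel for two traits.

    Parameters
    ----------
    v_alpha : float
        Variance of mutational effects on trait 1 (squared trait units).
    rho_m : float
        Mutational correlation between the two traits, in (-1, 1).
    phi_m : float
        Ratio of mutational variances, trait 2 over trait 1 (> 0).
    mu : float
        Per-allele, per-locus, per-generation mutation probability.
    n_loci : int
        Number of unlinked diploid loci; total mutation rate is ``2*n_loci*mu``.
    """

    v_alpha: float
    rho_m: float
    phi_m: float = 1.0
    mu: float = 0.01
    n_loci: int = 20

    def __post_init__(self) -> None:
        _check_positive(self.v_alpha, "v_alpha")
        _check_correlation(self.rho_m, "rho_m")
        _check_positive(self.phi_m, "phi_m")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not (isinstance(self.n_loci, (int, np.integer)) and self.n_loci >= 1):
            raise ValueError(f"n_loci must be a positive integer, got {self.n_loci}")

    def matrix(self) -> np.ndarray:
        return build_mutation_matrix(self)


@dataclass(frozen=True)
class SelectionParams:
    """Gaussian fitness-peak description on breeding values (two traits).

    ``v_s`` is the squared width of the peak for trait 1 (inversely
    proportional to the strength of stabilizing selection), ``phi_s`` the
    ratio of squared widths trait 2 / trait 1, and ``rho_s`` the
    correlational-selection coefficient.
    """

    v_s: float
    rho_s: float
    phi_s: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(self.v_s, "v_s")
        _check_correlation(self.rho_s, "rho_s")
        _check_positive(self.phi_s, "phi_s")

    def matrix(self) -> np.ndarray:
        return build_selection_matrix(self)


def _scaled_shape(scale: float, rho: float, phi: float) -> np.ndarray:
    off = rho * np.sqrt(phi)
    return scale * np.array([[1.0, off], [off, phi]])


def build_mutation_matrix(p: MutationParams) -> np.ndarray:
    """Return the 2x2 per-locus mutation covariance matrix M."""
    return _scaled_shape(p.v_alpha, p.rho_m, p.phi_m)


def build_selection_matrix(p: SelectionParams) -> np.ndarray:
    """Return the 2x2 stabilizing-selection width matrix V on breeding values."""
    return _scaled_shape(p.v_s, p.rho_s, p.phi_s)


def as_cov_matrix(a, name: str = "matrix", require_pd: bool = False) -> np.ndarray:
    """Validate ``a`` as a symmetric positive-(semi)definite covariance matrix.

    Symmetry is required to within ``PSD_RTOL`` relative; eigenvalues may dip
    to ``-PSD_RTOL`` times the largest eigenvalue (double-precision noise).
    With ``require_pd=True`` the matrix must be strictly positive-definite.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim == 0:
        a = a.reshape(1, 1)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    scale = np.max(np.abs(a)) or 1.0
    if np.max(np.abs(a - a.T)) > PSD_RTOL * scale:
        raise ValueError(f"{name} is not symmetric")
    a = 0.5 * (a + a.T)
    w = np.linalg.eigvalsh(a)
    if require_pd:
        if w[0] <= PSD_RTOL * max(w[-1], 0.0):
            raise ValueError(f"{name} is not positive-definite (min eigenvalue {w[0]:g})")
    elif w[0] < -PSD_RTOL * max(w[-1], 0.0):
        raise ValueError(f"{name} is not positive-semidefinite (min eigenvalue {w[0]:g})")
    return a


def peak_on_phenotype(V, E) -> np.ndarray:
    """Width matrix of the fitness peak on expressed phenotypes, Omega = V - E.

    Selection is parameterized on breeding values through ``V``; the
    individual-level fitness function acts on phenotypes (breeding value plus
    residual with covariance ``E``) with width ``Omega = V - E``.  Raises if
    ``V - E`` is not positive-definite, i.e. if selection on breeding values
    is narrower than the residual variation permits.
    """
    V = as_cov_matrix(V, "V", require_pd=True)
    E = as_cov_matrix(E, "E")
    if V.shape != E.shape:
        raise ValueError("V and E must have the same dimension")
    return as_cov_matrix(V - E, "Omega = V - E", require_pd=True)


def _drift_inflation_factor(Omega, E) -> float:
    """det[I - ((Omega+E)^-1 E)^2], the effective-size reduction factor."""
    Omega = as_cov_matrix(Omega, "Omega")
    E = as_cov_matrix(E, "E")
    if Omega.shape != E.shape:
        raise ValueError("Omega and E must have the same dimension")
    V = as_cov_matrix(Omega + E, "Omega + E", require_pd=True)
    B = np.linalg.solve(V, E)
    k = V.shape[0]
    return float(np.linalg.det(np.eye(k) - B @ B))


def effective_size(N: float, Omega, E) -> float:
    """Effective population size under stabilizing selection on residual variation.

    Selection on the non-heritable component of the phenotype creates fitness
    variance among parents with identical breeding values, inflating genetic
    drift.  Near the optimum this reduces the effective size to::

        Ne = N * det[I - ((Omega + E)^-1 E)^2]

    which satisfies ``Ne <= N``, with equality iff ``E = 0``.  The result is
    an approximation valid when breeding values sit close to the optimum
    (genetic variances small relative to the fitness-peak width); it is not
    extrapolated beyond that regime.
    """
    if not N > 0:
        raise ValueError("N must be positive")
    return N * _drift_inflation_factor(Omega, E)


def census_for_target_ne(Ne: float, Omega, E) -> int:
    """Census size N yielding a target effective size Ne under selection on E.

    Inverts :func:`effective_size`, rounding to the nearest integer (the
    rounding error in Ne is O(1/N)).  Used to hold Ne constant as the
    strength of selection varies across simulation runs.
    """
    if not Ne > 0:
        raise ValueError("Ne must be positive")
    N = int(round(Ne / _drift_inflation_factor(Omega, E)))
    return max(N, 1)


@dataclass(frozen=True)
class ShapeSummary:
    """Eigen-summary of a 2x2 (or k x k) covariance matrix.

    ``angle`` is the orientation of the first eigenvector relative to the
    trait-1 axis, reported with non-negative trait-1 loading so it lies in
    (-pi/2, pi/2] (eigenvectors are sign-ambiguous). ``correlation`` is the
    off-diagonal correlation for k=2; for k > 2 both fields are NaN and the
    full pairwise correlation matrix should be computed from the input.
    """

    eigenvalues: np.ndarray
    angle: float
    total_variance: float
    correlation: float


def cov_to_shape(C) -> ShapeSummary:
    """Summarize size, shape and orientation of a covariance matrix.

    Raises ``ValueError`` for a zero matrix, whose correlation is undefined.
    """
    C = as_cov_matrix(C, "C")
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = w[order]
    U = U[:, order]
    if np.all(C == 0.0):
        raise ValueError("zero matrix: correlation and orientation are undefined")
    k = C.shape[0]
    if k == 2:
        v = U[:, 0]
        if v[0] < 0 or (v[0] == 0 and v[1] < 0):
            v = -v
        angle = float(np.arctan2(v[1], v[0]))
        if angle <= -np.pi / 2:  # v[0] == 0 edge
            angle += np.pi
        corr = float(C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]))
    else:
        angle = float("nan")
        corr = float("nan")
    return ShapeSummary(
        eigenvalues=w,
        angle=angle,
        total_variance=float(np.trace(C)),
        correlation=corr,
    )


@dataclass(frozen=True)
class ExtractedParams:
    """Shape parameters recovered from explicit 2x2 mutation/selection matrices.

    ``phi = phi_s / phi_m`` is the compound shape-ratio parameter governing
    the mutation-selection-balance genetic correlation: the ratio of
    strengths of stabilizing selection between the two traits times the
    ratio of their mutational variances.  The genetic correlation is
    invariant under ``phi -> 1/phi``.
    """

    v_alpha: float
    rho_m: float
    phi_m: float
    v_s: float
    rho_s: float
    phi_s: float
    phi: float


def params_from_cov(M, V) -> ExtractedParams:
    """Recover (Va, rho_m, phi_m), (Vs, rho_s, phi_s) and phi from 2x2 M and V."""
    M = as_cov_matrix(M, "M", require_pd=True)
    V = as_cov_matrix(V, "V", require_pd=True)
    if M.shape != (2, 2) or V.shape != (2, 2):
        raise ValueError("params_from_cov requires 2x2 matrices")
    v_alpha = float(M[0, 0])
    phi_m = float(M[1, 1] / M[0, 0])
    rho_m = float(M[0, 1] / np.sqrt(M[0, 0] * M[1, 1]))
    v_s = float(V[0, 0])
    phi_s = float(V[1, 1] / V[0, 0])
    rho_s = float(V[0, 1] / np.sqrt(V[0, 0] * V[1, 1]))
    return ExtractedParams(
        v_alpha=v_alpha,
        rho_m=rho_m,
        phi_m=phi_m,
        v_s=v_s,
        rho_s=rho_s,
        phi_s=phi_s,
        phi=phi_s / phi_m,
    )


# ---------------------------------------------------------------------------
# plain-text interfaces


def read_matrix(path: Union[str, Path]) -> np.ndarray:
    """Read a whitespace-delimited k x k covariance matrix from a text file."""
    return as_cov_matrix(np.loadtxt(path, ndmin=2), str(path))


def write_matrix(path: Union[str, Path], C) -> None:
    """Write a covariance matrix as a whitespace-delimited text table."""
    np.savetxt(path, np.atleast_2d(np.asarray(C, dtype=float)), fmt="%.17g")


def load_config(path: Union[str, Path]) -> dict:
    """Load a TOML parameter file.

    Recognized keys: ``Va, rho_m, phi_m, mu, n_loci, Vs, rho_s, phi_s, Ne, E``
    plus run control (``generations, burn_in, sampling_interval, seed``).
    ``E`` may be a scalar (isotropic residual variance) or a list of rows.
    """
    if sys.version_info >= (3, 11):
        import tomllib
    else:  # pragma: no cover
        import tomli as tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)
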