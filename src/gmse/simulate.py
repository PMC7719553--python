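"""Genetically explicit forward-time simulation of stabilizing selection.

Wright-Fisher-like population of N hermaphroditic, sexually reproducing
diploid individuals with non-overlapping generations.  Each individual
carries ``n_loci`` unlinked, fully pleiotropic loci; every allele is a
k-vector of real-valued effects (continuum of alleles) and the breeding
value is the sum over all ``2*n_loci`` allelic vectors.  One generation is:

1. **Phenotype and fitness** - phenotype = breeding value + residual drawn
   from N(0, E); expected fitness ``W(z) = exp(-z^T Omega^{-1} z / 2)`` with
   the optimum at the origin and ``Omega = V - E``.
2. **Selection and reproduction** - N mating events; each draws two distinct
   parents with probability proportional to fitness (with replacement across
   events; selfing excluded) and produces exactly one offspring.
3. **Offspring production** - one random allele from each parent at every
   locus (free recombination); each transmitted allele then mutates with
   probability ``mu``, adding an increment drawn from N(0, M).

Because selection on the residual (non-heritable) phenotypic component adds
fitness variance among parents, it intensifies drift; the census size is
therefore set from the target effective size with
:func:`gmse.params.census_for_target_ne` so Ne stays constant across
selection strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .params import (
    MutationParams,
    SelectionParams,
    ShapeSummary,
    as_cov_matrix,
    census_for_target_ne,
    cov_to_shape,
    peak_on_phenotype,
)

__all__ = [
    "SimConfig",
    "PopulationState",
    "GEstimate",
    "init_population",
    "step_generation",
    "estimate_G",
    "genic_decomposition",
    "realized_ne",
    "reproductive_effective_size",
    "run_simulation",
]


@dataclass
class SimConfig:
    """Run configuration for the individual-based simulation.

    ``M``, ``V`` and ``E`` are k x k covariance matrices (any k >= 1);
    ``V - E`` must be positive-definite.  ``ne_target`` is the effective size
    the run should realize; the census size is derived from it.  The fitness
    optimum is fixed at the zero vector and the population starts monomorphic
    there.  ``burn_in`` defaults to 30% of ``generations``; G is sampled
    every ``sampling_interval`` generations after the burn-in (set to 1 for
    every-generation sampling), and the run must contain at least 10 samples.
    """

    M: np.ndarray
    V: np.ndarray
    mu: float
    n_loci: int
    ne_target: float
    generations: int
    E: Optional[np.ndarray] = None
    burn_in: Optional[int] = None
    sampling_interval: int = 10
    seed: Optional[int] = None
    track_genic: bool = True

    # derived, set in __post_init__
    Omega: np.ndarray = field(init=False, repr=False)
    census_n: int = field(init=False)
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.M = as_cov_matrix(self.M, "M", require_pd=True)
        self.V = as_cov_matrix(self.V, "V", require_pd=True)
        self.k = self.M.shape[0]
        if self.E is None:
            self.E = np.eye(self.k)
        self.E = as_cov_matrix(self.E, "E")
        if self.V.shape != self.M.shape or self.E.shape != self.M.shape:
            raise ValueError("M, V and E must have the same dimension")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be a positive integer")
        self.Omega = peak_on_phenotype(self.V, self.E)
        self.census_n = census_for_target_ne(self.ne_target, self.Omega, self.E)
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if self.burn_in is None:
            self.burn_in = int(0.3 * self.generations)
        if not 0 <= self.burn_in < self.generations:
            raise ValueError("burn_in must be a non-negative integer < generations")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be a positive integer")
        n_samples = (self.generations - self.burn_in - 1) // self.sampling_interval + 1
        if n_samples < 10:
            raise ValueError(
                f"run too short: only {n_samples} post-burn-in samples "
                "(need at least 10; lengthen the run or shrink the interval)"
            )
        # cached per-run constants
        self._chol_E = np.linalg.cholesky(self.E) if np.any(self.E) else np.zeros_like(self.E)
        self._chol_M = np.linalg.cholesky(self.M)
        self._inv_Omega = np.linalg.inv(self.Omega)

    @classmethod
    def from_params(
        cls,
        mutation: MutationParams,
        selection: SelectionParams,
        ne_target: float,
        generations: int,
        **kwargs,
    ) -> "SimConfig":
        """Build a two-trait configuration from scalar parameter sets."""
        return cls(
            M=mutation.matrix(),
            V=selection.matrix(),
            mu=mutation.mu,
            n_loci=mutation.n_loci,
            ne_target=ne_target,
            generations=generations,
            **kwargs,
        )


@dataclass
class PopulationState:
    """Allelic effect values, indexed (individual, locus, allele, trait)."""

    alleles: np.ndarray  # shape (N, n_loci, 2, k)
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def breeding_values(self) -> np.ndarray:
        """(N, k) array: sum of the 2*n_loci allelic vectors per individual."""
        return self.alleles.sum(axis=(1, 2))


def init_population(config: SimConfig) -> PopulationState:
    """Monomorphic population at the optimum (all allelic values zero)."""
    N = config.census_n
    return PopulationState(
        alleles=np.zeros((N, config.n_loci, 2, config.k)), generation=0
    )


def _fitness_weights(config: SimConfig, bv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    N = bv.shape[0]
    z = bv + rng.standard_normal((N, config.k)) @ config._chol_E.T
    logw = -0.5 * np.einsum("ij,jk,ik->i", z, config._inv_Omega, z)
    return np.exp(logw)


def _sample_parent_pairs(
    w: np.ndarray, N: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """N events, two distinct fitness-proportional parents each (no selfing)."""
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise RuntimeError(
            "all fitnesses are numerically zero: the population is too far "
            "from the optimum for the chosen selection matrix"
        )
    cum = np.cumsum(w)
    a = np.searchsorted(cum, rng.random(N) * total)
    b = np.searchsorted(cum, rng.random(N) * total)
    clash = a == b
    while clash.any():  # redraw the second parent of each selfing event
        b[clash] = np.searchsorted(cum, rng.random(int(clash.sum())) * total)
        clash = a == b
    return a, b


def step_generation(
    state: PopulationState,
    config: SimConfig,
    rng: np.random.Generator,
    return_parents: bool = False,
):
    """Advance the population by one full life cycle.

    Returns the next :class:`PopulationState`; with ``return_parents=True``
    also returns the two parent-index arrays of the N mating events.
    """
    alleles = state.alleles
    N, n, _, k = alleles.shape
    w = _fitness_weights(config, alleles.sum(axis=(1, 2)), rng)
    a, b = _sample_parent_pairs(w, N, rng)

    # one random allele per locus from each parent (free recombination)
    loci = np.arange(n)
    flat = alleles.reshape(N * n * 2, k)
    idx_a = (a[:, None] * n + loci) * 2 + rng.integers(0, 2, (N, n))
    idx_b = (b[:, None] * n + loci) * 2 + rng.integers(0, 2, (N, n))
    offspring = np.stack([flat[idx_a], flat[idx_b]], axis=2)

    # continuum-of-alleles mutation: increment the transmitted allelic value
    mutated = rng.random((N, n, 2)) < config.mu
    n_mut = int(mutated.sum())
    if n_mut:
        offspring[mutated] += rng.standard_normal((n_mut, k)) @ config._chol_M.T

    new_state = PopulationState(alleles=offspring, generation=state.generation + 1)
    if return_parents:
        return new_state, (a, b)
    return new_state


def estimate_G(state: PopulationState) -> np.ndarray:
    """Realized genetic covariance matrix of breeding values (denominator N-1)."""
    if state.n_individuals < 2:
        raise ValueError("at least 2 individuals are required to estimate G")
    bv = state.breeding_values
    return np.atleast_2d(np.cov(bv, rowvar=False, ddof=1))


def genic_decomposition(state: PopulationState) -> Tuple[np.ndarray, np.ndarray]:
    """Split realized G into genic and between-locus association components.

    The genic part sums, over the ``2*n_loci`` allele slots, the
    across-individual covariance of that slot's allelic vector - the variance
    expected if allelic values were independent between slots.  The remainder
    (``estimate_G - genic``) is the contribution of between-locus
    associations (linkage disequilibrium), the "hidden" variance that builds
    up under strong stabilizing selection even for unlinked loci.  The two
    parts sum to the realized G exactly, by construction.
    """
    if state.n_individuals < 2:
        raise ValueError("at least 2 individuals are required")
    N, n, _, k = state.alleles.shape
    slots = state.alleles.reshape(N, 2 * n, k)
    dev = slots - slots.mean(axis=0)
    genic = np.einsum("isj,isk->jk", dev, dev) / (N - 1)
    genic = 0.5 * (genic + genic.T)
    linkage = estimate_G(state) - genic
    return genic, linkage


def realized_ne(offspring_counts: np.ndarray) -> float:
    """Variance-effective size from one generation of offspring counts.

    ``offspring_counts[i]`` is the number of gametes parent ``i`` contributed
    (two per offspring, summing to 2N).  Uses the classical offspring-number
    variance estimator ``Ne = (4N - 2) / (Vk + 2)``: equal contributions give
    the minimal-drift bound ``Ne = 2N - 1 >= N``, Wright-Fisher (multinomial)
    reproduction gives ``Ne ~= N``.
    """
    counts = np.asarray(offspring_counts, dtype=float)
    N = counts.size
    if N < 2:
        raise ValueError("need counts for at least 2 parents")
    if counts.sum() != 2 * N or (counts < 0).any():
        raise ValueError("offspring counts must be non-negative and sum to 2N")
    vk = counts.var(ddof=0)
    return float((4 * N - 2) / (vk + 2))


def reproductive_effective_size(
    config: SimConfig,
    n_generations: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo variance-effective size of the reproduction step alone.

    Holds the population monomorphic at the optimum (so all fitness variance
    comes from the residual component E) and repeats the selection/mating
    step of the life cycle, estimating Ne from the mean offspring-number
    variance across ``n_generations`` independent replicate generations.
    This is the direct empirical counterpart of
    :func:`gmse.params.effective_size`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N = config.census_n
    bv = np.zeros((N, config.k))
    vks = np.empty(n_generations)
    for i in range(n_generations):
        w = _fitness_weights(config, bv, rng)
        a, b = _sample_parent_pairs(w, N, rng)
        counts = np.bincount(a, minlength=N) + np.bincount(b, minlength=N)
        vks[i] = counts.var(ddof=0)
    return float((4 * N - 2) / (vks.mean() + 2))


@dataclass
class GEstimate:
    """Time series and stationary summary of the realized G matrix."""

    G_samples: np.ndarray  # (S, k, k)
    generations_sampled: np.ndarray  # (S,)
    mean_G: np.ndarray
    rho_g: float
    se_rho_g: float
    shape: Optional[ShapeSummary]
    census_n: int
    realized_ne_mean: float
    seed: Optional[int]
    genic_samples: Optional[np.ndarray] = None
    genic_mean: Optional[np.ndarray] = None

    @property
    def rho_series(self) -> np.ndarray:
        G = self.G_samples
        if G.shape[1] != 2:
            raise ValueError("per-sample correlation series is defined for k = 2")
        with np.errstate(invalid="ignore", divide="ignore"):
            return G[:, 0, 1] / np.sqrt(G[:, 0, 0] * G[:, 1, 1])


def _rho_of(G: np.ndarray) -> float:
    if G.shape[0] != 2 or G[0, 0] <= 0 or G[1, 1] <= 0:
        return float("nan")
    return float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))


def run_simulation(config: SimConfig, progress: bool = False) -> GEstimate:
    """Run the full chain and summarize G at stationarity.

    Iterates the life cycle for ``config.generations`` generations from a
    monomorphic start, sampling the realized G (and its genic decomposition)
    every ``sampling_interval`` generations after the burn-in.  The
    stationary mean is taken over the post-burn-in samples; the standard
    error of the stationary genetic correlation uses 10 batch means, which is
    robust to the autocorrelation of the chain.  Offspring-number variance is
    recorded at each sampled generation as a realized-Ne diagnostic.
    """
    import sys

    rng = np.random.default_rng(config.seed)
    state = init_population(config)
    N = config.census_n
    G_samples, gens, genic_samples, vks = [], [], [], []
    next_report = config.generations // 10 or 1
    for _ in range(config.generations):
        state, (a, b) = step_generation(state, config, rng, return_parents=True)
        g = state.generation
        if g > config.burn_in and (g - config.burn_in - 1) % config.sampling_interval == 0:
            G = estimate_G(state)
            if not np.isfinite(G).all():
                raise RuntimeError(f"non-finite G at generation {g}; aborting run")
            G_samples.append(G)
            gens.append(g)
            counts = np.bincount(a, minlength=N) + np.bincount(b, minlength=N)
            vks.append(counts.var(ddof=0))
            if config.track_genic:
                genic_samples.append(genic_decomposition(state)[0])
        if progress and g % next_report == 0:
            print(f"generation {g}/{config.generations}", file=sys.stderr)

    G_samples = np.array(G_samples)
    mean_G = G_samples.mean(axis=0)
    rho = _rho_of(mean_G)

    # batch-means SE of the stationary correlation
    S = len(G_samples)
    n_batches = min(10, S)
    if mean_G.shape[0] == 2:
        edges = np.linspace(0, S, n_batches + 1).astype(int)
        batch_rhos = [
            _rho_of(G_samples[lo:hi].mean(axis=0)) for lo, hi in zip(edges[:-1], edges[1:])
        ]
        se = float(np.std(batch_rhos, ddof=1) / np.sqrt(n_batches))
    else:
        se = float("nan")

    try:
        shape = cov_to_shape(mean_G)
    except ValueError:
        shape = None
    genic_arr = np.array(genic_samples) if genic_samples else None
    return GEstimate(
        G_samples=G_samples,
        generations_sampled=np.array(gens),
        mean_G=mean_G,
        rho_g=rho,
        se_rho_g=se,
        shape=shape,
        census_n=N,
        realized_ne_mean=float((4 * N - 2) / (np.mean(vks) + 2)),
        seed=config.seed,
        genic_samples=genic_arr,
        genic_mean=genic_arr.mean(axis=0) if genic_arr is not None else None,
    )
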