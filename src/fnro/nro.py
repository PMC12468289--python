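"""Nuclear Reaction Optimization (NRO) over a continuous [0,1]^d search space.

NRO is a physics-inspired population metaheuristic alternating two phases:

* **fission** (exploration): each solution is perturbed by a Gaussian draw
  centered on itself or the global best, with an adaptive per-dimension
  scale ``(log g / g) * |difference to best|`` plus a recoil term built from
  a "heated neutron" — the mean of two random population members — scaled by
  an integer mutation factor.
* **fusion** (exploitation): an *ionization* sub-phase recombines
  coordinates of random peers, then a *fusion* sub-phase pulls solutions
  toward the global best using two random peers.  Whenever the solutions
  involved are too similar to produce a useful difference vector, a
  heavy-tailed Lévy flight (Mantegna's algorithm) supplies a long jump to
  escape stagnation.

For gene selection, a position in [0,1]^d over a filtered gene pool is
decoded to a fixed-size subset by taking the k largest components.  Survivor
selection is greedy elitist: a candidate replaces its parent only when
strictly better.  Search stops after ``max_generations`` or after
``patience`` consecutive generations without strict improvement of the
global best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

from .exceptions import ConfigError, DomainError, PipelineError, StateError


@dataclass
class NROConfig:
    """Tunable parameters of the NRO search.

    ``population_size``/``max_generations``/``patience`` default to the
    full-scale protocol values (500 / 30 / 5); the branch probability
    ``p_beta`` and the Lévy scale/exponent default to 0.5 and (0.01, 1.5),
    the canonical Mantegna choice.
    """

    population_size: int = 500
    max_generations: int = 30
    patience: int = 5
    p_beta: float = 0.5
    levy_alpha: float = 0.01
    levy_exponent: float = 1.5
    similarity_tol: float = 1e-10
    seed: int | None = None
    neutron_mode: str = "mean"  # or "product"
    decoder: str = "topk"  # or "threshold"

    def __post_init__(self):
        if self.population_size < 4:
            raise ConfigError(
                "population_size must be >= 4 (operators draw two distinct "
                "peers besides self and best)"
            )
        if not 0.0 <= self.p_beta <= 1.0:
            raise ConfigError("p_beta must lie in [0, 1]")
        if self.similarity_tol <= 0:
            raise ConfigError("similarity_tol must be positive")
        if not 0.0 < self.levy_exponent <= 2.0:
            raise ConfigError("levy_exponent must lie in (0, 2]")
        if self.neutron_mode not in ("mean", "product"):
            raise ConfigError("neutron_mode must be 'mean' or 'product'")
        if self.decoder not in ("topk", "threshold"):
            raise ConfigError("decoder must be 'topk' or 'threshold'")


@dataclass
class Solution:
    """One NRO individual: a continuous position with its decoded gene
    subset and cached fitness."""

    position: np.ndarray
    fitness: float | None = None
    decoded: tuple | None = None


@dataclass
class NROTrace:
    """Audit record of one NRO run."""

    best_fitness_per_generation: list = field(default_factory=list)
    generations_run: int = 0
    stopped_early: bool = False
    evaluations: int = 0


# ---------------------------------------------------------------------------
# primitive operators
# ---------------------------------------------------------------------------

def initialize_population(n: int, d: int, rng) -> np.ndarray:
    """Uniform random positions on [0,1]^d, shape (n, d)."""
    if n < 4:
        raise ConfigError("population size must be >= 4")
    if d < 1:
        raise ConfigError("dimension must be >= 1")
    return rng.uniform(0.0, 1.0, size=(n, d))


def _two_distinct_peers(n: int, i: int, rng) -> tuple[int, int]:
    """Two indices, distinct from each other and from i."""
    pool = np.delete(np.arange(n), i)
    p, q = rng.choice(pool, size=2, replace=False)
    return int(p), int(q)


def heated_neutron(pop: np.ndarray, i: int, rng, mode: str = "mean") -> np.ndarray:
    """Combination of two random population members (both != i), injected
    into the fission recoil term.  Default is the elementwise mean, which
    keeps the neutron inside the bounds."""
    n = pop.shape[0]
    if n < 3:
        raise StateError("population too small for heated neutron (need >= 3)")
    p, q = _two_distinct_peers(n, i, rng)
    if mode == "product":
        return pop[p] * pop[q]
    return 0.5 * (pop[p] + pop[q])


def mantegna_sigma(beta: float) -> float:
    """Standard deviation of the numerator normal in Mantegna's Lévy
    algorithm: sigma_u = {Gamma(1+b) sin(pi b/2) / [Gamma((1+b)/2) b
    2^((b-1)/2)]}^(1/b)."""
    if not 0.0 < beta <= 2.0:
        raise ConfigError("levy exponent must lie in (0, 2]")
    num = _gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(beta: float, n: int, rng) -> np.ndarray:
    """``n`` heavy-tailed Lévy steps via Mantegna: u / |v|^(1/beta) with
    u ~ N(0, sigma_u^2), v ~ N(0, 1)."""
    sigma_u = mantegna_sigma(beta)
    u = rng.normal(0.0, sigma_u, size=n)
    v = rng.normal(0.0, 1.0, size=n)
    return u / np.abs(v) ** (1.0 / beta)


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def fission_step(
    pop: np.ndarray, best: np.ndarray, g: int, rng, cfg: NROConfig
) -> np.ndarray:
    """Fission-phase candidates for every solution at generation ``g``.

    With probability ``p_beta`` the Gaussian is centered on the global best
    with per-dimension scale (log g / g)|X_i - X_best| and the recoil uses a
    mutation factor in {1, 2}; otherwise it is centered on X_i with scale
    (log g / g)|X_r - X_best| (X_r a random peer) and a factor in {2, 3}.
    Results are clipped to [0, 1].
    """
    if g < 1:
        raise DomainError("generation index starts at 1")
    n, d = pop.shape
    shrink = math.log(g) / g  # 0 at g=1: Gaussian degenerates to its center
    out = np.empty_like(pop)
    for i in range(n):
        nei = heated_neutron(pop, i, rng, mode=cfg.neutron_mode)
        branch = rng.uniform()
        factor_draw = rng.uniform()
        randn = rng.standard_normal(d)
        if branch <= cfg.p_beta:
            sigma = shrink * np.abs(pop[i] - best)
            pne = int(np.rint(factor_draw + 1.0))  # in {1, 2}
            center = best
        else:
            r = int(rng.choice(np.delete(np.arange(n), i)))
            sigma = shrink * np.abs(pop[r] - best)
            pne = int(np.rint(factor_draw + 2.0))  # in {2, 3}
            center = pop[i]
        gauss = rng.normal(center, sigma) if shrink > 0 else center.copy()
        out[i] = _clip(gauss + randn * (best - pne * nei))
    return out


def ionization_step(
    pop: np.ndarray, best: np.ndarray, rng, cfg: NROConfig
) -> np.ndarray:
    """Ionization sub-phase: per-dimension recombination of two random peers,
    falling back to a Lévy flight on dimensions where the difference term is
    below ``similarity_tol``."""
    n, d = pop.shape
    if n < 3:
        raise StateError("population too small for ionization (need >= 3)")
    out = np.empty_like(pop)
    for i in range(n):
        r1, r2 = _two_distinct_peers(n, i, rng)
        rand = rng.uniform(size=d)
        levy = levy_step(cfg.levy_exponent, d, rng)
        diff = pop[r2] - pop[i]
        similar = np.abs(diff) < cfg.similarity_tol
        recomb = np.where(
            rand <= 0.5, pop[r1] + rand * diff, pop[r1] - rand * diff
        )
        levy_move = pop[i] + cfg.levy_alpha * levy * (pop[i] - best)
        out[i] = _clip(np.where(similar, levy_move, recomb))
    return out


def fusion_step(
    pop: np.ndarray, best: np.ndarray, rng, cfg: NROConfig
) -> np.ndarray:
    """Fusion sub-phase: pull each solution toward the best using two random
    peers; when the peers nearly coincide (vector norm below
    ``similarity_tol``) take a Lévy flight along the direction to the best
    instead."""
    n, d = pop.shape
    if n < 3:
        raise StateError("population too small for fusion (need >= 3)")
    out = np.empty_like(pop)
    for i in range(n):
        r1, r2 = _two_distinct_peers(n, i, rng)
        if np.linalg.norm(pop[r1] - pop[r2]) >= cfg.similarity_tol:
            ra, rb = rng.uniform(), rng.uniform()
            out[i] = _clip(
                pop[i] + ra * (pop[r1] - best) + rb * (pop[r2] - best)
            )
        else:
            levy = levy_step(cfg.levy_exponent, d, rng)
            out[i] = _clip(pop[i] + cfg.levy_alpha * levy * (pop[i] - best))
    return out


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_top_k(position: np.ndarray, k: int) -> tuple:
    """Indices of the ``k`` largest components, ties by ascending index,
    returned as a sorted tuple."""
    position = np.asarray(position)
    d = position.size
    if not 1 <= k <= d:
        raise DomainError(f"k={k} out of range for dimension {d}")
    order = np.argsort(-position, kind="stable")
    return tuple(sorted(int(j) for j in order[:k]))


def decode_threshold(position: np.ndarray, threshold: float = 0.5) -> tuple:
    """Alternative decoder: components >= threshold are selected (variable
    subset size; may be empty)."""
    position = np.asarray(position)
    return tuple(int(j) for j in np.flatnonzero(position >= threshold))


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run_nro(fitness_fn, d: int, k: int, cfg: NROConfig) -> tuple[Solution, NROTrace]:
    """Run the full NRO search and return the best solution ever seen.

    Parameters
    ----------
    fitness_fn : callable
        Maps a decoded gene-index tuple to an accuracy in [0, 1]; must be
        deterministic for a fixed subset.
    d : int
        Search dimension (size of the filtered gene pool).
    k : int
        Subset size decoded from each position.
    cfg : NROConfig
        Search parameters, including the seed for all randomness.

    Each generation applies fission, ionization and fusion; after each
    phase every candidate is evaluated and greedily replaces its parent iff
    strictly better.  The patience counter increments on every generation
    without strict improvement of the global best and stops the search when
    it reaches ``cfg.patience``.
    """
    if k > d:
        raise DomainError(f"k={k} exceeds dimension {d}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population_size
    decode = (
        (lambda pos: decode_top_k(pos, k))
        if cfg.decoder == "topk"
        else decode_threshold
    )
    trace = NROTrace()

    def evaluate(pos: np.ndarray) -> float:
        subset = decode(pos)
        f = float(fitness_fn(subset))
        if not math.isfinite(f):
            raise PipelineError(f"fitness_fn returned non-finite value {f}")
        trace.evaluations += 1
        return f

    pop = initialize_population(n, d, rng)
    fits = np.array([evaluate(pop[i]) for i in range(n)])
    best_i = int(np.argmax(fits))
    best_pos = pop[best_i].copy()
    best_fit = float(fits[best_i])

    no_improve = 0
    for g in range(1, cfg.max_generations + 1):
        improved = False
        for phase in ("fission", "ionization", "fusion"):
            if phase == "fission":
                cand = fission_step(pop, best_pos, g, rng, cfg)
            elif phase == "ionization":
                cand = ionization_step(pop, best_pos, rng, cfg)
            else:
                cand = fusion_step(pop, best_pos, rng, cfg)
            for i in range(n):
                f = evaluate(cand[i])
                if f > fits[i]:
                    pop[i] = cand[i]
                    fits[i] = f
                if f > best_fit:
                    best_fit = f
                    best_pos = cand[i].copy()
                    improved = True
        trace.best_fitness_per_generation.append(best_fit)
        trace.generations_run = g
        if improved:
            no_improve = 0
        else:
            no_improve += 1
        if no_improve >= cfg.patience:
            trace.stopped_early = True
            break

    best = Solution(position=best_pos, fitness=best_fit, decoded=decode(best_pos))
    return best, trace
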