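"""Binary-encoded genetic algorithm for wavelet-kernel ELM hyperparameters.

Each individual is a 20-bit chromosome: bits 1-4 encode the wavelet
oscillation parameter w (1..16), bits 5-8 the oscillation scale x (1..16),
bits 9-12 the envelope width y (1..16), and bits 13-20 the hidden-neuron
count (5..260).  Every field is an offset binary code: range minimum plus the
unsigned MSB-first value of the bit slice.

Fitness is the training accuracy of a center-subset wavelet-kernel ELM built
from the decoded parameters.  The loop is the classic generational scheme:
fitness-proportionate (roulette) selection, single-point crossover, per-bit
mutation, and elitism carrying the best individual unchanged, which makes the
best-fitness history non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .elm import TrainConfig, fit, predict
from .kernels import KernelSpec

__all__ = [
    "CHROMOSOME_LENGTH",
    "DecodedParams",
    "GAConfig",
    "GAResult",
    "decode",
    "encode",
    "random_chromosome",
    "fitness",
    "select_parents",
    "crossover",
    "mutate",
    "ga_optimize",
]

CHROMOSOME_LENGTH = 20
# (start, stop, range minimum) of each field's bit slice
_FIELDS = {"w": (0, 4, 1), "x": (4, 8, 1), "y": (8, 12, 1), "n_hidden": (12, 20, 5)}


@dataclass(frozen=True)
class DecodedParams:
    """Decoded hyperparameters: kernel (w, x, y) in [1, 16], neurons in [5, 260]."""

    w: int
    x: int
    y: int
    n_hidden: int

    def __post_init__(self) -> None:
        for name in ("w", "x", "y"):
            v = getattr(self, name)
            if not 1 <= v <= 16:
                raise ValueError(f"{name} must be in [1, 16], got {v}")
        if not 5 <= self.n_hidden <= 260:
            raise ValueError(f"n_hidden must be in [5, 260], got {self.n_hidden}")

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(family="wavelet", w=self.w, x=self.x, y=self.y)


def _check_chromosome(chrom) -> np.ndarray:
    bits = np.asarray(chrom, dtype=int)
    if bits.shape != (CHROMOSOME_LENGTH,):
        raise ValueError(
            f"chromosome must have exactly {CHROMOSOME_LENGTH} bits, got shape {bits.shape}"
        )
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("chromosome bits must all be 0 or 1")
    return bits


def _bits_to_int(bits: np.ndarray) -> int:
    """Unsigned integer value of an MSB-first bit slice."""
    return int(bits @ (1 << np.arange(bits.size - 1, -1, -1)))


def _int_to_bits(value: int, width: int) -> np.ndarray:
    return np.array([(value >> k) & 1 for k in range(width - 1, -1, -1)], dtype=int)


def decode(chrom) -> DecodedParams:
    """Decode a 20-bit chromosome into hyperparameters."""
    bits = _check_chromosome(chrom)
    values = {
        name: lo + _bits_to_int(bits[a:b]) for name, (a, b, lo) in _FIELDS.items()
    }
    return DecodedParams(**values)


def encode(params: DecodedParams) -> np.ndarray:
    """Inverse of :func:`decode`: decode(encode(p)) == p."""
    bits = np.empty(CHROMOSOME_LENGTH, dtype=int)
    for name, (a, b, lo) in _FIELDS.items():
        bits[a:b] = _int_to_bits(getattr(params, name) - lo, b - a)
    return bits


def random_chromosome(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=CHROMOSOME_LENGTH)


def fitness(chrom, train_X, train_labels, E: float = 1.0, *, seed: int = 0) -> float:
    """Training accuracy of the center-subset WK-ELM decoded from ``chrom``.

    The neuron count is capped at the number of training samples.  Training
    failures yield fitness 0 with a logged warning rather than an exception.
    """
    params = decode(chrom)
    train_X = np.asarray(train_X, dtype=float)
    n = train_X.shape[0]
    config = TrainConfig(
        E=E, variant="center_subset", n_hidden=min(params.n_hidden, n), seed=seed
    )
    try:
        model = fit(train_X, train_labels, params.kernel_spec(), config)
        return float(np.mean(predict(model, train_X) == np.asarray(train_labels)))
    except Exception as exc:  # noqa: BLE001 - fitness must not abort the search
        warnings.warn(f"fitness evaluation failed ({exc}); scoring 0", RuntimeWarning)
        return 0.0


def select_parents(population, fitnesses, rng: np.random.Generator):
    """Fitness-proportionate (roulette) sampling of two parents, with
    replacement; degenerate all-zero fitness falls back to uniform sampling."""
    if len(population) == 0:
        raise ValueError("empty population")
    f = np.asarray(fitnesses, dtype=float)
    if f.shape[0] != len(population):
        raise ValueError("fitnesses must align with the population")
    total = f.sum()
    p = None if total <= 0 else f / total
    i, j = rng.choice(len(population), size=2, replace=True, p=p)
    return population[i].copy(), population[j].copy()


def crossover(a, b, prob: float, rng: np.random.Generator):
    """Single-point crossover with probability ``prob``; otherwise the
    children are exact copies of the parents."""
    a = _check_chromosome(a)
    b = _check_chromosome(b)
    if rng.random() < prob:
        cut = int(rng.integers(1, CHROMOSOME_LENGTH))
        return (
            np.concatenate([a[:cut], b[cut:]]),
            np.concatenate([b[:cut], a[cut:]]),
        )
    return a.copy(), b.copy()


def mutate(chrom, prob_per_bit: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``prob_per_bit``."""
    bits = _check_chromosome(chrom)
    flips = rng.random(CHROMOSOME_LENGTH) < prob_per_bit
    return np.where(flips, 1 - bits, bits)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob_per_bit: float = 0.02
    elitism_count: int = 1
    seed: int = 0
    stall_generations: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_prob_per_bit <= 1.0:
            raise ValueError("mutation_prob_per_bit must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.stall_generations is not None and self.stall_generations < 1:
            raise ValueError("stall_generations must be >= 1")


@dataclass
class GAResult:
    best_params: DecodedParams
    best_fitness: float
    best_chromosome: np.ndarray
    history: list[tuple[float, float]]  # per generation: (best, mean) fitness
    evaluations: int


def _rank_key(fit_value: float, bits: np.ndarray):
    """Sort key: higher fitness first; ties broken by fewer neurons, then the
    lexicographically smaller bit string (keeps the cheapest model)."""
    return (-fit_value, decode(bits).n_hidden, tuple(bits))


def ga_optimize(
    train_X, train_labels, config: GAConfig | None = None, E: float = 1.0
) -> GAResult:
    """Run the generational GA and return the best-ever parameter set.

    Seeded and fully deterministic: the same (data, config, E) reproduce a
    bit-identical result.  Fitness values are cached per bit string, so the
    number of model fits never exceeds population_size * (generations + 1).
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    train_X = np.asarray(train_X, dtype=float)
    train_labels = np.asarray(train_labels)

    cache: dict[bytes, float] = {}
    n_evals = 0

    def evaluate(chrom: np.ndarray) -> float:
        nonlocal n_evals
        key = chrom.astype(np.uint8).tobytes()
        if key not in cache:
            cache[key] = fitness(chrom, train_X, train_labels, E)
            n_evals += 1
        return cache[key]

    population = [random_chromosome(rng) for _ in range(config.population_size)]
    best_bits: np.ndarray | None = None
    best_fit = -np.inf
    history: list[tuple[float, float]] = []
    stall = 0

    for _generation in range(config.generations + 1):
        fits = np.array([evaluate(c) for c in population])
        order = sorted(range(len(population)), key=lambda i: _rank_key(fits[i], population[i]))
        gen_best_i = order[0]
        history.append((float(fits[gen_best_i]), float(fits.mean())))

        if best_bits is None or _rank_key(fits[gen_best_i], population[gen_best_i]) < _rank_key(
            best_fit, best_bits
        ):
            best_bits = population[gen_best_i].copy()
            best_fit = float(fits[gen_best_i])
            stall = 0
        else:
            stall += 1

        if _generation == config.generations:
            break
        if config.stall_generations is not None and stall >= config.stall_generations:
            break

        next_pop = [population[i].copy() for i in order[: config.elitism_count]]
        while len(next_pop) < config.population_size:
            pa, pb = select_parents(population, fits, rng)
            ca, cb = crossover(pa, pb, config.crossover_prob, rng)
            next_pop.append(mutate(ca, config.mutation_prob_per_bit, rng))
            if len(next_pop) < config.population_size:
                next_pop.append(mutate(cb, config.mutation_prob_per_bit, rng))
        population = next_pop

    return GAResult(
        best_params=decode(best_bits),
        best_fitness=best_fit,
        best_chromosome=best_bits,
        history=history,
        evaluations=n_evals,
    )
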