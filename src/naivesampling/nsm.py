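"""The naive sampling model (lazy) and an eager on-line comparator.

The naive sampling model (NSM) is a *lazy* account of intuitive statistics:
every experienced value is stored in long-term memory as a raw exemplar, no
summary is computed during exposure, and a judgment is formed only when a
query arrives — by retrieving a small random sample (short-term-memory
size, about 4 +/- 2 items) and computing the requested statistic on that
sample. Sample means are unbiased under uniform retrieval, so central
tendency judgments come out accurate; dispersion statistics are biased low
in small samples, so variability is systematically underestimated; and
because retrieval probability is independent of encoding time, presentation
order leaves no trace in the judgments.

Retrieval can instead be weighted toward late (recency) or early (primacy)
positions via a geometric decay, which is how the simulator expresses the
order-sensitive alternatives the uniform model is contrasted with.

The *eager* comparator maintains exponentially weighted running estimates
of mean and variance during exposure and discards the raw data, so its
final state overweights whatever arrived late when the weight is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import SCALE_MAX, SCALE_MIN, DecileProfile, largest_remainder
from .stimuli import HistogramPrototype, MatrixTrial, StimulusSet

POLICIES = ("uniform", "recency", "primacy")

#: STM sample size bounds used when per-participant jitter is enabled (4 +/- 2)
K_JITTER_RANGE = (2, 6)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ExemplarMemory:
    """Long-term store: raw values with contiguous encoding indices 1..N."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=int).copy()
        if v.ndim != 1 or v.size == 0:
            raise ValueError("memory requires a non-empty 1-d value sequence")
        if v.min() < SCALE_MIN or v.max() > SCALE_MAX:
            raise ValueError(f"values must lie in [{SCALE_MIN}, {SCALE_MAX}]")
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def encoding_index(self) -> np.ndarray:
        return np.arange(1, self.size + 1)

    @property
    def size(self) -> int:
        return int(self.values.size)

    def decode(self) -> np.ndarray:
        """Return the stored values in encoding order (storage is lossless)."""
        return self.values.copy()


def encode(sequence) -> ExemplarMemory:
    """Store a presented sequence as exemplars; no computation is performed."""
    if isinstance(sequence, StimulusSet):
        return ExemplarMemory(sequence.values)
    return ExemplarMemory(np.asarray(sequence))


@dataclass(frozen=True)
class SamplingScheme:
    """Retrieval policy and STM sample size.

    ``decay`` is the weight ratio per position step away from the favored
    end of the sequence; 1 makes every policy uniform. ``k`` is the STM
    sample size; with ``k_jitter`` a per-participant k is drawn uniformly
    from 2..6.
    """

    policy: str = "uniform"
    decay: float = 1.0
    k: int = 4
    with_replacement: bool = False
    k_jitter: bool = False

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if not 0 < self.decay <= 1:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    def resolve_k(self, rng) -> int:
        if self.k_jitter:
            lo, hi = K_JITTER_RANGE
            return int(_rng(rng).integers(lo, hi + 1))
        return self.k

    def label(self) -> str:
        tag = self.policy if self.decay == 1.0 or self.policy == "uniform" \
            else f"{self.policy}({self.decay})"
        return f"{tag},k={self.k}"


def retrieval_weights(memory_size: int, scheme: SamplingScheme) -> np.ndarray:
    """Unnormalized retrieval weights for exemplars at positions 1..N."""
    t = np.arange(1, memory_size + 1, dtype=float)
    if scheme.policy == "uniform" or scheme.decay == 1.0:
        return np.ones(memory_size)
    if scheme.policy == "recency":
        return scheme.decay ** (memory_size - t)
    return scheme.decay ** (t - 1)  # primacy


def draw_sample(memory: ExemplarMemory, scheme: SamplingScheme, seed=None,
                k: int | None = None) -> np.ndarray:
    """Retrieve an STM sample of k values from memory under the scheme.

    Sampling is without replacement by default: an exemplar already active
    in STM is not retrieved again within one query.
    """
    if k is None:
        k = scheme.k
    if k > memory.size and not scheme.with_replacement:
        raise ValueError(f"cannot draw {k} exemplars without replacement from {memory.size}")
    rng = _rng(seed)
    if scheme.policy == "uniform" or scheme.decay == 1.0:
        idx = rng.choice(memory.size, size=k, replace=scheme.with_replacement)
    else:
        w = retrieval_weights(memory.size, scheme)
        idx = rng.choice(memory.size, size=k, replace=scheme.with_replacement,
                         p=w / w.sum())
    return memory.values[idx]


@dataclass(frozen=True)
class DescriptiveEstimates:
    mean: float
    median: float
    mad: float


def estimate_descriptives(sample) -> DescriptiveEstimates:
    """Mean, median, and mean absolute deviation (about the mean) of a sample.

    The median uses the midpoint convention for even sizes; MAD is the mean
    of the distances of each value from their total mean.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute descriptives of an empty sample")
    m = float(np.mean(x))
    return DescriptiveEstimates(
        mean=m,
        median=float(np.median(x)),
        mad=float(np.mean(np.abs(x - m))),
    )


def pooled_profile(memory: ExemplarMemory, scheme: SamplingScheme,
                   n_pools: int = 5, seed=None, k: int | None = None) -> DecileProfile:
    """Empirical decile profile of ``n_pools`` independent STM retrievals."""
    rng = _rng(seed)
    pools = [draw_sample(memory, scheme, rng, k=k) for _ in range(n_pools)]
    return DecileProfile.from_values(np.concatenate(pools))


def simulate_production(memory: ExemplarMemory, scheme: SamplingScheme,
                        total: int = 120, n_pools: int = 5, seed=None,
                        k: int | None = None) -> np.ndarray:
    """Produce per-decile frequencies summing to ``total`` from pooled samples.

    A single STM sample is too coarse to fill a 120-count histogram; the
    simulant pools ``n_pools`` independent retrievals and rescales the
    pooled empirical proportions to the required total by largest-remainder
    rounding.
    """
    profile = pooled_profile(memory, scheme, n_pools=n_pools, seed=seed, k=k)
    return largest_remainder(profile.bins, total)


def simulate_identification(memory: ExemplarMemory, scheme: SamplingScheme,
                            prototypes: list[HistogramPrototype],
                            n_pools: int = 5, seed=None,
                            k: int | None = None) -> int:
    """Choose the prototype (1-based) nearest the pooled remembered profile.

    Nearness is Euclidean distance between proportion vectors; exact ties
    break toward the uniform prototype, then toward the lower index.
    """
    profile = pooled_profile(memory, scheme, n_pools=n_pools, seed=seed, k=k)
    dists = np.array([profile.distance(p.profile) for p in prototypes])
    best = np.flatnonzero(dists == dists.min())
    for i in best:
        if prototypes[i].shape == "uniform":
            return int(i) + 1
    return int(best[0]) + 1


def simulate_sampling_task(memory: ExemplarMemory, scheme: SamplingScheme,
                           matrix: MatrixTrial, n_pools: int = 5, seed=None,
                           k: int | None = None, n_select: int = 10) -> np.ndarray:
    """Pick the matrix values most representative of the remembered profile.

    Greedy construction: starting from an empty selection, repeatedly add
    the matrix value whose inclusion minimizes the Euclidean distance
    between the selection's decile profile and the pooled remembered
    profile. The choice depends only on decile membership, never on whether
    a value was actually seen (old/new provenance is invisible here).
    """
    if len(matrix) < n_select:
        raise ValueError(f"matrix holds {len(matrix)} values; cannot select {n_select}")
    target = pooled_profile(memory, scheme, n_pools=n_pools, seed=seed, k=k).bins
    remaining = list(matrix.values)
    sel_counts = np.zeros(10)
    selected = []
    for step in range(n_select):
        best_j, best_d = 0, np.inf
        for j, v in enumerate(remaining):
            d = int(v - SCALE_MIN) // 100
            trial = sel_counts.copy()
            trial[d] += 1
            dist = float(np.linalg.norm(trial / (step + 1) - target))
            if dist < best_d - 1e-12:
                best_d, best_j = dist, j
        v = remaining.pop(best_j)
        sel_counts[int(v - SCALE_MIN) // 100] += 1
        selected.append(v)
    return np.asarray(selected, dtype=int)


def eager_running_estimates(sequence, learning_rate: float | str = "harmonic"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Running mean/variance trajectories of the eager on-line comparator.

    Updates are m <- m + eta (x - m), then v <- v + eta ((x - m)^2 - v)
    with the updated m. ``learning_rate`` is either a fixed eta in (0, 1]
    (exponential forgetting: late values dominate) or ``"harmonic"`` for
    eta_t = 1/t, in which case the final running mean equals the exact
    sample mean.
    """
    if isinstance(sequence, StimulusSet):
        sequence = sequence.values
    x = np.asarray(sequence, dtype=float)
    if x.size == 0:
        raise ValueError("sequence must be non-empty")
    harmonic = isinstance(learning_rate, str)
    if harmonic:
        if learning_rate != "harmonic":
            raise ValueError(f"unknown learning_rate {learning_rate!r}")
    elif not 0 < learning_rate <= 1:
        raise ValueError(f"learning rate must be in (0, 1], got {learning_rate}")
    means = np.empty_like(x)
    variances = np.empty_like(x)
    m = v = 0.0
    for t, xt in enumerate(x, start=1):
        eta = 1.0 / t if harmonic else float(learning_rate)
        if t == 1 and not harmonic:
            # initialize at the first observation so a constant stream is exact
            m, v = xt, 0.0
        else:
            m = m + eta * (xt - m)
            v = v + eta * ((xt - m) ** 2 - v)
        means[t - 1], variances[t - 1] = m, v
    return means, variances


# ---------------------------------------------------------------------------
# One simulated participant
# ---------------------------------------------------------------------------


@dataclass
class ResponseRecord:
    """One simulated participant's answers at one test time."""

    participant_id: str
    condition: str
    scheme: SamplingScheme
    test_time: str = "final"  # "intermediate" | "final"
    k_used: int | None = None
    production: np.ndarray | None = None
    production_total: int | None = None
    identification: int | None = None
    sample_selections: dict[int, np.ndarray] = field(default_factory=dict)
    sample_provenance: dict[int, str] = field(default_factory=dict)
    est_mean: float | None = None
    est_median: float | None = None
    est_mad: float | None = None
    task_order: tuple[str, ...] | None = None


ALL_TASKS = ("production", "identification", "sampling", "descriptive")


def simulate_participant(
    memory: ExemplarMemory,
    scheme: SamplingScheme,
    seed=None,
    *,
    participant_id: str = "P000",
    condition: str = "UN",
    test_time: str = "final",
    tasks=ALL_TASKS,
    prototypes: list[HistogramPrototype] | None = None,
    matrices: list[MatrixTrial] = (),
    production_total: int = 120,
    n_pools: int = 5,
    response_noise_sd: float = 0.0,
) -> ResponseRecord:
    """Run one simulated participant through the requested tasks.

    Each task query triggers fresh STM retrievals (the lazy model computes
    nothing until asked). ``response_noise_sd`` adds optional zero-mean
    Gaussian report noise (rating units) to the descriptive estimates.
    """
    rng = _rng(seed)
    k = scheme.resolve_k(rng)
    rec = ResponseRecord(participant_id=participant_id, condition=condition,
                         scheme=scheme, test_time=test_time, k_used=k)
    for task in tasks:
        if task == "production":
            rec.production = simulate_production(
                memory, scheme, total=production_total, n_pools=n_pools, seed=rng, k=k)
            rec.production_total = production_total
        elif task == "identification":
            if prototypes is None:
                raise ValueError("identification task requires prototypes")
            rec.identification = simulate_identification(
                memory, scheme, prototypes, n_pools=n_pools, seed=rng, k=k)
        elif task == "sampling":
            for trial in matrices:
                rec.sample_selections[trial.trial_index] = simulate_sampling_task(
                    memory, scheme, trial, n_pools=n_pools, seed=rng, k=k)
                rec.sample_provenance[trial.trial_index] = trial.provenance
        elif task == "descriptive":
            # one fresh retrieval per queried statistic
            est_mean = estimate_descriptives(draw_sample(memory, scheme, rng, k=k)).mean
            est_median = estimate_descriptives(draw_sample(memory, scheme, rng, k=k)).median
            est_mad = estimate_descriptives(draw_sample(memory, scheme, rng, k=k)).mad
            if response_noise_sd > 0:
                est_mean += rng.normal(0, response_noise_sd)
                est_median += rng.normal(0, response_noise_sd)
                est_mad += rng.normal(0, response_noise_sd)
            rec.est_mean, rec.est_median, rec.est_mad = est_mean, est_median, est_mad
        else:
            raise ValueError(f"unknown task {task!r}")
    return rec


def participant_schemes(scheme: SamplingScheme, n: int, seed=None) -> list[SamplingScheme]:
    """Materialize per-participant schemes (resolving k jitter reproducibly)."""
    rng = _rng(seed)
    out = []
    for _ in range(n):
        k = scheme.resolve_k(rng)
        out.append(replace(scheme, k=k, k_jitter=False))
    return out
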