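"""Experimental materials: exposure sequences, matrices, and prototypes.

The exposure set ``E`` is a 120-value sample from [1, 1000] constrained to
12 values per decile (so the experienced population is exactly uniform at
decile resolution). A partition of ``E`` into a unimodal half ``E_a``
(decile counts following Beta(2.4, 2.4)) and its complement ``E_b`` — the
reflection of ``E_a`` with respect to the uniform count vector — defines
the three presentation-order conditions:

* ``U-B``: all of ``E_a`` (unimodal) before all of ``E_b`` (bimodal);
* ``B-U``: the reverse;
* ``UN``: both halves interleaved at random, so the running distribution
  is uniform throughout.

A second, disjoint set ``T`` is withheld for the sampling task, whose 8
trials are 30-value matrices (3 values per decile), four drawn from ``E``
("old") and four from ``T`` ("new"). The identification task offers 7
histogram prototypes: one uniform, three unimodal of decreasing variance,
three bimodal of increasing variance, reconstructed as a symmetric
Beta(a, a) family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    N_BINS,
    SCALE_MAX,
    SCALE_MIN,
    DecileProfile,
    decile_of,
    largest_remainder,
)

CONDITIONS = ("U-B", "B-U", "UN")
HALF_TAGS = ("A", "B")

#: condition spelling used in CSV files (hyphen-free)
_CONDITION_TO_CSV = {"U-B": "UB", "B-U": "BU", "UN": "UN"}
_CONDITION_FROM_CSV = {v: k for k, v in _CONDITION_TO_CSV.items()}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass
class StimulusSet:
    """An ordered sequence of rating values with half/condition annotations.

    ``half`` tags each value as belonging to the unimodal half (``A``) or
    the bimodal half (``B``); it is ``None`` for a raw uniform set that has
    not been partitioned. ``order_index`` is implicit in row order (1..N).
    """

    values: np.ndarray
    half: np.ndarray | None = None
    condition: str | None = None
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-d sequence")
        if self.values.size and (
            self.values.min() < SCALE_MIN or self.values.max() > SCALE_MAX
        ):
            raise ValueError(f"values must lie in [{SCALE_MIN}, {SCALE_MAX}]")
        if self.half is not None:
            self.half = np.asarray(self.half, dtype=object)
            if self.half.shape != self.values.shape:
                raise ValueError("half tags must match values in length")
            bad = set(self.half) - set(HALF_TAGS)
            if bad:
                raise ValueError(f"unknown half tags: {sorted(bad)}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def order_index(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def deciles(self) -> np.ndarray:
        return decile_of(self.values)

    def decile_counts(self) -> np.ndarray:
        return np.bincount(self.deciles - 1, minlength=N_BINS)

    def profile(self) -> DecileProfile:
        return DecileProfile.from_values(self.values)

    def validate(self, n: int = 120, per_decile: int = 12) -> None:
        """Assert the design invariants (counts, halves, condition order)."""
        if len(self) != n:
            raise ValueError(f"expected {n} values, got {len(self)}")
        counts = self.decile_counts()
        if not np.all(counts == per_decile):
            raise ValueError(f"expected {per_decile} values per decile, got {counts}")
        if self.half is not None:
            n_a = int(np.sum(self.half == "A"))
            if n_a != len(self) // 2:
                raise ValueError(f"expected {len(self) // 2} A-tagged values, got {n_a}")
            if self.condition == "U-B":
                if not np.all(self.half[: len(self) // 2] == "A"):
                    raise ValueError("U-B requires all A values before all B values")
            elif self.condition == "B-U":
                if not np.all(self.half[: len(self) // 2] == "B"):
                    raise ValueError("B-U requires all B values before all A values")

    # -- tabular round trip ---------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "value": self.values,
                "order_index": self.order_index,
                "half": self.half if self.half is not None else [""] * len(self),
                "condition": _CONDITION_TO_CSV.get(self.condition, "")
                if self.condition
                else "",
                "decile": self.deciles,
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        df = df.sort_values("order_index")
        half = None
        if "half" in df and df["half"].astype(str).str.len().gt(0).all():
            half = df["half"].astype(str).to_numpy()
        condition = None
        if "condition" in df:
            raw = str(df["condition"].iloc[0])
            if raw:
                condition = _CONDITION_FROM_CSV.get(raw, raw if raw in CONDITIONS else None)
        return cls(df["value"].to_numpy(), half=half, condition=condition)

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


@dataclass
class MatrixTrial:
    """One sampling-task trial: a 30-value matrix, uniform at 3 per decile."""

    values: np.ndarray
    provenance: str  # "old" (from E) | "new" (from T)
    trial_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.provenance not in ("old", "new"):
            raise ValueError(f"provenance must be 'old' or 'new', got {self.provenance!r}")
        counts = np.bincount(decile_of(self.values) - 1, minlength=N_BINS)
        if not np.all(counts == len(self.values) // N_BINS):
            raise ValueError("matrix values must be uniform across deciles")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class HistogramPrototype:
    """One identification-task histogram: a decile profile with a shape tag."""

    profile: DecileProfile
    shape: str  # "uniform" | "unimodal" | "bimodal"
    variance_rank: int | None = None

    def __post_init__(self):
        if self.shape not in ("uniform", "unimodal", "bimodal"):
            raise ValueError(f"unknown shape tag {self.shape!r}")
        if self.shape == "uniform" and self.variance_rank is not None:
            raise ValueError("uniform prototype carries no variance rank")
        if self.shape != "uniform" and self.variance_rank not in (1, 2, 3):
            raise ValueError("variance_rank must be 1..3 for shaped prototypes")


# ---------------------------------------------------------------------------
# Generation operations
# ---------------------------------------------------------------------------


def generate_uniform_set(
    n: int = 120,
    per_decile: int = 12,
    seed=None,
    exclude=(),
) -> StimulusSet:
    """Sample a uniform stimulus set with exactly ``per_decile`` values per decile.

    Values are drawn uniformly *within* each decile without replacement, so
    the set is both uniform at decile resolution (exactly) and uniform within
    deciles (stochastically). ``exclude`` removes integers from the sampling
    pool — used to draw a test set disjoint from the exposure set.
    """
    if n != N_BINS * per_decile:
        raise ValueError(f"n must equal {N_BINS} * per_decile ({N_BINS * per_decile}), got {n}")
    if per_decile > 100:
        raise ValueError("per_decile > 100: more values requested than integers per decile")
    rng = _rng(seed)
    exclude = np.asarray(sorted(exclude), dtype=int)
    chunks = []
    for d in range(N_BINS):
        lo = SCALE_MIN + d * 100
        pool = np.setdiff1d(np.arange(lo, lo + 100), exclude)
        if pool.size < per_decile:
            raise ValueError(
                f"decile {d + 1}: only {pool.size} integers available after exclusions"
            )
        chunks.append(rng.choice(pool, size=per_decile, replace=False))
    values = np.concatenate(chunks)
    rng.shuffle(values)
    return StimulusSet(values, seed=seed if isinstance(seed, int) else None)


def partition_unimodal_bimodal(
    E: StimulusSet, alpha: float = 2.4, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``E`` into a unimodal half and its reflection about uniform.

    The unimodal half's per-decile counts are the Beta(alpha, alpha) decile
    probabilities scaled to half the set size and integerized by
    largest-remainder rounding; the bimodal half takes the complement to the
    uniform count vector. Within each decile the specific members are chosen
    uniformly at random.
    """
    per_decile = len(E) // N_BINS
    E.validate(n=len(E), per_decile=per_decile)
    probs = DecileProfile.from_beta(alpha, alpha)
    target = largest_remainder(probs.bins, len(E) // 2)
    if np.any(target > per_decile):
        raise ValueError(
            f"Beta({alpha}, {alpha}) requires more than {per_decile} values in a "
            f"decile (targets {target.tolist()}); not realizable from a uniform set"
        )
    rng = _rng(seed)
    deciles = E.deciles
    e_a, e_b = [], []
    for d in range(1, N_BINS + 1):
        members = E.values[deciles == d]
        picked = rng.choice(members.size, size=target[d - 1], replace=False)
        mask = np.zeros(members.size, dtype=bool)
        mask[picked] = True
        e_a.append(members[mask])
        e_b.append(members[~mask])
    return np.concatenate(e_a), np.concatenate(e_b)


def order_by_condition(E_a, E_b, condition: str, seed=None) -> StimulusSet:
    """Arrange the two halves into one presentation order for a condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    E_a = np.asarray(E_a, dtype=int)
    E_b = np.asarray(E_b, dtype=int)
    if E_a.size != E_b.size:
        raise ValueError("E_a and E_b must have equal size")
    rng = _rng(seed)
    a = rng.permutation(E_a)
    b = rng.permutation(E_b)
    if condition == "U-B":
        values = np.concatenate([a, b])
        half = np.array(["A"] * a.size + ["B"] * b.size, dtype=object)
    elif condition == "B-U":
        values = np.concatenate([b, a])
        half = np.array(["B"] * b.size + ["A"] * a.size, dtype=object)
    else:  # UN: both halves scattered over all positions
        values = np.concatenate([a, b])
        half = np.array(["A"] * a.size + ["B"] * b.size, dtype=object)
        perm = rng.permutation(values.size)
        values, half = values[perm], half[perm]
    return StimulusSet(values, half=half, condition=condition,
                       seed=seed if isinstance(seed, int) else None)


def generate_matrices(E: StimulusSet, T: StimulusSet, seed=None) -> list[MatrixTrial]:
    """Build the 8 sampling-task matrices (4 old from E, 4 new from T).

    Each matrix holds 30 values, 3 per decile; the four same-provenance
    matrices partition their 120-value source set exactly (no value reused).
    Trial order is randomized; provenance travels with each trial.
    """
    if np.intersect1d(E.values, T.values).size:
        raise ValueError("E and T must be disjoint")
    per_decile = len(E) // N_BINS
    n_trials = 4
    if per_decile % n_trials:
        raise ValueError(f"per-decile count {per_decile} not divisible into {n_trials} matrices")
    per_cell = per_decile // n_trials
    rng = _rng(seed)
    trials = []
    for source, provenance in ((E, "old"), (T, "new")):
        source.validate(n=len(source), per_decile=per_decile)
        layout = [[] for _ in range(n_trials)]
        deciles = source.deciles
        for d in range(1, N_BINS + 1):
            members = rng.permutation(source.values[deciles == d])
            for j in range(n_trials):
                layout[j].append(members[j * per_cell : (j + 1) * per_cell])
        for j in range(n_trials):
            vals = rng.permutation(np.concatenate(layout[j]))
            trials.append((provenance, vals))
    order = rng.permutation(len(trials))
    return [
        MatrixTrial(values=trials[i][1], provenance=trials[i][0], trial_index=rank + 1)
        for rank, i in enumerate(order)
    ]


def generate_prototypes(
    unimodal_shapes=(2.0, 4.0, 8.0),
    bimodal_shapes=(0.8, 0.5, 0.3),
) -> list[HistogramPrototype]:
    """Build the 7 identification histograms as a symmetric Beta(a, a) family.

    Returns, in order: the uniform prototype (Beta(1,1)), three unimodal
    prototypes of strictly decreasing variance (shapes > 1, increasing), and
    three bimodal prototypes of strictly increasing variance (shapes < 1,
    decreasing).
    """
    uni = np.asarray(unimodal_shapes, dtype=float)
    bim = np.asarray(bimodal_shapes, dtype=float)
    if uni.size != 3 or bim.size != 3:
        raise ValueError("exactly three unimodal and three bimodal shapes required")
    if np.any(uni <= 1) or np.any(np.diff(uni) <= 0):
        raise ValueError("unimodal shapes must be > 1 and strictly increasing")
    if np.any(bim >= 1) or np.any(bim <= 0) or np.any(np.diff(bim) >= 0):
        raise ValueError("bimodal shapes must be in (0, 1) and strictly decreasing")
    protos = [HistogramPrototype(DecileProfile.from_beta(1.0, 1.0), "uniform")]
    for rank, a in enumerate(uni, start=1):
        protos.append(
            HistogramPrototype(DecileProfile.from_beta(a, a), "unimodal", variance_rank=rank)
        )
    for rank, a in enumerate(bim, start=1):
        protos.append(
            HistogramPrototype(DecileProfile.from_beta(a, a), "bimodal", variance_rank=rank)
        )
    uni_vars = [p.profile.variance() for p in protos if p.shape == "unimodal"]
    bim_vars = [p.profile.variance() for p in protos if p.shape == "bimodal"]
    if not all(np.diff(uni_vars) < 0):
        raise ValueError("unimodal prototype variances are not strictly decreasing")
    if not all(np.diff(bim_vars) > 0):
        raise ValueError("bimodal prototype variances are not strictly increasing")
    return protos
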