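"""Decile profiles over the rating scale.

All shape computations in the package run through a single currency: a
10-bin histogram over the rating range [1, 1000], with bins
[1, 100], [101, 200], ..., [901, 1000]. A :class:`DecileProfile` stores the
bin proportions (summing to one) and, when the profile originated from
counts, the total count so it can be converted back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

N_BINS = 10
SCALE_MIN = 1
SCALE_MAX = 1000
_BIN_WIDTH = (SCALE_MAX - SCALE_MIN + 1) // N_BINS

_SUM_TOL = 1e-9


def decile_of(values) -> np.ndarray:
    """Map rating values in [1, 1000] to 1-based decile indices 1..10."""
    v = np.asarray(values)
    if v.size and (v.min() < SCALE_MIN or v.max() > SCALE_MAX):
        raise ValueError(
            f"values must lie in [{SCALE_MIN}, {SCALE_MAX}]; "
            f"got range [{v.min()}, {v.max()}]"
        )
    return (v - SCALE_MIN) // _BIN_WIDTH + 1


def largest_remainder(proportions, total: int) -> np.ndarray:
    """Integerize ``proportions * total`` while preserving the exact total.

    Floors each target count and hands the remaining units to the bins with
    the largest fractional remainders (ties broken by bin order, which keeps
    the procedure deterministic).
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or np.any(p < 0):
        raise ValueError("proportions must be a 1-d non-negative vector")
    target = p / p.sum() * total
    counts = np.floor(target).astype(int)
    shortfall = int(total - counts.sum())
    if shortfall:
        remainders = target - counts
        top = np.argsort(-remainders, kind="stable")[:shortfall]
        counts[top] += 1
    return counts


@dataclass(frozen=True)
class DecileProfile:
    """A 10-bin probability profile over [1, 1000].

    Parameters
    ----------
    bins
        Bin proportions; must be non-negative and sum to 1 (tol 1e-9).
    total
        Optional declared total when the profile represents counts.
    """

    bins: np.ndarray
    total: int | None = field(default=None)

    def __post_init__(self):
        b = np.asarray(self.bins, dtype=float).copy()
        if b.shape != (N_BINS,):
            raise ValueError(f"profile must have {N_BINS} bins, got shape {b.shape}")
        if np.any(b < 0):
            raise ValueError("bin proportions must be non-negative")
        if abs(b.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"bin proportions must sum to 1, got {b.sum()!r}")
        b.flags.writeable = False
        object.__setattr__(self, "bins", b)

    # -- constructors -------------------------------------------------

    @classmethod
    def uniform(cls) -> "DecileProfile":
        return cls(np.full(N_BINS, 1.0 / N_BINS))

    @classmethod
    def from_proportions(cls, proportions) -> "DecileProfile":
        return cls(np.asarray(proportions, dtype=float))

    @classmethod
    def from_counts(cls, counts) -> "DecileProfile":
        c = np.asarray(counts)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        total = int(c.sum())
        if total == 0:
            raise ValueError("counts sum to zero; profile undefined")
        return cls(c / total, total=total)

    @classmethod
    def from_values(cls, values) -> "DecileProfile":
        v = np.asarray(values)
        if v.size == 0:
            raise ValueError("cannot build a profile from an empty value set")
        counts = np.bincount(decile_of(v) - 1, minlength=N_BINS)
        return cls.from_counts(counts)

    @classmethod
    def from_beta(cls, alpha: float, beta: float) -> "DecileProfile":
        """Decile probabilities of a Beta(alpha, beta) law on the unit scale."""
        if alpha <= 0 or beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        edges = np.linspace(0.0, 1.0, N_BINS + 1)
        cdf = _sps.beta.cdf(edges, alpha, beta)
        return cls(np.diff(cdf))

    # -- views ---------------------------------------------------------

    @property
    def proportions(self) -> np.ndarray:
        return self.bins

    def counts(self, total: int | None = None) -> np.ndarray:
        """Integer counts summing to ``total`` (largest-remainder rounding)."""
        if total is None:
            total = self.total
        if total is None:
            raise ValueError("no total declared; pass total= explicitly")
        return largest_remainder(self.bins, int(total))

    def variance(self) -> float:
        """Variance of the bin-midpoint distribution on the unit scale.

        Used only for ordering profiles by dispersion (e.g. ranking the
        identification-task prototypes); midpoints are (i + 0.5)/10.
        """
        mids = (np.arange(N_BINS) + 0.5) / N_BINS
        m = float(np.dot(self.bins, mids))
        return float(np.dot(self.bins, mids**2) - m**2)

    def distance(self, other: "DecileProfile") -> float:
        """Euclidean distance between two profiles' proportion vectors."""
        return float(np.linalg.norm(self.bins - other.bins))

    def __len__(self) -> int:
        return N_BINS


def beta_decile_probabilities(alpha: float, beta: float) -> DecileProfile:
    """Decile profile of a Beta(alpha, beta) distribution (see from_beta)."""
    return DecileProfile.from_beta(alpha, beta)
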