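"""The Shape Index and the deviation measures.

The Shape Index (SI) scores a judged 10-bin histogram against the normative
uniform profile:

    SI = sum_i  s_i * (x_i - p_i)

where ``x_i`` is the judged proportion in decile *i*, ``p_i`` the normative
proportion (0.1 throughout, since the experienced distribution is uniform),
and ``s_i`` a sign vector that is 0 on two excluded, shape-uninformative
bins, +1 on the central bins where a unimodal distribution exceeds uniform,
and -1 on the extreme bins. SI = 0 for a uniform judgment, SI > 0 for a
unimodal-leaning and SI < 0 for a bimodal-leaning judgment.

The default excludes the 301-400 and 801-900 intervals (bins 4 and 9).
That pair is asymmetric; a symmetric variant excluding 301-400 and 601-700
(bins 4 and 7) is available as :data:`SYMMETRIC_CONFIG`.

Accuracy of the descriptive estimates is measured by signed and absolute
deviation between an estimate ``e_s`` and its normative value ``n_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import N_BINS, DecileProfile

#: Beta shape of the unimodal half; defines which bins count as "central".
REFERENCE_ALPHA = 2.4

_PROPORTION_TOL = 1e-6


def _default_sign_vector(excluded_bins: tuple[int, ...],
                         reference_alpha: float = REFERENCE_ALPHA) -> tuple[int, ...]:
    """Sign vector: 0 on excluded bins, +1 where Beta(a, a) mass > 0.1, else -1."""
    ref = DecileProfile.from_beta(reference_alpha, reference_alpha).bins
    signs = []
    for i in range(1, N_BINS + 1):
        if i in excluded_bins:
            signs.append(0)
        elif ref[i - 1] > 1.0 / N_BINS:
            signs.append(1)
        else:
            signs.append(-1)
    return tuple(signs)


@dataclass(frozen=True)
class ShapeIndexConfig:
    """Exclusions and bin orientation for the Shape Index.

    ``excluded_bins`` uses 1-based decile indices; the default (4, 9)
    excludes the 301-400 and 801-900 intervals. ``sign_vector`` must be zero
    exactly on the excluded bins and oriented so unimodal profiles score
    positive.
    """

    excluded_bins: tuple[int, ...] = (4, 9)
    sign_vector: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        excluded = tuple(sorted(set(int(b) for b in self.excluded_bins)))
        if any(b < 1 or b > N_BINS for b in excluded):
            raise ValueError("excluded bins must be 1-based decile indices 1..10")
        object.__setattr__(self, "excluded_bins", excluded)
        sv = self.sign_vector
        if sv is None:
            sv = _default_sign_vector(excluded)
        sv = tuple(int(s) for s in sv)
        if len(sv) != N_BINS or any(s not in (-1, 0, 1) for s in sv):
            raise ValueError("sign_vector must hold 10 values in {-1, 0, +1}")
        for i, s in enumerate(sv, start=1):
            if (s == 0) != (i in excluded):
                raise ValueError("sign_vector must be zero exactly on excluded bins")
        object.__setattr__(self, "sign_vector", sv)

    @property
    def signs(self) -> np.ndarray:
        return np.asarray(self.sign_vector, dtype=float)


#: paper-literal exclusions: 301-400 and 801-900
DEFAULT_CONFIG = ShapeIndexConfig()
#: symmetric variant: 301-400 and 601-700
SYMMETRIC_CONFIG = ShapeIndexConfig(excluded_bins=(4, 7))


@dataclass(frozen=True)
class ShapeIndexResult:
    si: float
    task: str  # "production" | "identification" | "sample"
    config: ShapeIndexConfig = DEFAULT_CONFIG


@dataclass(frozen=True)
class DeviationResult:
    """Signed and absolute deviation of an estimate from its normative value."""

    absolute: float
    signed: float
    measurement: str = "central_tendency"  # or "variability"


def _as_proportions(x) -> np.ndarray:
    if isinstance(x, DecileProfile):
        return x.bins
    arr = np.asarray(x, dtype=float)
    if arr.shape != (N_BINS,):
        raise ValueError(f"profile must have {N_BINS} bins, got shape {arr.shape}")
    if abs(arr.sum() - 1.0) > _PROPORTION_TOL:
        raise ValueError(f"judged proportions must sum to 1 (tol {_PROPORTION_TOL}), got {arr.sum()!r}")
    return arr


def shape_index(x, p=None, config: ShapeIndexConfig = DEFAULT_CONFIG) -> float:
    """Shape Index of judged profile ``x`` against normative profile ``p``.

    ``p`` defaults to the uniform profile (the study's normative case).
    """
    xv = _as_proportions(x)
    pv = _as_proportions(p) if p is not None else np.full(N_BINS, 1.0 / N_BINS)
    return float(np.dot(config.signs, xv - pv))


def si_from_production(freqs, total: int = 120,
                       config: ShapeIndexConfig = DEFAULT_CONFIG) -> ShapeIndexResult:
    """SI of a production-task response: per-decile frequencies summing to ``total``."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (N_BINS,):
        raise ValueError(f"production response must have {N_BINS} frequencies")
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(f.sum() - total) > 1e-9:
        raise ValueError(f"frequencies must sum to {total}, got {f.sum()!r}")
    return ShapeIndexResult(shape_index(f / total, config=config), "production", config)


def si_from_identification(choice: int, prototypes,
                           config: ShapeIndexConfig = DEFAULT_CONFIG) -> ShapeIndexResult:
    """SI of an identification-task response: the chosen prototype's profile.

    ``choice`` is a 1-based index into the 7 prototypes.
    """
    if not 1 <= choice <= len(prototypes):
        raise ValueError(f"choice must be in 1..{len(prototypes)}, got {choice}")
    profile = prototypes[choice - 1].profile
    return ShapeIndexResult(shape_index(profile, config=config), "identification", config)


def si_from_sample(selected, config: ShapeIndexConfig = DEFAULT_CONFIG) -> ShapeIndexResult:
    """SI of a sampling-task response: the empirical profile of chosen values."""
    values = np.asarray(selected)
    if values.size == 0:
        raise ValueError("selection is empty; SI undefined")
    profile = DecileProfile.from_values(values)  # validates the value range
    return ShapeIndexResult(shape_index(profile, config=config), "sample", config)


def deviation(e_s: float, n_s: float,
              measurement: str = "central_tendency") -> DeviationResult:
    """Signed (e_s - n_s) and absolute |e_s - n_s| deviation of an estimate."""
    if not math.isfinite(n_s):
        raise ValueError("normative value must be finite")
    signed = float(e_s) - float(n_s)
    return DeviationResult(absolute=abs(signed), signed=signed, measurement=measurement)
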