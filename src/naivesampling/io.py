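"""File round-trips: run configs (YAML) and the tabular artifacts (CSV).

The CSV schemas follow the response-sheet layout: stimulus sequences carry
(value, order_index, half, condition, decile); response tables carry one
row per task instance with production bins, identification choice,
semicolon-joined sampling selections and the three descriptive estimates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .experiment import ExperimentConfig
from .nsm import SamplingScheme
from .shape_index import DEFAULT_CONFIG, ShapeIndexConfig

_SCHEME_KEYS = ("policy", "decay", "k", "with_replacement", "k_jitter")
_CONFIG_KEYS = ("experiment", "n_per_condition", "n_pools", "seed", "n_values",
                "per_decile", "beta_alpha", "task_order_counterbalance",
                "anchor_weight", "response_noise_sd")


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a flat YAML mapping.

    Recognized keys: the ExperimentConfig fields, the SamplingScheme fields
    (policy, decay, k, with_replacement, k_jitter), and optional
    ``excluded_bins`` / ``sign_vector`` for the Shape Index configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    known = set(_SCHEME_KEYS) | set(_CONFIG_KEYS) | {"excluded_bins", "sign_vector"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    scheme = SamplingScheme(**{k: raw[k] for k in _SCHEME_KEYS if k in raw})
    if "excluded_bins" in raw or "sign_vector" in raw:
        si_config = ShapeIndexConfig(
            excluded_bins=tuple(raw.get("excluded_bins", (4, 9))),
            sign_vector=tuple(raw["sign_vector"]) if "sign_vector" in raw else None,
        )
    else:
        si_config = DEFAULT_CONFIG
    kwargs = {k: raw[k] for k in _CONFIG_KEYS if k in raw}
    return ExperimentConfig(scheme=scheme, si_config=si_config, **kwargs)


def save_config(config: ExperimentConfig, path) -> None:
    data = {k: getattr(config, k) for k in _CONFIG_KEYS}
    data.update({k: getattr(config.scheme, k) for k in _SCHEME_KEYS})
    data["excluded_bins"] = list(config.si_config.excluded_bins)
    data["sign_vector"] = list(config.si_config.sign_vector)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_table(path) -> pd.DataFrame:
    """Read a package CSV, keeping empty strings distinct from NaN."""
    return pd.read_csv(Path(path), keep_default_na=False, na_values=[""])


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)
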