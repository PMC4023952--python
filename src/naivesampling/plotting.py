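"""Figures for simulated runs: SI by task/condition and the two-test crossover."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _si_table(scored: pd.DataFrame) -> pd.DataFrame:
    return scored[(scored["measure"] == "si")
                  & ((scored["task"] != "sample") | (scored["provenance"] == "all"))]


def plot_si_by_task(scored: pd.DataFrame, ax=None):
    """Mean final-test SI per task and condition with 95% CIs (cf. a 3x3 design)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = _si_table(scored[scored["test_time"] == "final"])
    tasks = sorted(data["task"].unique())
    conditions = sorted(data["condition"].unique())
    width = 0.8 / max(len(conditions), 1)
    for ci, cond in enumerate(conditions):
        means, errs = [], []
        for task in tasks:
            v = data[(data["task"] == task) & (data["condition"] == cond)]["value"]
            means.append(v.mean())
            errs.append(1.96 * v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        x = np.arange(len(tasks)) + ci * width
        ax.bar(x, means, width=width, yerr=errs, capsize=3, label=cond)
    ax.axhline(0.0, color="k", linestyle="--", linewidth=1)
    ax.set_xticks(np.arange(len(tasks)) + width * (len(conditions) - 1) / 2)
    ax.set_xticklabels(tasks)
    ax.set_ylabel("Shape Index")
    ax.legend(title="condition")
    return ax


def plot_intermediate_final(scored: pd.DataFrame, ax=None):
    """Production-task SI at intermediate vs final test per condition.

    Under uniform retrieval the three conditions diverge at the intermediate
    test (each group has seen a different distribution so far) and converge
    on zero at the final test — the crossover signature.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = scored[(scored["task"] == "production") & (scored["measure"] == "si")]
    times = [t for t in ("intermediate", "final") if t in set(data["test_time"])]
    for cond in sorted(data["condition"].unique()):
        means, errs = [], []
        for tt in times:
            v = data[(data["condition"] == cond) & (data["test_time"] == tt)]["value"]
            means.append(v.mean())
            errs.append(1.96 * v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        ax.errorbar(range(len(times)), means, yerr=errs, marker="o", capsize=3,
                    label=cond)
    ax.axhline(0.0, color="k", linestyle="--", linewidth=1)
    ax.set_xticks(range(len(times)))
    ax.set_xticklabels(times)
    ax.set_ylabel("Shape Index (production)")
    ax.legend(title="condition")
    return ax


def plot_deviations(scored: pd.DataFrame, ax=None):
    """Signed deviation of central tendency vs variability estimates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = scored[scored["measure"].str.startswith("signed_dev_", na=False)].copy()
    rows["measurement"] = rows["measure"].str.replace("signed_dev_", "", regex=False)
    labels, means, errs = [], [], []
    for m, g in rows.groupby("measurement", observed=True):
        labels.append(m)
        means.append(g["value"].mean())
        errs.append(1.96 * g["value"].std(ddof=1) / np.sqrt(len(g)))
    ax.bar(labels, means, yerr=errs, capsize=3)
    ax.axhline(0.0, color="k", linestyle="--", linewidth=1)
    ax.set_ylabel("signed deviation (rating units)")
    return ax
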