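"""Analysis layer: mixed ANOVA, order analysis, collapsing, and power.

The designs analyzed here are split-plot: one between-subjects factor
(presentation-order condition) crossed with one within-subjects factor
(task, measurement type, test time, or matrix provenance). The between
effect is tested against the subjects-within-groups error; the within main
effect and the interaction against the subject-by-within residual. All
within factors in scope have two or three levels and are tested with plain
(uncorrected) F ratios.

Between-subjects power uses the noncentral F distribution with
noncentrality lambda = n (k - 1) RMSSE^2, where RMSSE is the
root-mean-square standardized effect across the k group means. This is the
convention under which a k = 3, n = 16 design has power close to .7 for
RMSSE = .5 at alpha = .05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .shape_index import DeviationResult


@dataclass(frozen=True)
class AnovaResult:
    effect: str  # "between" | "within" | "interaction"
    F: float
    df1: int
    df2: int
    p: float

    def to_dict(self) -> dict:
        return {"effect": self.effect, "F": self.F, "df1": self.df1,
                "df2": self.df2, "p": self.p}


@dataclass(frozen=True)
class PowerSpec:
    """Design and effect size for a between-subjects ANOVA power computation."""

    k_groups: int
    n_per_group: int
    rmsse: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.rmsse < 0:
            raise ValueError("rmsse must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _f_ratio(ss_effect: float, df_effect: int, ss_error: float, df_error: int,
             effect: str) -> AnovaResult:
    ms_error = ss_error / df_error
    if ms_error <= 0:
        # degenerate (e.g. constant dv): no variance anywhere -> F = 0
        f = 0.0 if ss_effect <= 1e-12 else np.inf
    else:
        f = (ss_effect / df_effect) / ms_error
    p = float(sps.f.sf(f, df_effect, df_error)) if np.isfinite(f) else 0.0
    return AnovaResult(effect=effect, F=float(f), df1=int(df_effect),
                       df2=int(df_error), p=p)


def mixed_anova(data: pd.DataFrame, dv: str, between: str, within: str,
                subject: str = "participant_id") -> dict[str, AnovaResult]:
    """Split-plot ANOVA: one between- and one within-subjects factor.

    ``data`` is a long table with one row per subject x within-level. Every
    subject must have exactly one observation at every within level (missing
    cells are rejected); group sizes may differ slightly.

    Returns results keyed ``between``, ``within``, ``interaction``; when the
    within factor has a single level the design degenerates to a one-way
    ANOVA and only the ``between`` entry is returned.
    """
    cols = {dv, between, within, subject}
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(
            f"missing cells: subjects {bad} lack observations at some {within} level")
    counts = data.groupby([subject, within], observed=True).size()
    if (counts > 1).any():
        raise ValueError(f"duplicate observations per subject x {within} cell")

    groups = data.groupby(subject, observed=True)[between].agg(lambda s: s.iloc[0])
    if data.groupby(subject, observed=True)[between].nunique().gt(1).any():
        raise ValueError("a subject appears under more than one between-level")
    groups = groups.loc[wide.index]

    y = wide.to_numpy(dtype=float)
    n_subj, b = y.shape
    a = groups.nunique()
    if a < 2:
        raise ValueError("between factor needs at least two levels")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_of = groups.to_numpy()
    levels = pd.unique(group_of)
    group_means = {g: subj_means[group_of == g].mean() for g in levels}
    n_g = {g: int((group_of == g).sum()) for g in levels}

    ss_between = b * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in levels)
    ss_subj = b * sum(
        ((subj_means[group_of == g] - group_means[g]) ** 2).sum() for g in levels)
    df_between, df_subj = a - 1, n_subj - a

    out: dict[str, AnovaResult] = {}
    if df_subj > 0:
        out["between"] = _f_ratio(ss_between, df_between, ss_subj, df_subj, "between")
    if b == 1:
        return out

    level_means = y.mean(axis=0)
    ss_within = n_subj * ((level_means - grand) ** 2).sum()
    cell = {g: y[group_of == g].mean(axis=0) for g in levels}
    ss_inter = sum(
        n_g[g] * ((cell[g] - group_means[g] - level_means + grand) ** 2).sum()
        for g in levels)
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between - ss_subj - ss_within - ss_inter
    ss_err_within = max(ss_err_within, 0.0)  # guard tiny negative round-off
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (n_subj - a) * (b - 1)

    if df_err > 0:
        out["within"] = _f_ratio(ss_within, df_within, ss_err_within, df_err, "within")
        out["interaction"] = _f_ratio(ss_inter, df_inter, ss_err_within, df_err,
                                      "interaction")
    return out


def anova_power_between(spec: PowerSpec) -> float:
    """Power of the between-subjects F test at the specified effect size.

    power = P( F'(k-1, k(n-1), lambda) > F_crit ), lambda = n (k-1) RMSSE^2.
    With RMSSE = 0 the noncentral F reduces to the central F and the power
    equals alpha exactly.
    """
    k, n = spec.k_groups, spec.n_per_group
    df1, df2 = k - 1, k * (n - 1)
    crit = sps.f.ppf(1 - spec.alpha, df1, df2)
    if spec.rmsse == 0:
        return float(spec.alpha)
    lam = n * (k - 1) * spec.rmsse**2
    return float(sps.ncf.sf(crit, df1, df2, lam))


def quarter_order_analysis(responses: pd.DataFrame, stimuli: pd.DataFrame,
                           quarter: int = 30, estimate_col: str = "est_mean",
                           subject: str = "participant_id") -> pd.DataFrame:
    """Per-participant absolute error of the mean estimate vs first/last/total mean.

    ``stimuli`` is a long table (participant_id, order_index, value) holding
    each participant's own presentation sequence; ``responses`` holds one
    mean estimate per participant. A primacy-driven judge tracks the first
    ``quarter`` values more closely than the total; a recency-driven judge
    tracks the last. Other partitions are supported by varying ``quarter``.
    """
    need = {subject, "order_index", "value"}
    if need - set(stimuli.columns):
        raise ValueError(f"stimuli table needs columns {sorted(need)}")
    rows = []
    est = responses.set_index(subject)[estimate_col]
    for pid, seq in stimuli.groupby(subject, observed=True):
        seq = seq.sort_values("order_index")["value"].to_numpy(dtype=float)
        if quarter > seq.size // 2:
            raise ValueError(
                f"quarter ({quarter}) exceeds half the sequence length ({seq.size})")
        if pid not in est.index:
            continue
        e = float(est.loc[pid])
        rows.append({
            subject: pid,
            "abs_err_first": abs(e - seq[:quarter].mean()),
            "abs_err_last": abs(e - seq[-quarter:].mean()),
            "abs_err_total": abs(e - seq.mean()),
        })
    if not rows:
        raise ValueError("no participants shared between responses and stimuli")
    return pd.DataFrame(rows)


def quarter_errors_long(errors: pd.DataFrame, conditions: pd.Series | None = None,
                        subject: str = "participant_id") -> pd.DataFrame:
    """Melt quarter-analysis errors to long form for the 3x3 mixed ANOVA."""
    long = errors.melt(id_vars=[subject],
                       value_vars=["abs_err_first", "abs_err_last", "abs_err_total"],
                       var_name="reference", value_name="abs_err")
    long["reference"] = long["reference"].str.replace("abs_err_", "", regex=False)
    if conditions is not None:
        long = long.merge(conditions.rename("condition"), left_on=subject,
                          right_index=True, how="left")
    return long


def collapse_central_tendency(dev_mean: DeviationResult,
                              dev_median: DeviationResult) -> DeviationResult:
    """Collapse mean and median deviations into one central-tendency measure.

    Signed deviations are averaged, and absolute deviations are averaged
    (rather than recomputed from the collapsed signed value), so a
    participant who overshoots the mean and undershoots the median by equal
    amounts still registers the inaccuracy.
    """
    return DeviationResult(
        absolute=0.5 * (dev_mean.absolute + dev_median.absolute),
        signed=0.5 * (dev_mean.signed + dev_median.signed),
        measurement="central_tendency",
    )


def screen_outliers(signed: pd.Series | np.ndarray, c: float = 3.0) -> np.ndarray:
    """Boolean keep-mask: drop values farther than c x IQR from the median.

    Off by default in every pipeline; provided because published analyses
    sometimes drop an extreme respondent without stating a rule.
    """
    x = np.asarray(signed, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.ones_like(x, dtype=bool)
    return np.abs(x - np.median(x)) <= c * iqr
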