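"""In-silico replications of the two order-effect experiments.

Experiment 1: three groups (n = 16 each) see the same 120 exposure values
under different orders (U-B, B-U, UN), then perform the production,
identification, sampling, and descriptive tasks once. Experiment 2 uses the
same design at n = 14 per group but interrupts exposure after 60 values
with an intermediate production test; the final test covers all 120 values.

Each simulated participant gets an independent presentation order of the
shared materials, encodes it as exemplars, and answers every task by
sampling from memory under the configured retrieval scheme. The result
bundle carries the raw stimulus sequences, the response table, the scored
table (Shape Index and deviations), and the ANOVA summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .nsm import (
    ExemplarMemory,
    ResponseRecord,
    SamplingScheme,
    encode,
    simulate_participant,
)
from .profiles import N_BINS, largest_remainder
from .shape_index import (
    DEFAULT_CONFIG,
    ShapeIndexConfig,
    deviation,
    si_from_identification,
    si_from_production,
    si_from_sample,
)
from .stats import (
    collapse_central_tendency,
    mixed_anova,
    quarter_errors_long,
    quarter_order_analysis,
)
from .stimuli import (
    CONDITIONS,
    HistogramPrototype,
    MatrixTrial,
    StimulusSet,
    generate_matrices,
    generate_prototypes,
    generate_uniform_set,
    order_by_condition,
    partition_unimodal_bimodal,
)

_TASK_ORDERS = (
    ("production", "identification", "sampling"),
    ("production", "sampling", "identification"),
    ("identification", "production", "sampling"),
    ("identification", "sampling", "production"),
    ("sampling", "production", "identification"),
    ("sampling", "identification", "production"),
)

RESPONSE_COLUMNS = (
    ["participant_id", "condition", "test_time", "task", "trial_index", "provenance"]
    + [f"bin_{i}" for i in range(1, N_BINS + 1)]
    + ["choice", "selected", "est_mean", "est_median", "est_mad",
       "policy", "decay", "k"]
)


@dataclass
class ExperimentConfig:
    """Design parameters of one simulated experiment run."""

    experiment: int = 1
    n_per_condition: int | None = None  # defaults: 16 (Exp 1), 14 (Exp 2)
    scheme: SamplingScheme = field(default_factory=SamplingScheme)
    n_pools: int = 5
    seed: int = 0
    n_values: int = 120
    per_decile: int = 12
    beta_alpha: float = 2.4
    si_config: ShapeIndexConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    task_order_counterbalance: bool = True
    anchor_weight: float = 0.0  # Exp 2 anchoring-and-adjustment variant; 0 = off
    response_noise_sd: float = 0.0

    def __post_init__(self):
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if not 0 <= self.anchor_weight <= 1:
            raise ValueError("anchor_weight must be in [0, 1]")
        if self.n_per_condition is None:
            self.n_per_condition = 16 if self.experiment == 1 else 14

    @property
    def intermediate_at(self) -> int | None:
        return self.n_values // 2 if self.experiment == 2 else None


@dataclass
class Materials:
    """The shared stimulus materials of one run (same for all participants)."""

    E: StimulusSet
    T: StimulusSet
    E_a: np.ndarray
    E_b: np.ndarray
    matrices: list[MatrixTrial]
    prototypes: list[HistogramPrototype]


def build_materials(config: ExperimentConfig, seed=None) -> Materials:
    ss = np.random.SeedSequence(config.seed) if seed is None else seed
    s_e, s_t, s_part, s_mat = ss.spawn(4)
    E = generate_uniform_set(config.n_values, config.per_decile, seed=s_e)
    T = generate_uniform_set(config.n_values, config.per_decile, seed=s_t,
                             exclude=E.values)
    E_a, E_b = partition_unimodal_bimodal(E, alpha=config.beta_alpha, seed=s_part)
    matrices = generate_matrices(E, T, seed=s_mat)
    return Materials(E=E, T=T, E_a=E_a, E_b=E_b, matrices=matrices,
                     prototypes=generate_prototypes())


# ---------------------------------------------------------------------------
# Response table plumbing
# ---------------------------------------------------------------------------


def record_to_rows(rec: ResponseRecord) -> list[dict]:
    """Flatten a ResponseRecord into one row per task instance."""
    base = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "test_time": rec.test_time,
        "policy": rec.scheme.policy,
        "decay": rec.scheme.decay,
        "k": rec.k_used if rec.k_used is not None else rec.scheme.k,
    }
    rows = []
    if rec.production is not None:
        row = dict(base, task="production")
        for i, c in enumerate(rec.production, start=1):
            row[f"bin_{i}"] = int(c)
        rows.append(row)
    if rec.identification is not None:
        rows.append(dict(base, task="identification", choice=int(rec.identification)))
    for trial_index, values in sorted(rec.sample_selections.items()):
        rows.append(dict(
            base, task="sample", trial_index=int(trial_index),
            provenance=rec.sample_provenance.get(trial_index, ""),
            selected=";".join(str(int(v)) for v in values),
        ))
    if rec.est_mean is not None:
        rows.append(dict(base, task="descriptive", est_mean=rec.est_mean,
                         est_median=rec.est_median, est_mad=rec.est_mad))
    return rows


def records_to_frame(records) -> pd.DataFrame:
    rows = [row for rec in records for row in record_to_rows(rec)]
    df = pd.DataFrame(rows)
    for col in RESPONSE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[list(RESPONSE_COLUMNS)]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_responses(responses: pd.DataFrame,
                    prototypes: list[HistogramPrototype],
                    normative: dict[str, float],
                    si_config: ShapeIndexConfig = DEFAULT_CONFIG,
                    production_total: int = 120) -> pd.DataFrame:
    """Score a response table: SI per shape task, deviations for descriptives.

    ``normative`` supplies the true mean/median/mad of the exposure set.
    Returns a long table (participant_id, condition, test_time, task,
    provenance, trial_index, measure, value); sampling-task rows appear once
    per matrix trial plus one "all" aggregate over every selected value.
    """
    bin_cols = [f"bin_{i}" for i in range(1, N_BINS + 1)]
    out = []

    def emit(row, task, measure, value, provenance="", trial_index=None):
        out.append({
            "participant_id": row["participant_id"],
            "condition": row["condition"],
            "test_time": row["test_time"],
            "task": task,
            "provenance": provenance,
            "trial_index": trial_index,
            "measure": measure,
            "value": float(value),
        })

    for (pid, tt), grp in responses.groupby(["participant_id", "test_time"],
                                            observed=True, sort=False):
        pooled_selected = []
        dev_rows = {}
        for _, row in grp.iterrows():
            task = row["task"]
            if task == "production":
                freqs = row[bin_cols].to_numpy(dtype=float)
                res = si_from_production(freqs, total=production_total, config=si_config)
                emit(row, "production", "si", res.si)
            elif task == "identification":
                res = si_from_identification(int(row["choice"]), prototypes, si_config)
                emit(row, "identification", "si", res.si)
            elif task == "sample":
                values = np.array([int(v) for v in str(row["selected"]).split(";")])
                pooled_selected.append(values)
                res = si_from_sample(values, config=si_config)
                emit(row, "sample", "si", res.si,
                     provenance=row["provenance"], trial_index=int(row["trial_index"]))
            elif task == "descriptive":
                dev_mean = deviation(row["est_mean"], normative["mean"])
                dev_median = deviation(row["est_median"], normative["median"])
                central = collapse_central_tendency(dev_mean, dev_median)
                variability = deviation(row["est_mad"], normative["mad"],
                                        measurement="variability")
                dev_rows = {"central_tendency": central, "variability": variability}
                for name, d in dev_rows.items():
                    emit(row, "descriptive", f"signed_dev_{name}", d.signed)
                    emit(row, "descriptive", f"abs_dev_{name}", d.absolute)
        if pooled_selected:
            res = si_from_sample(np.concatenate(pooled_selected), config=si_config)
            last = grp[grp["task"] == "sample"].iloc[0]
            emit(last, "sample", "si", res.si, provenance="all")
    return pd.DataFrame(out)


def old_new_comparison(scored: pd.DataFrame) -> dict:
    """Summarize sampling-task SI by matrix provenance (old vs new).

    Averages each participant's per-trial SI within provenance, then across
    participants. If a provenance class is absent the summary is flagged
    incomplete — the old/new contrast is then undefined.
    """
    rows = scored[(scored["task"] == "sample")
                  & (scored["provenance"].isin(["old", "new"]))]
    summary: dict = {"old": None, "new": None, "difference": None, "incomplete": False}
    per_subject = {}
    for prov in ("old", "new"):
        sub = rows[rows["provenance"] == prov]
        if sub.empty:
            summary["incomplete"] = True
            continue
        by_subject = sub.groupby("participant_id", observed=True)["value"].mean()
        per_subject[prov] = by_subject
        summary[prov] = {"mean_si": float(by_subject.mean()),
                         "sd_si": float(by_subject.std(ddof=1)) if len(by_subject) > 1 else 0.0,
                         "n": int(len(by_subject))}
    if not summary["incomplete"]:
        summary["difference"] = summary["old"]["mean_si"] - summary["new"]["mean_si"]
    return summary


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def _effects_to_dict(effects: dict) -> dict:
    return {name: res.to_dict() for name, res in effects.items()}


def _subject_table(scored: pd.DataFrame, mask, within_col: str,
                   value_from: str = "value") -> pd.DataFrame:
    sub = scored[mask]
    return sub.rename(columns={value_from: "dv"})[
        ["participant_id", "condition", within_col, "dv"]]


def analyze_scored(scored: pd.DataFrame, experiment: int,
                   responses: pd.DataFrame | None = None,
                   stimuli: pd.DataFrame | None = None,
                   quarter: int = 30) -> dict:
    """Run the experiment's ANOVA suite on a scored table.

    Returns a JSON-ready dict of effect tables and group means. Experiment 1
    analyzes final-test SI across the three shape tasks; Experiment 2
    analyzes production SI across test times. Both analyze the deviation
    measures, the old/new sampling contrast and — when the raw responses and
    stimulus sequences are supplied — the first/last-quarter order analysis.
    """
    analysis: dict = {}
    final = scored[scored["test_time"] == "final"]

    si_all = final[(final["measure"] == "si")
                   & ((final["task"] != "sample") | (final["provenance"] == "all"))]
    if experiment == 1 and si_all["task"].nunique() > 1:
        tbl = si_all.rename(columns={"value": "dv"})
        analysis["si_task_anova"] = _effects_to_dict(
            mixed_anova(tbl, dv="dv", between="condition", within="task"))
    if experiment == 2:
        prod = scored[(scored["task"] == "production") & (scored["measure"] == "si")]
        if prod["test_time"].nunique() == 2:
            tbl = prod.rename(columns={"value": "dv"})
            analysis["si_test_time_anova"] = _effects_to_dict(
                mixed_anova(tbl, dv="dv", between="condition", within="test_time"))
        analysis["si_production_means"] = {
            tt: {cond: float(g["value"].mean())
                 for cond, g in sub.groupby("condition", observed=True)}
            for tt, sub in prod.groupby("test_time", observed=True)
        }
    analysis["si_task_means"] = {
        task: {cond: float(g["value"].mean())
               for cond, g in sub.groupby("condition", observed=True)}
        for task, sub in si_all.groupby("task", observed=True)
    }

    for kind in ("signed", "abs"):
        dev = final[final["measure"].str.startswith(f"{kind}_dev_", na=False)].copy()
        if dev.empty:
            continue
        dev["measurement"] = dev["measure"].str.replace(f"{kind}_dev_", "", regex=False)
        tbl = dev.rename(columns={"value": "dv"})
        analysis[f"deviation_{kind}_anova"] = _effects_to_dict(
            mixed_anova(tbl, dv="dv", between="condition", within="measurement"))
        analysis[f"deviation_{kind}_means"] = {
            m: float(g["dv"].mean()) for m, g in tbl.groupby("measurement", observed=True)}

    trials = final[(final["task"] == "sample")
                   & (final["provenance"].isin(["old", "new"]))]
    if not trials.empty:
        per = (trials.groupby(["participant_id", "condition", "provenance"],
                              observed=True)["value"].mean().reset_index())
        analysis["old_new_comparison"] = old_new_comparison(final)
        if per["provenance"].nunique() == 2:
            tbl = per.rename(columns={"value": "dv"})
            analysis["old_new_anova"] = _effects_to_dict(
                mixed_anova(tbl, dv="dv", between="condition", within="provenance"))

    if responses is not None and stimuli is not None:
        desc = responses[(responses["task"] == "descriptive")
                         & (responses["test_time"] == "final")]
        if not desc.empty:
            errors = quarter_order_analysis(desc, stimuli, quarter=quarter)
            conditions = desc.set_index("participant_id")["condition"]
            long = quarter_errors_long(errors, conditions=conditions)
            tbl = long.rename(columns={"abs_err": "dv"})
            analysis["quarter_order_anova"] = _effects_to_dict(
                mixed_anova(tbl, dv="dv", between="condition", within="reference"))
            analysis["quarter_order_means"] = {
                ref: float(g["dv"].mean())
                for ref, g in tbl.groupby("reference", observed=True)}
    return analysis


# ---------------------------------------------------------------------------
# The run itself
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    materials: Materials
    stimuli: pd.DataFrame
    responses: pd.DataFrame
    scored: pd.DataFrame
    analysis: dict
    normative: dict[str, float]

    def save(self, outdir) -> None:
        """Write stimuli/responses/scored CSVs, analysis JSON, and a run log."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.stimuli.to_csv(out / "stimuli.csv", index=False)
        self.responses.to_csv(out / "responses.csv", index=False)
        self.scored.to_csv(out / "scored.csv", index=False)
        with open(out / "analysis.json", "w") as fh:
            json.dump(self.analysis, fh, indent=2)
        cfg = dataclasses.asdict(self.config)
        cfg["si_config"] = {"excluded_bins": list(self.config.si_config.excluded_bins),
                            "sign_vector": list(self.config.si_config.sign_vector)}
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"naivesampling {_pkg_version}\n")
            fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
            fh.write(json.dumps(cfg, indent=2, default=str) + "\n")
            fh.write(json.dumps({"normative": self.normative}, indent=2) + "\n")


def _anchored_production(intermediate: np.ndarray, fresh: np.ndarray,
                         weight: float, total: int) -> np.ndarray:
    blend = weight * intermediate / intermediate.sum() + (1 - weight) * fresh / fresh.sum()
    return largest_remainder(blend, total)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate one full experiment and analyze it.

    Fully reproducible from ``config.seed``: materials and every participant
    draw from independent child streams of one seed sequence, so individual
    participants can be regenerated regardless of execution order.
    """
    root = np.random.SeedSequence(config.seed)
    mat_ss, part_root = root.spawn(2)
    materials = build_materials(config, seed=mat_ss)
    norm_values = materials.E.values.astype(float)
    m = float(norm_values.mean())
    normative = {
        "mean": m,
        "median": float(np.median(norm_values)),
        "mad": float(np.mean(np.abs(norm_values - m))),
    }

    n = config.n_per_condition
    participant_seeds = part_root.spawn(len(CONDITIONS) * n)
    stim_rows, records = [], []
    idx = 0
    for cond in CONDITIONS:
        for j in range(n):
            pid = f"P{idx + 1:03d}"
            pseed = participant_seeds[idx]
            idx += 1
            s_order, s_tasks, s_inter = pseed.spawn(3)
            sequence = order_by_condition(materials.E_a, materials.E_b, cond,
                                          seed=s_order)
            frame = sequence.to_frame()
            frame.insert(0, "participant_id", pid)
            stim_rows.append(frame)

            task_order = (_TASK_ORDERS[idx % len(_TASK_ORDERS)]
                          if config.task_order_counterbalance else _TASK_ORDERS[0])

            if config.intermediate_at is not None:
                memory_half = encode(sequence.values[: config.intermediate_at])
                rec_inter = simulate_participant(
                    memory_half, config.scheme, seed=s_inter,
                    participant_id=pid, condition=cond, test_time="intermediate",
                    tasks=("production",),
                    production_total=config.n_values,
                    n_pools=config.n_pools,
                    response_noise_sd=config.response_noise_sd,
                )
                records.append(rec_inter)

            memory = encode(sequence)
            rec = simulate_participant(
                memory, config.scheme, seed=s_tasks,
                participant_id=pid, condition=cond, test_time="final",
                tasks=tuple(task_order) + ("descriptive",),
                prototypes=materials.prototypes, matrices=materials.matrices,
                production_total=config.n_values, n_pools=config.n_pools,
                response_noise_sd=config.response_noise_sd,
            )
            rec.task_order = tuple(task_order)
            if (config.intermediate_at is not None and config.anchor_weight > 0
                    and rec.production is not None):
                rec.production = _anchored_production(
                    records[-1].production.astype(float),
                    rec.production.astype(float),
                    config.anchor_weight, config.n_values)
            records.append(rec)

    stimuli = pd.concat(stim_rows, ignore_index=True)
    responses = records_to_frame(records)
    scored = score_responses(responses, materials.prototypes, normative,
                             si_config=config.si_config,
                             production_total=config.n_values)
    analysis = analyze_scored(scored, config.experiment,
                              responses=responses, stimuli=stimuli)
    return ExperimentResult(config=config, materials=materials, stimuli=stimuli,
                            responses=responses, scored=scored, analysis=analysis,
                            normative=normative)
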