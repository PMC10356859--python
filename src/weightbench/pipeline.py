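"""End-to-end pipeline: simulate -> filter -> predict -> validate -> compare.

``run_simulate`` writes a raw participant table from the synthetic-cohort
generator; ``run_validate`` builds the analysis cohort, generates expected
weights from both prediction models, computes the weekly observed-vs-
expected statistics, and runs the percentile-bootstrap MSE comparison.
Every output embeds the config hash and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants as c
from .bootstrap_inference import ComparisonVerdict, compare_models_mse
from .cohort_filter import (
    CohortComposition,
    ExclusionTally,
    IncludedParticipant,
    build_cohort,
)
from .io import config_hash, read_participant_table, write_participant_table, write_yaml
from .synthetic_cohort import (
    DiscrepancyConfig,
    FlowConfig,
    PopulationConfig,
    SexStats,
    generate_enrollment,
)
from .types import (
    FOLLOWUP_WEEKS,
    ActivityConfig,
    IntakeSchedule,
    KG_PER_LB,
    ModelId,
    ObservedExpectedPair,
    ParticipantRecord,
)
from .validation_stats import (
    model_accuracy_contrast,
    relative_weight_difference,
    summaries_to_frame,
    weekly_summaries,
)
from .weight_models import predict_cohort


@dataclass(frozen=True)
class PipelineConfig:
    population: PopulationConfig = PopulationConfig()
    flow: FlowConfig = FlowConfig()
    discrepancy: DiscrepancyConfig = DiscrepancyConfig()
    schedule: IntakeSchedule = IntakeSchedule.standard_program()
    pal: float = c.PAL_DEFAULT
    models: tuple[ModelId, ...] = (ModelId.NIH_BWP, ModelId.PBRC_WLP)
    truth_model: ModelId = ModelId.NIH_BWP
    comparison_week: int = 7
    bootstrap_resamples: int = 1000
    bootstrap_level: float = 83.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = [m.value for m in self.models]
        d["truth_model"] = self.truth_model.value
        d["schedule"] = {
            "segments": [list(s) for s in self.schedule.segments],
            "horizon_days": self.schedule.horizon_days,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "population" in kwargs:
            pop = dict(kwargs["population"])
            for sex_key in ("female", "male"):
                if sex_key in pop:
                    pop[sex_key] = SexStats(**pop[sex_key])
            for bounds in ("age_bounds", "height_bounds", "weight_bounds"):
                if bounds in pop:
                    pop[bounds] = tuple(pop[bounds])
            kwargs["population"] = PopulationConfig(**pop)
        if "flow" in kwargs:
            kwargs["flow"] = FlowConfig(**kwargs["flow"])
        if "discrepancy" in kwargs:
            kwargs["discrepancy"] = DiscrepancyConfig(**kwargs["discrepancy"])
        if "schedule" in kwargs:
            s = kwargs["schedule"]
            kwargs["schedule"] = IntakeSchedule(
                segments=tuple(tuple(seg) for seg in s["segments"]),
                horizon_days=int(s["horizon_days"]),
            )
        if "models" in kwargs:
            kwargs["models"] = tuple(ModelId(m) for m in kwargs["models"])
        if "truth_model" in kwargs:
            kwargs["truth_model"] = ModelId(kwargs["truth_model"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        write_yaml(self.to_dict(), path)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def run_simulate(config: PipelineConfig, out_path: Optional[str | Path] = None) -> pd.DataFrame:
    """Generate the raw participant table; optionally write it as CSV."""
    records = generate_enrollment(
        config.population,
        config.flow,
        config.discrepancy,
        schedule=config.schedule,
        pal=config.pal,
        truth_model=config.truth_model,
        seed=config.seed,
    )
    from .io import records_to_frame

    frame = records_to_frame(records)
    if out_path is not None:
        write_participant_table(records, out_path)
    return frame


@dataclass
class ValidationReport:
    """All computed outputs of one validation run."""

    tally: ExclusionTally
    composition: CohortComposition
    summaries: pd.DataFrame  # tidy: model, statistic, week, n, mean, ...
    mse_table: pd.DataFrame  # model, week, n, mse_lb2
    errors: pd.DataFrame  # subject_id, model, week, observed_kg, expected_kg
    comparison: Optional[ComparisonVerdict]
    comparison_week: int
    config_hash: str
    seed: int

    def summary_value(self, model: str, statistic: str, week: int, column: str) -> float:
        df = self.summaries
        row = df[(df.model == model) & (df.statistic == statistic) & (df.week == week)]
        return float(row[column].iloc[0])

    def mse(self, model: ModelId | str, week: int) -> float:
        m = ModelId(model).value
        df = self.mse_table
        return float(df[(df.model == m) & (df.week == week)]["mse_lb2"].iloc[0])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config_hash, "seed": self.seed}
        self.summaries.to_csv(outdir / "summaries.csv", index=False)
        self.mse_table.to_csv(outdir / "mse.csv", index=False)
        self.errors.to_csv(outdir / "errors.csv", index=False, float_format="%.6f")
        write_yaml({**meta, "tally": self.tally.to_dict()}, outdir / "tally.yaml")
        write_yaml({**meta, "composition": self.composition.to_dict()}, outdir / "composition.yaml")
        payload = {**meta, "comparison_week": self.comparison_week}
        if self.comparison is not None:
            payload["comparison"] = self.comparison.to_dict()
        write_yaml(payload, outdir / "comparison.yaml")

    def report_text(self) -> str:
        lines = [
            f"weightbench validation report (config {self.config_hash}, seed {self.seed})",
            f"screened {self.tally.n_screened}, included {self.tally.n_included} "
            f"({100 - self.tally.percent_excluded:.1f}%)",
            "exclusions: "
            + ", ".join(
                f"{k}={v}" for k, v in self.tally.to_dict()["counts"].items()
            ),
            f"cohort: {self.composition.percent_female:.1f}% female, "
            f"{self.composition.percent_with_at_least(5):.1f}% with >=5 follow-up weights",
            "",
            "week-7 statistics:",
        ]
        for model in sorted(self.mse_table.model.unique()):
            try:
                mean_rd = self.summary_value(model, "relative_difference_pct", 7, "mean")
                sd_rd = self.summary_value(model, "relative_difference_pct", 7, "sd")
                lines.append(
                    f"  {model}: mean relative difference {mean_rd:+.2f}% (SD {sd_rd:.2f}), "
                    f"MSE {self.mse(model, 7):.1f} lb^2"
                )
            except (IndexError, KeyError):
                continue
        if self.comparison is not None:
            v = self.comparison
            lines += [
                "",
                f"bootstrap comparison at week {self.comparison_week} "
                f"({v.model_a.n_resamples} resamples, {v.model_a.level:.0f}% CIs):",
                f"  {v.model_a.statistic}: {v.model_a.point_estimate:.1f} "
                f"({v.model_a.ci_low:.1f}-{v.model_a.ci_high:.1f})",
                f"  {v.model_b.statistic}: {v.model_b.point_estimate:.1f} "
                f"({v.model_b.ci_low:.1f}-{v.model_b.ci_high:.1f})",
                f"  intervals overlap: {v.intervals_overlap}; "
                f"significant at p<0.05: {v.significant_at_0_05}",
            ]
        return "\n".join(lines)


def _observed_change_frames(cohort: Sequence[IncludedParticipant]) -> pd.DataFrame:
    rows = []
    for part in cohort:
        base = part.baseline.value
        for w in part.record.followup_weeks():
            obs = part.record.weights_by_week[w]
            rows.append(
                {
                    "subject_id": part.record.subject_id,
                    "week": w,
                    "change_lb": (obs - base) / KG_PER_LB,
                    "relative_change_pct": 100.0 * (obs - base) / base,
                }
            )
    return pd.DataFrame(rows)


def run_validate(
    config: PipelineConfig,
    records: Optional[Sequence[ParticipantRecord] | str | Path] = None,
    outdir: Optional[str | Path] = None,
) -> ValidationReport:
    """Filter the cohort, predict with both models, compute all statistics.

    ``records`` may be a list of :class:`ParticipantRecord`, a path to a
    participant table, or None to simulate under ``config`` first.
    """
    if records is None:
        records = generate_enrollment(
            config.population,
            config.flow,
            config.discrepancy,
            schedule=config.schedule,
            pal=config.pal,
            truth_model=config.truth_model,
            seed=config.seed,
        )
    elif isinstance(records, (str, Path)):
        records = read_participant_table(records)

    cohort, tally = build_cohort(records)
    composition = CohortComposition.from_cohort(cohort)
    activity = ActivityConfig(config.pal)
    profiles = [p.profile for p in cohort]

    summary_frames = []
    mse_rows = []
    error_rows = []
    rd_by_model: dict[str, dict[int, dict[str, float]]] = {}

    change_df = _observed_change_frames(cohort)
    if not change_df.empty:
        for stat in ("change_lb", "relative_change_pct"):
            summaries = weekly_summaries(change_df, value_column=stat)
            label = "weight_change_lb" if stat == "change_lb" else "relative_weight_change_pct"
            summary_frames.append(
                summaries_to_frame(summaries, model="observed", statistic=label)
            )

    for model in config.models:
        series = predict_cohort(model, profiles, config.schedule, activity)
        rd_weeks: dict[int, dict[str, float]] = {w: {} for w in FOLLOWUP_WEEKS}
        pairs_by_week: dict[int, list[ObservedExpectedPair]] = {w: [] for w in FOLLOWUP_WEEKS}
        for part, s in zip(cohort, series):
            expected = s.as_dict()
            for w in part.record.followup_weeks():
                obs = part.record.weights_by_week[w]
                exp = expected[w]
                pairs_by_week[w].append(
                    ObservedExpectedPair(part.record.subject_id, w, obs, exp)
                )
                rd_weeks[w][part.record.subject_id] = relative_weight_difference(obs, exp)
                error_rows.append(
                    {
                        "subject_id": part.record.subject_id,
                        "model": model.value,
                        "week": w,
                        "observed_kg": obs,
                        "expected_kg": exp,
                    }
                )
        rd_by_model[model.value] = rd_weeks
        rd_values = {w: list(d.values()) for w, d in rd_weeks.items() if d}
        summary_frames.append(
            summaries_to_frame(
                weekly_summaries(rd_values), model=model.value, statistic="relative_difference_pct"
            )
        )
        for w, pairs in pairs_by_week.items():
            if not pairs:
                continue
            err_lb = np.array([(p.observed - p.expected) / KG_PER_LB for p in pairs])
            mse_rows.append(
                {"model": model.value, "week": w, "n": len(pairs), "mse_lb2": float(np.mean(err_lb**2))}
            )

    # Patient-specific contrast between the first two models (Tukey panel D).
    if len(config.models) >= 2:
        a, b = config.models[0].value, config.models[1].value
        contrast_summaries = []
        for w in FOLLOWUP_WEEKS:
            if rd_by_model[a].get(w) and rd_by_model[b].get(w):
                contrast_summaries.append(
                    model_accuracy_contrast(rd_by_model[a][w], rd_by_model[b][w], w).summary
                )
        if contrast_summaries:
            summary_frames.append(
                summaries_to_frame(
                    contrast_summaries,
                    model=f"{a}-{b}",
                    statistic="accuracy_contrast_pct",
                )
            )

    summaries = (
        pd.concat(summary_frames, ignore_index=True) if summary_frames else pd.DataFrame()
    )
    mse_table = pd.DataFrame(mse_rows, columns=["model", "week", "n", "mse_lb2"])
    errors = pd.DataFrame(
        error_rows, columns=["subject_id", "model", "week", "observed_kg", "expected_kg"]
    )

    comparison = None
    if len(config.models) >= 2:
        comparison = compare_week_mse(
            errors,
            config.models[0],
            config.models[1],
            week=config.comparison_week,
            level=config.bootstrap_level,
            n_resamples=config.bootstrap_resamples,
            seed=config.seed,
        )

    report = ValidationReport(
        tally=tally,
        composition=composition,
        summaries=summaries,
        mse_table=mse_table,
        errors=errors,
        comparison=comparison,
        comparison_week=config.comparison_week,
        config_hash=config.hash,
        seed=config.seed,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def compare_week_mse(
    errors: pd.DataFrame,
    model_a: ModelId | str,
    model_b: ModelId | str,
    *,
    week: int = 7,
    level: float = 83.0,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> Optional[ComparisonVerdict]:
    """Paired bootstrap MSE comparison (lb^2) from a tidy errors table.

    Returns None when no subject has observations under both models at the
    requested week.
    """
    a_name, b_name = ModelId(model_a).value, ModelId(model_b).value
    at_week = errors[errors.week == week]
    pivots = {}
    for name in (a_name, b_name):
        sub = at_week[at_week.model == name].set_index("subject_id")
        pivots[name] = (sub.observed_kg - sub.expected_kg) / KG_PER_LB
    common = pivots[a_name].index.intersection(pivots[b_name].index)
    if len(common) == 0:
        return None
    return compare_models_mse(
        pivots[a_name].loc[common].to_numpy(),
        pivots[b_name].loc[common].to_numpy(),
        label_a=a_name,
        label_b=b_name,
        level=level,
        n_resamples=n_resamples,
        seed=seed,
    )
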