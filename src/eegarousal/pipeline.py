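"""End-to-end orchestration: simulate -> preprocess -> stage -> score ->
analyze, with one master seed fanning out to per-participant child
seeds (via ``numpy.random.SeedSequence.spawn``) so every subject is
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preproc import (
    ArtifactParams,
    GraphoelementParams,
    detect_graphoelements,
    mark_artifacts,
    preprocess,
    segment,
    write_eeg,
)
from .stability import (
    HYPERAROUSED,
    ScoringRules,
    StabilityResult,
    arousal_stability_score,
)
from .staging import ClassifierThresholds, classify_recording
from .stages import STAGE_B1, STAGE_B23, STAGE_C, StageSequence
from .stats import (
    chi_square_2x2,
    ids_severity_band,
    levene_test,
    mann_whitney,
    one_way_anova,
    roc_auc,
    screening_metrics,
    two_way_anova,
)
from .synthetic import (
    CohortParams,
    SynthesisConfig,
    generate_cohort,
    generate_stage_script,
    synthesize_eeg,
)

log = logging.getLogger("eegarousal")


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 42
    output_dir: Path = Path("pipeline_out")
    cohort: CohortParams = field(default_factory=CohortParams)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    rules: ScoringRules = field(default_factory=ScoringRules)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    graphoelements: GraphoelementParams = field(default_factory=GraphoelementParams)
    write_eeg_files: bool = False
    eeg_format: str = "edf"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "cohort", "synthesis", "thresholds", "rules", "artifacts",
                "graphoelements",
            ):
                sub_cls = {
                    "cohort": CohortParams,
                    "synthesis": SynthesisConfig,
                    "thresholds": ClassifierThresholds,
                    "rules": ScoringRules,
                    "artifacts": ArtifactParams,
                    "graphoelements": GraphoelementParams,
                }[f.name]
                if "channel_names" in value:
                    value["channel_names"] = tuple(value["channel_names"])
                for key in ("sem_band", "sigma_band", "lf_band"):
                    if key in value:
                        value[key] = tuple(value[key])
                kwargs[f.name] = sub_cls(**value)
            elif f.name == "output_dir":
                kwargs[f.name] = Path(value)
            else:
                kwargs[f.name] = value
        return cls(**kwargs)


def _declining_params(rng: np.random.Generator) -> dict:
    """Random emergence minutes for a non-hyperaroused trajectory."""
    params: dict = {STAGE_B1: int(rng.integers(1, 13))}
    if rng.random() < 0.5:
        params[STAGE_B23] = int(rng.integers(params[STAGE_B1], 21))
    if rng.random() < 0.3:
        last = params.get(STAGE_B23, params[STAGE_B1])
        params[STAGE_C] = int(rng.integers(last, 21))
    return params


def process_participant(
    participant_id: str,
    group_truth: str,
    child_seed: np.random.SeedSequence,
    config: PipelineConfig,
    out_dir: Path,
) -> StabilityResult:
    """Simulate, stage and score one participant; writes stages + score."""
    rng = np.random.default_rng(child_seed)
    script_seed, eeg_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    stage_name = "simulate-script"
    try:
        if group_truth == HYPERAROUSED:
            script = generate_stage_script("hyperaroused", seed=script_seed)
        else:
            script = generate_stage_script(
                "declining", _declining_params(rng), seed=script_seed
            )
        stage_name = "simulate-eeg"
        rec = synthesize_eeg(script, config.synthesis, seed=eeg_seed)
        if config.write_eeg_files:
            suffix = ".edf" if config.eeg_format == "edf" else ".vhdr"
            write_eeg(rec, out_dir / f"{participant_id}{suffix}")
        stage_name = "preprocess"
        rec = preprocess(rec)
        stage_name = "stage"
        grid = segment(rec)
        grid = mark_artifacts(grid, config.artifacts)
        grid = detect_graphoelements(grid, config.graphoelements)
        seq = classify_recording(grid, config.thresholds)
        seq.to_tsv(out_dir / f"{participant_id}_stages.tsv")
        stage_name = "score"
        result = arousal_stability_score(seq, config.rules)
        result.to_json(out_dir / f"{participant_id}_score.json")
        return result
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage_name!r} failed for participant "
            f"{participant_id}: {exc}"
        ) from exc


def analyze_cohort(table: pd.DataFrame, rules: ScoringRules | None = None) -> dict:
    """Run the statistics layer on a scored participant table.

    Expects columns ``ids_sr_sum``, ``gender``, ``psqi_total``,
    ``ess_total``, ``score`` and the scored ``arousal_group``.
    """
    rules = rules or ScoringRules()
    if table.empty:
        raise ValueError("cannot analyze an empty participant table")
    required = ["ids_sr_sum", "gender", "psqi_total", "ess_total", "score", "arousal_group"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"participant table lacks columns: {missing}")

    hyper = table["arousal_group"] == HYPERAROUSED
    report: dict = {
        "n_total": int(len(table)),
        "n_hyper": int(hyper.sum()),
        "n_nonhyper": int((~hyper).sum()),
        "pct_above_cutoff": round(100.0 * hyper.sum() / len(table), 1),
    }

    ids = table["ids_sr_sum"].to_numpy(float)
    groups = table["arousal_group"].to_numpy()
    if report["n_hyper"] >= 2 and report["n_nonhyper"] >= 2:
        res = one_way_anova(ids, groups)
        report["anova_ids"] = dataclasses.asdict(res)
        report["anova_ids"]["p_one_tailed"] = res.p / 2.0  # main hypothesis
        lev_stat, lev_p = levene_test(ids, groups)
        report["levene_ids"] = {"statistic": lev_stat, "p": lev_p}
        try:
            report["two_way_anova_ids"] = {
                effect: dataclasses.asdict(r)
                for effect, r in two_way_anova(
                    ids, groups, table["gender"].to_numpy()
                ).items()
            }
        except ValueError as exc:
            report["two_way_anova_ids"] = {"error": str(exc)}

        counts = [
            [
                int((hyper & (table["gender"] == "f")).sum()),
                int((hyper & (table["gender"] == "m")).sum()),
            ],
            [
                int((~hyper & (table["gender"] == "f")).sum()),
                int((~hyper & (table["gender"] == "m")).sum()),
            ],
        ]
        try:
            chi2, df, p = chi_square_2x2(counts)
            report["chi2_gender"] = {
                "table": counts, "statistic": chi2, "df": df, "p": p,
            }
        except ValueError as exc:
            report["chi2_gender"] = {"table": counts, "error": str(exc)}

        # exploratory two-tailed item-style comparisons
        for column in ("psqi_total", "ess_total"):
            x = table.loc[hyper, column].to_numpy(float)
            y = table.loc[~hyper, column].to_numpy(float)
            U, Z, p = mann_whitney(x, y)
            report[f"mwu_{column}"] = {"U": U, "Z": Z, "p": p}

    condition = table["ids_sr_sum"].map(
        lambda v: ids_severity_band(int(v)) in ("moderate", "severe")
    ).to_numpy()
    if condition.any() and not condition.all():
        sm_ = screening_metrics(hyper.to_numpy(), condition)
        report["screening"] = dataclasses.asdict(sm_)
        report["roc_auc_graded"] = roc_auc(table["score"].to_numpy(float), condition)
    else:
        report["screening"] = {
            "error": "no moderate-to-severe cases (or no non-cases) in cohort"
        }
    return report


_DESCRIPTIVE_ROWS = (
    "n", "female_n", "male_n", "dx_cancer_n", "dx_neuroinflammatory_autoimmune_n",
    "mfi_median", "ids_mean", "ids_sd", "ids_min", "ids_max",
    "psqi_mean", "psqi_sd", "ess_mean", "ess_sd",
    "score_median", "score_min", "score_max",
    "depression_none_n", "depression_mild_n", "depression_moderate_severe_n",
)


def _descriptives(sub: pd.DataFrame) -> dict[str, float]:
    bands = sub["ids_sr_sum"].map(lambda v: ids_severity_band(int(v)))
    return {
        "n": len(sub),
        "female_n": int((sub["gender"] == "f").sum()),
        "male_n": int((sub["gender"] == "m").sum()),
        "dx_cancer_n": int((sub["dx_class"] == "cancer").sum()),
        "dx_neuroinflammatory_autoimmune_n": int(
            (sub["dx_class"] == "neuroinflammatory_autoimmune").sum()
        ),
        "mfi_median": float(sub["mfi_sum"].median()),
        "ids_mean": float(sub["ids_sr_sum"].mean()),
        "ids_sd": float(sub["ids_sr_sum"].std(ddof=1)) if len(sub) > 1 else 0.0,
        "ids_min": float(sub["ids_sr_sum"].min()),
        "ids_max": float(sub["ids_sr_sum"].max()),
        "psqi_mean": float(sub["psqi_total"].mean()),
        "psqi_sd": float(sub["psqi_total"].std(ddof=1)) if len(sub) > 1 else 0.0,
        "ess_mean": float(sub["ess_total"].mean()),
        "ess_sd": float(sub["ess_total"].std(ddof=1)) if len(sub) > 1 else 0.0,
        "score_median": float(sub["score"].median()),
        "score_min": float(sub["score"].min()),
        "score_max": float(sub["score"].max()),
        "depression_none_n": int((bands == "none").sum()),
        "depression_mild_n": int((bands == "mild").sum()),
        "depression_moderate_severe_n": int(bands.isin(["moderate", "severe"]).sum()),
    }


def make_report(
    table: pd.DataFrame, analysis: dict, out_dir: Path
) -> dict[str, Path]:
    """Write the human-readable summary: descriptives TSV, JSON, figure."""
    if table.empty:
        raise ValueError("cannot report on empty results")
    missing = [
        c
        for c in (
            "arousal_group", "gender", "dx_class", "mfi_sum", "ids_sr_sum",
            "psqi_total", "ess_total", "score",
        )
        if c not in table.columns
    ]
    if missing:
        raise ValueError(f"results table lacks fields: {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups = [HYPERAROUSED, "non_hyperaroused"]
    columns = {g: _descriptives(table[table["arousal_group"] == g]) for g in groups}
    columns["all"] = _descriptives(table)
    lines = ["descriptive\t" + "\t".join(groups + ["all"])]
    for row in _DESCRIPTIVE_ROWS:
        cells = [f"{columns[g][row]:g}" for g in groups + ["all"]]
        lines.append(row + "\t" + "\t".join(cells))
    tsv_path = out_dir / "descriptives.tsv"
    tsv_path.write_text("\n".join(lines) + "\n")

    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(analysis, indent=2, sort_keys=True) + "\n")

    fig_path = out_dir / "group_means.png"
    _group_means_figure(table, fig_path)
    return {"descriptives": tsv_path, "report": json_path, "figure": fig_path}


def _group_means_figure(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    means, sds, labels = [], [], []
    for group in (HYPERAROUSED, "non_hyperaroused"):
        sub = table.loc[table["arousal_group"] == group, "ids_sr_sum"]
        if len(sub):
            means.append(sub.mean())
            sds.append(sub.std(ddof=1) if len(sub) > 1 else 0.0)
            labels.append(group.replace("_", "-"))
    ax.bar(labels, means, yerr=sds, capsize=4, color=["#c44e52", "#4c72b0"][: len(means)])
    ax.set_ylabel("IDS-SR sum-score")
    ax.set_title("Depression score by arousal group")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic study; returns the analysis report dict.

    Writes, under ``config.output_dir``: the cohort CSV, per-participant
    stage TSVs and score JSONs, the merged participant table, the
    descriptives TSV, the analysis JSON and a group-means figure.
    Identical seeds yield identical reports.
    """
    config = config or PipelineConfig()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(config.seed)
    cohort_seed, *_ = master.spawn(1)
    cohort = dataclasses.replace(
        config.cohort, seed=int(np.random.default_rng(cohort_seed).integers(2**31 - 1))
    )
    table = generate_cohort(cohort)
    table.to_csv(out_dir / "cohort.csv", index=False)
    if table.empty:
        raise ValueError("empty cohort: nothing to analyze")

    children = master.spawn(len(table) + 1)[1:]
    scores, scored_groups = [], []
    for (idx, row), child in zip(table.iterrows(), children):
        log.info("processing participant %s (%s)", row["id"], row["group"])
        result = process_participant(
            row["id"], row["group"], child, config, out_dir
        )
        scores.append(result.score)
        scored_groups.append(result.group)
    table = table.assign(score=scores, arousal_group=scored_groups)
    table.to_csv(out_dir / "participants_scored.csv", index=False)

    analysis = analyze_cohort(table, config.rules)
    make_report(table, analysis, out_dir)
    return analysis
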