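"""End-to-end orchestration: tables in, single report bundle out."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contexts, individuals, lca, reliability, repertoire
from .io import validate_dataset
from .vocab import ModifierVocabulary, default_vocabulary


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis in one place."""

    min_tokens: int = repertoire.DEFAULT_MIN_TOKENS
    action_min: int = lca.DEFAULT_ACTION_MIN
    morph_min: int = lca.DEFAULT_MORPH_MIN
    k_max: int = lca.DEFAULT_K_MAX
    n_restarts: int = lca.DEFAULT_RESTARTS
    regular_use_target: float = repertoire.DEFAULT_REGULAR_USE_TARGET
    reliability_fraction: float = reliability.DEFAULT_FRACTION
    n_permutations: int = 0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineReport:
    config: PipelineConfig
    stage_sizes: dict[str, int]
    contribution_table: pd.DataFrame
    average_contribution: float
    regular_use: list[str]
    accumulation: repertoire.AccumulationCurve
    exclusion: lca.ExclusionReport
    morph_repertoire: lca.MorphRepertoire
    morph_stats: dict
    action_results: list[lca.ActionResult]
    individual_summaries: pd.DataFrame
    class_summary: pd.DataFrame
    context_distribution: contexts.ContextDistribution
    overall_rate: float
    reliability_table: pd.DataFrame | None = None
    new_action_summary: repertoire.FlagSummary | None = None
    threshold_report: repertoire.ThresholdReport | None = None

    def summary_dict(self) -> dict:
        morphs = [
            {
                "morph_id": m.morph_id,
                "gesture_action": m.gesture_action,
                "token_count": m.token_count,
                "modal_configuration": m.modal_configuration,
            }
            for result in self.action_results
            for m in result.morphs
        ]
        out = {
            "config": asdict(self.config),
            "stage_sizes": self.stage_sizes,
            "average_contribution": self.average_contribution,
            "regular_use": self.regular_use,
            "regular_use_size": len(self.regular_use),
            "overall_rate_per_hour": self.overall_rate,
            "accumulation": {
                "last_novelty_index": self.accumulation.last_novelty_index,
                "last_novelty_fraction": self.accumulation.last_novelty_fraction,
            },
            "morph_stats": self.morph_stats,
            "morphs": morphs,
            "unimorphic": self.morph_repertoire.unimorphic,
            "polymorphic": {
                a: [m.morph_id for m in ms]
                for a, ms in self.morph_repertoire.polymorphic.items()
            },
            "unspecified": self.morph_repertoire.unspecified,
            "context_distribution": self.context_distribution.pooled.to_dict("records"),
        }
        if self.new_action_summary is not None:
            out["new_action_summary"] = {
                "n_actions": self.new_action_summary.n_actions,
                "n_new": self.new_action_summary.n_new,
                "shared_pct": self.new_action_summary.shared_pct,
                "new_token_pct": self.new_action_summary.new_token_pct,
            }
        if self.reliability_table is not None:
            out["reliability"] = self.reliability_table.to_dict("records")
        return out

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(
    tokens: pd.DataFrame,
    individuals_table: pd.DataFrame,
    effort: pd.DataFrame,
    config: PipelineConfig | None = None,
    vocab: ModifierVocabulary | None = None,
    rater2: pd.DataFrame | None = None,
    reliability_variables: tuple[str, ...] = ("gesture_action",),
    new_actions: frozenset[str] | set[str] | None = None,
) -> PipelineReport:
    """Execute the full analysis; any stage failure aborts with a
    stage-tagged error."""
    config = config or PipelineConfig()
    vocab = vocab or default_vocabulary()

    if len(tokens) == 0:
        raise PipelineError("validation", "empty token table")
    report = validate_dataset(tokens, individuals_table, effort)
    if not report.ok:
        raise PipelineError(
            "validation", f"{len(report.failures)} cross-reference failure(s)"
        )

    try:
        kept, kept_actions, threshold_report = repertoire.apply_repertoire_threshold(
            tokens, min_tokens=config.min_tokens
        )
        table, average = repertoire.build_contribution_table(kept)
        regular = repertoire.regular_use_set(table, config.regular_use_target)
        curve = repertoire.accumulation_curve(
            kept, "action", n_permutations=config.n_permutations, seed=config.seed
        )
        rate = repertoire.overall_rate(tokens, effort)
    except ValueError as exc:
        raise PipelineError("action_repertoire", str(exc)) from exc

    try:
        results, exclusion, morph_rep, morph_stats = lca.analyze_actions(
            kept,
            vocab,
            action_min=config.action_min,
            morph_min=config.morph_min,
            k_max=config.k_max,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
    except ValueError as exc:
        raise PipelineError("morph_lca", str(exc)) from exc

    try:
        assignments = individuals.assign_maturation_classes(individuals_table, effort)
        summaries = individuals.individual_summaries(tokens, effort)
        class_summary = individuals.summarize_by_class(tokens, assignments, effort)
    except ValueError as exc:
        raise PipelineError("individual_stats", str(exc)) from exc

    try:
        context_dist = contexts.context_distribution(tokens)
    except ValueError as exc:
        raise PipelineError("context_stats", str(exc)) from exc

    reliability_table = None
    if rater2 is not None:
        try:
            joined = tokens.merge(rater2, on="token_id", suffixes=("", "_r2"))
            rows = []
            for variable in reliability_variables:
                result = reliability.agreement_stats(
                    joined[variable], joined[f"{variable}_r2"], variable
                )
                rows.append(
                    {
                        "variable": result.variable,
                        "n_items": result.n_items,
                        "percentage_agreement": result.percentage_agreement,
                        "kappa": result.kappa,
                    }
                )
            reliability_table = pd.DataFrame(rows)
        except (KeyError, ValueError) as exc:
            raise PipelineError("reliability", str(exc)) from exc

    flag = (
        repertoire.flag_summary(table, new_actions) if new_actions is not None else None
    )
    stage_sizes = {
        "n_tokens": len(tokens),
        "n_repertoire_tokens": len(kept),
        "n_repertoire_actions": len(kept_actions),
        "n_lca_tokens": exclusion.n_analyzed,
        "n_lca_actions": len(results),
    }
    return PipelineReport(
        config=config,
        stage_sizes=stage_sizes,
        contribution_table=table,
        average_contribution=average,
        regular_use=regular,
        accumulation=curve,
        exclusion=exclusion,
        morph_repertoire=morph_rep,
        morph_stats=morph_stats,
        action_results=results,
        individual_summaries=summaries,
        class_summary=class_summary,
        context_distribution=context_dist,
        overall_rate=rate,
        reliability_table=reliability_table,
        new_action_summary=flag,
        threshold_report=threshold_report,
    )


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    """Serialise the report bundle: one JSON summary plus CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    report.contribution_table.to_csv(outdir / "contribution_table.csv", index=False)
    report.accumulation.to_frame().to_csv(outdir / "accumulation_curve.csv", index=False)
    report.individual_summaries.to_csv(outdir / "individual_summaries.csv")
    report.class_summary.to_csv(outdir / "class_summary.csv", index=False)
    report.context_distribution.pooled.to_csv(outdir / "context_distribution.csv", index=False)
    morph_rows = [
        {
            "morph_id": m.morph_id,
            "gesture_action": m.gesture_action,
            "token_count": m.token_count,
            **{f"modal_{k}": v for k, v in m.modal_configuration.items()},
        }
        for result in report.action_results
        for m in result.morphs
    ]
    pd.DataFrame(morph_rows).to_csv(outdir / "morph_inventory.csv", index=False)
    model_rows = []
    for result in report.action_results:
        model = result.model
        model_rows.append(
            {
                "gesture_action": model.gesture_action,
                "k": model.k,
                "n_obs": model.n_obs,
                "log_likelihood": model.log_likelihood,
                "bic": model.bic,
                "class_weights": ";".join(f"{w:.6f}" for w in model.class_weights),
            }
        )
    pd.DataFrame(model_rows).to_csv(outdir / "lca_models.csv", index=False)
    if report.reliability_table is not None:
        report.reliability_table.to_csv(outdir / "reliability.csv", index=False)
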